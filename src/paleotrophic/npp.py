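"""Productivity time-series comparison and stadial/interstadial statistics.

The dissimilarity between two net-primary-productivity (NPP) trajectories
combines the proximity of their raw values (Euclidean distance) with their
temporal correlation CORT — the correlation of first differences — through an
adaptive exponential tuning function f(x) = 2 / (1 + exp(k x)).  With the
default k = 2 the temporal-behaviour component contributes 76% of the
dissimilarity and value proximity 24%.  Series are grouped by agglomerative
hierarchical clustering on the resulting dCORT matrix, and productivity is
stratified into Greenland stadial (GS) and interstadial (GI) phases for
summary statistics and a Wilcoxon rank-sum comparison.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

#: canonical NPP unit; Table-style outputs may declare kg km-2 instead
G_M2_PER_KG_KM2 = 1.0 / 1000.0  # 1 g m-2 = 1000 kg km-2


class NPPError(ValueError):
    pass


class AlignmentError(NPPError):
    pass


@dataclass
class NPPSeries:
    """One site's NPP trajectory on a strictly ordered kyr BP time grid."""

    site_id: str
    region: str
    times: np.ndarray
    values: np.ndarray
    unit: str = "g m-2 yr-1"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise NPPError("times and values length mismatch")
        if len(self.times) < 2:
            raise NPPError("series needs at least 2 points")
        d = np.diff(self.times)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise NPPError("times must be strictly ordered")
        if np.any(~np.isfinite(self.values)):
            raise NPPError("missing values not allowed after ingestion")
        if np.any(self.values < 0):
            raise NPPError("NPP must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Phase:
    name: str
    kind: str  # "stadial" | "interstadial"
    start: float  # kyr BP, older edge
    end: float  # kyr BP, younger edge

    def __post_init__(self):
        if self.kind not in ("stadial", "interstadial"):
            raise NPPError(f"unknown phase kind {self.kind!r}")
        if not self.start > self.end:
            raise NPPError(f"{self.name}: start must exceed end in kyr BP")

    def contains(self, t: float) -> bool:
        # half-open on the younger edge so adjacent phases partition time
        return self.end < t <= self.start


@dataclass
class PhaseTable:
    """Ordered, non-overlapping GS/GI phases with alternating kinds."""

    phases: list[Phase]

    def __post_init__(self):
        ordered = sorted(self.phases, key=lambda p: -p.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start > a.end + 1e-9:
                raise NPPError(f"phases {a.name} and {b.name} overlap")
            if a.kind == b.kind:
                raise NPPError("phase kinds must alternate")
        self.phases = ordered

    def classify(self, t: float) -> Phase | None:
        for p in self.phases:
            if p.contains(t):
                return p
        return None

    def by_name(self, name: str) -> Phase:
        for p in self.phases:
            if p.name == name:
                return p
        raise NPPError(f"no phase named {name!r}")

    @classmethod
    def from_b2k(cls, rows: Iterable[tuple[str, str, float, float]],
                 offset_kyr: float = 0.05) -> "PhaseTable":
        """Build from (name, kind, start, end) in kyr b2k (before AD 2000);
        converted to BP (before 1950) by subtracting ``offset_kyr``."""
        return cls([Phase(n, k, s - offset_kyr, e - offset_kyr)
                    for n, k, s, e in rows])


# Approximate Greenland event stratigraphy for late MIS 3 (kyr b2k), used as a
# user-replaceable default; supply a CSV for any other chronology.
_DEFAULT_GS_GI_B2K: list[tuple[str, str, float, float]] = [
    ("GI-14", "interstadial", 54.22, 49.60),
    ("GS-14", "stadial", 49.60, 49.28),
    ("GI-13", "interstadial", 49.28, 48.34),
    ("GS-13", "stadial", 48.34, 46.86),
    ("GI-12", "interstadial", 46.86, 44.28),
    ("GS-12", "stadial", 44.28, 43.34),
    ("GI-11", "interstadial", 43.34, 42.24),
    ("GS-11", "stadial", 42.24, 41.46),
    ("GI-10", "interstadial", 41.46, 40.80),
    ("GS-10", "stadial", 40.80, 40.16),
    ("GI-9", "interstadial", 40.16, 39.90),
    ("GS-9", "stadial", 39.90, 38.22),
    ("GI-8", "interstadial", 38.22, 36.58),
    ("GS-8", "stadial", 36.58, 35.48),
    ("GI-7", "interstadial", 35.48, 34.74),
    ("GS-7", "stadial", 34.74, 33.84),
    ("GI-6", "interstadial", 33.84, 33.36),
    ("GS-6", "stadial", 33.36, 32.52),
    ("GI-5", "interstadial", 32.52, 32.04),
    ("GS-5", "stadial", 32.04, 30.60),
]


def default_phase_table() -> PhaseTable:
    return PhaseTable.from_b2k(_DEFAULT_GS_GI_B2K)


@dataclass
class RegionSpecies:
    region: str
    species: frozenset[str]

    def __post_init__(self):
        self.species = frozenset(self.species)
        if not self.species:
            raise NPPError("species set must be non-empty")


# ---------------------------------------------------------------------------
# dissimilarity
# ---------------------------------------------------------------------------

def _aligned(s1: NPPSeries, s2: NPPSeries) -> None:
    if len(s1) != len(s2) or not np.allclose(s1.times, s2.times):
        raise AlignmentError(
            f"series {s1.site_id} and {s2.site_id} are not on the same time "
            "grid; resample explicitly before comparing")


def cort(s1: NPPSeries, s2: NPPSeries) -> float:
    """Temporal correlation of two series: correlation of first differences.

    Bounded in [-1, 1]; +1 means the series rise and fall at the same rate in
    every interval, -1 anti-phase, 0 independent trends.  A constant series
    yields a zero denominator and returns 0 with a warning.
    """
    _aligned(s1, s2)
    du = np.diff(s1.values)
    dv = np.diff(s2.values)
    den = np.sqrt(np.sum(du ** 2)) * np.sqrt(np.sum(dv ** 2))
    if den == 0:
        warnings.warn("degenerate (constant) series in CORT; returning 0",
                      UserWarning)
        return 0.0
    return float(np.clip(np.sum(du * dv) / den, -1.0, 1.0))


def tuning(x: float | np.ndarray, k: float = 2.0) -> float | np.ndarray:
    """Adaptive tuning function f(x) = 2 / (1 + exp(k x)), k >= 0."""
    if k < 0:
        raise NPPError("tuning constant k must be >= 0")
    return 2.0 / (1.0 + np.exp(k * np.asarray(x, dtype=float)))


def behaviour_contribution_percent(k: float = 2.0) -> float:
    """Percent reduction of the raw distance at maximal temporal correlation,
    (1 - f(1)) * 100 — the share of the dissimilarity carried by temporal
    behaviour rather than value proximity."""
    return float((1.0 - tuning(1.0, k)) * 100.0)


def dcort(s1: NPPSeries, s2: NPPSeries, k: float = 2.0) -> float:
    """Behaviour-weighted dissimilarity f(CORT) * Euclidean distance."""
    _aligned(s1, s2)
    d = float(np.linalg.norm(s1.values - s2.values))
    if d == 0.0:
        return 0.0
    return float(tuning(cort(s1, s2), k)) * d


def dissimilarity_matrix(series: Sequence[NPPSeries],
                         k: float = 2.0) -> np.ndarray:
    """Square symmetric dCORT matrix with a zero diagonal."""
    n = len(series)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dcort(series[i], series[j], k)
    return D


def cluster_series(matrix: np.ndarray, n_clusters: int = 3,
                   linkage: str = "average",
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering of the dissimilarity matrix.

    Returns (labels, scipy linkage matrix); labels are 1..n_clusters and the
    result is deterministic given the matrix.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n_clusters > n:
        raise NPPError(f"n_clusters={n_clusters} exceeds {n} series")
    Z = hierarchy.linkage(squareform(matrix, checks=False), method=linkage)
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return labels, Z


def cluster_region_composition(assignments: Sequence[int],
                               regions: Sequence[str]) -> pd.DataFrame:
    """Row-normalised contingency (percent of each region's sites per cluster)."""
    if len(assignments) != len(regions):
        raise NPPError("label vectors must have equal length")
    tab = pd.crosstab(pd.Series(regions, name="region"),
                      pd.Series(assignments, name="cluster"))
    return tab.div(tab.sum(axis=1), axis=0) * 100.0


def jsi(a_set: RegionSpecies, b_set: RegionSpecies) -> float:
    """Jaccard similarity: shared species over total distinct species."""
    a, b = a_set.species, b_set.species
    union = a | b
    if not union:
        raise NPPError("JSI undefined for two empty sets")
    return len(a & b) / len(union)


# ---------------------------------------------------------------------------
# phase statistics
# ---------------------------------------------------------------------------

def phase_stats(series: NPPSeries | Sequence[NPPSeries],
                phases: PhaseTable) -> dict:
    """Stadial/interstadial summary and Wilcoxon rank-sum comparison.

    Pools the values of one or several aligned series, classifies every time
    point into a phase kind, and reports mean, standard deviation and the
    coefficient of variation (100 * sd / mean) per kind, plus the two-sided
    rank-sum statistic W and p for stadial vs interstadial values.
    Unclassifiable time points are excluded and listed.
    """
    if isinstance(series, NPPSeries):
        series = [series]
    vals = {"stadial": [], "interstadial": []}
    unclassified = []
    for s in series:
        for t, v in zip(s.times, s.values):
            ph = phases.classify(t)
            if ph is None:
                unclassified.append((s.site_id, float(t)))
            else:
                vals[ph.kind].append(v)
    if unclassified:
        warnings.warn(f"{len(unclassified)} time points fall outside the "
                      "phase table and were excluded", UserWarning)
    out = {"unclassified": unclassified}
    for kind, v in vals.items():
        v = np.asarray(v, dtype=float)
        mean = float(v.mean()) if len(v) else np.nan
        sd = float(v.std(ddof=1)) if len(v) > 1 else np.nan
        cv = 100.0 * sd / mean if len(v) > 1 and mean != 0 else np.nan
        out[kind] = {"n": len(v), "mean": mean, "sd": sd, "cv_percent": cv}
    st, it = map(np.asarray, (vals["stadial"], vals["interstadial"]))
    if len(st) >= 2 and len(it) >= 2:
        if np.ptp(np.concatenate([st, it])) == 0:
            out["wilcoxon"] = {"W": len(st) * len(it) / 2.0, "p": 1.0,
                               "degenerate": True}
        else:
            res = stats.mannwhitneyu(st, it, alternative="two-sided")
            out["wilcoxon"] = {"W": float(res.statistic),
                               "p": float(res.pvalue), "degenerate": False}
    else:
        out["wilcoxon"] = {"W": np.nan, "p": np.nan, "degenerate": True}
    return out


def percent_change(series: NPPSeries | Sequence[NPPSeries],
                   phases: PhaseTable,
                   phase_from: str, phase_to: str) -> float:
    """Signed percent change of mean NPP between two named phases."""
    if isinstance(series, NPPSeries):
        series = [series]
    means = {}
    for name in (phase_from, phase_to):
        ph = phases.by_name(name)
        v = np.concatenate([s.values[(s.times > ph.end) & (s.times <= ph.start)]
                            for s in series])
        if len(v) == 0:
            raise NPPError(f"phase {name!r} contains no data")
        means[name] = v.mean()
    if means[phase_from] == 0:
        raise NPPError("percent change undefined for zero baseline mean")
    return float(100.0 * (means[phase_to] - means[phase_from])
                 / means[phase_from])
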
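"""Herbivore carrying capacity from net primary productivity.

The macroecological model has two stages.  First, total herbivore biomass
(THB) sustainable by an ecosystem follows a log-log law fitted robustly to
modern density compilations::

    log10(THB) = slope * log10(NPP) + intercept

with reference coefficients slope = 1.401 and intercept = -0.642 (THB and NPP
in g m-2 yr-1).  Second, the THB is partitioned over the species of a
community by Damuth's allometry D_i = c * W_i^(-3/4) (density in ind km-2, W
in kg), where the constant c = THB / sum(W_i^(1/4)) guarantees the partition
closes exactly: sum(D_i * W_i) = THB.

Palaeocommunities are assembled by the minimum-census rule (a species belongs
to every stadial/interstadial phase its regional chronological range overlaps)
and their completeness is assessed by incidence-based rarefaction and
extrapolation of species richness.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .npp import PhaseTable

#: unit conversion for declared units; nothing converts silently
KG_KM2_PER_G_M2 = 1000.0

SIZE_CLASSES = ("small", "medium", "medium_large", "large")


class CarryingCapacityError(ValueError):
    pass


def size_class(mass_kg: float) -> str:
    """Weight category under the half-open convention [10,100), [100,500)."""
    if mass_kg < 10:
        return "small"
    if mass_kg < 100:
        return "medium"
    if mass_kg < 500:
        return "medium_large"
    return "large"


@dataclass
class SpeciesMass:
    taxon: str
    W: float  # mean adult body mass of both sexes, kg

    def __post_init__(self):
        if self.W <= 0:
            raise CarryingCapacityError(f"{self.taxon}: mass must be positive")

    @property
    def size_class(self) -> str:
        return size_class(self.W)


@dataclass
class AllometryModel:
    """THB-NPP regression coefficients plus the mass-scaling exponent."""

    slope: float = 1.401
    intercept: float = -0.642
    scaling_exponent: float = -0.75
    thb_unit: str = "g m-2"
    npp_unit: str = "g m-2 yr-1"
    cov: np.ndarray | None = None  # 2x2 covariance of (intercept, slope)
    resid_scale: float | None = None
    slope_ci: tuple[float, float] | None = None
    intercept_ci: tuple[float, float] | None = None
    n_fit: int | None = None

    def __post_init__(self):
        if self.scaling_exponent >= 0:
            raise CarryingCapacityError("scaling exponent must be negative")


@dataclass
class BiomassResult:
    THB: float
    c: float
    species: list[SpeciesMass]
    D: dict[str, float]  # taxon -> ind km-2 (unit scale of THB/W)
    B: dict[str, float]  # taxon -> biomass per area
    size_class_totals: dict[str, float]


@dataclass
class ModernSiteRecord:
    site: str
    npp: float
    species: list[SpeciesMass]
    observed_density: dict[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.observed_density.values()):
            raise CarryingCapacityError(f"{self.site}: negative density")


@dataclass
class Palaeocommunity:
    region: str
    phase: str
    species: list[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.species)) != len(self.species):
            raise CarryingCapacityError("duplicate taxa in palaeocommunity")


# ---------------------------------------------------------------------------
# THB-NPP regression
# ---------------------------------------------------------------------------

def fit_thb_model(npp: Sequence[float], thb: Sequence[float],
                  method: str = "robust_mm") -> AllometryModel:
    """Robust log-log fit of total herbivore biomass on NPP.

    Uses a two-stage robust linear estimator (Huber M-estimate for starting
    values, then redescending Tukey biweight) on log10-transformed data;
    ``method="ols"`` selects plain least squares.  Exactly collinear or very
    small datasets fall back to least squares.
    """
    npp = np.asarray(npp, dtype=float)
    thb = np.asarray(thb, dtype=float)
    bad = np.nonzero((npp <= 0) | (thb <= 0))[0]
    if len(bad):
        raise CarryingCapacityError(
            f"non-positive NPP/THB at records {bad.tolist()}")
    if len(npp) < 2:
        raise CarryingCapacityError("need at least 2 sites")
    x = np.log10(npp)
    y = np.log10(thb)
    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()
    perfect = float(np.max(np.abs(ols.resid))) < 1e-12
    if method == "ols" or perfect or len(npp) < 4:
        params, cov = ols.params, np.asarray(ols.cov_params())
        scale = float(np.sqrt(ols.scale)) if len(npp) > 2 else 0.0
        if perfect:
            cov = np.zeros((2, 2))
            scale = 0.0
    elif method == "robust_mm":
        huber = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit()
        fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight()).fit(
            start_params=huber.params)
        params, cov = fit.params, np.asarray(fit.bcov_scaled)
        scale = float(fit.scale)
    else:
        raise CarryingCapacityError(f"unknown method {method!r}")
    intercept, slope = float(params[0]), float(params[1])
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(0.975)
    return AllometryModel(
        slope=slope, intercept=intercept, cov=cov, resid_scale=scale,
        slope_ci=(slope - z * se[1], slope + z * se[1]),
        intercept_ci=(intercept - z * se[0], intercept + z * se[0]),
        n_fit=len(npp))


def predict_thb(npp: float, model: AllometryModel,
                with_ci: bool = False):
    """THB = 10^(slope * log10(NPP) + intercept), in the model's units.

    With ``with_ci`` and a fitted model, also returns the 95% prediction
    interval derived from the parameter covariance and residual scale.
    """
    if np.any(np.asarray(npp) <= 0):
        raise CarryingCapacityError("NPP must be positive")
    logx = np.log10(npp)
    logy = model.slope * logx + model.intercept
    point = float(10.0 ** logy)
    if not with_ci:
        return point
    if model.cov is None:
        raise CarryingCapacityError("model carries no covariance")
    x0 = np.array([1.0, logx])
    var = float(x0 @ model.cov @ x0) + float(model.resid_scale or 0.0) ** 2
    half = stats.norm.ppf(0.975) * math.sqrt(max(var, 0.0))
    return point, (float(10.0 ** (logy - half)), float(10.0 ** (logy + half)))


# ---------------------------------------------------------------------------
# Damuth partitioning
# ---------------------------------------------------------------------------

def damuth_constant(THB: float, species: Sequence[SpeciesMass]) -> float:
    """c = THB / sum(W_i^(1/4)), the community-level Damuth constant."""
    if THB < 0:
        raise CarryingCapacityError("THB must be non-negative")
    species = list(species)
    if not species:
        raise CarryingCapacityError("empty species list")
    return THB / sum(s.W ** 0.25 for s in species)


def partition_biomass(THB: float,
                      species: Sequence[SpeciesMass]) -> BiomassResult:
    """Partition THB over a community by Damuth's rule.

    D_i = c * W_i^(-3/4) and B_i = D_i * W_i = c * W_i^(1/4); the partition
    closes exactly (sum B_i = THB) because c absorbs the normalisation.
    """
    species = list(species)
    taxa = [s.taxon for s in species]
    if len(set(taxa)) != len(taxa):
        raise CarryingCapacityError("duplicate taxa would double-count biomass")
    c = damuth_constant(THB, species)
    D = {s.taxon: c * s.W ** -0.75 for s in species}
    B = {s.taxon: D[s.taxon] * s.W for s in species}
    totals = {cls: 0.0 for cls in SIZE_CLASSES}
    for s in species:
        totals[s.size_class] += B[s.taxon]
    return BiomassResult(THB=THB, c=c, species=species, D=D, B=B,
                         size_class_totals=totals)


def size_class_totals(result: BiomassResult) -> dict[str, float]:
    return dict(result.size_class_totals)


@dataclass
class BiomassCI:
    """Point partition plus partitions at the 95% THB band endpoints."""

    point: BiomassResult
    lower: BiomassResult
    upper: BiomassResult


def propagate_ci(model: AllometryModel, npp: float,
                 species: Sequence[SpeciesMass]) -> BiomassCI:
    """Carry the regression's 95% prediction band through the partition.

    Partitioning is linear in THB, so applying it to the interval endpoints
    yields exact intervals for every per-species and per-class quantity.
    """
    if model.cov is None:
        raise CarryingCapacityError("model carries no covariance")
    point, (lo, hi) = predict_thb(npp, model, with_ci=True)
    return BiomassCI(point=partition_biomass(point, species),
                     lower=partition_biomass(lo, species),
                     upper=partition_biomass(hi, species))


# ---------------------------------------------------------------------------
# validation against modern densities
# ---------------------------------------------------------------------------

def validate_model(modern: Sequence[ModernSiteRecord], model: AllometryModel,
                   log_scale: bool = True) -> dict:
    """Correlate observed and model-predicted per-species densities.

    Predictions pair with observations by taxon.  Correlation is computed on
    log10 densities by default (Damuth's relations are log-linear); sites with
    fewer than 3 usable species are skipped and reported.
    """
    per_site = {}
    skipped = []
    pooled_obs, pooled_pred = [], []
    for site in modern:
        thb = predict_thb(site.npp, model)
        res = partition_biomass(thb, site.species)
        pairs = [(site.observed_density[s.taxon], res.D[s.taxon])
                 for s in site.species if s.taxon in site.observed_density]
        if log_scale:
            pairs = [(o, p) for o, p in pairs if o > 0 and p > 0]
        if len(pairs) < 3:
            skipped.append(site.site)
            continue
        obs = np.array([o for o, _ in pairs])
        pred = np.array([p for _, p in pairs])
        if log_scale:
            obs, pred = np.log10(obs), np.log10(pred)
        if np.ptp(obs) == 0 or np.ptp(pred) == 0:
            per_site[site.site] = {"r": np.nan, "p": np.nan, "n": len(pairs)}
        else:
            r, p = stats.pearsonr(obs, pred)
            per_site[site.site] = {"r": float(r), "p": float(p),
                                   "n": len(pairs)}
        pooled_obs.extend(obs)
        pooled_pred.extend(pred)
    pooled = {"r": np.nan, "p": np.nan, "n": len(pooled_obs)}
    if len(pooled_obs) >= 3 and np.ptp(pooled_obs) > 0:
        r, p = stats.pearsonr(pooled_obs, pooled_pred)
        pooled = {"r": float(r), "p": float(p), "n": len(pooled_obs)}
    sig = [v for v in per_site.values()
           if np.isfinite(v["p"]) and v["p"] < 0.05 and v["r"] > 0]
    frac = len(sig) / len(per_site) if per_site else np.nan
    return {"per_site": per_site, "pooled": pooled,
            "fraction_significant": frac, "skipped_sites": skipped}


# ---------------------------------------------------------------------------
# minimum census and rarefaction
# ---------------------------------------------------------------------------

@dataclass
class LFARecord:
    """One local faunal assemblage occurrence of a species with its dated
    95.4% calendar range (cal BP)."""

    lfa_id: str
    species: str
    region: str
    lower: float  # younger bound, cal BP
    upper: float  # older bound, cal BP

    def __post_init__(self):
        if self.upper < self.lower:
            raise CarryingCapacityError(
                f"{self.lfa_id}: upper bound must be the older (larger) age")


def minimum_census(lfas: Sequence[LFARecord], phases: PhaseTable,
                   ) -> dict[tuple[str, str], Palaeocommunity]:
    """Assemble palaeocommunities per region and phase by minimum census.

    A species' regional chronological range spans from the oldest upper bound
    to the youngest lower bound over its LFAs (a single LFA contributes its
    own 95.4% interval); the species is then a member of every phase its range
    overlaps.
    """
    ranges: dict[tuple[str, str], dict] = {}
    for rec in lfas:
        key = (rec.region, rec.species)
        r = ranges.setdefault(key, {"old": -np.inf, "young": np.inf,
                                    "lfas": []})
        r["old"] = max(r["old"], rec.upper)
        r["young"] = min(r["young"], rec.lower)
        r["lfas"].append(rec.lfa_id)
    out: dict[tuple[str, str], Palaeocommunity] = {}
    for phase in phases.phases:
        start_bp = phase.start * 1000.0
        end_bp = phase.end * 1000.0
        for (region, species), r in ranges.items():
            if r["young"] <= start_bp and r["old"] >= end_bp:  # overlap
                key = (region, phase.name)
                pc = out.get(key)
                if pc is None:
                    pc = Palaeocommunity(region=region, phase=phase.name,
                                         species=[], provenance={})
                    out[key] = pc
                pc.species.append(species)
                pc.provenance[species] = sorted(r["lfas"])
    return out


def _interpolated_richness(incidence: np.ndarray, h: int) -> float:
    """Expected richness in h of T LFAs (sample-based hypergeometric form)."""
    T, _ = incidence.shape
    Yk = incidence.sum(axis=0)
    denom = math.comb(T, h)
    miss = sum(math.comb(T - int(y), h) for y in Yk if T - y >= h)
    return float(incidence.shape[1] - miss / denom)


def _extrapolated_richness(incidence: np.ndarray, target: int) -> float:
    """Incidence-based asymptotic (Chao2-type) extrapolation beyond T LFAs."""
    T, S_obs = incidence.shape[0], int((incidence.sum(axis=0) > 0).sum())
    Yk = incidence.sum(axis=0)
    Q1 = int(np.sum(Yk == 1))
    Q2 = int(np.sum(Yk == 2))
    if Q1 == 0:
        return float(S_obs)
    if Q2 > 0:
        Q0 = (T - 1) / T * Q1 ** 2 / (2 * Q2)
    else:
        Q0 = (T - 1) / T * Q1 * (Q1 - 1) / 2
    m = target - T
    if Q0 == 0:
        return float(S_obs)
    return float(S_obs + Q0 * (1 - (1 - Q1 / (Q1 + T * Q0)) ** m))


def expected_richness(incidence: np.ndarray, target: int) -> float:
    """Rarefied (target <= T) or extrapolated (target > T) species richness."""
    incidence = (np.asarray(incidence) > 0).astype(int)
    T = incidence.shape[0]
    if target < 1:
        raise CarryingCapacityError("target sample size must be >= 1")
    if target <= T:
        return _interpolated_richness(incidence, target)
    return _extrapolated_richness(incidence, target)


def rarefy_richness(incidence: np.ndarray, target: int = 100,
                    n_boot: int = 500, seed: int | None = None) -> dict:
    """Observed vs expected species richness at a standardised LFA count.

    ``incidence`` is an LFAs x species presence matrix.  The bootstrap
    resamples LFAs with replacement to give a percentile 95% CI on the
    expected richness at ``target``.
    """
    incidence = (np.asarray(incidence) > 0).astype(int)
    T, S = incidence.shape
    if T < 2 or S < 1:
        raise CarryingCapacityError("need >= 2 LFAs and >= 1 species")
    if target < 1:
        raise CarryingCapacityError("target sample size must be >= 1")
    s_obs = int((incidence.sum(axis=0) > 0).sum())
    est = expected_richness(incidence, target)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        rows = rng.integers(0, T, size=T)
        boots[b] = expected_richness(incidence[rows], target)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {"observed": s_obs, "expected": float(est),
            "ci95": (float(lo), float(hi)), "target": target,
            "n_boot": n_boot}
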
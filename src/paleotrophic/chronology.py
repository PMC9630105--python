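"""Chronometric dating machinery: calibration, date filtering and combination,
summed probability distributions (SPD) and optimal linear estimation (OLE) of
technocomplex start/end boundaries.

Calendar ages are expressed in cal BP (calibrated years before 1950) throughout.
Radiocarbon determinations are calibrated against a piecewise-linear calibration
curve (IntCal20 ``.14c`` dialect, see :mod:`paleotrophic.io`); luminescence and
U-series determinations already live on the calendar axis and bypass the curve.

Boundary estimation follows the Roberts–Solow optimal linear estimator on the
``k`` most extreme calibrated medians: the joint distribution of the extremes is
modelled as Weibull, its shape estimated from the log-spacings of the record,
and the boundary obtained as the optimally weighted sum of the extremes.  Date
uncertainty is propagated by redrawing each sighting from a normal distribution
and repeating the estimate (10,000 iterations by default).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

REGIONS = ("Eurosiberian", "Supramediterranean", "Mesomediterranean",
           "Thermomediterranean")
CULTURES = ("Mousterian", "Chatelperronian", "Aurignacian", "Palaeontological")
METHODS = ("14C", "TL", "OSL", "U-series")

#: inclusive coefficient-of-variation cut-off for SPD/OLE eligibility
CV_THRESHOLD = 0.05

#: quality flags a date (or its level) may carry
FLAG_STRATIGRAPHIC = "stratigraphic_issue"
FLAG_CULTURAL = "cultural_attribution_issue"


class ChronologyError(ValueError):
    """Base class for chronology-domain errors."""


class OutOfCurveRangeError(ChronologyError):
    pass


class InsufficientDataError(ChronologyError):
    pass


class DegenerateRecordError(ChronologyError):
    pass


class MixedMethodError(ChronologyError):
    pass


@dataclass
class RadiocarbonDate:
    """One chronometric determination.

    ``age`` is in radiocarbon years BP for ``method == "14C"`` and in calendar
    years BP otherwise; ``error_1sigma`` is the laboratory 1-sigma error in the
    same units.
    """

    lab_code: str
    site_id: str
    level_id: str
    region: str
    culture: str
    method: str
    age: float
    error_1sigma: float
    material: str = "bone"
    flags: frozenset[str] = frozenset()
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.age <= 0:
            raise ChronologyError(f"{self.lab_code}: age must be positive")
        if self.error_1sigma <= 0:
            raise ChronologyError(f"{self.lab_code}: error must be positive")
        self.flags = frozenset(self.flags)

    @property
    def cv(self) -> float:
        """Coefficient of variation of the determination."""
        return self.error_1sigma / self.age


@dataclass
class CombinedDate(RadiocarbonDate):
    """Inverse-variance weighted combination of same-level 14C dates.

    Carries the chi-square consistency statistic of the combination; a failed
    test (``consistent == False``) is reported but the combination is kept,
    mirroring how same-level determinations are pooled before calibration.
    """

    chi2_stat: float = 0.0
    chi2_df: int = 0
    chi2_p: float = 1.0
    consistent: bool = True
    n_combined: int = 1


@dataclass
class CalibrationCurve:
    """Piecewise-linear calibration curve on a strictly ordered cal BP grid."""

    grid: np.ndarray
    mu14c: np.ndarray
    sigma_curve: np.ndarray
    name: str = "curve"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.mu14c = np.asarray(self.mu14c, dtype=float)
        self.sigma_curve = np.asarray(self.sigma_curve, dtype=float)
        if self.grid.ndim != 1 or len(self.grid) < 2:
            raise ChronologyError("curve needs at least two knots")
        d = np.diff(self.grid)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ChronologyError("curve grid must be strictly monotone")
        if np.any(d < 0):  # store ascending
            self.grid = self.grid[::-1]
            self.mu14c = self.mu14c[::-1]
            self.sigma_curve = self.sigma_curve[::-1]
        if np.any(self.sigma_curve < 0):
            raise ChronologyError("curve sigma must be non-negative")

    def mu(self, cal: np.ndarray) -> np.ndarray:
        return np.interp(cal, self.grid, self.mu14c)

    def sigma(self, cal: np.ndarray) -> np.ndarray:
        return np.interp(cal, self.grid, self.sigma_curve)


@dataclass
class CalDensity:
    """Calibrated probability mass over a fixed-step calendar grid (cal BP)."""

    grid: np.ndarray
    p: np.ndarray
    median: float
    range95: tuple[float, float]

    @classmethod
    def from_grid(cls, grid: np.ndarray, p: np.ndarray) -> "CalDensity":
        grid = np.asarray(grid, dtype=float)
        p = np.asarray(p, dtype=float)
        if np.any(p < 0):
            raise ChronologyError("negative probability mass")
        total = p.sum()
        if total <= 0:
            raise ChronologyError("empty density")
        p = p / total
        cum = np.cumsum(p)
        med = float(np.interp(0.5, cum, grid))
        lo = float(np.interp(0.023, cum, grid))
        hi = float(np.interp(0.977, cum, grid))
        return cls(grid=grid, p=p, median=med, range95=(lo, hi))

    @property
    def sigma_equivalent(self) -> float:
        """Normal-equivalent sigma of the 95.4% range: (upper - lower) / 4."""
        return (self.range95[1] - self.range95[0]) / 4.0


@dataclass
class Assemblage:
    """All dates from one archaeological level, plus their merged density."""

    site_id: str
    level_id: str
    culture: str
    region: str
    dates: list[RadiocarbonDate]
    merged_density: CalDensity | None = None


@dataclass
class Sighting:
    median: float
    range95: tuple[float, float]
    sigma_equivalent: float


@dataclass
class SightingSet:
    """The terminal (oldest or youngest) calibrated dates of one record."""

    entries: list[Sighting]
    direction: str  # "end_boundary" (youngest) or "start_boundary" (oldest)

    def __post_init__(self):
        if self.direction not in ("end_boundary", "start_boundary"):
            raise ChronologyError(f"unknown direction {self.direction!r}")
        if len(self.entries) < 3:
            raise InsufficientDataError(
                "at least 3 sightings are required for boundary estimation")

    @property
    def k(self) -> int:
        return len(self.entries)


@dataclass
class BoundaryEstimate:
    point: float
    ci95: tuple[float, float]
    n_iter: int = 1
    per_iteration: np.ndarray | None = None


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate(date: RadiocarbonDate, curve: CalibrationCurve | None,
              step: float = 20.0) -> CalDensity:
    """Calibrate one determination onto the calendar axis.

    For 14C dates the likelihood at calendar age theta is a normal density of
    ``age - mu14c(theta)`` with variance ``error^2 + sigma_curve(theta)^2``,
    normalised over the curve's support.  Non-radiocarbon dates return a
    normal density centred on their (calendar) age.
    """
    if step <= 0:
        raise ChronologyError("step must be positive")
    if date.method == "14C":
        if curve is None:
            raise ChronologyError("14C calibration requires a curve")
        mu_lo, mu_hi = float(curve.mu14c.min()), float(curve.mu14c.max())
        if not (mu_lo <= date.age <= mu_hi):
            raise OutOfCurveRangeError(
                f"{date.lab_code}: 14C age {date.age} outside curve "
                f"support [{mu_lo}, {mu_hi}]")
        if date.age + 2 * date.error_1sigma > mu_hi:
            warnings.warn(
                f"{date.lab_code}: within 2 sigma of the calibration curve "
                "limit; calibrated density may be unstable", UserWarning)
        lo = np.ceil(curve.grid[0] / step) * step
        hi = np.floor(curve.grid[-1] / step) * step
        grid = np.arange(lo, hi + 0.5 * step, step)
        var = date.error_1sigma ** 2 + curve.sigma(grid) ** 2
        logp = -0.5 * (date.age - curve.mu(grid)) ** 2 / var - 0.5 * np.log(var)
        p = np.exp(logp - logp.max())
    else:
        half = 5.0 * date.error_1sigma
        lo = np.floor((date.age - half) / step) * step
        hi = np.ceil((date.age + half) / step) * step
        grid = np.arange(lo, hi + 0.5 * step, step)
        p = np.exp(-0.5 * ((grid - date.age) / date.error_1sigma) ** 2)
    # trim negligible tails so SPD sums stay cheap
    nz = np.nonzero(p > 1e-12 * p.max())[0]
    grid, p = grid[nz[0]:nz[-1] + 1], p[nz[0]:nz[-1] + 1]
    return CalDensity.from_grid(grid, p)


def combine_same_level(dates: Sequence[RadiocarbonDate]) -> RadiocarbonDate:
    """Pool same-level 14C determinations by inverse-variance weighting.

    The combined age is the weighted mean, the combined error ``(sum w)^-1/2``
    and a chi-square consistency statistic ``T = sum w (age - mean)^2`` with
    ``k - 1`` degrees of freedom is attached.  A failure at alpha = 0.05 is
    reported via a warning but does not abort.  Mixing methods is refused.
    """
    dates = list(dates)
    if not dates:
        raise ChronologyError("nothing to combine")
    if len(dates) == 1:
        return dates[0]
    methods = {d.method for d in dates}
    if methods != {"14C"}:
        raise MixedMethodError(
            f"refusing to combine mixed methods {sorted(methods)}; "
            "keep non-14C dates separate")
    ages = np.array([d.age for d in dates])
    w = 1.0 / np.array([d.error_1sigma for d in dates]) ** 2
    mean = float(np.sum(w * ages) / np.sum(w))
    err = float(np.sum(w) ** -0.5)
    T = float(np.sum(w * (ages - mean) ** 2))
    df = len(dates) - 1
    p = float(stats.chi2.sf(T, df))
    consistent = p >= 0.05
    if not consistent:
        warnings.warn(
            f"combination of {[d.lab_code for d in dates]} fails the "
            f"chi-square consistency test (T={T:.2f}, df={df}, p={p:.3g})",
            UserWarning)
    proto = dates[0]
    return CombinedDate(
        lab_code="+".join(d.lab_code for d in dates),
        site_id=proto.site_id, level_id=proto.level_id,
        region=proto.region, culture=proto.culture, method="14C",
        age=mean, error_1sigma=err, material=proto.material,
        flags=frozenset().union(*(d.flags for d in dates)),
        chi2_stat=T, chi2_df=df, chi2_p=p, consistent=consistent,
        n_combined=len(dates))


# removal reason codes
REASON_CV = "cv_threshold"
REASON_SHELL = "shell_material"
REASON_FLAGGED = "flagged_level"


def filter_for_spd(dataset: Iterable[RadiocarbonDate],
                   ) -> tuple[list[RadiocarbonDate],
                              list[tuple[RadiocarbonDate, list[str]]]]:
    """Apply the SPD/OLE eligibility filters.

    Removes dates with coefficient of variation >= 0.05 (inclusive), shell
    material dates (marine reservoir uncertainty) and dates from levels with
    stratigraphic or cultural-attribution flags.  Every removal is returned
    with machine-readable reason codes.
    """
    kept, removed = [], []
    for d in dataset:
        reasons = []
        if d.cv >= CV_THRESHOLD:
            reasons.append(REASON_CV)
        if d.material == "shell":
            reasons.append(REASON_SHELL)
        if d.flags:
            reasons.append(REASON_FLAGGED)
        if reasons:
            removed.append((d, reasons))
        else:
            kept.append(d)
    return kept, removed


def build_assemblages(dates: Iterable[RadiocarbonDate],
                      curve: CalibrationCurve | None,
                      step: float = 20.0) -> list[Assemblage]:
    """Group dates by (site, level), combine same-method 14C dates, calibrate.

    A level mixing methods keeps one calibrated density per method group; the
    assemblage density is their unit-mass average so each occupational unit
    contributes exactly once to the SPD.
    """
    groups: dict[tuple[str, str], list[RadiocarbonDate]] = {}
    for d in dates:
        groups.setdefault((d.site_id, d.level_id), []).append(d)
    out = []
    for (site, level), ds in sorted(groups.items()):
        c14 = [d for d in ds if d.method == "14C"]
        other = [d for d in ds if d.method != "14C"]
        units: list[RadiocarbonDate] = []
        if c14:
            units.append(combine_same_level(c14) if len(c14) > 1 else c14[0])
        units.extend(other)
        densities = [calibrate(u, curve, step) for u in units]
        merged = _average_densities(densities, step)
        out.append(Assemblage(site_id=site, level_id=level,
                              culture=ds[0].culture, region=ds[0].region,
                              dates=ds, merged_density=merged))
    return out


def _average_densities(densities: list[CalDensity], step: float) -> CalDensity:
    lo = min(d.grid[0] for d in densities)
    hi = max(d.grid[-1] for d in densities)
    grid = np.arange(lo, hi + 0.5 * step, step)
    total = np.zeros_like(grid)
    for d in densities:
        idx = np.rint((d.grid - lo) / step).astype(int)
        ok = (idx >= 0) & (idx < len(grid))
        np.add.at(total, idx[ok], d.p[ok])
    total /= len(densities)
    return CalDensity.from_grid(grid, total)


def spd(assemblages: Sequence[Assemblage], step: float = 20.0,
        window: tuple[float, float] | None = None,
        ) -> tuple[np.ndarray, np.ndarray]:
    """Summed probability distribution of assemblage densities.

    Each assemblage contributes its merged density at unit mass; the sum is
    restricted to ``window = (old, young)`` cal BP when given.  Densities
    crossing the window edge are truncated without renormalisation (logged via
    a warning), so the total SPD mass equals the number of assemblages lying
    wholly inside the window plus the truncated fractions.
    """
    if not assemblages:
        return np.array([]), np.array([])
    if window is None:
        old = max(a.merged_density.grid[-1] for a in assemblages)
        young = min(a.merged_density.grid[0] for a in assemblages)
    else:
        old, young = window
        if old <= young:
            raise ChronologyError("window must be (old, young) with old > young")
    lo = np.floor(young / step) * step
    hi = np.ceil(old / step) * step
    grid = np.arange(lo, hi + 0.5 * step, step)
    total = np.zeros_like(grid)
    truncated = 0
    for a in assemblages:
        d = a.merged_density
        idx = np.rint((d.grid - lo) / step).astype(int)
        ok = (idx >= 0) & (idx < len(grid))
        if not ok.all():
            truncated += 1
        np.add.at(total, idx[ok], d.p[ok])
    if truncated:
        warnings.warn(f"{truncated} assemblage densities truncated at the "
                      "analysis window edge (not renormalised)", UserWarning)
    return grid, total


# ---------------------------------------------------------------------------
# optimal linear estimation
# ---------------------------------------------------------------------------

def select_terminal_dates(dataset: Iterable[RadiocarbonDate],
                          curve: CalibrationCurve | None,
                          which: str,
                          culture: str | None = None,
                          region: str | None = None,
                          m: int = 10,
                          step: float = 20.0) -> SightingSet:
    """Pick the ``m`` most extreme eligible calibrated dates of a record.

    ``which`` is ``"youngest"`` (for an end boundary) or ``"oldest"`` (for a
    start boundary); between five and ten terminal dates are the recommended
    record size.  Eligibility re-applies the SPD filters.
    """
    if which not in ("youngest", "oldest"):
        raise ChronologyError("which must be 'youngest' or 'oldest'")
    if not 1 <= m <= 10:
        raise ChronologyError("m must be between 1 and 10")
    pool = [d for d in dataset
            if (culture is None or d.culture == culture)
            and (region is None or d.region == region)]
    eligible, _ = filter_for_spd(pool)
    if len(eligible) < 3:
        raise InsufficientDataError(
            f"only {len(eligible)} eligible dates; OLE needs at least 3")
    dens = [calibrate(d, curve, step) for d in eligible]
    sightings = [Sighting(dn.median, dn.range95, dn.sigma_equivalent)
                 for dn in dens]
    reverse = which == "oldest"
    sightings.sort(key=lambda s: s.median, reverse=reverse)
    direction = "end_boundary" if which == "youngest" else "start_boundary"
    return SightingSet(entries=sightings[:min(m, len(sightings))],
                       direction=direction)


def _ole_on_transformed(x: np.ndarray, alpha: float) -> tuple[float, float]:
    """Roberts–Solow OLE on an axis where the boundary lies beyond max(x).

    Returns (point estimate, one-sided 1-alpha bound), both > max(x) for a
    non-degenerate record.
    """
    x = np.sort(np.asarray(x, dtype=float))[::-1]
    k = len(x)
    if k < 3:
        raise InsufficientDataError("OLE needs k >= 3 sightings")
    rng_ = x[0] - x[-1]
    if rng_ <= 0:
        raise DegenerateRecordError("all sightings coincide")
    # Weibull shape from the log-spacings of the record
    with np.errstate(divide="ignore"):
        terms = np.log(rng_ / (x[0] - x[1:-1]))
    terms = terms[np.isfinite(terms)]
    v = float(terms.sum() / (k - 1))
    if not np.isfinite(v) or v < 0:
        raise DegenerateRecordError("degenerate spacing structure")
    # covariance of the k extremes under the joint Weibull model
    i = np.arange(1, k + 1, dtype=float)
    hi = np.maximum(i[:, None], i[None, :])
    lo = np.minimum(i[:, None], i[None, :])
    lam = np.exp(gammaln(2 * v + hi) + gammaln(v + lo)
                 - gammaln(v + hi) - gammaln(lo))
    e = np.ones(k)
    try:
        sol = np.linalg.solve(lam, e)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(lam, e, rcond=None)[0]
    a = sol / sol.sum()
    point = float(a @ x)
    S = (-np.log(alpha) / k) ** (-v)
    bound = float(x[0] + rng_ / (S - 1.0)) if S > 1.0 else np.inf
    return point, bound


def ole_point(s: SightingSet, alpha: float = 0.05) -> BoundaryEstimate:
    """Single OLE boundary estimate from the sighting medians.

    End boundaries are computed on negated cal BP so that "beyond the most
    recent occurrence" is always "beyond the maximum" on the working axis;
    the returned estimate and bound are mapped back to cal BP.
    """
    meds = np.array([e.median for e in s.entries], dtype=float)
    sign = -1.0 if s.direction == "end_boundary" else 1.0
    point_x, bound_x = _ole_on_transformed(sign * meds, alpha)
    point = sign * point_x
    bound = sign * bound_x
    extreme = float(meds.min() if s.direction == "end_boundary" else meds.max())
    ci = (min(bound, extreme), max(bound, extreme))
    return BoundaryEstimate(point=point, ci95=ci, n_iter=1)


def ole_resample(s: SightingSet, n_iter: int = 10000,
                 seed: int | None = None,
                 alpha: float = 0.05) -> BoundaryEstimate:
    """OLE with Monte-Carlo propagation of calibrated-date uncertainty.

    Each iteration redraws every sighting as Normal(median, sigma_equivalent),
    re-sorts, and applies the point estimator; the returned estimate is the
    median of the iterations with the 2.5/97.5 percentiles as the 95% interval.
    """
    rng = np.random.default_rng(seed)
    meds = np.array([e.median for e in s.entries], dtype=float)
    sigmas = np.array([e.sigma_equivalent for e in s.entries], dtype=float)
    sign = -1.0 if s.direction == "end_boundary" else 1.0
    ests = np.empty(n_iter)
    n_bad = 0
    for it in range(n_iter):
        draw = rng.normal(meds, sigmas)
        try:
            p, _ = _ole_on_transformed(sign * draw, alpha)
        except ChronologyError:
            n_bad += 1
            ests[it] = np.nan
            continue
        ests[it] = sign * p
    if n_bad > n_iter / 2:
        raise DegenerateRecordError(
            f"{n_bad}/{n_iter} resampling iterations degenerate")
    ok = ests[np.isfinite(ests)]
    point = float(np.median(ok))
    lo, hi = np.percentile(ok, [2.5, 97.5])
    return BoundaryEstimate(point=point, ci95=(float(lo), float(hi)),
                            n_iter=n_iter, per_iteration=ok)


def boundary_overlap(end_a: BoundaryEstimate,
                     start_b: BoundaryEstimate) -> float:
    """Chronological overlap (years) between the end of record A and the start
    of record B: positive when B begins (older cal BP) before A ends."""
    return start_b.point - end_a.point
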
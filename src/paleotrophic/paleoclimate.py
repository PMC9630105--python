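"""Pollen-based climate reconstruction and simulated-climate bias correction.

Weighted-averaging (WA) transfer functions assume each taxon is most abundant
near its climatic optimum: a taxon's optimum is the abundance-weighted mean of
the climate variable over the modern training samples, a sample's initial
estimate is the abundance-weighted mean of its taxa's optima, and the shrinkage
inherent in averaging twice is undone by inverse (classical) deshrinking — an
ordinary regression of observed climate on the initial estimates.  Mean annual
temperature (MAT, deg C) and mean annual precipitation (MAP, mm yr-1) are
fitted independently.

Simulated palaeoclimate fields are bias-corrected with the delta method:
additive for temperature, multiplicative for precipitation, anchored on the
present-day observed/simulated discrepancy.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

MIN_POLLEN_COUNT = 100
MIN_TAXON_PERCENT = 5.0

VARIABLES = ("MAT", "MAP")


class PaleoclimateError(ValueError):
    pass


class RejectedAssemblage(PaleoclimateError):
    """Raised when an assemblage fails the pollen filtering criteria."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


class NoAnalogueError(PaleoclimateError):
    pass


@dataclass
class PollenAssemblage:
    """One (fossil or modern) pollen spectrum as taxon percentages."""

    sample_id: str
    site_id: str
    taxa: dict[str, float]  # taxon -> percentage
    total_count: float
    terrestrial: dict[str, bool] = field(default_factory=dict)

    def is_terrestrial(self, taxon: str) -> bool:
        return self.terrestrial.get(taxon, True)


@dataclass
class TrainingSet:
    """Modern calibration data: percentage matrix Y (samples x taxa) plus the
    per-sample climate observations."""

    Y: pd.DataFrame
    climate: pd.DataFrame  # columns: MAT and/or MAP

    def __post_init__(self):
        if (self.Y.sum(axis=1) == 0).any():
            raise PaleoclimateError("training set contains all-zero samples")
        if not np.isfinite(self.climate.to_numpy(dtype=float)).all():
            raise PaleoclimateError("non-finite climate values")


@dataclass
class TransferFunction:
    optima: pd.Series  # taxon -> climate optimum
    deshrink: tuple[float, float]  # (slope, intercept)
    variable: str
    apparent_r2: float = np.nan


@dataclass
class CVReport:
    r2: float
    rmse: float
    n_boot: int
    variable: str
    n_skipped_cycles: int = 0
    degenerate: bool = False


# ---------------------------------------------------------------------------
# pollen filtering
# ---------------------------------------------------------------------------

def _renormalize(taxa: dict[str, float]) -> dict[str, float]:
    total = sum(taxa.values())
    return {t: 100.0 * v / total for t, v in taxa.items()}


def filter_pollen(a: PollenAssemblage) -> PollenAssemblage:
    """Apply the pollen quality criteria to one assemblage.

    Rejects assemblages with fewer than 100 counted grains; removes
    non-terrestrial taxa (ferns, aquatics, non-pollen palynomorphs) and taxa
    below 5% representation; renormalises the remaining percentages to 100.
    """
    if a.total_count < MIN_POLLEN_COUNT:
        raise RejectedAssemblage(
            f"{a.sample_id}: total count {a.total_count} < {MIN_POLLEN_COUNT}")
    taxa = {t: v for t, v in a.taxa.items() if v > 0 and a.is_terrestrial(t)}
    if not taxa:
        raise RejectedAssemblage(f"{a.sample_id}: no terrestrial taxa left")
    taxa = _renormalize(taxa)
    taxa = {t: v for t, v in taxa.items() if v >= MIN_TAXON_PERCENT}
    if not taxa:
        raise RejectedAssemblage(
            f"{a.sample_id}: all taxa below {MIN_TAXON_PERCENT}%")
    return PollenAssemblage(sample_id=a.sample_id, site_id=a.site_id,
                            taxa=_renormalize(taxa),
                            total_count=a.total_count,
                            terrestrial=dict(a.terrestrial))


# ---------------------------------------------------------------------------
# weighted averaging
# ---------------------------------------------------------------------------

def wa_fit(train: TrainingSet, variable: str,
           deshrink: str = "inverse") -> TransferFunction:
    """Fit a weighted-averaging transfer function for one climate variable.

    ``deshrink`` is ``"inverse"`` (classical; regression of observed climate
    on initial estimates) or ``"none"`` (identity).
    """
    if variable not in train.climate.columns:
        raise PaleoclimateError(f"training set lacks variable {variable!r}")
    Y = train.Y.to_numpy(dtype=float)
    if Y.shape[0] < 2 or Y.shape[1] < 1:
        raise PaleoclimateError("need >= 2 samples and >= 1 taxon")
    x = train.climate[variable].to_numpy(dtype=float)
    colsum = Y.sum(axis=0)
    if (colsum == 0).any():
        dropped = list(train.Y.columns[colsum == 0])
        warnings.warn(f"taxa with zero total abundance excluded: {dropped}",
                      UserWarning)
        Y = Y[:, colsum > 0]
        cols = train.Y.columns[colsum > 0]
        colsum = colsum[colsum > 0]
    else:
        cols = train.Y.columns
    optima = (Y.T @ x) / colsum
    initial = (Y @ optima) / Y.sum(axis=1)
    if deshrink == "inverse":
        if np.ptp(initial) == 0:  # constant initial estimates: predict mean
            slope, intercept = 1.0, float(x.mean() - initial[0])
        else:
            slope, intercept, *_ = stats.linregress(initial, x)
    elif deshrink == "none":
        slope, intercept = 1.0, 0.0
    else:
        raise PaleoclimateError(f"unknown deshrinking {deshrink!r}")
    fitted = intercept + slope * initial
    ss_tot = np.sum((x - x.mean()) ** 2)
    r2 = 1.0 - np.sum((x - fitted) ** 2) / ss_tot if ss_tot > 0 else np.nan
    return TransferFunction(optima=pd.Series(optima, index=cols),
                            deshrink=(float(slope), float(intercept)),
                            variable=variable, apparent_r2=float(r2))


def wa_predict(tf: TransferFunction,
               fossil: PollenAssemblage | Mapping[str, float]) -> float:
    """Reconstruct the climate variable for one pollen spectrum."""
    taxa = fossil.taxa if isinstance(fossil, PollenAssemblage) else dict(fossil)
    shared = {t: v for t, v in taxa.items() if t in tf.optima.index and v > 0}
    if not shared:
        raise NoAnalogueError("no fossil taxon overlaps the transfer function")
    ab = np.array(list(shared.values()), dtype=float)
    opt = tf.optima[list(shared)].to_numpy()
    raw = float(np.sum(ab * opt) / ab.sum())
    slope, intercept = tf.deshrink
    return intercept + slope * raw


def bootstrap_cv(train: TrainingSet, variable: str, n_boot: int = 500,
                 seed: int | None = None,
                 deshrink: str = "inverse") -> CVReport:
    """Bootstrap cross-validation of the transfer function.

    Each cycle refits on a bootstrap resample of the training samples and
    predicts the out-of-bag samples; r2 (squared Pearson correlation) and RMSE
    are computed on the pooled out-of-bag predictions.
    """
    n = len(train.Y)
    if n < 10:
        raise PaleoclimateError("bootstrap CV needs >= 10 training samples")
    rng = np.random.default_rng(seed)
    obs_all, pred_all = [], []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if len(oob) == 0:
            skipped += 1
            continue
        boot = TrainingSet(Y=train.Y.iloc[idx], climate=train.climate.iloc[idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            tf = wa_fit(boot, variable, deshrink=deshrink)
        for i in oob:
            row = train.Y.iloc[i]
            try:
                pred = wa_predict(tf, row[row > 0].to_dict())
            except NoAnalogueError:
                continue
            obs_all.append(train.climate[variable].iloc[i])
            pred_all.append(pred)
    obs = np.asarray(obs_all, dtype=float)
    pred = np.asarray(pred_all, dtype=float)
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        return CVReport(r2=0.0, rmse=rmse, n_boot=n_boot, variable=variable,
                        n_skipped_cycles=skipped, degenerate=True)
    r = float(np.corrcoef(obs, pred)[0, 1])
    return CVReport(r2=r * r, rmse=rmse, n_boot=n_boot, variable=variable,
                    n_skipped_cycles=skipped, degenerate=False)


# ---------------------------------------------------------------------------
# delta-method bias correction
# ---------------------------------------------------------------------------

def delta_correct_temperature(t_sim_raw_t, t_obs_0, t_sim_raw_0):
    """Additive delta correction: T_sim(x,t) + (T_obs(x,0) - T_sim(x,0))."""
    for v in (t_sim_raw_t, t_obs_0, t_sim_raw_0):
        if v is None:
            raise PaleoclimateError("missing temperature baseline")
    return np.asarray(t_sim_raw_t, dtype=float) + (
        np.asarray(t_obs_0, dtype=float) - np.asarray(t_sim_raw_0, dtype=float))


def delta_correct_precipitation(p_sim_raw_t, p_obs_0, p_sim_raw_0,
                                eps: float = 1e-9):
    """Multiplicative delta correction: P_sim(x,t) * P_obs(x,0) / P_sim(x,0).

    Cells whose present-day simulated baseline does not exceed ``eps`` are
    masked (NaN) rather than divided, with a warning.
    """
    pt = np.asarray(p_sim_raw_t, dtype=float)
    po = np.asarray(p_obs_0, dtype=float)
    p0 = np.asarray(p_sim_raw_0, dtype=float)
    bad = p0 <= eps
    if np.any(bad):
        warnings.warn(f"{int(np.sum(bad))} cells with simulated baseline "
                      f"precipitation <= {eps} masked", UserWarning)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, pt * po / np.where(bad, np.nan, p0))
    if out.ndim == 0 and not bad:
        return float(out)
    return out


def bias_assessment(reconstructed, simulated_before, simulated_after) -> dict:
    """Compare reconstructed values with raw and bias-corrected simulations.

    Returns mean absolute differences and Pearson correlations (with two-sided
    p) before and after correction.  Constant series flag the correlation as
    undefined rather than raising.
    """
    rec = np.asarray(reconstructed, dtype=float)
    before = np.asarray(simulated_before, dtype=float)
    after = np.asarray(simulated_after, dtype=float)
    if len(rec) < 3:
        raise PaleoclimateError("bias assessment needs >= 3 pairs")

    def _corr(a, b):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return {"r": np.nan, "p": np.nan, "degenerate": True}
        r, p = stats.pearsonr(a, b)
        return {"r": float(r), "p": float(p), "degenerate": False}

    return {
        "mean_abs_diff_before": float(np.mean(np.abs(rec - before))),
        "mean_abs_diff_after": float(np.mean(np.abs(rec - after))),
        "corr_before": _corr(rec, before),
        "corr_after": _corr(rec, after),
        "n": len(rec),
    }
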
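"""Ground-truth-known synthetic inputs for every pipeline stage.

Each generator draws from an explicit process model so that every downstream
method can be tested for parameter recovery without external data:

* chronometric dates come from bounded occupation phases sampled uniformly in
  calendar time, mapped through a calibration curve and perturbed by lab error,
  with configurable fractions of shell, flagged and high-CV dates injected so
  the quality filters have work to do;
* NPP series follow region profiles with distinct stadial/interstadial level
  means plus Gaussian noise on a shared time grid;
* pollen taxa respond unimodally (Gaussian) to a climate gradient with
  multinomial counting noise;
* modern herbivore compilations follow the log-log THB-NPP law with lognormal
  scatter, and per-species densities follow an exact Damuth partition times
  lognormal noise.

All generators are deterministic under a fixed seed and scenario, and
scenarios round-trip through plain-dict serialization.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chronology import CalibrationCurve, RadiocarbonDate
from .npp import NPPSeries, PhaseTable, default_phase_table
from .paleoclimate import PollenAssemblage, TrainingSet
from .carrying_capacity import ModernSiteRecord, SpeciesMass


@dataclass
class ChronologyScenario:
    true_start: float = 48000.0  # cal BP, older boundary of the occupation
    true_end: float = 40000.0  # cal BP, younger boundary
    n_levels: int = 30
    dates_per_level: int = 2
    lab_error: tuple[float, float] = (150.0, 400.0)  # 1-sigma range, years
    shell_fraction: float = 0.0
    flagged_fraction: float = 0.0
    high_cv_fraction: float = 0.0
    region: str = "Eurosiberian"
    culture: str = "Mousterian"


@dataclass
class RegionProfile:
    region: str
    stadial_mean: float
    interstadial_mean: float
    n_sites: int = 8


@dataclass
class NPPScenario:
    # default profiles mirror the three distinct productivity regimes the
    # clustering is expected to separate (levels in kg km-2 yr-1 display units)
    profiles: list[RegionProfile] = field(default_factory=lambda: [
        RegionProfile("Eurosiberian", 0.271, 0.339),
        RegionProfile("Mesomediterranean", 0.300, 0.312),
        RegionProfile("Thermomediterranean", 0.259, 0.258),
    ])
    noise_sd: float = 0.01
    time_start: float = 54.0  # kyr BP, old edge of the grid
    time_end: float = 30.6  # kyr BP, young edge
    time_step: float = 0.2


@dataclass
class PollenScenario:
    n_taxa: int = 12
    n_train: int = 60
    mat_gradient: tuple[float, float] = (-5.0, 15.0)  # deg C
    map_gradient: tuple[float, float] = (300.0, 1500.0)  # mm yr-1
    tolerance: float = 3.0  # Gaussian response breadth on the MAT axis
    depth: int | None = 400  # grains counted; None = noise-free proportions
    n_fossil: int = 10


@dataclass
class AllometryScenario:
    slope: float = 1.401
    intercept: float = -0.642
    scatter_sd: float = 0.10  # lognormal scatter of THB, log10 units
    n_sites: int = 516
    richness: tuple[int, int] = (3, 15)
    mass_bounds: tuple[float, float] = (1.0, 1000.0)  # kg, log-uniform
    npp_bounds: tuple[float, float] = (50.0, 2000.0)  # g m-2 yr-1, log-uniform
    density_noise_sd: float = 0.10  # per-species lognormal noise, log10 units


@dataclass
class SyntheticScenario:
    seed: int = 0
    chronology: ChronologyScenario = field(default_factory=ChronologyScenario)
    npp: NPPScenario = field(default_factory=NPPScenario)
    pollen: PollenScenario = field(default_factory=PollenScenario)
    allometry: AllometryScenario = field(default_factory=AllometryScenario)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScenario":
        d = dict(d)
        sub = {
            "chronology": ChronologyScenario,
            "npp": NPPScenario,
            "pollen": PollenScenario,
            "allometry": AllometryScenario,
        }
        kwargs = {"seed": d.get("seed", 0)}
        for key, typ in sub.items():
            if key in d:
                v = dict(d[key])
                if key == "npp" and "profiles" in v:
                    v["profiles"] = [RegionProfile(**dict(p))
                                     for p in v["profiles"]]
                for f_ in dataclasses.fields(typ):
                    if f_.name in v and isinstance(v[f_.name], list) \
                            and f_.name != "profiles":
                        v[f_.name] = tuple(v[f_.name])
                kwargs[key] = typ(**v)
        return cls(**kwargs)


def synthetic_curve(cal_min: float = 28000.0, cal_max: float = 58000.0,
                    knot_step: float = 100.0) -> CalibrationCurve:
    """A smooth monotone stand-in calibration curve (synthetic).

    The 14C/calendar offset and the wiggle amplitude are loosely modelled on
    the glacial portion of real calibration curves; the curve exists so tests
    and simulations never require a download.
    """
    grid = np.arange(cal_min, cal_max + 0.5 * knot_step, knot_step)
    mu = 0.95 * grid - 800.0 + 150.0 * np.sin(grid / 1200.0)
    sigma = 50.0 + 0.002 * (grid - cal_min)
    return CalibrationCurve(grid=grid, mu14c=mu, sigma_curve=sigma,
                            name="synthetic")


def gen_radiocarbon_dataset(scenario: SyntheticScenario,
                            curve: CalibrationCurve | None = None,
                            seed: int | None = None,
                            ) -> tuple[list[RadiocarbonDate], dict]:
    """Dates drawn from a bounded occupation phase, with injected defects.

    Returns the dates plus a truth record with the phase boundaries, per-date
    true calendar ages, and the lab codes of every injected defect.
    """
    ch = scenario.chronology
    if ch.true_start <= ch.true_end:
        raise ValueError("true_start must be older than true_end (cal BP)")
    if curve is None:
        curve = synthetic_curve()
    if not (curve.grid[0] <= ch.true_end and ch.true_start <= curve.grid[-1]):
        raise ValueError("occupation interval outside curve support")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    dates: list[RadiocarbonDate] = []
    true_ages: dict[str, float] = {}
    injected = {"shell": [], "flagged": [], "high_cv": []}
    n_dates = ch.n_levels * ch.dates_per_level
    true_cal = rng.uniform(ch.true_end, ch.true_start, size=n_dates)
    for i, cal in enumerate(true_cal):
        level = i // ch.dates_per_level
        lab = f"SYN-{i:04d}"
        err = rng.uniform(*ch.lab_error)
        age14 = float(curve.mu(cal) + rng.normal(0.0, err))
        material, flags = "bone", frozenset()
        if rng.random() < ch.shell_fraction:
            material = "shell"
            injected["shell"].append(lab)
        if rng.random() < ch.flagged_fraction:
            flags = frozenset({"stratigraphic_issue"})
            injected["flagged"].append(lab)
        if rng.random() < ch.high_cv_fraction:
            err = 0.06 * age14  # cv = 0.06, above the 0.05 cut
            injected["high_cv"].append(lab)
        dates.append(RadiocarbonDate(
            lab_code=lab, site_id=f"site{level:03d}",
            level_id=f"L{level:03d}", region=ch.region, culture=ch.culture,
            method="14C", age=age14, error_1sigma=err, material=material,
            flags=flags))
        true_ages[lab] = float(cal)
    truth = {"true_start": ch.true_start, "true_end": ch.true_end,
             "true_ages": true_ages, "injected": injected}
    return dates, truth


def gen_npp_series(scenario: SyntheticScenario,
                   phases: PhaseTable | None = None,
                   seed: int | None = None,
                   ) -> tuple[list[NPPSeries], dict]:
    """Region-profile NPP series on a shared grid, with cluster truth labels."""
    npp = scenario.npp
    if phases is None:
        phases = default_phase_table()
    if len(phases.phases) < 2:
        raise ValueError("need at least 2 phases")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    times = np.arange(npp.time_start, npp.time_end - 0.5 * npp.time_step,
                      -npp.time_step)
    kinds = [phases.classify(t) for t in times]
    series: list[NPPSeries] = []
    labels: dict[str, int] = {}
    for ci, prof in enumerate(npp.profiles):
        means = np.array([
            prof.stadial_mean if (k is not None and k.kind == "stadial")
            else prof.interstadial_mean for k in kinds])
        for j in range(prof.n_sites):
            vals = means + rng.normal(0.0, npp.noise_sd, size=len(times))
            vals = np.clip(vals, 0.0, None)
            sid = f"{prof.region[:4].lower()}_{j:02d}"
            series.append(NPPSeries(site_id=sid, region=prof.region,
                                    times=times.copy(), values=vals,
                                    unit="kg km-2 yr-1"))
            labels[sid] = ci
    truth = {"labels": labels,
             "profiles": [dataclasses.asdict(p) for p in npp.profiles]}
    return series, truth


def gen_pollen(scenario: SyntheticScenario, seed: int | None = None,
               ) -> tuple[TrainingSet, list[PollenAssemblage], dict]:
    """Gaussian-response pollen data over a climate gradient.

    Training climates span the MAT gradient (MAP varies in step so both
    variables are reconstructable); fossil samples sit at held-out climates.
    With ``depth=None`` the spectra are the exact response proportions;
    otherwise counts are multinomial at that depth.
    """
    po = scenario.pollen
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    lo, hi = po.mat_gradient
    mat = np.linspace(lo, hi, po.n_train)
    mlo, mhi = po.map_gradient
    map_ = np.linspace(mlo, mhi, po.n_train)
    optima = np.linspace(lo, hi, po.n_taxa)
    taxa = [f"taxon_{chr(ord('A') + i)}" for i in range(po.n_taxa)]

    def spectrum(x: float) -> np.ndarray:
        resp = np.exp(-0.5 * ((x - optima) / po.tolerance) ** 2) + 1e-9
        p = resp / resp.sum()
        if po.depth is None:
            return 100.0 * p
        counts = rng.multinomial(po.depth, p)
        return 100.0 * counts / counts.sum()

    Y = pd.DataFrame([spectrum(x) for x in mat], columns=taxa)
    climate = pd.DataFrame({"MAT": mat, "MAP": map_})
    train = TrainingSet(Y=Y, climate=climate)

    f_mat = np.linspace(lo + 0.07 * (hi - lo), hi - 0.07 * (hi - lo),
                        po.n_fossil)
    f_map = np.interp(f_mat, mat, map_)
    fossils = []
    for i, x in enumerate(f_mat):
        spec = spectrum(x)
        fossils.append(PollenAssemblage(
            sample_id=f"fossil_{i:02d}", site_id=f"fsite_{i:02d}",
            taxa={t: float(v) for t, v in zip(taxa, spec) if v > 0},
            total_count=po.depth if po.depth is not None else 10000,
            terrestrial={t: True for t in taxa}))
    truth = {"optima": dict(zip(taxa, optima.tolist())),
             "fossil_mat": f_mat.tolist(), "fossil_map": f_map.tolist()}
    return train, fossils, truth


def gen_modern_density_dataset(scenario: SyntheticScenario,
                               seed: int | None = None,
                               ) -> tuple[list[ModernSiteRecord], dict]:
    """Modern density compilation following the planted THB-NPP law."""
    al = scenario.allometry
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    sites = []
    for i in range(al.n_sites):
        log_npp = rng.uniform(np.log10(al.npp_bounds[0]),
                              np.log10(al.npp_bounds[1]))
        npp = 10.0 ** log_npp
        log_thb = (al.slope * log_npp + al.intercept
                   + rng.normal(0.0, al.scatter_sd))
        thb = 10.0 ** log_thb
        n_sp = int(rng.integers(al.richness[0], al.richness[1] + 1))
        masses = 10.0 ** rng.uniform(np.log10(al.mass_bounds[0]),
                                     np.log10(al.mass_bounds[1]), size=n_sp)
        species = [SpeciesMass(taxon=f"sp_{i:03d}_{j:02d}", W=float(w))
                   for j, w in enumerate(masses)]
        c = thb / sum(s.W ** 0.25 for s in species)
        obs = {s.taxon: float(c * s.W ** -0.75
                              * 10.0 ** rng.normal(0.0, al.density_noise_sd))
               for s in species}
        sites.append(ModernSiteRecord(site=f"park_{i:03d}", npp=float(npp),
                                      species=species, observed_density=obs))
    truth = {"slope": al.slope, "intercept": al.intercept,
             "scatter_sd": al.scatter_sd,
             "density_noise_sd": al.density_noise_sd}
    return sites, truth
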
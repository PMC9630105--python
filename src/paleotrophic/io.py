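"""Readers and writers for the package's plain-text interchange formats.

All tabular formats are CSV via pandas; the calibration curve reader accepts
the IntCal-style ``.14c`` dialect (``#`` header lines; columns cal BP, 14C age
BP, curve sigma; comma- or whitespace-separated).  Dendrograms are exported as
Newick text.
"""
from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .chronology import CalibrationCurve, RadiocarbonDate
from .npp import NPPSeries, Phase, PhaseTable
from .paleoclimate import PollenAssemblage, TrainingSet
from .carrying_capacity import LFARecord, ModernSiteRecord, SpeciesMass

DATE_COLUMNS = ["lab_code", "site_id", "level_id", "region", "culture",
                "method", "age", "error_1sigma", "material", "flags"]


def read_calibration_curve(path, name: str | None = None) -> CalibrationCurve:
    """Read an IntCal-dialect ``.14c`` file (first three columns used)."""
    path = Path(path)
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 3:
            raise ValueError(f"{path}: malformed curve line {line!r}")
        rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
    arr = np.asarray(rows)
    return CalibrationCurve(grid=arr[:, 0], mu14c=arr[:, 1],
                            sigma_curve=arr[:, 2],
                            name=name or path.stem)


def write_calibration_curve(curve: CalibrationCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {curve.name}\n# cal BP, 14C age BP, sigma\n")
        for g, m, s in zip(curve.grid[::-1], curve.mu14c[::-1],
                           curve.sigma_curve[::-1]):
            fh.write(f"{g:.1f},{m:.1f},{s:.1f}\n")


def read_dates_csv(path) -> list[RadiocarbonDate]:
    """Read a chronometric-date table; unknown columns are preserved in
    each date's ``extra`` mapping."""
    df = pd.read_csv(path)
    missing = [c for c in DATE_COLUMNS if c not in df.columns
               and c not in ("material", "flags")]
    if missing:
        raise ValueError(f"dates table missing columns {missing}")
    extra_cols = [c for c in df.columns if c not in DATE_COLUMNS]
    dates = []
    for _, row in df.iterrows():
        flags = frozenset()
        if "flags" in df.columns and isinstance(row.get("flags"), str) \
                and row["flags"].strip():
            flags = frozenset(row["flags"].split(";"))
        dates.append(RadiocarbonDate(
            lab_code=str(row["lab_code"]), site_id=str(row["site_id"]),
            level_id=str(row["level_id"]), region=str(row["region"]),
            culture=str(row["culture"]), method=str(row["method"]),
            age=float(row["age"]), error_1sigma=float(row["error_1sigma"]),
            material=str(row.get("material", "bone")), flags=flags,
            extra={c: row[c] for c in extra_cols}))
    return dates


def write_dates_csv(dates: Sequence[RadiocarbonDate], path) -> None:
    rows = []
    for d in dates:
        row = {"lab_code": d.lab_code, "site_id": d.site_id,
               "level_id": d.level_id, "region": d.region,
               "culture": d.culture, "method": d.method, "age": d.age,
               "error_1sigma": d.error_1sigma, "material": d.material,
               "flags": ";".join(sorted(d.flags))}
        row.update(d.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_npp_csv(path) -> list[NPPSeries]:
    """Long-format NPP table: site_id, region, time_kyr_bp, npp[, unit]."""
    df = pd.read_csv(path)
    series = []
    for (site, region), grp in df.groupby(["site_id", "region"], sort=True):
        grp = grp.sort_values("time_kyr_bp", ascending=False)
        unit = str(grp["unit"].iloc[0]) if "unit" in grp.columns \
            else "g m-2 yr-1"
        series.append(NPPSeries(site_id=str(site), region=str(region),
                                times=grp["time_kyr_bp"].to_numpy(),
                                values=grp["npp"].to_numpy(), unit=unit))
    return series


def write_npp_csv(series: Sequence[NPPSeries], path) -> None:
    rows = [{"site_id": s.site_id, "region": s.region,
             "time_kyr_bp": t, "npp": v, "unit": s.unit}
            for s in series for t, v in zip(s.times, s.values)]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_phase_table_csv(path, b2k: bool = False) -> PhaseTable:
    """Phase table CSV: name, kind, start, end (kyr BP, or kyr b2k with
    ``b2k=True``)."""
    df = pd.read_csv(path)
    rows = [(str(r["name"]), str(r["kind"]), float(r["start"]),
             float(r["end"])) for _, r in df.iterrows()]
    if b2k:
        return PhaseTable.from_b2k(rows)
    return PhaseTable([Phase(*r) for r in rows])


def write_phase_table_csv(phases: PhaseTable, path) -> None:
    pd.DataFrame([{"name": p.name, "kind": p.kind, "start": p.start,
                   "end": p.end} for p in phases.phases]
                 ).to_csv(path, index=False)


def read_pollen_csv(samples_path, meta_path=None,
                    ) -> list[PollenAssemblage]:
    """Wide pollen table: sample_id, site_id, total_count, then taxon columns
    (percentages); optional taxon metadata CSV with columns taxon,
    terrestrial."""
    df = pd.read_csv(samples_path)
    terrestrial = {}
    if meta_path is not None:
        meta = pd.read_csv(meta_path)
        terrestrial = {str(r["taxon"]): bool(r["terrestrial"])
                       for _, r in meta.iterrows()}
    id_cols = {"sample_id", "site_id", "total_count"}
    taxa_cols = [c for c in df.columns if c not in id_cols]
    out = []
    for _, row in df.iterrows():
        taxa = {t: float(row[t]) for t in taxa_cols
                if pd.notna(row[t]) and float(row[t]) > 0}
        out.append(PollenAssemblage(
            sample_id=str(row["sample_id"]), site_id=str(row["site_id"]),
            taxa=taxa, total_count=float(row["total_count"]),
            terrestrial=terrestrial))
    return out


def read_training_csv(pollen_path, climate_path) -> TrainingSet:
    """Training set from a wide pollen CSV (sample_id + taxon columns) and a
    climate CSV keyed by sample_id with MAT/MAP columns."""
    Y = pd.read_csv(pollen_path).set_index("sample_id")
    Y = Y.drop(columns=[c for c in ("site_id", "total_count")
                        if c in Y.columns])
    climate = pd.read_csv(climate_path).set_index("sample_id")
    climate = climate.loc[Y.index]
    return TrainingSet(Y=Y, climate=climate)


def write_training_csv(train: TrainingSet, pollen_path, climate_path) -> None:
    train.Y.rename_axis("sample_id").reset_index().to_csv(pollen_path,
                                                          index=False)
    train.climate.rename_axis("sample_id").reset_index().to_csv(climate_path,
                                                                index=False)


def read_modern_density_csv(path) -> list[ModernSiteRecord]:
    """Modern compilation: site, npp, taxon, density, mass_kg (long format)."""
    df = pd.read_csv(path)
    out = []
    for site, grp in df.groupby("site", sort=True):
        species = [SpeciesMass(taxon=str(r["taxon"]), W=float(r["mass_kg"]))
                   for _, r in grp.iterrows()]
        obs = {str(r["taxon"]): float(r["density"]) for _, r in grp.iterrows()}
        out.append(ModernSiteRecord(site=str(site),
                                    npp=float(grp["npp"].iloc[0]),
                                    species=species, observed_density=obs))
    return out


def write_modern_density_csv(sites: Sequence[ModernSiteRecord], path) -> None:
    rows = [{"site": s.site, "npp": s.npp, "taxon": sp.taxon,
             "density": s.observed_density.get(sp.taxon, np.nan),
             "mass_kg": sp.W} for s in sites for sp in s.species]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_lfa_csv(path) -> list[LFARecord]:
    """LFA occurrences: lfa_id, species, region, lower, upper (cal BP)."""
    df = pd.read_csv(path)
    return [LFARecord(lfa_id=str(r["lfa_id"]), species=str(r["species"]),
                      region=str(r["region"]), lower=float(r["lower"]),
                      upper=float(r["upper"])) for _, r in df.iterrows()]


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.left), walk(node.right)
        dl = node.dist - (node.left.dist if not node.left.is_leaf() else 0.0)
        dr = node.dist - (node.right.dist if not node.right.is_leaf() else 0.0)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(tree) + ";"
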
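"""End-to-end orchestration from a single YAML config.

``run_all`` executes: date filtering -> same-level combination and calibration
-> SPD and OLE boundaries per culture x region -> phase statistics, dCORT
clustering and Jaccard comparison of regional faunas -> carrying capacity per
region x phase -> a manifest recording parameters, seeds, row counts and
output hashes.  Any stage failure aborts with the stage name; path problems
are caught at validation time, before any stage runs.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chronology as chron
from . import io as pio
from . import npp as nppmod
from . import carrying_capacity as cc

DEFAULT_PARAMS = {
    "step": 20.0,
    "k": 2.0,
    "n_clusters": 3,
    "linkage": "average",
    "m": 10,
    "iters": 10000,
    "boot": 500,
    "seed": 0,
    "ole_min_dates": 3,
}


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, reason: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {reason}")


@dataclass
class RunConfig:
    paths: dict[str, str]
    parameters: dict = field(default_factory=dict)
    units: dict = field(default_factory=dict)
    output_dir: str = "out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "paths" not in raw:
            raise ConfigError("config must be a mapping with a 'paths' block")
        cfg = cls(paths=dict(raw["paths"]),
                  parameters=dict(raw.get("parameters", {})),
                  units=dict(raw.get("units", {})),
                  output_dir=str(raw.get("output_dir", "out")))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.parameters) - set(DEFAULT_PARAMS)
        if unknown:
            raise ConfigError(f"unknown parameters {sorted(unknown)}")
        for key, p in self.paths.items():
            if not Path(p).exists():
                raise ConfigError(f"path {key!r} does not exist: {p}")

    def param(self, name: str):
        return self.parameters.get(name, DEFAULT_PARAMS[name])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every configured stage; returns the manifest dict."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "runlog.jsonl"
    log_fh = open(log_path, "w")
    manifest = {"parameters": {k: config.param(k) for k in DEFAULT_PARAMS},
                "units": dict(config.units), "stages": {}, "outputs": {}}
    step = float(config.param("step"))
    seed = int(config.param("seed"))

    def log(stage: str, **info):
        rec = {"stage": stage, "time": time.time(), **info}
        log_fh.write(json.dumps(rec) + "\n")
        log_fh.flush()
        manifest["stages"][stage] = info

    try:
        phases = (pio.read_phase_table_csv(config.paths["phases"])
                  if "phases" in config.paths
                  else nppmod.default_phase_table())

        if "dates" in config.paths:
            _stage_chronology(config, out, phases, step, seed, log)
        if "npp" in config.paths:
            _stage_npp(config, out, phases, log)
        if "densities" in config.paths:
            _stage_capacity(config, out, phases, log)
    finally:
        log_fh.close()

    for p in sorted(out.glob("*")):
        if p.name not in ("manifest.json", "runlog.jsonl") and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stage_chronology(config, out: Path, phases, step, seed, log):
    try:
        curve = (pio.read_calibration_curve(config.paths["curve"])
                 if "curve" in config.paths else None)
        dates = pio.read_dates_csv(config.paths["dates"])
        kept, removed = chron.filter_for_spd(dates)
        pd.DataFrame([{"lab_code": d.lab_code, "reasons": ";".join(r)}
                      for d, r in removed]
                     ).to_csv(out / "removed_dates.csv", index=False)
        log("filter_dates", n_in=len(dates), n_kept=len(kept),
            n_removed=len(removed))

        groups = sorted({(d.region, d.culture) for d in kept})
        spd_rows, boundary_rows = [], []
        for region, culture in groups:
            sub = [d for d in kept
                   if d.region == region and d.culture == culture]
            asm = chron.build_assemblages(sub, curve, step)
            grid, total = chron.spd(asm, step)
            spd_rows.extend({"region": region, "culture": culture,
                             "cal_bp": g, "spd": s}
                            for g, s in zip(grid, total))
            for which, bname in (("youngest", "end"), ("oldest", "start")):
                try:
                    ss = chron.select_terminal_dates(
                        sub, curve, which=which, m=int(config.param("m")),
                        step=step)
                    est = chron.ole_resample(
                        ss, n_iter=int(config.param("iters")), seed=seed)
                except chron.ChronologyError:
                    continue
                boundary_rows.append({
                    "region": region, "culture": culture, "boundary": bname,
                    "median": est.point, "lower": est.ci95[0],
                    "upper": est.ci95[1], "n_iter": est.n_iter,
                    "k": ss.k})
        pd.DataFrame(spd_rows).to_csv(out / "spd.csv", index=False)
        pd.DataFrame(boundary_rows).to_csv(out / "boundaries.csv",
                                           index=False)
        log("chronology", n_groups=len(groups),
            n_boundaries=len(boundary_rows))
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError("chronology", exc) from exc


def _stage_npp(config, out: Path, phases, log):
    try:
        series = pio.read_npp_csv(config.paths["npp"])
        k = float(config.param("k"))
        D = nppmod.dissimilarity_matrix(series, k)
        labels, Z = nppmod.cluster_series(
            D, n_clusters=int(config.param("n_clusters")),
            linkage=str(config.param("linkage")))
        pd.DataFrame({"site_id": [s.site_id for s in series],
                      "region": [s.region for s in series],
                      "cluster": labels}).to_csv(out / "clusters.csv",
                                                 index=False)
        comp = nppmod.cluster_region_composition(
            labels, [s.region for s in series])
        comp.to_csv(out / "cluster_composition.csv")
        (out / "dendrogram.nwk").write_text(
            pio.linkage_to_newick(Z, [s.site_id for s in series]))

        rows = []
        for region in sorted({s.region for s in series}):
            rs = [s for s in series if s.region == region]
            st = nppmod.phase_stats(rs, phases)
            for kind in ("stadial", "interstadial"):
                rows.append({"region": region, "period": kind,
                             "mean": st[kind]["mean"], "sd": st[kind]["sd"],
                             "cv_percent": st[kind]["cv_percent"],
                             "W": st["wilcoxon"]["W"],
                             "p": st["wilcoxon"]["p"]})
        pd.DataFrame(rows).to_csv(out / "phase_stats.csv", index=False)
        log("npp_dynamics", n_series=len(series),
            n_clusters=int(labels.max()))
    except Exception as exc:  # noqa: BLE001
        raise StageError("npp_dynamics", exc) from exc


def _stage_capacity(config, out: Path, phases, log):
    try:
        modern = pio.read_modern_density_csv(config.paths["densities"])
        npp = [s.npp for s in modern]
        thb = [sum(d * sp.W for sp in s.species
                   for t, d in s.observed_density.items() if t == sp.taxon)
               for s in modern]
        model = cc.fit_thb_model(npp, thb)
        with open(out / "thb_model.json", "w") as fh:
            json.dump({"slope": model.slope, "intercept": model.intercept,
                       "slope_ci": model.slope_ci,
                       "intercept_ci": model.intercept_ci,
                       "n": model.n_fit}, fh, indent=2)
        report = cc.validate_model(modern, model)
        with open(out / "validation.json", "w") as fh:
            json.dump({"pooled": report["pooled"],
                       "fraction_significant": report["fraction_significant"],
                       "n_sites": len(report["per_site"]),
                       "skipped": report["skipped_sites"]}, fh, indent=2)
        rows = []
        if "lfas" in config.paths and "masses" in config.paths:
            lfas = pio.read_lfa_csv(config.paths["lfas"])
            masses = pd.read_csv(config.paths["masses"])
            mass_map = {str(r["taxon"]): float(r["mass_kg"])
                        for _, r in masses.iterrows()}
            npp_series = (pio.read_npp_csv(config.paths["npp"])
                          if "npp" in config.paths else [])
            communities = cc.minimum_census(lfas, phases)
            for (region, phase), pc in sorted(communities.items()):
                rs = [s for s in npp_series if s.region == region]
                if not rs:
                    continue
                ph = phases.by_name(phase)
                vals = np.concatenate(
                    [s.values[(s.times > ph.end) & (s.times <= ph.start)]
                     for s in rs])
                if len(vals) == 0:
                    continue
                species = [cc.SpeciesMass(t, mass_map[t]) for t in pc.species
                           if t in mass_map]
                if not species:
                    continue
                thb_est = cc.predict_thb(float(vals.mean()), model)
                res = cc.partition_biomass(thb_est, species)
                row = {"region": region, "phase": phase,
                       "npp_mean": float(vals.mean()), "THB": res.THB,
                       "n_species": len(species)}
                row.update({f"biomass_{k}": v
                            for k, v in res.size_class_totals.items()})
                rows.append(row)
            pd.DataFrame(rows).to_csv(out / "carrying_capacity.csv",
                                      index=False)
        log("carrying_capacity", n_modern=len(modern),
            n_communities=len(rows))
    except Exception as exc:  # noqa: BLE001
        raise StageError("carrying_capacity", exc) from exc


def emit_tables(manifest: dict, output_dir) -> dict:
    """Re-encode the phase-statistics and boundary tables as JSON, checking
    CSV/JSON number identity."""
    out = Path(output_dir)
    emitted = {}
    for name in ("phase_stats", "boundaries"):
        csv_path = out / f"{name}.csv"
        if not csv_path.exists():
            continue
        df = pd.read_csv(csv_path)
        payload = df.to_dict(orient="records")
        with open(out / f"{name}.json", "w") as fh:
            json.dump(payload, fh, indent=2)
        emitted[name] = payload
    return emitted
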
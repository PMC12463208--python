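"""End-to-end orchestration: simulate/load -> match -> expose -> fit -> burden.

Note on stage order: exposure is evaluated at each matched-set member's
reference date, so matched sets are built before exposure profiles are
assigned.  Every stage writes its table under the output directory, and the
manifest records the config hash, seed and per-stage row counts so reruns
can be compared bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from . import matching, model, synthetic_data
from .exposure import build_exposure_profiles, exposure_events, interpolate_track, read_tracks

log = logging.getLogger("cyclomort")

INPUT_NAMES = ("children", "clusters", "tracks", "weather", "grid")


@dataclasses.dataclass
class RunConfig:
    """One pipeline run: either a simulate block or the five input paths."""

    seed: int = 0
    outdir: str = "cyclomort_run"
    simulate: synthetic_data.SimConfig | None = None
    paths: dict[str, str] | None = None
    model: model.ModelSpec = dataclasses.field(default_factory=model.ModelSpec)
    stratifiers: tuple[str, ...] = ()
    sensitivity: bool = False
    burden: bool = True
    burden_years: tuple[int, ...] | None = None
    grid_spacing_km: float = 50.0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.simulate is None and self.paths is None:
            raise ValueError("config needs either a 'simulate' block or 'paths'")
        if self.paths is not None:
            missing = [n for n in INPUT_NAMES if n not in self.paths]
            if missing:
                raise ValueError(f"missing input paths: {missing}")

    @classmethod
    def from_yaml(cls, path, seed: int | None = None,
                  outdir: str | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if seed is not None:
            raw["seed"] = seed
        if outdir is not None:
            raw["outdir"] = outdir
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim.setdefault("seed", raw.get("seed", 0))
            for key in ("children_per_mother_range", "r34_range_km"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "study_window" in sim:
                sim["study_window"] = tuple(sim["study_window"])
            if "bbox" in sim:
                sim["bbox"] = tuple(sim["bbox"])
            if "death_age_distribution" in sim:
                sim["death_age_distribution"] = tuple(sim["death_age_distribution"])
            sim = synthetic_data.SimConfig(**sim)
        spec = raw.pop("model", None)
        spec = model.ModelSpec(**spec) if spec else model.ModelSpec()
        raw["stratifiers"] = tuple(raw.get("stratifiers", ()))
        if raw.get("burden_years"):
            raw["burden_years"] = tuple(raw["burden_years"])
        return cls(simulate=sim, model=spec, **raw)

    def canonical(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir", None)     # where a run writes does not change results
        d.pop("log_level", None)
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _load_inputs(cfg: RunConfig, outdir: Path) -> dict[str, pd.DataFrame]:
    if cfg.simulate is not None:
        sim = dataclasses.replace(cfg.simulate, seed=cfg.seed)
        years = cfg.burden_years or tuple(
            range(sim.window[1].year - 2, sim.window[1].year + 1))
        tracks = synthetic_data.generate_tracks(sim)
        clusters = synthetic_data.generate_clusters(sim)
        children, clusters = synthetic_data.generate_cohort(
            sim, tracks=tracks, clusters=clusters)
        wx_seed = int(np.random.SeedSequence(sim.seed).spawn(8)[3]
                      .generate_state(1)[0] % (2 ** 31))
        weather = synthetic_data.generate_weather(clusters, sim.study_window, wx_seed)
        grid = synthetic_data.generate_grid(sim, years,
                                            spacing_km=cfg.grid_spacing_km)
        data = {"children": children, "clusters": clusters, "tracks": tracks,
                "weather": weather, "grid": grid}
        for name, df in data.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        return data
    data = {}
    for name in INPUT_NAMES:
        df = pd.read_csv(cfg.paths[name])
        if name == "children":
            for c in ("birth_date", "interview_date", "maternal_birth_date"):
                if c in df:
                    df[c] = pd.to_datetime(df[c])
        if name == "tracks":
            df = read_tracks(df) if "r34" in {c.lower() for c in df.columns} else df
            df["time"] = pd.to_datetime(df["time"])
        data[name] = df
    return data


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage and return the artifact directory."""
    logging.basicConfig(level=cfg.log_level)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    data = _load_inputs(cfg, outdir)
    for name, df in data.items():
        counts[f"input_{name}_rows"] = len(df)

    dense = interpolate_track(data["tracks"], step_minutes=60)
    events = exposure_events(data["clusters"][["cluster_id", "lat", "lon"]], dense)
    exposed_countries = None
    if "country" in data["clusters"].columns and not events.empty:
        cl2c = dict(zip(data["clusters"]["cluster_id"], data["clusters"]["country"]))
        exposed_countries = {cl2c[c] for c in events["cluster_id"].unique()}

    children, excl_log = matching.apply_exclusions(
        data["children"], data["clusters"], exposed_countries=exposed_countries)
    sets, match_log = matching.build_matched_sets(children)
    counts["matched_set_members"] = len(sets)
    sets_out = sets[["set_id", "role", "child_id", "reference_date"]]
    sets_out.to_csv(outdir / "matched_sets.csv", index=False,
                    date_format="%Y-%m-%d")
    with open(outdir / "exclusion_log.json", "w") as fh:
        json.dump({"exclusions": excl_log, "matching": match_log}, fh, indent=2)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(matching.summarize(sets), fh, indent=2, default=str)

    analysis = build_exposure_profiles(sets, data["clusters"], data["tracks"],
                                       data["weather"])
    analysis.to_csv(outdir / "analysis.csv", index=False, date_format="%Y-%m-%d")
    counts["analysis_rows"] = len(analysis)

    fits = {}
    for window in ("lag0", "lag1", "lag2", "lag02"):
        spec = dataclasses.replace(cfg.model, exposure_window=window)
        try:
            fits[window] = model.clogit_fit(analysis, spec).to_dict()
        except ValueError as exc:
            fits[window] = {"error": str(exc)}
    with open(outdir / "fit.json", "w") as fh:
        json.dump(fits, fh, indent=2)

    if cfg.stratifiers:
        strat_out = {}
        for s in cfg.stratifiers:
            per, pairs = model.stratified_analysis(analysis, s, cfg.model)
            strat_out[s] = {
                "fits": {k: f.to_dict() for k, f in per.items()},
                "pairwise_z": pairs.to_dict(orient="records"),
            }
        with open(outdir / "stratified.json", "w") as fh:
            json.dump(strat_out, fh, indent=2)

    if cfg.sensitivity:
        sens = model.sensitivity_suite(analysis, cfg.model)
        with open(outdir / "sensitivity.json", "w") as fh:
            json.dump({k: v.to_dict() if isinstance(v, model.FitResult) else v
                       for k, v in sens.items()}, fh, indent=2)

    if cfg.burden:
        main = fits.get("lag0", {})
        if "or_" in main:
            grid = burden_mod.grid_exposure_counts(data["grid"], data["tracks"])
            per_cell, summary = burden_mod.excess_deaths(
                grid, main["or_"], main["ci_low"], main["ci_high"])
            per_cell.to_csv(outdir / "burden.csv", index=False)
            with open(outdir / "burden_summary.json", "w") as fh:
                json.dump(summary, fh, indent=2, default=str)
            counts["burden_rows"] = len(per_cell)
        else:
            log.warning("burden skipped: lag0 fit unavailable")

    manifest = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                "row_counts": counts}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir
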
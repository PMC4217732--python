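"""Configuration-driven orchestration of the full analysis.

Stages run in order: synthgen -> community -> landcover -> lmselect ->
scenario -> project.  Each stage writes plain-text outputs (ASCII grids,
CSV, JSON) into the run directory and records a block in the machine-
readable run report.  A stage that is requested without its upstream stages
reloads their outputs from disk, so re-running a tail of the pipeline is
cheap, and re-running the whole pipeline with an identical config
reproduces identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as comm
from . import landcover, lmselect, project, scenario as scen, synthgen
from .grids import (Landscape, read_ascii_grid, read_landscape, write_ascii_grid,
                    write_landscape)

STAGES = ("synthgen", "community", "landcover", "lmselect", "scenario", "project")

METRICS = ("abundance", "diversity", "composition")

DEFAULT_CLASS_WEIGHTS = {
    "wind": 0.30, "flowering_annual": 0.15, "grassland": 0.20, "forest": 0.20,
    "perennial_flowering": 0.02, "wetland": 0.04, "suburb": 0.05,
    "city": 0.02, "other": 0.02,
}

DEFAULT_MARGINAL_FRACTIONS = {"grassland": 0.55, "wind": 0.25, "flowering_annual": 0.25}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration with defaults filled in."""

    outdir: str = "out"
    seed: int = 0
    radius_m: float = 1500.0
    n_rows: int = 400
    n_cols: int = 400
    cell_size: float = 100.0
    patchiness: float = 600.0
    class_weights: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))
    marginal_fraction_by_class: dict = field(
        default_factory=lambda: dict(DEFAULT_MARGINAL_FRACTIONS))
    n_sites: int = 20
    min_separation_m: float = 3000.0
    visits_per_site: tuple[int, int] = (3, 5)
    delta_cutoff: float | None = None
    n_perm: int = 199
    nmds_starts: int = 20
    annual_area_ha: float = 6000.0
    perennial_wind_area_ha: float = 3600.0
    perennial_fa_area_ha: float = 2400.0


_KNOWN_KEYS = set(RunConfig.__dataclass_fields__)


def validate_config(raw: dict | RunConfig) -> RunConfig:
    """Cross-check a raw config mapping and fill defaults.

    Raises ConfigError with an itemized report of every problem found.
    """
    if isinstance(raw, RunConfig):
        raw = asdict(raw)
    problems: list[str] = []
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")
    merged = asdict(RunConfig()) | {k: v for k, v in raw.items() if k in _KNOWN_KEYS}
    if merged["radius_m"] <= 0:
        problems.append(f"radius_m must be positive, got {merged['radius_m']}")
    if merged["radius_m"] < merged["cell_size"]:
        problems.append("radius_m is smaller than one cell")
    if merged["n_sites"] <= 0:
        problems.append("n_sites must be positive")
    weights = merged["class_weights"]
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        problems.append(f"class_weights sum to {total}, expected 1")
    from .grids import CLASS_CODES
    known_classes = set(CLASS_CODES.values())
    for key in ("class_weights", "marginal_fraction_by_class"):
        bad = set(merged[key]) - known_classes
        if bad:
            problems.append(f"{key} references unknown classes {sorted(bad)}")
    # scenario sources must be mapped classes with a marginal fraction
    for src in ("grassland", "wind", "flowering_annual"):
        if src not in weights or weights[src] <= 0:
            problems.append(f"scenario source class {src!r} has no cover weight")
    lo, hi = tuple(merged["visits_per_site"])
    if not (1 <= lo <= hi):
        problems.append(f"visits_per_site range {merged['visits_per_site']} invalid")
    if problems:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(problems))
    merged["visits_per_site"] = (int(lo), int(hi))
    return RunConfig(**merged)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return validate_config(raw)


# ---------------------------------------------------------------------------
# stages


def _write_csv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, index=index, float_format="%.10g")


def _stage_synthgen(cfg: RunConfig, out: Path, state: dict) -> dict:
    spec = synthgen.LandscapeSpec(
        n_rows=cfg.n_rows, n_cols=cfg.n_cols, cell_size=cfg.cell_size,
        class_weights=cfg.class_weights,
        marginal_fraction_by_class=cfg.marginal_fraction_by_class,
        patchiness=cfg.patchiness, seed=cfg.seed,
    )
    landscape = synthgen.generate_landscape(spec)
    # sites are stratified along the grassland gradient, emulating a design
    # where fields are chosen to span annual-crop- to grassland-dominated
    # landscapes
    gradient = landcover.proportion_surface(landscape.cover, "grassland",
                                            cfg.radius_m, cfg.cell_size)
    sites = synthgen.generate_sites(landscape, cfg.n_sites, cfg.min_separation_m,
                                    seed=cfg.seed, edge_margin=cfg.radius_m,
                                    gradient=gradient)
    props = landcover.class_proportions_at_points(landscape, sites, cfg.radius_m)
    truth = synthgen.TruthParams()
    surveys = synthgen.generate_surveys(sites, props, truth,
                                        visits_per_site=cfg.visits_per_site,
                                        seed=cfg.seed)
    paths = write_landscape(landscape, out)
    _write_csv(synthgen.sites_to_frame(sites), out / "sites.csv", index=False)
    _write_csv(props, out / "site_proportions.csv")
    _write_csv(surveys, out / "surveys.csv", index=False)
    state.update(landscape=landscape, sites=sites, site_props=props, surveys=surveys)
    return {
        "seed": cfg.seed,
        "class_fractions": landscape.class_fractions(),
        "n_sites": len(sites),
        "n_survey_rows": int(len(surveys)),
        "files": [str(p) for p in paths.values()]
        + [str(out / f) for f in ("sites.csv", "site_proportions.csv", "surveys.csv")],
    }


def _need(state: dict, key: str, out: Path):
    if key in state:
        return state[key]
    loaders = {
        "landscape": lambda: read_landscape(out),
        "surveys": lambda: pd.read_csv(out / "surveys.csv"),
        "site_props": lambda: pd.read_csv(out / "site_proportions.csv", index_col="site_id"),
        "sites": lambda: synthgen.frame_to_sites(pd.read_csv(out / "sites.csv")),
        "metrics": lambda: pd.read_csv(out / "site_metrics.csv", index_col="site_id"),
    }
    try:
        state[key] = loaders[key]()
    except FileNotFoundError as err:
        raise ConfigError(f"stage input {key!r} not in memory and not on disk: {err}") from err
    return state[key]


def _stage_community(cfg: RunConfig, out: Path, state: dict) -> dict:
    surveys = _need(state, "surveys", out)
    props = _need(state, "site_props", out)
    abundance = comm.site_abundance(surveys)
    diversity = comm.site_diversity(surveys)
    matrix = comm.build_community_matrix(surveys)
    dist = comm.bray_curtis(matrix)
    ordination = comm.nmds(dist, k=2, n_starts=cfg.nmds_starts, seed=cfg.seed)
    ordination = comm.orient_axis(ordination, props["wind"])
    fits = comm.envfit(ordination, props, n_perm=cfg.n_perm, seed=cfg.seed)
    groups = {s: ("high" if v > 0 else "low") for s, v in ordination.axis(1).items()}
    simper_table = comm.simper(matrix, groups)
    metrics = pd.DataFrame({
        "abundance": abundance,
        "diversity": diversity,
        "composition": ordination.axis(1),
    })
    _write_csv(metrics, out / "site_metrics.csv")
    _write_csv(matrix.values, out / "community_matrix.csv")
    _write_csv(pd.DataFrame(dist.values, index=dist.ids, columns=dist.ids),
               out / "bray_curtis.csv")
    _write_csv(ordination.scores, out / "nmds_scores.csv")
    envfit_frame = pd.DataFrame(
        [{"variable": f.variable, "r2": f.r2, "p_value": f.p_value,
          **{f"dir{i + 1}": v for i, v in enumerate(f.direction)}} for f in fits])
    _write_csv(envfit_frame, out / "envfit.csv", index=False)
    _write_csv(simper_table, out / "simper.csv", index=False)
    state.update(metrics=metrics, ordination=ordination)
    return {
        "nmds_stress": ordination.stress,
        "nmds_converged": bool(ordination.converged),
        "envfit": {f.variable: {"r2": f.r2, "p": f.p_value} for f in fits},
        "top_simper_species": simper_table["species"].head(3).tolist(),
        "files": [str(out / f) for f in
                  ("site_metrics.csv", "community_matrix.csv", "bray_curtis.csv",
                   "nmds_scores.csv", "envfit.csv", "simper.csv")],
    }


def _stage_landcover(cfg: RunConfig, out: Path, state: dict) -> dict:
    landscape = _need(state, "landscape", out)
    stack = landcover.proportion_stack(landscape, cfg.radius_m)
    files = []
    for name, band in stack.bands().items():
        path = out / f"prop_{name}.asc"
        write_ascii_grid(path, band.astype(np.float32), cfg.cell_size)
        files.append(str(path))
    state["stack"] = stack
    return {"radius_m": cfg.radius_m, "files": files}


def _load_stack(cfg: RunConfig, out: Path) -> landcover.ProportionStack:
    bands = {}
    for name in ("grassland", "forest", "wind", "flowering_annual"):
        values, cell_size, _ = read_ascii_grid(out / f"prop_{name}.asc")
        bands[name] = values
    return landcover.ProportionStack(radius=cfg.radius_m, cell_size=cfg.cell_size, **bands)


def _stage_lmselect(cfg: RunConfig, out: Path, state: dict) -> dict:
    metrics = _need(state, "metrics", out)
    props = _need(state, "site_props", out)
    sites = _need(state, "sites", out)
    coords = np.array([[s.x, s.y] for s in sites])
    site_order = [s.site_id for s in sites]
    averaged: dict[str, lmselect.AveragedModel] = {}
    block: dict = {}
    files = []
    for metric in METRICS:
        y = metrics[metric]
        models = lmselect.enumerate_models(y, props, metric=metric)
        avg = lmselect.average_coefficients(models, delta_cutoff=cfg.delta_cutoff)
        pred = pd.Series(avg.predict(props), index=props.index)
        avg.pseudo_r2 = lmselect.pseudo_r2(y, pred)
        resid = (y - pred).reindex(site_order).to_numpy()
        correlogram = lmselect.residual_correlogram(resid, coords, n_perm=cfg.n_perm,
                                                    seed=cfg.seed)
        table_path = out / f"model_table_{metric}.csv"
        _write_csv(models.table(), table_path, index=False)
        corr_path = out / f"correlogram_{metric}.csv"
        _write_csv(pd.DataFrame({
            "bin_centre_m": correlogram.bin_centres,
            "morans_i": correlogram.morans_i,
            "n_pairs": correlogram.n_pairs,
            "env_low": correlogram.envelope_low,
            "env_high": correlogram.envelope_high,
            "significant": correlogram.significant,
        }), corr_path, index=False)
        files += [str(table_path), str(corr_path)]
        averaged[metric] = avg
        block[metric] = {
            "intercept": avg.intercept,
            "coefficients": avg.coefficients,
            "variable_weights": avg.variable_weights,
            "pseudo_r2": avg.pseudo_r2,
            "best_subset": list(models.fits[0].predictors),
            "residual_autocorrelation_detected": correlogram.any_significant(),
        }
    models_path = out / "averaged_models.json"
    with open(models_path, "w") as fh:
        json.dump({m: {"metric": m, "intercept": a.intercept,
                       "coefficients": a.coefficients,
                       "variable_weights": a.variable_weights,
                       "pseudo_r2": a.pseudo_r2}
                   for m, a in averaged.items()}, fh, indent=2)
    files.append(str(models_path))
    state["averaged"] = averaged
    block["files"] = files
    return block


def _load_averaged(out: Path) -> dict[str, lmselect.AveragedModel]:
    with open(out / "averaged_models.json") as fh:
        raw = json.load(fh)
    return {m: lmselect.AveragedModel(metric=m, intercept=d["intercept"],
                                      coefficients=d["coefficients"],
                                      variable_weights=d.get("variable_weights", {}),
                                      pseudo_r2=d.get("pseudo_r2", float("nan")))
            for m, d in raw.items()}


def _stage_scenario(cfg: RunConfig, out: Path, state: dict) -> dict:
    landscape = _need(state, "landscape", out)
    specs = {
        "annual": scen.annual_scenario(cfg.annual_area_ha, seed=cfg.seed + 1),
        "perennial": scen.perennial_scenario(cfg.perennial_wind_area_ha,
                                             cfg.perennial_fa_area_ha,
                                             seed=cfg.seed + 2),
    }
    results = {}
    block: dict = {}
    files = []
    for name, spec in specs.items():
        result = scen.convert(landscape, spec)
        results[name] = result
        cover_path = out / f"scenario_{name}_cover.asc"
        changed_path = out / f"scenario_{name}_changed.asc"
        write_ascii_grid(cover_path, result.cover_after.astype(np.int16),
                         cfg.cell_size, fmt="%d")
        write_ascii_grid(changed_path, result.changed.astype(np.uint8),
                         cfg.cell_size, fmt="%d")
        files += [str(cover_path), str(changed_path)]
        block[name] = {
            "seed": spec.seed,
            "converted_area_ha": {f"{s}->{t}": ha
                                  for (s, t), ha in result.converted_area_ha.items()},
            "n_changed_cells": int(result.changed.sum()),
        }
    state["scenarios"] = results
    block["files"] = files
    return block


def _load_scenarios(cfg: RunConfig, out: Path,
                    landscape: Landscape) -> dict[str, scen.ScenarioResult]:
    results = {}
    for name in ("annual", "perennial"):
        cover, _, _ = read_ascii_grid(out / f"scenario_{name}_cover.asc")
        changed, _, _ = read_ascii_grid(out / f"scenario_{name}_changed.asc")
        results[name] = scen.ScenarioResult(
            cover_after=cover.astype(np.int16),
            changed=changed.astype(bool), converted_area_ha={})
    return results


def _stage_project(cfg: RunConfig, out: Path, state: dict) -> dict:
    landscape = _need(state, "landscape", out)
    if "stack" not in state:
        try:
            state["stack"] = _load_stack(cfg, out)
        except FileNotFoundError:
            state["stack"] = landcover.proportion_stack(landscape, cfg.radius_m)
    if "averaged" not in state:
        state["averaged"] = _load_averaged(out)
    if "scenarios" not in state:
        state["scenarios"] = _load_scenarios(cfg, out, landscape)
    stack = state["stack"]
    averaged = state["averaged"]
    scenarios = state["scenarios"]

    summary_rows = []
    files = []
    block: dict = {}
    for name, result in scenarios.items():
        scen_landscape = Landscape(result.cover_after, landscape.marginal,
                                   landscape.cell_size, landscape.class_codes)
        scen_stack = landcover.proportion_stack(scen_landscape, cfg.radius_m)
        for metric in METRICS:
            model = averaged[metric]
            current = project.predict_surface(stack, model)
            future = project.predict_surface(scen_stack, model)
            if metric == "composition":
                change = project.difference_surface(current, future)
                kind = "difference"
            else:
                change = project.percent_change_surface(current, future)
                kind = "percent"
            path = out / f"change_{name}_{metric}.asc"
            write_ascii_grid(path, change.astype(np.float32), cfg.cell_size)
            files.append(str(path))
            for summary in (project.landscape_summary(change, landscape),
                            project.local_summary(change, result.changed)):
                summary_rows.append({
                    "scenario": name, "metric": metric, "kind": kind,
                    **asdict(summary),
                })
    summaries = pd.DataFrame(summary_rows)
    path = out / "change_summaries.csv"
    _write_csv(summaries, path, index=False)
    files.append(str(path))
    block["summaries"] = summary_rows
    block["files"] = files
    state["summaries"] = summaries
    return block


_STAGE_FUNCS = {
    "synthgen": _stage_synthgen,
    "community": _stage_community,
    "landcover": _stage_landcover,
    "lmselect": _stage_lmselect,
    "scenario": _stage_scenario,
    "project": _stage_project,
}


def run_pipeline(config: RunConfig | dict, stages: tuple[str, ...] | str = "all",
                 outdir: str | Path | None = None) -> dict:
    """Run the requested stages in canonical order and write a run report."""
    cfg = validate_config(config if isinstance(config, (dict, RunConfig)) else dict(config))
    out = Path(outdir if outdir is not None else cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if stages == "all":
        wanted = STAGES
    else:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        wanted = tuple(s for s in STAGES if s in stages)
    state: dict = {}
    report: dict = {"seed": cfg.seed, "stages": {}, "config": asdict(cfg)}
    for stage in wanted:
        report["stages"][stage] = _STAGE_FUNCS[stage](cfg, out, state)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
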
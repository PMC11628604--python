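"""Pipeline orchestration: simulate -> segment -> measure -> test.

`run_all` executes the full synthetic study under one global seed (fanned
out to per-stage child seeds), writes per-stage CSV tables, a deterministic
machine-readable summary JSON of every statistic, and a run log that echoes
the configuration.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConfigurationError, PipelineStageError, child_seed
from . import synthetic, features, plaques, instances, spatial, spots, stats
from .io import load_yaml

DEFAULT_ANALYSES = ("dose_response", "microglia_regression", "spot_anova",
                    "treatment_contrast")


@dataclass
class RunConfig:
    output_dir: str = "gliaquant_run"
    seed: int = 0
    groups: object = "default"           # "default" or list of GroupSpec kwargs
    include_plx_arms: bool = False
    mice_per_group: int = 6
    fovs_per_mouse: int = 3
    pixel_size_um: float = synthetic.DEFAULT_PIXEL_SIZE_UM
    fov_size_um: float = synthetic.FOV_40X_UM
    render_fovs_per_group: int = 1
    association_threshold_um: float = spatial.ASSOCIATION_THRESHOLD_UM
    fusion: instances.FusionConfig = field(default_factory=instances.FusionConfig)
    spot_config: spots.SpotDetectionConfig = field(
        default_factory=spots.SpotDetectionConfig)
    spot_frames_per_group: int = 3
    analyses: tuple = DEFAULT_ANALYSES

    def group_specs(self) -> list:
        if self.groups == "default":
            specs = synthetic.default_groups()
        else:
            specs = [g if isinstance(g, synthetic.GroupSpec)
                     else synthetic.GroupSpec(**g) for g in self.groups]
        if self.include_plx_arms:
            specs = specs + [synthetic.plx_treated(s) for s in specs
                             if s.plaque_density > 0]
        return specs


def validate_config(source) -> tuple[RunConfig, list[str]]:
    """Normalize a config mapping or YAML path into a RunConfig.

    Fills defaults (with a logged warning for a missing pixel size), checks
    units and cross-field constraints; raises ConfigurationError listing
    every violation with its field path.
    """
    raw = load_yaml(source) if isinstance(source, (str, Path)) else dict(source)
    warnings_out = []
    errors = []
    if "pixel_size_um" not in raw:
        warnings_out.append("pixel_size_um missing: default 0.43 µm/px used")
    fusion_raw = raw.pop("fusion", {})
    spot_raw = raw.pop("spot_config", {})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    for k in sorted(unknown):
        errors.append(f"{k}: unknown field")
        raw.pop(k)
    try:
        fusion = instances.FusionConfig(**fusion_raw)
    except (ConfigurationError, TypeError) as e:
        errors.append(f"fusion: {e}")
        fusion = instances.FusionConfig()
    try:
        spot_cfg = spots.SpotDetectionConfig(**spot_raw)
    except (ConfigurationError, TypeError) as e:
        errors.append(f"spot_config: {e}")
        spot_cfg = spots.SpotDetectionConfig()
    cfg = RunConfig(**raw, fusion=fusion, spot_config=spot_cfg)
    if cfg.pixel_size_um <= 0:
        errors.append("pixel_size_um: must be > 0 (µm per pixel)")
    if cfg.fov_size_um <= 2 * cfg.pixel_size_um:
        errors.append("fov_size_um: must span more than two pixels")
    if cfg.association_threshold_um < 0:
        errors.append("association_threshold_um: must be >= 0")
    if cfg.mice_per_group < 1:
        errors.append("mice_per_group: must be >= 1")
    if errors:
        raise ConfigurationError("; ".join(errors))
    return cfg, warnings_out


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except PipelineStageError:
                raise
            except Exception as e:  # noqa: BLE001 - rewrap with stage name
                raise PipelineStageError(name, str(e)) from e
        return wrapped
    return deco


@_stage("simulate")
def _simulate(cfg: RunConfig):
    cohort_cfg = synthetic.CohortConfig(
        groups=cfg.group_specs(), mice_per_group=cfg.mice_per_group,
        fovs_per_mouse=cfg.fovs_per_mouse,
        rng_seed=child_seed(cfg.seed, "simulate"))
    table = synthetic.simulate_cohort_table(cohort_cfg)
    rendered = []
    for spec in cfg.group_specs():
        for k in range(cfg.render_fovs_per_group):
            fov, gt = synthetic.generate_fov(
                spec, child_seed(cfg.seed, f"render/{spec.name}/{spec.treatment}/{k}"),
                pixel_size_um=cfg.pixel_size_um, fov_size_um=cfg.fov_size_um)
            rendered.append((spec, k, fov, gt))
    return table, rendered


@_stage("plaques")
def _plaque_stage(cfg: RunConfig, rendered):
    rows, per_plaque = [], []
    masks = {}
    for spec, k, fov, gt in rendered:
        chan = fov.channel("plaque")
        mask = features.threshold_plaques(chan, noise_floor_sigmas=6.0)
        labels, recs = plaques.segment_plaques(mask.mask, fov.pixel_size_um)
        plaques.compute_plaque_asm(chan, labels, recs)
        summ = plaques.summarize_fov(recs, fov)
        # association runs against the segmented (>= min diameter) plaque
        # area, so Otsu noise speckles in plaque-free FOVs do not count
        masks[(spec.name, spec.treatment, k)] = labels > 0
        rows.append(dict(group=spec.name, treatment=spec.treatment, fov=k,
                         n_plaques=summ.n_plaques,
                         area_fraction=summ.area_fraction,
                         true_n_plaques=gt.n_plaques))
        for r in recs:
            per_plaque.append(dict(group=spec.name, treatment=spec.treatment,
                                   fov=k, **vars(r)))
    return pd.DataFrame(rows), pd.DataFrame(per_plaque), masks


@_stage("microglia")
def _microglia_stage(cfg: RunConfig, rendered, plaque_masks):
    per_cell, rows = [], []
    for spec, k, fov, gt in rendered:
        chan = fov.channel("microglia")
        sem = features.threshold_plaques(chan)  # Otsu semantic mask
        labels, soma = instances.segment_microglia(
            chan, sem, cfg.fusion, fov.pixel_size_um)
        body, _ = instances.split_body_process(sem, cfg.fusion, fov.pixel_size_um)
        df = spatial.measure_microglia(
            labels, body, plaque_masks[(spec.name, spec.treatment, k)],
            fov.pixel_size_um, threshold_um=cfg.association_threshold_um)
        n_pa = int(df["plaque_associated"].sum()) if len(df) else 0
        rows.append(dict(group=spec.name, treatment=spec.treatment, fov=k,
                         n_microglia=len(df), n_pa=n_pa,
                         n_nonpa=len(df) - n_pa,
                         true_n_microglia=gt.n_microglia))
        if len(df):
            df.insert(0, "group", spec.name)
            df.insert(1, "treatment", spec.treatment)
            df.insert(2, "fov", k)
            per_cell.append(df)
    cells = pd.concat(per_cell, ignore_index=True) if per_cell else pd.DataFrame()
    return pd.DataFrame(rows), cells


@_stage("spots")
def _spot_stage(cfg: RunConfig, table):
    det_rows = []
    for spec in cfg.group_specs():
        for f in range(cfg.spot_frames_per_group):
            fov, gt = synthetic.generate_simpull_fov(
                spec, child_seed(cfg.seed, f"spotframe/{spec.name}/{spec.treatment}/{f}"))
            rec = spots.detect_spots(fov.channel("spots"), cfg.spot_config,
                                     frame_id=f, mouse_id=spec.name)
            det_rows.append(dict(group=spec.name, treatment=spec.treatment,
                                 frame=f, detected=rec.n_spots,
                                 truth=gt.n_spots))
    return pd.DataFrame(det_rows)


@_stage("stats")
def _stats_stage(cfg: RunConfig, table):
    out = {}
    log = []
    mice = table.mice
    if "dose_response" in cfg.analyses:
        rows = []
        for (g, t), sub in mice.groupby(["group", "treatment"]):
            if sub["apoe_level"].nunique() < 3:
                log.append(f"dose_response: group {g}/{t} skipped "
                           "(APOE level nearly constant)")
                continue
            r = stats.ols_fit(sub["apoe_level"], sub["abeta42"])
            rows.append(dict(group=g, treatment=t, formula="abeta42 ~ apoe_level",
                             slope=r.slope, intercept=r.intercept,
                             r_squared=r.r_squared, p=r.pvalues["x"], n=r.n))
        out["dose_response"] = rows
    if "microglia_regression" in cfg.analyses:
        ctrl = mice[mice["treatment"] == "control"]
        af = ctrl["mean_plaque_area_fraction"]
        if af.nunique() < 3 or af.max() == 0:
            log.append("microglia_regression skipped: no plaque area "
                       "fraction variation (all zero plaques)")
            out["microglia_regression"] = []
        else:
            rows = []
            for col, lab in (("mean_n_pa", "plaque_associated"),
                             ("mean_n_nonpa", "non_plaque_associated"),
                             ("mean_n_microglia", "total")):
                r = stats.ols_fit(af, ctrl[col])
                rows.append(dict(population=lab,
                                 formula=f"{col} ~ mean_plaque_area_fraction",
                                 slope=r.slope, r_squared=r.r_squared,
                                 p=r.pvalues["x"], n=r.n))
            out["microglia_regression"] = rows
    if "spot_anova" in cfg.analyses:
        per_mouse = (table.spots.groupby(["group", "treatment", "mouse_id", "replicate"])
                     ["n_spots"].mean().groupby(["group", "treatment", "mouse_id"]).mean()
                     .reset_index(name="mean_spots"))
        ctrl = per_mouse[per_mouse["treatment"] == "control"]
        groups = [sub["mean_spots"].to_numpy() for _, sub in ctrl.groupby("group")]
        labels = [g for g, _ in ctrl.groupby("group")]
        if len(groups) >= 2:
            r = stats.anova_tukey(groups, labels)
            out["spot_anova"] = dict(formula="mean_spots ~ group",
                                     f=r.statistic, p=r.p_value,
                                     n=int(len(ctrl)),
                                     pairwise=r.pairwise.to_dict("records"))
        else:
            log.append("spot_anova skipped: fewer than 2 groups")
    if "treatment_contrast" in cfg.analyses:
        rows = []
        for g, sub in mice.groupby("group"):
            if sub["treatment"].nunique() < 2:
                continue
            treat = (sub["treatment"] != "control").astype(float)
            r = stats.multiple_regression(sub["abeta42"], treat,
                                          sub["apoe_level"])
            rows.append(dict(group=g,
                             formula="abeta42 ~ treatment + apoe_level",
                             beta_treatment=r.params["treatment"],
                             se=r.se["treatment"],
                             p=r.pvalues["treatment"], n=r.n))
        out["treatment_contrast"] = rows
    return out, log


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the summary dict (also written as JSON)."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed: {config.seed}",
                 f"python: {platform.python_version()}",
                 f"numpy: {np.__version__}",
                 f"config: {_config_echo(config)}"]

    table, rendered = _simulate(config)
    table.mice.to_csv(out_dir / "mice.csv", index=False)
    table.fovs.to_csv(out_dir / "fovs.csv", index=False)
    table.spots.to_csv(out_dir / "spot_counts.csv", index=False)

    plq_summary, per_plaque, masks = _plaque_stage(config, rendered)
    plq_summary.to_csv(out_dir / "fov_plaques.csv", index=False)
    per_plaque.to_csv(out_dir / "plaque_records.csv", index=False)

    mic_summary, per_cell = _microglia_stage(config, rendered, masks)
    mic_summary.to_csv(out_dir / "fov_microglia.csv", index=False)
    per_cell.to_csv(out_dir / "microglia_records.csv", index=False)

    spot_det = _spot_stage(config, table)
    spot_det.to_csv(out_dir / "spot_detection.csv", index=False)

    analyses, stat_log = _stats_stage(config, table)
    log_lines.extend(stat_log)

    def _totals(df, cols):
        return {name: int(df[col].sum()) if len(df) else 0
                for name, col in cols.items()}

    summary = {
        "seed": config.seed,
        "n_mice": int(len(table.mice)),
        "n_fovs": int(len(table.fovs)),
        "rendered_fovs": int(len(rendered)),
        "plaques": _totals(plq_summary, {"total_segmented": "n_plaques",
                                         "total_true": "true_n_plaques"}),
        "microglia": _totals(mic_summary, {"total_segmented": "n_microglia",
                                           "total_true": "true_n_microglia"}),
        "spot_detection": _totals(spot_det, {"detected": "detected",
                                             "truth": "truth"}),
        "analyses": analyses,
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out_dir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return summary


def _config_echo(config: RunConfig) -> str:
    d = asdict(config)
    d["groups"] = (config.groups if isinstance(config.groups, str)
                   else [getattr(g, "name", str(g)) for g in config.group_specs()])
    return json.dumps(d, sort_keys=True, default=str)
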
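"""Configuration-driven orchestration of the full study analog.

``run_pipeline`` chains the stages: simulate a withering series (rendered
images or direct feature table), extract features, Kennard-Stone split,
standardize + PCA (fitted on calibration rows by default), tune and fit the
requested models, evaluate, and write reports plus a run manifest.  All
stage seeds derive deterministically from one master seed, so a rerun with
the same config reproduces byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import models as M
from .features import FEATURE_NAMES, extract_feature_table
from .metrics import MetricsReport, correlation_table, model_comparison, regression_metrics
from .prep import kennard_stone_split, pca_apply, pca_fit, zscore_apply, zscore_fit
from .simulate import (
    RenderParams,
    WitheringDesign,
    render_withering_dataset,
    simulate_feature_table,
)

log = logging.getLogger("withervision")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class ModelConfig:
    families: tuple[str, ...] = ("pls", "svr", "rf")
    # PLS
    npc_range: tuple[int, int] = (1, 10)
    npc_criterion: str = "rmsecv"
    npc_folds: int = 10
    # SVR
    svr_kernel: str = "rbf"
    svr_epsilon: float = 0.01
    svr_log2c: tuple[int, int] = (-10, 10)
    svr_log2g: tuple[int, int] = (-10, 10)
    svr_folds: int = 5
    # RF
    rf_pc_range: tuple[int, int] = (1, 10)
    rf_n_range: tuple[int, int, int] = (50, 1000, 50)
    rf_criterion: str = "oob"
    # shared input dimensionality
    n_pcs: int = 10


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults mirror the reference study design."""

    mode: str = "features"  # "features" (direct table) or "images"
    design: WitheringDesign = field(default_factory=WitheringDesign)
    render: RenderParams = field(default_factory=RenderParams)
    roi: tuple[int, int] | None = None  # auto-ROI size for image mode
    n_levels: int = 256
    n_calibration: int = 95
    split_metric: str = "mahalanobis"
    fit_scope: str = "calibration"  # or "all" (replication mode)
    models: ModelConfig = field(default_factory=ModelConfig)
    out_dir: str = "withervision_run"
    seed: int = 42

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def semantic_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Load a config from YAML; unspecified fields keep their defaults."""
    import yaml

    from .simulate import PiecewiseLink

    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig()
    if "design" in raw:
        cfg.design = WitheringDesign(**raw.pop("design"))
    if "render" in raw:
        r = raw.pop("render")
        for key in ("color_links",):
            if key in r:
                r[key] = {k: PiecewiseLink(**v) for k, v in r[key].items()}
        if "texture_amplitude_link" in r:
            r["texture_amplitude_link"] = PiecewiseLink(**r["texture_amplitude_link"])
        if "image_size" in r:
            r["image_size"] = tuple(r["image_size"])
        cfg.render = RenderParams(**r)
    if "models" in raw:
        m = raw.pop("models")
        for key in ("families",):
            if key in m:
                m[key] = tuple(m[key])
        for key in ("npc_range", "svr_log2c", "svr_log2g", "rf_pc_range", "rf_n_range"):
            if key in m:
                m[key] = tuple(m[key])
        cfg.models = ModelConfig(**m)
    if "roi" in raw and raw["roi"] is not None:
        raw["roi"] = tuple(raw["roi"])
    for k, v in raw.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown config field: {k}")
        setattr(cfg, k, v)
    return cfg


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    state = np.random.SeedSequence(master).generate_state(len(names) + 1)[1:]
    return {n: int(s % (2**31)) for n, s in zip(names, state)}


def _write_csv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False)
    return str(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ["simulate", "npc", "svr", "rf"])
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.semantic_hash(),
        "seeds": seeds,
        "outputs": [],
        "stages": {},
    }
    outputs: list[str] = manifest["outputs"]

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001
                _write_manifest(manifest, out)
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            dt = time.perf_counter() - t0
            manifest["stages"][name] = round(dt, 3)
            log.info("stage %s: done in %.2fs", name, dt)
            return result

        return deco

    # -- simulate / extract ------------------------------------------------
    def _simulate() -> pd.DataFrame:
        design = WitheringDesign(**{**asdict(config.design), "seed": seeds["simulate"]})
        if config.mode == "features":
            return simulate_feature_table(design)
        if config.mode == "images":
            img_dir = out / "images"
            sample_manifest, _ = render_withering_dataset(
                design, params=config.render, out_dir=img_dir
            )
            outputs.append(_write_csv(sample_manifest, out / "samples.csv"))
            from .features import load_image

            images = (
                load_image(row.image_path, sample_id=row.sample_id,
                           moisture=row.moisture)
                for row in sample_manifest.itertuples()
            )
            roi = "auto" if config.roi is not None else None
            feats = extract_feature_table(
                images, roi=roi,
                auto_size=config.roi or (0, 0), n_levels=config.n_levels,
            )
            feats.insert(1, "time_h", sample_manifest["time_h"].to_numpy())
            return feats
        raise ValueError(f"unknown mode: {config.mode!r}")

    features = stage("simulate")(_simulate)
    outputs.append(_write_csv(features, out / "features.csv"))

    # -- correlation report ------------------------------------------------
    corr = stage("correlation")(lambda: correlation_table(features))
    outputs.append(_write_csv(corr.r.round(6).reset_index(names="parameter"),
                              out / "correlation.csv"))
    outputs.append(_write_csv(corr.formatted().reset_index(names="parameter"),
                              out / "correlation_stars.csv"))

    # -- split -------------------------------------------------------------
    split = stage("split")(
        lambda: kennard_stone_split(features, config.n_calibration,
                                    metric=config.split_metric)
    )
    outputs.append(_write_csv(split.to_frame(features["sample_id"].to_numpy()),
                              out / "split.csv"))
    cal = features.iloc[np.sort(split.calibration)].reset_index(drop=True)
    pred = features.iloc[split.prediction].reset_index(drop=True)

    # -- preprocessing -----------------------------------------------------
    def _preprocess():
        fit_table = features if config.fit_scope == "all" else cal
        std = zscore_fit(fit_table)
        z_fit = zscore_apply(std, fit_table)
        # PCA rank cannot exceed the number of fit rows
        n_pcs = min(config.models.n_pcs, len(fit_table), len(FEATURE_NAMES))
        proj = pca_fit(z_fit, n_components=n_pcs)
        return std, proj

    std, proj = stage("preprocess")(_preprocess)
    y_cal = cal["moisture"].to_numpy()
    y_pred = pred["moisture"].to_numpy()
    X_cal = pca_apply(proj, zscore_apply(std, cal))
    X_pred = pca_apply(proj, zscore_apply(std, pred))

    # -- models ------------------------------------------------------------
    reports: list[MetricsReport] = []
    mc = config.models

    def _make_report(name: str, fitted, spec: dict) -> MetricsReport:
        model = M.FittedModel(family=name, regressor=fitted, standardizer=std,
                              pca=proj, n_input_pcs=X_cal.shape[1], spec=spec)
        M.save_model(model, out / f"model_{name}")
        return regression_metrics(
            y_cal, fitted.predict(X_cal), y_pred, fitted.predict(X_pred),
            model=name, spec=spec,
        )

    if "pls" in mc.families:
        def _pls():
            lo, hi = mc.npc_range
            best_npc, curve = M.select_npc(
                X_cal, y_cal, npc_range=range(lo, hi + 1),
                criterion=mc.npc_criterion, folds=mc.npc_folds, seed=seeds["npc"],
            )
            outputs.append(_write_csv(curve, out / "pls_npc_curve.csv"))
            return _make_report("pls", M.fit_pls(X_cal, y_cal, best_npc),
                                {"npc": best_npc})

        reports.append(stage("pls")(_pls))

    if "svr" in mc.families:
        def _svr():
            c_grid = 2.0 ** np.arange(mc.svr_log2c[0], mc.svr_log2c[1] + 1)
            g_grid = 2.0 ** np.arange(mc.svr_log2g[0], mc.svr_log2g[1] + 1)
            spec, surface = M.grid_search_svr(
                X_cal, y_cal, c_grid=c_grid, g_grid=g_grid,
                kernel=mc.svr_kernel, epsilon=mc.svr_epsilon,
                folds=mc.svr_folds, seed=seeds["svr"],
            )
            outputs.append(_write_csv(surface, out / "svr_surface.csv"))
            return _make_report("svr", M.fit_svr(X_cal, y_cal, spec),
                                {"kernel": spec.kernel, "c": spec.c, "g": spec.g,
                                 "epsilon": spec.epsilon})

        reports.append(stage("svr")(_svr))

    if "rf" in mc.families:
        def _rf():
            lo, hi = mc.rf_pc_range
            n0, n1, step = mc.rf_n_range
            spec, grid = M.optimize_rf(
                X_cal, y_cal, pc_range=range(lo, hi + 1),
                n_range=range(n0, n1 + 1, step),
                criterion=mc.rf_criterion, seed=seeds["rf"],
            )
            outputs.append(_write_csv(grid, out / "rf_grid.csv"))
            return _make_report("rf", M.fit_rf(X_cal, y_cal, spec),
                                {"n_trees": spec.n_trees,
                                 "n_input_pcs": spec.n_input_pcs})

        reports.append(stage("rf")(_rf))

    # -- evaluation --------------------------------------------------------
    def _evaluate():
        comparison = model_comparison(reports)
        outputs.append(_write_csv(comparison, out / "comparison.csv"))
        (out / "metrics.json").write_text(
            json.dumps([r.to_dict() for r in reports], indent=2, default=float)
        )
        outputs.append(str(out / "metrics.json"))
        return comparison

    stage("evaluate")(_evaluate)

    manifest["n_samples"] = int(len(features))
    manifest["n_calibration"] = int(split.n_calibration)
    manifest["n_prediction"] = int(len(split.prediction))
    manifest["models"] = [r.model for r in reports]
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
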
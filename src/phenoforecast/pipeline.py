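"""End-to-end reproducible run: simulate -> image/preprocess/segment ->
features -> forecast -> fresh-weight chain -> statistical validation.

A single root seed deterministically derives one sub-seed per stage; with
the linear learner the whole run is byte-reproducible (identical CSV
checksums for identical configs).  Each stage writes its artifacts and the
manifest as soon as it completes, so a partial failure leaves completed
artifacts and a resumable state behind.
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

from . import forecast as fc
from . import fwchain, phenofeat, preprocess, segmetrics, synthgen, validate
from .timegrid import DEFAULT_HORIZONS, CANONICAL_WINDOWS, TimeGrid

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run (reduced scale by default)."""

    seed: int = 0
    out_dir: str = "run_out"
    n_plants: int = 36
    windows: tuple[str, ...] = ("T1", "T2", "T3", "T4", "T5", "T6")
    learner: str = "gbt"
    horizons: tuple[int, ...] = DEFAULT_HORIZONS
    lookback: int = 24
    checkpoint_horizon: int = 24
    noise_sd: float = 0.03
    # imaging stage
    tray_rows: int = 4
    tray_cols: int = 4
    cell_size: int = 64
    warp_strength: float = 0.02
    seg_pairs: int = 60
    seg_epochs: int = 12
    # fresh-weight stage
    early_harvests: tuple[tuple[int, int], ...] = ((14, 5), (17, 5), (20, 5))
    late_harvest_das: int = 23
    late_harvest_n: int = 12
    resume: bool = False

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        for key in ("windows", "horizons"):
            if key in data:
                data[key] = tuple(data[key])
        if "early_harvests" in data:
            data["early_harvests"] = tuple(
                tuple(x) for x in data["early_harvests"]
            )
        return cls(**data)

    def validate(self) -> None:
        grid = TimeGrid()
        for name in self.windows:
            if name not in CANONICAL_WINDOWS:
                raise ValueError(f"unknown window {name!r}")
            w = CANONICAL_WINDOWS[name]
            if max(self.horizons) > w.test_end - w.train_start:
                raise ValueError(
                    f"max horizon {max(self.horizons)} cannot reach the test "
                    f"window of {name}"
                )
        if self.checkpoint_horizon not in self.horizons:
            raise ValueError("checkpoint_horizon must be one of horizons")
        n_early = sum(n for _, n in self.early_harvests)
        if n_early + self.late_harvest_n > self.n_plants:
            raise ValueError("harvest plan exceeds plant count")
        if self.late_harvest_das > grid.first_das + (grid.total_steps - 1) // grid.steps_per_day:
            raise ValueError("late harvest beyond the time grid")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31 - 1)) for s in state]


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns the manifest dict.

    The manifest lists every produced file with its SHA-256 checksum, stage
    timings and row counts, and is itself written to ``manifest.json`` after
    each stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": asdict(config),
                      "stages": {}, "files": {}}
    manifest_path = out / "manifest.json"
    if config.resume and manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        if prev.get("config") == manifest["config"]:
            manifest = prev

    seeds = _stage_seeds(config.seed)

    def record(stage: str, t0: float, files: dict[str, Path], counts: dict) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            **counts,
        }
        for name, path in files.items():
            manifest["files"][name] = _sha256(path)
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("stage %s done in %.2fs %s", stage, time.time() - t0, counts)

    def done(stage: str) -> bool:
        return config.resume and stage in manifest["stages"]

    # --- stage 1: simulate growth + features table -------------------------
    t0 = time.time()
    features_path = out / "features.csv"
    if not done("simulate"):
        try:
            sim = synthgen.GrowthSimConfig(
                n_plants=config.n_plants, noise_sd=config.noise_sd, seed=seeds[0]
            )
            records = synthgen.simulate_growth_curves(sim)
            _write_csv(records, features_path)
        except Exception as e:  # noqa: BLE001
            raise StageError("simulate", str(e)) from e
        record("simulate", t0, {"features.csv": features_path},
               {"rows": len(records)})
    records = pd.read_csv(features_path)

    # --- stage 2: imaging round-trip (tray -> segmentation -> features) ---
    t0 = time.time()
    segm_path = out / "seg_metrics.csv"
    imfeat_path = out / "image_features.csv"
    if not done("imaging"):
        try:
            rng = np.random.default_rng(seeds[1])
            geom = synthgen.TrayGeometry(
                rows=config.tray_rows, cols=config.tray_cols,
                cell_size=config.cell_size,
            )
            step = TimeGrid().total_steps
            at_step = records[records.time_step == step].head(
                geom.rows * geom.cols
            )
            max_pa = 0.45 * config.cell_size**2
            crops = []
            for _, row in at_step.iterrows():
                target = float(np.clip(row.pa, 40.0, max_pa))
                crops.append(
                    synthgen.render_rosette(
                        synthgen.RosetteSpec(
                            target_pa=target,
                            image_size=config.cell_size,
                            seed=int(rng.integers(0, 2**31 - 1)),
                        )
                    )
                )
            H = synthgen.random_perspective(geom, config.warp_strength, rng)
            scene = synthgen.compose_tray(crops, geom, homography=H,
                                          seed=int(rng.integers(0, 2**31 - 1)))
            corners = preprocess.detect_markers(scene.rgb)
            rect = preprocess.rectify(scene.rgb, corners, geom)
            cells = preprocess.crop_cells(rect, geom)

            pairs = synthgen.generate_training_pairs(
                config.seg_pairs, image_size=config.cell_size, seed=seeds[2]
            )
            model, _log = segmetrics.train_segmenter(
                pairs, epochs=config.seg_epochs, seed=seeds[2]
            )
            seg_rows, feat_rows = [], []
            for cell, (_, truth) in zip(cells, crops):
                pred = segmetrics.refine_mask(model.predict_proba(cell.rgb))
                score = segmetrics.seg_score(pred, truth)
                seg_rows.append(
                    {"plant_id": cell.plant_id, "iou": score.iou,
                     "precision": score.precision, "recall": score.recall,
                     "f1": score.fbeta}
                )
                feats = (
                    phenofeat.mask_features(pred)
                    if pred.any()
                    else {"pa": 0.0, "hull_area": np.nan,
                          "perimeter": np.nan, "compactness": np.nan}
                )
                feat_rows.append({"plant_id": cell.plant_id,
                                  "time_step": step, **feats})
            _write_csv(pd.DataFrame(seg_rows), segm_path)
            _write_csv(pd.DataFrame(feat_rows), imfeat_path)
        except Exception as e:  # noqa: BLE001
            raise StageError("imaging", str(e)) from e
        record("imaging", t0,
               {"seg_metrics.csv": segm_path, "image_features.csv": imfeat_path},
               {"cells": len(cells)})

    # --- stage 3: fresh-weight harvests ------------------------------------
    t0 = time.time()
    fw_path = out / "fresh_weight.csv"
    surv_path = out / "surviving_records.csv"
    if not done("harvest"):
        try:
            harvests = dict(config.early_harvests)
            harvests[config.late_harvest_das] = config.late_harvest_n
            fw_table, surviving = synthgen.simulate_fresh_weight(
                records, harvests, synthgen.AllometryParams(), seed=seeds[3]
            )
            _write_csv(fw_table, fw_path)
            _write_csv(surviving, surv_path)
        except Exception as e:  # noqa: BLE001
            raise StageError("harvest", str(e)) from e
        record("harvest", t0,
               {"fresh_weight.csv": fw_path, "surviving_records.csv": surv_path},
               {"harvested": len(fw_table)})
    fw_table = pd.read_csv(fw_path)
    surviving = pd.read_csv(surv_path)

    # --- stage 4: forecasting over the windows -----------------------------
    t0 = time.time()
    pred_path = out / "predictions.csv"
    errs_path = out / "window_summary.csv"
    cp_path = out / "checkpoints.csv"
    if not done("forecast"):
        try:
            full = surviving.groupby("plant_id").time_step.count()
            complete = full[full == TimeGrid().total_steps].index
            fc_records = surviving[surviving.plant_id.isin(complete)]
            cfg = fc.ForecastConfig(
                horizons=config.horizons, lookback=config.lookback,
                learner=config.learner, seed=seeds[4],
            )
            specs = {n: CANONICAL_WINDOWS[n] for n in config.windows}
            all_preds = []
            summary_rows = []
            for name, wspec in specs.items():
                designs = fc.build_design(fc_records, wspec, cfg)
                fitted = fc.fit_forecaster(designs, wspec, cfg)
                result = fc.predict_window(fitted, fc_records)
                _, summ = fc.summarize_errors(result)
                preds = result.predictions.copy()
                preds.insert(0, "window", name)
                all_preds.append(preds)
                summary_rows.append(
                    {"window": name, "mae": summ.mae, "rmse": summ.rmse,
                     "global_mae": summ.global_mae,
                     "global_rmse": summ.global_rmse, "n": summ.n}
                )
            predictions = pd.concat(all_preds, ignore_index=True)
            checkpoints = predictions[
                predictions.time_step == TimeGrid().total_steps
            ].reset_index(drop=True)
            _write_csv(predictions, pred_path)
            _write_csv(pd.DataFrame(summary_rows), errs_path)
            _write_csv(checkpoints, cp_path)
        except Exception as e:  # noqa: BLE001
            raise StageError("forecast", str(e)) from e
        record("forecast", t0,
               {"predictions.csv": pred_path, "window_summary.csv": errs_path,
                "checkpoints.csv": cp_path},
               {"predictions": len(predictions)})
    checkpoints = pd.read_csv(cp_path)

    # --- stage 5: fresh-weight chain ---------------------------------------
    t0 = time.time()
    chain_path = out / "chain_report.csv"
    fwmodel_path = out / "fw_model.json"
    if not done("fwchain"):
        try:
            model = fwchain.fit_fw_model(fw_table, das_range=(14.0, 20.0))
            late = fw_table[fw_table.das == config.late_harvest_das]
            report = fwchain.score_chain(
                model, checkpoints, late, horizon_h=config.checkpoint_horizon
            )
            fwmodel_path.write_text(model.to_json())
            _write_csv(pd.DataFrame([asdict(report)]), chain_path)
        except Exception as e:  # noqa: BLE001
            raise StageError("fwchain", str(e)) from e
        record("fwchain", t0,
               {"chain_report.csv": chain_path, "fw_model.json": fwmodel_path},
               {"n_chain": report.n})

    # --- stage 6: statistical validation -----------------------------------
    t0 = time.time()
    val_txt = out / "validation.txt"
    val_csv = out / "validation.csv"
    if not done("validate"):
        try:
            report = validate.run_validation(
                checkpoints, horizon_h=config.checkpoint_horizon
            )
            val_txt.write_text(report.to_text() + "\n")
            _write_csv(report.window_tests, val_csv)
        except Exception as e:  # noqa: BLE001
            raise StageError("validate", str(e)) from e
        record("validate", t0,
               {"validation.txt": val_txt, "validation.csv": val_csv},
               {"windows": len(report.window_tests)})

    return manifest
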
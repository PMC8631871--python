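"""Per-plant direct multi-horizon forecasting of projected area.

One gradient-boosted (or ordinary-least-squares) regression model is fitted
per plant and per forecast horizon h: the model for horizon h learns to map
lagged shape features observed at a forecast origin o (lags 1..L, lag 1 being
the value at o itself) plus calendar features of the target step to the PA at
step o+h.  This is *direct* multi-horizon forecasting — no recursive
one-step iteration — and evaluation over a testing window is rolling-origin:
the prediction for target step t at horizon h is conditioned only on
observations at steps <= t-h.

Errors are mean absolute error and root mean squared error; the "global"
variants average the per-plant, per-horizon summaries with equal weight.

Tree learners cannot extrapolate beyond the target range seen in training;
a model trained on a window ending before the plants stop growing will
underpredict later steps.  That behaviour is intrinsic to the method and is
surfaced (rather than hidden) by the window-comparison analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timegrid import DEFAULT_HORIZONS, CANONICAL_WINDOWS, TimeGrid, WindowSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForecastConfig:
    """Forecasting setup.

    ``lookback`` is the maximum feature lag L (lags 1..L, capped per horizon
    so at least one training row exists); ``dynamic_features`` are the
    columns lagged as predictors; calendar features (decimal DAS,
    day-of-month and month of the target step, dated from ``sowing_date``)
    are always known ahead and may be attached to any horizon.
    """

    horizons: tuple[int, ...] = DEFAULT_HORIZONS
    lookback: int = 48
    dynamic_features: tuple[str, ...] = ("pa", "hull_area", "compactness")
    calendar_features: bool = True
    learner: str = "gbt"  # "gbt" | "linear"
    learner_params: dict = field(default_factory=dict)
    sowing_date: str = "2021-03-01"
    grid: TimeGrid = field(default_factory=TimeGrid)
    seed: int = 0

    def validate(self, window: WindowSpec) -> None:
        # A horizon is usable if at least one test step has its forecast
        # origin at or after the training window start.
        if max(self.horizons) > window.test_end - window.train_start:
            raise ValueError(
                f"max horizon {max(self.horizons)} cannot reach the test "
                f"window of {window.name} from within its training window"
            )
        if self.lookback < 1:
            raise ValueError("lookback must be >= 1")
        if self.lookback >= window.n_train + min(self.horizons):
            raise ValueError(
                f"lookback {self.lookback} leaves no training rows in "
                f"window {window.name} ({window.n_train} steps)"
            )
        if self.learner not in ("gbt", "linear"):
            raise ValueError(f"unknown learner {self.learner!r}")

    def lags_for(self, window: WindowSpec, horizon: int) -> list[int]:
        """Lags 1..L capped so the training design is nonempty."""
        cap = window.n_train - horizon
        return list(range(1, min(self.lookback, cap) + 1))


def _calendar(das: float, sowing_date: str) -> tuple[float, int, int]:
    date = pd.Timestamp(sowing_date) + pd.Timedelta(days=int(das))
    return das, date.day, date.month


def _plant_series(records: pd.DataFrame, window: WindowSpec) -> dict[int, pd.DataFrame]:
    """Per-plant step-indexed frames, checked for interior gaps in the window."""
    out = {}
    for pid, grp in records.groupby("plant_id"):
        grp = grp.sort_values("time_step").set_index("time_step")
        have = set(grp.index)
        missing = [s for s in window.train_steps if s not in have]
        if missing:
            raise ValueError(
                f"plant {pid} missing steps {missing[:6]}{'...' if len(missing) > 6 else ''} "
                f"inside window {window.name}"
            )
        out[int(pid)] = grp
    return out


def _feature_row(
    series: pd.DataFrame,
    origin: int,
    target_step: int,
    lags: list[int],
    config: ForecastConfig,
) -> list[float]:
    row = []
    for feat in config.dynamic_features:
        col = series[feat]
        row.extend(float(col.loc[origin - lag + 1]) for lag in lags)
    if config.calendar_features:
        das = config.grid.das_of(target_step)
        row.extend(_calendar(das, config.sowing_date))
    return row


def _columns(lags: list[int], config: ForecastConfig) -> list[str]:
    cols = [
        f"{feat}_lag{lag}" for feat in config.dynamic_features for lag in lags
    ]
    if config.calendar_features:
        cols += ["das", "day", "month"]
    return cols


def build_design(
    records: pd.DataFrame, window: WindowSpec, config: ForecastConfig
) -> dict[int, dict[int, tuple[pd.DataFrame, pd.Series]]]:
    """Per-plant, per-horizon training designs.

    Row at forecast origin o holds lagged dynamic features {f(o-l+1)} for
    lags l plus calendar features of the target step o+h; the target is
    pa(o+h).  Origins run over the training window; rows whose lags or
    targets would leave the window are dropped.  Plants with interior gaps
    raise an error naming the plant and steps.
    """
    config.validate(window)
    per_plant = _plant_series(records, window)
    designs: dict[int, dict[int, tuple[pd.DataFrame, pd.Series]]] = {}
    for pid, series in per_plant.items():
        designs[pid] = {}
        for h in config.horizons:
            lags = config.lags_for(window, h)
            if not lags:
                designs[pid][h] = (pd.DataFrame(), pd.Series(dtype=float))
                continue
            o_lo = window.train_start + max(lags) - 1
            o_hi = window.train_end - h
            rows, targets, idx = [], [], []
            for o in range(o_lo, o_hi + 1):
                rows.append(_feature_row(series, o, o + h, lags, config))
                targets.append(float(series["pa"].loc[o + h]))
                idx.append(o)
            X = pd.DataFrame(rows, columns=_columns(lags, config), index=idx)
            y = pd.Series(targets, index=idx, name="pa_target")
            designs[pid][h] = (X, y)
    return designs


# ---------------------------------------------------------------------------
# learners


class _MeanModel:
    """Fallback predictor for degenerate designs."""

    def __init__(self, value: float):
        self.value = float(value)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(len(X), self.value)


class _LinearModel:
    """Ordinary least squares with intercept (minimum-norm on collinear X)."""

    def __init__(self, X: np.ndarray, y: np.ndarray):
        A = np.column_stack([X, np.ones(len(X))])
        self.coef, *_ = np.linalg.lstsq(A, y, rcond=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        A = np.column_stack([X, np.ones(len(X))])
        return A @ self.coef


def _make_gbt(params: dict, seed: int):
    from xgboost import XGBRegressor

    defaults = dict(
        n_estimators=60,
        max_depth=3,
        learning_rate=0.3,
        subsample=1.0,
        colsample_bytree=1.0,
        reg_lambda=1.0,
        tree_method="hist",
        n_jobs=1,
    )
    defaults.update(params)
    return XGBRegressor(random_state=seed, **defaults)


@dataclass
class FittedForecaster:
    """Per-plant, per-horizon fitted direct models for one window."""

    window: WindowSpec
    config: ForecastConfig
    models: dict[tuple[int, int], object]
    lags: dict[int, list[int]]
    hyperparams: dict


def fit_forecaster(
    designs: dict[int, dict[int, tuple[pd.DataFrame, pd.Series]]],
    window: WindowSpec,
    config: ForecastConfig,
) -> FittedForecaster:
    """Fit one direct model per (plant, horizon).

    Degenerate designs (fewer than 5 rows, or a constant target) fall back
    to a mean predictor with a warning; an empty design (horizon longer than
    the training window permits) falls back to the training-window mean PA.
    """
    if not designs:
        raise ValueError("no designs to fit")
    models: dict[tuple[int, int], object] = {}
    lags = {h: config.lags_for(window, h) for h in config.horizons}
    for pid, per_h in designs.items():
        for h, (X, y) in per_h.items():
            seed = (config.seed * 100003 + pid * 1009 + h) % (2**31 - 1)
            if len(y) < 5 or float(np.ptp(y)) == 0.0:
                fallback = float(y.mean()) if len(y) else np.nan
                logger.warning(
                    "degenerate design for plant %s horizon %s (%d rows); "
                    "using mean predictor",
                    pid,
                    h,
                    len(y),
                )
                models[(pid, h)] = _MeanModel(fallback)
            elif config.learner == "linear":
                models[(pid, h)] = _LinearModel(X.to_numpy(float), y.to_numpy(float))
            else:
                m = _make_gbt(config.learner_params, seed)
                m.fit(X.to_numpy(np.float32), y.to_numpy(np.float32))
                models[(pid, h)] = m
    hp = dict(learner=config.learner, lookback=config.lookback,
              **config.learner_params)
    return FittedForecaster(window=window, config=config, models=models,
                            lags=lags, hyperparams=hp)


# ---------------------------------------------------------------------------
# prediction and evaluation


@dataclass
class ForecastResult:
    """Rolling-origin predictions over a testing window."""

    window: WindowSpec
    predictions: pd.DataFrame  # plant_id, horizon_h, time_step, das, observed_pa, predicted_pa
    n_skipped: int


def predict_window(
    fitted: FittedForecaster, records: pd.DataFrame
) -> ForecastResult:
    """Predict every test step at every horizon, causally.

    The prediction for target step t at horizon h uses features observed at
    steps <= t-h only.  Targets whose feature window would reach before the
    training window start are skipped and counted.
    """
    window, config = fitted.window, fitted.config
    per_plant = _plant_series(records, window)
    rows = []
    n_skipped = 0
    for pid, series in per_plant.items():
        for h in config.horizons:
            lags = fitted.lags[h]
            model = fitted.models.get((pid, h))
            if model is None or not lags:
                n_skipped += window.n_test
                continue
            feats, steps = [], []
            for t in window.test_steps:
                o = t - h
                if o - max(lags) + 1 < window.train_start or o < 1:
                    n_skipped += 1
                    continue
                feats.append(_feature_row(series, o, t, lags, config))
                steps.append(t)
            if not steps:
                continue
            pred = model.predict(np.asarray(feats, dtype=float))
            for t, p in zip(steps, pred):
                rows.append(
                    {
                        "plant_id": pid,
                        "horizon_h": h,
                        "time_step": t,
                        "das": config.grid.display_das(t),
                        "observed_pa": float(series["pa"].loc[t])
                        if t in series.index
                        else np.nan,
                        "predicted_pa": float(p),
                    }
                )
    return ForecastResult(
        window=window,
        predictions=pd.DataFrame(
            rows,
            columns=[
                "plant_id", "horizon_h", "time_step", "das",
                "observed_pa", "predicted_pa",
            ],
        ),
        n_skipped=n_skipped,
    )


@dataclass(frozen=True)
class ErrorSummary:
    mae: float
    rmse: float
    n: int
    global_mae: float | None = None
    global_rmse: float | None = None

    def __post_init__(self) -> None:
        if self.n > 0 and self.rmse < self.mae - 1e-12:
            raise ValueError("RMSE cannot be smaller than MAE")


def error_summary(observed, predicted) -> ErrorSummary:
    """MAE and RMSE of one aligned observed/predicted pair of vectors."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted lengths differ")
    if obs.size < 1:
        raise ValueError("need at least one value")
    err = obs - pred
    return ErrorSummary(
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err**2))),
        n=int(obs.size),
    )


def summarize_errors(result: ForecastResult) -> tuple[pd.DataFrame, ErrorSummary]:
    """Per-(plant, horizon) MAE/RMSE table plus the global summary.

    Global MAE/RMSE are the unweighted means of the per-plant, per-horizon
    summaries over all forecast steps; the pooled mae/rmse over every
    prediction row are also reported.
    """
    df = result.predictions.dropna(subset=["observed_pa"])
    if df.empty:
        raise ValueError("no scored predictions")
    per = (
        df.groupby(["plant_id", "horizon_h"])
        .apply(
            lambda g: pd.Series(
                {
                    "mae": float(np.mean(np.abs(g.observed_pa - g.predicted_pa))),
                    "rmse": float(
                        np.sqrt(np.mean((g.observed_pa - g.predicted_pa) ** 2))
                    ),
                    "n": len(g),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    pooled = error_summary(df.observed_pa, df.predicted_pa)
    return per, ErrorSummary(
        mae=pooled.mae,
        rmse=pooled.rmse,
        n=pooled.n,
        global_mae=float(per.mae.mean()),
        global_rmse=float(per.rmse.mean()),
    )


def compare_windows(
    records: pd.DataFrame,
    window_specs: dict[str, WindowSpec] | None = None,
    config: ForecastConfig = ForecastConfig(),
    checkpoint_steps: tuple[int, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit and evaluate every window with a shared seed.

    Returns ``(summary, checkpoints)``: one summary row per window (pooled
    and global MAE/RMSE), and the per-plant predictions at the checkpoint
    steps (default: the last measured step) across all horizons, for the
    statistical validation stage.
    """
    if window_specs is None:
        window_specs = CANONICAL_WINDOWS
    if checkpoint_steps is None:
        checkpoint_steps = (config.grid.total_steps,)
    summary_rows = []
    checkpoint_frames = []
    for name, wspec in window_specs.items():
        designs = build_design(records, wspec, config)
        fitted = fit_forecaster(designs, wspec, config)
        result = predict_window(fitted, records)
        _, summ = summarize_errors(result)
        summary_rows.append(
            {
                "window": name,
                "mae": summ.mae,
                "rmse": summ.rmse,
                "global_mae": summ.global_mae,
                "global_rmse": summ.global_rmse,
                "n": summ.n,
                "n_skipped": result.n_skipped,
            }
        )
        cp = result.predictions[
            result.predictions.time_step.isin(checkpoint_steps)
        ].copy()
        cp.insert(0, "window", name)
        checkpoint_frames.append(cp)
    summary = pd.DataFrame(summary_rows)
    checkpoints = pd.concat(checkpoint_frames, ignore_index=True)
    return summary, checkpoints
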
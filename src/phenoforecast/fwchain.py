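"""Fresh-weight estimation chained onto projected-area forecasts.

A linear regression FW ~ PA is fitted on destructive harvests from the early
pre-flowering range (default 14-20 DAS), reported with the Spearman rank
coefficient of the pairs (rank correlation is the convention for all R values
in this pipeline).  The fitted model converts checkpoint PA forecasts into
predicted FW at the late stage, which is scored against held-out harvest FW.
An optional power-law form is available for sensitivity checks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FWModel:
    """Fitted PA -> fresh-weight regression."""

    slope: float
    intercept: float
    fit_r: float  # Spearman rank coefficient of the fitted pairs
    residual_sd: float
    n_fit: int
    fit_das_range: tuple[float, float]
    slope_se: float = float("nan")
    exponent: float | None = None  # power-law form if not None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def fit_fw_model(
    fw_table: pd.DataFrame,
    das_range: tuple[float, float] = (14.0, 20.0),
    form: str = "linear",
) -> FWModel:
    """OLS fit of FW on PA over harvests inside ``das_range`` (inclusive).

    ``fw_table`` needs columns (pa, fw, das).  At least 3 pairs are required.
    ``form="power"`` fits FW = slope * PA**exponent instead.
    """
    lo, hi = das_range
    sub = fw_table[(fw_table.das >= lo) & (fw_table.das <= hi)]
    if len(sub) < 3:
        raise ValueError(
            f"need >= 3 (PA, FW) pairs in DAS range {das_range}; got {len(sub)}"
        )
    pa = sub.pa.to_numpy(float)
    fw = sub.fw.to_numpy(float)
    rho = float(stats.spearmanr(pa, fw).statistic)
    if form == "linear":
        fit = stats.linregress(pa, fw)
        resid = fw - (fit.slope * pa + fit.intercept)
        return FWModel(
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            fit_r=rho,
            residual_sd=float(np.std(resid, ddof=2)),
            n_fit=len(sub),
            fit_das_range=(float(lo), float(hi)),
            slope_se=float(fit.stderr),
        )
    if form == "power":
        (a, b), _ = optimize.curve_fit(
            lambda x, a, b: a * np.power(x, b), pa, fw, p0=(fw.mean() / pa.mean(), 1.0)
        )
        resid = fw - a * np.power(pa, b)
        return FWModel(
            slope=float(a),
            intercept=0.0,
            fit_r=rho,
            residual_sd=float(np.std(resid, ddof=2)),
            n_fit=len(sub),
            fit_das_range=(float(lo), float(hi)),
            exponent=float(b),
        )
    raise ValueError(f"unknown form {form!r}")


def estimate_fw(model: FWModel, pa_values) -> np.ndarray:
    """Elementwise FW estimate; negative estimates are clipped to 0 (logged)."""
    pa = np.asarray(pa_values, dtype=float)
    if model.exponent is None:
        fw = model.slope * pa + model.intercept
    else:
        fw = model.slope * np.power(pa, model.exponent) + model.intercept
    neg = fw < 0
    if neg.any():
        logger.info("clipped %d negative FW estimates to 0", int(neg.sum()))
        fw = np.where(neg, 0.0, fw)
    return fw


@dataclass(frozen=True)
class ChainReport:
    """Forecast-PA -> FW chain scored against measured harvest FW."""

    spearman_r: float
    mae_fw: float
    rmse_fw: float
    n: int
    checkpoint_step: int
    horizon_h: int


def score_chain(
    model: FWModel,
    checkpoint_predictions: pd.DataFrame,
    fw_truth: pd.DataFrame,
    horizon_h: int = 24,
) -> ChainReport:
    """Convert checkpoint predicted PA to FW and score against measured FW.

    ``checkpoint_predictions`` needs (plant_id, horizon_h, time_step,
    predicted_pa); ``fw_truth`` needs (plant_id, fw).  Plants present in both
    are scored; fully disjoint sets are an error.
    """
    preds = checkpoint_predictions[checkpoint_predictions.horizon_h == horizon_h]
    if preds.empty:
        raise ValueError(f"no checkpoint predictions at horizon {horizon_h}")
    merged = preds.merge(fw_truth[["plant_id", "fw"]], on="plant_id")
    if merged.empty:
        raise ValueError("forecast and FW-truth plant sets are disjoint")
    fw_pred = estimate_fw(model, merged.predicted_pa.to_numpy())
    fw_obs = merged.fw.to_numpy(float)
    err = fw_obs - fw_pred
    return ChainReport(
        spearman_r=float(stats.spearmanr(fw_obs, fw_pred).statistic),
        mae_fw=float(np.mean(np.abs(err))),
        rmse_fw=float(np.sqrt(np.mean(err**2))),
        n=len(merged),
        checkpoint_step=int(merged.time_step.iloc[0]),
        horizon_h=horizon_h,
    )
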
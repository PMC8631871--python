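"""Statistical validation of the window comparison at a late checkpoint.

Protocol: at the checkpoint step (default: the last measured step, when
flower buds form and the forecast matters most), (1) one-way ANOVA across
the per-window predicted-PA groups together with the observed group, (2)
Tukey's honestly significant difference pairwise comparisons at a 95%
family-wise confidence level, (3) per-window paired t-tests of observed vs
predicted values, and (4) per-window Spearman rank correlations.
Significance is flagged at alpha = 0.01 throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ALPHA = 0.01


def anova_one_way(groups: list[np.ndarray]) -> tuple[float, float]:
    """Standard one-way ANOVA: F = MS_between / MS_within.

    Zero within-group variance with equal means is defined as (F=0, p=1),
    logged, rather than 0/0.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    groups = [np.asarray(g, dtype=float) for g in groups]
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = all_x.size - len(groups)
    if ss_within == 0:
        if ss_between == 0:
            logger.info("zero variance everywhere; ANOVA defined as F=0, p=1")
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return float(f), p


def tukey_hsd(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    family_conf: float = 0.95,
) -> pd.DataFrame:
    """Tukey HSD simultaneous intervals and adjusted p per pair.

    Columns: group_a, group_b, diff, low, high, p_adj, significant (at
    1 - family_conf family-wise level... significance flagged at ALPHA).
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    if all(np.ptp(g) == 0 for g in groups) and len({g.mean() for g in groups}) == 1:
        rows = [
            {"group_a": labels[i], "group_b": labels[j], "mean_diff": 0.0,
             "low": 0.0, "high": 0.0, "p_adj": 1.0, "significant": False}
            for i, j in combinations(range(len(groups)), 2)
        ]
        return pd.DataFrame(rows)
    res = stats.tukey_hsd(*groups)
    ci = res.confidence_interval(confidence_level=family_conf)
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                "low": float(ci.low[i, j]),
                "high": float(ci.high[i, j]),
                "p_adj": float(res.pvalue[i, j]),
                "significant": bool(res.pvalue[i, j] < ALPHA),
            }
        )
    return pd.DataFrame(rows)


def observed_vs_predicted_tests(
    checkpoints: pd.DataFrame,
    horizon_h: int = 24,
    paired: bool = True,
) -> pd.DataFrame:
    """Per-window t-test p and Spearman R of observed vs predicted PA.

    ``checkpoints`` is the compare_windows checkpoint frame (columns window,
    plant_id, horizon_h, observed_pa, predicted_pa).  The t-test is paired by
    plant by default (the same plants are observed and predicted); a
    two-sample variant is available.  Identical vectors are defined as p=1.
    """
    sub = checkpoints[checkpoints.horizon_h == horizon_h]
    if sub.empty:
        raise ValueError(f"no checkpoint rows at horizon {horizon_h}")
    rows = []
    for window, grp in sub.groupby("window", sort=False):
        obs = grp.observed_pa.to_numpy(float)
        pred = grp.predicted_pa.to_numpy(float)
        if len(obs) < 3:
            raise ValueError(f"window {window}: n={len(obs)} < 3")
        diffs = obs - pred
        if np.allclose(diffs, 0.0):
            p = 1.0
        elif paired:
            p = float(stats.ttest_rel(obs, pred).pvalue)
        else:
            p = float(stats.ttest_ind(obs, pred).pvalue)
        r = float(stats.spearmanr(obs, pred).statistic)
        rows.append(
            {
                "window": window,
                "n": len(obs),
                "t_p": p,
                "spearman_r": r,
                "mae": float(np.mean(np.abs(diffs))),
                "significant": bool(p < ALPHA),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    checkpoint_step: int
    checkpoint_das: float
    horizon_h: int
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame
    window_tests: pd.DataFrame
    alpha: float = ALPHA
    notes: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            f"Validation at checkpoint step {self.checkpoint_step} "
            f"(DAS {self.checkpoint_das}), horizon {self.horizon_h} h",
            f"ANOVA across groups: F = {self.anova_f:.4f}, p = {self.anova_p:.4g}",
            "",
            "Observed vs predicted per window (paired t, Spearman R):",
            self.window_tests.to_string(index=False),
            "",
            f"Tukey HSD pairs (95% family confidence, flag at alpha={self.alpha}):",
            self.tukey.to_string(index=False),
        ]
        lines += [""] + self.notes
        return "\n".join(lines)


def run_validation(
    checkpoints: pd.DataFrame,
    horizon_h: int = 24,
    include_observed_group: bool = True,
) -> ValidationReport:
    """Full validation protocol on a compare_windows checkpoint frame."""
    sub = checkpoints[checkpoints.horizon_h == horizon_h]
    if sub.empty:
        raise ValueError(f"no checkpoint rows at horizon {horizon_h}")
    step = int(sub.time_step.iloc[0])
    das = float(sub.das.iloc[0])
    windows = list(dict.fromkeys(sub.window))
    groups = [
        sub.loc[sub.window == w, "predicted_pa"].to_numpy(float) for w in windows
    ]
    labels = list(windows)
    if include_observed_group:
        first = windows[0]
        groups.append(sub.loc[sub.window == first, "observed_pa"].to_numpy(float))
        labels.append("observed")
    f, p = anova_one_way(groups)
    tukey = tukey_hsd(groups, labels=labels)
    tests = observed_vs_predicted_tests(checkpoints, horizon_h=horizon_h)
    return ValidationReport(
        checkpoint_step=step,
        checkpoint_das=das,
        horizon_h=horizon_h,
        anova_f=f,
        anova_p=p,
        tukey=tukey,
        window_tests=tests,
    )
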
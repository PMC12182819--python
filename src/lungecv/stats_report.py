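"""Group statistics and table formatting.

Paired t-tests compare baseline vs regurgitation (each subject its own
control); unpaired t-tests compare volume-loaded vs naive controls.
Repeated-measures comparisons across >= 3 conditions use a one-way
within-subjects ANOVA with the Greenhouse-Geisser sphericity correction:
the correction factor epsilon is estimated from the double-centered sample
covariance of the subject-by-condition matrix,

    epsilon = trace(S)^2 / ((k-1) * sum(S^2)),

bounded in [1/(k-1), 1], and both F degrees of freedom are scaled by it.
Significance threshold is p < 0.05 throughout; continuous variables are
reported as mean +/- SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import ValidationError

__all__ = [
    "GroupSample",
    "paired_t",
    "unpaired_t",
    "rm_anova_gg",
    "RMAnovaResult",
    "format_mean_sd",
    "summary_table",
]


@dataclass
class GroupSample:
    """Per-subject scalars for one condition, with optional pairing keys."""

    values: np.ndarray
    condition: str
    subject_ids: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.subject_ids is not None and len(self.subject_ids) != self.values.size:
            raise ValidationError("subject ids misaligned with values")


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, GroupSample) else np.asarray(x, float)


def paired_t(a, b) -> tuple[float, float]:
    """Two-sided paired t-test; identical samples return (0, 1).

    When both arguments are GroupSamples with subject ids, the pairing is
    checked for alignment.
    """
    if isinstance(a, GroupSample) and isinstance(b, GroupSample):
        if (a.subject_ids is not None and b.subject_ids is not None
                and list(a.subject_ids) != list(b.subject_ids)):
            raise ValidationError("paired samples have misaligned subject ids")
    av, bv = _values(a), _values(b)
    if av.size != bv.size:
        raise ValidationError("paired samples must have equal length")
    if av.size < 2:
        raise ValidationError("need n >= 2 per group")
    if np.allclose(av, bv):
        return 0.0, 1.0
    t, p = sps.ttest_rel(av, bv)
    return float(t), float(p)


def unpaired_t(a, b) -> tuple[float, float]:
    """Two-sided unpaired (equal-variance) t-test."""
    av, bv = _values(a), _values(b)
    if av.size < 2 or bv.size < 2:
        raise ValidationError("need n >= 2 per group")
    t, p = sps.ttest_ind(av, bv)
    return float(t), float(p)


@dataclass
class RMAnovaResult:
    f: float
    df_num: float
    df_den: float
    epsilon: float
    p_uncorrected: float
    p_gg: float


def rm_anova_gg(data: np.ndarray) -> RMAnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``data`` is a complete (n_subjects, k_conditions) matrix.  With k = 2
    conditions epsilon is exactly 1 by definition.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValidationError("need a subjects x conditions matrix")
    if np.any(~np.isfinite(x)):
        raise ValidationError("matrix has missing cells")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValidationError("need >= 2 subjects and >= 2 conditions")

    grand = x.mean()
    subj_means = x.mean(axis=1, keepdims=True)
    cond_means = x.mean(axis=0, keepdims=True)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    resid = x - subj_means - cond_means + grand
    ss_err = np.sum(resid ** 2)
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err == 0:
        f = np.inf if ms_cond > 0 else 0.0
    else:
        f = ms_cond / ms_err

    # Greenhouse-Geisser epsilon from the double-centered covariance
    s = np.cov(x, rowvar=False, ddof=1)
    j = np.eye(k) - np.ones((k, k)) / k
    sc = j @ s @ j
    denom = (k - 1) * np.sum(sc ** 2)
    eps = 1.0 if denom == 0 else float(np.trace(sc) ** 2 / denom)
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))

    p_unc = float(sps.f.sf(f, df_cond, df_err)) if np.isfinite(f) else 0.0
    p_gg = float(sps.f.sf(f, eps * df_cond, eps * df_err)) if np.isfinite(f) else 0.0
    return RMAnovaResult(f=float(f), df_num=eps * df_cond, df_den=eps * df_err,
                         epsilon=eps, p_uncorrected=p_unc, p_gg=p_gg)


# --------------------------------------------------------------------------- #
# Formatting
# --------------------------------------------------------------------------- #

def format_mean_sd(values, decimals: int = 0) -> str:
    """``mean +/- SD`` string with round-half-even at ``decimals`` places."""
    v = np.asarray(values, dtype=float)
    mean = round(float(np.mean(v)), decimals)
    sd = 0.0 if v.size < 2 else round(float(np.std(v, ddof=1)), decimals)
    if decimals == 0:
        return f"{int(mean)}±{int(sd)}"
    return f"{mean:.{decimals}f}±{sd:.{decimals}f}"


def summary_table(
    results: dict[str, dict[str, np.ndarray]],
    percent_metrics: tuple[str, ...] = (),
    decimals: int = 0,
) -> pd.DataFrame:
    """Mean +/- SD summary table: rows = metrics, columns = groups.

    ``results`` maps group label -> {metric -> per-subject values}.  Metrics
    named in ``percent_metrics`` are multiplied by 100 before formatting.
    Fractions are rounded to the nearest integer percent (round-half-even,
    Python's banker's rounding) at the default ``decimals=0``.
    """
    groups = list(results)
    metrics: list[str] = []
    for g in groups:
        for m in results[g]:
            if m not in metrics:
                metrics.append(m)
    table = {}
    for g in groups:
        col = {}
        for m in metrics:
            if m not in results[g]:
                col[m] = "N/A"
                continue
            vals = np.asarray(results[g][m], dtype=float)
            if m in percent_metrics:
                vals = vals * 100.0
            col[m] = format_mean_sd(vals, decimals=decimals)
        table[g] = col
    return pd.DataFrame(table, index=metrics)
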
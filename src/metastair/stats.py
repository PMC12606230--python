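"""Pre-registered frequentist tests and the exploratory set-size controls.

Conventions follow the registered analysis: condition differences are
parameterized as WM minus IM; the effect size for a paired t statistic is
Cohen's d_z = |t| / sqrt(n); equivalence is declared by the TOST procedure
(two one-sided paired t-tests against the bounds, reported p = the larger
one-sided p, reported statistic = the one-sided t with that p).
Standardized TOST bounds are interpreted on the SD scale of the paired
differences, matching the d_z convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .roc import type2_roc

__all__ = [
    "TestResult",
    "paired_t",
    "cohens_d_from_t",
    "tost_paired",
    "partial_eta_sq",
    "setsize_variability_analysis",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    """A frequentist test outcome (paired t, TOST, or a regression term)."""

    __test__ = False  # not a pytest collectible despite the name

    kind: str
    statistic: float
    df: float
    p_value: float
    alpha: float = 0.05
    effect_size_d: float | None = None
    mean_difference: float | None = None
    bounds: tuple[float, float] | None = None
    standardized: bool | None = None
    df2: float | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "significant": self.significant,
        }
        if self.effect_size_d is not None:
            d["effect_size_d"] = self.effect_size_d
        if self.mean_difference is not None:
            d["mean_difference"] = self.mean_difference
        if self.bounds is not None:
            d["bounds"] = list(self.bounds)
            d["standardized_bounds"] = self.standardized
        if self.df2 is not None:
            d["df2"] = self.df2
        return d


def _paired_diffs(x, y) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    return d


def paired_t(x, y, alpha: float = 0.05) -> TestResult:
    """Two-sided dependent-samples t-test on ``x - y`` (df = n-1)."""
    d = _paired_diffs(x, y)
    n = len(d)
    res = sps.ttest_rel(x, y)
    t = float(res.statistic)
    return TestResult(
        kind="paired_t",
        statistic=t,
        df=n - 1,
        p_value=float(res.pvalue),
        alpha=alpha,
        effect_size_d=cohens_d_from_t(t, n),
        mean_difference=float(d.mean()),
    )


def cohens_d_from_t(t: float, n: int) -> float:
    """Paired-design effect size d_z = |t| / sqrt(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return abs(t) / np.sqrt(n)


def tost_paired(
    x,
    y,
    lower: float,
    upper: float,
    standardized: bool = True,
    alpha: float = 0.05,
) -> TestResult:
    """Two one-sided paired t-tests for equivalence of ``x`` and ``y``.

    ``lower``/``upper`` are the equivalence bounds for the mean of ``x - y``;
    when ``standardized`` they are in units of the SD of the paired
    differences (d_z scale) and are converted to raw units internally.
    Equivalence is claimed when the larger one-sided p is below ``alpha``.
    """
    if not lower < upper:
        raise ValueError("lower bound must be below upper bound")
    d = _paired_diffs(x, y)
    n = len(d)
    sd = d.std(ddof=1)
    se = sd / np.sqrt(n)
    if standardized:
        lo_raw, up_raw = lower * sd, upper * sd
    else:
        lo_raw, up_raw = lower, upper
    t_lower = (d.mean() - lo_raw) / se  # H0: diff <= lower, reject when large
    t_upper = (d.mean() - up_raw) / se  # H0: diff >= upper, reject when small
    p_lower = float(sps.t.sf(t_lower, n - 1))
    p_upper = float(sps.t.cdf(t_upper, n - 1))
    if p_lower >= p_upper:
        t, p = t_lower, p_lower
    else:
        t, p = t_upper, p_upper
    return TestResult(
        kind="tost",
        statistic=float(t),
        df=n - 1,
        p_value=p,
        alpha=alpha,
        effect_size_d=cohens_d_from_t(float(d.mean() / se), n),
        mean_difference=float(d.mean()),
        bounds=(lower, upper),
        standardized=standardized,
    )


def partial_eta_sq(F: float, df_effect: float, df_error: float) -> float:
    """Partial eta squared from an F statistic: F*df_eff / (F*df_eff + df_err)."""
    if F < 0:
        raise ValueError("F must be nonnegative")
    if df_effect < 1 or df_error < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return F * df_effect / (F * df_effect + df_error)


def _modal_set_size(n_items: pd.Series) -> int:
    """Most frequent set size; ties resolved to the smaller set size."""
    counts = n_items.value_counts()
    top = counts[counts == counts.max()].index
    if len(top) > 1:
        logger.info("modal set-size tie %s resolved to %s", sorted(top), min(top))
    return int(min(top))


def setsize_variability_analysis(
    summaries: pd.DataFrame, records: pd.DataFrame, alpha_modal: float = 0.025
) -> dict:
    """Exploratory controls for staircase-induced set-size variability.

    (a) paired t on the per-subject SD of the displayed set size (WM - IM);
    (b) OLS of AUROC-2 on the z-normalized SD, a WM indicator and their
    interaction (two rows per subject), so the WM coefficient reads as the
    metacognition gap at the average set-size variability;
    (c) AUROC-2 recomputed per subject x condition on modal-set-size trials
    only, compared by paired t and TOST (standardized bounds +-0.325) at
    ``alpha_modal``; accuracy-degenerate subjects are dropped with a log
    entry.
    """
    wide = summaries.pivot(index="subject_id", columns="condition")
    if len(wide) < 2:
        raise ValueError("need at least 2 retained subjects")
    sd_wm = wide[("sd_items", "WM")]
    sd_im = wide[("sd_items", "IM")]
    sd_comparison = paired_t(sd_wm, sd_im)

    z_sd = (summaries["sd_items"] - summaries["sd_items"].mean()) / summaries[
        "sd_items"
    ].std(ddof=1)
    X = pd.DataFrame(
        {
            "sd_items_z": z_sd,
            "WM": (summaries["condition"] == "WM").astype(float),
        }
    )
    X["WM_x_sd"] = X["WM"] * X["sd_items_z"]
    ols = sm.OLS(summaries["auroc2"], sm.add_constant(X)).fit()
    regression = {
        name: TestResult(
            kind="ols_term",
            statistic=float(ols.tvalues[name]),
            df=float(ols.df_resid),
            p_value=float(ols.pvalues[name]),
            mean_difference=float(ols.params[name]),
        )
        for name in ("sd_items_z", "WM", "WM_x_sd")
    }

    modal_auc: dict[str, dict[int, float]] = {"IM": {}, "WM": {}}
    for (subject, cond), g in records.groupby(["subject_id", "condition"]):
        mode = _modal_set_size(g["n_items"])
        sub = g[g["n_items"] == mode]
        curve = type2_roc(
            np.asarray(sub["confidence"], float), np.asarray(sub["correct"], float)
        )
        if not curve.defined:
            logger.warning(
                "modal-set-size AUROC-2 undefined for subject %s condition %s",
                subject,
                cond,
            )
            continue
        modal_auc[cond][subject] = curve.area()
    common = sorted(set(modal_auc["IM"]) & set(modal_auc["WM"]))
    dropped = sorted(
        set(records["subject_id"].unique()) - set(common)
    )
    wm_vals = np.array([modal_auc["WM"][s] for s in common])
    im_vals = np.array([modal_auc["IM"][s] for s in common])
    modal_t = paired_t(wm_vals, im_vals, alpha=alpha_modal)
    modal_tost = tost_paired(
        wm_vals, im_vals, -0.325, 0.325, standardized=True, alpha=alpha_modal
    )
    return {
        "sd_comparison": sd_comparison,
        "regression": regression,
        "modal_t": modal_t,
        "modal_tost": modal_tost,
        "modal_excluded_subjects": dropped,
    }
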
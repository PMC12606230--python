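"""Type-2 ROC curves and AUROC-2, the metacognitive-sensitivity statistic.

For 4-level confidence ratings every criterion c in {>=2, >=3, >=4} splits
ratings into "high" and "low".  The type-2 hit rate at c is the proportion
of correct trials rated >= c, and the type-2 false-alarm rate the
proportion of incorrect trials rated >= c.  Plotting hit rate against
false-alarm rate (with endpoints (0,0) and (1,1)) and taking the area under
the piecewise-linear curve gives the AUROC-2: 0.5 means confidence carries
no information about the subject's own accuracy, 1 means perfect
discrimination.  The trapezoidal area is identical to the tie-corrected
probability that a randomly drawn correct trial carries higher confidence
than a randomly drawn incorrect one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Roc2Curve", "type2_roc", "auroc2", "subject_summaries"]

logger = logging.getLogger(__name__)

N_LEVELS = 4


@dataclass(frozen=True)
class Roc2Curve:
    """A type-2 ROC curve; undefined when either outcome class is empty."""

    fa_rates: np.ndarray
    hit_rates: np.ndarray
    n_correct: int
    n_incorrect: int

    @property
    def defined(self) -> bool:
        return self.n_correct > 0 and self.n_incorrect > 0

    def area(self) -> float:
        """Trapezoidal area under the curve; NaN when undefined."""
        if not self.defined:
            return float("nan")
        return float(np.trapezoid(self.hit_rates, self.fa_rates))

    def plot(self, ax=None, **kwargs):
        """Draw the curve (lazy matplotlib import)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fa_rates, self.hit_rates, marker="o", **kwargs)
        ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=1)
        ax.set_xlabel("type-2 false-alarm rate")
        ax.set_ylabel("type-2 hit rate")
        ax.set_aspect("equal")
        return ax

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fa_rate": self.fa_rates, "hit_rate": self.hit_rates})


def _check_confidence(confidence: np.ndarray) -> None:
    if confidence.size and (
        confidence.min() < 1
        or confidence.max() > N_LEVELS
        or not np.allclose(confidence, np.rint(confidence))
    ):
        raise ValueError("confidence ratings must be integers in 1..4")


def type2_roc(confidence, correct) -> Roc2Curve:
    """Type-2 ROC points from trialwise confidence (1..4) and correctness (0/1).

    When all trials are correct (or all incorrect) the curve is undefined;
    a curve object with ``defined == False`` is returned rather than raising,
    so a degenerate subject can be flagged without aborting a cohort.
    """
    confidence = np.asarray(confidence, dtype=float)
    correct = np.asarray(correct, dtype=float)
    if confidence.shape != correct.shape or confidence.ndim != 1:
        raise ValueError("confidence and correct must be equal-length 1-d arrays")
    if confidence.size == 0:
        raise ValueError("empty input")
    _check_confidence(confidence)
    if not np.isin(correct, (0.0, 1.0)).all():
        raise ValueError("correct must be 0/1")
    conf_c = confidence[correct == 1.0]
    conf_i = confidence[correct == 0.0]
    n_c, n_i = len(conf_c), len(conf_i)
    hits = [1.0]
    fas = [1.0]
    for c in range(2, N_LEVELS + 1):  # criteria >=2, >=3, >=4
        hits.append((conf_c >= c).sum() / n_c if n_c else np.nan)
        fas.append((conf_i >= c).sum() / n_i if n_i else np.nan)
    hits.append(0.0)
    fas.append(0.0)
    # order from (0,0) to (1,1)
    return Roc2Curve(
        fa_rates=np.array(fas[::-1]),
        hit_rates=np.array(hits[::-1]),
        n_correct=n_c,
        n_incorrect=n_i,
    )


def auroc2(curve: Roc2Curve) -> float:
    """Area under a type-2 ROC curve (NaN propagated for undefined curves)."""
    return curve.area()


def subject_summaries(records: pd.DataFrame) -> pd.DataFrame:
    """Per subject x condition summaries of the analysis-ready trials.

    Columns: accuracy (proportion correct), mean_items and sd_items of the
    displayed set size, mean_confidence and auroc2 (NaN, with a warning,
    for a subject whose condition lacks correct or incorrect trials).
    Expects preprocessed records (practice/burn-in/timeouts removed), so
    ``correct`` and ``confidence`` are complete.
    """
    rows = []
    for (subject, cond), g in records.groupby(["subject_id", "condition"], sort=True):
        correct = np.asarray(g["correct"], dtype=float)
        conf = np.asarray(g["confidence"], dtype=float)
        curve = type2_roc(conf, correct)
        auc = curve.area()
        if not curve.defined:
            logger.warning(
                "AUROC-2 undefined for subject %s condition %s "
                "(%d correct / %d incorrect trials)",
                subject,
                cond,
                curve.n_correct,
                curve.n_incorrect,
            )
        rows.append(
            {
                "subject_id": subject,
                "condition": cond,
                "n_trials": len(g),
                "accuracy": correct.mean(),
                "mean_items": g["n_items"].mean(),
                "sd_items": g["n_items"].std(ddof=1),
                "mean_confidence": conf.mean(),
                "auroc2": auc,
            }
        )
    return pd.DataFrame(rows)
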
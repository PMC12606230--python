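"""Pre-registered trial- and subject-level exclusion rules.

Trials are dropped, in this reporting order, when they are practice trials,
staircase burn-in (the first 30 experimental trials of each memory
condition in each session), timeouts (no decision before 4 s and/or no
confidence report before 3 s), anticipatory responses (decision or
confidence RT under 150 ms), or displays of fewer than four items.  A trial
failing several rules is counted once, under the first matching rule; the
kept set does not depend on the rule order.

A subject is retained only if both conditions keep at least 180 trials
(i.e. no condition loses more than 10% of its 200 valid trials).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExclusionReport", "filter_trials", "exclude_subjects", "preprocess"]

#: Reporting precedence of the exclusion rules.
REASONS = ("practice", "burn_in", "timeout", "fast_rt", "too_few_items", "kept")

BURN_IN_TRIALS = 30
MIN_RT_S = 0.15
MIN_ITEMS = 4
MIN_VALID_PER_CONDITION = 180

_REQUIRED = {
    "subject_id",
    "session",
    "phase",
    "condition",
    "n_items",
    "correct",
    "confidence",
    "rt_decision_s",
    "rt_confidence_s",
}


@dataclass
class ExclusionReport:
    """Book-keeping of the exclusion cascade.

    ``reasons`` holds one label per input trial (aligned with the input
    index); ``counts`` is a subject x condition x reason table;
    ``subject_kept`` maps subject id to the retention flag (filled by
    :func:`exclude_subjects`).
    """

    reasons: pd.Series
    counts: pd.DataFrame
    subject_kept: dict[int, bool] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return len(self.reasons)

    @property
    def n_kept(self) -> int:
        return int((self.reasons == "kept").sum())

    def summary(self) -> dict:
        """JSON-ready summary of trial- and subject-level exclusions."""
        by_reason = self.reasons.value_counts().to_dict()
        return {
            "n_trials": self.n_total,
            "n_kept_trials": self.n_kept,
            "trials_by_reason": {r: int(by_reason.get(r, 0)) for r in REASONS},
            "n_subjects": len(self.subject_kept) or None,
            "n_subjects_kept": (
                sum(self.subject_kept.values()) if self.subject_kept else None
            ),
            "subjects_excluded": sorted(
                s for s, kept in self.subject_kept.items() if not kept
            ),
        }


def _validate(records: pd.DataFrame) -> None:
    missing = _REQUIRED - set(records.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    conf = records["confidence"].dropna()
    bad = conf[(conf < 1) | (conf > 4)]
    if len(bad):
        raise ValueError(
            f"confidence outside 1..4 at rows {bad.index[:5].tolist()}"
        )
    # confidence present implies a confidence RT was recorded
    orphans = records.index[
        records["confidence"].notna() & records["rt_confidence_s"].isna()
    ]
    if len(orphans):
        raise ValueError(
            f"confidence without confidence RT at rows {orphans[:5].tolist()}"
        )


def _staircase_order(records: pd.DataFrame) -> pd.Series:
    """Per-condition experimental trial counter within each session."""
    if "staircase_order" in records.columns:
        return records["staircase_order"]
    exp = records["phase"] == "experimental"
    order = pd.Series(0, index=records.index)
    order[exp] = (
        records[exp]
        .groupby(["subject_id", "session", "condition"])
        .cumcount()
        + 1
    )
    return order


def filter_trials(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the trial-level exclusion rules.

    Returns the kept trials and an :class:`ExclusionReport`; input rows are
    conserved (kept + excluded = total).
    """
    _validate(records)
    order = _staircase_order(records)
    reasons = pd.Series("kept", index=records.index, dtype=object)

    practice = records["phase"] == "practice"
    burn_in = ~practice & (order <= BURN_IN_TRIALS)
    timeout = records["rt_decision_s"].isna() | records["rt_confidence_s"].isna()
    fast = (records["rt_decision_s"] < MIN_RT_S) | (
        records["rt_confidence_s"] < MIN_RT_S
    )
    fast = fast.fillna(False)
    too_few = records["n_items"] < MIN_ITEMS

    # first matching rule wins for the reason label
    for label, mask in [
        ("too_few_items", too_few),
        ("fast_rt", fast),
        ("timeout", timeout),
        ("burn_in", burn_in),
        ("practice", practice),
    ]:
        reasons[np.asarray(mask, dtype=bool)] = label

    counts = (
        pd.DataFrame(
            {
                "subject_id": records["subject_id"],
                "condition": records["condition"],
                "reason": reasons,
            }
        )
        .groupby(["subject_id", "condition", "reason"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(REASONS), fill_value=0)
    )
    kept = records.loc[reasons == "kept"].copy()
    return kept, ExclusionReport(reasons=reasons, counts=counts)


def exclude_subjects(
    kept: pd.DataFrame,
    report: ExclusionReport,
    min_valid: int = MIN_VALID_PER_CONDITION,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop subjects with fewer than ``min_valid`` kept trials in any condition."""
    if len(kept) == 0:
        return kept, report
    per = kept.groupby(["subject_id", "condition"]).size().unstack(fill_value=0)
    for cond in ("IM", "WM"):
        if cond not in per.columns:
            per[cond] = 0
    ok = (per >= min_valid).all(axis=1)
    report.subject_kept = {int(s): bool(v) for s, v in ok.items()}
    retained = kept[kept["subject_id"].map(ok).fillna(False)].copy()
    return retained, report


def preprocess(
    records: pd.DataFrame, min_valid: int = MIN_VALID_PER_CONDITION
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Full cascade: trial filter then subject retention."""
    kept, report = filter_trials(records)
    return exclude_subjects(kept, report, min_valid=min_valid)
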
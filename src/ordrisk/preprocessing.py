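"""Participant-exclusion rules applied before model fitting.

Two rules, applied per dataset (i.e. per domain):

* attention — a subject who fails 6 or more catch trials is removed; a
  failure is choosing the dominated lottery (a chance at the level-1
  outcome) over the certain level-1 outcome;
* no variability — a subject who chooses the lottery on fewer than 2
  non-catch trials is removed, because a constant choice pattern carries
  no information for the choice function.

Catch trials are dropped from the fitting input for retained subjects:
they compare identical outcomes and carry no value information under any
of the models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .simulate import ChoiceDataset

__all__ = ["ATTENTION_FAILURE_THRESHOLD", "MIN_LOTTERY_CHOICES", "ExclusionReport", "apply_exclusions"]

ATTENTION_FAILURE_THRESHOLD = 6
MIN_LOTTERY_CHOICES = 2

log = logging.getLogger(__name__)


@dataclass
class ExclusionReport:
    """Per-subject exclusion bookkeeping; ``reason`` is 'attention',
    'no_variability' or 'retained'."""

    table: pd.DataFrame

    @property
    def n_excluded(self) -> int:
        return int(self.table["excluded"].sum())

    @property
    def retained_ids(self) -> list:
        return self.table.loc[~self.table["excluded"], "subject_id"].tolist()


def apply_exclusions(data: ChoiceDataset) -> tuple[ChoiceDataset, ExclusionReport]:
    """Filter a dataset by the attention and variability rules.

    Returns the retained subjects' non-catch trials plus a per-subject
    report. Filtering is idempotent: re-applying it to the output excludes
    nobody further (a dataset without catch trials trivially has zero
    catch failures).
    """
    df = data.table
    if "is_catch" not in df.columns:
        raise ValueError("dataset must carry an is_catch flag")

    rows = []
    for sid, sub in df.groupby("subject_id", sort=True):
        catch = sub[sub["is_catch"]]
        noncatch = sub[~sub["is_catch"]]
        n_fail = int(catch["chose_lottery"].sum())
        n_lotto = int(noncatch["chose_lottery"].sum())
        if n_fail >= ATTENTION_FAILURE_THRESHOLD:
            reason = "attention"
        elif n_lotto < MIN_LOTTERY_CHOICES:
            reason = "no_variability"
        else:
            reason = "retained"
        if reason != "retained":
            log.info(
                "excluding subject %s: %s (catch failures=%d, lottery choices=%d)",
                sid, reason, n_fail, n_lotto,
            )
        rows.append(
            {
                "subject_id": sid,
                "n_catch_failures": n_fail,
                "n_lottery_choices": n_lotto,
                "excluded": reason != "retained",
                "reason": reason,
            }
        )
    report = ExclusionReport(table=pd.DataFrame(rows))

    keep = set(report.retained_ids)
    filtered = df[df["subject_id"].isin(keep) & ~df["is_catch"]].reset_index(drop=True)
    true_params = data.true_params
    if true_params is not None:
        true_params = true_params[true_params["subject_id"].isin(keep)].reset_index(
            drop=True
        )
    return ChoiceDataset(table=filtered, true_params=true_params), report
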
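"""Longitudinal endpoints: percent latency change from baseline, and the
early-delay stratification of diseased eyes.

The analysis unit is the *eye* (each mouse contributes two).  Every latency
measure (P1, N1, P2 and the three implicit times) is converted to percent
change relative to the same eye's day-0 session; eyes without a baseline, or
with the measure absent at baseline, contribute no endpoint for that measure.

Stratification reproduces the "with / without latency delay" split: a
diseased eye is labeled *with* early delay when its N1 percent change at the
early timepoint (day 7 by default) exceeds a threshold, by default the
healthy eyes' mean + 2 SD at that same timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .components import MEASURES, VEPMarks

__all__ = [
    "percent_change",
    "SessionMarks",
    "build_cohort_table",
    "StratificationRule",
    "stratify_eyes",
    "pool_groups",
    "UNCLASSIFIABLE",
    "WITH_DELAY",
    "WITHOUT_DELAY",
]

WITH_DELAY = "EAE W LD"
WITHOUT_DELAY = "EAE W/O LD"
UNCLASSIFIABLE = "unclassifiable"


def percent_change(value_ms: float | None, baseline_ms: float | None) -> float | None:
    """100 * (value - baseline) / baseline; ``None`` propagates."""
    if value_ms is None or baseline_ms is None:
        return None
    if baseline_ms <= 0:
        raise ValueError("baseline latency must be positive")
    return 100.0 * (value_ms - baseline_ms) / baseline_ms


@dataclass
class SessionMarks:
    """Marks for one eye x day, with cohort metadata."""

    eye_id: str
    mouse_id: str
    group: str
    day: float
    marks: VEPMarks


def build_cohort_table(records: Sequence[SessionMarks]) -> pd.DataFrame:
    """Long-format endpoint table: one row per eye x day x measure.

    Columns: eye_id, mouse_id, group_design, group_stratified (initially the
    design label), day, measure, value_ms, pct_change.  Percent change is
    computed against the eye's day-0 value; rows whose measure is absent at
    either end carry NaN explicitly rather than being dropped.
    """
    if not records:
        raise ValueError("no session records")
    keys = [(r.eye_id, r.day) for r in records]
    if len(set(keys)) != len(keys):
        dup = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (eye_id, day) records: {dup}")

    baselines: dict[str, VEPMarks] = {r.eye_id: r.marks for r in records if r.day == 0}
    rows = []
    for r in records:
        base = baselines.get(r.eye_id)
        for measure in MEASURES:
            value = r.marks.measure(measure)
            base_value = base.measure(measure) if base is not None else None
            pct = percent_change(value, base_value)
            rows.append(
                {
                    "eye_id": r.eye_id,
                    "mouse_id": r.mouse_id,
                    "group_design": r.group,
                    "group_stratified": r.group,
                    "day": r.day,
                    "measure": measure,
                    "value_ms": np.nan if value is None else value,
                    "pct_change": np.nan if pct is None else pct,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StratificationRule:
    """Rule assigning diseased eyes to the early-delay strata.

    ``threshold_pct`` overrides the healthy-referenced threshold
    (healthy mean + ``n_sd`` * SD of ``measure`` percent change at ``day``).
    """

    measure: str = "N1"
    day: float = 7.0
    n_sd: float = 2.0
    threshold_pct: float | None = None
    healthy_label: str = "Healthy"
    with_label: str = WITH_DELAY
    without_label: str = WITHOUT_DELAY


def stratify_eyes(
    table: pd.DataFrame,
    rule: StratificationRule | None = None,
    diseased_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Relabel diseased eyes as with/without early latency delay.

    Healthy eyes are never relabeled; a diseased eye missing the rule's
    timepoint (or the measure there) becomes ``unclassifiable``.  Returns a
    copy of the table with ``group_stratified`` updated on every row of each
    classified eye.
    """
    rule = rule or StratificationRule()
    if diseased_labels is None:
        diseased_labels = [
            g for g in table["group_design"].unique() if g != rule.healthy_label
        ]

    at_rule = table[(table["day"] == rule.day) & (table["measure"] == rule.measure)]
    if rule.threshold_pct is not None:
        threshold = rule.threshold_pct
    else:
        healthy = at_rule.loc[
            at_rule["group_design"] == rule.healthy_label, "pct_change"
        ].dropna()
        if healthy.empty:
            raise ValueError(
                "stratification needs Healthy reference or absolute threshold"
            )
        threshold = healthy.mean() + rule.n_sd * healthy.std(ddof=1)

    out = table.copy()
    for eye_id, eye_rows in out[out["group_design"].isin(diseased_labels)].groupby(
        "eye_id"
    ):
        sel = at_rule[at_rule["eye_id"] == eye_id]["pct_change"]
        if sel.empty or sel.isna().all():
            label = UNCLASSIFIABLE
        elif float(sel.iloc[0]) > threshold:
            label = rule.with_label
        else:
            label = rule.without_label
        out.loc[out["eye_id"] == eye_id, "group_stratified"] = label
    return out


def pool_groups(
    table: pd.DataFrame,
    labels: Sequence[str],
    pooled_label: str = "EAE",
    column: str = "group_design",
    into: str = "group_pooled",
) -> pd.DataFrame:
    """Merge several design groups into one pooled label (new column)."""
    out = table.copy()
    out[into] = out[column].where(~out[column].isin(list(labels)), pooled_label)
    return out
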
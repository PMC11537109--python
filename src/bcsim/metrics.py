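"""Derived measures over simulated and observed specimen timelines.

Four "key node" intervals anchor calibration and sensitivity analysis,
all measured from receipt in the laboratory:

* ``receipt_to_load`` — receipt to loading onto the incubator (all
  specimens);
* ``receipt_to_flag`` — receipt to growth detection (positives);
* ``receipt_to_unload`` — receipt to unloading from the incubator
  (positives);
* ``receipt_to_gram`` — receipt to reporting of the Gram stain
  (positives).

The module also implements the waste-time accounting used for directly
observed task sessions (any gap between consecutive tasks within a
session is waste) and the record-exclusion bookkeeping applied to
retrospective laboratory extracts before distribution fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .engine import SimulationResult
from .errors import IntegrityError

KEY_NODES = ("receipt_to_load", "receipt_to_flag", "receipt_to_unload", "receipt_to_gram")

_NODE_EVENTS = {
    "receipt_to_load": "load_analyzer",
    "receipt_to_flag": "flag_positive",
    "receipt_to_unload": "unload",
    "receipt_to_gram": "read_report_gram",
}


def key_intervals(result: SimulationResult, include_warmup: bool = False) -> pd.DataFrame:
    """Per-specimen key-node intervals (minutes) for a simulation run.

    Specimens collected during warmup are excluded (unless requested), as
    are specimens still in transport (no receipt yet).  Negatives carry
    only ``receipt_to_load``; intervals whose terminal event has not
    happened are NaN.
    """
    if not result.specimens:
        raise IntegrityError("empty simulation result")
    rows = []
    warmup = result.config.warmup
    for sp in result.specimens:
        if not include_warmup and sp.collection < warmup:
            continue
        receipt = sp.events.get("receipt")
        if receipt is None:
            if sp.completed:
                raise IntegrityError(f"completed specimen {sp.id} has no receipt event")
            continue
        row = {"specimen_id": sp.id, "is_positive": sp.is_positive, "completed": sp.completed}
        for node, event in _NODE_EVENTS.items():
            if node != "receipt_to_load" and not sp.is_positive:
                row[node] = np.nan
                continue
            end = sp.events.get(event)
            row[node] = (end - receipt) if end is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["specimen_id", "is_positive", "completed", *KEY_NODES])


@dataclass
class WasteSummary:
    """Waste-time accounting per category and per observation session."""

    task_time: dict = field(default_factory=dict)
    waste_time: dict = field(default_factory=dict)
    fraction: dict = field(default_factory=dict)
    session_fractions: dict = field(default_factory=dict)  # category -> list


def waste_fraction(sessions, categories) -> WasteSummary:
    """Waste accounting over timed observation sessions.

    Each session is an ordered list of (start, end) task intervals;
    the gap between consecutive tasks is waste, and the waste fraction
    is waste / (waste + task time), i.e. the wasted share of the session
    span.  ``categories`` labels each session (e.g. "pre-analytical" /
    "analytical"); totals and fractions are reported per category, with
    per-session fractions alongside for range statements.
    """
    if len(sessions) != len(categories):
        raise IntegrityError("one category label required per session")
    summary = WasteSummary()
    for session, cat in zip(sessions, categories):
        task = 0.0
        waste = 0.0
        prev_end = None
        for start, end in session:
            if end < start:
                raise IntegrityError(f"task ends before it starts: ({start}, {end})")
            if prev_end is not None:
                if start < prev_end:
                    raise IntegrityError(f"overlapping tasks at {start} < {prev_end}")
                waste += start - prev_end
            task += end - start
            prev_end = end
        summary.task_time[cat] = summary.task_time.get(cat, 0.0) + task
        summary.waste_time[cat] = summary.waste_time.get(cat, 0.0) + waste
        span = task + waste
        summary.session_fractions.setdefault(cat, []).append(waste / span if span > 0 else 0.0)
    for cat in summary.task_time:
        span = summary.task_time[cat] + summary.waste_time[cat]
        summary.fraction[cat] = summary.waste_time[cat] / span if span > 0 else 0.0
    return summary


def _pct(numer: int, denom: int) -> float:
    """Percentage rounded half-up to 1 decimal, as printed in reports."""
    if denom == 0:
        return float("nan")
    exact = Decimal(100) * Decimal(numer) / Decimal(denom)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class FilterAccounting:
    """Telescoping record-exclusion counts with printed-style percentages."""

    n_initial: int
    n_missing_data: int
    pct_missing_data: float
    n_after_missing: int
    n_load_before_receipt: int
    pct_load_before_receipt: float
    n_remaining: int
    n_missing_collection_date: int
    pct_missing_collection_date: float
    n_complete: int
    pct_complete: float


def filter_retrospective(records: pd.DataFrame) -> FilterAccounting:
    """Apply the retrospective record-exclusion rules, in order.

    ``records`` needs columns ``missing_data`` (bool), ``receipt_time``,
    ``load_time`` and ``collection_time`` (NaN = absent).  Rules: (1) drop
    records flagged as having missing data; (2) drop records whose
    incubator load time predates laboratory receipt; (3) mark records
    lacking a collection time as unusable for collection-to-receipt
    analysis.  Percentages use the running denominators (initial, after
    rule 1, after rule 2) except the final complete fraction, which is a
    share of the initial count.
    """
    if records.empty:
        raise IntegrityError("no records")
    n_initial = len(records)
    missing = records["missing_data"].astype(bool)
    n_missing = int(missing.sum())
    after_missing = records.loc[~missing]
    n_after = len(after_missing)
    load_before = after_missing["load_time"] < after_missing["receipt_time"]
    n_load_before = int(load_before.sum())
    remaining = after_missing.loc[~load_before]
    n_remaining = len(remaining)
    no_collection = remaining["collection_time"].isna()
    n_no_collection = int(no_collection.sum())
    n_complete = n_remaining - n_no_collection
    return FilterAccounting(
        n_initial=n_initial,
        n_missing_data=n_missing,
        pct_missing_data=_pct(n_missing, n_initial),
        n_after_missing=n_after,
        n_load_before_receipt=n_load_before,
        pct_load_before_receipt=_pct(n_load_before, n_after),
        n_remaining=n_remaining,
        n_missing_collection_date=n_no_collection,
        pct_missing_collection_date=_pct(n_no_collection, n_remaining),
        n_complete=n_complete,
        pct_complete=_pct(n_complete, n_initial),
    )


def summarize(intervals: pd.DataFrame, nodes=KEY_NODES) -> pd.DataFrame:
    """Per-node mean, median, quartiles, IQR and n (missing ignored)."""
    if intervals.empty:
        raise IntegrityError("empty interval table")
    rows = []
    for node in nodes:
        x = pd.to_numeric(intervals[node], errors="coerce").dropna()
        if len(x) == 0:
            rows.append({"node": node, "n": 0, "mean": np.nan, "median": np.nan,
                         "q1": np.nan, "q3": np.nan, "iqr": np.nan})
            continue
        q1, q3 = np.percentile(x, [25, 75])
        rows.append({"node": node, "n": int(len(x)), "mean": float(x.mean()),
                     "median": float(x.median()), "q1": float(q1), "q3": float(q3),
                     "iqr": float(q3 - q1)})
    return pd.DataFrame(rows).set_index("node")
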
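"""Feasibility metrics of an accelerometer study protocol.

Summarises recruitment, retention and logistics counts as the
percentages a feasibility report tabulates, and Likert-scale burden and
value responses as median (IQR) with inclusive (Tukey) quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FeasibilityCounts:
    """Raw counts and responses behind the feasibility metrics."""

    n_referred: int = 0
    n_enrolled: int = 0
    n_completed: int = 0
    n_cards_provided: int = 0
    n_cards_returned: int = 0
    n_monitors_dispensed: int = 0
    n_monitors_returned: int = 0
    n_monitors_extracted: int = 0
    nonwear_min_per_day: list[float] = field(default_factory=list)
    burden_scores: list[int] = field(default_factory=list)
    value_scores: list[int] = field(default_factory=list)

    def __post_init__(self):
        counts = [self.n_referred, self.n_enrolled, self.n_completed,
                  self.n_cards_provided, self.n_cards_returned,
                  self.n_monitors_dispensed, self.n_monitors_returned,
                  self.n_monitors_extracted]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.n_enrolled > self.n_referred:
            raise ValueError("enrolled cannot exceed referred")
        if self.n_completed > self.n_enrolled:
            raise ValueError("completed cannot exceed enrolled")
        for scores in (self.burden_scores, self.value_scores):
            if any(not (0 <= s <= 10) for s in scores):
                raise ValueError("Likert scores must be integers in [0, 10]")


def _pct(numerator: int, denominator: int) -> float | None:
    """Percentage to one decimal; None when undefined."""
    if denominator == 0:
        return None
    return round(100.0 * numerator / denominator, 1)


def tukey_quartiles(values) -> tuple[float, float, float]:
    """(Q1, median, Q3) by the inclusive (Tukey) method.

    Quartiles are medians of the lower and upper halves, each half
    including the overall median when n is odd.
    """
    x = np.sort(np.asarray(values, float))
    n = x.size
    if n == 0:
        raise ValueError("no values")
    med = float(np.median(x))
    half = (n + 1) // 2  # inclusive halves
    return float(np.median(x[:half])), med, float(np.median(x[n - half:]))


def likert_summary(values) -> dict:
    """Median (IQR) summary of an 11-point Likert item."""
    q1, med, q3 = tukey_quartiles(values)
    return {"median": med, "q1": q1, "q3": q3,
            "formatted": f"{med:g} ({q1:g}–{q3:g})"}


def feasibility_metrics(counts: FeasibilityCounts) -> dict:
    """The protocol's practicality and acceptability metrics.

    Percentages (one decimal): recruitment = enrolled/referred,
    retention = completed/enrolled, activity-card return =
    returned/provided, monitor return = returned/dispensed, monitor
    extraction = extracted/returned.  Likert items as median (IQR);
    non-wear as mean minutes/day.  Undefined ratios (zero denominator)
    are reported as None.
    """
    metrics: dict = {
        "recruitment_pct": _pct(counts.n_enrolled, counts.n_referred),
        "retention_pct": _pct(counts.n_completed, counts.n_enrolled),
        "card_return_pct": _pct(counts.n_cards_returned, counts.n_cards_provided),
        "monitor_return_pct": _pct(counts.n_monitors_returned,
                                   counts.n_monitors_dispensed),
        "monitor_extraction_pct": _pct(counts.n_monitors_extracted,
                                       counts.n_monitors_returned),
    }
    if counts.nonwear_min_per_day:
        metrics["nonwear_min_mean"] = round(
            float(np.mean(counts.nonwear_min_per_day)), 1)
    else:
        metrics["nonwear_min_mean"] = None
    metrics["burden"] = (likert_summary(counts.burden_scores)
                         if counts.burden_scores else None)
    metrics["value"] = (likert_summary(counts.value_scores)
                        if counts.value_scores else None)
    return metrics
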
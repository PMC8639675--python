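"""Strategy-report consistency filtering, Cohen's kappa, and behavioral
summaries (accuracy and response time) by strategy and operation.

Problem size proxies strategy (small -> retrieval, large -> procedure), but
children's trial-by-trial verbal reports do not always agree with it.  Only
trials where report and size-based expectation coincide are retained
("consistency filter"); trials reported with an unknown strategy are always
dropped.  Agreement between the two categorizations is quantified with
Cohen's kappa on the 2x2 table that remains after dropping unknowns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stimuli import SizeClass
from .synthdata import TrialEvent, size_expected_strategy

__all__ = [
    "ConsistencyTable",
    "consistency_filter",
    "cohen_kappa",
    "summarize_accuracy",
    "summarize_rt",
]

_SIZES = ("large", "small")
_REPORT_COLS = ("procedure", "retrieve", "unknown")


@dataclass
class ConsistencyTable:
    """Trial counts for size (rows: large, small) x report (columns:
    procedure, retrieve, unknown)."""

    counts: np.ndarray  # 2x3 integer array

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 3):
            raise ValueError("counts must be 2x3 (size x report)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_unknown(self) -> int:
        return int(self.counts[:, 2].sum())

    def agreement_table(self) -> np.ndarray:
        """2x2 size-by-report table after dropping the unknown column.

        Rows: large, small; columns: procedure, retrieve.  The diagonal
        holds size-consistent reports.
        """
        return self.counts[:, :2].copy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(_SIZES), columns=list(_REPORT_COLS))


def consistency_filter(
    trials: Sequence[TrialEvent],
) -> tuple[list[TrialEvent], ConsistencyTable, list[tuple[TrialEvent, str]]]:
    """Retain trials whose report matches the size-based expectation.

    Retained iff (small and retrieve) or (large and procedure); unknown
    reports are always excluded.  Returns (retained, counts table,
    exclusion log of (trial, reason)).  Always: retained + excluded = input.
    """
    counts = np.zeros((2, 3), dtype=int)
    retained: list[TrialEvent] = []
    excluded: list[tuple[TrialEvent, str]] = []
    for tr in trials:
        size = tr.problem.size
        row = 0 if size is SizeClass.LARGE else 1
        col = _REPORT_COLS.index(tr.report)
        counts[row, col] += 1
        if tr.report == "unknown":
            excluded.append((tr, "unknown"))
        elif tr.report == size_expected_strategy(size):
            retained.append(tr)
        else:
            excluded.append((tr, f"report {tr.report} inconsistent with {size.value} problem"))
    return retained, ConsistencyTable(counts), excluded


def cohen_kappa(table: np.ndarray) -> tuple[float, float]:
    """Agreement proportion and Cohen's kappa for a 2x2 agreement table.

    ``p_o`` is the diagonal share; ``p_e`` the chance agreement from the
    marginal products; ``kappa = (p_o - p_e) / (1 - p_e)``.  With degenerate
    marginals (``p_e == 1``) kappa is undefined and returned as NaN.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 agreement table")
    n = t.sum()
    if n <= 0:
        raise ValueError("agreement table is empty")
    p_o = np.trace(t) / n
    p_e = float((t.sum(axis=1) / n) @ (t.sum(axis=0) / n))
    if p_e >= 1.0:
        return float(p_o), float("nan")
    return float(p_o), float((p_o - p_e) / (1.0 - p_e))


def _condition_frame(trials: Sequence[TrialEvent]) -> pd.DataFrame:
    rows = [
        {
            "participant": tr.participant,
            "strategy": size_expected_strategy(tr.problem.size),
            "operation": tr.problem.operation.value,
            "rt": tr.rt,
            "correct": tr.correct,
        }
        for tr in trials
    ]
    return pd.DataFrame(rows)


def summarize_accuracy(trials: Sequence[TrialEvent]) -> pd.DataFrame:
    """Per-condition accuracy: per-participant proportion correct, then mean
    and SD across participants.

    Participant-condition cells with zero trials are missing and excluded
    from the mean/SD with a warning.
    """
    df = _condition_frame(trials)
    if df.empty:
        raise ValueError("no trials to summarize")
    per_part = (
        df.groupby(["strategy", "operation", "participant"], sort=False)["correct"]
        .mean()
        .reset_index()
    )
    out = (
        per_part.groupby(["strategy", "operation"], sort=False)["correct"]
        .agg(n="count", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    n_participants = df["participant"].nunique()
    missing = out.loc[out["n"] < n_participants]
    if not missing.empty:
        import warnings

        for _, row in missing.iterrows():
            warnings.warn(
                f"condition ({row['strategy']}, {row['operation']}): only "
                f"{row['n']}/{n_participants} participants contribute"
            )
    return out


def summarize_rt(trials: Sequence[TrialEvent]) -> pd.DataFrame:
    """Pooled RT summary per condition: min, q1, median, mean, q3, max (s).

    Only correct trials should be passed in.  Quartiles use linear
    interpolation.  Trials are pooled over participants so min/max refer to
    individual problems.
    """
    df = _condition_frame(trials)
    if df.empty:
        raise ValueError("no trials to summarize")

    def _stats(s: pd.Series) -> pd.Series:
        q1, med, q3 = np.quantile(s, [0.25, 0.5, 0.75])
        return pd.Series(
            {
                "n": len(s),
                "min": s.min(),
                "q1": q1,
                "median": med,
                "mean": s.mean(),
                "q3": q3,
                "max": s.max(),
            }
        )

    return (
        df.groupby(["strategy", "operation"], sort=False)["rt"]
        .apply(_stats)
        .unstack()
        .reset_index()
    )
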
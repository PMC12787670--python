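"""Mean-rank evaluation of ranking methods against confirmed outcomes.

The performance statistic is the *mean rank*: the average fractional
position of the experimentally confirmed solvate-forming solvents in a
method's ranked list.  A method that consistently places true formers near
the top of the panel attains a low mean rank; an uninformative ranking has
expectation ``(n_panel + 1) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Set

import numpy as np
import pandas as pd

from .ranking import RankTable

__all__ = [
    "EvaluationResult",
    "mean_rank",
    "compare_methods",
    "recovery_report",
    "baseline_mean_rank",
]


@dataclass(frozen=True)
class EvaluationResult:
    """Mean rank of one method's table against a confirmed-former set."""

    compound_id: str
    method_id: str
    mean_rank: float
    n_confirmed: int
    n_panel: int

    def __post_init__(self) -> None:
        k, n = self.n_confirmed, self.n_panel
        lo, hi = (k + 1) / 2, n - (k - 1) / 2
        if not (lo - 1e-9 <= self.mean_rank <= hi + 1e-9):
            raise ValueError(
                f"mean_rank {self.mean_rank} outside attainable bounds "
                f"[{lo}, {hi}] for {k} confirmed of {n}"
            )


def baseline_mean_rank(n_panel: int) -> float:
    """Expected mean rank of an uninformative (random) ranking."""
    return (n_panel + 1) / 2


def mean_rank(
    table: RankTable,
    confirmed: Set[str] | Iterable[str],
    compound_id: str = "",
) -> EvaluationResult:
    """Average fractional position of the confirmed formers in ``table``.

    Raises if the confirmed set is empty or names a solvent absent from
    the panel.
    """
    confirmed = set(confirmed)
    if not confirmed:
        raise ValueError("confirmed solvent set is empty")
    missing = confirmed - table.solvents()
    if missing:
        raise ValueError(
            f"confirmed solvent(s) absent from panel: {sorted(missing)}"
        )
    positions = [table.ranks[s] for s in confirmed]
    return EvaluationResult(
        compound_id=compound_id,
        method_id=table.method_id,
        mean_rank=float(np.mean(positions)),
        n_confirmed=len(confirmed),
        n_panel=table.n,
    )


def compare_methods(
    individual: Mapping[str, RankTable],
    combos: Mapping[str, RankTable],
    confirmed: Set[str] | Iterable[str],
    compound_id: str = "",
) -> list[EvaluationResult]:
    """Evaluate all individual and consensus tables on one confirmed set.

    Returns one result per table, sorted ascending by mean rank with ties
    broken by canonical method label, so the best-performing method comes
    first.  The best individual method and the best method overall are the
    first entries of the respective slices.
    """
    keys = list(individual) + list(combos)
    if len(set(keys)) != len(keys):
        dup = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate method label(s): {dup}")
    tables = {**individual, **combos}
    panels = {frozenset(t.solvents()) for t in tables.values()}
    if len(panels) > 1:
        raise ValueError("all tables must share one solvent panel")
    results = [
        mean_rank(t, confirmed, compound_id=compound_id)
        for t in tables.values()
    ]
    return sorted(results, key=lambda r: (r.mean_rank, r.method_id))


def recovery_report(
    results: Iterable[EvaluationResult] | pd.DataFrame,
) -> pd.DataFrame:
    """Aggregate replicate evaluations into per-method mean and dispersion.

    Accepts EvaluationResults (or a frame with columns ``method_id``,
    ``mean_rank``, ``n_panel``) pooled over replicates and returns one row
    per method with the replicate mean, standard deviation and count of the
    mean-rank statistic, plus a ``baseline`` row holding the uninformative
    expectation ``(n_panel + 1) / 2``.
    """
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        df = pd.DataFrame(
            [(r.method_id, r.mean_rank, r.n_panel) for r in results],
            columns=["method_id", "mean_rank", "n_panel"],
        )
    if df.empty:
        raise ValueError("no evaluation results to aggregate")
    grouped = df.groupby("method_id")["mean_rank"]
    report = pd.DataFrame({
        "mean": grouped.mean(),
        "sd": grouped.std(ddof=1).fillna(0.0),
        "n_replicates": grouped.count(),
    }).reset_index()
    n_panels = df["n_panel"].unique()
    if len(n_panels) == 1:
        baseline = pd.DataFrame({
            "method_id": ["baseline"],
            "mean": [baseline_mean_rank(int(n_panels[0]))],
            "sd": [0.0],
            "n_replicates": [0],
        })
        report = pd.concat([report, baseline], ignore_index=True)
    return report.sort_values("mean", kind="stable").reset_index(drop=True)


def results_to_frame(results: Iterable[EvaluationResult]) -> pd.DataFrame:
    """CSV-ready frame: one row per (compound, method)."""
    return pd.DataFrame(
        [(r.compound_id, r.method_id, r.mean_rank, r.n_confirmed, r.n_panel)
         for r in results],
        columns=["compound_id", "method_id", "mean_rank",
                 "n_confirmed", "n_panel"],
    )
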
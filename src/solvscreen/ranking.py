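"""Fractional rank tables and consensus rank aggregation.

Each scoring method orders the solvent panel in its own favorability
direction (HBP descending, MC / CV / Hex ascending).  Ties receive
fractional (mean-of-tied-positions) ranks, which keeps every table's rank
sum at ``n(n+1)/2`` and makes downstream rank sums permutation-invariant.
Undefined scores (HBP with no heteromeric pairing) are placed strictly
after all defined scores, tied among themselves — absence of a
donor--acceptor pathway is read conservatively as "least likely to form".

A consensus ranking over a set of methods sums each solvent's fractional
rank across the member tables and re-ranks the sums ascending; lower
consensus values indicate better agreement across methods that the solvent
is a likely solvate former.  Eleven combinations of the four methods are
screened: all six pairs, four of the triples, and the full four-way
combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "RankTable",
    "COMBINATIONS",
    "combo_label",
    "rank_method",
    "rank_scores",
    "consensus",
    "all_combinations",
    "rank_tables_to_wide",
    "rank_tables_to_long",
]


@dataclass
class RankTable:
    """Fractional rank position of each panel solvent under one method.

    ``ranks`` maps solvent_id -> fractional position >= 1; positions over
    the whole panel always sum to n(n+1)/2.  ``statistic`` optionally
    carries the per-solvent quantity the ranks were derived from (a score,
    or a consensus rank sum).
    """

    method_id: str
    ranks: dict[str, float]
    statistic: dict[str, float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.ranks)

    def __post_init__(self) -> None:
        n = self.n
        if n:
            total = sum(self.ranks.values())
            if not np.isclose(total, n * (n + 1) / 2):
                raise ValueError(
                    f"rank table {self.method_id!r}: positions sum to "
                    f"{total}, expected n(n+1)/2 = {n * (n + 1) / 2}"
                )

    def position(self, solvent_id: str) -> float:
        return self.ranks[solvent_id]

    def solvents(self) -> set[str]:
        return set(self.ranks)

    def as_series(self) -> pd.Series:
        s = pd.Series(self.ranks, name=self.method_id)
        s.index.name = "solvent_id"
        return s.sort_values(kind="stable")


# The 11 screened method combinations (canonical alphabetical member order).
COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("COSMO", "CV"),
    ("COSMO", "MC"),
    ("COSMO", "HBP"),
    ("CV", "MC"),
    ("CV", "HBP"),
    ("HBP", "MC"),
    ("COSMO", "CV", "MC"),
    ("COSMO", "CV", "HBP"),
    ("CV", "HBP", "MC"),
    ("COSMO", "HBP", "MC"),
    ("COSMO", "CV", "HBP", "MC"),
)


def combo_label(members: Iterable[str]) -> str:
    """Canonical label of a method combination: sorted members joined by '-'."""
    return "-".join(sorted(members))


def _fractional_ranks(
    values: np.ndarray, undefined: np.ndarray, direction: str
) -> np.ndarray:
    """Fractional ranks with undefined entries tied after all defined ones."""
    if direction not in ("ascending", "descending"):
        raise ValueError(f"direction must be ascending|descending, "
                         f"got {direction!r}")
    n = len(values)
    out = np.empty(n, dtype=float)
    defined = ~undefined
    n_def = int(defined.sum())
    if n_def:
        vals = values[defined]
        if direction == "descending":
            vals = -vals
        out[defined] = rankdata(vals, method="average")
    n_undef = n - n_def
    if n_undef:
        # tied among themselves, strictly after every defined score
        out[undefined] = n_def + (n_undef + 1) / 2
    return out


def rank_method(
    scores: Mapping[str, float] | pd.Series,
    direction: str,
    method_id: str = "",
    undefined: Iterable[str] = (),
) -> RankTable:
    """Rank one method's scores over the panel.

    Parameters
    ----------
    scores
        Mapping solvent_id -> score; one entry per panel solvent.  Entries
        listed in ``undefined`` (or holding NaN) are treated as undefined.
    direction
        ``"descending"`` ranks the highest score first (HBP);
        ``"ascending"`` ranks the lowest first (MC, CV, Hex).
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_dict()
    ids = list(scores)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate solvent_id in scores")
    values = np.array([scores[s] for s in ids], dtype=float)
    undef = np.array(
        [s in set(undefined) for s in ids], dtype=bool
    ) | np.isnan(values)
    ranks = _fractional_ranks(values, undef, direction)
    return RankTable(
        method_id=method_id,
        ranks=dict(zip(ids, ranks.tolist())),
        statistic={s: float(v) for s, v in zip(ids, values)},
    )


def rank_scores(scores: pd.DataFrame, method: str,
                direction: str | None = None) -> RankTable:
    """Rank a long-format score frame (one target) for one method.

    ``direction`` defaults to the method's favorability direction
    (HBP descending, others ascending).
    """
    from .scoring import METHOD_DIRECTIONS

    sub = scores[scores["method"] == method]
    if sub.empty:
        return RankTable(method_id=method, ranks={})
    if sub["solvent_id"].duplicated().any():
        dup = sub.loc[sub["solvent_id"].duplicated(), "solvent_id"].iloc[0]
        raise ValueError(f"duplicate solvent {dup!r} for method {method}")
    if direction is None:
        direction = METHOD_DIRECTIONS[method]
    undefined = sub.loc[~sub["defined"].astype(bool), "solvent_id"]
    return rank_method(
        dict(zip(sub["solvent_id"], sub["value"])),
        direction=direction,
        method_id=method,
        undefined=set(undefined),
    )


def consensus(tables: Sequence[RankTable], combo_name: str | None = None) -> RankTable:
    """Consensus ranking: re-ranked sum of fractional rank positions.

    All input tables must cover the same solvent panel.  The per-solvent
    consensus statistic is the arithmetic sum of its positions in each
    member table; the returned table ranks these sums ascending with
    fractional ties, and keeps the raw sums in ``statistic``.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("consensus requires at least two rank tables")
    panel = tables[0].solvents()
    for t in tables[1:]:
        if t.solvents() != panel:
            diff = sorted(panel.symmetric_difference(t.solvents()))
            raise ValueError(
                f"panel mismatch between {tables[0].method_id!r} and "
                f"{t.method_id!r}: {diff}"
            )
    name = combo_name or combo_label(t.method_id for t in tables)
    sums = {s: sum(t.ranks[s] for t in tables) for s in panel}
    table = rank_method(sums, direction="ascending", method_id=name)
    table.statistic = sums
    return table


def all_combinations(individual: Mapping[str, RankTable]) -> dict[str, RankTable]:
    """Build the 11 screened consensus tables from the 4 individual ones.

    ``individual`` maps method name -> RankTable and must contain exactly
    HBP, MC, CV and COSMO over one shared panel.  Keys of the result are
    canonical combination labels (alphabetical member order).
    """
    from .scoring import METHODS

    missing = [m for m in METHODS if m not in individual]
    if missing:
        raise ValueError(f"missing individual method table(s): {missing}")
    out: dict[str, RankTable] = {}
    for members in COMBINATIONS:
        label = combo_label(members)
        out[label] = consensus([individual[m] for m in members],
                               combo_name=label)
    return out


def rank_tables_to_wide(tables: Iterable[RankTable]) -> pd.DataFrame:
    """Solvent x method grid of fractional positions."""
    df = pd.concat([t.as_series() for t in tables], axis=1)
    return df.sort_index()


def rank_tables_to_long(tables: Iterable[RankTable]) -> pd.DataFrame:
    rows = [
        (t.method_id, s, pos, t.statistic.get(s, np.nan))
        for t in tables
        for s, pos in sorted(t.ranks.items())
    ]
    return pd.DataFrame(rows, columns=["method_id", "solvent_id",
                                       "position", "statistic"])
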
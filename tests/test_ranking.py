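"""Fractional rank tables, tie handling and consensus aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from solvscreen import (
    COMBINATIONS,
    RankTable,
    all_combinations,
    combo_label,
    consensus,
    rank_method,
    rank_scores,
)
from solvscreen.ranking import rank_tables_to_long, rank_tables_to_wide
from solvscreen.scoring import scores_to_frame, MethodScore


def table(name, ranks, statistic=None):
    return RankTable(name, ranks, statistic or {})


class TestRankMethod:
    def test_descending_sort(self):
        t = rank_method({"A": 0.3, "B": 0.1, "C": 0.2}, "descending")
        assert t.ranks == {"A": 1.0, "C": 2.0, "B": 3.0}

    def test_fractional_tie(self):
        t = rank_method({"A": -0.5, "B": -0.5, "C": 0.1}, "ascending")
        assert t.ranks == {"A": 1.5, "B": 1.5, "C": 3.0}

    def test_undefined_tied_after_all_defined(self):
        t = rank_method({"A": 0.4, "B": float("nan"), "C": float("nan")},
                        "descending")
        assert t.ranks == {"A": 1.0, "B": 2.5, "C": 2.5}

    def test_empty_panel_gives_empty_table(self):
        assert rank_method({}, "ascending").ranks == {}

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError, match="ascending|descending"):
            rank_method({"A": 1.0}, "downhill")

    def test_duplicate_solvent_in_frame_rejected(self):
        frame = scores_to_frame([
            MethodScore("COSMO", "T", "A", -1.0),
            MethodScore("COSMO", "T", "A", -2.0),
        ])
        with pytest.raises(ValueError, match="duplicate"):
            rank_scores(frame, "COSMO")

    @given(st.lists(st.integers(0, 3), min_size=1, max_size=12))
    def test_rank_sum_conserved(self, values):
        scores = {f"S{i}": float(v) for i, v in enumerate(values)}
        t = rank_method(scores, "ascending")
        n = len(values)
        assert sum(t.ranks.values()) == pytest.approx(n * (n + 1) / 2)

    @given(st.lists(st.integers(0, 3), min_size=2, max_size=10),
           st.randoms(use_true_random=False))
    def test_input_order_never_changes_any_rank(self, values, rnd):
        items = [(f"S{i}", float(v)) for i, v in enumerate(values)]
        t1 = rank_method(dict(items), "descending")
        rnd.shuffle(items)
        t2 = rank_method(dict(items), "descending")
        assert t1.ranks == t2.ranks

    def test_rank_table_rejects_non_conserved_sum(self):
        with pytest.raises(ValueError, match=r"n\(n\+1\)/2"):
            RankTable("bad", {"A": 1.0, "B": 1.0})


class TestConsensus:
    def test_opposite_orders_tie_everywhere(self):
        t = consensus([table("m1", {"A": 1.0, "B": 2.0}),
                       table("m2", {"A": 2.0, "B": 1.0})])
        assert t.ranks == {"A": 1.5, "B": 1.5}
        assert t.statistic == {"A": 3.0, "B": 3.0}

    def test_identical_tables_preserve_order(self):
        base = table("m", {"A": 1.0, "B": 2.0, "C": 3.0})
        t = consensus([base, base])
        assert t.ranks == base.ranks

    def test_unanimous_first_place_wins(self):
        tables = [table("m0", {"A": 1.0, "B": 2.0, "C": 3.0}),
                  table("m1", {"A": 1.0, "B": 3.0, "C": 2.0}),
                  table("m2", {"A": 1.0, "B": 2.0, "C": 3.0})]
        t = consensus(tables)
        assert t.ranks["A"] == 1.0

    def test_panel_mismatch_names_the_difference(self):
        with pytest.raises(ValueError, match="'C'"):
            consensus([table("m1", {"A": 1.0, "B": 2.0}),
                       table("m2", {"A": 1.5, "C": 1.5})])

    def test_requires_two_tables(self):
        with pytest.raises(ValueError, match="at least two"):
            consensus([table("m1", {"A": 1.0})])

    def test_improving_a_member_rank_never_worsens_the_statistic(self):
        fixed = table("m1", {"A": 2.0, "B": 1.0, "C": 3.0})
        worse = consensus([fixed, table("m2", {"A": 3.0, "B": 1.5, "C": 1.5})])
        better = consensus([fixed, table("m2", {"A": 1.0, "B": 2.5, "C": 2.5})])
        assert better.statistic["A"] <= worse.statistic["A"]


class TestAllCombinations:
    @pytest.fixture
    def individual(self):
        rng = np.random.default_rng(0)
        panel = [f"S{i}" for i in range(6)]
        out = {}
        for m in ("HBP", "MC", "CV", "COSMO"):
            scores = dict(zip(panel, rng.normal(size=len(panel))))
            out[m] = rank_method(scores, "ascending", method_id=m)
        return out

    def test_exactly_the_eleven_screened_combinations(self, individual):
        combos = all_combinations(individual)
        assert len(combos) == 11
        expected = {combo_label(c) for c in COMBINATIONS}
        assert set(combos) == expected
        # all six pairs, four of five triples, and the single four-way
        sizes = sorted(len(label.split("-")) for label in combos)
        assert sizes == [2] * 6 + [3] * 4 + [4]

    def test_pairwise_combo_equals_consensus_of_members(self, individual):
        combos = all_combinations(individual)
        direct = consensus([individual["COSMO"], individual["HBP"]])
        assert combos[combo_label(["COSMO", "HBP"])].ranks == direct.ranks

    def test_missing_method_rejected(self, individual):
        del individual["MC"]
        with pytest.raises(ValueError, match="MC"):
            all_combinations(individual)


def test_four_way_consensus_is_permutation_invariant():
    rng = np.random.default_rng(1)
    panel = [f"S{i}" for i in range(7)]
    tables = [rank_method(dict(zip(panel, rng.normal(size=7))), "ascending",
                          method_id=m)
              for m in ("HBP", "MC", "CV", "COSMO")]
    a = consensus(tables, combo_name="four")
    b = consensus(tables[::-1], combo_name="four")
    assert a.ranks == b.ranks


def test_wide_and_long_exports_agree():
    t1 = table("m1", {"A": 1.0, "B": 2.0})
    t2 = table("m2", {"A": 2.0, "B": 1.0})
    wide = rank_tables_to_wide([t1, t2])
    long = rank_tables_to_long([t1, t2])
    assert wide.loc["A", "m1"] == 1.0
    assert set(long["method_id"]) == {"m1", "m2"}
    assert len(long) == 4
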
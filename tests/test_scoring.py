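"""The four per-method scores: worked examples and structural properties."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, strategies as st

from solvscreen import (
    CVRecord,
    HexRecord,
    MCDescriptor,
    MCNormalization,
    MethodScore,
    MulticomponentCV,
    PropensityRecord,
    delta_cv,
    delta_cv_best,
    hbp_star,
    hex_score,
    mc_n,
    mc_n_best,
    score_panel,
)


def prop(pair_class, p, target="T", solvent="S"):
    return PropensityRecord(target, solvent, "d", "a", pair_class, p)


# ---------------------------------------------------------------------------
# HBP*
# ---------------------------------------------------------------------------

class TestHBPStar:
    def test_strongest_hetero_minus_strongest_homo(self):
        records = [prop("hetero", 0.62), prop("hetero", 0.35),
                   prop("homo_target", 0.41), prop("homo_solvent", 0.18)]
        assert hbp_star(records).value == pytest.approx(0.21)

    def test_equal_propensities_give_zero(self):
        records = [prop("hetero", 0.50), prop("homo_target", 0.50)]
        assert hbp_star(records).value == pytest.approx(0.0)

    def test_no_heteromeric_pairing_is_undefined_not_zero(self):
        # the alkane / dichloromethane case: nothing links the two molecules
        score = hbp_star([prop("homo_target", 0.4)])
        assert not score.defined
        assert math.isnan(score.value)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            hbp_star([])

    def test_mixed_pair_keys_rejected(self):
        with pytest.raises(ValueError, match="multiple pairs"):
            hbp_star([prop("hetero", 0.5, solvent="S1"),
                      prop("hetero", 0.5, solvent="S2")])

    @given(
        hetero=st.lists(st.floats(0, 1), min_size=1, max_size=5),
        homo=st.lists(st.floats(0, 1), min_size=1, max_size=5),
    )
    def test_defined_score_is_a_difference_of_probabilities(self, hetero, homo):
        records = [prop("hetero", p) for p in hetero] + [
            prop("homo_solvent", p) for p in homo
        ]
        score = hbp_star(records)
        assert score.defined
        assert -1.0 <= score.value <= 1.0


# ---------------------------------------------------------------------------
# MC_N
# ---------------------------------------------------------------------------

def desc(S, M, L, dipole, frac_no, species="X", conformer=0):
    return MCDescriptor(species, conformer, S, M, L, dipole, frac_no)


class TestMCN:
    def test_unit_deltas_sum_to_five(self):
        # each derived-descriptor delta equals its normalization constant,
        # so each of the five terms contributes exactly 1
        target = desc(4.0, 5.0, 8.0, 5.94, 0.294)   # S/L=0.5, M/L=0.625
        S_s = 4.0 - 3.23                            # delta S = 3.23
        L_s = S_s / (0.5 - 0.275)                   # delta(S/L) = 0.275
        M_s = (0.625 - 0.31) * L_s                  # delta(M/L) = 0.31
        solvent = desc(S_s, M_s, L_s, 0.0, 0.0)
        assert mc_n(target, solvent) == pytest.approx(5.0)

    def test_identical_descriptors_score_zero(self):
        d = desc(2.0, 3.0, 4.0, 1.5, 0.3)
        assert mc_n(d, d) == 0.0

    def test_single_term_evaluation(self):
        # only the M/L ratio differs: delta(M/L) = 0.62 -> 0.62/0.31 = 2
        target = desc(1.0, 8.0, 10.0, 1.0, 0.2)          # M/L = 0.80
        solvent = desc(1.0, 1.8, 10.0, 1.0, 0.2)         # M/L = 0.18
        assert mc_n(target, solvent) == pytest.approx(2.0)

    @given(
        st.tuples(*[st.floats(0.5, 10)] * 3),
        st.tuples(*[st.floats(0.5, 10)] * 3),
        st.floats(0, 8), st.floats(0, 8),
        st.floats(0, 1), st.floats(0, 1),
    )
    def test_symmetric_and_nonnegative(self, ax1, ax2, d1, d2, f1, f2):
        a = desc(*sorted(ax1), d1, f1)
        b = desc(*sorted(ax2), d2, f2)
        assert mc_n(a, b) == pytest.approx(mc_n(b, a))
        assert mc_n(a, b) >= 0.0


class TestMCNBest:
    def test_singleton_reduction(self):
        t, s = desc(2, 3, 4, 1, 0.2, "T"), desc(1, 2, 3, 2, 0.1, "S")
        assert mc_n_best([t], [s]).value == pytest.approx(mc_n(t, s))

    def test_matches_exhaustive_minimization(self):
        # independent oracle: recompute the formula inline over all pairs
        rng = np.random.default_rng(42)
        norm = MCNormalization()
        for _ in range(20):
            nt, ns = rng.integers(1, 6, size=2)
            ts = [desc(*sorted(rng.uniform(0.5, 8, 3)), rng.uniform(0, 6),
                       rng.uniform(0, 1), "T", i) for i in range(nt)]
            ss = [desc(*sorted(rng.uniform(0.5, 8, 3)), rng.uniform(0, 6),
                       rng.uniform(0, 1), "S", i) for i in range(ns)]
            expected = min(
                abs(t.axis_M / t.axis_L - s.axis_M / s.axis_L) / norm.w_M_over_L
                + abs(t.axis_S - s.axis_S) / norm.w_S
                + abs(t.axis_S / t.axis_L - s.axis_S / s.axis_L) / norm.w_S_over_L
                + abs(t.dipole - s.dipole) / norm.w_dipole
                + abs(t.frac_NO - s.frac_NO) / norm.w_frac_NO
                for t, s in product(ts, ss)
            )
            assert mc_n_best(ts, ss).value == pytest.approx(expected)

    def test_adding_a_conformer_never_increases_the_score(self):
        t = desc(2, 3, 4, 1, 0.2, "T")
        s1 = desc(1, 2, 3, 2, 0.1, "S")
        s2 = desc(2.1, 2.9, 4.2, 1.1, 0.22, "S", 1)
        assert (mc_n_best([t], [s1, s2]).value
                <= mc_n_best([t], [s1]).value + 1e-12)

    def test_empty_conformer_set_rejected(self):
        with pytest.raises(ValueError, match="at least one conformer"):
            mc_n_best([], [desc(1, 2, 3, 1, 0.1)])


# ---------------------------------------------------------------------------
# delta CV
# ---------------------------------------------------------------------------

class TestDeltaCV:
    def test_additive_worked_example(self):
        # |D-A| multi = |2-6| = 4; components both 2 -> (4-2)+(4-2) = 4
        score = delta_cv(CVRecord("T", 2, 4), CVRecord("S", 0, 2))
        assert score.value == pytest.approx(4.0)
        assert score.method == "CV"

    def test_balanced_species_stay_balanced(self):
        score = delta_cv(CVRecord("T", 1, 1), CVRecord("S", 2, 2))
        assert score.value == pytest.approx(0.0)

    def test_supplied_multicomponent_can_go_negative(self):
        multi = MulticomponentCV("T", "S", 1, 1, provenance="supplied")
        score = delta_cv(CVRecord("T", 2, 4), CVRecord("S", 0, 2), multi)
        assert score.value == pytest.approx(-4.0)

    @given(
        st.tuples(st.floats(0, 10), st.floats(0, 10)),
        st.tuples(st.floats(0, 10), st.floats(0, 10)),
    )
    def test_additive_form_is_swap_invariant(self, t, s):
        a = delta_cv(CVRecord("T", *t), CVRecord("S", *s))
        b = delta_cv(CVRecord("S", *s), CVRecord("T", *t))
        assert a.value == pytest.approx(b.value)

    def test_negative_coordination_value_rejected(self):
        with pytest.raises(Exception, match=">= 0"):
            CVRecord("T", -1, 2)

    def test_best_over_conformers_matches_brute_force(self):
        rng = np.random.default_rng(7)
        ts = [CVRecord("T", *rng.integers(0, 6, 2).astype(float), i)
              for i in range(3)]
        ss = [CVRecord("S", *rng.integers(0, 6, 2).astype(float), i)
              for i in range(4)]
        expected = min(
            (abs((t.D + s.D) - (t.A + s.A)) - abs(t.D - t.A))
            + (abs((t.D + s.D) - (t.A + s.A)) - abs(s.D - s.A))
            for t, s in product(ts, ss)
        )
        assert delta_cv_best(ts, ss).value == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Hex
# ---------------------------------------------------------------------------

class TestHexScore:
    @pytest.mark.parametrize("hex_value", [-3.1, 0.0, 1.7])
    def test_identity_passthrough(self, hex_value):
        score = hex_score(HexRecord("T", "S", hex_value))
        assert score.value == hex_value
        assert score.method == "COSMO"

    def test_non_finite_rejected(self):
        with pytest.raises(Exception, match="finite"):
            hex_score(HexRecord("T", "S", float("nan")))


# ---------------------------------------------------------------------------
# Panel-level scoring
# ---------------------------------------------------------------------------

class TestScorePanel:
    def test_one_score_per_method_and_solvent(self, tiny_bundle):
        scores = score_panel(tiny_bundle, "T")
        counts = scores.groupby("method").size()
        assert set(counts.index) == {"HBP", "MC", "CV", "COSMO"}
        assert (counts == 3).all()

    def test_undefined_hbp_propagated_not_dropped(self, tiny_bundle):
        # solvent C has no propensity records at all
        scores = score_panel(tiny_bundle, "T")
        row = scores[(scores["method"] == "HBP")
                     & (scores["solvent_id"] == "C")]
        assert len(row) == 1
        assert not row["defined"].iloc[0]

    def test_undefined_forbidden_outside_hbp(self):
        with pytest.raises(ValueError, match="only permitted for HBP"):
            MethodScore("MC", "T", "S", float("nan"), defined=False)
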
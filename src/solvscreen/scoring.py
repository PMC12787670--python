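"""Per-method solvate-formation scores.

Four methods score a target--solvent pair:

HBP*  (hydrogen-bond propensity difference)
    ``HBP* = max(P_hetero) - max(P_homo)``, the strongest heteromeric
    (target--solvent) hydrogen-bond propensity minus the strongest homomeric
    one (target--target or solvent--solvent pooled).  Positive values favor
    solvate formation; solvents are ranked by descending HBP*.  A solvent
    with no heteromeric donor--acceptor pairing at all (e.g. an alkane or
    dichloromethane) has an *undefined* HBP*, which is kept as a flagged
    undefined score rather than coerced to zero.

MC_N  (normalized molecular complementarity)
    ``MC_N = |d(M/L)|/0.31 + |dS|/3.23 + |d(S/L)|/0.275 + |d dipole|/5.94
    + |d frac_NO|/0.294`` where each ``d`` is the target-minus-solvent
    difference of the derived descriptor.  Lower = more complementary;
    ranked ascending.  With multiple conformers per species the minimum
    over all conformer pairs is taken (the most complementary accessible
    pairing).

dCV  (coordination-value mismatch)
    ``dCV = (|D-A|_multi - |D-A|_target) + (|D-A|_multi - |D-A|_solvent)``:
    the donor/acceptor imbalance of the multicomponent system relative to
    each pure component.  Lower = more favorable; ranked ascending.  When
    no multicomponent coordination values are supplied they default to the
    additive combination ``D_multi = D_target + D_solvent`` (likewise A),
    recorded via ``provenance='additive'``.

Hex  (excess enthalpy)
    The excess enthalpy of mixing in kcal/mol, passed through unchanged;
    more negative = stronger interaction; ranked ascending.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import (
    CVRecord,
    DescriptorBundle,
    HexRecord,
    MCDescriptor,
    MCNormalization,
    MulticomponentCV,
    PropensityRecord,
)

__all__ = [
    "METHODS",
    "METHOD_DIRECTIONS",
    "MethodScore",
    "hbp_star",
    "mc_n",
    "mc_n_best",
    "delta_cv",
    "delta_cv_best",
    "hex_score",
    "score_panel",
    "scores_to_frame",
]

METHODS = ("HBP", "MC", "CV", "COSMO")

#: Favorability direction used when ranking each method's scores.
METHOD_DIRECTIONS = {
    "HBP": "descending",   # higher propensity difference is better
    "MC": "ascending",     # lower dissimilarity is better
    "CV": "ascending",     # lower mismatch is better
    "COSMO": "ascending",  # more negative excess enthalpy is better
}


@dataclass(frozen=True)
class MethodScore:
    """A single method's score for one target--solvent pair.

    ``defined=False`` is permitted only for HBP (a solvent with no
    donor--acceptor pairing to the target); it is propagated through
    ranking, never silently dropped.
    """

    method: str
    target_id: str
    solvent_id: str
    value: float
    defined: bool = True

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not self.defined and self.method != "HBP":
            raise ValueError(
                f"defined=False only permitted for HBP, not {self.method}"
            )


# ---------------------------------------------------------------------------
# HBP*
# ---------------------------------------------------------------------------

def hbp_star(propensities: Sequence[PropensityRecord]) -> MethodScore:
    """Best heteromeric minus best homomeric hydrogen-bond propensity.

    All records must belong to the same (target, solvent) pair.  If the
    pair has no heteromeric record the score is undefined (``defined=False``,
    value NaN): nothing in the propensity model connects the two molecules,
    which is not the same as a zero-propensity connection.
    """
    records = list(propensities)
    if not records:
        raise ValueError("hbp_star requires at least one propensity record")
    keys = {(r.target_id, r.solvent_id) for r in records}
    if len(keys) != 1:
        raise ValueError(
            f"hbp_star received records for multiple pairs: {sorted(keys)}"
        )
    target_id, solvent_id = next(iter(keys))

    hetero = [r.propensity for r in records if r.pair_class == "hetero"]
    homo = [r.propensity for r in records
            if r.pair_class in ("homo_target", "homo_solvent")]
    if not hetero:
        return MethodScore("HBP", target_id, solvent_id, float("nan"),
                           defined=False)
    best_homo = max(homo) if homo else 0.0
    return MethodScore("HBP", target_id, solvent_id, max(hetero) - best_homo)


# ---------------------------------------------------------------------------
# MC_N
# ---------------------------------------------------------------------------

def mc_n(
    target: MCDescriptor,
    solvent: MCDescriptor,
    norm: MCNormalization = MCNormalization(),
) -> float:
    """Normalized complementarity dissimilarity of one conformer pair.

    Sum of the absolute differences of the five derived descriptors
    (M/L ratio, S axis, S/L ratio, dipole, N+O fraction), each divided by
    its normalization constant.  Zero iff all five derived descriptors
    coincide; symmetric in its two arguments.
    """
    d_ml = target.axis_M / target.axis_L - solvent.axis_M / solvent.axis_L
    d_s = target.axis_S - solvent.axis_S
    d_sl = target.axis_S / target.axis_L - solvent.axis_S / solvent.axis_L
    d_dip = target.dipole - solvent.dipole
    d_no = target.frac_NO - solvent.frac_NO
    return (
        abs(d_ml) / norm.w_M_over_L
        + abs(d_s) / norm.w_S
        + abs(d_sl) / norm.w_S_over_L
        + abs(d_dip) / norm.w_dipole
        + abs(d_no) / norm.w_frac_NO
    )


def mc_n_best(
    target_conformers: Sequence[MCDescriptor],
    solvent_conformers: Sequence[MCDescriptor],
    norm: MCNormalization = MCNormalization(),
) -> MethodScore:
    """Minimum MC_N over all target x solvent conformer pairs.

    Conformers are generated to improve accessibility; the most
    complementary accessible pairing represents the pair.
    """
    targets = list(target_conformers)
    solvents = list(solvent_conformers)
    if not targets or not solvents:
        raise ValueError("mc_n_best requires at least one conformer per species")
    best = min(mc_n(t, s, norm) for t, s in product(targets, solvents))
    return MethodScore("MC", targets[0].species_id, solvents[0].species_id, best)


# ---------------------------------------------------------------------------
# delta CV
# ---------------------------------------------------------------------------

def _imbalance(D: float, A: float) -> float:
    return abs(D - A)


def delta_cv(
    target: CVRecord,
    solvent: CVRecord,
    multi: MulticomponentCV | None = None,
) -> MethodScore:
    """Coordination-value mismatch of the multicomponent system.

    With ``multi=None`` the multicomponent coordination values are formed
    additively from the components (provenance ``additive``).
    """
    if multi is None:
        multi = MulticomponentCV(
            target_id=target.species_id,
            solvent_id=solvent.species_id,
            D=target.D + solvent.D,
            A=target.A + solvent.A,
            provenance="additive",
        )
    value = (_imbalance(multi.D, multi.A) - _imbalance(target.D, target.A)) + (
        _imbalance(multi.D, multi.A) - _imbalance(solvent.D, solvent.A)
    )
    return MethodScore("CV", multi.target_id, multi.solvent_id, value)


def delta_cv_best(
    target_conformers: Sequence[CVRecord],
    solvent_conformers: Sequence[CVRecord],
    multi: MulticomponentCV | None = None,
) -> MethodScore:
    """Minimum delta CV over all conformer combinations.

    When ``multi`` is supplied it is held fixed across conformer pairs;
    otherwise the additive multicomponent values are rebuilt per pair.
    """
    targets = list(target_conformers)
    solvents = list(solvent_conformers)
    if not targets or not solvents:
        raise ValueError(
            "delta_cv_best requires at least one conformer per species"
        )
    scores = [delta_cv(t, s, multi) for t, s in product(targets, solvents)]
    best = min(scores, key=lambda s: s.value)
    return best


# ---------------------------------------------------------------------------
# Hex
# ---------------------------------------------------------------------------

def hex_score(record: HexRecord) -> MethodScore:
    """Excess enthalpy passed through as the COSMO method score."""
    if not np.isfinite(record.hex):
        raise ValueError(f"hex must be finite, got {record.hex}")
    return MethodScore("COSMO", record.target_id, record.solvent_id,
                       float(record.hex))


# ---------------------------------------------------------------------------
# Panel-level scoring
# ---------------------------------------------------------------------------

def _mc_descriptors(mc: pd.DataFrame, species_id: str) -> list[MCDescriptor]:
    rows = mc[mc["species_id"] == species_id]
    return [
        MCDescriptor(species_id, int(r.conformer_id), float(r.axis_S),
                     float(r.axis_M), float(r.axis_L), float(r.dipole),
                     float(r.frac_NO))
        for r in rows.itertuples()
    ]


def _cv_records(cv: pd.DataFrame, species_id: str) -> list[CVRecord]:
    rows = cv[cv["species_id"] == species_id]
    return [
        CVRecord(species_id, float(r.D), float(r.A), int(r.conformer_id))
        for r in rows.itertuples()
    ]


def score_panel(
    bundle: DescriptorBundle,
    target_id: str,
    norm: MCNormalization = MCNormalization(),
    methods: Iterable[str] = METHODS,
) -> pd.DataFrame:
    """Score every panel solvent against ``target_id`` with each method.

    Returns a long-format frame with columns
    ``method, target_id, solvent_id, value, defined``, one row per
    (method, solvent).  Solvents are taken from the bundle's panel; a
    solvent lacking the inputs a method needs raises, except for HBP where
    a missing heteromeric pairing yields an undefined score by design.
    """
    methods = list(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown method(s): {sorted(unknown)}")
    solvent_ids = [s for s in bundle.solvent_ids() if s != target_id]
    out: list[MethodScore] = []

    prop = bundle.propensity
    prop_pair = prop[prop["target_id"] == target_id]
    hexes = bundle.hex[bundle.hex["target_id"] == target_id]
    mcv = bundle.multicomponent_cv

    for sid in solvent_ids:
        if "HBP" in methods:
            rows = prop_pair[prop_pair["solvent_id"] == sid]
            records = [
                PropensityRecord(target_id, sid, str(r.donor_group),
                                 str(r.acceptor_group), str(r.pair_class),
                                 float(r.propensity))
                for r in rows.itertuples()
            ]
            if records:
                out.append(hbp_star(records))
            else:
                # no propensity rows at all: solvent has no donors/acceptors
                out.append(MethodScore("HBP", target_id, sid, float("nan"),
                                       defined=False))
        if "MC" in methods:
            out.append(mc_n_best(_mc_descriptors(bundle.mc, target_id),
                                 _mc_descriptors(bundle.mc, sid), norm))
        if "CV" in methods:
            multi = None
            if mcv is not None:
                m = mcv[(mcv["target_id"] == target_id)
                        & (mcv["solvent_id"] == sid)]
                if len(m):
                    r = m.iloc[0]
                    multi = MulticomponentCV(target_id, sid, float(r["D"]),
                                             float(r["A"]),
                                             str(r["provenance"]))
            out.append(delta_cv_best(_cv_records(bundle.cv, target_id),
                                     _cv_records(bundle.cv, sid), multi))
        if "COSMO" in methods:
            h = hexes[hexes["solvent_id"] == sid]
            if not len(h):
                raise ValueError(
                    f"no excess-enthalpy record for pair "
                    f"({target_id}, {sid})"
                )
            out.append(hex_score(HexRecord(target_id, sid,
                                           float(h["hex"].iloc[0]))))
    return scores_to_frame(out)


def scores_to_frame(scores: Iterable[MethodScore]) -> pd.DataFrame:
    """Long-format export: method, target_id, solvent_id, value, defined."""
    return pd.DataFrame(
        [(s.method, s.target_id, s.solvent_id, s.value, s.defined)
         for s in scores],
        columns=["method", "target_id", "solvent_id", "value", "defined"],
    )
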
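"""Descriptor tables, outcome panels and their delimited-text schemas.

Every downstream stage (scoring, ranking, evaluation) consumes the validated
tables defined here.  Five CSV schemas are supported, all comma-separated,
UTF-8, with a mandatory header row and ``.`` as decimal separator:

``propensity``
    One row per donor--acceptor pair for a target--solvent system:
    ``target_id, solvent_id, donor_group, acceptor_group, pair_class,
    propensity``.  ``pair_class`` is one of ``hetero`` (target--solvent),
    ``homo_target`` (target--target) or ``homo_solvent`` (solvent--solvent);
    ``propensity`` is a probability in [0, 1].

``mc``
    One row per conformer of a species: ``species_id, conformer_id, axis_S,
    axis_M, axis_L, dipole, frac_NO``.  Axes are in angstroms and must
    satisfy 0 < S <= M <= L; ``dipole`` is in Debye; ``frac_NO`` is the
    fraction of nitrogen plus oxygen atoms, in [0, 1].

``cv``
    One row per conformer: ``species_id, conformer_id, D, A`` — the donor
    and acceptor hydrogen-bond coordination values, both >= 0.

``hex``
    One row per target--solvent pair: ``target_id, solvent_id, hex`` — the
    excess enthalpy of mixing in kcal/mol (negative = favorable).

``outcomes``
    One row per tested compound--solvent pair: ``compound_id, solvent_id,
    formed, evidence`` with ``evidence`` in {structure, unit_cell,
    literature, ambiguous}.  Pairs absent from the table are treated as
    not formed (closed world); a ``formed=False`` row records a pair that
    was tested and did not yield a solvate.

Solvent identity is by caller-supplied label, not by SMILES canonicalization:
descriptor exports from crystallographic and thermodynamic screening tools
key on solvent names, and so do we.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "SolventRecord",
    "PropensityRecord",
    "MCDescriptor",
    "MCNormalization",
    "CVRecord",
    "MulticomponentCV",
    "HexRecord",
    "OutcomePanel",
    "DescriptorBundle",
    "PAIR_CLASSES",
    "EVIDENCE_CLASSES",
    "read_panel",
    "write_panel",
    "builtin_outcomes",
]


class SchemaError(ValueError):
    """A table is missing a required column or is otherwise malformed."""


class ValidationError(ValueError):
    """A value violates a documented invariant; message names row and field."""


PAIR_CLASSES = ("hetero", "homo_target", "homo_solvent")
EVIDENCE_CLASSES = ("structure", "unit_cell", "literature", "ambiguous")


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolventRecord:
    """A solvent in the screening panel, keyed by a short unique label."""

    solvent_id: str
    name: str = ""
    smiles: str | None = None

    def __post_init__(self) -> None:
        if not self.solvent_id:
            raise ValidationError("solvent_id must be non-empty")


@dataclass(frozen=True)
class PropensityRecord:
    """One donor--acceptor hydrogen-bond propensity for a target--solvent pair.

    ``propensity`` is the statistical probability that the donor--acceptor
    pair forms a hydrogen bond, as produced by propensity models trained on
    crystal-structure databases.
    """

    target_id: str
    solvent_id: str
    donor_group: str
    acceptor_group: str
    pair_class: str
    propensity: float

    def __post_init__(self) -> None:
        if self.pair_class not in PAIR_CLASSES:
            raise ValidationError(
                f"pair_class {self.pair_class!r} not one of {PAIR_CLASSES}"
            )
        if not 0.0 <= self.propensity <= 1.0:
            raise ValidationError(
                f"propensity {self.propensity} outside [0, 1]"
            )


@dataclass(frozen=True)
class MCDescriptor:
    """Shape/polarity descriptors of one conformer.

    Axes in angstroms with 0 < S <= M <= L; dipole moment in Debye;
    ``frac_NO`` the fraction of N + O atoms among all atoms.
    """

    species_id: str
    conformer_id: int
    axis_S: float
    axis_M: float
    axis_L: float
    dipole: float
    frac_NO: float

    def __post_init__(self) -> None:
        if self.conformer_id < 0:
            raise ValidationError("conformer_id must be >= 0")
        if not (0.0 < self.axis_S <= self.axis_M <= self.axis_L):
            raise ValidationError(
                f"axes must satisfy 0 < S <= M <= L, got "
                f"S={self.axis_S}, M={self.axis_M}, L={self.axis_L}"
            )
        if not 0.0 <= self.frac_NO <= 1.0:
            raise ValidationError(f"frac_NO {self.frac_NO} outside [0, 1]")
        if self.dipole < 0:
            raise ValidationError(f"dipole {self.dipole} must be >= 0")


@dataclass(frozen=True)
class MCNormalization:
    """Divisors normalizing the five complementarity deltas.

    Defaults are the published calibration of the normalized molecular
    complementarity score: each delta is divided by its constant so the five
    terms contribute on a common scale.
    """

    w_M_over_L: float = 0.31
    w_S: float = 3.23
    w_S_over_L: float = 0.275
    w_dipole: float = 5.94
    w_frac_NO: float = 0.294

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValidationError(f"normalization {name} must be > 0")


@dataclass(frozen=True)
class CVRecord:
    """Donor (D) and acceptor (A) coordination values for one conformer."""

    species_id: str
    D: float
    A: float
    conformer_id: int = 0

    def __post_init__(self) -> None:
        if self.D < 0 or self.A < 0:
            raise ValidationError(
                f"coordination values must be >= 0, got D={self.D}, A={self.A}"
            )
        if self.conformer_id < 0:
            raise ValidationError("conformer_id must be >= 0")


@dataclass(frozen=True)
class MulticomponentCV:
    """Coordination values of the combined target + solvent system.

    ``provenance`` records whether D/A were supplied by an external
    calculation (``supplied``) or formed additively from the component
    conformer values (``additive``).
    """

    target_id: str
    solvent_id: str
    D: float
    A: float
    provenance: str = "supplied"

    def __post_init__(self) -> None:
        if self.D < 0 or self.A < 0:
            raise ValidationError(
                f"coordination values must be >= 0, got D={self.D}, A={self.A}"
            )
        if self.provenance not in ("supplied", "additive"):
            raise ValidationError(
                f"provenance {self.provenance!r} not in ('supplied', 'additive')"
            )


@dataclass(frozen=True)
class HexRecord:
    """Excess enthalpy of mixing for a target--solvent pair (kcal/mol)."""

    target_id: str
    solvent_id: str
    hex: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.hex):
            raise ValidationError(f"hex must be finite, got {self.hex}")


# ---------------------------------------------------------------------------
# Outcome panel
# ---------------------------------------------------------------------------

@dataclass
class OutcomePanel:
    """Confirmed solvate-formation outcomes per compound--solvent pair.

    Closed-world semantics: a pair absent from ``entries`` is reported as
    not formed and not tested.  A present row with ``formed=False`` records
    a tested pair that yielded no solvate.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        self.entries = validate_outcomes(self.entries)

    def formed(self, compound_id: str, solvent_id: str) -> bool:
        """Whether the pair is a confirmed former (False if unknown)."""
        m = (self.entries["compound_id"] == compound_id) & (
            self.entries["solvent_id"] == solvent_id
        )
        if not m.any():
            return False
        return bool(self.entries.loc[m, "formed"].iloc[0])

    def tested(self, compound_id: str, solvent_id: str) -> bool:
        """Whether the pair appears in the panel at all."""
        m = (self.entries["compound_id"] == compound_id) & (
            self.entries["solvent_id"] == solvent_id
        )
        return bool(m.any())

    def evidence(self, compound_id: str, solvent_id: str) -> str | None:
        m = (self.entries["compound_id"] == compound_id) & (
            self.entries["solvent_id"] == solvent_id
        )
        if not m.any():
            return None
        return str(self.entries.loc[m, "evidence"].iloc[0])

    def confirmed_solvents(
        self, compound_id: str, include_ambiguous: bool = True
    ) -> set[str]:
        """The set of solvents confirmed to form a solvate with ``compound_id``.

        ``include_ambiguous=False`` drops entries whose evidence class is
        ``ambiguous`` (e.g. a reported solvate that later proved
        indistinguishable from a hydrate).
        """
        df = self.entries
        m = (df["compound_id"] == compound_id) & df["formed"]
        if not include_ambiguous:
            m &= df["evidence"] != "ambiguous"
        return set(df.loc[m, "solvent_id"])

    def compounds(self) -> list[str]:
        return sorted(self.entries["compound_id"].unique())


# ---------------------------------------------------------------------------
# Table validation
# ---------------------------------------------------------------------------

_SCHEMAS: dict[str, list[str]] = {
    "propensity": [
        "target_id", "solvent_id", "donor_group", "acceptor_group",
        "pair_class", "propensity",
    ],
    "mc": [
        "species_id", "conformer_id", "axis_S", "axis_M", "axis_L",
        "dipole", "frac_NO",
    ],
    "cv": ["species_id", "conformer_id", "D", "A"],
    "hex": ["target_id", "solvent_id", "hex"],
    "outcomes": ["compound_id", "solvent_id", "formed", "evidence"],
    "solvents": ["solvent_id", "name"],
    "multicomponent_cv": ["target_id", "solvent_id", "D", "A", "provenance"],
}


def _require_columns(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in _SCHEMAS[table] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{table} table missing required column(s): {', '.join(missing)}"
        )


def _check(df: pd.DataFrame, table: str, column: str, ok: pd.Series, bound: str) -> None:
    """Raise ValidationError naming the first offending row if any check fails."""
    bad = ~ok.to_numpy(dtype=bool)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"{table} table, row {row}, column {column!r}: "
            f"value {df[column].iloc[row]!r} violates {bound}"
        )


def validate_propensity(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, "propensity")
    df = df.copy()
    df["propensity"] = pd.to_numeric(df["propensity"], errors="coerce")
    _check(df, "propensity", "propensity",
           df["propensity"].notna() & (df["propensity"] >= 0) & (df["propensity"] <= 1),
           "0 <= propensity <= 1")
    _check(df, "propensity", "pair_class",
           df["pair_class"].isin(PAIR_CLASSES),
           f"pair_class in {PAIR_CLASSES}")
    return df.reset_index(drop=True)


def validate_mc(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, "mc")
    df = df.copy()
    for c in ("axis_S", "axis_M", "axis_L", "dipole", "frac_NO"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
        _check(df, "mc", c, df[c].notna(), "a finite number")
    df["conformer_id"] = pd.to_numeric(df["conformer_id"], errors="coerce")
    _check(df, "mc", "conformer_id",
           df["conformer_id"].notna() & (df["conformer_id"] >= 0),
           "conformer_id >= 0")
    _check(df, "mc", "axis_S", df["axis_S"] > 0, "axis_S > 0")
    _check(df, "mc", "axis_S", df["axis_S"] <= df["axis_M"],
           "axis ordering S <= M <= L")
    _check(df, "mc", "axis_M", df["axis_M"] <= df["axis_L"],
           "axis ordering S <= M <= L")
    _check(df, "mc", "dipole", df["dipole"] >= 0, "dipole >= 0")
    _check(df, "mc", "frac_NO",
           (df["frac_NO"] >= 0) & (df["frac_NO"] <= 1), "0 <= frac_NO <= 1")
    df["conformer_id"] = df["conformer_id"].astype(int)
    return df.reset_index(drop=True)


def validate_cv(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, "cv")
    df = df.copy()
    for c in ("D", "A"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
        _check(df, "cv", c, df[c].notna() & (df[c] >= 0), f"{c} >= 0")
    df["conformer_id"] = pd.to_numeric(df["conformer_id"], errors="coerce")
    _check(df, "cv", "conformer_id",
           df["conformer_id"].notna() & (df["conformer_id"] >= 0),
           "conformer_id >= 0")
    df["conformer_id"] = df["conformer_id"].astype(int)
    return df.reset_index(drop=True)


def validate_hex(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, "hex")
    df = df.copy()
    df["hex"] = pd.to_numeric(df["hex"], errors="coerce")
    _check(df, "hex", "hex",
           df["hex"].notna() & np.isfinite(df["hex"]), "a finite number")
    return df.reset_index(drop=True)


def validate_outcomes(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, "outcomes")
    df = df.copy()
    if df["formed"].dtype != bool:
        mapping = {"true": True, "false": False, "1": True, "0": False,
                   True: True, False: False}
        formed = df["formed"].map(
            lambda v: mapping.get(str(v).strip().lower(), None)
        )
        _check(df.assign(formed=formed), "outcomes", "formed",
               formed.notna(), "a boolean (true/false)")
        df["formed"] = formed.astype(bool)
    _check(df, "outcomes", "evidence",
           df["evidence"].isin(EVIDENCE_CLASSES),
           f"evidence in {EVIDENCE_CLASSES}")
    dup = df.duplicated(subset=["compound_id", "solvent_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        pair = (df["compound_id"].iloc[row], df["solvent_id"].iloc[row])
        raise ValidationError(
            f"outcomes table, row {row}: duplicate (compound_id, solvent_id) "
            f"pair {pair}"
        )
    return df.reset_index(drop=True)


def validate_solvents(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, "solvents")
    df = df.copy()
    _check(df, "solvents", "solvent_id",
           df["solvent_id"].astype(str).str.len() > 0, "a non-empty label")
    dup = df.duplicated(subset=["solvent_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"solvents table, row {row}: duplicate solvent_id "
            f"{df['solvent_id'].iloc[row]!r}"
        )
    return df.reset_index(drop=True)


def validate_multicomponent_cv(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, "multicomponent_cv")
    df = df.copy()
    for c in ("D", "A"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
        _check(df, "multicomponent_cv", c, df[c].notna() & (df[c] >= 0),
               f"{c} >= 0")
    _check(df, "multicomponent_cv", "provenance",
           df["provenance"].isin(("supplied", "additive")),
           "provenance in ('supplied', 'additive')")
    return df.reset_index(drop=True)


_VALIDATORS = {
    "propensity": validate_propensity,
    "mc": validate_mc,
    "cv": validate_cv,
    "hex": validate_hex,
    "outcomes": validate_outcomes,
    "solvents": validate_solvents,
    "multicomponent_cv": validate_multicomponent_cv,
}


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class DescriptorBundle:
    """The four validated descriptor tables plus optional side tables."""

    propensity: pd.DataFrame
    mc: pd.DataFrame
    cv: pd.DataFrame
    hex: pd.DataFrame
    solvents: pd.DataFrame | None = None
    multicomponent_cv: pd.DataFrame | None = None
    outcomes: OutcomePanel | None = None

    def solvent_ids(self) -> list[str]:
        """Panel solvent labels: the solvents table if present, else the
        union of solvent_id across the hex and propensity tables."""
        if self.solvents is not None:
            return list(self.solvents["solvent_id"])
        ids = set(self.hex["solvent_id"]) | set(self.propensity["solvent_id"])
        return sorted(ids)

    def target_ids(self) -> list[str]:
        return sorted(set(self.hex["target_id"]))

    def to_json(self) -> str:
        """JSON export of the validated bundle (records orientation)."""
        payload: dict[str, object] = {
            name: getattr(self, name).to_dict(orient="records")
            for name in ("propensity", "mc", "cv", "hex")
        }
        if self.solvents is not None:
            payload["solvents"] = self.solvents.to_dict(orient="records")
        if self.multicomponent_cv is not None:
            payload["multicomponent_cv"] = self.multicomponent_cv.to_dict(
                orient="records")
        if self.outcomes is not None:
            payload["outcomes"] = self.outcomes.entries.to_dict(
                orient="records")
        return json.dumps(payload, indent=2, sort_keys=True)


_FILENAMES = {
    "propensity": "propensity.csv",
    "mc": "mc.csv",
    "cv": "cv.csv",
    "hex": "hex.csv",
    "outcomes": "outcomes.csv",
    "solvents": "solvents.csv",
    "multicomponent_cv": "multicomponent_cv.csv",
}


def read_panel(paths: Mapping[str, str | Path] | str | Path) -> DescriptorBundle:
    """Read and validate a descriptor panel.

    ``paths`` is either a directory containing the standard file names
    (``propensity.csv``, ``mc.csv``, ``cv.csv``, ``hex.csv`` and optionally
    ``outcomes.csv``, ``solvents.csv``, ``multicomponent_cv.csv``) or a
    mapping from table name to file path.

    Raises
    ------
    SchemaError
        A required file or column is missing.
    ValidationError
        A value violates an invariant; the message names the row, column
        and violated bound.
    """
    if isinstance(paths, (str, Path)):
        root = Path(paths)
        mapping = {
            name: root / fname
            for name, fname in _FILENAMES.items()
            if (root / fname).exists()
        }
    else:
        mapping = {k: Path(v) for k, v in paths.items()}

    for required in ("propensity", "mc", "cv", "hex"):
        if required not in mapping:
            raise SchemaError(f"no {required} table provided")
        if not mapping[required].exists():
            raise SchemaError(f"{required} file not found: {mapping[required]}")

    tables: dict[str, pd.DataFrame] = {}
    for name, path in mapping.items():
        if name not in _VALIDATORS:
            raise SchemaError(f"unknown table name {name!r}")
        tables[name] = _VALIDATORS[name](pd.read_csv(path))

    outcomes = None
    if "outcomes" in tables:
        outcomes = OutcomePanel(tables["outcomes"])
    return DescriptorBundle(
        propensity=tables["propensity"],
        mc=tables["mc"],
        cv=tables["cv"],
        hex=tables["hex"],
        solvents=tables.get("solvents"),
        multicomponent_cv=tables.get("multicomponent_cv"),
        outcomes=outcomes,
    )


def write_panel(bundle: DescriptorBundle, directory: str | Path) -> dict[str, Path]:
    """Write every table of ``bundle`` to ``directory``; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in ("propensity", "mc", "cv", "hex", "solvents",
                 "multicomponent_cv"):
        df = getattr(bundle, name)
        if df is None:
            continue
        path = directory / _FILENAMES[name]
        df.to_csv(path, index=False)
        written[name] = path
    if bundle.outcomes is not None:
        path = directory / _FILENAMES["outcomes"]
        bundle.outcomes.entries.to_csv(path, index=False)
        written["outcomes"] = path
    return written


# ---------------------------------------------------------------------------
# Built-in confirmed-solvate fixture
# ---------------------------------------------------------------------------

def builtin_outcomes() -> OutcomePanel:
    """Confirmed solvate formers of the three curcuminoids.

    Curated from reported crystal structures, unit-cell-only determinations
    and literature descriptions of curcumin (CUR), demethoxycurcumin (DMC)
    and bisdemethoxycurcumin (BDMC) solvates and hydrates:

    - CUR: 1,4-dioxane (DOX), acetone (ACE), dichloromethane (DCM) and
      methyl acetate (MAC), water, and DMSO (unit-cell only).
    - BDMC: DOX, isopropanol (ISP), acetone, methanol (MET), water,
      tetrahydrofuran (THF, ambiguous: the reported phase may be a distinct
      hydrate rather than a genuine THF solvate) and DMSO (literature).
    - DMC: DOX and acetonitrile (ACN, unit-cell only).

    Water is a rankable solvent here, so hydrates count as confirmed
    formers.  Pairs absent from the panel are treated as not formed.
    """
    rows = [
        # compound, solvent, formed, evidence
        ("CUR", "DOX", True, "structure"),       # e.g. LADXEX, LADXIB
        ("CUR", "ACE", True, "structure"),       # FIHRUN
        ("CUR", "DCM", True, "structure"),       # OJIWOV (weak-contact solvate)
        ("CUR", "MAC", True, "literature"),
        ("CUR", "WATER", True, "literature"),
        ("CUR", "DMSO", True, "unit_cell"),
        ("BDMC", "DOX", True, "structure"),
        ("BDMC", "ISP", True, "structure"),      # XIWDEP
        ("BDMC", "ACE", True, "structure"),      # XIWDAL
        ("BDMC", "MET", True, "structure"),      # BUWKUZ
        ("BDMC", "WATER", True, "structure"),    # GANJAG and two new hydrates
        ("BDMC", "THF", True, "ambiguous"),
        ("BDMC", "DMSO", True, "literature"),
        ("DMC", "DOX", True, "structure"),
        ("DMC", "ACN", True, "unit_cell"),
    ]
    return OutcomePanel(pd.DataFrame(
        rows, columns=["compound_id", "solvent_id", "formed", "evidence"]
    ))
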
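"""Seeded synthetic descriptor panels with planted solvate formers.

The generator emulates the statistical shape of a solvate-screening data
set — a panel of polar and nonpolar solvents scored against one target
compound — without any external crystallographic or quantum-chemistry
software.  A known subset of "true former" solvents is planted:

- their heteromeric hydrogen-bond propensities are shifted up by
  ``hetero_boost`` (clamped to 1), so the propensity-difference method
  can find them;
- their excess enthalpies are shifted by ``hex_shift`` kcal/mol (negative
  = favorable), so the enthalpy ranking can find them;
- the shape/polarity and coordination-value channels carry *no* planted
  signal, mirroring the empirical situation where hydrogen bonding, not
  molecular shape, drives solvate formation.  This gives the test suite a
  known method ordering: HBP and COSMO informative, MC and CV not.

A small fraction of non-former solvents (default 1 in 48) is generated
with no hydrogen-bond donors or acceptors at all — no propensity records —
to exercise the undefined-propensity path (the dichloromethane case).

Each descriptor table draws from its own pseudo-random stream derived from
the master seed by a fixed labeled offset, so adding or regenerating one
table never perturbs the draws of the others.  A fixed seed yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .io import (
    DescriptorBundle,
    OutcomePanel,
    validate_cv,
    validate_hex,
    validate_mc,
    validate_propensity,
    validate_solvents,
)

__all__ = ["PanelConfig", "PanelTruth", "generate_panel", "null_panel"]

# fixed labeled stream offsets: one stream per table
_STREAMS = {
    "labels": 0,
    "propensity": 1,
    "mc": 2,
    "cv": 3,
    "hex": 4,
}


@dataclass(frozen=True)
class PanelConfig:
    """Configuration of one synthetic screening panel.

    Parameters
    ----------
    n_solvents
        Panel size; 48 matches a typical polar + nonpolar screening set.
    n_formers
        Number of planted true solvate formers.
    seed
        Master seed; fixed seed implies fully deterministic output.
    hetero_boost
        Upward shift (propensity units, in (0, 1)) applied to the formers'
        heteromeric propensities, clamped to 1.
    hex_shift
        Shift (kcal/mol) applied to the formers' excess enthalpies;
        negative = favorable.
    hex_noise_sd
        Standard deviation (kcal/mol) of the excess-enthalpy noise.
    propensity_concentration
        Concentration (a + b) of the Beta distribution propensities are
        drawn from (mean fixed at 0.4): larger = tighter around the mean.
    mc_axis_scale
        Median molecular-axis length (angstrom) for the log-scale axis draw.
    cv_rate
        Mean donor/acceptor coordination value (counts-like Poisson rate).
    no_hb_fraction
        Fraction of solvents generated with no hydrogen-bond donors or
        acceptors (no propensity records; undefined propensity score).
    target_id
        Label of the single target compound the panel is scored against.
    """

    n_solvents: int = 48
    n_formers: int = 6
    seed: int = 0
    hetero_boost: float = 0.25
    hex_shift: float = -2.0
    hex_noise_sd: float = 1.0
    propensity_concentration: float = 4.0
    mc_axis_scale: float = 4.0
    cv_rate: float = 2.0
    no_hb_fraction: float = 1.0 / 48.0
    target_id: str = "TARGET"

    def __post_init__(self) -> None:
        if self.n_solvents < 0:
            raise ValueError("n_solvents must be >= 0")
        if not 0 <= self.n_formers <= self.n_solvents:
            raise ValueError(
                f"n_formers must lie in [0, n_solvents], got "
                f"{self.n_formers} of {self.n_solvents}"
            )
        if not 0.0 <= self.hetero_boost < 1.0:
            raise ValueError("hetero_boost must lie in [0, 1)")
        if self.hex_noise_sd <= 0:
            raise ValueError("hex_noise_sd must be > 0")
        if self.propensity_concentration <= 0:
            raise ValueError("propensity_concentration must be > 0")
        if self.mc_axis_scale <= 0:
            raise ValueError("mc_axis_scale must be > 0")
        if self.cv_rate < 0:
            raise ValueError("cv_rate must be >= 0")
        if not 0.0 <= self.no_hb_fraction <= 1.0:
            raise ValueError("no_hb_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PanelTruth:
    """Ground-truth labels of a generated panel."""

    formers: frozenset[str]
    no_hb_solvents: frozenset[str]
    config: PanelConfig


def _rng(config: PanelConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


# propensity draws per pair: 3 heteromeric, 2 homomeric-solvent;
# the homomeric-target pool is drawn once and shared across all pairs
_N_HETERO = 3
_N_HOMO_SOLVENT = 2
_N_HOMO_TARGET = 2
_PROPENSITY_MEAN = 0.4


def generate_panel(config: PanelConfig) -> tuple[DescriptorBundle, PanelTruth]:
    """Generate one synthetic descriptor panel plus its truth labels.

    Returns a validated :class:`~solvscreen.io.DescriptorBundle` (all four
    descriptor tables, a solvents table and an outcome panel listing the
    planted formers) and a :class:`PanelTruth` naming the formers and the
    no-donor/no-acceptor solvents.
    """
    n = config.n_solvents
    solvent_ids = [f"S{i + 1:03d}" for i in range(n)]
    tgt = config.target_id

    rng = _rng(config, "labels")
    formers = set(
        rng.choice(solvent_ids, size=config.n_formers, replace=False).tolist()
    ) if n else set()
    non_formers = [s for s in solvent_ids if s not in formers]
    n_no_hb = min(int(round(config.no_hb_fraction * n)), len(non_formers))
    no_hb = set(
        rng.choice(non_formers, size=n_no_hb, replace=False).tolist()
    ) if n_no_hb else set()

    a, b = _beta_params(_PROPENSITY_MEAN, config.propensity_concentration)

    # --- propensity table -------------------------------------------------
    rng = _rng(config, "propensity")
    homo_target = rng.beta(a, b, size=_N_HOMO_TARGET)
    prop_rows: list[tuple] = []
    for sid in solvent_ids:
        # draws consumed for every solvent so that label changes (former /
        # no-HB) never shift the stream for the other solvents
        hetero = rng.beta(a, b, size=_N_HETERO)
        homo_solv = rng.beta(a, b, size=_N_HOMO_SOLVENT)
        if sid in no_hb:
            continue
        if sid in formers:
            hetero = np.clip(hetero + config.hetero_boost, 0.0, 1.0)
        for j, p in enumerate(hetero):
            prop_rows.append((tgt, sid, f"don{j}", f"acc{j}", "hetero",
                              float(p)))
        for j, p in enumerate(homo_target):
            prop_rows.append((tgt, sid, f"tdon{j}", f"tacc{j}",
                              "homo_target", float(p)))
        for j, p in enumerate(homo_solv):
            prop_rows.append((tgt, sid, f"sdon{j}", f"sacc{j}",
                              "homo_solvent", float(p)))
    propensity = validate_propensity(pd.DataFrame(
        prop_rows,
        columns=["target_id", "solvent_id", "donor_group", "acceptor_group",
                 "pair_class", "propensity"],
    ))

    # --- shape/polarity table (no planted signal) -------------------------
    rng = _rng(config, "mc")
    species = [tgt] + solvent_ids
    axes = np.sort(
        rng.lognormal(mean=np.log(config.mc_axis_scale), sigma=0.4,
                      size=(len(species), 3)),
        axis=1,
    )
    dipole = rng.gamma(shape=2.0, scale=1.5, size=len(species))
    frac_no = rng.beta(2.0, 5.0, size=len(species))
    mc = validate_mc(pd.DataFrame({
        "species_id": species,
        "conformer_id": 0,
        "axis_S": axes[:, 0],
        "axis_M": axes[:, 1],
        "axis_L": axes[:, 2],
        "dipole": dipole,
        "frac_NO": frac_no,
    }))

    # --- coordination-value table (no planted signal) ----------------------
    rng = _rng(config, "cv")
    D = rng.poisson(config.cv_rate, size=len(species)).astype(float)
    A = rng.poisson(config.cv_rate, size=len(species)).astype(float)
    cv = validate_cv(pd.DataFrame({
        "species_id": species,
        "conformer_id": 0,
        "D": D,
        "A": A,
    }))

    # --- excess-enthalpy table ---------------------------------------------
    rng = _rng(config, "hex")
    hex_vals = rng.normal(0.0, config.hex_noise_sd, size=n)
    former_mask = np.array([s in formers for s in solvent_ids], dtype=bool)
    hex_vals = hex_vals + np.where(former_mask, config.hex_shift, 0.0)
    hex_table = validate_hex(pd.DataFrame({
        "target_id": tgt,
        "solvent_id": solvent_ids,
        "hex": hex_vals,
    }))

    solvents = validate_solvents(pd.DataFrame({
        "solvent_id": solvent_ids,
        "name": [f"solvent {i + 1}" for i in range(n)],
    }))

    outcomes = OutcomePanel(pd.DataFrame(
        [(tgt, s, True, "structure") for s in sorted(formers)],
        columns=["compound_id", "solvent_id", "formed", "evidence"],
    ))

    bundle = DescriptorBundle(
        propensity=propensity,
        mc=mc,
        cv=cv,
        hex=hex_table,
        solvents=solvents,
        outcomes=outcomes,
    )
    truth = PanelTruth(
        formers=frozenset(formers),
        no_hb_solvents=frozenset(no_hb),
        config=config,
    )
    return bundle, truth


def null_panel(config: PanelConfig) -> tuple[DescriptorBundle, PanelTruth]:
    """A signal-free panel: same draws, zero boost and zero enthalpy shift.

    Former labels are still emitted (for blind evaluation) but carry no
    information — every method's expected mean rank is the uninformative
    baseline.
    """
    return generate_panel(
        replace(config, hetero_boost=0.0, hex_shift=0.0)
    )
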
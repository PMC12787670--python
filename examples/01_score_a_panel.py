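"""Score a small solvent panel against one target with all four methods.

Builds a three-solvent descriptor panel in memory, scores it, and prints
the long-format score table.  HBP* is the strongest heteromeric minus the
strongest homomeric hydrogen-bond propensity (higher = solvate-favoring);
MC_N is a normalized shape/polarity dissimilarity and dCV a donor/acceptor
imbalance (both lower = better); COSMO is the excess enthalpy of mixing in
kcal/mol (more negative = stronger interaction).  Solvent C carries no
hydrogen-bond donors or acceptors, so its HBP* is undefined rather than
zero.
"""

import pandas as pd

from solvscreen import DescriptorBundle, OutcomePanel, score_panel

propensity = pd.DataFrame(
    [
        ("T", "A", "OH", "C=O", "hetero", 0.62),
        ("T", "A", "OH", "O", "hetero", 0.35),
        ("T", "A", "OH", "OH", "homo_target", 0.41),
        ("T", "A", "CH", "O", "homo_solvent", 0.18),
        ("T", "B", "OH", "N", "hetero", 0.50),
        ("T", "B", "OH", "OH", "homo_target", 0.50),
    ],
    columns=["target_id", "solvent_id", "donor_group", "acceptor_group",
             "pair_class", "propensity"],
)
mc = pd.DataFrame(
    [
        ("T", 0, 3.0, 5.0, 9.0, 2.5, 0.20),
        ("A", 0, 2.0, 3.0, 4.0, 1.0, 0.33),
        ("B", 0, 1.5, 2.5, 3.5, 3.9, 0.25),
        ("C", 0, 2.2, 2.8, 5.1, 0.0, 0.00),
    ],
    columns=["species_id", "conformer_id", "axis_S", "axis_M", "axis_L",
             "dipole", "frac_NO"],
)
cv = pd.DataFrame(
    [("T", 0, 2.0, 4.0), ("A", 0, 0.0, 2.0),
     ("B", 0, 1.0, 1.0), ("C", 0, 3.0, 0.0)],
    columns=["species_id", "conformer_id", "D", "A"],
)
hex_table = pd.DataFrame(
    [("T", "A", -3.1), ("T", "B", 0.0), ("T", "C", 1.7)],
    columns=["target_id", "solvent_id", "hex"],
)
solvents = pd.DataFrame({"solvent_id": ["A", "B", "C"],
                         "name": ["acetone-like", "amine-like", "alkane-like"]})

bundle = DescriptorBundle(propensity=propensity, mc=mc, cv=cv,
                          hex=hex_table, solvents=solvents)
scores = score_panel(bundle, "T")
print(scores.to_string(index=False))
print()
print("HBP* of solvent A = 0.62 - 0.41 = 0.21 (solvate-favoring);")
print("solvent C has defined=False for HBP: no donor/acceptor pathway.")
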
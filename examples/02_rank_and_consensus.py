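"""Fractional ranking and the eleven consensus combinations.

Simulates a small panel, ranks each method's scores in its favorability
direction, and aggregates them into the eleven screened consensus
rankings (all method pairs, four triples and the four-way combination).
A consensus rank sums a solvent's fractional positions across the member
methods and re-ranks the sums ascending: lower = broader agreement that
the solvent is a likely solvate former.
"""

from solvscreen import (
    METHODS,
    PanelConfig,
    all_combinations,
    generate_panel,
    rank_scores,
    score_panel,
)
from solvscreen.ranking import rank_tables_to_wide

bundle, truth = generate_panel(PanelConfig(n_solvents=10, n_formers=3,
                                           seed=42))
scores = score_panel(bundle, "TARGET")
individual = {m: rank_scores(scores, m) for m in METHODS}
combos = all_combinations(individual)

wide = rank_tables_to_wide(list(individual.values()) + list(combos.values()))
print(wide.round(1).to_string())
print()
print(f"planted formers: {sorted(truth.formers)}")
print("columns are fractional rank positions (1 = most promising);")
print("tied scores share the mean of the positions they span.")
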
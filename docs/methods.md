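# Methods

## Problem and model

`solvscreen` addresses solid-form screening: predicting which solvents in
a crystallization panel will be incorporated into a target compound's
crystal lattice as a solvate (or hydrate, when the solvent is water).
Four per-solvent scores are computed from descriptor tables, each solvent
is ranked in each method's favorability direction, consensus rankings are
formed by summing rank positions, and every ranking is judged by the mean
rank of the experimentally confirmed formers.

The scores and their assumptions:

- **HBP\*** `= max(P_hetero) − max(P_homo)`. Propensities P are
  probabilities, supplied per donor–acceptor functional-group pair and
  classed as heteromeric (target–solvent), homomeric-target or
  homomeric-solvent. The score assumes the single strongest interaction
  on each side decides the competition between cross-association and
  self-association; cooperative or weak C–H···O/Cl contacts are outside
  the model, which is why a weak-contact solvate can rank poorly. When a
  pair has heteromeric records but no homomeric ones, the homomeric
  maximum is taken as 0 (no competing self-interaction). When it has *no*
  heteromeric record the score is undefined: it is flagged and ranked
  after all defined scores rather than set to 0, because "no
  donor–acceptor pathway" and "a pathway of zero strength" are different
  statements and conflating them would hide the method's blind spot.
- **MC_N** sums five absolute normalized deltas (M/L, S, S/L, dipole,
  N+O fraction) with divisors 0.31, 3.23, 0.275, 5.94, 0.294. Absolute
  deltas are used: the score must be a non-negative dissimilarity for
  "lowest = most complementary" to be well defined, and it is then
  symmetric in target and solvent. With multiple conformers the minimum
  over conformer pairs represents the pair (the most complementary
  accessible pairing); the minimum is monotone — adding a conformer can
  only keep or lower the score.
- **ΔCV** compares the donor/acceptor imbalance `|D − A|` of the
  multicomponent system with that of each pure component. Supplied
  multicomponent coordination values are used when present; otherwise
  they are formed additively (`D_multi = D_target + D_solvent`, likewise
  A), which is the only combination computable from the stated inputs.
  The choice is recorded in the record's `provenance` field so results
  can be audited. With conformers, the minimum ΔCV over conformer
  combinations is used, mirroring the MC convention.
- **Hex** is used as supplied (kcal/mol); the module adds only the
  ascending favorability direction.

## Ranking and tie handling

All ranks are fractional: tied scores share the mean of the positions
they span. The convention is a package decision — the alternatives
(ordinal with arbitrary tie-break, or competition ranking) make rank sums
depend on input order or lose the `n(n+1)/2` conservation that keeps the
mean-rank statistic comparable across methods. Undefined HBP scores form
a final tied block after all defined scores. Consensus over a method set
is the arithmetic sum of fractional positions, re-ranked ascending; the
raw sums are kept alongside the derived positions. Combination labels
are canonicalized to alphabetical member order (`COSMO-HBP`, not
`HBP-COSMO`), with eleven combinations screened: all 6 pairs, all 4
triples and the 4-way sum; `consensus()` also accepts any ad-hoc member
list.

## Evaluation

`mean_rank` averages the fractional positions of the confirmed formers;
its attainable range is `[(k+1)/2, n − (k−1)/2]` for k formers of n
solvents, and a random ranking has expectation `(n+1)/2`. Fractional
positions are used directly, not re-ordinalized, keeping the statistic
consistent with the ranking convention. Outcome entries tagged
`ambiguous` (a literature solvate later indistinguishable from a
hydrate) are included by default and excluded with
`include_ambiguous=False` / `--exclude-ambiguous`; water is an ordinary
rankable solvent, so hydrates count as formers. The outcome panel is
closed-world: an absent pair reads as "not formed, not tested", while an
explicit `formed=False` row records a tested failure.

## Synthetic panels

The generator emulates the *statistical shape* of a screening data set,
not its chemistry. Defaults: 48 solvents, 6 planted formers, master seed
with one labeled sub-stream per table (so regenerating or reparametrizing
one table never moves another's draws; a fixed seed is byte-reproducible).

- Propensities ~ Beta with mean 0.4 and concentration 4 (a broad,
  realistic spread of pair propensities); 3 heteromeric and 2
  homomeric-solvent draws per pair, with one shared homomeric-target pool.
  Formers' heteromeric propensities are shifted up by `hetero_boost`
  (default 0.25, clamped to 1).
- Excess enthalpies ~ Normal(0, 1 kcal/mol); formers shifted by
  `hex_shift` (default −2 kcal/mol) — a strong but not overwhelming
  interaction signal.
- Molecular axes: three lognormal draws (median 4 Å, σ = 0.4) sorted into
  S ≤ M ≤ L; dipole ~ Gamma(2, 1.5 Debye); N+O fraction ~ Beta(2, 5).
- Coordination values: Poisson(2) counts for D and A.
- One solvent in 48 (a non-former) is emitted with no propensity records
  at all, exercising the undefined-HBP path.

Signal is planted in the HBP and enthalpy channels only: the shape (MC)
and coordination (CV) tables are independent of the former labels. This
mirrors the empirical finding that hydrogen bonding, not shape matching,
drives solvate formation in strongly hydrogen-bonding targets, and gives
tests a known method ordering (HBP/COSMO informative; MC/CV calibrated
at the baseline). `null_panel` zeroes both shifts for calibration runs.

What passing tests therefore show: the pipeline recovers planted formers
through exactly the channels that carry signal, and stays calibrated when
none does. What they do not show: performance on real descriptor tables,
where channels are correlated, propensity models are imperfect and the
former/non-former contrast is not a clean location shift.

## Numerical choices and degenerate inputs

- Cell volume uses the closed-form metric expression
  `abc·√(1 − cos²α − cos²β − cos²γ + 2cosα·cosβ·cosγ)`; cells whose
  angle triple yields a non-positive discriminant are rejected at
  construction. Angles are taken in degrees, lengths in Å; printed
  standard uncertainties are not parsed.
- Validation errors always name the table, row index, column and violated
  bound, so a bad spreadsheet export fails loudly and locatably.
- Empty panels rank to empty tables; an empty confirmed set is an error
  (the mean rank of nothing is meaningless rather than 0).
- Replicate seeds are derived from a base seed through an independent
  generator stream and kept below 2³¹.

## Problem sizes

Simulation-backed checks use 200 replicates of the default 48-solvent
panel (calibration and recovery), 100 replicates × 3 boost levels on a
16-solvent panel (boost monotonicity), and 1000 randomized panels of ≤ 8
solvents for the exhaustive tie-enumeration oracle — sizes chosen so the
Monte-Carlo error is small against the effects being checked while the
whole suite stays quick on a laptop.

## Known limitations

- Descriptors are inputs: the package computes none of the propensities,
  axes, dipoles, coordination values or enthalpies from molecular
  structure.
- The additive multicomponent-CV default is an assumption, flagged in
  `provenance`; supplied values override it.
- Consensus is the plain rank sum — no weighted or Kemeny-style
  aggregation.
- Mean rank is the sole performance metric; no ROC/enrichment curves.
- The builtin outcome fixture records confirmed formers named in the
  source literature; tested-but-failed solvents are representable
  (`formed=False`) but not enumerated there.
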
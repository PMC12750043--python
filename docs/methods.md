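# Methods

## Scope and model of the problem

`oligoscore` assesses predicted 3D models of protein complexes against an
experimental reference ("target") and turns tables of such scores into
group rankings of the kind used in community-wide blind assessments of
oligomer prediction. Assessment proceeds at three levels:

1. **Per-interface similarity.** An interface is the set of inter-chain
   residue contacts of one chain pair, a contact being a residue pair from
   two different chains whose minimal heavy-atom distance is strictly below
   5 Å. Four interface metrics are computed: ICS (F1 of contact sets), IPS
   (Jaccard coefficient of interface-residue sets), QS in Dice form
   (2·|shared| / (|target| + |model|)), and DockQ
   (mean of Fnat, 1/(1+(iRMS/1.5)²) and 1/(1+(LRMS/8.5)²), with the 10 Å
   interface definition and backbone atoms of the published DockQ method).
   Two global metrics complement them: superposition-free lDDT (thresholds
   0.5/1/2/4 Å, 15 Å inclusion radius, intra- and inter-chain pairs, no
   stereochemistry checks) and a TM-score normalised by target length
   (d0 = 1.24·(L−15)^⅓ − 1.8, floored at 0.5) under a seed-and-extend
   iterative superposition. Empty-vs-empty contact sets score 1.0: a
   correctly predicted non-interface is not an error.

2. **Target-level aggregation.** Per-interface scores s_Ij are combined as
   S_I = Σⱼ aⱼ·s_Ij / Σⱼ aⱼ with aⱼ = log10(interface size / 2). This damps
   the dominance of large, easy interfaces while keeping small ones from
   being drowned out entirely. "Interface size" is read as the number of
   distinct interface residues over both chains; a contacts-based variant
   is available via `weight_mode="contacts"`. Because log10 ≤ 0 for sizes
   ≤ 2, weights are clamped below at 0.05 so tiny interfaces never receive
   zero or negative weight.

3. **Ranking statistics.** Per (target, metric), model scores are
   standardised in two rounds: round 1 uses the mean/SD of all values and
   discards outliers at z ≤ −2; round 2 restandardises everyone against the
   kept set's mean/SD and floors final z at −2. Metric z-scores are
   averaged with equal weight, models are selected per group ("first" =
   lowest model id; "best" = argmax average z, ties to the lowest id;
   Model 6 excluded from selection), and cumulative z is summed over
   targets. Head-to-head significance bootstraps the targets common to a
   pair of groups (default 1000 replicates, seeded).

## Evaluation pipelines

* **Standard** (stoichiometry-matched): chains are grouped into entities by
  sequence identity (≥ 0.95 within an assembly) and target entities paired
  with model entities at ≥ 0.7 identity normalised by the shorter sequence
  (tolerant of trimmed modelling constructs). Within multi-copy entities
  the assignment maximising a structural objective (default: global lDDT)
  is chosen — exhaustively when the candidate count is ≤ 720, otherwise by
  linear assignment on per-chain objective values. Every target interface
  is scored against the mapped model chain pair (a missing model interface
  scores as an empty contact set; a target interface whose chains are
  unmapped scores 0); unmapped model chains are ignored. This reproduces
  the known blind spot of mapping-based evaluation: spurious extra copies
  and their interfaces cost nothing.

* **Reciprocal Best Match (RBM)** for stoichiometry mismatches: each target
  interface is matched to the model interface maximising each metric, and
  vice versa; each direction is a log-size-weighted average over its own
  interfaces, and the final score per metric is the minimum of the two
  directions. A reference interface with no counterpart contributes 0 to
  its direction — RBM is deliberately a penalty mechanism. Candidate pairs
  are restricted to entity-compatible chains; when an entity is absent from
  the other side every interface is a candidate, but pairings below 50%
  sequence identity score zero, because a global alignment of unrelated
  sequences matches ~30–40% of the shorter chain by chance and residue
  numbering coincidences would otherwise let unrelated interfaces score.
  Per-interface DockQ/lDDT/TM in RBM are computed on the two-chain
  sub-assemblies. In direction 2 the model acts as the reference for the
  reference-normalised metrics. The two directions use their own interface
  weights.

* **Antibody–antigen (AA)**: chain classes (antibody/nanobody vs antigen)
  are provided as input annotation, never inferred. Only cross-class
  interfaces are scored, and the profile is restricted to
  {ICS, IPS, QS, DockQ} — global-fold metrics reward the easy
  antibody–antibody and antigen–antigen packing rather than the interface
  that matters. A concatenated mode merges all antibody chains into one
  pseudo-chain and all antigen chains into another (residues renumbered
  sequentially) before interface detection, yielding a single unified AA
  interface.

Per-category metric profiles: normal = {ICS, IPS, DockQ, QS, TM, lDDT};
AA = {ICS, IPS, DockQ, QS}; hybrid (protein–nucleic-acid) =
{ICS, IPS, lDDT}. Nucleic-acid chains are treated as residue chains for
contacts and lDDT; no NA-specific scoring is attempted.

## Cross-cohort statistics

Progress between assessment rounds is confounded by target difficulty,
estimated here as the baseline predictor's first-model DockQ. Two
controls are implemented: (a) Hungarian matching
(`scipy.optimize.linear_sum_assignment`) pairing targets one-to-one across
rounds to minimise summed difficulty differences, and (b) weighted
bootstrap resampling where Gaussian KDEs (Scott bandwidth) are fitted to
both difficulty distributions and source targets are resampled with
weights ∝ density_reference/density_source, clipped to [0, 20] to prevent
single-point blow-ups.

MSA diversity is summarised as Neff = Σᵢ 1/nᵢ, where nᵢ counts rows
(including i) within 80% identity of row i, identity computed over columns
non-gap in both rows; rows sharing fewer than 10 non-gap columns are
treated as dissimilar. This is the inverse-cluster-size convention without
length normalisation; the threshold is configurable. Paired (hetero)
interface MSAs keep only rows covering both chain blocks.

## Synthetic data: what it emulates and what it does not

The generator builds CA-only bead chains (3.8 Å virtual bonds). Each
declared interface is a pair of anti-parallel segments 4.5 Å apart, so
every opposed bead pair is a contact under the strict 5 Å rule while
off-diagonal pairs sit at √(4.5² + 3.8²) ≈ 5.9 Å; undeclared chain pairs
are kept ≥ 50 Å apart. A small (±0.05 Å) seeded jitter keeps coordinates
generic without crossing any contact threshold. Model ensembles are made
by perturbations (single-chain rigid shifts, whole-assembly rotations,
chain deletion/duplication, coordinate swaps); per-group quality profiles
map to shift magnitudes whose exponential decay spans DockQ ≈ [0, 1].

`make_submission_set` can skip structure generation entirely
(`structural=False`) and emit metric values directly from the drawn
severities. Selection statistics (first-pick rate, ordering recovery)
depend only on the within-group ordering of model qualities, which both
modes realise identically; the table mode exists so that large simulation
studies (10⁴ targets, 100 ranking replicates) stay cheap. The reported
first-pick baseline is nevertheless recomputed with the full structural
pipeline in `scripts/acceptance.py`.

Synthetic MSAs realise identity structure by construction: a conserved
column fraction equal to the between-cluster identity, and disjoint
per-cluster letter sets on variable columns, so cross-cluster identity is
exact and within-cluster identity is bounded below by 2·within − 1. Neff
ground truth is therefore analytic, not approximate.

What the synthetic data does **not** emulate: real protein geometry (no
side chains, secondary structure, or sterics), partially correct
interfaces with realistic error correlation between metrics, sequence
homology gradients between entities (entities are near-random sequences),
or missing residues/insertion codes. Passing tests demonstrate the
correctness of the scoring logic and statistics under controlled truth,
not calibration against experimental assessments.

## Numerical choices and edge cases

* Contact rule is strictly `< 5 Å` everywhere (the boundary is not a
  contact); lDDT thresholds are also strict.
* Population (n-denominator) SD in z-scores; an SD at round-off level
  relative to the mean (≤ 1e-12·max(1, |mean|)) is treated as zero spread
  and yields all-zero z-scores, so equal-valued targets cannot amplify
  floating-point noise into ±1 z-scores. The
  round-1 outlier rule excludes z ≤ −2 (boundary included in the
  exclusion): a single extreme outlier among n equal values lands at
  exactly z = −2 under the population SD, and the floor imputes −2 anyway,
  so the boundary case is treated as an outlier.
* Missing (group, target) combinations contribute 0 to cumulative z (not
  −2); head-to-head comparisons avoid the issue by using common targets
  only. Flagged in ranking metadata.
* Best-model ties break to the lowest model id; head-to-head uses strict
  inequality (ties favour neither side).
* 95% quantiles use linear interpolation between order statistics.
* Alternate locations keep the highest occupancy (first on tie); waters
  and non-polymer ligands are dropped; selenomethionine reads as M;
  unknown residues read as X.
* Receptor/ligand in DockQ: the longer target chain is the receptor, ties
  to the lexicographically smaller chain id.
* Degenerate inputs: single-chain assemblies yield empty contact sets (not
  errors); an empty chain mapping yields missing scores; empty score lists
  aggregate to missing; comparing a filamentous ("An") stoichiometry is an
  error by design.

## Problem sizes used in tests and the acceptance script

Test complexes use 10–30-residue chains with 4–12-contact interfaces —
large enough to exercise every code path (multi-copy entities, antiparallel
contact pairing, interface weighting) while keeping brute-force oracles
(factorial assignment search, all-pairs DockQ terms) exact and fast. The
first-pick simulation uses 10,000 targets; ordering recovery uses 100
replicates of 20 targets × 4 groups.

## Known limitations

* QS is the Dice form of the one-line definition, not the full published
  QS-score (no distance-agreement weighting); reported as `qs`.
* The TM-score search is a simplified seed-and-extend, not the published
  exhaustive protocol; on adversarial inputs it can underestimate the
  optimum (it is validated on identity, known-transform, and displacement
  cases).
* No biological-assembly expansion, no crystallographic-interface
  detection, no CDR detection, and no attempt to reproduce official
  leaderboards, which would require the full submission archives.
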
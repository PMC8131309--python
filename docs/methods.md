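# Methods

This note documents the models, conventions, and numerical choices behind
`dualsarm`, and what the synthetic test bed does and does not show.

## Fragmentation and the SAR matrix

**Eligible bond.** A cut bond must be single, acyclic, and connect two
heavy (non-hydrogen, non-wildcard) atoms.  Only single cuts are performed:
the package models analog series with one substitution site.  Ring bonds
are never cut, so stereochemistry inside rings is untouched; attachment
points are written as unlabeled wildcard atoms (`*`), exactly one per
fragment (two for the shared scaffolds produced by the second cut).

**Key/value assignment.** The key (core) is the fragment with more heavy
atoms; ties break by lexicographic canonical SMILES.  A substituent is
capped at 13 heavy atoms and at half the parent's heavy atoms
(`max_value_atoms`, `max_value_fraction`; both configurable).  The cap is a
practical convention from matched-molecular-pair practice, not a law: it
keeps "substituent" meaning a decorating group rather than half the
molecule.

**Salts.** Multi-component SMILES are rejected at parse time.  Callers
strip salts; the package never guesses which component matters.

**Core grouping.** Cores are re-fragmented by the same rule (the original
attachment point is inert).  The piece holding the original attachment
point is the shared scaffold (two attachment points); the split-off piece
is the distinguishing substructure.  Additionally, every position of a
core carrying a hydrogen is offered as scaffold + hydrogen, so an
unsubstituted core (phenyl) groups with its substituted analogs
(4-F-phenyl).  A group needs at least two distinct member cores; a core
may sit in several groups, one per admissible decomposition.

**Matrix construction.** Rows are a group's member cores; columns are the
union of substituents observed with any member.  Every (row, column) pair
is a cell: existing if an indexed compound realizes it (duplicate
measurements aggregated by the median, which is robust and
order-independent), virtual otherwise.  Rows and columns are ordered by
descending count of existing cells, then canonical SMILES — deterministic,
with dense regions top-left.  Matrices with fewer than two existing
compounds carry no SAR information and are dropped.  A compound may appear
in several matrices; no cross-matrix deduplication is attempted.

**Expansion.** Generated fragments extend the row/column lists after
canonical deduplication.  Every newly created combination becomes a
generated-virtual cell scored by the sum of its fragments' log-likelihood
scores; fragments already present in the original matrix are treated as
certain and contribute 0 to that sum.  Existing cells are copied
unchanged — expansion never touches measured data.

## Local Free-Wilson prediction

The additive model assumes a compound's potency is an intercept plus
independent core and substituent contributions.  For a virtual cell the
neighborhood estimator averages pot(i,l) + pot(k,j) − pot(k,l) over all
complete neighborhoods; the spread (population sd of the per-neighborhood
estimates) is reported so callers can down-weight unstable predictions.
Aggregation is the unweighted mean.  The minimum neighborhood count for
reporting defaults to 1 and is configurable; with zero neighborhoods the
function returns an explicit no-prediction (`None`), never a number.

The reference estimator solves the least-squares additive decomposition
with the identifiability convention that row and column effects sum to
zero over the measured rows/columns (the minimum-norm solution is
re-centered).  The measurement pattern must connect all measured rows and
columns when viewed as a bipartite graph; otherwise the decomposition is
ambiguous and the disconnected blocks are reported in the error.  On
noise-free additive data both estimators are exact to machine precision;
under noise they agree closely on well-filled matrices (the test bed
checks < 0.1 pIC50 at 80% fill, noise sd 0.1).

Predictions are always per-target; nothing is imputed across targets,
because dual-target prioritization needs independent evidence per target.

## Fragment generators

Each generator role (scaffold, core-substructure, substituent) is a
sequence-to-sequence model over SMILES tokens: one shared embedding, a
single-layer LSTM encoder, a single-layer LSTM decoder, and a softmax
output layer, implemented directly in NumPy with hand-written
backpropagation through time and Adam (gradients verified against finite
differences in the test suite).  Defaults — embedding 32, hidden size 128,
batch 32, learning rate 5e-3 — train a few-hundred-line fragment corpus in
seconds to minutes on one CPU; all sizes are configurable.

Training pairs follow the staged pipeline: the scaffold generator maps
scaffolds to themselves; the substructure generator maps a scaffold to a
substructure observed with it; the substituent generator maps a core to a
substituent observed with it.  Pre-training uses the pooled corpus from
both target classes; fine-tuning re-runs training on the focus fragments
(e.g. from known dual-target ligands) and keeps the parameters with the
lowest focus-corpus NLL seen, including the starting point — so
fine-tuning can never make the focus set less likely.

Sampling is multinomial with temperature (default 1.0) and an optional
top-k cap; the pad/start tokens are structurally excluded from sampling.
The reported score of a sample is the sum of per-token log-probabilities
under the *untempered* decoder distribution (end token included), so it is
exactly reproducible by a teacher-forced pass and always ≤ 0.  Invalid
decodes, wrong attachment-point counts, and bare-wildcard outputs are
counted and logged, never returned.  The default score filter is the 10th
percentile of the scores the generator assigns to its own known-good
fragments — self-calibrating, since no absolute threshold is meaningful
across models.

Scale is the main deliberate limitation: these are desk-scale models for
corpora of hundreds of fragments.  They learn fragment syntax and the
local structural spectrum, not broad medicinal-chemistry space.

## Potency models and dual-target ranking

Compounds are featurized as binary Morgan fingerprints (radius 2, 1024
bits — a standard default; configurable).  One LightGBM regressor per
target is fitted on an 80/20 split (500 trees, learning rate 0.05,
min_child_samples 5 — settings for data sets of hundreds of compounds;
single-threaded and deterministic under the seed).  Mixed measurement
types (IC50 vs Ki) are rejected because they are not comparable on one
pIC50 scale.  Since models are trained on actives only, predictions are
relative — they fall inside the training potency range, and the code logs
this caveat on every prediction call.

Candidates are ranked by the worst (largest) of their two per-target dense
ranks — the best worst-case — so a compound must rank well against *both*
targets to lead; ties break by mean predicted potency, then generator
score.  Mean-rank combination is available as an option.

## Molecular Grid Maps

Pairwise Tanimoto similarity (Morgan, 2048 bits) is the reference frame.
Embedding is PCA followed by t-SNE (skipped below 8 items, where
perplexity is meaningless; perplexity defaults to min(30, (n−1)/3));
either stage can be disabled.  Grid side defaults to
ceil(sqrt(n·(1+slack))) with slack 0.1.

Initial placement minimizes the total squared distance between min-max
scaled embedded coordinates and grid-cell centers, solved exactly as a
rectangular assignment problem.  Note the two cost scales: the assignment
layout stores this displacement cost; the optimizer works on the
similarity objective Σ_{i<j} sim(i,j)·dist(cell_i, cell_j) and stores that.
Refinement is steepest-descent local search over all single relocations
and pairwise swaps, fully vectorized; each step applies the best
improving move, so the cost trace is monotone non-increasing by
construction and the placement stays injective.  Plain swap search is
used instead of a self-organizing-map heuristic because it is transparent
and directly testable against the stated objective.

Rendering writes SVG directly: each compound is a circle split into left
(target A) and right (target B) halves on a continuous red→yellow→green
scale anchored at the pooled min/max of the displayed values per target;
border color encodes the compound category (existing / virtual /
generated).  Output bytes are deterministic for fixed input.

## Synthetic data

The generator emulates the structure the pipeline assumes: four scaffold
families (para-substituted benzenes, thiophenes, cyclohexanes, pyridines;
five members each differing at one ring position), thirty substituents,
and per-target potencies pIC50(i,j) = μ_t + a_i(t) + b_j(t) + noise with
scaffold effects N(0, 0.75), substituent effects N(0, 0.5), μ_A = 6.5,
μ_B = 6.0, noise sd 0.2 by default.  Scaffold decorations (F, Cl, Br, OH)
are disjoint from the substituent vocabulary so every scaffold×substituent
product is a distinct, valid molecule.  Cell filling observes every
scaffold and substituent at least once when the budget allows (as real
combinatorial series do) and is uniform beyond that.  The dual-target
split assigns each compound to both targets with the overlap probability,
otherwise to one alternately.  "Planted" cells boost one scaffold row and
the first substituent columns to 2.5 sd in both targets and hold those
cells out as virtual, giving known dual-target optima for ranking tests.

What passing tests show: the pipeline's accounting, round-trips,
additivity recovery, training dynamics, and ranking logic are correct
under exactly additive signal plus Gaussian noise.  What they do not show:
performance on real data with non-additive SAR (activity cliffs),
heterogeneous assay noise, scaffold diversity beyond four ring families,
or fingerprint collisions at real chemical diversity.  The regression R²
achieved here (~0.85–0.9) reflects the easy, additive synthetic task, not
expected real-world accuracy.

## Study sizes used in tests and the acceptance script

Fragmentation round-trips use ~510 compounds (20×30 grid at 85% fill).
Generator checks use a 200-line substituent corpus, 30 pre-training
epochs, and a 20-fragment focus set.  Dual-target recovery uses a 20×30
grid at 97% fill with 2 planted cells and overlap 0.75, giving ≈500
compounds per target.  Grid checks use n ≤ 12 with exhaustive oracles
where stated.  These sizes exercise every code path at full fidelity while
keeping a complete run in the order of a minute.
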
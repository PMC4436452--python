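# Methods

## Setting and data model

A protein is a bag X = {x₁,…,x_n} of instance vectors, one per conserved
domain; its annotation is a binary label vector over L Gene Ontology
molecular-function terms. Three label-matrix roles are kept distinct
throughout: the full ground truth Y, the observed weak matrix Ŷ ≤ Y
(zeros mean *unknown*), and the learner-corrected Ȳ ≥ Ŷ. The per-label
weak-label ratio W.L.R. = ‖Ŷ·,l‖₁/‖Y·,l‖₁ quantifies annotation
completeness.

GO labels are built by true-path propagation: a protein annotated with a
term also carries every is_a ancestor. Only is_a edges are used (part_of
ignored — the conservative closure), and the namespace root GO:0003674 is
never emitted as a label: it is positive for every annotated protein and
would only dilute macro-F1. Label columns are ordered lexicographically by
GO id and bag rows follow input order, so matrices are deterministic.

## Featurization

Domain sequences are encoded as conjoint-triad frequencies: residues map
to 6 physicochemical classes, a sliding window of 3 consecutive residues
takes one of 6³ = 216 triad types, and counts are normalized by the number
of valid windows, so every instance lies on the 216-simplex. The exact
6-class partition behind the published 216-dimensional encoding is not
standardized; the package defaults to the Dayhoff-style grouping
{C}, {A,G,P,S,T}, {D,E,N,Q}, {H,K,R}, {I,L,M,V}, {F,W,Y} and accepts any
partition via a JSON config, which isolates this choice. Ambiguity codes
(B, J, O, U, X, Z) map to no class; windows containing them are skipped
rather than rejecting the sequence, and normalization by *valid* windows
keeps vectors on the simplex regardless. A sequence with no valid window
is an error naming the offending record.

## Weak-label masking

Masking is per label column, matching the columnwise W.L.R. definition:
a column with p positives keeps k = max(min_keep, round(r·p)) of them
(round half to even), chosen uniformly from a seeded generator. The
default min_keep = 1 guarantees no label vanishes from training — an
all-zero column is unlearnable and makes macro-F1 ill-defined. Whether
the masking should be per-column exact or merely exact in expectation is
underdetermined; per-column exact was chosen because it makes realized
ratios verifiable to rounding error. Fully unlabeled proteins are realized
by the cross-validation test fold rather than a separate masking mode —
the semantics are identical.

## The MIMLwel learner

**Bag embedding.** Φ(X) has K+1 coordinates: RBF responses
exp(−d(X,Mₖ)²/2(μδ)²) to K medoid bags plus a bias 1. K = max(1,
round(α·m)) with cluster fraction α; medoids come from PAM k-medoids
(seeded random init, best-improving swap per sweep, ≤ 100 sweeps, ties to
the lowest index) under the average Hausdorff distance
(Σ_a min_b‖a−b‖ + Σ_b min_a‖a−b‖)/(|A|+|B|). The base width δ is the mean
distance of a training bag to its nearest medoid, with fallbacks (smallest
positive inter-medoid distance, then 1) for the degenerate all-coincident
case; μ scales it. The maximum Hausdorff variant is provided for the
baseline's configurability. The embedding is isolated behind one model
object so an alternative bag-level feature map is drop-in.

**Label relations.** R_{ll'} = 1 iff the cosine similarity of the observed
columns l, l' is ≥ τ (zero-norm columns are unrelated to everything, even
at τ = 0); diagonal forced to 0, symmetric.

**Objective.** With targets coded ±1 from the current Ȳ,

  η Σ_l Σ_i (w_lᵀφ_i − (2ȳ_il−1))² + Σ_{R_{ll'}=1} ‖[w_l w_l']‖²₂,₁

subject to Ȳ ≥ Ŷ and, per label, at most ⌊ε·‖Ŷ_l‖₁⌋ corrections. Squared
loss was chosen for the per-label loss V because it admits a closed-form
normal-equations oracle in the decoupled limit (R ≡ 0, ε = 0), which the
tests exploit; the (2,1)-norm is smoothed as √(·+ς²) with ς = 1e−8 —
exactness at this ς is far below test tolerances.

**Optimization.** Alternating minimization. The W-step minimizes the
smoothed objective with a quasi-Newton (L-BFGS) descent on the analytic
gradient, warm-started from the previous W, run to relative objective
change below 1e−6 (tighter in practice) or 500 iterations. The Ȳ-step is
the *exact* minimizer of the loss over the feasible corrections given the
scores: flipping ŷ = 0 → ȳ = 1 changes the squared loss by −4·f_l(X), so
the optimal feasible correction promotes the top-budget entries with
strictly positive score; requiring f > 0 even when budget remains also
avoids arbitrary tie-breaking among zero-score candidates. Because the
W-step cannot increase the objective (line search, warm start) and the
Ȳ-step is exact, the objective trace is non-increasing — asserted after
every fit. The outer loop stops when Ȳ is unchanged or after max_outer =
20 rounds. Prediction thresholds the score at 0, the symmetric boundary
under ±1 coding.

**Defaults.** μ = 1.0 and α = 0.1 follow the published parameter study
(the grid μ ∈ {0.2,…,1.0}, α ∈ {0.02,…,0.1} is reproduced in
`analysis/04_param_grid.py`, and on synthetic data the optimum lands on
the same (1.0, 0.1) corner). η = 1.0, ε = 0.2 and τ = 0.5 are package
choices — the originals are unpublished — and all are exposed in the CLI
and estimator.

## MIML-kNN baseline

For a query bag, references are its n_neighbors nearest training bags and
citers are the training bags that would count the query among their
n_citers nearest (computed over training ∪ {query}, with the query losing
distance ties to training bags). Label scores are the positive fraction
among references ∪ citers; calls at score ≥ 0.5. Defaults 10/20 are the
standard setting. The original second-stage linear transform of neighbor
label counts is deliberately simplified to direct voting; the comparison
on synthetic data is qualitative.

## Evaluation protocol

Hamming loss is the fraction of mismatched bag–label cells; macro-F1
averages per-label F1 over *all* labels with the zero-division convention
F1 = 0 (any other convention inflates macro-F1 when most rare labels go
unpredicted); micro-F1 pools confusion counts over all cells. Repeated
k-fold CV (default 10×10) shuffles with a per-repetition derived seed into
near-equal folds; **training folds are masked to the target W.L.R., test
folds are scored against full labels** — recovering unobserved positives
is the quantity of interest. Fold structure depends only on (seed,
repetition), so ratio sweeps are paired across ratios; labels with no
positive left in a training fold are predicted negative for that fold.
Folds are plain random, not label-stratified: with hundreds of labels on a
few hundred bags stratification is infeasible. Paired two-sided t-tests
compare methods across fold × repetition cells; zero-variance differences
resolve to p = 1 (identical) or p = 0 (constant shift), and a ● marks a
comparison where MIMLwel is better with p < 0.05.

## Synthetic data generator

The generator plants recoverable signal with proteome-like statistics:
bag sizes round(N(3.2, 1.2²)) clipped to ≥ 1; label-set sizes
1 + Poisson(2.3) (mean 3.3); label popularity Zipf(exponent 1.0), so a few
labels are common and most are rare — the regime behind the very small
macro-F1 values typical of GO prediction. Each label owns a prototype
drawn from a sparse Dirichlet(0.05) on the 216-simplex; correlated label
pairs share one prototype ("related functions realized by the same
domain"). Every positive (bag, label) pair places one prototype-derived
instance (prototype + N(0, 0.01²) per coordinate, Euclidean-projected back
onto the simplex); when a bag carries more labels than instances, labels
share slots round-robin and the slot instance derives from the mean of its
labels' prototypes. Leftover slots are, with probability 0.5, fresh sparse
Dirichlet draws (background domains: *distinct* real domains have distant
triad vectors, so background must not cluster around the simplex centre —
an earlier dense-Dirichlet background collapsed all unannotated domains
into one tight cluster and was replaced for exactly this reason) and
otherwise an extra draw of one of the bag's own prototypes. The latent
instance→label assignment is returned as ground truth. Summary statistics
use the population-std convention (ddof = 0).

What passing tests on this generator show: the pipeline recovers planted
bag-level signal well above a closed-form frequency-random baseline, and
performance responds to supervision completeness in the expected
direction. What they do not show: performance on real proteomes — the
generator does not emulate domain-sequence statistics, the nesting of
propagated GO labels, or curation biases.

The frequency-random reference predicts each (bag, label l) positive
independently with probability q_l (the label's observed frequency); its
expected micro-F1 is computed in closed form from expected confusion
counts, 2E[TP]/(2E[TP]+E[FP]+E[FN]).

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds; the CLI derives
per-stage streams by hashing the user seed with the stage name, and the CV
harness derives per-(repetition, fold) streams via seed sequences, so
every reported table is bit-reproducible and result JSON is byte-identical
across reruns (timestamps live only in run manifests). Distance ties in
k-medoids and kNN break toward the lowest index; argsorts are stable.
Dataset and model files are single JSON documents with explicit schema
versions. Analysis drivers default to 3 CV repetitions and the acceptance
script to 2 (rather than 10) — the package's chosen desk-scale protocol;
the full 10×10 protocol is a flag away.

## Known limitations

- The 6-class triad partition and the (η, ε, τ) defaults are declared
  substitutes for unpublished originals.
- The embedding's expressiveness is bounded by K = round(α·m) medoid
  responses; rare labels whose positives do not align with medoid
  geometry are often unpredicted (visible as small macro-F1).
- Bags whose labels outnumber their instances force shared-prototype
  instances; such positives are intrinsically harder to recover (on the
  default generator their recall is roughly half that of
  dedicated-instance positives).
- The learner completes missing *positives* only; annotation noise
  (false positives) is out of scope.
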
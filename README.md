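# weakmiml

Multi-instance multi-label (MIML) protein function prediction with
**incomplete** Gene Ontology annotation.

## The problem

Curated proteome annotation is systematically incomplete: when a protein is
tagged with a handful of GO molecular-function terms, the absent terms are
*unknown*, not negative. Treating those zeros as negatives teaches a
classifier to reproduce the gaps. This package implements a weak-label MIML
pipeline for that setting:

- a **protein is a bag** of instances, one per conserved domain, each
  encoded as a 216-dimensional conjoint-triad frequency vector (residues
  mapped to 6 physicochemical classes; 6³ triad types);
- its **functions are a label set** of GO molecular-function terms,
  true-path-propagated over the is_a DAG;
- the observed label matrix Ŷ retains only a fraction of the true
  positives per label — the **weak-label ratio**
  W.L.R. = ‖Ŷ·,l‖₁ / ‖Y·,l‖₁.

## The learner

Each bag X is embedded as Φ(X): RBF responses
exp(−d(X, Mₖ)² / 2(μδ)²) to K = ⌈α·m⌋ medoid bags (PAM k-medoids under the
average Hausdorff bag distance), plus a bias. Per-label linear scorers
f_l(X) = w_lᵀΦ(X) are trained on ±1-coded targets by alternating
minimization of

    η Σ_l Σ_i ( w_lᵀφ_i − (2ȳ_il − 1) )²  +  Σ_{R_{ll'}=1} ‖[w_l w_l']‖²₂,₁
    s.t.  Ȳ ≥ Ŷ,   ‖Ȳ_l − Ŷ_l‖₁ ≤ ⌊ε·‖Ŷ_l‖₁⌋ per label,

where R relates label pairs whose observed columns have cosine ≥ τ, the
squared (2,1)-norm couples related labels to share embedding coordinates
("related functions share domains"), and the corrected matrix Ȳ may
promote, per label, up to an ε-budget of unobserved entries — the
highest-scoring ones with positive score — to positives. Both alternating
steps decrease the objective, so the recorded trace is non-increasing.

A MIML-kNN baseline (neighbor/citer voting over Hausdorff distances,
10 neighbors / 20 citers) and the full evaluation protocol — Hamming loss,
macro-F1, micro-F1 under repeated 10-fold CV, masking only the *training*
folds and scoring held-out bags against full annotation, with paired
t-tests — are included, along with a synthetic-data generator that plants
label prototypes in bags with proteome-like statistics (~3.2 domains/bag,
~3.3 labels/bag, Zipf-skewed label popularity) so the whole pipeline is
exercisable without downloads.

## Worked example

```
$ weakmiml simulate --m 375 --labels 60 --seed 0 --out data.json
{
  "n_bags": 375,
  "n_labels": 60,
  "instances_per_bag_mean": 3.2666666666666666,
  "instances_per_bag_std": 1.2234741063418093,
  "labels_per_bag_mean": 3.344,
  "labels_per_bag_std": 1.5254498789974495
}
$ weakmiml mask --in data.json --ratio 0.8 --seed 0 --out weak.json
{"requested_wlr": 0.8, "realized_wlr_mean": 0.7926018358662864}
$ weakmiml train --data weak.json --mu 1.0 --alpha 0.1 --seed 0 --out model.json
$ weakmiml predict --model model.json --data data.json --out pred.tsv
```

`pred.tsv` holds one row per (protein, GO term) with the real-valued score
f_l(X) and the binary call (score > 0). The analysis drivers chain these
stages; `analysis/02_wlr_sweep.py` prints the central result — performance
as a function of how complete the training annotation is:

```
MIMLwel, 10-fold CV x 3 reps (mean ± std per fold-cell)
 W.L.R.              HL↓            maF1↑            miF1↑
   20% 0.058 ± 0.003  0.002 ± 0.004  0.004 ± 0.008
   40% 0.053 ± 0.004  0.047 ± 0.014  0.168 ± 0.042
   60% 0.046 ± 0.004  0.103 ± 0.018  0.388 ± 0.056
   80% 0.041 ± 0.004  0.143 ± 0.022  0.527 ± 0.041
```

Reading: with only 20% of true positives visible during training the model
recovers almost nothing; each additional 20% of supervision buys a large
micro-F1 gain, while Hamming loss falls. Macro-F1 stays small because most
of the 60 labels are rare (Zipf tail) — exactly the regime real GO
annotation sits in. `analysis/03_compare_baseline.py` shows MIMLwel beating
MIML-kNN on every metric at every ratio (paired t-tests, p < 0.05), and
`analysis/04_param_grid.py` locates the best (μ, α) at the (1.0, 0.1)
corner of the standard grid.

Real data enter through `weakmiml featurize --domains domains.tsv
--annotations ann.tsv --obo go_subset.obo --out data.json` (TSV of
per-protein domain sequences, TSV of GO terms, OBO ontology subset).

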
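# Methods

## Problem and model

`rtkpair` treats receptor tyrosine kinase (RTK) / ligand interaction as
supervised binary classification over (receptor, ligand) pairs. The
positive class is the set of curated interacting pairs; the negative
class is every other receptor × ligand combination, enumerated
exhaustively rather than sampled. This makes the class ratio a property
of the data (95 : 2183 on a 34 × 67 problem) and motivates the two
design anchors of the model: per-class misclassification weights
*w₊ = n₋/n₊*, *w₋ = 1* in the C-SVM, and AUC as the headline metric,
since accuracy is nearly meaningless at a 4% positive rate.

The SVM is scikit-learn's `SVC` (libsvm's C-SVC) with an RBF kernel by
default and a linear kernel as a config option. RBF was chosen because
the feature vectors are dense, bounded and low-to-moderate dimensional
(40–894), the regime where the RBF default is standard practice; nothing
in the pipeline depends on the kernel choice.

## Features

Four recipes, all producing `[receptor block | ligand block]`
concatenations with deterministic layouts:

- **k-mer frequencies** (k = 1, 2; alphabet ACDEFGHIKLMNPQRSTVWY in fixed
  lexicographic order). Each coordinate is the count of that k-mer among
  windows consisting solely of canonical letters, divided by the number
  of such windows — a relative frequency, so sequence length is not a
  confounder and coordinates sum to 1 on clean sequences. Windows
  containing ambiguity codes (X, B, Z, U, O, J) are dropped from both
  numerator and denominator rather than pseudo-counted, because the
  20-letter basis cannot represent them; a sequence with no valid window
  yields an all-zero vector and a logged warning.
- **Domain / superfamily presence** vectors: binary, one coordinate per
  domain (or superfamily) type in the vocabulary, 1 iff the protein has
  at least one retained hit of that type. Several domains of one
  superfamily still light a single superfamily coordinate (the
  superfamily vector is exactly the OR-projection of the domain vector
  through the domain→superfamily map, a tested invariant). Receptor and
  ligand vocabularies are kept separate, so an accession annotated on
  both roles occupies one coordinate in each block. Hit coordinates are
  carried for provenance but unused — the encoding is presence/absence
  only, with no domain-order information.
- **Composite**: 2-mer pair block then superfamily pair block, the
  best-performing combination of one sequence-level and one
  annotation-level view.

Domain hits are read from a 6-column TSV (protein_id, domain_acc,
superfamily_acc, e_value, start, end) modelled on NCBI Batch CD-Search
hit tables, filtered at read time with `e_value ≤ cutoff` semantics and a
default cutoff of 1.0 × 10⁻⁸. Duplicate hits of one type are harmless
(presence/absence makes deduplication moot).

**Vocabulary provenance.** During cross-validation the vocabulary is
rebuilt from the training folds' proteins by default (`vocab_scope=
"train"`), so domain types seen only at test time cannot leak dimensions
into training; such types are dropped at featurization with a logged
warning. `vocab_scope="all"` switches to a whole-dataset vocabulary for
protocols that assume a fixed, globally known annotation universe.

## Dataset construction

- **Redundancy reduction**: greedy representative-based clustering.
  Proteins are visited longest-first (ties by id); each joins the first
  cluster whose representative is ≥ 80% identical, else founds a new
  cluster. Identity is identical columns / total columns of an
  end-to-end global alignment (match 1, mismatch 0, linear gap −1) —
  the full-length alignment itself realises a 100%-coverage criterion.
  This is a deterministic stand-in for BLASTclust-style clustering with
  the same thresholds, not a bit-exact clone. Clustering is per role;
  arguments are ordered canonically before aligning so identity is
  exactly symmetric.
- **Splits**: stratified k-fold via shuffled `StratifiedKFold`
  (per-class fold counts balanced to ±1); the holdout split is
  implemented directly with per-class `floor(fraction · n)` test counts
  — with 2183 negatives at fraction 0.2 this gives the conventional 436,
  where generic round-to-total splitters give 437. All splits are
  deterministic given their seed.

## Protocols

- **Cross-validation**: per repeat, stratified 5 folds; per fold, the
  vocabulary and the hyperparameter tuning use the training portion
  only; held-out decision values are pooled over the 5 folds into one
  report per repeat (one confusion tetrad and one ROC per repeat), and
  the mean report averages metrics and counts (as reals) across repeats.
  Pooling was chosen over per-fold averaging because the target report
  format carries a single confusion tetrad per method. A ratio metric
  undefined in some repeats is averaged over the repeats where it is
  defined, and rendered "—" only if undefined everywhere.
- **Independent test**: per repeat, stratified 80/20 holdout; tuning by
  inner 5-fold CV (criterion: mean AUC) on training data only; refit on
  all training data; one evaluation on the holdout; mean over repeats.
- **Combination**: within each CV fold, both models are trained on the
  same training portion; their inner-CV AUCs (never the evaluation fold)
  give weights a = AUC_A − 0.5, b = AUC_B − 0.5, floored at ε = 10⁻⁶ so a
  chance-level or inverted model degrades gracefully to near-zero weight
  instead of producing a zero or negative denominator; held-out decision
  values are merged per element as (a·f_A + b·f_B)/(a+b).

**Tuning.** Grid search maximizing mean inner-CV AUC, ties broken toward
smaller C then smaller gamma for reproducibility. The default grid is a
coarse 4 × 3 grid (C ∈ {0.1, 1, 10, 100}, gamma ∈ {0.01, 0.1, 1}) chosen
to keep repeated-CV protocols at desk scale; `model.libsvm_grid()`
provides the classic wide libsvm grid (C ∈ 2⁻⁵…2¹⁵, gamma ∈ 2⁻¹⁵…2³,
step 2²) for thorough single fits. The untuned `gamma` default is the
sentinel `"scale"` (variance-scaled), robust across binary and frequency
features; tuned configs always carry numeric values.

**Metric conventions.** Predicted positive iff decision value > 0
(strict, so an exact 0 counts negative). ROC is the descending-score
sweep with tied scores collapsed into single steps; the trapezoidal area
then equals pairwise concordance with ties counted ½ (verified against a
brute-force oracle in the tests). Precision is undefined (reported "—")
when nothing is predicted positive; F is undefined if either component
is, or if p + r = 0.

## Synthetic-data generator

The generator emulates the structural assumptions of the real curation
pipeline: two disjoint role sets; per-protein domain annotations drawn
without replacement from role-specific vocabularies, each domain mapped
to exactly one superfamily (every superfamily nonempty); interaction
driven at the superfamily level — a pair truly interacts iff it carries
at least one compatible (receptor SF, ligand SF) combination — with
optional label-noise flips; and sequences drawn residue-wise from
(1 − β)·uniform + β·(mean of the protein's domains' Dirichlet preference
profiles), where β = `composition_bias`, so k-mer features carry a
tunable echo of the annotation signal. Interaction is planted at the
superfamily rather than domain level because superfamily features are
the structurally faithful signal carrier in this problem. Ground truth
(the noise-free rule label for every pair, i.e. the Bayes-optimal
prediction) ships with every bundle.

Defaults mirror the curated dataset's shape: 34 receptors × 67 ligands,
80/98 domain types in 26/68 superfamilies, 2–6 domains per protein,
sequence lengths 150–1000, positive-rate target 95/2278, label noise 0
(the compatibility rule *is* the definition of interaction; noise is an
explicit option), composition bias 0.5, plus a 20% chance per protein of
one weak decoy hit (E-value 10⁻⁶–10⁻¹) to exercise the read-time filter.
When no explicit compatibility set is given, it is calibrated by a
best-fit greedy search: each round adds the superfamily pair whose
newly-covered positives land the count closest to the target (largest
non-overshooting gain, else smallest overshoot; ties along a seeded
random order), stopping when any addition would overshoot worse than
stopping short. On the default shape this hits the 95-positive target
exactly across seeds; a config warning reports the achieved rate if the
draw cannot get within 20% of target.

**What passing tests do and do not show.** The generator plants
composition-level and annotation-level structure only: no motifs,
indels, domain order, phylogeny or binding-site geometry. Recovery of
the planted signal validates the pipeline's mechanics (encoding,
weighting, tuning, pooling, combination), not biological performance on
real RTK data. One consequence worth knowing: under pair-level CV the
same proteins appear in training and evaluation folds, so a kernel SVM
can memorize per-protein k-mer fingerprints and k-mer recipes score far
above chance even at β = 0. The composition-bias effect on k-mer
informativeness is therefore measured on protein-disjoint splits in the
test suite, where it is cleanly monotone. The same memorization
dynamic applies to any pair-level CV protocol of this design, real data
included.

## Numerical and degenerate-input choices

- Grid ties: strict improvement (> by 10⁻¹²) required to displace the
  current best, with candidates visited in (C asc, gamma asc) order.
- `combine_decisions` on identical inputs returns them exactly; the
  ε-floor bounds the drift from a chance-level partner by
  ε/(a+ε) · |f_B − f_A|.
- Empty feature blocks concatenate as identities; an empty pair list
  yields a 0 × 0 matrix.
- All-ambiguous sequences featurize to zero vectors (warning), never
  NaN; model training rejects non-finite features outright.
- Fractional averaged confusion counts are kept as reals and only
  rounded for display.

## Problem sizes used in shipped runs

The test suite and the acceptance script run the full-size 34 × 67
problem (2278 pairs) for the superfamily protocol (5 × 5 CV), one repeat
of the 2-mer + superfamily combination protocol, and three repeats of the
composite independent test; component tests use a 12 × 16 bundle. These
sizes were chosen so the complete pipeline — including per-fold
vocabulary rebuilds and inner-CV tuning — runs comfortably on a single
CPU while exercising the exact dataset shape of the motivating problem.

## Known limitations

- The identity clustering is greedy and order-dependent (longest-first);
  it honors the 80%/full-coverage criterion but is not guaranteed to
  match BLASTclust's partitions.
- No probability calibration: decision values are ranked-ordered scores,
  not probabilities.
- Position-aware sequence features, gapped k-mers and domain-architecture
  encodings are deliberately out of scope; the feature set is
  presence/absence and composition only.
- Generated sequences are i.i.d. residue draws; any method exploiting
  realistic sequence structure would look no better than composition
  methods here.
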
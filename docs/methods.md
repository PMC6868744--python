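# Methods

## Problem and data model

The package predicts whether a given cysteine is S-sulphenylated from
its sequence neighbourhood. The atomic sample is a 21-residue motif:
the candidate cysteine plus 10 flanking residues on each side,
1-based-coordinated against the source protein. Cysteines closer than
10 residues to a terminus are kept, with missing positions padded by
the gap residue `X`; the alternative (dropping them) would make
terminal cysteines unpredictable. Non-standard residues (B, J, O, U,
Z, `*`) are also mapped to `X`, keeping the 21-letter encoder alphabet
closed. Homology reduction of training collections is left to external
clustering tools and is out of scope here.

## Feature encoders

Nine blocks are computed per motif and concatenated in a fixed order
(AAC, CKSAAP, BLOSUM62, PSSM, AAindex, BINARY, DISOPRED, PSIPRED,
ACC), with deterministic column names `<CLUSTER>.<position|pair>.<detail>`
so that selected-feature lists are portable across runs.

* **AAC** — counts of the 20 amino acids divided by the window length
  21; `X` contributes to no dimension, so the vector sums to
  (21 − #X)/21.
* **CKSAAP** — for spacing k = 0..5 and each ordered residue pair, the
  pair count divided by the number of k-spaced slots, W − k − 1 with
  W = 21. Pairs containing `X` are dropped from the numerator only;
  the denominator stays fixed, so values are comparable across motifs
  with different padding. For an `X`-free motif each k-block sums to
  exactly 1.
* **BINARY** — per position a 21-length one-hot over the alphabet
  A,C,D,…,Y followed by `X`.
* **BLOSUM62** — per position the substitution-score row of the
  standard matrix: the 20 amino-acid columns plus the terminal `*`
  column as a 21st "terminal signal" entry; `X` positions use the
  matrix's X row. The matrix itself comes from Biopython.
* **PSSM** — per position the 20 log-odds of a PSI-BLAST profile
  (re-ordered to the package's alphabetical residue order), plus, at
  the default width 21, the per-position information content
  (441 columns). The block is configurable because published
  descriptions of this encoding disagree on its width: `pssm_width=20`
  gives 420 columns, and additionally dropping the C-terminal window
  position (`EncoderConfig.table2()`) gives 400, the configuration
  under which the nine blocks total 5297. Padded positions contribute
  zero rows.
* **AAindex** — per position the residue's value under each of 64
  physicochemical indices (8 property clusters × 8), 1344 columns.
  The default table is a curated synthetic stand-in (see
  `data/aaindex64_synthetic.txt`): the historical 64-index selection
  this design descends from was never published, so the package ships
  its own set — widely used published scales where available,
  constructed property scales otherwise — and accepts any replacement
  table in the same format. `X` takes the mean of the 20 residue
  values of each index.
* **DISOPRED** — the 10 upstream + 10 downstream per-residue disorder
  probabilities (central cysteine excluded); padded positions are 0.
* **PSIPRED** — per position the predicted class (coded C=0, E=1, H=2)
  and the three class probabilities; padded positions are (0,0,0,0).
* **ACC** — per position the seven NetSurfP-1.1 scores in file-column
  order (buried/exposed flag, relative and absolute accessibility,
  Z-fit, three secondary-structure probabilities). Because the raw
  ranges differ by orders of magnitude, each score type is min-max
  rescaled with constants fitted on the training data
  (V′ = (V − min)/(max − min)); at prediction time out-of-range values
  are clipped to [0,1]. Constant score types map to 0 with a warning.
  Padded positions are excluded from fitting and encode as 0.

Structural inputs are parsed from the ASCII outputs of the predictors
practitioners already run (PSI-BLAST 2.2.x `-out_ascii_pssm`,
DISOPRED3 `.diso`, PSIPRED 3.x `.ss2`, NetSurfP-1.1 tabular), with a
directory convention `<annot_dir>/<protein_id>.{pssm,diso,ss2,nsp}`.
Parsers validate residue counts (and, for PSSM, residue letters)
against the FASTA sequence when available and fail loudly on other
dialects. A deterministic mock provider (keyed blake2b hash of
seed/protein/position — no float RNG state, hence platform-independent)
stands in for all four tools in tests. Providers accept annotations
computed on full proteins or on the 21-mers themselves; only the
positions under the window are read.

## Feature selection

Continuous features are first discretized by supervised entropy
binning with the Fayyad–Irani minimum-description-length stop: a cut
is accepted only when its information gain exceeds
(log2(N−1) + log2(3^k − 2) − [k·Ent(S) − k1·Ent(S1) − k2·Ent(S2)])/N,
recursively. Features with no accepted cut collapse to a single bin
and carry zero relevance — on label-shuffled data essentially every
feature does, and the ranking then degenerates to column order, which
is the intended null behaviour rather than an error (only a literally
constant matrix is rejected).

Ranking uses greedy mRMR with the MID (difference) criterion:
argmax over remaining features of I(f;y) − mean over selected s of
I(f;s), plug-in mutual information in natural log on the discretized
copies, ties broken by column order. MID was chosen over MIQ as the
classic default of the reference mRMR implementations and because the
quotient form is unstable near zero redundancy.

Forward incremental selection then walks the ranking with two wrapper
models — a balanced random forest and an RBF SVM on standardized
inputs — under 5-fold
stratified inner CV (cheaper than the 10-fold used at model level; a
documented knob). A candidate is kept iff neither model's CV AUC
decreases and at least one strictly increases; the pass stops after
`patience` (default 20) consecutive rejections, implementing
"stop once the AUC curve has peaked" without scanning all 5297
features. The looser reading of the acceptance rule ("higher AUC for
both") is ambiguous; non-decrease-plus-one-strict-increase is the
interpretation that makes a duplicate of an already selected feature
inadmissible.

Random-forest permutation importance is computed per tree on its
out-of-bag samples: (correct OOB classifications − correct after
permuting feature j)/|OOB|, averaged over trees. Bootstrap indices are
reconstructed from each tree's stored seed exactly as the forest drew
them (verified against scikit-learn's internal accounting in the test
suite), so a feature the forest never splits on scores exactly 0.

## Two-stage stacked model

Stage 1 trains, per feature set (nine clusters + the selected subset),
one random forest and one SVM. The RF uses balanced class weights and
tree count = round(√p) floored at 100 — the square-root rule applied
literally gives 4 trees for the 20-column AAC block, which is
statistically meaningless, so the floor is the default and the literal
value remains available via `min_trees`. The SVM kernel (linear,
polynomial, RBF) is chosen per set by cross-validated AUC on decision
values; the winner is refit with Platt-calibrated probabilities.
Every SVM standardizes its inputs (zero mean, unit variance, fitted on
the training fold): raw feature columns differ in scale by orders of
magnitude, on which the SMO solver's iteration count explodes — most
dramatically on signal-free data — and the kernel-SVM implementations
this design follows scale inputs by default. A generous iteration cap
(2 × 10⁵) bounds the residual worst case; hitting it on noise data is
expected and harmless.

Stage 2 is a feed-forward network with 20 inputs (the RF and SVM
positive-class probabilities of the ten sets), one logistic hidden
unit and one logistic output, L2 weight decay 0.1, trained to
convergence by L-BFGS from a seeded initialization; a 3×3 grid
({1,3,5} hidden units × {0, 4e-4, 0.1} decay) is available behind a
flag. The two "balancing nodes" of the classic three-layer description
are realized as the ordinary bias terms of the hidden and output
layers.

The meta network is trained on **out-of-fold** stage-1 probabilities:
every sample's stacking inputs come from base models that never saw
it. In-sample stacking reaches near-perfect cross-validated AUC even
on weak data purely through leakage; the package's design makes that
construction impossible, and the label-shuffle control in the
acceptance suite (held-out AUC ≈ 0.5 after permuting training labels)
verifies it. At prediction time the base models refit on the full
training set are used, together with the training-time feature
manifest and normalization constants; the decision threshold on the
meta output is 0.5, configurable. All randomness (folds, bootstraps,
net init) flows from one run seed stored in the model archive, which
also records a format version checked at load.

## Evaluation

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy, and Matthews
correlation (TP·TN − FP·FN)/√((TP+FN)(TN+FP)(TP+FP)(TN+FN)) with the
0/0 → 0 convention. AUC is the Mann–Whitney rank statistic with
midranks for ties — identical to the trapezoidal ROC area and checked
against an all-pairs count in the tests. Cross-validation is
stratified, seed-fixed, 10-fold by default; headline CV numbers are
pooled over the concatenated out-of-fold scores, with per-fold
mean ± sd also available.

## Synthetic data

Negative motifs draw each flank residue independently from a
background distribution, uniform over the 20 amino acids by default
(a proteome background is configurable); positives draw from the
background tilted by per-residue log-odds shifts, by default +1 nat
for L, K, E, D and −1 nat for C, S, F — the qualitative
over/under-representation pattern seen around real sulphenylation
sites. `strong_enrichment()` doubles the shifts to 2 nats for
stress-testing signal recovery. Pseudo-annotations are
class-conditional: positives' disorder and accessibility means shift
by `structural_effect` (default 0.3 on the [0,1] scales, a
moderate-but-detectable offset); secondary structure carries no class
signal; pseudo conservation profiles derive from the motif's own
residues plus integer noise, so the PSSM block is informative only
through composition. Everything is reproducible from one seed.

The null-signal control (`shuffle_labels`) reassigns labels by a
*stratified* (balanced) permutation: each original class contributes
to each new label exactly in proportion to its size. An unrestricted
permutation leaves a chance association of order ±1/√n between the new
labels and the old — at n = 1000 roughly ±1.6% — and because rank AUC
is scale-invariant, models trained on such labels amplify that tiny
shared tilt into held-out AUCs far from 0.5 whenever the features
separate the original classes strongly (observed: a permutation with
52.4% residual agreement produced held-out AUC 0.70 from base models
whose cross-validated AUC on the shuffled labels was an honest
0.47–0.60). The balanced permutation removes the association exactly,
so the control measures what it is meant to measure — leakage in the
training machinery — rather than permutation noise.

Passing tests on this generator show that the pipeline recovers
planted composition/structural signal and does not manufacture signal
from noise. They do not show real-data performance: real motifs have
positional dependence, homologous redundancy, annotation noise and a
heavily imbalanced class ratio that the generator does not emulate.

## Numerical and design choices

* Terminal padding with `X` rather than discarding terminal
  cysteines; coordinates 1-based.
* MDL entropies in bits (as in the original criterion), mutual
  information for mRMR in nats; both are plug-in estimates.
* `X`-containing pairs excluded from CKSAAP numerators only.
* Min-max fitting ignores padded (NaN) positions; prediction-time
  clipping to [0,1].
* Degenerate inputs: proteins without cysteine yield an empty (not
  erroneous) prediction set; constant features collapse to one MDL
  bin; MCC of a degenerate confusion table is 0; single-class AUC is
  an error.
* Problem sizes in the shipped checks: the end-to-end recovery and
  leakage runs use 500+500 training and 200+200 held-out motifs, an
  mRMR ranking of length 60, selection patience 10, 5-fold CV and
  60-tree wrapper forests; smaller unit-test instances exercise the
  same code paths.

## Known limitations

* The AAindex default table is a constructed stand-in; analyses that
  depend on specific published index values should supply their own
  table.
* Newer predictor dialects (NetSurfP-2/3, fresh PSI-BLAST formats)
  are rejected rather than guessed at.
* The square-root tree-count rule and the single-hidden-unit meta
  network are faithful to the design this package implements, not
  tuned optima; the grid search exists for exploration.
* No GPU paths; training scales to tens of thousands of motifs on one
  CPU but the SVM stage dominates beyond that.
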
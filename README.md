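# sulfenpred

Sequence-based prediction of cysteine **S-sulphenylation** sites.
S-sulphenylation is the reversible oxidation of a cysteine thiol
(Cys–SH) to sulfenic acid (Cys–SOH), a redox post-translational
modification that regulates signalling proteins. `sulfenpred` is a
toolkit for researchers who want to score candidate cysteines from
sequence (plus, optionally, the outputs of standard structure
predictors) or to retrain the model on their own site collections.

## Method

Every candidate site is a 21-residue motif centred on a cysteine
(10 residues either side; windows beyond a terminus are padded with
`X`). Nine feature blocks encode each motif:

| cluster  | content                                                  | dim |
|----------|----------------------------------------------------------|-----|
| AAC      | amino-acid composition, counts/21                        | 20  |
| CKSAAP   | k-spaced residue pairs, `N_i / (W − k − 1)`, k = 0..5    | 2400|
| BLOSUM62 | per-position substitution rows (20 aa + terminal `*`)    | 441 |
| PSSM     | per-position profile rows from PSI-BLAST                 | 400 |
| AAindex  | 64 physicochemical indices per position                  | 1344|
| BINARY   | per-position one-hot over 20 aa + `X`                    | 441 |
| DISOPRED | flank disorder scores (10 up + 10 downstream)            | 20  |
| PSIPRED  | per-position secondary-structure class + 3 probabilities | 84  |
| ACC      | 7 NetSurfP accessibility scores, min-max normalized      | 147 |

for a total of 5297 columns (the PSSM width is configurable: 441 with
the per-position information column, 420 or 400 without it).

A tenth feature set is chosen from the full matrix by **mRMR** ranking
(greedy mutual-information difference on MDL-discretized features)
followed by **forward incremental selection**: a feature is kept only
if it does not decrease either a random-forest or an SVM
cross-validated AUC, until the AUC curve passes its peak.

The classifier is a **two-stage stack**: per feature set one random
forest (balanced class weights, tree count = √(#predictors), floored)
and one SVM (standardized inputs, kernel ∈ {linear, polynomial, RBF}
chosen by CV AUC, Platt probabilities) — 20 base learners whose out-of-fold probabilities feed
a feed-forward neural network (1 hidden unit, logistic activations, L2
weight decay 0.1). Out-of-fold stacking is essential: meta-training on
in-sample scores leaks labels and is deliberately impossible here.

Evaluation reports sensitivity, specificity, accuracy, Matthews
correlation, and rank-based (Mann–Whitney) AUC under stratified k-fold
cross-validation.

A synthetic-data module generates labelled motif datasets with the
flank composition bias observed around real sulphenylation sites
(L/K/E/D enriched, C/S/F depleted in positives) plus class-conditional
pseudo-structural annotations, so the entire pipeline is testable with
no downloads.

## Worked example

```bash
sulfenpred simulate --n-pos 30 --n-neg 30 --strong --seed 1 --out sim
sulfenpred encode  --motif-table sim/motifs.tsv --fasta sim/proteins.fasta \
                   --annot-dir sim/annotations --out feats.tsv
sulfenpred select  --features feats.tsv --motif-table sim/motifs.tsv \
                   --n-rank 20 --patience 5 --inner-folds 3 --out sel.json
sulfenpred train   --motif-table sim/motifs.tsv --fasta sim/proteins.fasta \
                   --annot-dir sim/annotations --selection sel.json \
                   --n-folds 3 --out model.joblib
sulfenpred evaluate --model model.joblib --motif-table sim/motifs.tsv \
                    --fasta sim/proteins.fasta --annot-dir sim/annotations \
                    --out metrics.json
```

On this run the commands print:

```
wrote 60 motifs to sim
wrote 60 x 5297 matrix to feats.tsv
selected 1 features (peak at trial 1)
meta network AUC on stacking inputs: 1.000
{"tp": 30, "tn": 30, "fp": 0, "fn": 0, "sensitivity": 1.0,
 "specificity": 1.0, "accuracy": 1.0, "mcc": 1.0, "auc": 1.0}
```

The 60 synthetic motifs carry a strong (2-nat) planted composition
signal, so one selected feature suffices and the stacked model
separates the classes perfectly; `metrics.json` holds the confusion
counts and derived measures. `sulfenpred predict --model model.joblib
--fasta yourproteins.fasta ...` then scores every cysteine in a FASTA
file, writing one `(protein_id, position, motif, probability, label)`
row per site.

Library use mirrors the CLI: `generate_dataset`,
`assemble_feature_matrix`, `mrmr_rank` / `forward_incremental_select`,
`train_stacked`, `predict_stacked`.

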
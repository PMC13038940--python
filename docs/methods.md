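# Methods

## Problem and model

The package classifies phage proteins into virion (structural, PVP = 1)
versus non-virion (PVP = 0) from evolutionary profiles. The input to the
classifier is not the raw sequence but the protein's position-specific
scoring matrix (PSSM): an L×20 integer log-odds profile produced by
iterative PSI-BLAST search against a large reference database (typically
three iterations, E-value 0.001, against UniRef50). Profile generation
is outside the package; profiles are consumed as PSI-BLAST
`-out_ascii_pssm` text files, one per sequence id.

### Dataset hygiene

Before encoding, sequences are upper-cased, trailing `*` stop characters
stripped, and two filters applied: sequences shorter than 50 residues
are rejected (`SHORT`), and sequences containing residues outside the
20-letter alphabet — in particular the ambiguity codes X, U, Z, B — are
rejected (`NONSTANDARD`). Length is counted on the raw sequence, before
considering ambiguous residues; when both filters apply, `SHORT` is
reported. Both thresholds are configurable. Redundancy clustering
(CD-HIT at 40% identity in the benchmark lineage) is deliberately not
reimplemented: it is an external preprocessing tool and its output is
the expected input here.

### Profile handling

PSI-BLAST prints columns in the order `A R N D C Q E G H I L K M F P S
T W Y V`; at parse time columns are remapped to a fixed alphabetical
order so no encoder ever depends on file layout. Only the 20 log-odds
columns are used; the weighted-percentage block and trailing
information-content reals are validated for presence and discarded.
Three normalizations are available: `raw` (identity), `sigmoid`
(1/(1+e^(−p))) and `row_standard` (each row centered/scaled over its 20
entries; zero-variance rows map to zeros). Defaults follow the
descriptors' original definitions — raw log-odds for AAC-PSSM, DPC-PSSM
and PSSM-COM, row standardization (applied internally) for Pse-PSSM.
Which normalization the original descriptor toolchains applied is not
always documented, so the choice is explicit and configurable rather
than baked in.

### Descriptors

Evolutionary blocks (860 = 20 + 400 + 400 + 40, concatenated in the
order AAC-PSSM ‖ DPC-PSSM ‖ PSSM-COM ‖ Pse-PSSM):

* **AAC-PSSM** — column means over all L rows. Common transcriptions of
  this formula mix the summation bound (L−1) and indices; the standard
  definition (mean over all rows) is implemented, which is also the only
  dimensionally sane reading.
* **DPC-PSSM** — y(i,j) = (1/(L−1)) Σ p(k,i)·p(k+1,j) with *distinct*
  first/second columns; collapsing both indices onto one column (a
  frequent typo) would leave only 20 distinct values among the 400.
* **PSSM-COM** — rows grouped by the identity of the *sequence* residue
  at each position and summed; divided by L by default (length
  normalization removes the trivial length confound; raw sums are
  available). Residues absent from the sequence give all-zero rows.
* **Pse-PSSM** — 20 means of the row-standardized profile plus 20 lag-ξ
  squared-difference terms, ξ = 1 by default (requires L > ξ). The
  40-dimensional form is the only one consistent with the 860-feature
  total; the variance-style 10-term transcription seen in some sources
  cannot produce it.

Classical blocks (723 = 20 + 400 + 5 + 25 + 39 + 39 + 195): AAC, DPC,
GAAC, GDPC over the five physicochemical residue groups (aliphatic
GAVLMI, aromatic FYW, positive KRH, negative DE, uncharged STCPNQ), and
the CTD family over 13 three-group physicochemical partitions (seven
hydrophobicity scales, van der Waals volume, polarity, polarizability,
charge, secondary structure, solvent accessibility), pinned in
`_ctd_constants.py`. CTDD percentile positions use 1-based indexing
with ceiling on fractional occurrence counts; absent groups yield five
zeros.

### Feature selection

Three selectors, each fit on training data only and serialized as an
ordered kept-name list so held-out data is subset identically, never
re-scored:

* **F-score** — two-group one-way ANOVA F per feature; top-k kept
  (default k = 400), ties broken by original feature order. A feature
  constant within classes but separating them receives +∞ and ranks
  first; a globally constant feature receives 0.
* **Variance** — population variance ≥ threshold; the default threshold
  is the 25th percentile of training feature variances (recorded in the
  selection's provenance). The source study states neither its variance
  threshold nor retained counts, so both defaults are explicit
  stand-ins, not reconstructions.
* **RFECV** — recursive elimination (default estimator: linear
  max-margin classifier, coefficient magnitudes as importances;
  tree-ensemble importances selectable), removing `step` features per
  round, subset size chosen by mean stratified-CV accuracy with ties
  resolved to the smallest count. A single-feature matrix is returned
  unchanged (there is nothing to eliminate).

### Stacking

For each selector's reduced matrix, every base algorithm is trained
under one shared fold plan (stratified, shuffled, seeded): the fold-f
model predicts fold-f rows' positive-class probability, assembling a
complete out-of-fold (OOF) column per algorithm, and a refit on all rows
is stored for inference. Meta-features are probabilities rather than
hard labels — they preserve base-model confidence and are the standard
stacking choice. Blocks are concatenated in fixed selector order (F,
Var, RFECV; width 12 per block) and a meta-classifier (LR, RF or SVM)
is trained on the OOF matrix against the training labels. At prediction
time the stored selections subset the incoming features, base refits
emit probabilities, and the meta model produces the final probability;
label = probability ≥ 0.5 (ties count positive; threshold
configurable). The experiment grid spans all 7 non-empty block subsets
× 3 meta tags = 21 stacked configurations over 12 × 3 = 36 base models;
the reference model is F + RFECV blocks with an RF meta-classifier.

Fold bookkeeping is retained (`fold_of_row`) so the no-leakage property
is checkable after the fact: each row's OOF value verifiably comes from
a model whose training set excluded that row. When stratification is
impossible by counting (n = folds, the leave-one-out boundary), plain
shuffled folds are used; a fold plan that would leave a single-class
training set raises with a suggestion to reduce folds.

Base hyperparameters are each library's defaults with seeds pinned and
single-threaded execution; ANN and MLP are both feedforward networks
distinguished by depth (one hidden layer of 32 vs two of 64/32). The
SVM slots use Platt-scaled probability estimates; the calibrated-CV
alternative cannot fit the single-sample folds the layer must support
at small n. CatBoost is an optional backend: constructing it without
the library raises an error naming the slot, and
`available_algorithms()` yields the documented reduced layer (11 slots
where xgboost and lightgbm are present). Nothing substitutes silently.

### Evaluation

ACC, Sn, Sp, Precision, F1 = 2TP/(2TP+FP+FN), and
MCC = (TP·TN − FP·FN)/√((TP+FN)(TP+FP)(TN+FP)(TN+FN)). Zero
denominators surface as NaN sentinels with a warning, never silent
zeros. Two "AUC"s are kept strictly apart: `roc_auc` is the rank-based
ROC area (average ranks for ties) used in all reports; `balanced_auc`
is (Sn+Sp)/2, a fixed-threshold balanced accuracy that part of this
literature prints under the AUC name. The cross-validation driver uses
stratified folds and reports per-fold metrics plus metrics on pooled
out-of-fold predictions.

## Synthetic data

Real benchmark reproduction needs PSI-BLAST profiles against UniRef50,
so correctness is demonstrated on synthetic data instead. Profiles are
random-coil-like: integer scores drawn as round(N(μ, 2)) clipped to the
realistic PSI-BLAST range [−10, 10], with residue strings uniform over
the alphabet. The class signal is a +δ mean shift on a chosen set of
profile columns (default: four columns) for positive samples — planted
in evolutionary-feature space, where the classifier looks. A
sequence-composition signal mode (positives over-sample chosen
residues) exercises the classical-descriptor path. Because a column
mean over L ≈ 60–120 rows has standard error ≈ 2/√L ≈ 0.2, even δ = 1
is strongly detectable; δ = 4 is essentially fully separable, and δ = 0
is an exact null.

What these fixtures do **not** emulate: homology structure between
samples, domain architecture, realistic amino-acid composition, or the
heavy-tailed conservation patterns of real profiles. Passing recovery
tests show the machinery finds a planted signal without leaking; they
do not certify performance on real phage proteins.

## Problem sizes and numerical choices

The recovery suite runs the full pipeline (encode → select → stack →
predict) at 100/100 training and 150/150 held-out proteins per class,
with a compact base layer (DT, RF, KNN, SVM), 5 training folds, F-score
top-100 plus RFECV (step 50, 3 folds) — sizes chosen so the whole suite
exercises every stage in about a minute while keeping the null AUC's
sampling error small (±0.03 at n_test = 300). The δ-monotonicity sweep
(δ ∈ {0, 1, 2, 4}, 5 seeds each, tolerance 0.03 on the means) uses a
lighter single-block configuration. All randomness flows from explicit
integer seeds; repeated runs produce bitwise-identical out-of-fold
matrices and prediction hashes for deterministic learners.

## Limitations

* Profile quality bounds everything: orphan proteins with no detectable
  homologs yield flat PSSMs and near-vacuous evolutionary features.
* The selectors' retained dimensionalities in the original study are
  unreported; defaults here are reasonable but not reconstructions.
* No probability calibration or hyperparameter search; the stack uses
  library defaults by design.
* Binary classification only — no virion-protein subtyping.
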
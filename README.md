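# stackpvp

Stacked-ensemble classification of **phage virion proteins (PVPs)** from
PSSM-derived evolutionary features.

PVPs are the structural proteins of the mature bacteriophage particle —
capsid, tail, and appendages — and mediate host recognition and genome
injection; distinguishing them from non-virion phage proteins (replication
and regulatory machinery) is a recurring annotation task in phage biology
and phage-therapy candidate screening. Because phage sequences are highly
diverse, plain composition features saturate quickly; this package instead
encodes each protein's **position-specific scoring matrix (PSSM)** — the
L×20 log-odds profile from iterative PSI-BLAST search — and classifies
with a two-layer stacked ensemble.

## Method

For a profile p(k, j) (position k = 1..L, amino acid j = 1..20) four
descriptor blocks are computed and concatenated into an 860-dimensional
evolutionary feature vector:

| block | dim | definition |
|---|---|---|
| AAC-PSSM | 20 | x_j = (1/L) Σ_k p(k, j) |
| DPC-PSSM | 400 | y(i, j) = (1/(L−1)) Σ_{k<L} p(k, i)·p(k+1, j) |
| PSSM-COM | 400 | R_i = (1/L) Σ_{k: s_k = a_i} r_k (row sums grouped by sequence residue) |
| Pse-PSSM | 40 | 20 means of the row-standardized profile + 20 lag-ξ terms (1/(L−ξ)) Σ_k (p̃(k,j) − p̃(k+ξ,j))² |

Seven classical descriptors (AAC, DPC, GAAC, GDPC, CTDC, CTDT, CTDD;
723 features) are available as the comparison family. Three selectors
(ANOVA F-score, variance threshold, RFECV) each produce a reduced
training matrix; on each, 12 base classifiers (DT, RF, extra trees,
GBDT, XGBoost, LightGBM, AdaBoost, CatBoost, SVM, ANN, KNN, MLP) are
trained under a shared stratified 10-fold plan. Each training row's
meta-feature is the out-of-fold positive-class probability, so the
second-layer classifier (LR, RF or SVM) never sees leaked predictions.
The reference configuration stacks the F-score and RFECV blocks under a
random-forest meta-classifier. The metric suite reports ACC, Sn, Sp,
Precision, F1, MCC and rank-based ROC AUC (plus (Sn+Sp)/2 under the
separate name `balanced_auc`).

The package consumes precomputed PSI-BLAST ASCII PSSM files
(`-out_ascii_pssm` dialect); it does not run PSI-BLAST. Redundancy
removal (e.g. CD-HIT at 40% identity) is likewise an upstream
preprocessing step. CatBoost is an optional backend: a spec naming it
fails loudly when the library is absent, and
`available_algorithms()` gives the documented fallback layer.

## Worked example

Everything below runs on synthetic fixtures (no downloads). A weak class
signal (δ = 0.4 log-odds on four profile columns) is planted so the
numbers are non-trivial:

```bash
stackpvp make-fixtures --out-dir train --n-pos 50 --n-neg 50 --effect-size 0.4 --seed 7
stackpvp make-fixtures --out-dir test  --n-pos 30 --n-neg 30 --effect-size 0.4 --seed 8
stackpvp extract --fasta train/sequences.fasta --pssm-dir train/pssm \
         --labels train/labels.tsv --out train_features.tsv
stackpvp extract --fasta test/sequences.fasta --pssm-dir test/pssm \
         --labels test/labels.tsv --out test_features.tsv
stackpvp select --table train_features.tsv --out-dir selections \
         --f-top-k 100 --rfecv-step 50 --rfecv-folds 3 --seed 7
stackpvp train --table train_features.tsv --selections selections --out-dir model \
         --algorithms DT,RF,KNN,SVM --folds 5 --seed 7
stackpvp predict --table test_features.tsv --model-dir model --out test_predictions.tsv
stackpvp evaluate --predictions test_predictions.tsv --labels test/labels.tsv --out-dir eval
```

which prints (abridged):

```
wrote 100 x 860 feature table to train_features.tsv
F: kept 100/860
Var: kept 645/860
RFECV: kept 10/860
trained RF meta on blocks ('F', 'RFECV'); training-set ROC AUC 1.0000
{
  "ACC": 0.9333,  "Sn": 0.9333,  "Sp": 0.9333,
  "Precision": 0.9333,  "F1": 0.9333,  "MCC": 0.8667,
  "roc_auc": 0.9933,  "balanced_auc": 0.9333
}
```

Reading: of 60 held-out synthetic proteins, 56 are classified correctly
at the 0.5 threshold (sensitivity and specificity both 28/30); the
rank-based ROC area of 0.993 says the stacked probability orders
positives above negatives almost perfectly. The training-set AUC of 1.0
is the usual refit optimism — held-out numbers are the ones that matter.
`stackpvp grid` runs all 21 stacked configurations (7 selector-block
combinations × 3 meta-classifiers) and writes one metrics row per model.

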
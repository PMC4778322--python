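# ubisite

Prediction of lysine ubiquitination sites in protein sequences from
physicochemical properties (PCPs) of the surrounding residues, with a
benchmark harness for comparing Bayesian and linear classifiers.

Ubiquitination attaches ubiquitin to lysine (K) residues of substrate
proteins and regulates degradation, DNA repair, signalling and trafficking.
Experimentally mapping which lysines are modified is slow and expensive, so
sequence-based predictors are used to triage candidate sites.  `ubisite`
implements a full pipeline of this kind:

1. **AAindex1 parsing** — read an amino-acid property database (each entry
   assigns one real value per amino acid), drop entries with missing values,
   and build the AA-PCP matrix (properties × 20 residues).
2. **Segment extraction** — from FASTA proteins, cut a fixed-length window
   (default 27, odd) around *every* K, padding with `-` at protein ends;
   a window is positive iff its central K is an annotated ubiquitination
   site (1-based coordinates).
3. **Featurization** — the feature value of segment *s* for property *p* is
   the mean of *p* over the standard residues of *s* (gaps and non-standard
   letters are excluded), giving the segments × properties matrix; for the
   discrete classifiers each column is cut into three equal-width bins.
4. **Classifiers** — four Bayesian network models on the binned features:
   naive Bayes (NB), greedy feature-selection NB scored by the
   Cooper–Herskovits (K2) marginal likelihood (FSNB), exact model-averaged
   NB over all 2^n feature subsets computed in O(n) (MANB), and a greedy
   target-centric structure search with the BDeu score (EBMC); and three
   linear baselines on the continuous features: class-weighted logistic
   regression (LR), class-weighted linear SVM, and squared-loss LASSO.
5. **Evaluation** — stratified 5-fold cross-validation scored by AUROC
   (rank/Mann–Whitney form, ties counted ½), sensitivity at a fixed false
   positive rate, and cross-dataset comparison statistics: outperformance
   percent, `mean_d 100·(AUC_a − AUC_b)/AUC_b`, and a paired two-sided
   t-test over datasets.

Every classifier follows one idiom: a model object is built from data, and
`fit()` returns a results object carrying the estimates
(`predict_proba`/`score_samples`, `summary()`).

A synthetic-data module generates AAindex1 files, FASTA protein sets and
labelled segment datasets with a planted, tunable class signal, so the whole
pipeline is testable without downloading any external dataset.

## Worked example

```python
from ubisite import (build_aa_pcp_matrix, parse_aaindex1, average_pcp_features,
                     discretize_equal_interval, cross_validate,
                     generate_aaindex, generate_labeled_segments, SignalSpec)

text, _ = generate_aaindex(40, na_fraction=0.1, seed=3)   # 4 entries carry an NA
aa_pcp = build_aa_pcp_matrix(parse_aaindex1(text))        # -> 36 x 20 matrix

spec = SignalSpec(n_segments=300, delta=0.8, n_informative=3, seed=11)
segments, informative = generate_labeled_segments(spec, aa_pcp)
cont = average_pcp_features(segments, aa_pcp)             # 300 x 36 features
disc = discretize_equal_interval(cont)                    # 3 bins per column

for method in ("nb", "ebmc", "lr"):
    print(cross_validate(method, continuous=cont, discretized=disc,
                         k=5, seed=42).summary())
```

prints

```
NB: 5-fold CV mean AUROC = 0.8976  (folds: 0.8967, 0.8622, 0.9389, 0.9144, 0.8756; seed 42)
EBMC: 5-fold CV mean AUROC = 0.8636  (folds: 0.8433, 0.8600, 0.8878, 0.8606, 0.8661; seed 42)
LR: 5-fold CV mean AUROC = 0.9484  (folds: 0.9722, 0.9278, 0.9611, 0.9500, 0.9311; seed 42)
```

i.e. with a strong planted composition signal (`delta = 0.8`) around
positive K sites, all methods recover the class structure well above chance;
at `delta = 0` the same pipeline returns AUROCs near 0.5.

The same pipeline is scriptable from the shell:

```sh
ubisite synth aaindex --n-entries 40 --na-fraction 0.1 --seed 3 --out aa.txt
ubisite synth segments aa.txt --n-segments 300 --delta 0.8 --seed 11 --out segs.tsv
ubisite features segs.tsv aa.txt --out-prefix feat
ubisite evaluate --discretized feat.discretized.tsv --method ebmc --out cv.json
```

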
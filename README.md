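# biradsrules

Interpretable benign/malignant classification of breast lesions from
discrete **BI-RADS** descriptor tables.

Radiologists score ultrasound lesions on a standardized lexicon — shape,
orientation, margin properties, echo pattern, posterior features,
calcification, and so on.  Each descriptor takes a small set of integer
levels (e.g. Shape: Oval/Round/Irregular → 0/1/2; Echo pattern has six
levels), so a case is one row of 14 small integers plus a benign/malignant
label.  Two things make such tables awkward for off-the-shelf classifiers:
the features are discrete (linear SMOTE-style interpolation produces
impossible scores), and clinical collections are imbalanced (screening
centres see mostly benign cases, cancer hospitals mostly malignant).  On
top of that, clinicians want classifiers whose decisions read like their
own diagnostic rules, not black-box scores.

This package implements a pipeline built around those constraints:

1. **Discrete-safe oversampling** (`DiscreteSMOTE`).  The *whole* input
   space is clustered with affinity propagation; synthesis happens only in
   *safe* clusters where minority samples strictly outnumber majority
   ones.  The generation rate is

       r = (N_maj − N_min) / N_csmin

   with `N_csmin` the minority total inside safe clusters; each safe
   cluster with `n` minority members contributes `round(n·r)` synthetic
   rows.  Every synthetic feature value is the *modal* value among the
   seed sample's k = 5 nearest in-cluster minority neighbours, so
   generated rows only ever contain scores that real minority samples
   carry (a closed-world guarantee).

2. **Entropy-scored coclustering** (`CoclusterMiner`, `mine`).  After
   per-column min-max normalization of the data matrix M, the miner looks
   for column-nearly-constant submatrices.  Quality is the **mean entropy
   score**: for a submatrix Ms with c columns,

       e_j = − Σ_i (N(i)/r) · ln(N(i)/r),       score(Ms) = Σ_j e_j / c,

   where the N(i) are the sizes of the exact-value groups in column j and
   r is the row count of Ms.  Seeds come from 1-D agglomerative clustering
   of each column (complete linkage cut at height *Mic*); each seed is
   expanded to all columns and greedily shrunk — always deleting the
   single row or column whose removal lowers the score most — until
   score(Ms) ≤ *delta*.  Blocks smaller than 5 rows × 3 columns are
   discarded.

3. **Rule extraction** (`extract_rules`).  A cocluster becomes a diagnosis
   rule by averaging its columns (the precondition) and majority-voting
   its rows' labels; the winning class must exceed a strict 0.65 winning
   rate or the cocluster is discarded.

4. **Boosted rule-pair classification** (`IsccadClassifier`).  Every
   (benign rule, malignant rule) pair is a weak classifier: a sample s is
   predicted benign iff

       D_b = ‖f_tb − f_b‖₂ / ‖f_maxb − f_minb‖₂  <  D_m  (analogous),

   the range-normalized distances to the two rule vectors in their feature
   subspaces.  Discrete AdaBoost selects and weights these fixed weak
   classifiers (T = pool size rounds); the final prediction is
   `sign(Σ_t w_t · wc_t(s))`.

A synthetic-data generator (`biradsrules.synthetic_data`) emulates such
tables with planted, label-coherent column-constant blocks, controllable
pattern fidelity, label noise and imbalance, so the whole pipeline is
testable end to end without clinical data.

## Worked example

```sh
$ biradsrules generate --n-benign 40 --n-malignant 20 --coherence 1.0 \
      --label-noise 0.0 --seed 1 --output demo.csv --ground-truth gt.json
wrote 60 samples (40 benign / 20 malignant) to demo.csv

$ biradsrules train --input demo.csv --model model.json --seed 0
trained on 60 samples: 24 rules (9 benign / 15 malignant), 135 weak classifiers

$ biradsrules evaluate --input demo.csv --seed 0
{
  "accuracy": 0.9166666666666666,
  "precision": 0.8,
  "recall": 1.0,
  "f1": 0.888888888888889
}
```

`generate` wrote a table whose benign rows share clinically typical
score patterns; `train` balanced it, mined coclusters, kept the rules
whose label vote was decisive, and boosted the 9 × 15 rule pairs.
`evaluate` holds out a stratified 20% split; malignant is the positive
class, so recall 1.0 means no malignant test case was missed, while
precision 0.8 means one in five malignant calls was actually benign.

Mined rules are stored with their raw-scale interpretation, e.g.

```sh
$ biradsrules mine-rules --input demo.csv --delta 0.05 --out rules.json
mined 32 coclusters, kept 23 rules
```

whose first rule reads: label `benign`, support 21, purity 1.0, with
conditions Shape = Oval (0), Orientation = Parallel (0), Edema = Absent
(0) — the kind of co-occurrence a radiologist would recognise.

The same pipeline is available programmatically:

```python
import biradsrules as br

table, blocks = br.generate(br.default_config(seed=1))
clf = br.IsccadClassifier(random_state=0).fit(table.values, table.labels)
print(len(clf.rules_), "rules,", len(clf.weak_classifiers_), "weak classifiers")
```

`IsccadClassifier` follows scikit-learn's estimator contract
(`get_params`/`set_params`, `fit`/`predict`, fitted attributes with a
trailing underscore) and composes with `sklearn.model_selection`.

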
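# hrvselect

Feature selection for cumulative-stress monitoring from heart rate
variability (HRV), built around a rodent chronic-mild-stress design with
three groups: unstressed **control**, **SS** (short-term stress, two weeks)
and **LS** (long-term stress, four weeks).

The package covers the whole analysis chain:

1. **Synthesis** — the original telemetry ECG recordings are not publicly
   available, so a calibrated generator produces (a) labelled 11-feature HRV
   tables whose per-group means and dispersions match the published
   post-test statistics (mean ± SEM, n = 15 rats/group, SD = SEM·√15), and
   (b) raw ECG-like traces with prescribed beat-interval structure for
   exercising the signal chain.
2. **Signal processing** — 150-s trial segmentation, Pan–Tompkins-style
   R-peak detection, R-R tachogram construction.
3. **HRV features** — six time-domain (mRR, mHR, SDRR, CVRR, RMSSD, pNN5)
   and five frequency-domain features (ln LF, ln HF, ln LF/HF, nLF, nHF)
   from Welch spectra over the rat bands LF 0.1–1.0 Hz, HF 1.0–3.5 Hz.
4. **Ranking** — one-versus-all multiclass SVM recursive feature
   elimination: three linear soft-margin SVMs (control-, SS- and LS-vs-rest)
   are trained on min-max-normalized data; feature *j* is scored by

   &nbsp;&nbsp;&nbsp;&nbsp;*J*<sub>*j*</sub> = max<sub>*r*=1,2,3</sub> (*w*<sub>*j*</sub><sup>*r*</sup>)²

   and the smallest-*J* feature is eliminated and the SVMs retrained, until
   one feature remains.  Features eliminated later rank higher.
5. **Subset evaluation** — for each prefix of the ranking, repeated
   stratified 5-fold cross-validated accuracy, ACC = (TP+TN)/(TP+TN+FP+FN),
   over six classifiers (linear/polynomial/RBF SVM, k-NN, LDA, QDA); the
   optimal subset per classifier is the prefix with maximal mean accuracy.

## Worked example

```python
import hrvselect as hv

table = hv.generate_feature_table(n_per_group=30, seed=7)   # 90 labelled rows
ranking = hv.SVMRFE.from_dataframe(table).fit()
print(ranking.summary())

res = hv.SubsetEvaluation.from_dataframe(table, ranking).fit(
    folds=5, repeats=10, seed=7
)
print(res.summary())
```

prints the elimination-order ranking

```
rank  feature
----  -------
   1  CVRR
   2  nLF
   3  lnHF
   4  nHF
   5  SDRR
   6  lnLFHF
   7  mHR
   8  lnLF
   9  mRR
  10  RMSSD
  11  pNN5
```

— CVRR, nLF, nHF, SDRR carry the largest maximal squared SVM weights, i.e.
at least one of the three group-vs-rest separations leans on them hardest —
and the subset sweep

```
Feature-subset evaluation (5-fold CV × 10 repeats, seed 7)
========================================================================
classifier   s*   acc(all)   acc(opt)    gain  optimal features
svm_linear    7     98.78%     98.89%   0.11%  CVRR|nLF|lnHF|nHF|SDRR|lnLFHF|mHR
svm_poly      7     96.11%     98.00%   1.89%  CVRR|nLF|lnHF|nHF|SDRR|lnLFHF|mHR
svm_rbf       8     98.78%     98.78%   0.00%  CVRR|nLF|lnHF|nHF|SDRR|lnLFHF|mHR|lnLF
knn           3     99.33%     99.56%   0.22%  CVRR|nLF|lnHF
lda           9     98.56%     98.89%   0.33%  CVRR|nLF|lnHF|nHF|SDRR|lnLFHF|mHR|lnLF|mRR
qda           3     93.22%     99.44%   6.22%  CVRR|nLF|lnHF
```

where `s*` is the optimal subset size, `acc(all)` the accuracy on all 11
features, `acc(opt)` on the optimal prefix, and `gain` their difference:
every classifier does at least as well on its selected subset as on the full
feature set.

The same chain is available from the shell:

```sh
hrvselect pipeline --n-per-group 30 --seed 7 --out-dir out/
hrvselect sim rr --duration 150 --seed 2 --out rr.csv
hrvselect extract features --in rr.csv
```

## Layout

- `src/hrvselect/simulate.py` — calibration table, feature-table / tachogram
  / ECG generators
- `src/hrvselect/signal.py` — segmentation, R-peak detection, tachogram
- `src/hrvselect/features.py` — the 11 HRV features
- `src/hrvselect/ranking.py` — OVA linear SVMs and the SVM-RFE criterion
  (`SVMRFE` → `SVMRFERanking`)
- `src/hrvselect/evaluation.py` — six classifiers, subset curves, optimal
  subset selection (`SubsetEvaluation` → `SubsetEvaluationResults`)
- `src/hrvselect/io.py`, `src/hrvselect/cli.py` — CSV/JSON interchange and
  the `hrvselect` command
- `docs/methods.md` — models, parameters, design choices, limitations
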
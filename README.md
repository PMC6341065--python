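# flowps

Floating-window data trimming (FloWPS) for SVM classification of clinical
drug response from gene expression.

## The problem

Cohorts linking tumor expression profiles to a treatment outcome are small
(tens of patients) and wide (thousands of genes). A support-vector machine
trained once on all samples and features must extrapolate whenever a new
patient's profile falls outside the training cloud on some gene, and on
such data it often fails outright — there may be no *global* order
separating responders from non-responders even when responders are locally
surrounded by responders.

FloWPS is a meta-algorithm that prevents that extrapolation by trimming
the training data *per test sample*:

1. **m-condition (feature trimming).** For validation sample *i*, a feature
   *f* is kept only if at least *m* training projections lie strictly below
   and at least *m* strictly above *f(i)* on that feature's axis.
2. **k-window (sample trimming).** In the surviving feature space only the
   *k* nearest training samples (Euclidean distance) are kept to fit a
   soft-margin SVM.
3. **Topogram model selection.** For each held-out sample, every (m, k)
   cell is scored by an internal leave-one-out AUC over the training
   samples, producing the topogram AUC(m, k). All cells with
   AUC ≥ p·max AUC (confidence p, typically 0.90 or 0.95) form the
   *prediction-accountable set S*, and the final score averages the
   per-cell SVM votes: **P_F = mean_S P(m, k)**, on a 0–100 scale
   (responders are encoded 100, non-responders 0).

The cell (m = 0, k = N−1) applies no trimming, so FloWPS restricted to
that corner *is* the classical SVM — the package's baselines exploit this
as a built-in consistency check. A PCA-assisted SVM (PC count pre-trained
by inner leave-one-out AUC) is included as the second comparison method,
and a marker-gene selector (top-30 single-gene Mann–Whitney AUC, plus the
leave-one-out "core" intersection) provides the feature-space pipeline.

## Worked example

```python
import flowps as fp

# locally ordered, globally disordered data: alternating clusters on a 4x4 grid
ds = fp.make_dataset(fp.GeneratorSpec(
    n_samples=64, n_features=4, n_informative=2,
    structure="checkerboard", seed=3))

records, report = fp.loo_evaluate(ds, fp.ClassifierConfig(kernel="linear", C=1.0, p=0.90))
_, svm_report = fp.classical_svm_loo(ds, fp.ClassifierConfig(kernel="linear", C=1.0))
print(f"flowps AUC={report.auc:.3f}  classical SVM AUC={svm_report.auc:.3f}")
```

prints

```
flowps AUC=0.368  classical SVM AUC=0.000
```

On this geometry the global SVM is worse than useless: under leave-one-out
the symmetric alternating clusters make it *anti*-predict every held-out
sample (AUC 0.0), while the per-sample trimmed ensemble stays clear of
that failure mode. On globally separable data (`structure="global_linear"`,
large effect size) both reach AUC 1.0, and the corner-restricted FloWPS
(`grid=fp.TrimGrid((0,), (63,))`) reproduces the classical SVM's
predictions bit for bit.

The same analyses are available from the shell:

```sh
flowps simulate --structure checkerboard --n 64 --seed 3 --out data/
flowps run      --matrix data/matrix.tsv --labels data/labels.tsv --p 0.90 --out results/
flowps baseline --method svm --matrix data/matrix.tsv --labels data/labels.tsv --out results-svm/
flowps select   --matrix data/matrix.tsv --labels data/labels.tsv --n 30 --out ranking.tsv
```

`flowps run` writes `predictions.tsv` (per-sample P_F) and `metrics.tsv`
(AUC, FDR, Sn, Sp, ACC, MCC and the threshold τ that minimizes FP+FN).

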
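# Methods

## Model

FloWPS is a transductive wrapper around the soft-margin SVM. Its premise
is that small expression cohorts often carry *local* order (a sample's
neighborhood is class-consistent) without *global* order (no single
separator works everywhere), and that SVM failure on such data is largely
an extrapolation artifact: the test profile leaves the training cloud
along uninformative axes. Trimming is therefore defined per validation
point:

* **m-condition.** Feature *j* is kept for validation value *v_j* iff
  `#{train values > v_j} >= m` and `#{train values < v_j} >= m`, with
  strict inequalities — training values exactly equal to *v_j* count as
  neither (this makes the rule well defined on tied, e.g. quantized,
  data). The per-feature cap `min(#below, #above)` is precomputed
  (`max_valid_m`), so the mask at any m is a threshold on that vector and
  masks are step functions of m.
* **k-window.** Euclidean distances are computed over the masked features
  only, on the data's given scale (the same geometry the SVM sees; no
  re-standardization). Ties are broken by ascending training index; k
  saturates at the number of available samples. Masking precedes the
  distance computation.
* **Topogram and accountable set.** For one training set the quality of a
  cell (m, k) is the Mann–Whitney AUC of internal leave-one-out
  predictions: each training sample is held out, trimmed against the rest,
  and scored by the cell's SVM. Cells with AUC within a factor *p* of the
  best valid cell form the accountable set S (threshold AUC ≥ p·max AUC;
  "≥" rather than ">" so the argmax cell is always a member and S is never
  empty). The final prediction averages the per-cell SVM outputs over S.

Predictions default to hard class votes encoded {0, 100}
(`prediction_mode="label"`), so P_F is a vote fraction on a 0–100 scale
and P_F·|S|/100 is an integer; `"decision"` averages signed margins
instead (a single-class neighbor set then contributes ±1, the sign of its
class). All SVM fits use libsvm through scikit-learn with default settings
apart from the kernel (linear or polynomial) and cost C.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `kernel` | linear | SVM kernel; polynomial uses libsvm defaults (degree 3, gamma "scale", coef0 0) |
| `C` | 1.0 | soft-margin cost; the regime of interest spans 0.1–1000 |
| `p` | 0.90 | accountable-set confidence; 0.95 is the stricter conventional setting |
| `k_min` | 20 | smallest neighbor count swept; below ~20 samples an SVM fit is too unstable to trust |
| `m_max` | auto | m sweep upper bound: the largest m at which the validation point keeps any feature, capped at half the training size |
| `prediction_mode` | label | hard 0/100 votes vs signed margins |

When the training set is smaller than `k_min` (tiny fixtures), the k grid
falls back to `max(3, N_train − 10)..N_train` so the method remains
exercisable.

## Nested cross-validation and determinism

Evaluation is leave-one-out end to end: the outer loop holds out each
sample; the topogram for that fold is built by an *inner* leave-one-out
over the remaining N−1 samples (mirroring the outer scheme avoids
optimistic resubstitution; the inner resampling scheme is a design choice
of this package). A cell invalid for *any* inner point (no surviving
feature at that m) is invalid entirely, keeping cell AUCs comparable;
rows of the m grid beyond the inner points' survivable range are marked
invalid without fitting. If a cell of S is invalid for the final
validation point it is skipped in the average and `n_cells` records the
cells actually used; in the measure-zero case that every cell of S is
unusable the no-trimming corner supplies the score with `n_cells = 0`.

Nothing in the classifier is randomized: given data and configuration the
P_F vector is reproducible bit for bit. Seeds enter only through the
synthetic generators and class equalization.

The inner sweep costs O(N · |masks| · |k grid|) SVM fits per outer fold.
Two exact optimizations keep this tractable: masks are step functions of
m, so cells sharing a mask share fits; and identical subproblems
(validation point, feature mask, neighbor set) recur across outer folds
and are memoized. Fits go through a thin wrapper on scikit-learn's
bundled libsvm that reproduces `SVC` semantics exactly (verified
bit-for-bit in the test suite) at ~60× lower per-call overhead.

## Baselines and feature selection

The classical baseline is `SVC` on all features and samples, equal by
construction to FloWPS at the corner cell (m = 0, k = N−1); the test
suite asserts bit-for-bit agreement of the two code paths. The
PCA-assisted baseline centers on training means, takes covariance
principal directions (no variance scaling, matching the untransformed
geometry used elsewhere), and picks the PC count from 1..min(10, N−2, s)
by inner leave-one-out AUC, smallest on ties; selection is nested inside
every outer fold so no held-out information reaches it.

Marker genes are ranked by single-gene Mann–Whitney AUC with 0.5 credit
per tied pair. Ranking uses the oriented statistic max(AUC, 1−AUC) by
default so down-regulated markers compete equally (`orient=False`
restores raw ranking); ties break lexicographically by gene ID. The
"core" set intersects the top-n lists of all N leave-one-out subdatasets.
Because those subdatasets share N−1 samples, null rankings are strongly
correlated: the core filter sheds unstable noise genes but a pure-noise
core is reduced, not empty — its value is enrichment (informative genes
survive, inert ones do not), which is what the tests assert.

## Preprocessing

Quantile normalization maps each sample's values to the rank-wise means
across samples; ties receive the mean of the reference values at their
tied ranks. On tie-free data the operation is idempotent and leaves all
rows with one common value multiset; with ties the tie rule deliberately
averages, which can perturb the cross-row multisets — a property of this
standard construction, not a defect. Missing values are rejected rather
than imputed: the m-condition is an order statistic and silent imputation
would corrupt it. Class equalization keeps the full smaller class and
subsamples the larger without replacement (seeded, order-preserving).
Labels are {0, 100} internally; {0, 1} inputs are rescaled on read. The
package assumes matrices are already normalized for platform effects
(e.g. RNA-seq library size); it treats values as given and never
log-transforms.

## Synthetic data

The generators produce the three regimes the method's argument needs, at
desk scale (N ≤ 100, s ≤ 2000) so full nested-LOO runs finish in minutes:

* `global_linear` — Gaussian classes split by `effect_size` along
  informative axes: the positive control where the classical SVM is
  already optimal.
* `checkerboard` — Gaussian clusters (sd 0.1 cell widths) on a 4×4 unit
  lattice with adjacent-cell class alternation: local order with no
  global linear order. Extra features are measurement jitter at the
  cluster-scatter scale (`noise_sd × cluster_sd`) so lattice geometry
  dominates distances — at unit-scale noise the locality the structure is
  meant to exhibit would be destroyed (a 5-nearest-neighbor vote drops
  from perfect to below chance). Under leave-one-out the lattice's
  symmetry makes the global SVM *anti*-predict (AUC near 0), which is the
  failure mode the trimming avoids rather than a property the generator
  aims for.
* `expression_like` — log2-scale gene baselines (uniform 2–12) with
  per-sample shifts (sd 0.3, giving quantile normalization real work),
  N(0, noise_sd) measurement noise, and `n_informative` genes shifted by
  `effect_size` in responders with alternating sign, so both marker
  orientations occur.

What these fixtures do *not* emulate: platform-specific artifacts,
count overdispersion, correlated gene modules, batch structure. Passing
tests demonstrate the algorithmic contracts and the qualitative
local-vs-global behavior, not clinical performance; clinical-cohort
results require the original cohort data (see
`scripts/reproduce_cohorts.py`) and are not asserted anywhere in the
suite.

## Numerical choices

* AUC threshold comparisons use a 1e-12 guard so the argmax cell never
  loses to floating-point rounding in p·max(AUC).
* The discrimination threshold τ scans midpoints of consecutive distinct
  scores plus below-min/above-max sentinels; "score > τ" (strict) calls a
  responder; ties in achieved FP+FN resolve to the smallest τ.
* MCC is 0 when any confusion marginal is empty; FDR is 0 when nothing is
  called positive.
* SVM training rows are passed in ascending sample order regardless of
  distance rank, so the corner cell is bit-identical to a plain SVC fit.
* PCA candidates exceeding the training-set rank are skipped with a
  warning (rank cutoff at 1e-10 of the leading singular value).

## Known limitations

* The per-sample nested sweep is O(N²·|grid|) SVM fits; full-size cohorts
  (N in the hundreds) take hours, which is inherent to the method.
* With `k_min = 20` and very tight clusters the window can never shrink
  to a purely local vote, so on extreme checkerboard-like geometry FloWPS
  avoids the SVM's failure rather than reaching kNN-level accuracy.
* The estimator API computes the topogram once per fitted training set;
  the leave-one-out functions re-fit per fold, which is where the
  protocol's per-sample adaptivity (including the per-point
  "auto" m cap) lives.
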
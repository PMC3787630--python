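# Methods

## Problem setting

Let `R = {r_1, …, r_m}` and `T = {t_1, …, t_n}` be the peak lists of a
reference and a target GC×GC-MS run. Each peak carries two retention times
(seconds) and a fragment-ion spectrum on a shared integer m/z grid of size
g. An aligner proposes matches (t_j, r_i); with s true correspondences and
u proposed matches of which TP are correct, accuracy is summarized by
TPR = TP/s, FPR = (u−TP)/(mn−s), PPV = TP/u, F1 = 2TP/(s+u), and by the
area under the ROC curve traced by thresholding match scores.

The package assumes homogeneous data: both runs come from identical
instrument conditions, so retention times are directly comparable and no
warping or retention-index calibration is attempted. Heterogeneous-data
alignment, raw-signal (profile) alignment, spectral deconvolution and
compound identification against reference libraries are out of scope.

## Similarity measures

Correlation-type measures treat each peak as a random variable observed
over the g m/z channels. Cosine and Pearson differ only by centering;
Spearman replaces intensities by average ranks, which makes it sensitive
to perturbations among the many low-intensity channels of a real spectrum.

The partial correlation of target spectrum X and reference spectrum Y_i
conditions on the remaining reference spectra Y^(i): both X and Y_i are
regressed (least squares, with intercept) on Y^(i), and the residuals are
correlated. The part (semipartial) correlation regresses only Y_i and
correlates raw X with that residual, so it is asymmetric in (X, Y_i).
Residual regression and inverse-covariance formulations are algebraically
equivalent for nonsingular designs; the implementation uses residual
regressions because residuals (orthogonal projections) remain unique even
for rank-deficient conditioning sets, where the minimum-norm least-squares
solution quietly handles duplicate spectra.

Numerical choices:

- Regressions include an intercept: residual correlations are then
  translation-invariant, matching the covariance formulation of partial
  correlation.
- A residual whose standard deviation falls below 1e-10 × the original
  spectrum's standard deviation is treated as numerically zero and the
  score as undefined (e.g. Y_i duplicated inside the conditioning set).
  Undefined scores become NaN in similarity matrices, never exceptions,
  and an aligner treats NaN as "candidate unavailable"; a target whose
  whole row is undefined stays unmatched.
- Constant spectra (zero variance) likewise yield undefined correlation
  scores.

### Two-step conditioning

With m−1 conditioning spectra and only g channel observations, the full
design is singular whenever m−1 ≥ g — the normal situation for dense
biological runs. The two-step form first ranks all reference peaks by
Pearson correlation with X (descending), then conditions only on the top
q. Decisions where the construction is underdetermined:

- The ranking is computed over Y^(i), i.e. peak i is removed before
  ranking and does not consume a rank slot.
- Ties in the pre-ranking break toward the lower reference index;
  undefined Pearson scores rank last. Both choices are purely for
  determinism.
- q ≥ m−1 reduces exactly to full conditioning.

The two-step matrix computation batches the shared work: for one target,
all references outside the global top-q share a single conditioning set,
so their residual regressions are one batched least-squares solve; only
the q members of the window need individual leave-one-out designs. The
batched path is required to agree with the naive per-pair construction to
1e-10 (and does so exactly, since both use the same design ordering).

### A structural property of the part correlation

The semipartial score of a peak against itself is
Corr(X, R_{X|Z}) = sd(R)/sd(X) = √(1−R²_{X|Z}) — strictly below 1
whenever the conditioning spectra explain part of X. Two consequences
surface in the tests: same-peak part scores are not 1 even in the
noise-free limit (they are merely positive), and SW-PAD with the part
measure can exclude true pairs at any positive similarity cut-off, so the
noise-free recovery check runs SW-PAD(part) at ρ = 0. This asymmetry is
intrinsic to the measure, not an implementation artifact, and is one
reason the part correlation is less suited to alignment (where query and
reference come from the same spectral population) than to library search.

## Distances and windows

Euclidean, Maximum, Manhattan and Canberra distances act on raw (rt1, rt2)
in seconds, without standardization: the two dimensions have very
different scales (thousands of seconds vs a few seconds), Canberra is
self-normalizing, and scale handling is treated as part of the measure
under study rather than hidden preprocessing. A Canberra term with zero
denominator (both coordinates zero) contributes 0. Distance-rank windows
take the k nearest references; boundary ties break toward the lower index.

## Aligners

All five aligners are independent per-target selections; a reference may
be matched by several targets. No bijection is enforced because the
evaluation counts matched pairs, not assignments; an optional one-to-one
mode (Hungarian assignment over the selection-score matrix) exists for
exploration and is off by default. Score ties break by smaller rt distance
(the method's own distance; Euclidean for PAS, which has none), then lower
reference index. Recorded match scores — used for ROC thresholding — are
the quantity each method maximizes or minimizes: similarity for PAS and
DW-PAS, −distance for PAD and SW-PAD, the mixture score for PAM.

The mixture score is read as `M = w/(1+D) + (1−w)·S`: the distance enters
through the decreasing transform 1/(1+D) ∈ (0, 1], so w = 1 recovers
distance-driven alignment and w = 0 similarity-driven alignment.

## Evaluation

TN = mn − s − FP by definition, so (TP+FN) = s and (FP+TN) = mn − s are
exact partitions. Two ROC constructions are deliberately kept apart:

- `roc_curve(scores, labels)`: the standard empirical ROC over any scored,
  labeled pair set; its trapezoidal AUC equals the Mann–Whitney statistic
  U/(n₊·n₋) on ties-free scores.
- `alignment_roc(result, truth, m, n)`: thresholds an aligner's own match
  scores, with the alignment denominators s and mn − s. When no match
  survives a cut-off, (FPR, TPR) = (0, 0).

Cut-offs default to the sorted unique observed scores; AUC integration is
trapezoidal with explicit (0,0) and (1,1) anchors.

The score-distribution diagnostic compares similarity scores over true
pairs vs all other cross pairs; separation is quantified by a histogram
overlap coefficient over the pooled score range (64 bins).

## Synthetic data

The generator emulates two regimes of homogeneous GC×GC-MS data:

| parameter | sparse (`data1_like`) | dense (`data2_like`) |
|---|---|---|
| compounds | 75 | 450 |
| m/z channels g | 120 | 160 |
| fragments/compound | 15 | 20 |
| shared-pool channels | 30 | 30 |
| shared-fragment draw fraction | 0.45 | 0.8 |
| multiplicative noise CV | 0.45 | 0.7 |
| baseline noise mean (base peak = 100) | 2.5 | 2.5 |
| rt jitter SD (s) | (3.0, 0.05) | (4.0, 0.08) |
| decoy peaks per side | 7 | 20 |

Each compound's base spectrum mixes fragments from a shared pool — pool
channels carry a characteristic intensity reused across compounds, as the
ubiquitous derivatization/backbone fragment ions of real metabolite
spectra do — with compound-specific fragments drawn from the remaining
channels. The dense regime's higher shared-fragment fraction is what
raises inter-compound spectral correlation; compound count alone cannot,
since pairwise overlap statistics on a fixed grid do not depend on how
many compounds are drawn. Retention times are uniform over
(300–3300 s) × (0.5–5.5 s).

A run pair shares s = round(shared_fraction · n_compounds) compounds, each
re-observed with independent Gaussian rt jitter per dimension,
multiplicative log-normal spectral noise (mean-one, given CV) on true
fragment channels, additive exponential baseline noise on every channel,
and a detection floor at 0.5% of the base peak. The baseline component
matters: without it, zero channels are perfectly reproducible across runs
and Spearman — which weights all channel ranks equally — becomes
unrealistically strong; low-level chemical/detector noise is precisely
what scrambles low-intensity ranks in real spectra. Decoy compounds come
from the same library distribution, so false positives are spectrally
plausible.

Noise and sharing magnitudes were calibrated once so that
similarity-only alignment lands in the qualitative accuracy ranges
characteristic of the two regimes (F1 ≈ 0.8–0.95 sparse, ≈ 0.5–0.75
dense, with Spearman trailing and partial correlation leading), and were
not revisited afterwards. What passing tests on this generator shows is
directional behavior — which measure wins, how the ranking shifts with
spectral density — not instrument-accurate error magnitudes. Real data
differ in ways the generator does not model: non-uniform retention-time
densities, correlated (non-independent) channel noise, abundance-dependent
detection, isotope structure, and deconvolution artifacts beyond simple
split peaks.

Split peaks for testing merge-by-area are produced by `add_split_peaks`
(same label, strictly smaller area, nearby rt) rather than inside
`generate_run_pair`, because ground-truth indices are defined on merged
lists; `truth_from_labels` rebuilds truth from labels after merging.

## Benchmark harness

`run_sweep` enumerates method × measure × distance × parameter
combinations over a list of run pairs, caching similarity and distance
matrices per pair. Default grids: k ∈ {3, 5, 10, 15, 20}; 13 equally
spaced ρ in [0.1, 0.99]; 13 equally spaced w in [0.01, 0.99]; q ∈
{3, 5, 7, 10, 15, 20, 30, 50, 70, 100}. The ρ and w grids are realized as
equally spaced because only their endpoints and count are standard;
two-step ranks q ≥ m are flagged skipped rather than failing the sweep.
`summarize_sweep` reports the mean and standard error of each metric
across pairs. For multi-run studies the convention is first run =
reference, every other run = target, metrics averaged across target runs.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use desk-scale sizes chosen to
exercise every code path: oracle suites at g ≤ 50, m ≤ 10, q ≤ 5 (200
instances) and n, m ≤ 30 (100 fixtures); noise-free recovery on the full
75- and 450-compound presets; directional comparisons on 10 replicate
pairs per regime with the dense regime scaled to 150 compounds, q = 30.
The acceptance script uses 5 replicate pairs per regime and reports PAS
F1/AUC per measure, the partial-vs-Spearman F1 gap in the dense regime,
the growth of the partial-vs-cosine gap from sparse to dense, and the
minimum noise-free F1 over all method/measure combinations.

## Known limitations

- Per-target matching can assign one reference peak to several targets;
  interpretation of u therefore differs from assignment-based aligners.
- Full-conditioning partial/part matrices cost one least-squares solve per
  pair and are intended for sparse-regime sizes; dense regimes should use
  the two-step variants (which are also statistically the right tool
  there).
- The ROC for windowed methods thresholds the final selection score; other
  thresholding conventions (e.g. on the window statistic) would give
  different curves.
- Retention-time units are fixed at seconds at generation/IO time; unit
  conversion is the caller's responsibility.
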
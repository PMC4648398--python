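# Methods

This note documents the models and procedures implemented in
`chemoprint`, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the package's known
limitations.

## Preprocessing

**Mass calibration.** A least-squares polynomial (default degree 2, range
1–3) maps measured m/z to the theoretical masses of a calibrant series.
Each reference mass is matched to its nearest observed centroid within a
window (default 0.05 u — deliberately generous, since matching happens
*before* calibration).  The fitted map must be monotone increasing over
the acquisition range; otherwise it is rejected rather than silently
scrambling peak order.  On simulated quadratic drifts with 0.5 mDa peak
noise the held-out prediction residual is below 1 mDa (see the test
suite), comfortably inside the 5 mDa feature windows used downstream.

**Centroiding.** A profile peak becomes one centroid at the
intensity-weighted mean m/z over the contiguous points at or above half
its apex (the FWHM region, consistent with resolving power quoted as
FWHM); centroid intensity is the summed intensity of that region.
Centroiding is intensity-scale equivariant by construction.  Overlapping
peaks are split wherever the profile dips below half of either apex; no
peak-shape deconvolution is attempted.

**Averaging and background subtraction** operate on a fixed m/z grid of
half-open bins `[lo, lo + w)` anchored at the acquisition-range lower
bound, so bin membership is unambiguous and independent of processing
order.  Averaging takes the arithmetic mean per bin over spectra (absent
peaks count as zero) with an intensity-weighted mean m/z; subtraction
clamps at zero and drops emptied bins.

**Normalization.** Intensities are rescaled so the base peak reads 100
(relative abundance %).  Base-peak normalization makes replicate heat
maps comparable, but it is brittle when the most abundant ion is lost:
the whole profile rescales by the ratio to the next peak.  The simulator
reproduces this artifact faithfully (see Limitations).

## Fingerprint representations

The **heat map** is a samples × m/z-bin matrix of relative abundances.
Within a bin the *maximum* peak intensity is kept, not the sum: spectra
are centroided, one chemotype ion is expected per bin, and a sum would
double-count split centroids.  Bins in which no sample reaches a
retention threshold (default 1% relative abundance) are dropped.  The
default bin width is 1 u (integer-mass binning): ppm-level mass error —
5 ppm is at most 0.005 u across the m/z 60–1000 range — then never
splits one compound's replicate peaks across bins, and chemotype-rich
spectra yield variable counts of the order of a few hundred.  Narrower
bins are supported (`bin_width_u`), but once the bin width approaches
the mass-error scale, replicate alignment degrades and correlation
distances inflate.

The **feature table** holds, per sample and target mass, the maximum
peak intensity within ±`tolerance_u` (default 0.01 u, supported range
0.001–0.05 u).  Windows must be pairwise disjoint; overlaps are a
configuration error naming the colliding pair.

The heat map exports to the tab-delimited Cluster 3.0 dialect
(`UNIQID` + bin centers to 4 decimals, one row per sample, samples are
the clustered items) and re-imports losslessly at that precision.

## Supervised analysis

Features are standardized to zero mean and unit variance per variable —
mass-spectral abundances span orders of magnitude — and the scaling is
stored in the model and refit inside every cross-validation fold, so no
information leaks from held-out samples.

**LDA** solves the generalized eigenproblem `S_B w = μ (S_W + λI) w` on
standardized data.  **KDA** (kernel Fisher discriminant) solves the same
criterion in kernel feature space: with kernel matrix `K`, between-class
scatter of the class-mean kernel rows, and within-class scatter
`N = K L K` (`L` the class-wise centering operator), it solves
`M α = μ (N + λI) α` for dual coefficient vectors α; a new sample
projects through its kernel row against the training set.  At most
k − 1 discriminant directions are returned for k classes.

Defaults, and why:

- **Kernel**: Gaussian (rbf) with bandwidth = median pairwise Euclidean
  distance of the standardized training features.  The median heuristic
  is self-scaling and parameter-free; a linear kernel is available and
  reproduces LDA assignments (verified property).
- **Regularization**: `λ = 1e-3 · trace(within-scatter)/dim`.  Feature
  tables routinely have p ≫ n, where the within-scatter is singular;
  the trace scaling makes λ unit-free.  `λ = 0` is allowed for LDA when
  the scatter is invertible and rejected otherwise with advice.
- **Classification rule**: nearest class centroid (Euclidean) in
  discriminant space; ties break to the lexicographically smallest
  label so results are deterministic.
- **Variance reporting**: for KDA ordination plots the discriminant
  eigenvalue fractions are reported and labelled as such (they are not
  principal-component variance fractions).

**LOOCV** retrains everything — standardization, bandwidth, directions,
centroids — on each fold of n − 1 samples.  If removing a sample leaves
its class with one member, that singleton class is dropped from the
fold's training set with a warning and the held-out sample is predicted
from the remaining classes' model; a two-member class therefore cannot
score above its other member's fold.

**PCA/KPCA.** Correlation-mode PCA standardizes variables (zero-variance
variables are an error naming the column) and is invariant to
per-variable affine rescaling; covariance mode is offered for scale-
carrying data.  Both are computed by SVD of the prepared data matrix,
which is algebraically the eigendecomposition of the correlation or
covariance matrix.  KPCA eigendecomposes the double-centered kernel
matrix, clipping small negative eigenvalues from round-off at zero with
a warning; scores are eigenvectors scaled by √eigenvalue, and with a
linear kernel on standardized data they equal correlation-PCA scores up
to column sign.

## Unsupervised analysis

The similarity between fingerprints is the **uncentered correlation**
`r = (1/n) Σ (xᵢ/σx⁰)(yᵢ/σy⁰)`, `σ⁰ = √((1/n) Σ vᵢ²)` — correlation
about zero, not about the mean, appropriate when the zero level of a
relative-abundance profile is meaningful.  Distance is `d = 1 − r`
(range [0, 2]); Pearson and Euclidean metrics are options, never the
default.  The clustered matrix is the base-peak-normalized heat map
itself; no log transform is applied by default (a configuration choice,
since intense ions then dominate the correlation — see Limitations).

**Single linkage** merges the pair of clusters with minimum pairwise
member distance, at that distance; ties break to the smallest node-id
pair, making the merge sequence deterministic.  Merge heights are
non-decreasing (asserted on every constructed dendrogram), and on a
strict ultrametric the cophenetic distances reproduce the input exactly.

**Newick export** writes branch lengths as parent-height minus
child-height, leaves at height zero: two leaves merged at height h are
`(A:h,B:h);`, so the tip-to-tip path length in the exported tree is
twice the cophenetic (lowest-common-merge) distance.  Duplicate leaf
labels are disambiguated with numeric suffixes and a warning.

**Purity** cuts the tree into k clusters by removing the k − 1 highest
merges (equivalently: stopping after n − k merges, since single-linkage
heights are monotone) and reports the mean majority-label fraction.

## Synthetic data generator

The generator emulates the *structure* of ambient chemotype studies:

- Each species is a set of compounds (default 25) observed as singly
  charged adduct ions (M+H, M−H, or M+O₂⁻ for nonpolar analytes in
  negative mode) over m/z 60–1000.  Neutral masses are drawn uniformly
  with a minimum spacing of 0.5 u across the whole pool, so compounds
  are chemically distinct and default feature windows never overlap.
- A `shared_fraction` of each species' compounds comes from a common
  pool; species differ on shared compounds through ±`separation` shifts
  of the mean log10 abundance (random sign per species and compound),
  and otherwise through private compounds.  `shared_fraction=1,
  separation=0` makes species statistically exchangeable — the synonym
  scenario in which two names label one chemotype.
- Replicate abundances are log-normal around each compound's mean with
  linear-scale coefficient of variation `abundance_cv` (default 0.1,
  i.e. ~10% replicate scatter, implemented as sd(log10 I) = CV/ln 10);
  mean log10 abundances are drawn on [4, 6], a 100-fold dynamic range.
- Noise: Gaussian ppm mass error (default 5 ppm — 0.002 u at m/z 400),
  Bernoulli compound dropout (default 2%), Poisson-distributed spurious
  baseline peaks (default rate 5 per spectrum, up to 2% of the base
  peak).  Spectra are emitted centroided and base-peak normalized.
- Reproducibility: per-spectrum random streams derive from
  `(master seed, species index, replicate index)`, so adding or removing
  a replicate never perturbs the others.

The default study — five species, five replicates, the noise above —
classifies at 100% LOOCV and clusters into species-pure clades when
chemotypes are disjoint.  What the generator does **not** emulate:
ionization physics and matrix effects, isotopologue envelopes (an
optional satellite is the only concession), multiple charge states,
correlated abundances within compound classes, temperature-programmed
volatility.  Passing tests therefore demonstrate the correctness and
statistical behavior of the *workflow*, not instrument-level
performance on real specimens.

## Pipeline and novelty flag

`run_classification` chains feature extraction → discriminant training →
LOOCV → optional blind-sample prediction, and `run_clustering` chains
heat map → Cluster-dialect export → uncentered-correlation single
linkage → Newick + purity.  Configs round-trip through YAML; reports
carry per-stage parameters and input hashes and serialize to JSON.

Blind predictions carry a **novel-class flag**: the sample is flagged
when its nearest-centroid distance exceeds the 95th percentile of the
training samples' own out-of-fold nearest-centroid distances (each
training sample scored under the model that did not see it; in-sample
distances are optimistically tight, especially for rbf-KDA).  This is a
screening aid, not a calibrated test: the distance statistic is
heavy-tailed, so genuine replicates are flagged at well above the
nominal 5% rate while clearly foreign chemotypes sit far beyond the
threshold.  Flags should prompt inspection, not rejection.

## Numerical choices

- Half-open bins anchored at the acquisition-range lower bound,
  everywhere.
- Duplicate m/z rows in peak lists merge by summing (split centroids of
  one ion); peak-list writers emit 9 decimals so round-trips agree to
  1e-9 u.
- Eigen-solvers: `scipy.linalg.eigh` for symmetric-definite generalized
  problems; SVD for PCA; eigenvector signs fixed by making the
  largest-magnitude loading positive.
- Equal-distance prediction ties go to the lexicographically smallest
  class label.
- The calibration map is validated for monotonicity on a 512-point grid
  over the acquisition range.

## Problem sizes

Simulated studies in the tests and the acceptance script use 5 species
× 5–8 replicates with 25 compounds per species (125 feature masses,
~100–200 heat-map bins), the scale at which the statistical phenomena
of interest — perfect LOOCV under separation, chance-level confusion of
synonymous labels and its repair by merging, species-pure clades — are
already stable across seeds.

## Known limitations

- Uncentered correlation of linear-scale abundances is dominated by the
  few most intense ions; a single compound boosted far above the rest
  can make unrelated species correlate.  A log transform before
  clustering would temper this but is deliberately not the default.
- Base-peak normalization makes any replicate that loses its most
  abundant ion an outlier across all representations.
- The novelty flag's false-positive rate is well above its nominal
  quantile (heavy-tailed distances); see above.
- Calibration assumes a single polynomial per acquisition; drift within
  a run is handled only by recalibrating from the nearest preceding
  calibrant file, without interpolation.
- The mzML reader covers MS1 spectra with base64/zlib float arrays —
  the subset this workflow consumes — not the full PSI schema.
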
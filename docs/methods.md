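# Methods

## The model

Each gene's expression trajectory over an interval `[a, b]` is treated as a
random smooth function. After subtracting the gene's own average level, the
centered trajectory is represented by a Karhunen–Loève expansion

    X_i(t) = sum_l xi_il * phi_l(t),

where the eigenfunctions `phi_l` (orthonormal in L²[a, b]) and eigenvalues
`lambda_l` come from the covariance function `G(s, t) = cov(X(s), X(t))`,
and the FPC scores `xi_il` are the gene's coordinates in that basis.
Observations are noisy, dense samples of these curves:

    Y_ik = X_i(t_k) + eps_ik,   eps_ik ~ iid (0, sigma²).

The crucial modelling assumption is a **shared covariance across genes**:
the empirical covariance is pooled over all genes, so the basis is
estimated from thousands of curves even when each gene has only ~15–30
time points and no replicates. Each gene then contributes only its own
scores, estimated by trapezoid-rule integration of `centered * phi_l`.

### Covariance estimation

* Per-gene mean centering removes magnitude differences so the pooled
  covariance captures shape variation only.
* The raw covariance `C(t_k, t_l)` averages products of centered values
  over genes, with pairwise-complete counts under missingness.
* Diagonal entries carry `sigma²` on top of the surface, so they are
  excluded from the 2-D local linear smoother that produces `G_hat`; the
  smoother evaluates the full grid, including the diagonal, from
  off-diagonal data.
* `sigma²` is estimated as the averaged gap between a 1-D local linear fit
  along the diagonal (keeping the contaminated entries) and a local
  quadratic fit perpendicular to the diagonal (off-diagonal data only),
  averaged over the central 80 % of the interval and clipped at zero.
* Eigenfunctions/eigenvalues come from the trapezoid-weighted matrix
  eigenproblem `W^{1/2} G_hat W^{1/2}`; negative eigenvalues (smoothed
  surfaces need not be PSD) are dropped, and enough components are kept for
  the cumulative fraction of variation explained (FVE) to exceed 0.90 by
  default.

## The tests

**One group** — is the trajectory flat? Null fit: the gene mean.
Alternative fit: the FPCA reconstruction. The statistic is a
variance-stabilized F ratio on the mean-squared-residual scale,

    F_i = (RSS_i0/K_i − RSS_i1/K_i) / (RSS_i1/K_i + delta),
    delta = sigma²_hat,

with `K_i` the gene's observed count. Working per observation keeps the
stabilizer on the same scale as the residual term: `delta` is a
per-observation noise variance, and adding it to a *sum* of K squared
residuals would make the statistic essentially scale-free, which destroys
the extra conservatism that pooling permutation statistics across genes is
meant to provide (high-variance genes must face a genuinely larger
denominator floor after permutation). It also handles missing values
naturally, each gene being normalized by its own `K_i`.

The null distribution is a permutation null: each gene's values are
randomly re-matched with the sampling times. Eigenfunctions and `delta`
stay frozen at their observed-data estimates (gene means and observation
counts are permutation-invariant, so RSS0 is reused). Permutations are
drawn **independently per gene** by default; a joint mode (one time-label
permutation applied to all genes, preserving inter-gene correlation under
the null) is available via `per_gene=False`. We measured both on the
built-in generator: per-gene permutation gives a visibly better calibrated
pooled null (realized false discovery proportion ≈ 0.005 at BH level 0.01
versus ≈ 0.016 for the joint mode) at identical sensitivity, hence the
default.

**Multiple groups** — do the groups share one trajectory? The alternative
fits each group separately (own eigensystem, own FVE-selected L, own
`sigma²_j`); the null pools all observations of all groups (per-gene mean
over every observation; covariance on the union time grid, observations
sharing a time averaged) and evaluates the common fitted curve back at each
group's times. RSS are summed over groups and `delta = max_j sigma²_j_hat`.
The permutation re-partitions the pooled observations into groups of the
original sizes, within each shared time point, or within time bins (default
width 10 time units) when the groups' sampling grids differ. Bins in which
some group has no observation are dropped from the permutation (their
observations still enter the statistics); the permuted group's fit uses its
frozen eigenfunctions linearly interpolated at whatever times it ends up
holding. The observed F entering the permutation comparison is computed by
the identity pass of the same code path as the null statistics so that
exact ties (e.g. duplicated groups) resolve consistently.

**p-values.** Two definitions: *genewise* (count a gene's own permutation
statistics at least as large as its F, divided by B) and *pooled* (count
over all genes' permutation statistics, divided by n·B). Pooled p-values
preserve the ordering of the F statistics and are markedly more
conservative in their false positive rates, because permuted high-variance
genes populate the pooled tail; they are the default. Neither applies a
+1/(B+1) correction, matching the plain counting definition; a `smoothed`
flag adds it for users worried about zero p-values. Multiplicity is
controlled by Benjamini–Hochberg step-up FDR (via statsmodels).

## The synthetic-data generator

Both generators mimic a yeast cell-cycle design and define the conditions
under which the package's operating characteristics are evaluated.

* **One group**: n = 1000 genes, 21 equally spaced times on [100, 305]
  (time in cell-cycle "lifeline" units). A fraction `pi0` of genes is
  differential with `X_i = sum_{l=1..3} xi_il phi_l`, `xi_il ~
  N(0, lambda_l)`, `lambda = (4, 2, 1)`, over an orthonormal cosine/sine
  Fourier basis; the rest are flat. Noise is N(0, 0.01).
* **Two groups**: 15 and 22 equally spaced times on [100, 244];
  `X_ij = sum_{l=1,2} (xi_il + gamma_ijl) psi_l` with
  `xi_il ~ N(0, (4, 2))` drawn once per gene and shared by both groups and,
  for differential genes only, `gamma_ijl ~ N(0, (5, 3))` drawn
  independently per group. Sharing `xi` is deliberate: it makes
  non-differential genes satisfy the null hypothesis exactly (identical
  underlying curves, independent noise). Drawing `xi` per group instead
  would give every "null" gene an expected squared between-curve distance
  of 2·(4+2) = 12 — the null would be false for all genes and the realized
  false discovery proportion of any exchangeability-based test saturates
  near 1 (we measured ≈ 0.93), which is not a usable null model.

What the generator does **not** emulate: the irregular (and unpublished)
yeast sampling times, periodic-gene structure, heteroscedastic noise, or
inter-gene correlation. Equally spaced grids are friendlier to curve
estimation than irregular ones, so sensitivities measured here are best
read as an upper end of what the method achieves on comparably sized real
designs; passing tests demonstrate correctness and calibration of the
machinery, not field performance.

## Numerical choices

* Gaussian kernels for all local polynomial smoothers (smooth, infinite
  support: no empty-window failures on irregular grids).
* Surface bandwidth by leave-diagonal-out GCV over a 10-point logarithmic
  grid from half the median time spacing to half the time range; the same
  bandwidth drives the noise-variance smoothers. A bandwidth too small to
  cover some target is enlarged by factors of 1.5 with a warning.
* Trapezoid quadrature for all inner products, scores and FVE.
* Eigenfunction signs fixed so the entry of largest magnitude is positive.
* `delta` floored at 1e-8 if `sigma²_hat` is zero.
* Missing values: RSS are computed over observed entries only; scores
  integrate linearly interpolated rows (nearest-value extension at the
  ends). The multi-group permutation operates on interpolation-filled
  columns (logged when it happens).
* Replicate columns (duplicated time labels in the TSV header) are averaged
  on read; the models then operate on replicate-averaged data.
* Studies (`run_study`) spawn per-replicate seed streams from one master
  seed, so runs are reproducible and extending `reps` keeps earlier
  replicates unchanged.

## Problem sizes

The bundled study harness defaults to a desk-scale profile — 50 replicates
with B = 1000 permutations per setting at n = 1000 genes — which pins the
method's operating characteristics down to within Monte-Carlo noise; the
full-scale protocol (100 replicates, B = 10000) is a parameter change
away. The default B for a single analysis (`one_group_test`,
`multi_group_test`, CLI) is 10000.

## Known limitations

* Dense-design score estimation only (trapezoid integration); the
  conditional-expectation/shrinkage estimators appropriate for sparse,
  irregular per-gene designs are out of scope.
* One homogeneous covariance per experimental group; heterogeneity would
  require clustering before covariance pooling.
* FVE is the only component-selection rule implemented.
* BH is the only multiplicity control; inter-gene correlation is not
  modelled in the adjustment.
* On the built-in two-group generator the pooled-p false positive rate is
  extremely conservative (often 0 at BH 0.05); expect the realized FDP to
  sit well below the nominal level.
* Under a *completely* null dataset (no differential gene at all) the test
  is mildly anti-conservative: the data-driven eigenbasis is then fit to
  the observed noise itself, and freezing it for the permutation samples
  gives the observed statistics a small edge — we measure a family-wise
  false-rejection probability of about 0.10 at BH level 0.05 (nominal
  0.05) on the one-group generator with pi0 = 0. As soon as a few percent
  of genes carry real signal the basis is signal-dominated and realized
  false discovery proportions drop far below nominal.
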
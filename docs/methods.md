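# Methods

## Coupling decomposition

The structural connectome is a weighted, symmetric, zero-diagonal adjacency
matrix over labeled cortical areas (edge = streamline count normalized by
median fiber length; unitless). It is converted to the symmetric normalized
Laplacian `L = I − D^{−1/2} A D^{−1/2}` (D = diagonal of row sums). Isolated
(zero-degree) nodes are a hard error rather than being dropped or patched:
node alignment across subjects must never shift. Because of the degree
normalization, rescaling all edge weights by a constant leaves L — and hence
everything downstream — unchanged.

`L` is eigendecomposed with a dense symmetric solver; eigenvalues are
ascending and clipped to the analytic range [0, 2] to absorb round-off.
Eigenvector sign is fixed by making the first component exceeding 1e−10 in
magnitude positive, so profiles and saliences are reproducible across linear
algebra backends. Degenerate eigenvalues are unproblematic: all downstream
quantities depend only on band projectors `U_band U_bandᵀ`, which are
basis-invariant.

Each BOLD volume is projected onto the eigenmodes (`x̂ = Uᵀx`); the energy
spectral density (ESD) is the per-mode mean squared coefficient over TRs.
The **median energy split** C is the smallest index whose cumulative ESD
reaches half the total (ties resolved by ≥); C is clipped into [1, N−1]
(with a warning at the top) so neither band is ever empty. By default C is
computed per subject; a `group_mean` mode derives one C from the
cohort-average ESD. Ideal band projectors then split the signal into a
coupled (low-frequency) and decoupled (high-frequency) part, which always
reconstruct the input exactly.

**S_C** and **S_D** are the temporal L2 norms of the filtered signals per
area, divided by √TRs by default (`per_tr` normalization) so values are
comparable across scan lengths; `none` disables the division. Note that the
band projectors are orthogonal complements in *node space per TR*, so total
energy summed over areas splits exactly into coupled + decoupled energy, but
a single area's S_C² + S_D² does not generally equal that area's signal
energy (the area's two filtered time courses are not orthogonal in time);
the per-node identity holds only for signals that are sums of pure-band
components.

## Behavior PLS

Profiles are stacked as conditions nested in groups — controls' S_C rows,
controls' S_D rows, athletes' S_C rows, athletes' S_D rows — with each
subject's age repeated on both of their rows. Correlation rows (one per
group × condition cell) are Pearson correlations between age and each area
across that cell's subjects; a zero-variance area in a cell yields
correlation 0 with a warning, never NaN. Two groups × two conditions give a
4 × N matrix and hence exactly 4 latent variables under full SVD. Per LV,
the design-salience entry of largest magnitude is made positive.

Permutation inference shuffles subject ages across the whole sample (both
rows of a subject keep their common shuffled age; group labels and brain
rows are untouched; an option permutes group labels instead). The p-value is
the strictly-greater count of permuted singular values over the observed
one, divided by the number of permutations — no +1 smoothing, so the
smallest reportable p is 0 and is displayed as "< 1/n_perm".

Bootstrap inference resamples subjects with replacement *within group* (a
draw leaving any group with fewer than 3 distinct subjects is redrawn, at
most 100 times). Each bootstrap's saliences are aligned to the observed ones
by orthogonal Procrustes on the design side before accumulating: without
alignment, axis reflection and rotation between resamples masquerade as
sampling variance and deflate bootstrap ratios. BSR = observed brain
salience / bootstrap standard deviation of the aligned saliences (zero SE
yields a ±inf sentinel with a warning). Confidence intervals are 2.5/97.5
percentiles of the aligned areal correlation loadings (correlation rows
projected onto the aligned design saliences). Network summaries average
BSRs beyond ±2.58 (the two-sided standard-normal 99% critical value) within
each network, separately by direction; averaging correlations instead of
BSRs is available behind a flag. A motion check reports Pearson r and p
between brain scores and mean framewise displacement per LV and condition —
reported, never enforced.

## Quadratic age models

Per area and metric, ordinary least squares of the coupling value on
centered age and its square; age is centered on the pooled sample mean
*before* squaring, both groups together (a per-group option exists, off by
default). The quadratic term's two-sided t-test p is corrected by
Benjamini–Hochberg, one family per metric (joint-family mode behind a flag).
BH adjustment is monotone and never below the raw p, but it is *not*
idempotent — re-adjusting adjusted values changes them — so no such property
is claimed or tested.

The cohort statistics use the pooled-variance (Student) two-sample t on mean
framewise displacement with df = n₁ + n₂ − 2, which reproduces the published
t = 1.75 (2 d.p.) on the published per-subject table; the published df of 32
and Cohen's d of 0.113 are inconsistent with the published group sizes (df
should be 31; pooled-SD d computes to 0.617) and are reported as computed,
not copied. Similarly, the published athlete mean age of 32.1 differs from
the mean of the listed athlete ages (31.84); the per-subject table is
treated as authoritative.

## Synthetic cohort generator

The generator's purpose is parameter recovery, not biophysical realism: it
emulates exactly the statistical structure the pipeline consumes, with
analytically known ground truth.

**Connectomes.** One cohort-template connectome is drawn from a weighted
block model: areas are partitioned evenly into networks; edges exist with
density 0.6 within blocks and 0.15 between, with gamma-distributed weights
(shape 4) of mean 1.0 within and 0.2 between. If the realized graph is
disconnected, bridging edges at the between-block mean are added and logged.
Each subject receives the template with every edge scaled by an independent
lognormal factor (log-s.d. 0.1), mirroring the empirical fact that
individual tractography connectomes share a common backbone; fully
independent per-subject connectomes were rejected because eigenvector
variability then dominates any plausible planted effect (a node's baseline
low-band energy varies ~64% relative s.d. across subjects).

**BOLD.** Signals are synthesized in each subject's own spectral domain:
per-mode coefficients are zero-mean Gaussians whose s.d. decays
geometrically from the first to the last mode by the factor
`baseline_low_high_ratio` (default 20), so low harmonics carry most energy,
as in real resting-state data. (A two-level low/high profile cannot satisfy
the limiting requirement that an infinitely structure-aligned signal yields
S_D = 0, because a measured median split always lands inside the occupied
band; the geometric profile degenerates cleanly to the first harmonic.)
Planted effects are node-space multiplicative gains on the low-band (S_C
trends) and high-band (S_D trends) components at target-network nodes:
`gain = 1 + slope·(age − 30) + curvature·(age − 30)²`, floored at 0.05, per
group. Node-space gains keep the planted effect spatially exact; their
price is that a gained component is no longer purely in-band, so strong S_C
trends bleed partly into measured S_D at the same nodes — an honest analogue
of areas carrying coupled and decoupled trends simultaneously. A symmetric
per-subject per-node amplitude factor (s.d. 0.15, truncated below at 0.1)
models between-subject heterogeneity of areal BOLD variance; it is symmetric
rather than lognormal because a skewed factor makes the n = 33 OLS t-tests
visibly anti-conservative. White observation noise (s.d. 0.05) is added
last. Ages are uniform within per-group ranges (athletes 23–45, controls
19–49) unless `ages_from_table` substitutes the published 33 ages and FDs;
mean FD is lognormal (median 0.075 mm, log-s.d. 0.45). The whole cohort is
a pure function of the seed, via per-subject substreams of one master
`SeedSequence`.

**Ground truth.** For each subject and network the generator records the
analytic expected S_C/S_D (per-TR band energies under the planted gains).
The downstream re-measured median split may reassign boundary modes, so
recovery tests assert ordering and correlation against the truth, not
equality.

**What the generator does not emulate:** hemodynamics, temporal
autocorrelation, spatially correlated noise, head-motion artifacts beyond a
scalar FD covariate, and tractography biases. Passing recovery tests
therefore demonstrates that the *pipeline* detects effects of the planted
form at the study's sample size — not that such effects exist in any real
population.

## Calibration and recovery properties (all recomputed by the test suite)

- Under a null cohort (no planted effect) the top LV's permutation p is
  uniform; verified by KS over 50 replicate cohorts (and, during
  development, at 200 replicates: mean p 0.494).
- With a planted athlete-only S_C slope of 0.10/yr at 60 nodes, the top LV
  reaches permutation p ≤ 0.005 with target-network-dominant BSRs in ≥ 90%
  of 20 replicates (n_perm = 1000, n_boot = 200). The slope is chosen for
  test power; the study reports no subject-level effect magnitudes to match.
- Under the global null, each BH family's probability of any q < 0.05 stays
  at the nominal 5% (60 replicate cohorts, 2-binomial-s.e. margin). Note the
  two metric families are separate: the chance of a false discovery in
  *either* is ≈ 1 − 0.95² ≈ 10% by construction.
- A planted quadratic gain (0.008/yr², low noise) is detected after FDR in
  ≥ 80% of 20 replicates; the limiting factor is how informative the random
  age design is about curvature, not measurement noise.

## Problem sizes

Property suites run at N ≤ 32 over 200 random graphs; calibration and
recovery suites use 60-node, 33-subject cohorts (the recovery suite at the
full 106 TRs); the analysis scripts run the full 360-area, 33-subject
configuration. The median-split statistic is coarse on very small graphs — a
single eigenmode entering or leaving the low band moves a visible fraction
of S_C — which is why calibration suites do not shrink below 60 nodes.

## Known limitations

- The median energy split is a per-subject discrete statistic; near the
  half-energy boundary, small energy changes reassign a whole eigenmode
  between bands. This is inherent to the method, not the implementation.
- Permutation p-values have resolution 1/n_perm and no +1 smoothing, by
  the method's counting definition.
- Bootstrap CIs are percentile intervals on correlation loadings; they are
  descriptive companions to the BSR, not calibrated frequentist intervals.
- With strong planted S_C effects the generator produces correlated S_D
  trends at the same nodes (band leakage of node-space gains); tests
  account for this by asserting target-vs-non-target dominance rather than
  absence of any S_D signal.
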
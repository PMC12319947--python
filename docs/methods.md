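# Methods

## Model and procedure

`neurogsp` treats region-level brain activity as a time-indexed family of
signals on a weighted undirected graph whose vertices are atlas regions and
whose edge weights are structural connection strengths (fiber-density-like,
arbitrary units; used as given, not binarized or log-transformed). The
analysis basis is the eigendecomposition of the symmetric normalized
Laplacian `L = I − D^(−1/2) A D^(−1/2)`, whose eigenvalues lie in [0, 2]
and whose zero-eigenvalue multiplicity equals the number of connected
components. Eigenpairs are sorted ascending; each eigenvector's sign is
fixed so that its largest-magnitude entry is positive (ties broken by
lowest index). This makes intermediate dumps reproducible across platforms;
the decoupling index itself is invariant to sign flips. Bases inside a
degenerate eigenspace remain non-unique up to rotation; downstream
projections onto index sets are only basis-independent when the cutoff does
not split such a subspace, so a `DegenerateCutoffWarning` is emitted when
the eigenvalue gap at the cutoff is below 1e-10.

Per subject and condition the pipeline is: graph Fourier transform
(`Uᵀ s_t`), graph PSD (time-averaged squared coefficients of the subject's
own signal — the ℓ2-normalized PSD variant exists only for group-average
display), median-energy cutoff `C` (smallest 1-based mode count whose
cumulative power reaches half the total, clipped to [1, N−1] so both
spectral halves stay non-empty), ideal complementary low/high filtering,
and per region the binary-log ℓ1-norm ratio of decoupled to coupled
components (the structural decoupling index, SDI). The ℓ1 sums are exact
sums over samples, never averaged per-sample ratios; whether they are
divided by T is immaterial since T cancels in the ratio. The cutoff is
deliberately subject-specific (and window-specific in the time-resolved
variant): it adapts the coupled/decoupled boundary to each signal's energy
distribution.

Time-resolved SDI uses non-overlapping windows aligned to sample 0, window
length `round(window_seconds × sampling_rate)` samples (default 1 s), a
trailing partial window discarded, and a fully local PSD → cutoff → filter
→ norm computation per window. Temporal fluctuation is the per-region
standard deviation of the window time course, with linear-interpolation
percentile masks for the most stable (bottom 20%) and most variable (top
20%) regions. Decile maps partition regions into 10 binary masks by SDI
rank; ties are resolved by stable region order so the partition is
deterministic even for degenerate maps.

## Surrogates and group statistics

Spectral randomization flips the signs of the GFT coefficients with an
i.i.d. ±1 diagonal and inverse-transforms: `s_surr = U P Uᵀ s`. One `P` is
drawn per surrogate and shared across all time samples — per-sample
randomization would destroy the temporal autocorrelation the null is meant
to preserve. The construction preserves the graph PSD and total energy
exactly, so the per-surrogate cutoff recomputation (kept for fidelity) must
reproduce the empirical cutoff; the test suite uses that as a free
consistency check. With k surrogates the rank test (empirical strictly
above all k → decoupled-significant; strictly below all → coupled-
significant; ties count as not significant) has one-sided level 1/(k+1);
the default k = 19 gives 0.05. Both one-sided tests are reported
separately, without joint two-sided correction.

Group consistency uses the smallest count `g` with binomial tail
probability `P(X ≥ g) ≤ α` for `X ~ Binomial(n_subjects, p_success)`,
with `p_success = α = 0.05`. The boundary is inclusive — a tail exactly at
α counts as significant, the same convention by which the k = 19 rank test
is a level-0.05 test — with a 1e-9 relative tolerance absorbing float
noise in the tail sum. For 43 subjects the threshold is 6.

Condition contrasts are per-region paired t-tests (two-sided) with
Benjamini–Hochberg FDR across regions at α = 0.05, computed on all regions
(restriction to group-significant regions is left to the caller). A
paired difference that is exactly constant has undefined t; a zero
constant yields t = 0, p = 1, while a nonzero constant is flagged
significant with t = ±inf and a warning rather than a silent NaN. Band
concordance is Spearman ρ between band pairs after averaging region maps
into the supplied network labels (the mapping is an external table; no
atlas is bundled). Reliability is the two-way random-effects ICC — ICC(2,k)
of the mean rating by default, ICC(2,1) by flag — with the F-distribution
95% confidence interval, delegated to `pingouin.intraclass_corr`; the test
suite validates it against a from-scratch ANOVA mean-squares oracle.

## Temporal preprocessing

Downsampling (default target 125 Hz) is polyphase resampling with its
built-in anti-aliasing FIR and mean-padding at the edges. Band-passing uses
a fifth-order Butterworth design applied forward and backward
(`sosfiltfilt`), i.e. zero phase with doubled effective magnitude order;
the one-pass causal response is available via the internal switch. Zero
phase was chosen because phase distortion would corrupt the Hilbert
envelopes extracted downstream. Band defaults: theta 4–8, alpha 8–13, low
beta 13–20, high beta 20–30, gamma 30–40 Hz; the theta upper edge is
sometimes placed at 7 Hz and is an ordinary constructor argument. Envelope
edges (roughly the first and last second) carry boundary transients and
should be excluded from envelope statistics; the envelope tests trim them.

## Synthetic data: what it emulates and what it does not

The generator produces geometric random connectomes (points uniform on a
sphere, weights `exp(−d/scale)`, pruned to a target density, redrawn until
connected), graph signals whose per-mode power decays as `k^(−psd_decay)`
carried by stationary AR(1) coefficient time courses (coefficient 0.9, so
envelope and windowed analyses see realistic smoothness; an exponent of 0
gives white carriers for calibration tests), and cohorts with per-subject
multiplicative log-normal weight jitter (sd 0.1, redrawn until connected)
and a two-condition contrast.

Planted decoupling injects an independent AR(1) carrier at a single node.
A node-localized source has its energy spread over all graph frequencies,
so with a low cutoff most of it lands in the decoupled component. Its
amplitude is calibrated in closed form: with background node variances
`v_lo, v_hi` under the two filters and projector diagonals
`p_lo + p_hi = 1`, the amplitude solves
`(v_hi + a² p_hi²)/(v_lo + a² p_lo²) = 2^(2·target)`, placing the
expected SDI at the target (+0.5 for planted nodes; condition effects
shift the target at chosen regions by `planted_effect`, default +0.5, at
10 regions). Because the coupled/decoupled components are zero-mean
Gaussian, the ℓ1-ratio converges to the ratio of standard deviations, so
the expected SDI is `0.5·log2(var_hi/var_lo)` per node — including exact
cross-node leakage of planted components — and is stored in the truth
table. This closed form is also the oracle the recovery tests compare
against.

The default decay exponent is 3. The generator is meant to emulate the
empirically observed regime in which the graph spectrum of brain activity
is 1/f-like with the bulk of power in the smoothest harmonics; at
shallower decays (≈2) a non-negligible fraction of nodes — those loading
weakly on the smoothest modes — have genuinely positive background SDI,
which would make "planted positive, background negative" an incoherent
ground truth. At decay 3 effectively every node's background is
low-mode-dominated (the median synthetic cutoff is C = 1), and planted
layouts are recovered by sign at >99% of nodes over 50 seeds.

Reference problem sizes: 64 regions, 43 subjects, 80 s at 125 Hz (10⁴
samples per condition). These sizes make a full cohort generate and
analyse in seconds while leaving the per-node SDI estimate ≈4 standard
errors away from zero for background nodes.

What the generator does **not** emulate: volume conduction / source
leakage between regions, nonstationary band power, distance-dependent
noise correlations, realistic fiber-density distributions (log-normal
heavy tails), or any biophysical neural dynamics. Passing tests therefore
demonstrate the correctness and calibration of the estimator and its null,
not robustness to the artefacts of real EEG source reconstruction.

## Numerical choices

- Symmetry: input matrices with max |A − Aᵀ| ≤ 1e-8 are repaired by
  averaging (tractography pipelines emit tiny asymmetries); larger
  asymmetry is an error.
- Zero-norm guard: if a region's coupled or decoupled ℓ1 norm is below
  1e-300 the SDI is set non-finite with a named warning; no epsilon is
  injected, to avoid biasing log-ratios. Non-finite empirical SDIs are
  "not significant" in the rank test, with a warning.
- Eigenvalue range and orthonormality are validated at 1e-8; GFT round
  trips and filter reconstructions hold to 1e-10 at 360 regions.
- All randomness flows through `numpy.random.Generator` seeded from
  explicit arguments; cohort generation is bit-reproducible from one
  master seed, and surrogate sets record a digest of their sign matrices.

## Known limitations

- Ideal (brick-wall) graph filters only; smooth or heat-kernel filters are
  out of scope.
- The cutoff rule is the half-energy split; alternative cutoff strategies
  can be slotted in by replacing `median_split_cutoff` in the pipeline,
  but none is shipped.
- Surrogate counts other than 19 change the test level as 1/(k+1); there
  is no interpolation-based p-value refinement.
- ICC confidence intervals degenerate (NaN) when the residual variance is
  exactly zero (duplicated raters).
- The on-disk format is plain delimited text; at 360 regions × 10⁵
  samples files are large but remain practical, and no binary container
  is provided.
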
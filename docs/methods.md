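# Methods

## Scope and model

`dmirelax` studies how the ordering of k-space encoding in multi-delay
²H-MRSI interacts with slow global changes of metabolite levels, and
what bias that induces in fitted relaxation times. The pipeline is a
noiseless simulation: every effect present in the output (partial-
volume mixing, drift bias) is deterministic and attributable.

Signal models:

- inversion recovery, fitted with three free parameters
  `M(TI) = C1 (1 − C2 e^(−TI/T1))`; simulated with perfect inversion
  (C2 = 2). IR signals are simulated and fitted as *signed* real
  values; magnitudes are never taken, so the recovery crosses zero at
  TI = T1 ln C2.
- spin echo `M(TE) = C1 e^(−TE/T2)` with two free parameters.
- bi-exponential water T2 with the CSF fraction fixed from anatomy;
  parameterized as (C1, T2short, δ) with T2long = T2short + δ, δ ≥ 0,
  so the component ordering is structural. The long component is
  flagged unconverged when its 1-SD uncertainty exceeds its value —
  with short maximum TEs it is often not identifiable.

## Synthetic phantom

Two concentric ellipsoids partition an outer "brain" ellipsoid: an
inner core (sWM, T1 = 310 ms, T2 = 25 ms) surrounded by a shell (sGM,
T1 = 350 ms, T2 = 35 ms), both with unit equilibrium amplitude. The
fraction maps are binary at the simulation resolution; all mixing
arises from the k-space downsampling, which mimics how gray matter
surrounds white matter at acquisition resolution. Default geometry:
outer semi-axes at 90 % of the half grid extent, core at 70 % of the
outer (core ≈ 34 % of brain volume), so both compartments contribute
well over 20 % of brain voxels.

What the phantom does *not* emulate: anatomical folding, CSF, B0/B1
inhomogeneity, lipid contamination, and noise. Passing tests therefore
demonstrate the encoding-ordering mechanism and the fitting machinery,
not robustness to in vivo confounds.

## Schedules and drift

Default experiment design (all configurable in `RunConfig`):

- IR: five TIs, linear fill of 5–900 ms → {5, 230, 455, 680, 900} ms.
- SE: seven TEs, linear fill of 6–60 ms → {6, 15, 24, 33, 42, 51, 60} ms.
- drift: linear, magnitude 0.35 (the level at the end of the scan is
  1 ± 0.35 times the initial level), direction ±1.

Only the ranges and counts of the delay lists are constrained by the
protocol being modelled; the intermediate values are a package
default. The consecutive-scheme bias magnitude is sensitive at the
level of several percentage points to this spacing (denser late
sampling increases it), which should be kept in mind when comparing
against any particular reported numbers.

Drift-to-weight mapping:

- **reordered**: every k-point is acquired (for all TI/TEs at once) at
  the acquisition-time fraction τ = rank/N given by its inside-out
  radial rank; weight w = 1 + direction·magnitude·τ, identical across
  timepoints and spherically symmetric.
- **consecutive**, default `"vector"` mode: each timepoint block b of
  n receives one scalar level 1 + direction·magnitude·b/(n − 1) — a
  per-timepoint vector reaching the full ±35 % at the last block,
  modelling a drift that is slow within one block. The alternative
  `"ramp"` mode additionally ramps the weight within each block along
  the inside-out traversal, τ = (b·N + rank)/(n·N); it yields a
  slightly weaker bias because the k-space center of block b is
  acquired at the start of the block.

Radial ranks resolve equal-radius ties by assigning the shell-average
rank (default), which makes reordered weight fields exactly
spherically symmetric and lets the consecutive scheme degenerate
exactly to the reordered one at n = 1; a lexicographic tie-break is
available.

## Reconstruction

Transforms are unitary and origin-centered (DC at index n//2).
High-resolution volumes go to acquisition resolution by: forward FT →
central crop to the target matrix (even targets keep the extra sample
on the negative-frequency side) → multiplication by the radial Hamming
window `0.54 + 0.46 cos(π r)` (r = normalized k-space radius; exactly
1 at DC, 0.08 at the band edge, 0 beyond — a separable variant is
available) and the scheme's weight field → inverse FT, scaled for unit
DC gain. For real objects the unpaired −n/2 Nyquist planes of even
axes are zeroed to keep the output exactly real (the imaginary residue
is asserted below 1e−9 of the signal); the Hamming window nearly
annihilates those planes anyway.

Tissue fractions are downsampled through the same pipeline, clipped to
[0, 1], and jointly renormalized where Gibbs overshoot would push the
total above 1. Non-Cartesian data are reconstructed with the direct
adjoint NUDFT *without* density compensation (duplicated samples add),
which equals the inverse FFT on exact Cartesian coverage; at these
matrix sizes no gridding approximation is needed.

A structural consequence asserted in the tests: for a homogeneous
tissue, any timepoint-invariant (reordered) weighting scales each
voxel's time series by a single constant, so T1/T2 fits are invariant
to machine precision at *any* drift magnitude. With two compartments
the invariance is only approximate (the weight field perturbs the PSF
differently than the Hamming window), which is why the reordered
scheme shows sub-0.1 % rather than exactly zero error.

## Spectral stage

The ²H basis (water 4.8, Glc 3.9, Glx 2.4 ppm; reference 45.7 MHz,
i.e. ²H at 7 T) is simulated as complex Lorentzians from truncated
FIDs; an acquisition delay imprints the corresponding first-order
phase (2π·f·delay at each line). Fitting is linear least squares on
stacked real/imaginary parts, so amplitudes are real and signed — an
inverted resonance simply fits negative, making a separate
180°-phase basis set redundant (the flipped members are still
materialized for compatibility). CRLBs are
σ·sqrt([(AᵀA)⁻¹]_ii)/|a_i| with σ estimated from a signal-free
window. Region averaging phases each voxel by the angle of its
complex integral over the water window and aligns frequencies by
integer-bin cross-correlation against the voxel-median magnitude
spectrum (±3 bins, ties toward zero). FWHM is measured on the
absorption-mode (phased) profile of the fitted line — the magnitude
profile of a Lorentzian is √3 wider than its absorption linewidth.

The relaxometry experiment fits the peak-amplitude image series
directly (the simulation carries the water resonance only); the
spectral stage exists as a separately exercised path and for
region-averaged fitting, mirroring pipelines where voxel-wise SNR is
too low for spectral fitting.

## Masks and summary statistics

Dominance masks: synthetic rule = fraction > 0.60 on the downsampled
maps; in vivo rule = fraction ≥ 0.40 *and* ≥ 1.5 × the other tissue.
Voxel-wise fits are averaged (mean ± SD) per mask; fits that fail to
converge are excluded with a logged count. Percent error is
100·|fit − reference|/reference against the drift-free gold-standard
run of the same pipeline (not against the nominal truth, so
partial-volume effects cancel). Coefficients of variation use the
sample SD; paired comparisons use the two-sided paired t-test, with
zero-variance differences flagged as undefined rather than raising.

## Numerical choices

- Nonlinear fits: `scipy.optimize.curve_fit` (Levenberg–Marquardt /
  TRF with bounds), unweighted. IR uses a multi-start T1 grid
  {50, 150, 350, 700} ms with C2 = 2; SE starts from the log-linear
  solution; the bi-exponential fit multi-starts over a grid of
  (T2short, δ) scaled to the TE span. Best residual wins.
- Uncertainties are 1-SD from the Jacobian-based covariance; in
  noiseless saturated fits (zero residual degrees of freedom) they are
  reported as 0.
- Determinism: the pipeline contains no random numbers; identical
  configurations produce bit-identical reports (asserted).

## Problem sizes

The default configuration runs an 80³ phantom downsampled to 20³
(4:1), which preserves the mechanism under study — the paper-style
protocol grid (220×220×210 → 22×22×21, 10:1) is available via
`paper_scale_config()` / `--paper-scale` for full-scale runs. At desk
scale the gold standard recovers T1 = 347.0/313.2 ms and
T2 = 34.3/25.8 ms for sGM/sWM (the deviation from 350/310 and 35/25
is pure partial-volume mixing), the reordered scheme reproduces the
gold standard to ≤ 0.06 % under ±35 % drift, and consecutive encoding
is biased by roughly 30–40 % (T1) and 16–25 % (T2), shortened for
decreasing and lengthened for increasing levels.

## Known limitations

- The drift is multiplicative k-space weighting of an ideal object,
  not a re-simulation of a time-varying object during readout.
- The consecutive-scheme bias magnitude depends on the delay-list
  spacing and on the vector-vs-ramp drift convention (see above);
  directions and the reordered scheme's invariance do not.
- The CRT geometry utility (`crt_rings`) describes trajectory
  coordinates only; gradient feasibility, dwell-time effects and
  spectral-spatial interleaving at the ADC level are out of scope.
- No noise model: fitted SDs across a mask reflect partial-volume
  heterogeneity, not measurement precision.
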
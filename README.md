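# dmirelax

Simulation and relaxometry pipeline for **deuterium metabolic imaging
(DMI)** with k-space-reordered concentric-ring-trajectory (CRT)
encoding.

## The problem

Mapping T1 and T2 of ²H-labeled metabolites (water, glucose, Glx) in
the human brain requires multi-delay MRSI scans lasting tens of
minutes, during which metabolite levels slowly drift after oral
²H-glucose administration. How the scanner orders its k-space encoding
decides whether that drift corrupts the fitted relaxation times:

- **k-space reordered** acquisition loops over *all* inversion/echo
  times at each ring before increasing the radius (inside-out). Every
  k-point then sees the same signal level across all TI/TEs, so the
  drift acts as a static spherical apodization that cancels out of
  every per-voxel relaxation fit.
- **Conventional consecutive** acquisition encodes the whole k-space
  once per TI/TE, so each timepoint is globally scaled by a different
  level — a bias that propagates directly into T1/T2.

`dmirelax` reproduces this comparison in silico: a noiseless
two-compartment digital brain (synthetic gray/white matter, sGM/sWM)
with T1 = 350/310 ms and T2 = 35/25 ms is simulated at high
resolution, Hamming-apodized and downsampled in k-space to the
acquisition matrix (reproducing the CRT point-spread function and
partial-volume mixing), weighted by the encoding scheme under a linear
±35 % level drift, fitted voxel-wise, and summarized over tissue-
dominance masks (fraction > 60 %).

## Models

Inversion recovery (three-parameter, signed):

    M(TI) = C1 (1 − C2 e^(−TI/T1))

Hahn spin echo (two-parameter):

    M(TE) = C1 e^(−TE/T2)

Bi-exponential water T2 with a fixed CSF fraction from anatomy:

    M(TE) = C1 [ f_CSF e^(−TE/T2long) + (1 − f_CSF) e^(−TE/T2short) ]

Sparse ²H spectra (water 4.8 / Glc 3.9 / Glx 2.4 ppm at 45.7 MHz) are
fitted as linear combinations of simulated complex Lorentzian basis
lines with *signed* amplitudes, so inverted lines below the IR null
need no separate 180°-phase basis set. Amplitude CRLBs come from the
Fisher information of the linear model.

## Worked example

```python
import numpy as np
from dmirelax import fit_ir, build_basis, lc_fit

ti = np.array([5., 230., 455., 680., 900.])
s = 1.0 * (1 - 2 * np.exp(-ti / 350.))
fit = fit_ir(ti, s)
print(f"T1 = {fit.t1_ms:.2f} ms  C1 = {fit.c1:.3f}  C2 = {fit.c2:.3f}  "
      f"null at {fit.null_time_ms:.1f} ms")

basis = build_basis(phase_flip=True)
spec = (-0.8 * basis.members["water"] + 0.3 * basis.members["Glc"]
        + 0.1 * basis.members["Glx"])
print({k: round(v, 3) for k, v in lc_fit(spec, basis).amplitudes.items()})
```

prints

```
T1 = 350.00 ms  C1 = 1.000  C2 = 2.000  null at 242.6 ms
{'water': -0.8, 'Glc': 0.3, 'Glx': 0.1}
```

The negative water amplitude is the signed fit of an inverted line
(equivalent to selecting its 180°-phase basis member); the null time
T1·ln C2 marks the inversion-recovery zero crossing.

The full experiment runs from the command line:

```sh
dmirelax --out out compare-schemes
```

and prints one row per scheme × compartment × constant, e.g. (default
desk-scale grid, 80³ → 20³):

```
constant               scheme compartment fitted_ms sd_ms  truth_ms gold_standard_ms percent_error
      T1        gold_standard         sGM    346.99  4.54     350.0           346.99          0.00
      T1   reordered_decrease         sGM    346.95  4.58     350.0           346.99          0.01
      T1 consecutive_increase         sGM    487.53  7.57     350.0           346.99         40.50
      T1 consecutive_decrease         sGM    241.54  2.88     350.0           346.99         30.39
      ...
```

The gold standard recovers the ground truth up to partial-volume
mixing; k-space reordering stays within a few hundredths of a percent
of it at ±35 % drift, while consecutive encoding is biased by tens of
percent, shortened under decreasing and lengthened under increasing
levels.

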
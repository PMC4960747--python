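# gluedit

Macromolecule-suppressed glutamate editing for single-voxel <sup>1</sup>H MRS
at 7 T: a physics-faithful five-spectrum acquisition simulator, the fully
automated post-processing chain, water-referenced absolute quantification,
and the test–retest statistics used to validate such measurements.

## Who this is for

MRS methods developers and neuroimaging researchers who quantify brain
glutamate (Glu, 2.35 ppm) with frequency-selective inversion (FSI)
difference editing. Measuring Glu changes of ≥ 0.5 mM in intervention
studies requires suppressing the two dominant error sources — baseline
distortion and macromolecule (MM) contamination — and an automated,
operator-free processing pipeline. `gluedit` implements that pipeline end
to end and, because in-vivo raw data are rarely shareable, pairs it with a
simulator that generates realistic labeled acquisitions with known ground
truth so every processing stage can be validated quantitatively.

## The method

One scan acquires five blocks sharing one eddy-current state:

| block | preparation |
|---|---|
| `water_ref` | no suppression — the phase/amplitude reference |
| `control1` | water suppressed, FSI mirrored across water (7.05 ppm) |
| `selinv1` | water suppressed, FSI at Glu (2.35 ppm) |
| `control2` | as `control1` plus double-inversion metabolite nulling |
| `selinv2` | as `selinv1` plus double-inversion metabolite nulling |

The FSI pulse is a truncated-Gaussian designed for 50 % inversion
(M<sub>z</sub> → 0) over a 60 Hz band — wide enough for the Glu multiplet
(±7 Hz) plus shim margin. The edited spectrum is

- phantom: `control1 − selinv1`
- in vivo: `(control1 − selinv1) − (control2 − selinv2)`,

where the second pair removes the short-T1 MM background that survives
metabolite nulling and is edited equally in both pairs. Processing is
automated: matched-filter coil combination and Klose eddy-current
correction from the water reference, ~7 Hz exponential apodization, FFT,
and water-derived zero-order phasing. Quantification integrates the edited
spectrum over 2.25–2.45 ppm and converts to millimolar against the fitted
water reference:

C = (A<sub>Glu</sub> / (κ·n<sub>Glu</sub>)) / (A<sub>w</sub> / n<sub>w</sub>) · f<sub>w</sub> · 55 510 mM,

with κ the editing efficiency of the inversion profile (≈ 0.5),
n<sub>Glu</sub> = n<sub>w</sub> = 2 protons, and tissue water content
f<sub>w</sub> = 1.0 (phantom) or 0.8 (brain). Repeatability of repeated
scans is summarized by the one-way random single-measures ICC with its
exact-F 95 % CI, the coefficient of variation, and per-subject absolute
scan differences.

## Worked example

```console
$ gluedit pipeline --mode phantom --glu-mM 9 --seed 1
ground truth:         9.000 mM (seed 1)
mode:                 phantom
editing efficiency:   0.4986
glu band integral:    17.0691
water integral:       212349
band capture:         0.7691
Glu concentration:    8.950 mM
```

A 9 mM phantom is simulated at protocol settings (TR 3 s, TE 21 ms, 4096
points, 6 kHz sweep, 8/32/32 averages), processed and quantified. The
editing efficiency 0.4986 is computed from the designed pulse's Bloch
profile at the Glu multiplet positions; the band capture 0.769 is the
fraction of the (apodized, 22 Hz wide) Lorentzian multiplet area inside
the integration band, which the quantifier divides out. The recovered
8.95 mM is within 0.6 % of truth. The same chain on simulated brain data
(`--mode invivo`) demonstrates MM suppression: quantifying the same data
with only the first difference pair overestimates Glu by ~14 %, the
four-spectrum combination stays within 5 %.

```console
$ gluedit retest        # packaged five-subject scan/rescan table
{
  "mean_mM": 9.569, "sd_mM": 0.632, "cov_percent": 6.60,
  "icc": 0.961, "icc_ci_low": 0.745, "icc_ci_high": 0.996,
  "max_abs_difference_mM": 0.25
}
$ gluedit scantime --preset invivo
468 s (7 min:48 s)
$ gluedit b1cal --s1 1.0 --s2 1.0
reference voltage: 150.00 V
```

Other verbs: `simulate` (write an acquisition bundle), `process`
(bundle → edited spectrum CSV), `quantify` (bundle → concentration report).

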
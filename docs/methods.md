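# Methods

This note records the physical model behind `gluedit`, the defaults and why
they were chosen, the numerical conventions, and what the simulator does and
does not emulate.

## Signal model

A voxel is a set of Lorentzian resonances grouped into water, metabolite and
macromolecule (MM) classes. Each line carries a chemical shift (ppm), an
amplitude in mM-protons (concentration × contributing protons), a Lorentzian
FWHM (Hz), an intrinsic phase, and a T1. The receiver carrier sits on water
(4.7 ppm; 297.2 MHz, the proton frequency at 7 T), so a line at shift δ
evolves at (δ − 4.7)·297.2 Hz in the rotating frame. A block's FID is

s(t) = Σ<sub>lines</sub> w·A·g<sub>c</sub>·e<sup>i(φ+θ<sub>c</sub>)</sup>·e<sup>2πi f t</sup>·e<sup>−π·FWHM·t</sup>·e<sup>iφ<sub>eddy</sub>(t)</sup> + noise,

where w is the block-state weight (below), (g<sub>c</sub>, θ<sub>c</sub>)
the channel sensitivity, and φ<sub>eddy</sub>(t) = Σ aᵢ e<sup>−t/τᵢ</sup> a
multi-exponential eddy-current phase transient shared by all five blocks —
the property the water-reference correction relies on. T2/TE decay is
absorbed into the linewidth and overall amplitude (TE = 21 ms is short, and
no relaxation correction is applied downstream either); there is no J
evolution during TE and no spatial modeling.

The Glu 2.35 ppm multiplet is modeled as a 1:2:1 pseudo-triplet (satellites
at ±7 Hz, total 2 protons). This captures what matters for editing and
integration — the multiplet width the 60 Hz inversion band must cover — at
the cost of not reproducing the true strongly-coupled lineshape; full
density-matrix simulation is out of scope.

## Block states and editing bookkeeping

A line left at longitudinal level M<sub>z</sub> by the selective inversion
contributes the fraction (1 + M<sub>z</sub>)/2 of its equilibrium signal, so
the control-minus-inversion difference retains the inversion depth
(1 − M<sub>z</sub>)/2. At the 50 % design point (M<sub>z</sub> = 0) half the
line survives in the difference: the editing efficiency κ = 0.5. The
quantifier uses κ computed from the actual designed profile at the triplet
positions (≈ 0.499) rather than the hard-coded ideal, keeping acquisition
and quantification consistent under configuration changes. The alternative
reading of "50 % inversion" (M<sub>z</sub> → −0.5) is selectable through
`target_inversion=0.75`; because simulator and quantifier share one
profile, recovered concentrations are invariant to this convention.

The control blocks invert at the mirror frequency 2·4.7 − 2.35 = 7.05 ppm.
Because the Bloch profile of a real symmetric envelope is even in offset,
the water line receives *exactly* the same weight in control and inversion
blocks, so any residual-water perturbation cancels identically in the
difference — this is tested as an exact (1e−10) property. Water suppression
itself is represented by a single amplitude factor 1/140 (the achieved
suppression of the seven-pulse scheme), not Bloch-simulated; its pulse
parameters are protocol metadata only.

The metabolite-nulled pair multiplies metabolite and MM lines by the
double-inversion-recovery residual
M<sub>z</sub>(T1) = 1 − 2e<sup>−TI2/T1</sup> + 2e<sup>−(TI1+TI2)/T1</sup>,
assuming full recovery each TR. At TR = 3 s and T1 ≤ 2 s recovery is only
~78–95 % complete, so real steady-state levels are slightly lower; this is
a known limitation, not modeled, and it cancels to first order between the
control/inversion pair of each difference.

## Pulse design

**FSI pulse.** Truncated-Gaussian envelope (±3σ, 512 segments), integrated
as piecewise-constant rotations without relaxation. The peak amplitude is
calibrated so the on-resonance depth equals the target exactly; bisection on
duration (1–100 ms cap) finds the longest — hence most selective — pulse
whose depth at the band edge (±30 Hz) is still ≥ 90 % of target. For the
default 60 Hz band this yields 10.36 ms and a depth < 0.01 beyond three
bandwidths. A 1 % in-band flatness requirement was considered and rejected:
for a Gaussian envelope it is jointly infeasible with useful selectivity
(verified with fine-step Bloch integration), while the 10 % edge tolerance
keeps the multiplet positions (±7 Hz) within 0.3 % of the design depth.

**Nulling delays.** Minimax optimization of max |M<sub>z</sub>(T1)| over
T1 ∈ [1, 2] s (the reported metabolite range at 7 T), constrained to
TI1 + TI2 ≤ 2.8 s so the preparation fits within TR: coarse 20 ms grid then
Nelder–Mead refinement, ties toward shorter totals. The optimum
(TI1 ≈ 2.13 s, TI2 ≈ 0.59 s) leaves |M<sub>z</sub>| ≤ 0.0247 across the
range — about ten times better than the best single inversion (0.236) —
while MM at T1 = 0.3 s retains M<sub>z</sub> ≈ 0.72. Consequently the
four-spectrum combination attenuates MM by a factor 1/(1 − 0.72) ≈ 3.6
relative to the two-spectrum difference; larger factors would require
shorter MM T1 or longer TI2 than the metabolite minimax permits.

**In-vivo κ correction.** The four-spectrum combination's net Glu weight is
κ·(1 − M<sub>z,DIR</sub>(T1)); the quantifier corrects κ by this factor at
the nominal metabolite T1 (default 1.5 s). The true T1 is unknown in vivo,
but the correction is bounded by the optimizer residual (±2.5 %).

## Processing conventions

* **Averages.** Stored FIDs are accumulated sums (as raw scanner exports
  are); processing divides by the recorded average count so the 8-average
  water block and 32-average suppressed blocks are directly comparable —
  without this the water-referenced concentration would be off 4×.
* **Combination.** Matched filter w<sub>c</sub> ∝ conj(water<sub>c</sub>[0]),
  normalized Σ|w|² = 1, derived once from the water reference and reused for
  all blocks. The method choice is the package's own (the standard
  SNR-optimal option needing only data the protocol already acquires).
* **ECC.** Klose pointwise phase deconvolution by the combined water FID.
  Exact when water dominates; with metabolites present the achievable
  accuracy is bounded by their ~1.6·10⁻⁴ contribution to the water FID's
  instantaneous phase. Below a 10⁻⁸ relative magnitude floor the last valid
  phase is carried forward and flagged. ECC and apodization are pointwise
  multiplications, so their order is immaterial (regression-tested).
* **Transform.** First FID sample halved, FFT scaled by 2·dwell: a line's
  frequency-domain integral (Hz) equals its t = 0 amplitude and the real
  part of a clean line is the absorption Lorentzian. The ppm axis decreases
  with index, carrier at 4.7 ppm. No zero-filling by default; no first-order
  phase (on-resonance acquisition plus ECC leaves none in this model — a
  documented limitation for real data).
* **Phasing.** φ₀ = −arg(∫ water window) of the water reference, applied to
  all blocks; idempotent by construction.

## Quantification

Water area comes from a complex Lorentzian + constant-offset least-squares
fit (analytic area parameter); the Glu number is the trapezoidal band
integral over 2.25–2.45 ppm (closed interval, native grid, no
interpolation), matching the distinct "fitted" vs "integrated" treatment of
the two signals. The band holds only ~77 % of the apodized multiplet's
Lorentzian area (CDF closed form at the fitted water linewidth, which
shares the metabolite linewidth in this model), so the integral is divided
by that capture fraction; without it every concentration would be biased
~23 % low while the water fit retains its full analytic area. In phantom
mode a Lorentzian fit of the edited peak is also reported as a diagnostic.
Relaxation corrections default to 1 (hooks provided).

## Simulator defaults (the study conditions)

| parameter | default | rationale |
|---|---|---|
| protocol | TR 3000 ms, TE 21 ms, 4096 pts, 6000 Hz, 4 dummies, 8/32/32(/32/32) averages | the phantom/in-vivo protocol |
| linewidth | 15 Hz | in-vivo-like shim; phantom shims deliberately mis-set to match |
| phantom series | 6, 9, 12, 15 mM, water fraction 1.0 | the validation series |
| brain Glu | 9.57 mM, water fraction 0.8 | cohort mean; assumed brain water content |
| neighbors | NAA 2.01 ppm (~12 mM), Cr 3.03 ppm (~8 mM) | configurable; no claim of full spectral fidelity |
| MM | 2.30 & 2.05 ppm, 3 mM-protons each, 25–30 Hz, T1 0.3 s | representative short-T1 background under the Glu band |
| Gln 2.44 ppm | off by default | band contamination probe only |
| water suppression | 1/140 | the achieved suppression factor |
| eddy transient | 1.0 rad/5 ms + 0.3 rad/50 ms | representative decaying transients; config, not claims |
| channels | 4 | sufficient to exercise the combination math (a 32-channel array adds nothing to the logic) |
| noise σ | 6.0 per complex sample | edited-spectrum peak SNR ≈ 60 at protocol averages, typical of 7 T edited acquisitions |

Noise is complex white Gaussian added after averaging as σ/√n (equal in
distribution to averaging noisy shots); a seed fixes the acquisition bit
for bit. What the simulator does **not** emulate — and what passing tests
therefore cannot certify on real data: frequency drift and motion between
averages, true coupled-spin lineshapes, baseline from broad resonances
outside the modeled set, chemical-shift displacement, B0/B1 inhomogeneity
across the voxel, and steady-state saturation.

## Statistics

ICC(1,1) from the subjects-as-groups one-way ANOVA,
(MSB − MSW)/(MSB + (k−1)·MSW), with the classical two-sided exact-F CI —
this pair of choices reproduces both printed bounds of the packaged
five-subject table (0.745, 0.996). Mean ± SD and CoV use the sample (n−1)
SD, required to reproduce 0.63 mM from the same ten values. Degenerate
zero-variance tables define ICC = 1 with a collapsed CI. CI calibration is
verified by simulation (93–97 % coverage at ICC 0.9, n = 5, k = 2, 2000
replicates).

## Problem sizes

Tests and the acceptance script run full-size protocols (4096-point FIDs,
four channels, five blocks); the phantom linearity series simulates four
complete acquisitions. The Monte-Carlo components (water-fit bias at 200
seeds, CI coverage at 2000 replicates, SNR comparison at 100 seeds) are
sized to bound the quantities of interest while keeping the whole suite
under a minute.

## Known limitations

* Phantom-mode and in-vivo recoveries inherit a few-percent bias budget:
  band-edge discretization, MM residual (~+3 %), and the nominal-T1 κ
  correction. The in-vivo default conditions land within 5 % of truth.
* The exact scanner nulling delays are not public; the optimizer reproduces
  the design objective, not undisclosed values.
* The editing-efficiency scaling is the physically explicit choice; an
  empirical calibration absorbed into κ would be indistinguishable from it
  given only absolute concentrations.
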
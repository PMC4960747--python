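"""Core domain types and spectral primitives.

Everything downstream (simulation, processing, quantification) shares the
conventions fixed here:

* The receiver carrier sits on the water resonance (``reference_ppm``,
  4.7 ppm by default), so a resonance at chemical shift ``delta`` ppm
  appears at an offset of ``(delta - reference_ppm) * f0_MHz`` Hz in the
  rotating frame (negative for upfield resonances such as Glu at 2.35 ppm).
* The ppm axis of a processed spectrum decreases with array index
  (high-field NMR display convention, water in the middle).
* Amplitudes are carried in "mM-proton" units, i.e. concentration times the
  number of contributing protons, so that water referencing needs no hidden
  scale factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BLOCK_LABELS",
    "PHANTOM_BLOCKS",
    "WATER_MOLARITY_MM",
    "WATER_PROTONS",
    "GLU_PPM",
    "WATER_PPM",
    "AcquisitionParams",
    "ResonanceLine",
    "SpectralSystem",
    "RawFID",
    "AcquisitionSet",
    "ProcessedSpectrum",
    "ppm_axis",
    "ppm_to_offset_hz",
    "offset_hz_to_ppm",
    "lorentzian",
    "phantom_protocol",
    "invivo_protocol",
]

#: The five acquisition blocks of one editing scan, in acquisition order.
BLOCK_LABELS = ("water_ref", "control1", "selinv1", "control2", "selinv2")

#: The subset acquired in phantom mode (no metabolite-nulled pair).
PHANTOM_BLOCKS = ("water_ref", "control1", "selinv1")

#: Proton molarity of pure water (2 * 55.51 M) expressed in mM-protons.
WATER_MOLARITY_MM = 55_510.0
WATER_PROTONS = 2

GLU_PPM = 2.35
WATER_PPM = 4.7


@dataclass(frozen=True)
class AcquisitionParams:
    """Protocol-level acquisition parameters for one scan.

    Parameters
    ----------
    tr_ms, te_ms
        Repetition and echo time in milliseconds.
    n_points
        Complex samples per FID.
    sweep_width_hz
        Receiver bandwidth; the dwell time is its reciprocal.
    dummy_scans
        Steady-state preparation shots per block (not stored).
    averages
        Mapping from block label to the number of averages acquired.
    spectrometer_freq_mhz
        Proton Larmor frequency; 297.2 MHz corresponds to 7 T.
    reference_ppm
        Chemical shift assigned to the carrier (water on resonance).
    """

    tr_ms: float
    te_ms: float
    n_points: int
    sweep_width_hz: float
    dummy_scans: int
    averages: Mapping[str, int]
    spectrometer_freq_mhz: float = 297.2
    reference_ppm: float = WATER_PPM

    def __post_init__(self) -> None:
        if self.n_points <= 0:
            raise ValueError("n_points must be positive")
        if self.sweep_width_hz <= 0:
            raise ValueError("sweep_width_hz must be positive")
        if self.spectrometer_freq_mhz <= 0:
            raise ValueError("spectrometer_freq_mhz must be positive")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if self.dummy_scans < 0:
            raise ValueError("dummy_scans must be non-negative")
        for label, n in dict(self.averages).items():
            if label not in BLOCK_LABELS:
                raise ValueError(f"unknown block label {label!r}")
            if n < 0:
                raise ValueError(f"negative average count for {label!r}")
        object.__setattr__(self, "averages", dict(self.averages))

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.sweep_width_hz


def phantom_protocol(**overrides) -> AcquisitionParams:
    """Three-block phantom protocol: TR 3 s, TE 21 ms, 4096 points,
    6 kHz sweep width, 4 dummies, 8/32/32 averages."""
    kw = dict(
        tr_ms=3000.0,
        te_ms=21.0,
        n_points=4096,
        sweep_width_hz=6000.0,
        dummy_scans=4,
        averages={"water_ref": 8, "control1": 32, "selinv1": 32},
    )
    kw.update(overrides)
    return AcquisitionParams(**kw)


def invivo_protocol(**overrides) -> AcquisitionParams:
    """Five-block in-vivo protocol: as the phantom protocol plus the
    metabolite-nulled control/inversion pair at 32 averages each."""
    kw = dict(
        tr_ms=3000.0,
        te_ms=21.0,
        n_points=4096,
        sweep_width_hz=6000.0,
        dummy_scans=4,
        averages={
            "water_ref": 8,
            "control1": 32,
            "selinv1": 32,
            "control2": 32,
            "selinv2": 32,
        },
    )
    kw.update(overrides)
    return AcquisitionParams(**kw)


@dataclass(frozen=True)
class ResonanceLine:
    """One Lorentzian resonance in the voxel.

    ``proton_amplitude`` is concentration times proton count (mM-protons);
    ``t1_s`` drives the double-inversion-recovery weighting of the
    metabolite-nulled blocks.
    """

    center_ppm: float
    proton_amplitude: float
    fwhm_hz: float
    t1_s: float
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.fwhm_hz <= 0:
            raise ValueError("fwhm_hz must be positive")
        if self.t1_s <= 0:
            raise ValueError("t1_s must be positive")
        if self.proton_amplitude < 0:
            raise ValueError("proton_amplitude must be non-negative")


@dataclass(frozen=True)
class SpectralSystem:
    """Ground-truth voxel content: water, metabolite and macromolecule lines.

    The water line amplitude follows the bookkeeping
    ``2 * 55,510 mM * water_fraction`` (two protons per molecule).
    """

    water: tuple[ResonanceLine, ...]
    metabolites: tuple[ResonanceLine, ...]
    macromolecules: tuple[ResonanceLine, ...]
    water_fraction: float
    glu_concentration_mM: float

    def __post_init__(self) -> None:
        if not 0 < self.water_fraction <= 1:
            raise ValueError("water_fraction must lie in (0, 1]")
        if self.glu_concentration_mM < 0:
            raise ValueError("glu_concentration_mM must be non-negative")
        object.__setattr__(self, "water", tuple(self.water))
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        object.__setattr__(self, "macromolecules", tuple(self.macromolecules))

    def lines_by_class(self) -> dict[str, tuple[ResonanceLine, ...]]:
        return {
            "water": self.water,
            "metabolite": self.metabolites,
            "macromolecule": self.macromolecules,
        }


@dataclass
class RawFID:
    """A time-domain complex FID from one receiver channel.

    ``samples`` holds the accumulated sum over ``n_averages`` shots (as raw
    scanner data does); dividing by ``n_averages`` recovers the mean shot.
    """

    samples: np.ndarray
    dwell_s: float
    n_averages: int
    channel_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.dwell_s <= 0:
            raise ValueError("dwell_s must be positive")
        if self.n_averages < 0:
            raise ValueError("n_averages must be non-negative")

    def copy_with(self, samples: np.ndarray) -> "RawFID":
        return RawFID(
            samples=np.asarray(samples, dtype=np.complex128),
            dwell_s=self.dwell_s,
            n_averages=self.n_averages,
            channel_index=self.channel_index,
        )


@dataclass
class AcquisitionSet:
    """The labeled multi-channel raw FIDs of one scan."""

    params: AcquisitionParams
    blocks: dict[str, list[RawFID]]

    def __post_init__(self) -> None:
        n_channels = None
        for label, fids in self.blocks.items():
            if label not in BLOCK_LABELS:
                raise ValueError(f"unknown block label {label!r}")
            if n_channels is None:
                n_channels = len(fids)
            elif len(fids) != n_channels:
                raise ValueError("all blocks must share the channel count")
            for fid in fids:
                if len(fid.samples) != self.params.n_points:
                    raise ValueError(
                        f"block {label!r}: FID length {len(fid.samples)} "
                        f"!= n_points {self.params.n_points}"
                    )

    @property
    def n_channels(self) -> int:
        return len(next(iter(self.blocks.values())))

    def require_blocks(self, labels: Sequence[str]) -> None:
        missing = [lab for lab in labels if lab not in self.blocks]
        if missing:
            raise ValueError(f"missing acquisition block(s): {missing}")


@dataclass
class ProcessedSpectrum:
    """A frequency-domain complex spectrum on a decreasing ppm axis."""

    values: np.ndarray
    ppm_axis: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=np.float64)
        if self.values.shape != self.ppm_axis.shape:
            raise ValueError("values and ppm_axis must have the same length")
        d = np.diff(self.ppm_axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm_axis must be strictly monotonic")

    def with_values(self, values: np.ndarray, step: dict | None = None) -> "ProcessedSpectrum":
        prov = list(self.provenance)
        if step is not None:
            prov.append(step)
        return ProcessedSpectrum(values=values, ppm_axis=self.ppm_axis, provenance=prov)


def ppm_to_offset_hz(ppm, params: AcquisitionParams):
    """Chemical shift (ppm) -> rotating-frame offset (Hz) from the carrier."""
    return (np.asarray(ppm, dtype=float) - params.reference_ppm) * params.spectrometer_freq_mhz


def offset_hz_to_ppm(offset_hz, params: AcquisitionParams):
    """Rotating-frame offset (Hz) -> chemical shift (ppm)."""
    return params.reference_ppm + np.asarray(offset_hz, dtype=float) / params.spectrometer_freq_mhz


def ppm_axis(params: AcquisitionParams) -> np.ndarray:
    """ppm coordinate per spectral point, decreasing with index.

    Matches ``np.fft.fftshift(np.fft.fftfreq(n, dwell))`` reversed, mapped to
    ppm through the carrier; spans ``sweep_width_hz / spectrometer_freq_mhz``
    ppm centered on ``reference_ppm``.
    """
    freqs = np.fft.fftshift(np.fft.fftfreq(params.n_points, d=params.dwell_s))
    return offset_hz_to_ppm(freqs[::-1], params)


def lorentzian(f, area, f0, fwhm, phase=0.0):
    """Complex Lorentzian spectral density versus frequency ``f`` (Hz).

    The real part at ``phase=0`` is the absorption lineshape: it integrates
    over all frequency to ``area`` and peaks at ``2 * area / (pi * fwhm)``.
    The imaginary part is the corresponding dispersion component.
    """
    if np.any(np.asarray(fwhm) <= 0):
        raise ValueError("fwhm must be positive")
    hw = fwhm / 2.0
    x = (np.asarray(f, dtype=float) - f0) / hw
    return area * np.exp(1j * phase) / (np.pi * hw) / (1.0 + 1j * x)
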
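"""On-disk acquisition bundles and packaged reference data.

A bundle is a directory holding a JSON manifest (protocol parameters, block
labels, channel count, simulation seed and ground truth when simulated) and
one FID table per block and channel.  The default dialect stores each FID
as a two-column CSV of real and imaginary parts printed with 17 significant
digits, which round-trips IEEE doubles exactly while remaining diff-able; a
``binary`` dialect (little-endian float64 pairs) is available for bulk use.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .repeatability import RetestTable
from .spectral_model import (
    AcquisitionParams,
    AcquisitionSet,
    RawFID,
)

__all__ = [
    "write_bundle",
    "read_bundle",
    "load_retest_table",
    "generate_fixtures",
]

MANIFEST_NAME = "manifest.json"


def _fid_filename(label: str, channel: int, dialect: str) -> str:
    ext = "csv" if dialect == "text" else "bin"
    return f"{label}_ch{channel:02d}.{ext}"


def write_bundle(
    acq: AcquisitionSet,
    path,
    dialect: str = "text",
    extra_manifest: dict | None = None,
) -> Path:
    """Serialize an acquisition to a bundle directory (created if needed)."""
    if dialect not in ("text", "binary"):
        raise ValueError("dialect must be 'text' or 'binary'")
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    p = acq.params
    manifest = {
        "format": "gluedit-bundle",
        "version": 1,
        "dialect": dialect,
        "params": {
            "tr_ms": p.tr_ms,
            "te_ms": p.te_ms,
            "n_points": p.n_points,
            "sweep_width_hz": p.sweep_width_hz,
            "dummy_scans": p.dummy_scans,
            "averages": dict(p.averages),
            "spectrometer_freq_mhz": p.spectrometer_freq_mhz,
            "reference_ppm": p.reference_ppm,
        },
        "blocks": {},
        "n_channels": acq.n_channels,
    }
    if extra_manifest:
        manifest.update(extra_manifest)

    for label, fids in acq.blocks.items():
        files = []
        for fid in fids:
            name = _fid_filename(label, fid.channel_index, dialect)
            files.append(
                {
                    "file": name,
                    "channel": fid.channel_index,
                    "n_averages": fid.n_averages,
                }
            )
            if dialect == "text":
                with open(root / name, "w") as fh:
                    fh.write("real,imag\n")
                    for z in fid.samples:
                        fh.write(f"{z.real:.17g},{z.imag:.17g}\n")
            else:
                np.ascontiguousarray(
                    np.column_stack([fid.samples.real, fid.samples.imag])
                ).astype("<f8").tofile(root / name)
        manifest["blocks"][label] = files

    with open(root / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return root


def read_bundle(path) -> AcquisitionSet:
    """Load a bundle directory back into an :class:`AcquisitionSet`.

    Raises ``ValueError`` naming the offending field or block on malformed
    manifests, missing files or length mismatches.
    """
    root = Path(path)
    mpath = root / MANIFEST_NAME
    if not mpath.exists():
        raise ValueError(f"no {MANIFEST_NAME} in {root}")
    with open(mpath) as fh:
        manifest = json.load(fh)

    for key in ("dialect", "params", "blocks"):
        if key not in manifest:
            raise ValueError(f"manifest missing field {key!r}")
    dialect = manifest["dialect"]
    try:
        params = AcquisitionParams(**manifest["params"])
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid manifest params: {exc}") from exc

    blocks: dict[str, list[RawFID]] = {}
    for label, files in manifest["blocks"].items():
        fids = []
        for entry in files:
            fpath = root / entry["file"]
            if not fpath.exists():
                raise ValueError(f"block {label!r}: missing FID file {entry['file']}")
            if dialect == "text":
                df = pd.read_csv(fpath, dtype=float, float_precision="round_trip")
                samples = df["real"].to_numpy() + 1j * df["imag"].to_numpy()
            else:
                raw = np.fromfile(fpath, dtype="<f8").reshape(-1, 2)
                samples = raw[:, 0] + 1j * raw[:, 1]
            if len(samples) != params.n_points:
                raise ValueError(
                    f"block {label!r} file {entry['file']}: {len(samples)} rows "
                    f"!= n_points {params.n_points}"
                )
            fids.append(
                RawFID(
                    samples=samples,
                    dwell_s=params.dwell_s,
                    n_averages=int(entry["n_averages"]),
                    channel_index=int(entry["channel"]),
                )
            )
        blocks[label] = fids
    return AcquisitionSet(params=params, blocks=blocks)


def load_retest_table() -> RetestTable:
    """The packaged five-subject scan/rescan occipital-cortex Glu table (mM)."""
    with resources.files("gluedit.data").joinpath("retest_occ.csv").open() as fh:
        df = pd.read_csv(fh)
    return RetestTable.from_frame(df, subject_col="subject")


def generate_fixtures(out_dir, seed: int = 0, noise_sigma: float | None = None) -> dict:
    """Regenerate the package's reference inputs under ``out_dir``.

    Writes the scan/rescan CSV, seeded phantom bundles at 6/9/12/15 mM, and
    one brain bundle; every bundle manifest records the seed and ground
    truth so the data are reproducible from this function alone.
    """
    from .pulse_design import design_fsi_pulse, optimize_double_ir_delays
    from .simulator import (
        default_artifacts,
        make_brain_system,
        make_phantom_system,
        simulate_acquisition,
    )
    from .spectral_model import invivo_protocol, phantom_protocol

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with resources.files("gluedit.data").joinpath("retest_occ.csv").open() as fh:
        (out / "retest_occ.csv").write_text(fh.read())

    fsi = design_fsi_pulse()
    ir = optimize_double_ir_delays()
    written = {"retest_csv": str(out / "retest_occ.csv"), "bundles": []}

    kwargs = {} if noise_sigma is None else {"noise_sigma": noise_sigma}
    for i, conc in enumerate((6.0, 9.0, 12.0, 15.0)):
        artifacts = default_artifacts(seed=seed + i, **kwargs)
        acq = simulate_acquisition(
            make_phantom_system(conc), phantom_protocol(), artifacts, fsi, ir,
            mode="phantom",
        )
        path = write_bundle(
            acq,
            out / f"phantom_{conc:g}mM",
            extra_manifest={"seed": seed + i, "ground_truth_glu_mM": conc,
                            "mode": "phantom"},
        )
        written["bundles"].append(str(path))

    artifacts = default_artifacts(seed=seed + 100, **kwargs)
    acq = simulate_acquisition(
        make_brain_system(), invivo_protocol(), artifacts, fsi, ir, mode="invivo"
    )
    path = write_bundle(
        acq,
        out / "brain_9.57mM",
        extra_manifest={"seed": seed + 100, "ground_truth_glu_mM": 9.57,
                        "mode": "invivo"},
    )
    written["bundles"].append(str(path))
    return written
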
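"""Reading and writing the package's on-disk formats.

Volumes and sequences are stored as TIFF stacks with a JSON sidecar
(``meta.json``) declaring voxel size, channel layout, times, and — for
synthetic data — the full ground-truth record.  Profiles, width series,
flux series and correlation curves are CSV; meshes are PLY or OBJ via
trimesh.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh

from .core import (
    CorrelationCurve,
    FluxSeries,
    GroundTruth,
    Profile,
    Volume,
    VolumeSequence,
    WidthSeries,
)

__all__ = [
    "save_volume",
    "load_volume",
    "save_sequence",
    "load_sequence",
    "save_profile",
    "load_profile",
    "save_flux_series",
    "save_width_series",
    "save_correlation_curve",
    "save_mesh",
    "load_mesh",
]


def save_volume(path, vol: Volume, ground_truth: GroundTruth | None = None) -> None:
    """Write one channel as TIFF plus a JSON sidecar with calibration."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, vol.data.astype(np.float32),
                     photometric="minisblack")
    meta = {
        "voxel_size_um": list(vol.voxel_size),
        "channel": vol.channel,
        "time_min": vol.time,
    }
    if ground_truth is not None:
        meta["ground_truth"] = json.loads(ground_truth.to_json())
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_volume(path) -> Volume:
    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return Volume(
        data=data,
        voxel_size=tuple(meta["voxel_size_um"]),
        channel=meta.get("channel", "microtubule"),
        time=meta.get("time_min"),
    )


def save_sequence(
    outdir, seq: VolumeSequence, ground_truth: GroundTruth | None = None
) -> None:
    """One TIFF per channel per timepoint plus a ``meta.json`` sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, (mt, k4) in enumerate(seq):
        tifffile.imwrite(outdir / f"t{i:03d}_microtubule.tif",
                         mt.data.astype(np.float32),
                         photometric="minisblack")
        tifffile.imwrite(outdir / f"t{i:03d}_kinesin.tif",
                         k4.data.astype(np.float32),
                         photometric="minisblack")
    meta = {
        "n_frames": len(seq),
        "times_min": seq.times.tolist(),
        "voxel_size_um": list(seq.voxel_size),
        "layout": "one file per channel per timepoint (t{i}_{channel}.tif)",
    }
    if ground_truth is not None:
        meta["ground_truth"] = json.loads(ground_truth.to_json())
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))


def load_sequence(outdir) -> VolumeSequence:
    outdir = Path(outdir)
    meta = json.loads((outdir / "meta.json").read_text())
    vsize = tuple(meta["voxel_size_um"])
    times = meta["times_min"]
    frames = []
    for i, t in enumerate(times):
        mt = Volume(tifffile.imread(outdir / f"t{i:03d}_microtubule.tif"),
                    vsize, channel="microtubule", time=t)
        k4 = Volume(tifffile.imread(outdir / f"t{i:03d}_kinesin.tif"),
                    vsize, channel="kinesin", time=t)
        frames.append((mt, k4))
    return VolumeSequence(frames=frames, times=np.asarray(times))


def save_profile(path, profile: Profile) -> None:
    df = pd.DataFrame({"coordinate_um": profile.coordinate,
                       "intensity": profile.intensity})
    if profile.stderr is not None:
        df["stderr"] = profile.stderr
    df.to_csv(path, index=False)


def load_profile(path, kind: str = "radial") -> Profile:
    df = pd.read_csv(path)
    return Profile(
        coordinate=df["coordinate_um"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        stderr=df["stderr"].to_numpy() if "stderr" in df else None,
        kind=kind,
    )


def save_flux_series(path, fs: FluxSeries) -> None:
    cols = {
        "time_min": fs.times, "A_um2": fs.area, "V_um3": fs.volume,
        "rhoS": fs.rho_s, "rhoV": fs.rho_v,
    }
    for name, attr in (("A_drhoS_dt", "term_a_drhos"),
                       ("rhoS_dA_dt", "term_rhos_da"),
                       ("flux", "flux"), ("residual", "residual")):
        val = getattr(fs, attr)
        if val is not None:
            cols[name] = val
    pd.DataFrame(cols).to_csv(path, index=False)


def save_width_series(path, ws: WidthSeries) -> None:
    pd.DataFrame({
        "time_min": ws.times, "width_um": ws.width,
        "width_normalized": ws.normalized, "valid": ws.valid,
    }).to_csv(path, index=False)


def save_correlation_curve(path, curve: CorrelationCurve) -> None:
    pd.DataFrame({
        "lambda_um": curve.lam, "C": curve.c, "n_pairs": curve.n_pairs,
    }).to_csv(path, index=False)


def save_mesh(path, mesh: trimesh.Trimesh) -> None:
    """PLY or OBJ by extension."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    mesh.export(path)


def load_mesh(path) -> trimesh.Trimesh:
    return trimesh.load_mesh(path)
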
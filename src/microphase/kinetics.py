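"""Contraction kinetics and aster-core morphometrics.

Width of a contracting slab network is measured per frame as the extent
over which the transverse intensity profile exceeds a relative level
(default 0.5: full width at half maximum), averaged over several
non-overlapping strips along the long axis.  The normalized width
Wn(t) = W(t)/W(0) is fitted by the exponential relaxation

    Wn(t) = Wn_inf + exp(-(t - t0)/tau) * (1 - Wn_inf),

with time offset t0, final width Wn_inf and contraction timescale tau.

Aster cores are segmented from the kinesin channel (Otsu threshold,
26-connected components) and characterised by centroid, volume and the
eigenvalues of the intensity-weighted second-moment tensor; the
major/minor moment ratio tracks elongation into wormlike shapes.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage
import scipy.optimize
import skimage.filters

from .core import AsterRecord, ContractionFit, Volume, VolumeSequence, WidthSeries
from .synthetic import contraction_model

__all__ = [
    "measure_width",
    "measure_width_series",
    "fit_contraction",
    "segment_cores",
    "aster_series",
]


def _profile_width(coord: np.ndarray, prof: np.ndarray, level: float) -> float:
    """Extent over which ``prof`` exceeds ``level * max``, with linear
    sub-bin interpolation of the two outermost crossings.  NaN if the
    profile never exceeds the level."""
    peak = prof.max()
    if peak <= 0:
        return np.nan
    thr = level * peak
    above = prof > thr
    if not above.any():
        return np.nan
    i0 = int(np.argmax(above))
    i1 = len(prof) - 1 - int(np.argmax(above[::-1]))
    lo = coord[i0]
    if i0 > 0:
        lo = np.interp(thr, [prof[i0 - 1], prof[i0]], [coord[i0 - 1], coord[i0]])
    hi = coord[i1]
    if i1 < len(prof) - 1:
        hi = np.interp(thr, [prof[i1 + 1], prof[i1]], [coord[i1 + 1], coord[i1]])
    return float(hi - lo)


def measure_width(
    vol: Volume,
    axis: int = 2,
    level: float = 0.5,
    n_positions: int = 5,
    long_axis: int | None = None,
) -> float:
    """Width of the network in one frame.

    The intensity is integrated over all axes except ``axis`` (the
    transverse/short axis) within each of ``n_positions`` non-overlapping
    strips along ``long_axis``; the per-strip widths at the relative
    ``level`` are averaged.  Invariant to global intensity scaling.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    data = vol.data
    if long_axis is None:
        cand = [a for a in range(vol.ndim) if a != axis]
        long_axis = max(cand, key=lambda a: data.shape[a] * vol.voxel_size[a])
    if long_axis == axis:
        raise ValueError("long_axis must differ from the width axis")

    coord = (np.arange(data.shape[axis]) + 0.5) * vol.voxel_size[axis]
    strips = np.array_split(np.arange(data.shape[long_axis]), n_positions)
    widths = []
    for s in strips:
        if s.size == 0:
            continue
        sub = np.take(data, s, axis=long_axis)
        prof = sub
        for a in sorted([a for a in range(vol.ndim) if a != axis], reverse=True):
            prof = prof.sum(axis=a)
        widths.append(_profile_width(coord, prof, level))
    widths = np.asarray(widths, dtype=float)
    good = np.isfinite(widths)
    return float(widths[good].mean()) if good.any() else np.nan


def measure_width_series(
    seq: VolumeSequence,
    axis: int = 2,
    level: float = 0.5,
    n_positions: int = 5,
    channel: str = "microtubule",
) -> WidthSeries:
    """Per-frame network width along ``axis``.

    Frames whose profile never exceeds the level are flagged invalid
    (NaN width) rather than dropped, preserving series length.
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    pick = 0 if channel == "microtubule" else 1
    widths = np.array(
        [measure_width(frame[pick], axis=axis, level=level,
                       n_positions=n_positions) for frame in seq]
    )
    return WidthSeries(times=seq.times.copy(), width=widths)


def fit_contraction(ws: WidthSeries) -> ContractionFit:
    """Nonlinear least-squares fit of the exponential contraction law.

    Initialization: Wn_inf from the series minimum, t0 at the first
    frame, tau from the time to reach halfway between 1 and Wn_inf.
    A series that never contracts (relative width range < 2%) is flagged
    degenerate and its tau is unreliable.
    """
    good = ws.valid
    t = ws.times[good]
    wn = ws.normalized[good]
    if t.size < 5:
        raise ValueError("need at least 5 valid time points")

    wn_range = float(wn.max() - wn.min())
    degenerate = wn_range < 0.02

    wn_inf0 = max(float(wn.min()), 1e-3)
    half = (1.0 + wn_inf0) / 2.0
    below = np.flatnonzero(wn <= half)
    tau0 = float(t[below[0]] - t[0]) if below.size else float(t[-1] - t[0])
    tau0 = max(tau0, float(np.diff(t).min()))
    p0 = (tau0, float(t[0]), wn_inf0)

    try:
        popt, _ = scipy.optimize.curve_fit(
            contraction_model, t, wn, p0=p0,
            bounds=([1e-6, t[0] - 10 * (t[-1] - t[0]), 1e-9],
                    [np.inf, t[-1], 1.0]),
            maxfev=20000,
        )
        converged = True
    except RuntimeError:
        popt = p0
        converged = False
    tau, t0, wn_inf = (float(v) for v in popt)
    resid = wn - contraction_model(t, tau, t0, wn_inf)
    return ContractionFit(
        tau=tau, t0=t0, wn_inf=wn_inf,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=converged, degenerate=degenerate,
    )


def segment_cores(
    k4: Volume,
    min_volume: float = 1.0,
    moment_ratio_sqrt: bool = False,
) -> list[AsterRecord]:
    """Segment kinesin-rich aster cores and measure their 3D moments.

    Otsu threshold on the nonzero voxels, 26-connected components,
    components smaller than ``min_volume`` (um^3) dropped.  Per
    component: intensity-weighted centroid, volume (voxel count times
    voxel volume) and the eigenvalues of the intensity-weighted
    second-moment (covariance) tensor in physical um^2, sorted
    descending.  ``moment_ratio`` is major/minor eigenvalue; with
    ``moment_ratio_sqrt`` the ratio of their square roots (an aspect
    ratio) is reported instead.
    """
    data = k4.data
    nz = data[data > 0]
    if nz.size == 0:
        return []
    if nz.max() == nz.min():  # binary input: nothing to threshold
        mask = data > 0
    else:
        mask = data >= skimage.filters.threshold_otsu(nz)
    structure = np.ones((3,) * k4.ndim, dtype=bool)  # 26-connectivity in 3D
    labels, n = scipy.ndimage.label(mask, structure=structure)
    if n == 0:
        return []

    vsize = np.asarray(k4.voxel_size)
    voxel_volume = float(np.prod(vsize))
    records = []
    for lab in range(1, n + 1):
        sel = labels == lab
        volume = float(sel.sum()) * voxel_volume
        if volume < min_volume:
            continue
        idx = np.nonzero(sel)
        pts = (np.stack(idx, axis=1) + 0.5) * vsize[None, :]
        w = data[sel]
        w = w / w.sum()
        centroid = (pts * w[:, None]).sum(axis=0)
        d = pts - centroid[None, :]
        cov = (d[:, :, None] * d[:, None, :] * w[:, None, None]).sum(axis=0)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        evals = np.maximum(evals, 0.0)
        minor = max(evals[-1], 1e-12)
        ratio = evals[0] / minor
        if moment_ratio_sqrt:
            ratio = float(np.sqrt(ratio))
        records.append(
            AsterRecord(label=lab, centroid=centroid, volume=volume,
                        moments=evals, moment_ratio=float(ratio))
        )
    return records


def aster_series(
    seq: VolumeSequence,
    min_volume: float = 1.0,
    moment_ratio_sqrt: bool = False,
) -> dict:
    """Per-frame mean aster volume and mean moment ratio with SDs.

    Asters are re-segmented independently per frame (no identity
    tracking); frames with no asters contribute NaNs so series length is
    preserved.
    """
    out = {k: [] for k in
           ("times", "mean_volume", "sd_volume", "mean_moment_ratio",
            "sd_moment_ratio", "n_asters")}
    for t, (mt, k4) in zip(seq.times, seq):
        recs = segment_cores(k4, min_volume=min_volume,
                             moment_ratio_sqrt=moment_ratio_sqrt)
        out["times"].append(float(t))
        out["n_asters"].append(len(recs))
        if recs:
            vols = np.array([r.volume for r in recs])
            ratios = np.array([r.moment_ratio for r in recs])
            out["mean_volume"].append(float(vols.mean()))
            out["sd_volume"].append(float(vols.std(ddof=0)))
            out["mean_moment_ratio"].append(float(ratios.mean()))
            out["sd_moment_ratio"].append(float(ratios.std(ddof=0)))
        else:
            for k in ("mean_volume", "sd_volume", "mean_moment_ratio",
                      "sd_moment_ratio"):
                out[k].append(np.nan)
    return {k: np.asarray(v) for k, v in out.items()}
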
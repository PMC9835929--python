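"""Seeded synthetic-data generators with known ground truth.

Each generator emulates one imaging regime of the microtubule/kinesin-4
system — tip-anchored radial asters, flat motor bilayers, exponentially
contracting slab networks, roughening condensates with a prescribed
interior-to-surface mass flux, and 2D filament textures with a target
nematic order parameter — so that every downstream analysis stage can be
validated against constructed truth without any external data.

All generators are pure functions of their parameters plus a single
integer seed: the same call reproduces the dataset bit-identically.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage
import trimesh
from scipy.special import sph_harm_y

from .core import GroundTruth, LengthDistribution, Volume, VolumeSequence

__all__ = [
    "fixed_length",
    "rasterize_segments",
    "make_aster_volume",
    "make_bilayer_volume",
    "make_contracting_sequence",
    "make_roughening_sequence",
    "make_aligned_field",
    "make_sphere_mesh",
]

#: sampling step along a segment, as a fraction of the smallest voxel edge
_RASTER_STEP_FRACTION = 0.25


def fixed_length(length: float) -> LengthDistribution:
    """A numerically degenerate length law: (almost) all mass at `length`."""
    return LengthDistribution(log_mu=float(np.log(length)), log_sigma=1e-9)


# ---------------------------------------------------------------------------
# anti-aliased segment rasterization
# ---------------------------------------------------------------------------

def rasterize_segments(
    starts: np.ndarray,
    ends: np.ndarray,
    shape: tuple[int, ...],
    voxel_size: tuple[float, ...],
) -> np.ndarray:
    """Deposit line segments onto a grid by anti-aliased line integration.

    Each segment is sampled at sub-voxel spacing and every sample point
    deposits an intensity equal to the arc length it represents, spread
    over the surrounding voxels with multilinear weights.  The total
    deposited intensity of a fully contained segment therefore equals its
    physical length (constant intensity per unit filament length), and
    profiles are robust to the grid resolution.

    Parameters
    ----------
    starts, ends:
        ``(n, d)`` arrays of segment endpoints in physical um, ordered
        like the grid axes.
    shape, voxel_size:
        Target grid shape and um-per-voxel calibration.

    Returns
    -------
    Intensity grid of the requested shape.
    """
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    ends = np.atleast_2d(np.asarray(ends, dtype=float))
    ndim = len(shape)
    if starts.shape != ends.shape or starts.shape[1] != ndim:
        raise ValueError("endpoint arrays must be (n, ndim)")
    vsize = np.asarray(voxel_size, dtype=float)
    grid = np.zeros(shape, dtype=float)

    step = _RASTER_STEP_FRACTION * vsize.min()
    lengths = np.linalg.norm(ends - starts, axis=1)
    n_samples = np.maximum(1, np.ceil(lengths / step).astype(int))

    pts_list = []
    w_list = []
    for s, e, L, n in zip(starts, ends, lengths, n_samples):
        # midpoint sampling: n equal sub-segments, one sample each
        t = (np.arange(n) + 0.5) / n
        pts_list.append(s[None, :] + t[:, None] * (e - s)[None, :])
        w_list.append(np.full(n, L / n if L > 0 else 1.0))
    pts = np.concatenate(pts_list, axis=0)
    weights = np.concatenate(w_list)

    # continuous voxel-index coordinates (voxel centre i sits at (i+0.5)*v)
    idx = pts / vsize[None, :] - 0.5
    base = np.floor(idx).astype(int)
    frac = idx - base

    shape_arr = np.asarray(shape)
    for corner in range(2**ndim):
        offs = np.array([(corner >> k) & 1 for k in range(ndim)])
        voxel = base + offs[None, :]
        w = weights.copy()
        for k in range(ndim):
            w = w * np.where(offs[k], frac[:, k], 1.0 - frac[:, k])
        inside = np.all((voxel >= 0) & (voxel < shape_arr[None, :]), axis=1)
        np.add.at(grid, tuple(voxel[inside].T), w[inside])
    return grid


def _apply_psf_and_noise(
    data: np.ndarray,
    voxel_size: tuple[float, ...],
    psf_sigma: float,
    noise_level: float,
    rng: np.random.Generator,
    poisson: bool = False,
    photons_per_unit: float = 100.0,
) -> np.ndarray:
    """Gaussian PSF blur (isotropic in physical um) + camera noise.

    Noise model: optional Poisson photon noise followed by Gaussian read
    noise with standard deviation ``noise_level`` times the signal peak.
    Negative excursions are clipped at zero.
    """
    out = data
    if psf_sigma > 0:
        sigma_vox = [psf_sigma / v for v in voxel_size]
        out = scipy.ndimage.gaussian_filter(out, sigma=sigma_vox)
    if poisson:
        out = rng.poisson(np.maximum(out, 0) * photons_per_unit) / photons_per_unit
    if noise_level > 0:
        peak = out.max() if out.max() > 0 else 1.0
        out = out + rng.normal(0.0, noise_level * peak, size=out.shape)
    return np.maximum(out, 0.0)


def _gaussian_blob(
    shape: tuple[int, ...],
    voxel_size: tuple[float, ...],
    center: np.ndarray,
    sigma: float,
    total: float,
) -> np.ndarray:
    """Analytic isotropic Gaussian with given integrated intensity."""
    coords = [(np.arange(s) + 0.5) * v for s, v in zip(shape, voxel_size)]
    sq = 0.0
    for k, c in enumerate(coords):
        sl = [None] * len(shape)
        sl[k] = slice(None)
        sq = sq + ((c - center[k]) ** 2)[tuple(sl)]
    sigma = max(sigma, 1e-6)
    g = np.exp(-sq / (2 * sigma**2))
    s = g.sum()
    return g * (total / s) if s > 0 else g


# ---------------------------------------------------------------------------
# asters
# ---------------------------------------------------------------------------

def make_aster_volume(
    n_filaments: int,
    core_sigma: float,
    length_law: LengthDistribution,
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size: tuple[float, float, float] | float = 0.5,
    psf_sigma: float = 0.2,
    noise_level: float = 0.0,
    seed: int = 0,
    poisson: bool = False,
) -> tuple[Volume, Volume, GroundTruth]:
    """Synthesize a radial aster: a compact kinesin core with tip-anchored
    microtubules pointing radially outward.

    The kinesin channel is a Gaussian core of width ``core_sigma`` at the
    grid centre.  Microtubule tips (anchor points) are drawn from the same
    Gaussian; each filament extends radially outward from the core centre
    with a length drawn from ``length_law`` and deposits constant
    intensity per unit length.

    Returns ``(microtubule, kinesin, ground_truth)``.
    """
    if n_filaments < 1:
        raise ValueError("n_filaments must be >= 1")
    if core_sigma < 0:
        raise ValueError("core_sigma must be >= 0")
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * 3
    voxel_size = tuple(float(v) for v in voxel_size)
    extent = np.array([s * v for s, v in zip(shape, voxel_size)])
    center = extent / 2.0

    l99 = float(length_law.ppf(0.99))
    required = 2 * (3 * core_sigma + l99 + 3 * psf_sigma)
    if np.any(extent < required):
        raise ValueError(
            f"grid extent {tuple(np.round(extent, 2))} um too small for aster; "
            f"need >= {required:.1f} um per axis "
            f"(2 x [3*core_sigma + 99th-percentile length + 3*psf_sigma])"
        )

    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, max(core_sigma, 1e-12), size=(n_filaments, 3))
    radii = np.linalg.norm(offsets, axis=1)
    dirs = np.where(
        radii[:, None] > 1e-9,
        offsets / np.maximum(radii[:, None], 1e-9),
        _random_unit_vectors(n_filaments, rng),
    )
    lengths = length_law.sample(n_filaments, rng)
    starts = center[None, :] + offsets
    ends = starts + dirs * lengths[:, None]

    mt = rasterize_segments(starts, ends, shape, voxel_size)
    mt = _apply_psf_and_noise(mt, voxel_size, psf_sigma, noise_level, rng, poisson)

    k4 = _gaussian_blob(shape, voxel_size, center, core_sigma, total=float(n_filaments))
    k4 = _apply_psf_and_noise(k4, voxel_size, psf_sigma, noise_level, rng, poisson)

    gt = GroundTruth(
        generator="make_aster_volume",
        params=dict(
            n_filaments=n_filaments, core_sigma=core_sigma,
            log_mu=length_law.log_mu, log_sigma=length_law.log_sigma,
            shape=list(shape), voxel_size=list(voxel_size),
            psf_sigma=psf_sigma, noise_level=noise_level, seed=seed,
            poisson=poisson, center=center.tolist(),
        ),
    )
    return (
        Volume(mt, voxel_size, channel="microtubule"),
        Volume(k4, voxel_size, channel="kinesin"),
        gt,
    )


def _random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# bilayers
# ---------------------------------------------------------------------------

def make_bilayer_volume(
    sheet_axis: int = 0,
    sheet_position: float | None = None,
    areal_density: float = 2.0,
    length_law: LengthDistribution | None = None,
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size: tuple[float, float, float] | float = 0.5,
    psf_sigma: float = 0.2,
    noise_level: float = 0.0,
    seed: int = 0,
    sheet_sigma: float = 0.25,
    poisson: bool = False,
) -> tuple[Volume, Volume, GroundTruth]:
    """Synthesize a motor bilayer: a thin 2D kinesin sheet with microtubules
    protruding from both sides along the sheet normal.

    Filament tips are anchored in the sheet (uniform areal density,
    filaments per um^2) and each filament extends along +normal or
    -normal with equal probability, length drawn from ``length_law``.
    """
    if length_law is None:
        length_law = LengthDistribution(1.4, 0.6)
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * 3
    voxel_size = tuple(float(v) for v in voxel_size)
    extent = np.array([s * v for s, v in zip(shape, voxel_size)])
    if sheet_position is None:
        sheet_position = extent[sheet_axis] / 2.0

    l99 = float(length_law.ppf(0.99))
    margin = l99 + 3 * psf_sigma
    if sheet_position - margin < 0 or sheet_position + margin > extent[sheet_axis]:
        raise ValueError(
            f"sheet at {sheet_position:.1f} um needs a margin of {margin:.1f} um "
            f"on both sides along axis {sheet_axis} "
            f"(grid extent {extent[sheet_axis]:.1f} um)"
        )

    rng = np.random.default_rng(seed)
    in_plane_axes = [a for a in range(3) if a != sheet_axis]
    sheet_area = float(np.prod(extent[in_plane_axes]))
    n_filaments = max(1, int(round(areal_density * sheet_area)))

    anchors = np.empty((n_filaments, 3))
    anchors[:, sheet_axis] = sheet_position
    for a in in_plane_axes:
        anchors[:, a] = rng.uniform(0.0, extent[a], size=n_filaments)
    signs = rng.choice([-1.0, 1.0], size=n_filaments)
    lengths = length_law.sample(n_filaments, rng)
    ends = anchors.copy()
    ends[:, sheet_axis] += signs * lengths

    mt = rasterize_segments(anchors, ends, shape, voxel_size)
    mt = _apply_psf_and_noise(mt, voxel_size, psf_sigma, noise_level, rng, poisson)

    # kinesin: thin Gaussian sheet along the normal axis
    coord = (np.arange(shape[sheet_axis]) + 0.5) * voxel_size[sheet_axis]
    sig = max(sheet_sigma, 1e-6)
    prof = np.exp(-((coord - sheet_position) ** 2) / (2 * sig**2))
    prof = prof / prof.sum() * n_filaments
    sl = [None, None, None]
    sl[sheet_axis] = slice(None)
    k4 = np.broadcast_to(
        prof[tuple(sl)], shape
    ).copy() / np.prod([shape[a] for a in in_plane_axes])
    k4 = _apply_psf_and_noise(k4, voxel_size, psf_sigma, noise_level, rng, poisson)

    gt = GroundTruth(
        generator="make_bilayer_volume",
        params=dict(
            sheet_axis=sheet_axis, sheet_position=float(sheet_position),
            areal_density=areal_density, n_filaments=n_filaments,
            log_mu=length_law.log_mu, log_sigma=length_law.log_sigma,
            shape=list(shape), voxel_size=list(voxel_size),
            psf_sigma=psf_sigma, noise_level=noise_level,
            sheet_sigma=sheet_sigma, seed=seed, poisson=poisson,
        ),
    )
    return (
        Volume(mt, voxel_size, channel="microtubule"),
        Volume(k4, voxel_size, channel="kinesin"),
        gt,
    )


# ---------------------------------------------------------------------------
# contracting slab networks
# ---------------------------------------------------------------------------

def contraction_model(t, tau, t0, wn_inf):
    """Normalized width Wn(t) = Wn_inf + exp(-(t-t0)/tau) (1 - Wn_inf)."""
    t = np.asarray(t, dtype=float)
    return wn_inf + np.exp(-(t - t0) / tau) * (1.0 - wn_inf)


def make_contracting_sequence(
    tau: float = 20.0,
    t0: float = 0.0,
    wn_inf: float = 0.3,
    n_frames: int = 20,
    shape: tuple[int, int, int] = (12, 64, 160),
    voxel_size: tuple[float, float, float] | float = (1.0, 1.0, 0.5),
    edge_accumulation: bool = False,
    seed: int = 0,
    axis: int = 2,
    initial_width_fraction: float = 0.7,
    duration: float | None = None,
    total_intensity: float = 1.0e4,
) -> tuple[VolumeSequence, GroundTruth]:
    """Synthesize a slab network whose width contracts exponentially.

    The slab is centred along ``axis`` (the chamber short axis) and spans
    the full grid along the other axes.  Its width follows the
    exponential relaxation law exactly; the integrated microtubule
    intensity is identical in every frame (global mass conservation).
    With ``edge_accumulation`` the transverse density profile develops
    peaks at the slab boundaries, as seen in contracting networks.
    """
    if not 0 < wn_inf <= 1:
        raise ValueError("wn_inf must lie in (0, 1]")
    if tau <= 0:
        raise ValueError("tau must be positive")
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * 3
    voxel_size = tuple(float(v) for v in voxel_size)
    extent = np.array([s * v for s, v in zip(shape, voxel_size)])
    w0 = initial_width_fraction * extent[axis]
    center = extent[axis] / 2.0
    if duration is None:
        duration = 4.0 * tau
    times = t0 + np.linspace(0.0, duration, n_frames)
    wn = contraction_model(times, tau, t0, wn_inf)

    coord_edges = np.arange(shape[axis] + 1) * voxel_size[axis]
    frames = []
    for t, w_n in zip(times, wn):
        w = w0 * w_n
        lo, hi = center - w / 2.0, center + w / 2.0
        # fractional voxel coverage of the slab interval
        cover = np.clip(
            (np.minimum(coord_edges[1:], hi) - np.maximum(coord_edges[:-1], lo))
            / voxel_size[axis],
            0.0,
            1.0,
        )
        prof = cover.astype(float)
        if edge_accumulation:
            centers = (coord_edges[:-1] + coord_edges[1:]) / 2.0
            sig = 2.0 * voxel_size[axis]
            bump = np.exp(-((centers - lo) ** 2) / (2 * sig**2)) + np.exp(
                -((centers - hi) ** 2) / (2 * sig**2)
            )
            prof = prof * (1.0 + 1.5 * bump)
        sl = [None, None, None]
        sl[axis] = slice(None)
        other = [a for a in range(3) if a != axis]
        grid = np.broadcast_to(prof[tuple(sl)], shape).copy()
        # exact conservation: rescale each frame to the same total mass
        grid *= total_intensity / grid.sum()
        mt = Volume(grid, voxel_size, channel="microtubule", time=float(t))
        k4 = Volume(grid * 0.5, voxel_size, channel="kinesin", time=float(t))
        frames.append((mt, k4))
        del other

    gt = GroundTruth(
        generator="make_contracting_sequence",
        params=dict(
            tau=tau, t0=t0, wn_inf=wn_inf, n_frames=n_frames,
            shape=list(shape), voxel_size=list(voxel_size),
            edge_accumulation=edge_accumulation, seed=seed, axis=axis,
            initial_width=w0, duration=duration,
            total_intensity=total_intensity,
            times=times.tolist(), wn=wn.tolist(),
        ),
    )
    return VolumeSequence(frames=frames, times=times), gt


# ---------------------------------------------------------------------------
# roughening condensates with prescribed flux
# ---------------------------------------------------------------------------

def _spherical_mode_field(dirs: np.ndarray, coeffs: dict) -> np.ndarray:
    """Band-limited random smooth field on the sphere, max|f| normalized to 1.

    ``dirs`` is (..., 3) unit vectors; ``coeffs`` maps (l, m) -> weight for
    real spherical harmonics.
    """
    z = np.clip(dirs[..., 2], -1.0, 1.0)
    theta = np.arccos(z)
    phi = np.arctan2(dirs[..., 1], dirs[..., 0])
    f = np.zeros(dirs.shape[:-1])
    for (l, m), w in coeffs.items():
        y = sph_harm_y(l, abs(m), theta, phi)
        if m > 0:
            f = f + w * np.sqrt(2) * (-1) ** m * y.real
        elif m < 0:
            f = f + w * np.sqrt(2) * (-1) ** m * y.imag
        else:
            f = f + w * y.real
    return f


def _draw_mode_coeffs(rng: np.random.Generator, l_max: int = 4, l_min: int = 2) -> dict:
    coeffs = {}
    for l in range(l_min, l_max + 1):
        for m in range(-l, l + 1):
            coeffs[(l, m)] = rng.normal()
    return coeffs


def perturbed_sphere_mesh(
    radius: float,
    amplitude: float,
    coeffs: dict,
    center: np.ndarray,
    subdivisions: int = 4,
) -> trimesh.Trimesh:
    """Icosphere displaced radially by ``amplitude * f(direction)``."""
    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    dirs = np.asarray(base.vertices)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    f = _spherical_mode_field(dirs, coeffs)
    scale = np.abs(f).max()
    f = f / scale if scale > 0 else f
    r = radius + amplitude * f
    verts = center[None, :] + dirs * r[:, None]
    return trimesh.Trimesh(vertices=verts, faces=base.faces, process=False)


def make_roughening_sequence(
    base_shape: str = "sphere",
    flux_schedule=None,
    perturbation_growth=None,
    n_frames: int = 8,
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size: tuple[float, float, float] | float = 1.0,
    seed: int = 0,
    radius: float = 20.0,
    shell_thickness: float = 5.0,
    total_intensity: float = 1.0e4,
    surface_mass_fraction0: float = 0.5,
    duration: float = 70.0,
    noise_level: float = 0.0,
) -> tuple[VolumeSequence, GroundTruth]:
    """Synthesize a condensate with a roughening closed surface and a
    prescribed interior-to-surface material flux.

    The surface is a sphere of radius ``radius`` perturbed radially by a
    fixed band-limited random mode set whose amplitude follows
    ``perturbation_growth(t)``.  Material is split between a surface
    shell (thickness ``shell_thickness``, measured inward from the
    surface by Euclidean distance) and the remaining interior so that the
    shell mass obeys d(M_S)/dt = flux_schedule(t) exactly, with the total
    intensity conserved across frames.

    ``flux_schedule`` and ``perturbation_growth`` accept a time in
    minutes and return intensity/min and um respectively; ``None`` means
    zero flux / zero perturbation.

    Returns the sequence and a ground truth holding, per frame, the mode
    coefficients, amplitudes, surface/interior masses, analytic mesh
    area and interior volume, so recovery can be checked exactly.
    """
    if base_shape != "sphere":
        raise NotImplementedError("only the spherical condensate is implemented")
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * 3
    voxel_size = tuple(float(v) for v in voxel_size)
    extent = np.array([s * v for s, v in zip(shape, voxel_size)])
    center = extent / 2.0

    times = np.linspace(0.0, duration, n_frames)
    if flux_schedule is None:
        flux = np.zeros(n_frames)
    elif callable(flux_schedule):
        flux = np.array([float(flux_schedule(t)) for t in times])
    else:
        flux = np.asarray(flux_schedule, dtype=float)
    if perturbation_growth is None:
        amps = np.zeros(n_frames)
    elif callable(perturbation_growth):
        amps = np.array([float(perturbation_growth(t)) for t in times])
    else:
        amps = np.asarray(perturbation_growth, dtype=float)
    if flux.size != n_frames or amps.size != n_frames:
        raise ValueError("flux and amplitude schedules must have n_frames entries")
    if np.any(amps >= radius - shell_thickness):
        raise ValueError(
            "perturbation amplitude must stay below radius - shell_thickness "
            "(no self-intersection)"
        )
    if radius + amps.max() + 2 > extent.min() / 2:
        raise ValueError(
            f"grid extent {extent.min():.0f} um too small for radius "
            f"{radius} um plus perturbation {amps.max():.1f} um"
        )

    rng = np.random.default_rng(seed)
    coeffs = _draw_mode_coeffs(rng)

    # shell mass follows the prescribed flux exactly (trapezoidal integral)
    m_s = surface_mass_fraction0 * total_intensity + np.concatenate(
        [[0.0], np.cumsum((flux[1:] + flux[:-1]) / 2.0 * np.diff(times))]
    )
    m_v = total_intensity - m_s
    if np.any(m_s <= 0) or np.any(m_v <= 0):
        raise ValueError("flux schedule drains the surface or interior dry")

    # voxel directions and radii about the centre (shared by all frames)
    coords = np.meshgrid(
        *[(np.arange(s) + 0.5) * v for s, v in zip(shape, voxel_size)],
        indexing="ij",
    )
    rel = np.stack([c - mu for c, mu in zip(coords, center)], axis=-1)
    r_vox = np.linalg.norm(rel, axis=-1)
    with np.errstate(invalid="ignore"):
        dirs = rel / np.maximum(r_vox[..., None], 1e-9)
    f_field = _spherical_mode_field(dirs, coeffs)
    f_scale = np.abs(
        _spherical_mode_field(
            _random_unit_vectors(4096, np.random.default_rng(12345)), coeffs
        )
    ).max()
    f_field = f_field / f_scale

    frames = []
    truth_area = []
    truth_interior_volume = []
    sampling = voxel_size
    for i, (t, a) in enumerate(zip(times, amps)):
        surf_r = radius + a * f_field
        mask = r_vox <= surf_r
        dist = scipy.ndimage.distance_transform_edt(mask, sampling=sampling)
        shell = mask & (dist <= shell_thickness)
        interior = mask & ~shell
        n_shell, n_int = int(shell.sum()), int(interior.sum())
        if n_shell == 0 or n_int == 0:
            raise ValueError("degenerate partition; enlarge radius or grid")
        grid = np.zeros(shape)
        grid[shell] = m_s[i] / n_shell
        grid[interior] = m_v[i] / n_int
        if noise_level > 0:
            grid = _apply_psf_and_noise(
                grid, voxel_size, 0.0, noise_level, rng
            )
        mt = Volume(grid, voxel_size, channel="microtubule", time=float(t))
        k4 = Volume(
            np.where(shell, grid, 0.25 * grid), voxel_size,
            channel="kinesin", time=float(t),
        )
        frames.append((mt, k4))
        mesh = perturbed_sphere_mesh(radius, a, coeffs, center)
        truth_area.append(float(mesh.area))
        truth_interior_volume.append(float(n_int * np.prod(voxel_size)))

    gt = GroundTruth(
        generator="make_roughening_sequence",
        params=dict(
            base_shape=base_shape, n_frames=n_frames, shape=list(shape),
            voxel_size=list(voxel_size), seed=seed, radius=radius,
            shell_thickness=shell_thickness, total_intensity=total_intensity,
            surface_mass_fraction0=surface_mass_fraction0,
            duration=duration, noise_level=noise_level,
            times=times.tolist(), flux=flux.tolist(),
            amplitudes=amps.tolist(),
            mode_coeffs={f"{l},{m}": w for (l, m), w in coeffs.items()},
            surface_mass=m_s.tolist(), interior_mass=m_v.tolist(),
            mesh_area=truth_area,
            interior_volume=truth_interior_volume,
        ),
    )
    return VolumeSequence(frames=frames, times=times), gt


# ---------------------------------------------------------------------------
# aligned 2D filament textures
# ---------------------------------------------------------------------------

def make_aligned_field(
    order_target: float,
    n_filaments: int = 5000,
    shape: tuple[int, int] = (1024, 1024),
    pixel_size: float = 0.5,
    segment_length: float = 15.0,
    seed: int = 0,
    mean_orientation: float | None = None,
    blur_sigma: float = 0.75,
) -> tuple[Volume, GroundTruth]:
    """Synthesize a 2D filament texture with a target nematic order S*.

    Orientations are drawn from a mixture that has resultant length of the
    doubled angle exactly equal to ``order_target``: with probability S*
    a segment takes the common director angle, otherwise its orientation
    is uniform on [0, pi).  S*=1 gives perfect alignment, S*=0 an
    isotropic texture.
    """
    if not 0 <= order_target <= 1:
        raise ValueError("order_target must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    extent = np.array([s * pixel_size for s in shape])
    theta0 = (
        float(mean_orientation)
        if mean_orientation is not None
        else rng.uniform(0, np.pi)
    )
    aligned = rng.random(n_filaments) < order_target
    theta = np.where(aligned, theta0, rng.uniform(0, np.pi, size=n_filaments))

    centers = rng.uniform(0, 1, size=(n_filaments, 2)) * extent[None, :]
    # grid axes are (y, x); orientation measured from the x axis
    half = (
        np.stack([np.sin(theta), np.cos(theta)], axis=1) * segment_length / 2.0
    )
    starts = centers - half
    ends = centers + half
    img = rasterize_segments(starts, ends, shape, (pixel_size, pixel_size))
    if blur_sigma > 0:
        img = scipy.ndimage.gaussian_filter(img, sigma=blur_sigma / pixel_size)

    gt = GroundTruth(
        generator="make_aligned_field",
        params=dict(
            order_target=order_target, n_filaments=n_filaments,
            shape=list(shape), pixel_size=pixel_size,
            segment_length=segment_length, seed=seed,
            mean_orientation=theta0, blur_sigma=blur_sigma,
        ),
    )
    return Volume(img, (pixel_size, pixel_size), channel="microtubule"), gt


# ---------------------------------------------------------------------------
# geometry fixtures
# ---------------------------------------------------------------------------

def make_sphere_mesh(radius: float, refinement: int = 4) -> trimesh.Trimesh:
    """Watertight outward-oriented icosphere triangulation (um units)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    mesh = trimesh.creation.icosphere(subdivisions=refinement, radius=radius)
    if mesh.volume < 0:
        mesh.invert()
    return mesh
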
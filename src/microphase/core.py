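"""Shared domain types for microtubule/kinesin-4 active-matter analysis.

Calibrated intensity grids (:class:`Volume`), two-channel time series
(:class:`VolumeSequence`), the log-normal filament length law
(:class:`LengthDistribution`), 1D intensity profiles (:class:`Profile`),
and the result records produced by the kinetics, surface-geometry,
density-partition and nematic-order stages.

Conventions
-----------
* Grids are indexed (z, y, x) for 3D data and (y, x) for 2D images.
* ``voxel_size`` is micrometres per voxel along each grid axis, in the
  same axis order as the data; anisotropy is allowed.
* Times are minutes; lengths micrometres; intensities arbitrary units.
* Triangle meshes are :class:`trimesh.Trimesh` objects with vertices in
  physical micrometres and outward-oriented normals.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.stats

__all__ = [
    "Volume",
    "VolumeSequence",
    "GroundTruth",
    "LengthDistribution",
    "Profile",
    "WidthSeries",
    "ContractionFit",
    "AsterRecord",
    "ShellPartition",
    "FluxSeries",
    "CorrelationCurve",
    "OrientationField",
    "OrderResult",
]

Channel = Literal["microtubule", "kinesin"]


@dataclass
class Volume:
    """A calibrated fluorescence intensity grid (single channel).

    Parameters
    ----------
    data:
        Non-negative intensity array, 2D ``(y, x)`` or 3D ``(z, y, x)``.
    voxel_size:
        Physical voxel edge length in um per grid axis (same order as
        ``data.shape``); strictly positive, may be anisotropic.
    channel:
        ``"microtubule"`` or ``"kinesin"``.
    time:
        Acquisition time in minutes, if part of a series.
    """

    data: np.ndarray
    voxel_size: tuple[float, ...]
    channel: Channel = "microtubule"
    time: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"Volume data must be 2D or 3D, got {self.data.ndim}D")
        self.voxel_size = tuple(float(v) for v in np.atleast_1d(self.voxel_size))
        if len(self.voxel_size) == 1:
            self.voxel_size = self.voxel_size * self.data.ndim
        if len(self.voxel_size) != self.data.ndim:
            raise ValueError("voxel_size must have one entry per data axis")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be strictly positive")
        if any(s < 2 for s in self.data.shape):
            raise ValueError("each grid axis needs at least 2 planes")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        if self.channel not in ("microtubule", "kinesin"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume (um^3) or area (um^2, for 2D) of one voxel."""
        return float(np.prod(self.voxel_size))

    @property
    def extent(self) -> tuple[float, ...]:
        """Physical extent of the grid along each axis, in um."""
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size))

    def coords(self) -> list[np.ndarray]:
        """Physical voxel-centre coordinates (um) along each axis."""
        return [
            (np.arange(s) + 0.5) * v for s, v in zip(self.shape, self.voxel_size)
        ]

    def total_intensity(self) -> float:
        return float(self.data.sum())

    def with_data(self, data: np.ndarray, channel: Channel | None = None) -> "Volume":
        return Volume(
            data=data,
            voxel_size=self.voxel_size,
            channel=channel or self.channel,
            time=self.time,
        )


@dataclass
class VolumeSequence:
    """An ordered two-channel time series of volumes.

    ``frames[i]`` is a ``(microtubule, kinesin)`` pair sharing grid shape
    and voxel size; ``times`` are strictly increasing minutes.
    """

    frames: list[tuple[Volume, Volume]]
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) != len(self.times):
            raise ValueError("one time per frame required")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.frames:
            ref = self.frames[0][0]
            for mt, k4 in self.frames:
                for vol in (mt, k4):
                    if vol.shape != ref.shape or vol.voxel_size != ref.voxel_size:
                        raise ValueError("all frames must share shape and voxel size")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def voxel_size(self) -> tuple[float, ...]:
        return self.frames[0][0].voxel_size

    def microtubule(self, i: int) -> Volume:
        return self.frames[i][0]

    def kinesin(self, i: int) -> Volume:
        return self.frames[i][1]


@dataclass
class GroundTruth:
    """Complete generating record of a synthetic dataset.

    Holds the generator name and every parameter (including the seed)
    needed to regenerate the dataset bit-identically.  Serializes to JSON.
    """

    generator: str
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return {"__ndarray__": o.tolist()}
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            raise TypeError(f"not JSON-serializable: {type(o)}")

        return json.dumps(
            {"generator": self.generator, "params": self.params},
            default=_default,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        def _hook(d):
            if "__ndarray__" in d:
                return np.asarray(d["__ndarray__"])
            return d

        raw = json.loads(text, object_hook=_hook)
        return cls(generator=raw["generator"], params=raw["params"])


@dataclass(frozen=True)
class LengthDistribution:
    """Log-normal filament length law, lengths in um.

    ``log_mu`` and ``log_sigma`` are the mean and standard deviation of
    ``ln L`` (the classical log-normal shape parameters, often printed as
    M and S).  ``log_sigma`` is named to avoid collision with the nematic
    order parameter S.
    """

    log_mu: float
    log_sigma: float

    def __post_init__(self) -> None:
        if not self.log_sigma > 0:
            raise ValueError("log_sigma must be > 0")

    @property
    def frozen(self) -> scipy.stats.rv_continuous:
        return scipy.stats.lognorm(s=self.log_sigma, scale=np.exp(self.log_mu))

    @property
    def mean(self) -> float:
        return float(np.exp(self.log_mu + self.log_sigma**2 / 2))

    @property
    def mode(self) -> float:
        return float(np.exp(self.log_mu - self.log_sigma**2))

    def pdf(self, x) -> np.ndarray:
        return self.frozen.pdf(x)

    def cdf(self, x) -> np.ndarray:
        return self.frozen.cdf(x)

    def survival(self, x) -> np.ndarray:
        """P(L > x): the tip-anchor kernel."""
        return self.frozen.sf(x)

    def ppf(self, q) -> np.ndarray:
        return self.frozen.ppf(q)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.exp(rng.normal(self.log_mu, self.log_sigma, size=n))


@dataclass
class Profile:
    """A 1D intensity profile: radial (r >= 0) or signed normal distance."""

    coordinate: np.ndarray
    intensity: np.ndarray
    stderr: np.ndarray | None = None
    kind: Literal["radial", "normal"] = "radial"

    def __post_init__(self) -> None:
        self.coordinate = np.asarray(self.coordinate, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.coordinate.shape != self.intensity.shape:
            raise ValueError("coordinate and intensity must align")
        if self.coordinate.size == 0:
            raise ValueError("empty profile")
        if np.any(np.diff(self.coordinate) <= 0):
            raise ValueError("profile bins must be strictly increasing")
        if np.any(self.intensity < -1e-12):
            raise ValueError("intensities must be non-negative")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
            if self.stderr.shape != self.intensity.shape:
                raise ValueError("stderr must align with intensity")

    def normalized(self) -> "Profile":
        """Unit-peak copy (the convention used for model comparison)."""
        peak = float(self.intensity.max())
        if peak <= 0:
            raise ValueError("cannot normalize an all-zero profile")
        return Profile(
            coordinate=self.coordinate.copy(),
            intensity=self.intensity / peak,
            stderr=None if self.stderr is None else self.stderr / peak,
            kind=self.kind,
        )

    def resampled(self, coordinate: np.ndarray) -> "Profile":
        """Linear interpolation onto new bin centres (0 outside support)."""
        vals = np.interp(coordinate, self.coordinate, self.intensity,
                         left=0.0, right=0.0)
        return Profile(coordinate=np.asarray(coordinate, dtype=float),
                       intensity=vals, kind=self.kind)


@dataclass
class WidthSeries:
    """Contracting-network width W(t) and its normalized form Wn(t)=W/W(0)."""

    times: np.ndarray
    width: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        if self.times.shape != self.width.shape:
            raise ValueError("times and width must align")
        if self.valid is None:
            self.valid = np.isfinite(self.width) & (self.width > 0)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def normalized(self) -> np.ndarray:
        """Wn(t) = W(t) / W(first valid frame)."""
        idx = np.flatnonzero(self.valid)
        if idx.size == 0:
            raise ValueError("no valid width measurements")
        return self.width / self.width[idx[0]]


@dataclass
class ContractionFit:
    """Exponential-relaxation fit Wn(t) = Wn_inf + exp(-(t-t0)/tau)(1-Wn_inf)."""

    tau: float
    t0: float
    wn_inf: float
    residual_rms: float
    converged: bool
    degenerate: bool = False

    def predict(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return self.wn_inf + np.exp(-(t - self.t0) / self.tau) * (1 - self.wn_inf)


@dataclass
class AsterRecord:
    """Morphometrics of one segmented kinesin-rich aster core."""

    label: int
    centroid: np.ndarray        # um, (z, y, x)
    volume: float               # um^3
    moments: np.ndarray         # eigenvalues of the 2nd-moment tensor, desc.
    moment_ratio: float         # major / minor eigenvalue

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.moments = np.asarray(self.moments, dtype=float)
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if np.any(np.diff(self.moments) > 1e-12):
            raise ValueError("moments must be sorted descending")


@dataclass
class ShellPartition:
    """Surface-shell / interior split of a segmented condensate."""

    shell: np.ndarray           # boolean mask: within `thickness` of surface
    interior: np.ndarray        # boolean mask: remaining enclosed voxels
    thickness: float            # um
    empty_interior: bool = False

    def __post_init__(self) -> None:
        if self.shell.shape != self.interior.shape:
            raise ValueError("shell and interior masks must share shape")
        if np.any(self.shell & self.interior):
            raise ValueError("shell and interior must be disjoint")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")


@dataclass
class FluxSeries:
    """Surface/interior mass bookkeeping of a contracting condensate.

    ``area`` is the mesh surface area A(t); ``volume`` the interior volume
    V(t); ``rho_s`` the areal surface density <rho_S>; ``rho_v`` the
    volumetric interior density <rho_V>.  After :func:`flux_terms` the
    derivative terms A d<rho_S>/dt and <rho_S> dA/dt, the interior-to-
    surface flux Phi, and the conservation residual
    ``A d<rho_S>/dt + <rho_S> dA/dt - Phi`` are populated.
    """

    times: np.ndarray
    area: np.ndarray
    volume: np.ndarray
    rho_s: np.ndarray
    rho_v: np.ndarray
    term_a_drhos: np.ndarray | None = None
    term_rhos_da: np.ndarray | None = None
    flux: np.ndarray | None = None
    residual: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("times", "area", "volume", "rho_s", "rho_v"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.times.size
        for name in ("area", "volume", "rho_s", "rho_v"):
            if getattr(self, name).size != n:
                raise ValueError("all series must share length")
        if n > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.area <= 0) or np.any(self.volume <= 0):
            raise ValueError("area and volume must be positive")

    def surface_mass(self) -> np.ndarray:
        return self.rho_s * self.area

    def interior_mass(self) -> np.ndarray:
        return self.rho_v * self.volume


@dataclass
class CorrelationCurve:
    """Normal-normal correlation C(Lambda) binned by geodesic separation."""

    lam: np.ndarray             # bin centres, um
    c: np.ndarray               # correlation values, NaN where bin empty
    n_pairs: np.ndarray
    time: float | None = None

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not (self.lam.shape == self.c.shape == self.n_pairs.shape):
            raise ValueError("lam, c, n_pairs must align")
        finite = np.isfinite(self.c)
        if np.any(np.abs(self.c[finite]) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class OrientationField:
    """Per-pixel filament orientation theta in [0, pi) with coherency."""

    theta: np.ndarray
    coherency: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if not (self.theta.shape == self.coherency.shape == self.mask.shape):
            raise ValueError("theta, coherency and mask must share shape")
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)


@dataclass
class OrderResult:
    """Scalar nematic order parameter S = <cos 2(theta - theta_bar)>."""

    theta_bar: float
    s: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels > 0 and not -1e-9 <= self.s <= 1 + 1e-9:
            raise ValueError("S must lie in [0, 1]")
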
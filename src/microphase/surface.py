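"""Surface extraction and roughening statistics on triangle meshes.

The condensate/network surface is segmented from a fluorescence volume
with a morphological active-contour (level-set) evolution and meshed by
marching cubes in physical micrometres.  On the resulting closed mesh
this module measures area, enclosed volume, per-vertex normals and
cotangent-Laplacian mean curvature, and the normal-normal correlation

    C(Lambda) = < n(r) . n(r + Lambda) > / < n(r) . n(r) >,

the spatial average of the dot product of unit surface normals over all
vertex pairs separated by a geodesic of length Lambda.  Geodesic
distances are shortest paths on a chordal neighbour graph (1- and 2-ring
edges by default; pure edge-graph distances overestimate geodesics by a
lattice-dependent factor of up to ~15%, which the wider stencil reduces
to the sub-percent level verified by the sphere oracle C = cos(Lambda/R)).
An exponential fit C ~ c0 + c1 exp(-Lambda/l) over a chosen range gives
the roughening correlation length l and large-distance plateau c0.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage
import scipy.optimize
import scipy.sparse
import scipy.sparse.csgraph
import skimage.filters
import skimage.measure
import skimage.morphology
import skimage.segmentation
import trimesh
import trimesh.smoothing

from .core import CorrelationCurve, Volume

__all__ = [
    "extract_surface",
    "mesh_area",
    "mesh_volume",
    "vertex_normals",
    "vertex_areas",
    "mean_curvature",
    "bisect_mesh",
    "geodesic_distances",
    "normal_correlation",
    "correlation_length",
]


# ---------------------------------------------------------------------------
# level-set surface extraction
# ---------------------------------------------------------------------------

def _initial_mask(data: np.ndarray, closing_radius: int = 2) -> np.ndarray:
    """Otsu threshold -> largest connected component -> morphological closing.

    The threshold is computed on the full histogram (background included)
    so that a structure with internal density contrast is kept whole.
    """
    thr = skimage.filters.threshold_otsu(data)
    mask = data >= thr
    labels, n = scipy.ndimage.label(mask)
    if n == 0:
        raise ValueError("no foreground above threshold")
    sizes = np.bincount(labels.ravel())[1:]
    mask = labels == (1 + int(np.argmax(sizes)))
    if closing_radius > 0:
        mask = scipy.ndimage.binary_closing(
            mask, structure=skimage.morphology.ball(closing_radius)
            if data.ndim == 3 else skimage.morphology.disk(closing_radius),
        )
    return mask


def extract_surface(
    vol: Volume,
    iterations: int = 10,
    smoothing: int = 1,
    init: np.ndarray | None = None,
    method: str = "chan_vese",
    keep_largest: bool = True,
    mesh_smooth_iterations: int = 20,
) -> tuple[np.ndarray, trimesh.Trimesh]:
    """Segment the bright structure and mesh its surface.

    A morphological active contour (region-based Chan-Vese by default,
    ``method="geodesic"`` for the edge-based variant) evolves from an
    initial mask (Otsu threshold, largest component, closing) for a fixed
    iteration budget.  The converged mask is triangulated by marching
    cubes at the 0.5 level, scaled to physical um (anisotropic voxels
    honoured), and the largest connected surface component is returned
    with outward orientation.  Taubin smoothing
    (``mesh_smooth_iterations``; 0 to disable) removes the voxel
    staircase, which would otherwise inflate the surface area by ~10%
    while leaving the enclosed volume essentially unchanged.

    Returns ``(mask, mesh)``.
    """
    data = vol.data.astype(float)
    if data.max() <= data.min():
        raise ValueError("volume has no dynamic range; nothing to segment")
    mask0 = _initial_mask(data) if init is None else init.astype(bool)

    if method == "chan_vese":
        mask = skimage.segmentation.morphological_chan_vese(
            data, num_iter=iterations, init_level_set=mask0,
            smoothing=smoothing,
        ).astype(bool)
    elif method == "geodesic":
        gimage = skimage.segmentation.inverse_gaussian_gradient(data)
        mask = skimage.segmentation.morphological_geodesic_active_contour(
            gimage, num_iter=iterations, init_level_set=mask0,
            smoothing=smoothing,
        ).astype(bool)
    else:
        raise ValueError(f"unknown level-set method {method!r}")
    if not mask.any():
        raise ValueError("level set collapsed to an empty mask")

    labels, n = scipy.ndimage.label(mask)
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        mask = labels == (1 + int(np.argmax(sizes)))

    padded = np.pad(mask.astype(float), 1)
    verts, faces, _, _ = skimage.measure.marching_cubes(
        padded, level=0.5, spacing=vol.voxel_size
    )
    verts = verts - np.asarray(vol.voxel_size)  # undo the 1-voxel pad
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if keep_largest:
        parts = mesh.split(only_watertight=False)
        if len(parts) > 1:
            mesh = max(parts, key=lambda m: m.area)
    if mesh_smooth_iterations > 0:
        trimesh.smoothing.filter_taubin(mesh, iterations=mesh_smooth_iterations)
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mask, mesh


# ---------------------------------------------------------------------------
# mesh measures
# ---------------------------------------------------------------------------

def mesh_area(mesh: trimesh.Trimesh) -> float:
    """Total surface area (um^2): sum of triangle areas."""
    return float(mesh.area)


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume (um^3) by the divergence theorem (signed tetrahedra).

    Requires a watertight mesh; positive for outward orientation.
    """
    if not mesh.is_watertight:
        raise ValueError("volume is only defined for a watertight mesh")
    return float(mesh.volume)


def vertex_normals(mesh: trimesh.Trimesh) -> np.ndarray:
    """Unit per-vertex normals (area-weighted average of face normals)."""
    n = np.asarray(mesh.vertex_normals, dtype=float)
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    return n / np.maximum(norms, 1e-12)


def vertex_areas(mesh: trimesh.Trimesh) -> np.ndarray:
    """Barycentric vertex areas: one third of incident face areas."""
    areas = np.zeros(len(mesh.vertices))
    np.add.at(areas, mesh.faces.ravel(),
              np.repeat(mesh.area_faces / 3.0, 3))
    return areas


def mean_curvature(mesh: trimesh.Trimesh) -> np.ndarray:
    """Per-vertex mean curvature H (um^-1) via the cotangent Laplacian.

    The discrete mean-curvature normal is ``K_i = (1/2A_i) sum_j
    (cot a_ij + cot b_ij)(v_i - v_j)`` with barycentric vertex areas
    A_i; H is half its magnitude, signed by the direction relative to
    the vertex normal (positive for a sphere with outward normals).
    Degenerate (zero-area) triangles are excluded.
    """
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces)
    face_areas = np.asarray(mesh.area_faces)
    good = face_areas > 1e-12
    f = f[good]

    lap = np.zeros_like(v)
    # for each corner k of each face, the opposite edge (i, j) gets cot(k)
    for k in range(3):
        i = f[:, (k + 1) % 3]
        j = f[:, (k + 2) % 3]
        o = f[:, k]
        e1 = v[i] - v[o]
        e2 = v[j] - v[o]
        cross = np.cross(e1, e2)
        denom = np.linalg.norm(cross, axis=1)
        cot = (e1 * e2).sum(axis=1) / np.maximum(denom, 1e-12)
        w = 0.5 * cot
        np.add.at(lap, i, w[:, None] * (v[i] - v[j]))
        np.add.at(lap, j, w[:, None] * (v[j] - v[i]))

    areas = vertex_areas(mesh)
    # mean-curvature normal K = lap / A (with the 1/2 already in the
    # edge weights); H = |K| / 2
    hn = lap / np.maximum(areas, 1e-12)[:, None]
    h = 0.5 * np.linalg.norm(hn, axis=1)
    sign = np.sign((hn * vertex_normals(mesh)).sum(axis=1))
    sign[sign == 0] = 1.0
    return h * sign


def bisect_mesh(
    mesh: trimesh.Trimesh,
) -> tuple[trimesh.Trimesh, trimesh.Trimesh]:
    """Split a mesh into top and bottom sheets.

    The cut plane passes through the area centroid with normal along the
    principal axis of smallest spatial extent (for a slab or flattened
    condensate: the thin direction), which removes most of the
    overall-curvature contribution from the normal-normal correlation.
    Faces are assigned by the side of their centroid; both halves are
    returned as open submeshes (positive side first).
    """
    v = np.asarray(mesh.vertices, dtype=float)
    centroid = (mesh.triangles_center * mesh.area_faces[:, None]).sum(axis=0)
    centroid = centroid / mesh.area
    cov = np.cov((v - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, 0]  # smallest spatial variance

    side = (mesh.triangles_center - centroid) @ axis
    halves = []
    for sel in (side >= 0, side < 0):
        sub = trimesh.Trimesh(
            vertices=v.copy(), faces=mesh.faces[sel], process=False
        )
        sub.remove_unreferenced_vertices()
        halves.append(sub)
    return halves[0], halves[1]


# ---------------------------------------------------------------------------
# geodesic normal-normal correlation
# ---------------------------------------------------------------------------

def _neighbor_graph(mesh: trimesh.Trimesh, rings: int = 2) -> scipy.sparse.csr_matrix:
    """Sparse symmetric graph of chordal distances between mesh vertices
    within ``rings`` edge-hops of each other."""
    n = len(mesh.vertices)
    edges = mesh.edges_unique
    adj = scipy.sparse.coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    adj = (adj + adj.T).tocsr()
    reach = adj.copy()
    acc = adj.copy()
    for _ in range(rings - 1):
        reach = reach @ adj
        acc = acc + reach
    acc = scipy.sparse.triu(acc.tocoo(), k=1)
    i, j = acc.row, acc.col
    d = np.linalg.norm(mesh.vertices[i] - mesh.vertices[j], axis=1)
    g = scipy.sparse.coo_matrix((d, (i, j)), shape=(n, n))
    return (g + g.T).tocsr()


def geodesic_distances(
    mesh: trimesh.Trimesh,
    sources: np.ndarray,
    rings: int = 2,
) -> np.ndarray:
    """Approximate geodesic distances from ``sources`` to every vertex:
    Dijkstra shortest paths on the chordal neighbour graph."""
    graph = _neighbor_graph(mesh, rings=rings)
    return scipy.sparse.csgraph.dijkstra(
        graph, directed=False, indices=np.asarray(sources)
    )


def normal_correlation(
    mesh: trimesh.Trimesh,
    lambda_bins: np.ndarray,
    n_samples: int | None = None,
    seed: int = 0,
    rings: int = 2,
    area_weighted: bool = True,
    time: float | None = None,
) -> CorrelationCurve:
    """Normal-normal correlation C(Lambda) binned by geodesic separation.

    All pairs (source, vertex) are used when the pair budget allows;
    otherwise ``n_samples`` source vertices are drawn (area-weighted,
    recorded seed) and paired with every vertex.  Within each bin the
    dot products of unit vertex normals are averaged with the product of
    barycentric vertex areas as weights (uniform if ``area_weighted`` is
    False).  Bins beyond the mesh diameter come back as NaN with zero
    pairs, not as zero correlation.
    """
    if len(mesh.vertices) < 100:
        raise ValueError("mesh too coarse for correlation statistics")
    edges = np.asarray(lambda_bins, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("lambda_bins must be increasing bin edges")

    n = len(mesh.vertices)
    rng = np.random.default_rng(seed)
    areas = vertex_areas(mesh)
    if n_samples is None or n_samples >= n:
        sources = np.arange(n)
    else:
        p = areas / areas.sum()
        sources = rng.choice(n, size=n_samples, replace=False, p=p)

    dist = geodesic_distances(mesh, sources, rings=rings)
    normals = vertex_normals(mesh)
    dots = normals[sources] @ normals.T  # (n_src, n)

    w_src = areas[sources][:, None] if area_weighted else np.ones((len(sources), 1))
    w_dst = areas[None, :] if area_weighted else np.ones((1, n))
    w = (w_src * w_dst).ravel()
    d = dist.ravel()
    c = dots.ravel()

    finite = np.isfinite(d)
    idx = np.digitize(d[finite], edges) - 1
    nb = edges.size - 1
    ok = (idx >= 0) & (idx < nb)
    idx, wv, cv = idx[ok], w[finite][ok], c[finite][ok]

    wsum = np.bincount(idx, weights=wv, minlength=nb)
    csum = np.bincount(idx, weights=wv * cv, minlength=nb)
    npairs = np.bincount(idx, minlength=nb)
    with np.errstate(invalid="ignore"):
        cmean = np.where(wsum > 0, csum / np.maximum(wsum, 1e-300), np.nan)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return CorrelationCurve(lam=centers, c=np.clip(cmean, -1, 1),
                            n_pairs=npairs, time=time)


def correlation_length(
    curve: CorrelationCurve,
    fit_range: tuple[float, float],
) -> dict:
    """Exponential correlation length from C(Lambda).

    Least-squares fit of ``c0 + c1 exp(-Lambda/l)`` over ``fit_range``
    (um).  Returns the length l, the plateau c0 and a ``decaying`` flag;
    a non-decaying curve is reported with ``l = inf``.
    """
    lo, hi = fit_range
    sel = (
        (curve.lam >= lo) & (curve.lam <= hi)
        & np.isfinite(curve.c) & (curve.n_pairs > 0)
    )
    lam = curve.lam[sel]
    c = curve.c[sel]
    if lam.size < 4:
        raise ValueError("need at least 4 populated bins inside fit_range")

    drop = float(c[0] - c[-1])
    if drop <= 1e-6:
        return {"length": np.inf, "plateau": float(np.mean(c)),
                "amplitude": 0.0, "decaying": False}

    span = hi - lo

    def model(x, c0, c1, ell):
        return c0 + c1 * np.exp(-x / ell)

    p0 = (float(c[-1]), drop * np.exp(lam[0] / span), span / 2.0)
    try:
        popt, _ = scipy.optimize.curve_fit(
            model, lam, c, p0=p0,
            bounds=([-1.0, 0.0, 1e-6], [1.0, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return {"length": np.inf, "plateau": float(np.mean(c)),
                "amplitude": 0.0, "decaying": False}
    c0, c1, ell = (float(x) for x in popt)
    return {"length": ell, "plateau": c0, "amplitude": c1, "decaying": True}
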
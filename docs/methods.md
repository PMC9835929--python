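# Methods

`microphase` quantifies the self-organization of microtubules driven by
tip-accumulating kinesin-4 motors from 3D two-channel fluorescence
volumes: aster and bilayer structure, global contraction kinetics,
surface roughening of condensates, the interior-to-surface mass flux,
and nematic order. Because no public raw volumes exist for this system,
the package ships seeded generators that emulate each imaging regime
with complete ground truth; every analysis stage is validated against
that constructed truth.

## Tip-anchor structure models

Filament lengths L follow a log-normal law with log-mean M and
log-standard-deviation S (defaults M = 1.4, S = 0.6, i.e. mean 4.9 um,
mode 2.8 um, the measured polydispersity of stabilized microtubules).
If filaments are anchored to a motor-rich structure by one tip and
labelled uniformly along their length, the expected microtubule
intensity at distance x from the anchor distribution g is the
convolution

    I_ideal(x) = (g * K)(x),      K(x) = P(L > x),

with K the survival function of the length law (`tip_anchor_kernel`).

Geometry matters for the radial aster. With filaments pointing radially
outward from a compact core, the 3D intensity at radius r carries a
1/r^2 solid-angle dilution. That factor cancels exactly when radial
profiles are read as *shell profiles* — total intensity per unit radius
(`radial_average(..., weight="shell")`) — and in that convention the 1D
convolution above is the exact forward model: against rasterized
synthetic asters (2000 filaments, 1 um core) the normalized RMSE is
~0.05, dominated by filament-count sampling noise. The familiar
annulus-mean of the z-projection is retained as the display convention
(`weight="mean"`); it is *not* directly comparable to the flat
convolution, because the projected mean profile decays several-fold
faster than the shell profile. For the bilayer the geometry is
genuinely one-dimensional (filaments leave the motor sheet along the
±normal), so the symmetric convolution with K(|x|) is exact for
plane-mean profiles; measured agreement is NRMSE ~0.02.

Model/measurement agreement is scored by `profile_agreement` as
RMSE divided by the measured peak (both profiles peak-normalized)
plus an ordinary R².

## Contraction kinetics

Network width W(t) is measured per frame as the extent over which the
transverse intensity profile exceeds a relative level (default 0.5,
i.e. FWHM of the integrated profile — the level is a free choice since
"width" has no unique operational definition), averaged over five
non-overlapping strips along the long axis, with linear sub-voxel
interpolation at the crossings. The normalized width Wn = W/W(0) is fit
by nonlinear least squares to the exponential relaxation

    Wn(t) = Wn_inf + exp(-(t - t0)/tau) (1 - Wn_inf),

initialized with Wn_inf at the series minimum and tau at the half-decay
time. Noiseless synthetic series are recovered exactly (<= 0.1% over a
tau x Wn_inf grid); with sigma = 0.02 Gaussian noise on Wn and 50
frames, tau is recovered within 10% in >= 95% of replicates. A series
whose relative range is below 2% is flagged degenerate (tau
meaningless). The fit is equivariant under time translation.

Aster cores are segmented from the kinesin channel by Otsu threshold
(per frame; binary inputs are taken as-is) and 26-connected labelling;
each core is characterised by intensity-weighted centroid, voxel
volume, and the eigenvalues of the intensity-weighted second-moment
tensor in physical um². The "moment ratio" is the major/minor
*eigenvalue* (variance) ratio — a 2:1:1 axis-SD blob gives 4 — with a
`moment_ratio_sqrt` switch for the aspect-ratio reading.

## Surface extraction and roughening statistics

Condensate surfaces are segmented by a morphological active contour
(region-based Chan–Vese by default, edge-based geodesic variant
selectable) initialized from an Otsu mask (largest component, closed),
then meshed by marching cubes at the 0.5 level in physical um
(anisotropic voxels honoured). The raw binary-mask isosurface
overestimates area by ~8–10% through voxel staircasing, so the mesh is
Taubin-smoothed (20 iterations; volume change < 0.1%); with that, a
clean 20 um sphere is recovered with < 1% area and volume error and a
5%-noise volume within a few percent.

Per-vertex normals are area-weighted face-normal averages; mean
curvature uses the cotangent Laplace–Beltrami mean-curvature normal
with barycentric vertex areas, signed positive for a sphere with
outward normals (sphere: median H within 0.3% of 1/R; cylinder:
1/(2 rho); plane: 0).

The normal-normal correlation C(Lambda) is the (area-weighted, by
default) average of n̂(r)·n̂(r') over vertex pairs whose geodesic
separation falls in a Lambda bin; the denominator <n̂·n̂> = 1 for unit
normals but is retained for robustness. Geodesics are shortest paths on
a chordal neighbour graph containing 1-ring *and* 2-ring links: pure
edge-graph distances overestimate geodesics by a direction-dependent
lattice factor of up to 2/sqrt(3) ≈ 1.15, which is a constant-factor
(not mesh-refinement) error; the 2-ring stencil reduces the worst-case
distortion to ~4%, and on a refinement-4 icosphere the measured curve
deviates from the exact cos(Lambda/R) by at most 0.019. The stencil
width is exposed (`rings`) for swapping the distance backend. Empty
bins beyond the mesh diameter are reported as missing (NaN), never as
zero. When the overall shape would dominate (flattened networks), the
mesh is first bisected by the plane through the area centroid normal to
the smallest-extent principal axis and each sheet is analysed
separately; for compact condensates bisection is off.

Correlation lengths come from least-squares fits of
c0 + c1 exp(-Lambda/l) over a chosen Lambda range; non-decaying curves
are flagged with l = inf. The plateau c0 is poorly constrained when the
fit range spans less than ~3 decay lengths — noisy-recovery tests
sample to ~4 l for that reason.

## Shell/interior partition and the flux balance

A segmented condensate is split into a surface shell (voxels within
thickness d — default 5 um — of the boundary, by an anisotropy-aware
Euclidean distance transform, measured inward only) and the interior.
The areal surface density <rho_S> divides the shell intensity by the
*mesh area* A, not the shell voxel volume, so that the dilution term
<rho_S> dA/dt means what it should; V is the *interior* volume, making

    A d<rho_S>/dt + <rho_S> dA/dt = Phi_{V->S} = -V d<rho_V>/dt - <rho_V> dV/dt

exactly the two sides of global mass conservation. Derivatives are
central differences on optionally moving-average-smoothed series
(default window 3 frames); the residual of the balance is always
reported. On synthetic condensates with a prescribed constant flux the
full pipeline (level-set segmentation -> partition -> densities ->
derivatives) recovers Phi within ~1% and keeps the conservation
residual below 2% of Phi; the zero-flux control returns |Phi| three
orders of magnitude below the mass-turnover scale.

## Nematic order

The local bundle orientation theta is the minor eigenvector of the
structure tensor (Gaussian scale default 2 um, about the bundle width),
with coherency (l1 - l2)/(l1 + l2) as a confidence measure. The
analysis mask combines an Otsu intensity mask (the structure's
interior) with a coherency floor (default 0.2). The mean orientation is
the circular mean of the doubled angle — required by the theta ~
theta + pi symmetry — and the order parameter S = <cos 2(theta -
theta_bar)> is computed as the mean resultant length of 2 theta, hence
S in [0, 1] by construction, unweighted over the mask (coherency or
intensity weighting would change the estimand; a weighted variant is a
one-line change on the masked angles).

Estimator caveat: the structure tensor averages *tensors* within its
smoothing window before eigen-decomposition. When several differently
oriented filaments cross inside one window, the per-pixel orientation
distribution sharpens toward the local mean and S is biased upward at
intermediate order (we measure S ≈ 0.77 on dense textures constructed
with S* = 0.6). The bias vanishes at both endpoints (S* = 0 and 1) and
in sparse textures (~1 filament per window), where S* = 0.6 is
recovered within ±0.05. Time series on projections therefore rank
order correctly but compress contrast at mid-range order.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed) and reproduce
bit-identically; every parameter, including derived schedules, is
recorded in a JSON-serializable `GroundTruth`.

* **Asters** — kinesin core: isotropic Gaussian (sigma 1 um); filament
  tips drawn from the core distribution, oriented radially outward,
  lengths log-normal(1.4, 0.6); anti-aliased line integration deposits
  constant intensity per unit length (profiles are grid-robust).
* **Bilayers** — thin Gaussian motor sheet; tips uniform in the sheet,
  filaments along ±normal with equal probability.
* **Contraction** — slab whose width follows the exponential law
  exactly, with optional edge accumulation; per-frame intensities are
  rescaled to identical totals (conservation to machine precision).
  The default grid is fine (0.5 um) along the width axis so FWHM
  tracking resolves Wn to < 0.5%.
* **Roughening condensates** — a sphere (R = 20 um) perturbed radially
  by a fixed band-limited random spherical-harmonic field (degrees
  2–4), amplitude following a schedule; mass is split between a shell
  and interior so the shell mass integrates the prescribed flux
  Phi*(t) exactly. The surface shell defaults to half the total mass so
  both compartments are comparably bright — a contrast regime in which
  threshold/level-set segmentation keeps the condensate whole, as in
  the real system where the surface layer densifies. A slab base shape
  is not implemented.
* **Aligned textures** — 2D segments whose orientations come from a
  mixture (probability S*: the common director; otherwise uniform),
  whose doubled-angle resultant is exactly S*; defaults: 5000 segments
  of 15 um in a 512 um field, mild blur.
* **Noise** — optional Poisson photon noise and Gaussian read noise as
  a fraction of the signal peak, clipped at zero. No camera model is
  published for this system; the defaults are conservative
  placeholders.

Not emulated: motor stepping and filament sliding dynamics,
photobleaching, chamber-wall optics, aster merging/identity, the
zippering mechanics of bilayer formation. Passing tests therefore
demonstrate that the *measurement pipeline* is unbiased on data obeying
the stated models at realistic SNR and resolution — not that the
biological system obeys them.

## Problem sizes

Defaults are chosen so the full validation (test suite plus acceptance
reruns) completes in a few minutes on one core: 80³–96³ voxel volumes
at 0.5–1 um, 8–20 frames per sequence, refinement-4 icospheres (2562
vertices) for geodesic statistics, 1024² orientation images. All scale
up by parameters only.
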
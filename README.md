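# microphase

Quantitative image analysis for **active microphase separation** in
mixtures of microtubules and tip-accumulating kinesin-4 motors.

Kinesin-4 walks to microtubule plus ends and accumulates there, turning
each filament into an amphiphile-like building block: motor-rich tip,
motor-poor body. Depending on filament concentration these mixtures
condense into radial **asters** with compact kinesin cores, globally
contracting networks that mature into flat **bilayers** (a 2D motor
sheet with filaments along ±normal), or condensates whose smooth
surface **roughens** while material fluxes from the interior to a
dense surface monolayer. This package provides the measurements those
phenomena call for, plus seeded synthetic-data generators with full
ground truth so the whole pipeline is testable without any microscopy
data:

* **Structure models** — tip-anchor forward model `I_ideal = g * K`,
  convolving a kinesin profile `g` with the filament-length survival
  function `K(x) = P(L > x)` (log-normal length law, `M = 1.4`,
  `S = 0.6`); radial/axial profile extraction from volumes.
* **Kinetics** — network width tracking and fits of the contraction law
  `Wn(t) = Wn∞ + e^{-(t-t0)/τ}(1 - Wn∞)`; 3D aster-core morphometrics
  (volume, second-moment eigenvalue ratios).
* **Surface geometry** — morphological level-set segmentation, marching
  cubes meshing, area/volume, cotangent mean curvature, and the
  geodesic normal–normal correlation
  `C(Λ) = ⟨n̂(r)·n̂(r+Λ)⟩ / ⟨n̂·n̂⟩` with exponential correlation
  lengths.
* **Density partition** — surface-shell vs interior split and the mass
  balance `A ∂t⟨ρS⟩ + ⟨ρS⟩ ∂tA = Φ_{V→S} = -V ∂t⟨ρV⟩ - ⟨ρV⟩ ∂tV`.
* **Nematic order** — structure-tensor orientation fields and
  `S = ⟨cos 2(θ - θ̄)⟩` (0 isotropic, 1 perfectly aligned).

## Worked example

Generate a contracting slab network (width follows the exponential law
with τ = 20 min, Wn∞ = 0.3 exactly; total fluorescence conserved) and
recover the contraction parameters from the images:

```bash
$ microphase simulate contraction --out demo/seq --seed 1
wrote contraction dataset to demo/seq
$ microphase contract --seq demo/seq --axis 2 --level 0.5 --out demo/res
tau=20.06 min  t0=0.01 min  Wn_inf=0.300
```

The fitted timescale (20.06 min) and plateau (0.300) match the
generating parameters to 0.3%: the FWHM width tracker plus the
nonlinear fit recover the contraction law from the rendered volumes.
The same session in Python, plus the length-law statistics:

```python
>>> from microphase import LengthDistribution, lognormal_stats
>>> s = lognormal_stats(LengthDistribution(1.4, 0.6))
>>> print(f"mean = {s['mean']:.1f} um, mode = {s['mode']:.1f} um")
mean = 4.9 um, mode = 2.8 um
```

Other presets: `simulate aster`, `simulate bilayer`,
`simulate roughening` (condensate with prescribed interior→surface
flux), `simulate aligned`; analysis commands `profile`, `asters`,
`surface`, `correlate`, `flux`, `order`. Every command is a thin
wrapper over the library (`microphase.structure`, `.kinetics`,
`.surface`, `.partition`, `.nematic`, `.synthetic`).

## Documentation

`docs/methods.md` describes the models, estimators, numerical choices,
and the limits of what the synthetic validation demonstrates.
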
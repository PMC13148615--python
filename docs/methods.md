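# Methods

## Scope and model

The package studies how the topology of a modulating membrane affects the
quality of images retrieved by single-mask X-ray imaging on a low-coherence
cone-beam bench.  Everything is referred to the detector through the plane
magnifications of a point-source geometry: membrane at 0.33 m from the
source, sample at 0.55 m, detector at 1.35 m (z₂ = 0.80 m behind the
sample), 75 µm pixels, 8.6 keV design energy, 50 µm source spot, and a mean
exposure of 75 000 counts/pixel with Poisson noise.  Simulation grids are
detector-conjugate with an integer oversampling factor (default 4); the
physical pitch at each plane is the detector pixel divided by that plane's
magnification times the oversampling.

### Membranes

Four point-pattern topologies at a common design spacing *s* (the mean
peak-to-peak modulation distance on the detector, in pixels): a square grid
of pitch *s*; a triangular (honeycomb) lattice of pitch *s*; a Vogel spiral
(r = c√k, θ = k·golden angle) with c = s/√π so its areal density matches
the square grid; and a sandpaper-like random pattern.  Modulations are
linearly tapered cones; drilled Ni-foil hole plates are the second
profile, matching the experimental style of membrane.  Per-point diameters
are drawn uniformly from 0.7–1.3 × s for *every* topology — the membranes
are built from cones of variable diameter, and making only the random
family variable would confound amplitude with topology.

The default cone material is nickel, not silica, and this is a deliberate
physical choice: the topology study holds the modulation *amplitude* fixed
while sweeping the modulation *size*, which is only true of a
fixed-height cone if the membrane is absorption-dominated (apex
transmission `exp(−µh)` is then size-independent).  Low-Z cones at
8.6 keV cannot reach a usable absorption amplitude without becoming steep
phase objects whose lensing — and at small sizes, caustics — makes the
amplitude vary strongly with size.  Micrometre-scale Ni cones (the same
metal as the drilled experimental masks) are absorption-dominated with
gentle slopes, so the study's stated design is physically realized.

The random membrane emulates an abrasive coating: grains deposited in
clusters (Thomas process, 4 grains/cluster on average, cluster scatter
1.5 s) with a hard core of 0.6 s (a grain monolayer — grains cannot
interpenetrate; multi-layer stacks are out of scope) and a target density
of 0.85/s².  These defaults were calibrated once so that the packing
density map of the rendered reference image shows the features reported
for real sandpaper membranes: a mean modulation density clearly below the
structured patterns and a much larger spatial spread.  A plain
dart-throwing generator (`gen_random_points`) is also provided and is the
oracle for the uniform-density tests.

The cone height sets the modulation amplitude.  The default (5 µm of Ni)
was fixed once so the simulated reference-image visibility (std/mean)
sits mid-way in the 5–20 % working band at the default 4 px spacing under
the full forward model; the 200 nm SiO₂ value quoted for the physical
membranes is kept as a preset (`PAPER_CONE_HEIGHT_UM`) but gives ~0.1 %
contrast at 8.6 keV, which no retrieval can use.

### Forward models

`warp` (default) is a geometric ray-optics model with intensity
transport.  Every feature on this bench — 60–100 µm modulations, ≥ 2 px
sample structures — has a Fresnel number of several tens with respect to
its effective propagation distance, so ray optics is the accurate regime
and diffraction a correction well below the Poisson noise.  The reference
pattern is the membrane's Beer–Lambert transmission *refracted by its own
relief*: rays deflect by `α = −δ∇t` and travel the membrane–detector
distance, which both displaces the pattern and locally crowds or dilutes
rays (first-order Jacobian `1/(1+∇·D)`, clipped at caustics) — this is
what turns cone rims into the bright/dark fringes that carry most of the
usable gradient.  After source blur (FWHM·(M−1) at the detector), the
sample arm applies the sample's transmission, its refraction displacement
field with the same Jacobian transport, and any oriented dark-field
diffusion kernel the phantom declares.  The displacement convention is
`D_px = z₂·α/p` with `α = −δ∇t` evaluated in sample-plane coordinates;
this is also what `theoretical_displacement` returns and what converts to
refraction angles via `α = D·p/z₂` (1 px ↔ 93.75 µrad at the default
geometry).  With the Jacobian and mask-refraction terms the generator is
*not* the model the LCS inverts: retrieval errors contain a deterministic,
membrane-locked component alongside Poisson noise, as on a real bench.

`fresnel` is a single-effective-plane wave-optical model (projection
screens, amplitude `exp(−µt/2)`, phase `−2πδt/λ`, propagated z₂/M in the
demagnified frame).  It exists as an independent cross-check of the
displacement physics — the warp/Fresnel consistency test drives a
constant-displacement wedge through both — but it is *grid-limited*: a
millimetre-thick nylon phantom or a 100 µm SiO₂ cone carries several
radians of phase per raster cell at any affordable oversampling, so for
the full-strength scenes its refraction transfer aliases away.  It is
therefore not used for the experiment protocols, only for thin/gentle
screens where its sampling criterion holds.  Dark-field diffusion is a
warp-model feature only — there is no reliable wave-optical generative
model for it.

### Phantoms

Six nylon phantoms with the study dimensions: a 1.5 mm wire along x (so
its refraction lives in D_y, the scored component), a 12 mm sphere, a 7 mm
cube, a 13/3/3 mm torus (elliptical tube cross-section — the only shape
consistent with all three printed diameters), a Shepp–Logan slab
(18 × 13 mm landscape, thickness mapped linearly to 1–5 mm) and an
escape-time Julia fractal (18 × 10 mm window, max 5 mm, c = −0.4 + 0.6i).
On reduced desk-scale fields the phantoms are scaled as solid objects
(footprint and thickness together), which preserves the displacement
distribution the full-scale scene would produce; thickness maps get a
half-pixel Gaussian rasterization antialias, standing in for the finite
edge slope of machined or printed parts.

## Retrieval

Per pixel, K rows `[I_r, ∂x I_r, ∂y I_r, −∇²I_r] · [I_obj, D_x, D_y, D_f] =
I_r − I_s` (second-order central differences, 5-point Laplacian, one-sided
at the flagged border).  The published coefficient convention is not
printable from the source material, so this linearization — which fixes
sign conventions such that attenuation, displacement-in-pixels and
blur-variance are all non-negative in their pure cases — is the package's
documented convention.  The normal equations are damped by a *relative*
Tikhonov term (10⁻³ of each diagonal entry, plus a tiny absolute floor): a
fixed absolute damping of the same nominal size would be ~10 % of the
gradient columns' scale at 75 000 counts and would visibly bias D and
crush D_f.  Pixels whose undamped normal matrix has condition number above
10⁸ are flagged, solved by the damped system, then replaced by a
normalized-convolution estimate from their neighbours; their count is
reported.  An optional window parameter pools the normal equations over a
w×w neighbourhood (default 1 = the pure per-pixel method).  The tensor
variant replaces the Laplacian column by `(−∂xx, −2∂xy, −∂yy)` (6 unknowns,
K ≥ 6) and clips non-PSD pixels to the nearest PSD tensor.

Phase is integrated from (D_x, D_y) with the Frankot–Chellappa
least-squares solver after conversion to per-cell phase increments, and is
reported zero-mean (it is defined only up to a constant).

## Image quality

NRMSE (`‖D−D₀‖/‖D₀‖`), SSIM (uniform 7×7 window, k₁ = 0.01, k₂ = 0.03, L =
dynamic range of the stacked pair — cross-checked against scikit-image),
MS-SSIM (5 dyadic scales, standard weights, truncated and renormalized on
small images), SR-SIM and VSI.  The latter two need a visual-saliency map;
the spectral-residual model is used for both (the colour-prior saliency of
the original VSI formulation has no meaning for single-channel
displacement maps), with the constants of the respective reference
descriptions frozen in the signatures.  All indices operate on
displacement maps, not phase — displacement is the directly estimated
quantity, and integration would smear local errors across the field.

FRC uses 1-bin rings, no apodization, mean-subtracted inputs, and linear
interpolation at the 1/7 crossing; two *independent realizations* (fresh
shifts, fresh noise, same membrane — re-imaging the same physical
membrane) provide the two maps.  If the curve never crosses, the Nyquist
limit of 2 px is reported with a flag.  Angular sensitivity is the mean ±
standard error over eight 5×40 px windows, auto-placed outside the phantom
support (dilated by 10 px, 8 px off the borders), of the per-window std of
`α_y = D_y·p/z₂`, in nanoradians.

## Diagnostics

Gradient statistics use magnitude-weighted orientation histograms (36
bins); the isotropy test treats the number of modulations — not the number
of pixels — as the effective multinomial sample size, since gradients
within one modulation are strongly correlated.  Packing density detects
modulation centers as prominence-filtered local maxima of a
difference-of-Gaussians band-pass tuned to the design spacing, counted in
32 px sliding windows (stride 8).

## Desk-scale protocol sizes

The experiment protocols run at reduced fields chosen to keep a full
reproduction within a desktop budget while leaving every ranking
mechanism intact: 512² for the FRC protocol, 256² for the modulation-size
sweep, the six-sample comparison and the angular-sensitivity table, 192²
for the dark-field comparison.  K = 10 pairs, 50–150 px membrane shifts
(x-only except the sweep, which uses both axes), one replicate.

## What the generator does and does not emulate

It emulates: cone-beam magnification and source blur, Poisson counting
statistics at the stated exposure, membrane-locked artifacts via wave
optics, the measured packing inhomogeneity of sandpaper membranes, and
oriented sub-pixel scattering (as a linearized diffusion kernel).  It does
not emulate: polychromaticity (monochromatic design energy; the constants
table carries smooth far-from-edge energy scaling), detector point spread
or charge sharing, scatter from the chamber, membrane thickness errors, or
any physical dark-field microstructure — so passing tests demonstrate the
relative behaviour of topologies under this model, not absolute agreement
with bench measurements.

## Noise-limited versus bias-limited regimes

At the stated exposure (75 000 counts/pixel, K = 10) the per-pixel
retrieval's displacement noise is of order 10⁻² px.  The strong phantoms
(millimetre thicknesses) produce edge displacements of order 1 px, beyond
the validity of the first-order optical-flow model, so whole-field NRMSE
on these scenes is dominated by *deterministic linearization bias* at
edges rather than by photon noise.  Two consequences worth knowing when
interpreting the protocol outputs: (i) the modulation-size sweep minimizes
bias, which keeps improving toward larger, smoother modulations (optimum
near 8–12 px here) instead of the noise-limited optimum a lower-noise
processing chain finds near 3–6 px; (ii) two independent realizations
share the bias, so the Fourier ring correlation can stay above the 1/7
threshold to Nyquist (reported as the flagged 2 px bound) even when the
noise floor alone would cross earlier.  The topology *orderings* —
the spiral membrane's advantage, the honeycomb's single-axis degeneracy,
the sandpaper pattern's packing penalty — are unaffected by which regime
dominates, and are the quantities the acceptance protocols assert
strictly.

## Known limitations

- Per-pixel retrieval at 75 000 counts/pixel with K = 10 has a
  Cramér–Rao-bounded displacement noise of order 10⁻² px (≈ 10³ nrad)
  at 5–20 % visibility; absolute angular sensitivities and FRC crossings
  therefore sit well above what a processing chain with spatial averaging
  would report, and should be compared between topologies, not across
  instruments.  The topology *ordering* is the robust observable.
- The square and hexagonal membranes under single-axis scanning produce
  rank-deficient pixels whose error is split between reproducible
  lattice artifacts and amplified noise; how much lands in each depends
  on the regularization, and the FRC of these membranes is accordingly
  fragile.
- NRMSE on phantoms with near-vertical edges (cube, full-thickness
  fractal) is dominated by displacement spikes beyond the linear regime
  of any optical-flow retrieval; differences between good topologies on
  such phantoms are at the noise level.
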
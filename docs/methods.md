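# Methods

`corrmicro` simulates and analyses a correlative microscopy experiment in
which the same adherent cell is imaged by three modalities sharing one
coordinate frame: confocal/STED fluorescence of the labeled actin
cytoskeleton, full-field in-line X-ray holography of the projected
electron density, and scanning small-angle X-ray scattering (SAXS) with a
nano-focused beam. This note records the models, the parameters that
matter, and the design choices made where more than one reasonable option
existed.

## Synthetic cell phantom

The phantom (`corrmicro.phantom`) is a 2D projected-density model of a
freeze-dried cardiac tissue cell:

* **cytoplasm envelope** — an ellipse elongated along the cell's main
  axis (semi-axes 0.42 x 0.30 of the field of view), with a flat plateau
  and a super-Gaussian edge; default amplitude 0.15 (arbitrary density
  units).
* **nucleus** — a centered ellipse with the projected-ellipsoid profile
  `sqrt(1 - rho^2)`, peak amplitude 1.0, plus a chromatin-like granular
  texture (Gaussian-filtered white noise, 150 nm correlation FWHM,
  amplitude 0.25, confined to the nuclear footprint). The texture matters:
  a smooth nucleus scatters only below the beamstop cutoff, whereas in
  real cells the nucleus is the strongest dark-field feature.
* **filament bundles** — straight chords of the envelope ellipse with
  Gaussian cross-sections, widths drawn uniformly from 100–400 nm (FWHM),
  amplitude 0.5, orientations from a wrapped normal around the main axis
  (default 30° ± 15°). A configurable fraction (default 0.7) carries
  fluorescent label; the nucleus and envelope are always unlabeled.

The phase map is strictly proportional to density, `phi = -c * rho_proj`
with `c = 0.4` rad per density unit by default, consistent with a pure
phase object at hard X-ray energies (peak |phi| ~ 1.3 rad at the nucleus,
~0.2 rad on a single filament). All randomness flows through
`numpy.random.default_rng(seed)`; regeneration is bit-identical.

Orientation convention used throughout the package: angles in degrees in
[0, 180), measured from the +y (column/horizontal) axis; image arrays are
indexed `[z (row), y (column)]` with the origin at the top-left.

### What the phantom does and does not emulate

It reproduces the *structural relationships* the analysis chain exploits:
labeled and unlabeled components, oriented bundles that scatter
anisotropically, a dense nucleus that dominates the dark field but is
invisible in fluorescence. It does **not** model 3D structure,
polychromaticity, partial coherence, detector point-spread functions, or
radiation damage. Tests passing on the phantom therefore validate the
algorithms and their couplings, not the instrument; absolute values such
as the resolution cross-overs depend on the synthetic photon budgets and
are not comparable to measured instrument values.

## Holography

**Geometry.** A divergent beam from a point source at distance `z1`
upstream and a detector at `z2 ~ 5 m` downstream is reduced to the
parallel-beam equivalent by the Fresnel scaling theorem: magnification
`M = (z1+z2)/z1`, effective pixel `p_eff = p/M` (detector pixel
p = 6.5 um), effective distance `z_eff = z1 z2/(z1+z2)`. Photon energy
13.8 keV (lambda = 0.08984 nm). Simulation and reconstruction both work
in this effective frame; holograms of phantoms are produced by resampling
the phase to `p_eff`, applying `exp(i phi)`, and Fresnel-propagating by
`z_eff`.

**Propagation.** Transfer-function (Fourier-multiplier) propagation with
kernel `exp(-i pi lambda d |nu|^2)` and forward DFT kernel
`exp(-i 2 pi nu r)`. The multiplier is unimodular, so energy is conserved
and back-propagation is the exact inverse. A sampling guard rejects
kernels whose phase changes by more than pi between adjacent frequency
samples (`lambda |d| >= N p^2`), and hologram simulation additionally
requires the per-pixel Fresnel number `p_eff^2/(lambda z_eff)` to lie in
[1e-4, 10]. The default demo geometry `z1 = 125 mm` gives
`p_eff = 158.5 nm`, alias-free at 512^2; smaller `z1` (finer `p_eff`)
requires proportionally larger grids.

**CTF inversion.** For weak phases the hologram spectrum is
`F[I-1] = 2 sin(chi) F[phi]`, `chi = pi lambda z_eff |nu|^2`. The inverse
filter `sin(chi) / (2 sin^2(chi) + alpha)` uses a two-level Tikhonov
`alpha`: `alpha_low = 1e-3` below the first CTF maximum, `alpha_high =
1e-1` above (defaults; noiseless tests use 1e-6). The DC coefficient is
untransferred (`sin chi = 0`), so the phase is recovered up to a global
offset; the optional `zero_border` correction pins the mean phase over an
empty border frame to zero. With it, noiseless weak-object inversion
reaches ~2% NRMSE; without it the missing offset alone costs ~8%.

**Support.** Gaussian-smooth the CTF phase (FWHM 6 px), threshold at 10%
of the most negative value, keep the largest connected component,
morphologically close and dilate (4 px). The dilation deliberately
over-covers: a slightly generous support is harmless to RAAR, a clipped
one is not.

**RAAR.** Object-plane iterate with `u <- beta/2 (R_S R_M + I) u +
(1-beta) P_M u`; `P_M` enforces the measured modulus in the detector
plane, `P_S` enforces unit amplitude, zero phase outside the support, and
(switchable, on by default) non-positive phase inside. Initialized from
the CTF phase. `beta` accepts a constant or a per-iteration schedule.
On noiseless data `beta = 0.99` converges fastest and is the default
(disc test: truth correlation > 0.9999 after 500 iterations). On
Poisson-noisy holograms the two constraint sets do not intersect and
near-unity beta drifts (residual grows ~10x, truth correlation drops to
~0.89); the demo configuration therefore uses `beta = 0.7`, measured to
give truth correlation ~0.999 on the same data. A guard aborts if the
magnitude residual exceeds 10x its initial value.

## Scanning SAXS

Frames are simulated per scan position as `|FFT(A exp(i phi_local))|^2`
with a unit-power Gaussian illumination A (300 x 300 nm^2 intensity
FWHM), scaled to `I0 * t = 1.1e11 ph/s x 0.05 s` incident photons, plus a
uniform background (10 counts/pixel/s), Poisson-sampled, and masked by a
centered 20 px beamstop disc and two 17 px horizontal module-gap stripes.
The q-calibration is constructed so the physical formula
`|q| = (4 pi/lambda) sin(atan(r/D)/2)` matches the FFT grid spacing in
the small-angle limit (relative difference ~1e-5 over the simulated
range). The detector window is 128^2 at the phantom pixel size: with the
default beam this puts the beamstop edge at ~6 sigma of the direct beam,
so beamstop leakage (<1 photon/frame) is negligible against the
background — a wider window (finer q per pixel) moves the beamstop edge
into the beam tail and floods the dark field, which is why window and
beamstop radius must be chosen together.

Simulated q extends to `pi/40 nm = 0.079 nm^-1` (set by the 40 nm phantom
pixel), a scaled-down range compared with a real nanodiffraction
experiment; the phantom contains no structure below ~100 nm, so nothing
is lost, and the PCA annulus default (q <= 0.8 nm^-1) simply includes all
simulated pixels.

Reductions:

* **dark field** — exact masked sum of counts per position (photons;
  divided by exposure only when compared to the validity threshold
  `I_df = 7.5e5 ph/s`).
* **PCA anisotropy** — intensity-weighted second moments of `(q_y, q_z)`
  about q = 0 (no mean subtraction: small-angle patterns of real-valued
  densities are Friedel-symmetric, so the centroid vanishes up to noise);
  weights are background-subtracted, non-negative counts. Eigenvalues
  `l1 >= l2` give `omega = (l1-l2)/(l1+l2)`; the principal axis angle is
  reported both in reciprocal space and rotated by 90° into real space
  (fibers scatter perpendicular to their axis). Exactly isotropic
  patterns return omega = 0 with an undefined (NaN) direction.
* **azimuthal average** — mean counts per |q| annulus over valid pixels,
  empty bins flagged NaN.

## Resolution estimation

The azimuthally averaged power spectral density of each modality's image
is computed (mean subtraction, Hann window by default, `|FFT|^2/Npix`,
radial bins of width `1/(N px)`), with the frequency axis rescaled to
`q = 2 pi nu`. A power law `a q^b` is fitted by least squares in log-log
over a configured signal range, a constant floor `bgr` as the mean over a
configured noise range, and the cross-over solves `a q_i^b = bgr`;
`d_cr = pi/q_i` is the smallest structure size attributable to signal.
Fit ranges are explicit configuration (defaults 0.004–0.018 and
0.05–0.078 nm^-1 for the 40 nm-pixel fluorescence images); there is no
automatic range selection. The fluorescence diffraction limit
`d_min = lambda_fl/(2 NA)` (651 nm, NA 0.95 -> ~343 nm) sets the confocal
PSF; the STED PSF is confocal/3 by default, reflecting a typical
depletion gain at this NA rather than a calibrated instrument value.

## Filament tracing

A deliberately simple tracer, validated against phantom ground truth
rather than reproducing any published implementation: zero-mean
elongated-Gaussian matched filters at 18 evenly spaced orientations give
per-pixel ridge strength; the strength map is thresholded at the 0.975
quantile (quantile-based, hence invariant to intensity scaling),
skeletonized, cut at junction pixels (more than two skeleton neighbors,
keeping branch orientations well-defined), and each branch of at least
8 px is fitted by a straight segment via its principal axis. Reported
orientations agree with segment endpoints by construction and recover
single synthetic lines to < 2°. Curved filaments are approximated
piecewise by the junction cutting; width estimation and sub-pixel
localization are out of scope.

## Registration and agreement

Images are brought to a common pixel size by exact area-weighted
rebinning (flux-conserving for counts, mean-preserving for phase), then
registered by Fourier phase cross-correlation with 100x sub-pixel
upsampling; accuracy on constructed shifts is better than 0.1 px. The
demo simulates a known integer stage offset between the holography and
fluorescence frames and recovers it. Filament-vs-SAXS agreement assigns
each traced segment to the 1 um scan cells it crosses (dense sampling at
step/20), computes the length-weighted circular mean filament orientation
per cell, and reports the circular distance (in [0, 90]°) to the SAXS
real-space principal axis at valid cells, summarized by the median and
the fraction below 20°.

## Pipeline, seeds, problem sizes

`run_demo` executes the full chain on a 512^2 phantom at 40 nm pixels
with a 16 x 16 scan at 1 um steps and 500 RAAR iterations (~45 s on one
CPU; the test suite uses a 256^2 / 6 x 6 / 40-iteration variant). These
sizes were chosen as the smallest at which every stage operates in its
intended regime — the scan resolves the filament network, the hologram
grid is alias-free, and dark-field thresholding separates cell from
background. One master seed deterministically derives per-stage seeds
(`numpy.random.SeedSequence`), so individual stages can be re-run
reproducibly; re-running the demo with the same configuration is
bit-identical, and every artifact is listed with its SHA-256 in
`manifest.json` together with the configuration hash.

## Known limitations

* Single-distance holography only; no multi-distance or astigmatic
  retrieval, no absorption.
* The SAXS simulation is a thin-sample, single-scattering Fourier model
  on the phantom grid; no absolute intensity calibration or detector
  distortion.
* PCA weighting and the background-frame protocol are simple documented
  choices (uniform background rate; off-cell frames usable as
  backgrounds); alternatives would change omega quantitatively but not
  the orientation analysis.
* The filament tracer is a functional stand-in; on dense crossings it
  fragments segments rather than resolving overlaps.
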
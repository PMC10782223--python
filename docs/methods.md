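# Methods

## Model

A polycrystalline foil contains many randomly oriented crystallites; each
crystallite at the Bragg condition contributes lattice fringes of spacing
`d`, and the ensemble traces a ring of radius `r = L·P/d` pixels in the
`L×L` power spectrum of a micrograph with magnified pixel size `P` (Å).
Measuring `r` therefore measures `P` absolutely, given `d`.

Supported reference materials:

| material | system | constants (Å) | key reflection |
|---|---|---|---|
| fcc gold | cubic | a(T) thermal model | (111), 2.35 Å at room T |
| hcp gold | hexagonal | a = 2.88, c = 4.96 | (002), 2.48 Å |
| graphitized carbon | cubic (parametrization) | a = 5.92 at 81 K | (111), 3.42 Å |

d-spacings use the standard formulas `d = a/√(h²+k²+l²)` (cubic) and
`1/d² = (4/3)(h²+hk+k²)/a² + l²/c²` (hexagonal, three-index convention).
Graphitized carbon is *modelled* as cubic with a = 5.92 Å purely so that
its (111) spacing reproduces the measured 3.42 Å peak; it is a
parametrization, not a structural claim. For the mixed index (1,−1,−1) of
hcp gold, note that the sign reading matters under the three-index
formula: (1,−1,−1) gives 2.23 Å, (−1,−1,1) does not.

The fcc gold lattice constant follows the linear law
`a(T) = 4.0611 + 5.67075e-5·T` (Å, T in K). Below 43 K the constant is
held at the measured 4.0636 Å: thermal contraction flattens out at low
temperature and the linear law overshoots. The hard switch leaves a
~6×10⁻⁵ Å discontinuity at 43 K (the clamp value is a measurement, not a
point on the line); this is accepted and documented rather than smoothed,
since no functional form for the roll-off is available. hcp gold and
graphitized carbon carry no thermal model (no data).

## Calibration pipeline

Per micrograph:

1. **Power spectrum** — |FFT|² of the mean-subtracted image, DC-centred at
   index (L/2, L/2); radii are measured from that bin. No apodization by
   default (windowing broadens Bragg peaks); zero-padding and a Hann
   window are available as options.
2. **Noise whitening** — a degree-5 polynomial is fitted to
   log(radial profile) vs radius with windows of ±10% around every
   expected Bragg ring excluded, then exponentiated into an isotropic 2D
   background which divides the spectrum. The whitened noise floor
   fluctuates about 1. Whitening prevents the decaying background from
   pulling weak-peak maxima toward the centre (which would bias `P` low);
   a fit is refused if the exclusion windows cover more than 80% of the
   usable radii.
3. **1D ring search** — the whitened radial profile is searched within
   ±5% (configurable) of the expected radius `L·P_nom/d`. The discrete
   argmax (ties broken toward the larger radius, i.e. the fcc ring) is
   refined by 3-point parabolic interpolation. A peak must exceed 4× the
   background scatter; the baseline and scatter are robust (median/MAD)
   estimates from the sidebands flanking the window, because a broad peak
   can fill the window itself. The two sidebands are compared and, if
   their medians disagree (a neighbouring ring contaminating one side),
   the quieter side is used. No peak ⇒ the micrograph is rejected with a
   recorded reason, never silently used.
4. **Mixed-lattice check** (fcc gold only) — the profile is also searched
   at the hcp (002) position (2.48 Å). A candidate found there is assigned
   to the nearer of the two expected rings by relative radius (the rings
   are only 5.5% apart, so the fcc flank can intrude into the hcp
   window); if a genuine hcp peak is stronger than the fcc peak the
   micrograph is flagged `mixed_lattice`.
5. **Azimuthal wedges** — the annulus around the 1D radius is split into
   36 wedges; each wedge's radial profile yields a sub-pixel radius. The
   wedge radius is an iterative intensity centroid of the
   baseline-subtracted profile rather than a parabola: within one wedge
   the "ring" is a handful of discrete crystallite spots, and an argmax
   locks onto the brightest speckle (≈1.4 px rms scatter on noiseless
   synthetic data) whereas the centroid averages over spots (≈0.15 px).
   Three refinements keep the centroid unbiased: the window is re-centred
   on the running estimate (symmetric tail truncation), a linear baseline
   through the sidebands removes the residual background slope, and the
   weights carry a factor r to undo the 1/r annular dilution of a 2D peak
   (which otherwise biases the centroid inward by ≈2σ²/R). Wedges without
   a significant peak are dropped; fewer than 2/3 of them ⇒
   incomplete-ring rejection.
6. **Ellipse fit** — a centred ellipse `1/r² = p + q·cos2θ + s·sin2θ` is
   fitted by linear least squares (the centre is pinned to DC: Friedel
   symmetry makes the ring centro-symmetric, so a free centre only adds
   variance; a free-centre fit exists as a diagnostic). Fits require ≥8
   points spanning ≥240° of azimuth. Anisotropy is reported as
   100·(a−b)/mean; note that an axis ratio of 1.017 corresponds to 1.69%
   under this definition.
7. **Pixel size** — `P = r·d/L` with `r = √(semi_major·semi_minor)`. The
   geometric mean preserves area scaling under anisotropy. A larger ring
   radius means a larger pixel size, so the ellipse's major axis is the
   direction of larger magnified pixel size.

Across micrographs the unweighted mean, standard deviation σ and standard
error σ/√n are reported (a prominence-weighted mean is available).
Fitting each micrograph separately is the default because σ across
micrographs is itself a useful diagnostic; a single accumulated-spectrum
mode is provided and agrees with the per-micrograph mean on synthetic
data to ≈0.1%.

On isotropic synthetic data the fitted anisotropy has a small positive
floor (≈0.02–0.03% at default noise): the fitted cos2θ amplitude is the
magnitude of a noisy 2-vector and is Rayleigh distributed, so it cannot
average to zero.

## CTF error analysis and the Z40 estimator

Phase shift and CTF are the standard forms

    χ(q) = π λ Δz q² + (π/2) λ³ Cs q⁴
    CTF(q) = √(1−W²) sin χ − W cos χ

with underfocus negative, W = 0.04 by default, and λ the relativistic
electron wavelength (0.0197 Å at 300 kV). User-facing units are kV, mm,
µm and Å; everything internal is Å and radians, with the conversions
covered by tests.

A pixel size wrong by a fraction ε maps the signal at true frequency q to
assumed frequency q(1+ε); the resulting CTF error can be partially
compensated by refitting the defocus (q² term) but not the spherical
aberration (q⁴ term), so the residual error is small at low q and grows
toward Nyquist. The defocus refit minimizes the RMS CTF difference over
q ∈ (0, 0.9·Nyquist] — RMS of the CTF itself rather than of the phase,
since that is what CTF-fitting programs effectively match. The objective
oscillates in defocus, so a 401-point grid search brackets the global
minimum before bounded scalar refinement.

Aberration refinement absorbs a q⁴ phase error into the Z40 coefficient
of the even-Zernike expansion, Z40·(6ρ⁴ − 6ρ² + 1) with ρ = q/q_max (the
lower-order terms are cancelled by lower-order coefficients). Matching q⁴
coefficients against (π/2)λ³ΔCs·q⁴ gives

    ΔCs = 12·Z40 / (π λ³ q_max⁴),     P_true = P_nom (Cs_true/Cs_apparent)^¼.

The normalization radius q_max is not recorded in STAR output; the
default here is the Nyquist frequency of the nominal pixel size (the
natural detector-defined scale), exposed as `--qmax` because upstream
conventions may differ. Validation is by round trip (inject a ΔCs for a
known pixel error, recover it to 1e-10), which is independent of the
convention chosen.

## Synthetic data

The generator emulates exactly the features the estimators consume:

- **Crystallites** — `n` seed points with nearest-seed (Voronoi) regions,
  each clipped to a disk of radius `crystallite_scale`; every crystallite
  carries one cosine fringe with random orientation and phase at period
  `d/P` pixels. Cosines reproduce Bragg peak positions exactly, which is
  all the estimators use; dynamical diffraction contrast is deliberately
  not modelled.
- **Defaults** mirror a 300 kV counting-mode exposure of a HexAuFoil-like
  support: 1024² pixels at 0.6484 Å, 200 crystallites of ≈48 px (≈3 nm —
  the small-grain regime that makes such foils good calibration
  specimens), fringe contrast 0.5, ≈25 counts/pixel (60 e⁻/Å² on a
  0.65 Å pixel) with Poisson statistics, and an isotropic spectral
  background with power envelope exp(−r/150 px) at 10% rms standing in
  for detector MTF and low-angle scattering.
- **Anisotropy** is an area-preserving affine stretch (√s along the axis,
  1/√s across): the ring becomes an ellipse of axis ratio exactly `s`
  while the geometric-mean pixel size stays equal to the configured
  truth, so both the scalar and the anisotropy have unambiguous ground
  truth. A one-sided stretch would silently change the scalar truth to
  P/√s.
- **Aliasing mode** (for pixel sizes where the fringe period falls below
  2 px) renders at 2× sampling and decimates without a low-pass filter;
  off by default, and plain super-Nyquist configs are rejected with an
  error.
- The scene is deterministic in its seed; datasets are written as MRC2014
  with a JSON ground-truth sidecar, and the header can carry a decoy
  nominal pixel size so that tests can prove the pipeline recovers the
  truth from the lattice rather than echoing the header.

What passing tests on this data do **not** show: robustness to foil
bending, beam-induced motion residuals, thick-ice backgrounds, dynamical
contrast (bend contours, extinction), detector fixed-pattern artefacts,
or the non-uniform azimuthal intensity of textured foils. Those affect
real data and are the reason the pipeline rejects, rather than guesses
on, micrographs with weak or incomplete rings.

One subtlety the synthetic tests did expose: the scene's fringe spacing
and the calibration's assumed d must refer to the same temperature.
Generating fringes at the room-temperature 2.35 Å and calibrating with
the 81 K spacing (2.3473 Å) produces a built-in −0.11% offset — exactly
the kind of error the thermal model exists to prevent on real data.

## Problem sizes and numerical choices

- End-to-end checks use ten 1024² micrographs with 200 crystallites, the
  recommended minimum dataset for a calibration session; unit tests use
  512² scenes with 80 crystallites.
- Whitening background: polynomial degree 5 in log-space (robust and
  parameter-light; the estimator is a free design choice since only the
  goal — a flat noise floor — is specified by the physics).
- Peak prominence threshold: 4× the MAD-based scatter; tie-breaks on
  equal maxima choose the larger radius.
- Degenerate inputs: blank or constant images fail peak detection and are
  rejected with per-file reasons; an all-rejected dataset raises a
  calibration error carrying those reasons; (0,0,0) is an invalid
  reflection; negative temperatures, non-positive lattice constants and
  non-positive Cs values raise domain errors.
- Determinism: every stochastic component (scene generation, tests) is
  seeded; `calibrate` itself is deterministic.

## Known limitations

- The Z40 → ΔCs constant depends on the upstream Zernike normalization;
  only the round trip is guaranteed, not agreement with any particular
  refinement program's convention (hence the exposed `q_max`).
- The ellipse model assumes pure (possibly anisotropic) linear
  magnification; higher-order distortion (e.g. spiral/pincushion) is not
  modelled.
- Aggregation treats micrographs as exchangeable; per-micrograph defocus
  dependence of magnification (non-parallel illumination) should be
  handled by grouping micrographs before calibration.
- The material catalogue lists only the reflections needed for
  calibration; no structure factors or extinction rules.
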
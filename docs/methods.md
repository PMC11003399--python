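# Methods

This note documents the physical model behind `aoholo`, the numerical
conventions, the default study geometry, and the design choices made where
several reasonable options existed.

## Optical model

The simulation works in paraxial Fourier optics with two conjugate planes:
the *holographic plane* (back focal plane, where the modulator sits) and
the *target plane* (front focal plane, where the intensity pattern forms).
Propagation between them is a unitary, DC-centered discrete Fourier
transform; with even grid size N the field center sits at index N // 2
(0-based).  Unitary normalization makes all power-efficiency metrics
convention-free: the total power Σ|A|² is invariant under propagation.

Out-of-focus (Fresnel) propagation, vectorial diffraction and high-NA
corrections are out of scope; reconstructions are in-focus scalar fields.

### Sampling geometry and the device aperture

`OpticalConfig` carries the wavelength λ, the grid size N, the
holographic-plane pitch Δs and the effective focal length f; the
target-plane pitch follows as Δu = λf/(NΔs).  In addition the config names
a *device aperture* of D samples (`aperture_samples`): the physical AOD
crystal occupies only the central D samples of the sampling window.  All
1D retrieval engines clamp the holographic amplitude to this aperture, and
all reconstructions apply it; 2D reconstructions use a circular or square
hard-edged aperture of the same default diameter.

The ratio N/D sets the diffraction-limited spot size in target-plane
samples and is the single most important parameter of the simulation: with
D = N every target sample is independently addressable and Gerchberg-
Saxton converges almost perfectly even on dense targets, which neither
matches real devices (whose line resolution is limited to a few hundred
resolvable spots) nor produces the speckle statistics that motivate
complex holography.

**Default geometry** (chosen once, used for every headline number):

| quantity | value |
|---|---|
| wavelength λ | 940 nm |
| grid size N | 1024 samples over a 15 mm window |
| device aperture D | 256 samples = 3.75 mm |
| target pitch Δu | 0.125 µm/sample (effective f ≈ 2.0 mm) |
| diffraction-limited spot | N/D = 4 samples = 0.5 µm |
| target-plane field of view | 128 µm |

These values are physically representative of a two-photon microscope fed
by a TeO₂ AOD (4–15 mm apertures, ~0.5–1 µm two-photon spots) and
reproduce the published benchmark levels for the five-point target error
and the complex-hologram power efficiency; the aperture-to-grid ratio and
sampling density were calibrated against those two numbers and then
frozen.  They are exposed in `OpticalConfig` for other geometries.

### Beams and apertures

Input beams are uniform or Gaussian; a Gaussian of 1/e² *intensity*
diameter d has amplitude exp(−4r²/d²).  Apertures are hard-edged (binary
on sample centers); no anti-aliased rim is applied.  Retrieval always
assumes a uniform beam through the aperture — the Gaussian beam enters at
reconstruction/efficiency time, mirroring an instrument whose CGH
computation ignores the beam profile.

## Target fixtures

Sparse point targets (3/5/7 equidistant points at 4/4/3.5 µm spacing,
overall lengths L_S = 8/16/21 µm, plus an inhomogeneous seven-point
variant) are one sample wide and exactly zero elsewhere.

Dense targets (line segments of 8/16/21 µm; triangular, parabolic and
raised-sinusoidal profiles over 8 µm) are sampled from their analytic
profile and then smoothed with a Gaussian of σ = one diffraction spot
(N/D samples).  A hard-edged boxcar is sharper than anything the
aperture-limited system can render; imposing it as an IFT constraint
leaves irreducible Gibbs residue (intensity CV ≈ 0.1 at full feedback
gain) that reflects the unrealizable target, not the algorithm.  The
smoothed profile keeps sub-resolution shoulders below the *target-domain
threshold* (10 % of peak); the target domain — the coordinate range where
the target appreciably differs from zero, on which all metrics are
evaluated — collects the samples at or above that threshold.

What the fixtures do **not** emulate: optical aberrations, AOD acoustic
attenuation and transducer response, chromatic dispersion, camera noise
and background.  Passing tests therefore demonstrate correctness of the
retrieval and analysis algorithms under an idealized scalar model, not
end-to-end instrument performance.

## Retrieval engines

All engines iterate target-plane and holographic-plane constraints for a
fixed budget (default 200 cycles, no early stopping, so parameter sweeps
stay comparable) starting from an i.i.d. uniform random phase in the
target plane (seeded; identical seed and config give bit-identical
holograms).

- **Static** (`gs_static`): the full target amplitude is imposed across
  the whole target plane every cycle; the holographic amplitude is clamped
  to the input beam through the aperture.  Output: phase-only (FM)
  hologram; the final holographic amplitude is retained.
- **Dynamic** (`gs_dynamic`): the amplitude is clamped only on the target
  domain; on the freedom domain (default: everything outside the target
  domain minus a guard band of 2 samples) the current amplitude is carried
  over, letting higher diffraction orders evolve freely.  With an empty
  freedom domain this reduces exactly to the static engine.
- **Apodization** (`apodize`): post hoc mask
  (1−g)·1 + g·A_final/max(A_final) applied to a phase-only hologram,
  turning it FM/AM.  Gain 1 nearly eliminates the target error of sparse
  patterns at a monotone power cost.
- **Complex** (`gs_complex`): each cycle the holographic amplitude is
  replaced by the gain-weighted blend
  (1−g_k)·beam + g_k·A/max(A), with g_k ramped linearly from 0 to g_AM
  over the first half of the iteration budget (ramp length configurable).
  The current amplitude is normalized to unit maximum before blending to
  prevent runaway decay.  Output: FM/AM hologram whose mask is the final
  blended amplitude.

The feedback gain may reach exactly 1 ("full amplitude feedback"), at
which the holographic amplitude is fully self-determined and dense-target
speckle collapses (CV ≈ 0.03 on the 8 µm line).  The decadic gain scale
g′ = ½·log₁₀(1/(1−g)) used for sweep axes diverges at g = 1, so sweeps cap
the linear gain at 0.99 (g′ = 1); at 0.99 the residual 1 % uniform
admixture leaves a slightly higher speckle floor (CV ≈ 0.07).

- **Extended** (`gs_extended`): identical to the chosen engine except that
  each forward propagation expands the current 1D field to a separable 2D
  field (same profile on both axes), imposes the circular system aperture,
  propagates in 2D and recovers the 1D target field from the midline.
  This optimizes the hologram for the circular pupil that a real
  instrument has; on dense ps2D targets it reduces the 2D reconstruction
  error severalfold relative to plain 1D retrieval (a square aperture is
  separable, so that case falls back to the plain engine with a warning).

## Metrics

- **Target error**: relative RMS amplitude deviation on the target domain
  after rescaling the reconstruction to unit peak there,
  √(Σ(Â/max Â − T)²/ΣT²); reconstructions and targets are presented
  peak-normalized throughout, and this convention reproduces the published
  five-point benchmark level (a least-squares rescale is available as an
  option and gives systematically smaller values).  A reconstruction that
  vanishes on the target domain scores 1.
- **Speckle noise**: coefficient of variation (std/mean) of the intensity
  divided pointwise by the target intensity, over the target domain; for
  flat targets this is the intensity CV.  Fully developed speckle
  (exponential intensity statistics) gives CV = 1.
- **Power efficiency**: first-Bragg-order power divided by input power,
  where input power is the beam power through the aperture before any
  amplitude mask and the mask-rejected power is counted as lost to the
  zero order (no explicit zero-order field is modeled).  A pure phase
  hologram has efficiency 1 by construction.
- **Moving phase variance**: sliding-window variance (default window
  0.5 µm; square window in 2D) of the target-plane phase, with each
  window's phase referenced to its circular mean direction so the ±π wrap
  produces no artifacts; edges are reflect-padded.

## ps2D modal basis

The separable polynomial family {1; x, y; x²+y², x²−y²; …; x⁸+y⁸, x⁸−y⁸}
is orthonormalized by (two-pass modified) Gram–Schmidt under the uniform
disk inner product ⟨f,g⟩ = (1/π)∫∫ fg dA, giving exactly 2n+1 modes up to
order n.  Numerics: the disk is discretized on a Cartesian grid (default
512²) whose rim pixels are weighted by their in-disk area fraction
(16×16 supersampling); the basis is orthonormalized with respect to this
*discrete* inner product, so its Gram matrix is the identity at machine
precision on the grid and approximates the continuum modes to O(h²).

Zernike polynomials (two-index (n, m), unit-RMS normalization, cosine for
m > 0 and sine for m < 0) are evaluated analytically and then symmetrically
(Löwdin) re-orthonormalized under the same discrete inner product — the
minimal perturbation of each mode that makes discrete Parseval identities
exact: Σc² + residual² = ‖input‖².  Decompositions of degree-k polynomials
should use a matching Zernike order (≥ k); far higher orders on coarse
grids only add near-rim quadrature noise.  A Nyquist-style check rejects
grids finer than 8 samples per radial order.

Structure reproduced by this construction: orders 1–2 are exactly Zernike
tilt, defocus and vertical astigmatism; odd orders ≥ 3 form ps-coma pairs
mixing coma with foil terms; even orders ≥ 4 split into ps-spherical
(spherical + quadrafoil, …) and ps-astigmatism, whose fourth-order member
coincides with Zernike secondary astigmatism; modes of unequal order share
no Zernike terms.

## AOD interface

The synchronous-mode transfer relation Δf(s) = v_ac/(2π)·dφ/ds is
discretized with central differences (one-sided stencils at the edges) on
the physical coordinate, obtained by mapping the N holographic samples
onto the configured aperture diameter.  The inverse integrates the
envelope with the exact algebraic inverse of that stencil (a second-order
leapfrog recursion anchored to zero phase at the left edge), so
phase → frequency → phase roundtrips are exact to machine precision up to
the additive constant; for external envelopes the integrator is
second-order accurate.  Validation checks the synchronous-mode laser-rate
bound r ≤ 1/T (T = aperture/v_ac; boundary inclusive) and the envelope
excursion against half the allocated bandwidth.  Default device: 15 mm
aperture, v_ac = 650 m/s (T ≈ 23 µs, max rate ≈ 43 kHz), 75 MHz carrier,
50 MHz bandwidth, 40 kHz laser.  Acoustic attenuation, transducer response
and RF synthesis are not modeled.

## Seven-segment serial holography

Segments are numbered 1 = top, 2 = upper-right, 3 = upper-left,
4 = bottom, 5 = lower-right, 6 = lower-left, 7 = middle, and grouped into
five meta segments {1}, {2,3}, {4}, {5,6}, {7}.  With this numbering the
two vertical groups collect bars of identical y-extent (upper halves,
lower halves), so each group's union over arbitrary characters is a
Cartesian product — every text decomposes into at most five separable
targets by construction.  (Numbering the vertical pairs by column instead
— right bar = one group — breaks separability for mixed texts such as
"PSG", where some characters use only the upper or only the lower right
bar.)

The merge rule is operational: any two groups whose union still passes the
rank-1 separability test (tolerance 1e−6) are merged into one hologram;
this realizes translation-symmetry merging without font-specific rules.
For "PSL" the top and middle groups merge (both active in exactly P and
S), giving four holograms; changing L to G breaks the degeneracy and "PSG"
needs the full five.

Per meta segment the rank-1 factors are smoothed to the system resolution,
retrieved per axis (hybrid default: complex FM/AM on the axis with larger
support, static FM on the other; FM-axes may be apodized to remove
second-order ghosts), composed, and reconstructed under the circular
aperture with a Gaussian beam to record per-hologram power efficiency.
The accumulated image is the pointwise intensity sum over frames
(optionally squared per frame for the two-photon camera model).

## Problem sizes and determinism

Headline quantities use the default 1024-sample geometry, 200 iterations
and 30 seeds.  2D-heavy checks (extended IFT, ps2D reconstruction
properties) run on a 256-sample grid with a 64-sample aperture — the same
pitch and aperture ratio — with ~100 iterations and ~10 seeds, which
preserves all qualitative behavior.  Every stochastic element derives from
an explicit integer seed through `numpy.random.default_rng`; identical
configs reproduce outputs bit-for-bit.

## Known limitations

- The choice of iteration budget and ramp schedule affects the residual
  speckle floor at high feedback gain; the defaults are adequate for the
  benchmark conditions but very dense targets may profit from longer runs.
- The hard-edged aperture makes targets with significant energy outside
  the aperture bandwidth unrealizable; fixtures avoid this by resolution
  smoothing, but user-supplied targets are not checked.
- `frequency_to_phase` on externally supplied envelopes uses a leapfrog
  recursion whose even/odd chains can develop a small parity offset
  (second differences alternate at O(h²)) for non-smooth envelopes.
- The separability test uses a full SVD of the pattern's bounding box;
  patterns without zero margins of size ≫ 2000² become slow.
- Two-photon rendering models only the quadratic nonlinearity, not
  fluorophore saturation or detection optics.
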
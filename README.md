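# aoholo — computer-generated acousto-optic holography

`aoholo` retrieves, composes and analyses computer-generated holograms
(CGHs) for acousto-optic deflectors (AODs) used as fast spatial light
modulators in microscopic light patterning — e.g. two-photon holographic
photostimulation and random-access functional imaging.

An AOD synchronised with a pulsed laser acts as a 1D complex modulator: in
the synchronous regime the wavefront slope is proportional to the local
acoustic frequency offset from the carrier,

    dφ/ds = (2π / v_ac) · Δf(s),        v_ac ≈ 650 m/s (shear wave, TeO₂)

so any *unwrapped* 1D phase profile maps to a frequency-modulation (FM)
envelope, and the acoustic amplitude adds amplitude modulation (AM).  Two
crossed AODs superpose their wavefronts, φ(x, y) = φx(x) + φy(y), so the
accessible 2D wavefronts are the separable, "pseudo-2D" (ps2D) functions,
and single-hologram targets are the rank-1 (Cartesian-product) intensity
patterns.

The package implements:

- **Gerchberg–Saxton iterative Fourier-transform (IFT) retrieval** of 1D
  holograms with several regularizations: static target (phase-only, FM),
  dynamic target with a freedom domain, post hoc **apodization** (the
  retained holographic amplitude reused as an AM mask to cancel ghost side
  lobes), and **complex IFT** with ramped amplitude feedback
  (gain g_AM ∈ [0, 1], decadic scale g′ = ½·log₁₀(1/(1−g))) that removes
  speckle from dense targets.
- An **extended 1D IFT** that accounts for a circular system aperture by
  temporarily expanding the 1D field to a separable 2D field and recovering
  it from the midline after 2D propagation.
- **ps2D synthesis**: composition of axis holograms (FM, FM/AM, or hybrid),
  2D numerical reconstruction under square/circular apertures and
  uniform/Gaussian beams, a rank-1 separability test, and two-photon
  (intensity-squared) rendering.
- **Quality metrics**: relative RMS target error, speckle noise
  (intensity CV on the target domain), first-Bragg-order power efficiency,
  moving phase variance.
- **AOD interface**: phase ↔ acoustic-frequency conversion and
  synchronous-mode device validation (laser rate vs. aperture fill time,
  bandwidth excursion).
- **ps2D modal analysis**: the orthonormal basis of separable polynomials
  on the unit disk (2n+1 modes to order n vs. n(n+3)/2 Zernike modes) and
  its Zernike decomposition (tilt/defocus/vertical astigmatism at low
  order; ps-coma, ps-spherical, ps-astigmatism with foil admixtures above).
- **Serial seven-segment holography**: text encoded on seven-segment
  displays, regrouped into at most five ps2D-separable *meta segments*
  (merged further when translation symmetry allows) and projected as a
  hologram sequence.

## Worked example

```python
import numpy as np
from aoholo import (
    default_config, make_fixture, IFTConfig, gs_static, gs_complex, apodize,
    reconstruct_1d, target_error, speckle_noise, BeamProfile,
)
from aoholo.ift_engines import efficiency_1d

optics = default_config()
# -> grid: 1024 samples, aperture 256 samples (3.75 mm), spot 0.50 um, FOV 128 um

# Phase-only holography of a sparse five-point grid (4 um spacing)
t5 = make_fixture("five_point", optics)
h = gs_static(t5, IFTConfig(iterations=200, seed=0), optics)
# -> five-point FM hologram: target error 19.5%
ha = apodize(h, 1.0)
err = target_error(reconstruct_1d(ha).amplitude, t5)
# -> after full apodization: error 0.31%, efficiency 43.7%

# Complex holography of a dense 8 um line
line = make_fixture("line_8um", optics)
beam = BeamProfile("gaussian", diameter=optics.aperture)
h0 = gs_complex(line, IFTConfig(seed=0, regularization="complex", am_gain=0.0), optics)
h1 = gs_complex(line, IFTConfig(seed=0, regularization="complex", am_gain=1.0), optics)
# -> line speckle: 0.39 (no feedback) -> 0.033 (full feedback)
h99 = gs_complex(line, IFTConfig(seed=0, regularization="complex", am_gain=0.99), optics)
eff = efficiency_1d(h99, beam)
# -> first-order efficiency at g_AM = 0.99, Gaussian beam: 42.9%
```

The numbers read as follows: a phase-only (FM) hologram renders the
five-point grid with ~20% RMS amplitude error, dominated by inhomogeneous
peaks and ghost side lobes; applying the retained holographic amplitude as
an apodization mask nearly eliminates the error at the cost of diffracting
only ~44% of the input power into the first Bragg order.  For the dense
line, amplitude feedback drives the speckle CV from 0.39 (fully structured
interference noise) to ~0.03 (visually smooth) at ~40% power efficiency.

From the shell:

```bash
aoholo retrieve --target line_8um --engine complex --gain 0.99 --out line.h5
aoholo reconstruct --holo line.h5 --aperture circular --beam gaussian --out line.tiff
aoholo ssd --text PSG --mode hybrid --out-dir psg/   # five serial holograms
aoholo basis --max-order 8 --out basis.h5 --table zernike.csv
```

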
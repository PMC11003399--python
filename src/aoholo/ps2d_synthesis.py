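"""Pseudo-2D hologram composition, reconstruction and separability tests.

Two crossed 1D modulators superpose their wavefronts additively, so the
accessible 2D wavefronts are exactly the separable functions
``phi(x, y) = phi_x(x) + phi_y(y)`` ("pseudo-2D", ps2D).  The reconstructed
amplitude of such a hologram under a square aperture is the outer product of
the two 1D reconstructions; valid single-hologram targets are therefore the
rank-1 (Cartesian-product) nonnegative patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .field_model import (
    ApertureSpec,
    BeamProfile,
    Field,
    OpticalConfig,
    Plane,
    apply_aperture,
    apply_beam,
    embed_ps2d,
    propagate,
)
from .ift_engines import Hologram1D

__all__ = [
    "Ps2DHologram",
    "ReconstructionResult",
    "compose",
    "reconstruct_2d",
    "is_ps2d_separable",
    "two_photon_render",
]


@dataclass
class Ps2DHologram:
    """An ordered pair of axis holograms forming one ps2D hologram."""

    hologram_x: Hologram1D
    hologram_y: Hologram1D
    label: str = ""

    def __post_init__(self) -> None:
        if self.hologram_x.n != self.hologram_y.n:
            raise ValueError("axis holograms must share one length")

    @property
    def mode(self) -> tuple[str, str]:
        return (self.hologram_x.mode, self.hologram_y.mode)

    @property
    def n(self) -> int:
        return self.hologram_x.n


@dataclass
class ReconstructionResult:
    """Target-plane reconstruction with power bookkeeping.

    ``input_power`` is measured after the input beam but before any
    amplitude mask or aperture; ``first_order_power`` is the total power of
    the reconstructed field (mask- and aperture-rejected power counts as
    lost to the zero Bragg order).
    """

    amplitude: np.ndarray
    phase: np.ndarray
    input_power: float
    first_order_power: float
    optics: OpticalConfig
    metrics: dict = dc_field(default_factory=dict)

    @property
    def intensity(self) -> np.ndarray:
        return self.amplitude**2

    @property
    def field(self) -> Field:
        return Field(self.amplitude * np.exp(1j * self.phase), Plane.TARGET, self.optics)


def compose(hx: Hologram1D, hy: Hologram1D, label: str = "") -> Ps2DHologram:
    """Pair two axis holograms.  An FM axis contributes a unit amplitude
    mask, an FM/AM axis its own mask; a hybrid pairs one of each."""
    return Ps2DHologram(hx, hy, label=label)


def reconstruct_2d(
    holo: Ps2DHologram,
    aperture: ApertureSpec | None = None,
    beam: BeamProfile | None = None,
    optics: OpticalConfig | None = None,
) -> ReconstructionResult:
    """Numerically reconstruct a ps2D hologram.

    The axis profiles are embedded into a separable 2D holographic field,
    the input beam and hard system aperture are applied, and the field is
    propagated to the target plane by a unitary 2D FFT.  Input power is the
    beam power through the aperture before the amplitude masks, so the
    mask-rejected power counts as lost to the zero Bragg order.
    """
    optics = optics or holo.hologram_x.optics
    beam = beam or BeamProfile("uniform")
    aperture = aperture or ApertureSpec("square", None)

    hx, hy = holo.hologram_x, holo.hologram_y
    field = embed_ps2d(
        hx.phase_unwrapped, hy.phase_unwrapped, hx.amplitude_mask, hy.amplitude_mask, optics
    )
    unit = Field(np.ones((optics.grid_size,) * 2, dtype=complex), Plane.HOLOGRAPHIC, optics)
    input_power = apply_aperture(apply_beam(unit, beam), aperture).power

    field = apply_beam(field, beam)
    field = apply_aperture(field, aperture)
    out = propagate(field, "to_target")
    return ReconstructionResult(
        amplitude=np.abs(out.samples),
        phase=np.angle(out.samples),
        input_power=input_power,
        first_order_power=out.power,
        optics=optics,
        metrics={"aperture": aperture.shape, "beam": beam.kind},
    )


def is_ps2d_separable(
    target2d: np.ndarray, tol: float = 1e-3
) -> tuple[bool, np.ndarray | None, np.ndarray | None]:
    """Test whether a nonnegative 2D pattern is a Cartesian product.

    The pattern is separable iff its best rank-1 approximation leaves a
    relative Frobenius residual below ``tol``.  When separable, the factor
    profiles ``(profile_x, profile_y)`` are returned scaled so that
    ``outer(profile_y, profile_x)`` reproduces the pattern (x varies along
    columns).  An all-zero pattern is trivially separable with zero
    profiles.
    """
    a = np.asarray(target2d, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2D pattern")
    if np.any(a < 0):
        raise ValueError("pattern must be nonnegative")
    total = np.linalg.norm(a)
    if total == 0:
        return True, np.zeros(a.shape[1]), np.zeros(a.shape[0])
    # crop to the nonzero bounding box; zero rows/columns do not affect the
    # singular values
    rows = np.flatnonzero(a.any(axis=1))
    cols = np.flatnonzero(a.any(axis=0))
    sub = a[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]
    u, s, vt = np.linalg.svd(sub, full_matrices=False)
    residual = np.sqrt(max(0.0, 1.0 - (s[0] / total) ** 2))
    if residual >= tol:
        return False, None, None
    # Perron-Frobenius: the leading singular vectors of a nonnegative matrix
    # can be chosen nonnegative; flip sign and clip numerical noise.
    scale = np.sqrt(s[0])
    uy = np.zeros(a.shape[0])
    vx = np.zeros(a.shape[1])
    uy[rows[0]: rows[-1] + 1] = u[:, 0] * np.sign(u[:, 0].sum() or 1.0)
    vx[cols[0]: cols[-1] + 1] = vt[0] * np.sign(vt[0].sum() or 1.0)
    return True, np.clip(vx, 0, None) * scale, np.clip(uy, 0, None) * scale


def two_photon_render(result: ReconstructionResult | np.ndarray) -> np.ndarray:
    """Two-photon excitation image: pointwise intensity squared, normalized
    to unit maximum.  The quadratic nonlinearity enhances any intensity
    inhomogeneity present in the excitation pattern."""
    intensity = result.intensity if isinstance(result, ReconstructionResult) else np.asarray(result)
    img = intensity.astype(float) ** 2
    peak = img.max()
    return img / peak if peak > 0 else img
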
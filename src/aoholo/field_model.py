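"""Sampled-field model and Fourier propagation between optical planes.

The optical system is described in paraxial Fourier optics: the hologram
lives in the back focal plane ("holographic plane") of a lens of effective
focal length ``f`` and the shaped intensity pattern forms in the front focal
plane ("target plane").  The two planes are exact Fourier conjugates, so
propagation is a unitary, DC-centered discrete Fourier transform.

Coordinate convention
---------------------
Fields are sampled on a regular grid of ``N`` points per axis with the field
center at index ``N // 2`` (0-based).  The holographic-plane pitch is
``delta_s`` (mm/sample) and the target-plane pitch follows from the Fourier
scaling ``delta_u = lambda * f / (N * delta_s)`` (um/sample).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Plane",
    "OpticalConfig",
    "Field",
    "ApertureSpec",
    "BeamProfile",
    "InvalidFieldError",
    "ConfigurationError",
    "propagate",
    "apply_aperture",
    "apply_beam",
    "embed_ps2d",
    "extract_midline",
    "centered_coords",
]


class InvalidFieldError(ValueError):
    """Raised when a field contains non-finite samples."""


class ConfigurationError(ValueError):
    """Raised for inconsistent optical/aperture configuration."""


class Plane(str, Enum):
    HOLOGRAPHIC = "holographic"
    TARGET = "target"

    @property
    def other(self) -> "Plane":
        return Plane.TARGET if self is Plane.HOLOGRAPHIC else Plane.HOLOGRAPHIC


@dataclass(frozen=True)
class OpticalConfig:
    """Optical sampling geometry.

    Parameters
    ----------
    wavelength_nm:
        Vacuum wavelength in nanometres (infrared two-photon systems
        typically use 940 nm).
    grid_size:
        Number of samples ``N`` per axis; must be even and >= 16.
    pitch_holo_mm:
        Holographic-plane sample pitch ``delta_s`` in mm/sample.  The grid
        then spans the physical modulator aperture ``N * delta_s``.
    focal_mm:
        Effective focal length of the Fourier lens in mm.  In a microscope
        this lumps the relay demagnification from the modulator to the
        objective back pupil into a single equivalent lens.
    """

    wavelength_nm: float = 940.0
    grid_size: int = 1024
    pitch_holo_mm: float = 15.0 / 1024
    focal_mm: float = 9.0
    aperture_samples: int | None = None  # device aperture; None -> grid_size // 4

    def __post_init__(self) -> None:
        if self.grid_size < 16 or self.grid_size % 2:
            raise ConfigurationError("grid_size must be even and >= 16")
        for name in ("wavelength_nm", "pitch_holo_mm", "focal_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.aperture_samples is not None and not (
            0 < self.aperture_samples <= self.grid_size
        ):
            raise ConfigurationError("aperture_samples must lie in (0, grid_size]")

    @property
    def pitch_target_um(self) -> float:
        """Target-plane pitch ``lambda * f / (N * delta_s)`` in um/sample."""
        lam_mm = self.wavelength_nm * 1e-6
        return lam_mm * self.focal_mm / (self.grid_size * self.pitch_holo_mm) * 1e3

    @property
    def fov_um(self) -> float:
        """Target-plane field of view in um."""
        return self.grid_size * self.pitch_target_um

    @property
    def aperture(self) -> int:
        """Device aperture diameter in samples (default: grid_size // 4)."""
        return self.aperture_samples if self.aperture_samples else self.grid_size // 4

    @property
    def resolution_samples(self) -> float:
        """Diffraction-limited spot size in target-plane samples, N / D."""
        return self.grid_size / self.aperture

    @property
    def resolution_um(self) -> float:
        """Diffraction-limited spot size in um."""
        return self.resolution_samples * self.pitch_target_um

    @classmethod
    def from_target_pitch(
        cls,
        target_pitch_um: float,
        wavelength_nm: float = 940.0,
        grid_size: int = 1024,
        window_mm: float = 15.0,
        aperture_samples: int | None = None,
    ) -> "OpticalConfig":
        """Build a config with a prescribed target-plane pitch.

        The holographic grid spans ``window_mm`` and the focal length is
        solved from the Fourier pitch relation.
        """
        pitch_holo_mm = window_mm / grid_size
        lam_mm = wavelength_nm * 1e-6
        focal_mm = target_pitch_um * 1e-3 * grid_size * pitch_holo_mm / lam_mm
        return cls(wavelength_nm, grid_size, pitch_holo_mm, focal_mm, aperture_samples)


def default_config() -> OpticalConfig:
    """Default simulation geometry.

    N = 1024 samples across a 15 mm sampling window with a 3.75 mm (256
    sample) device aperture; target-plane pitch 0.125 um/sample, hence a
    0.5 um diffraction-limited spot and a 128 um field of view.
    """
    return OpticalConfig.from_target_pitch(0.125)


def aperture_slit(optics: OpticalConfig) -> np.ndarray:
    """1D binary transmission of the device aperture (slit profile)."""
    c = centered_coords(optics.grid_size)
    return (np.abs(c) <= optics.aperture / 2).astype(float)


@dataclass
class Field:
    """A uniformly sampled complex light field tagged with its plane."""

    samples: np.ndarray
    plane: Plane
    optics: OpticalConfig

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        self.plane = Plane(self.plane)
        if self.samples.ndim not in (1, 2):
            raise InvalidFieldError("fields are 1D or 2D")
        n = self.optics.grid_size
        if self.samples.shape != (n,) * self.samples.ndim:
            raise InvalidFieldError(
                f"field shape {self.samples.shape} does not match grid size {n}"
            )

    @property
    def ndim(self) -> int:
        return self.samples.ndim

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.samples)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.samples)

    @property
    def power(self) -> float:
        return float(np.sum(np.abs(self.samples) ** 2))

    @property
    def pitch(self) -> float:
        """Sample pitch in the field's own plane (mm holographic, um target)."""
        if self.plane is Plane.HOLOGRAPHIC:
            return self.optics.pitch_holo_mm
        return self.optics.pitch_target_um

    def copy_with(self, samples: np.ndarray, plane: Plane | None = None) -> "Field":
        return Field(samples, self.plane if plane is None else plane, self.optics)


@dataclass(frozen=True)
class ApertureSpec:
    """Hard-edged system aperture in the holographic plane."""

    shape: str = "circular"  # "circular" | "square"
    diameter: int | None = None  # samples; None -> full grid

    def __post_init__(self) -> None:
        if self.shape not in ("circular", "square"):
            raise ConfigurationError(f"unknown aperture shape {self.shape!r}")
        if self.diameter is not None and self.diameter < 0:
            raise ConfigurationError("aperture diameter must be >= 0")


@dataclass(frozen=True)
class BeamProfile:
    """Input illumination profile in the holographic plane."""

    kind: str = "uniform"  # "uniform" | "gaussian"
    diameter: float | None = None  # 1/e^2 intensity diameter, samples

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "gaussian"):
            raise ConfigurationError(f"unknown beam kind {self.kind!r}")
        if self.kind == "gaussian":
            if self.diameter is None or self.diameter <= 0:
                raise ConfigurationError("gaussian beam needs diameter > 0")


def centered_coords(n: int) -> np.ndarray:
    """Sample-center coordinates with the origin at index n // 2."""
    return np.arange(n) - n // 2


def _check_finite(samples: np.ndarray) -> None:
    if not np.all(np.isfinite(samples)):
        raise InvalidFieldError("field contains non-finite samples")


def fft_centered(x: np.ndarray) -> np.ndarray:
    """Unitary DC-centered forward DFT (holographic -> target)."""
    axes = tuple(range(x.ndim))
    y = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes), axes=axes)
    return y / np.sqrt(x.size)


def ifft_centered(x: np.ndarray) -> np.ndarray:
    """Unitary DC-centered inverse DFT (target -> holographic)."""
    axes = tuple(range(x.ndim))
    y = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(x, axes=axes), axes=axes), axes=axes)
    return y * np.sqrt(x.size)


def propagate(field: Field, direction: str | None = None) -> Field:
    """Propagate a field to the conjugate plane by unitary centered (I)FFT.

    ``direction`` may be ``"to_target"`` or ``"to_hologram"``; if given it
    must be consistent with the field's plane tag.  Total power is preserved
    and the plane tag is flipped.
    """
    _check_finite(field.samples)
    if direction is not None:
        expected = Plane.HOLOGRAPHIC if direction == "to_target" else Plane.TARGET
        if direction not in ("to_target", "to_hologram"):
            raise ValueError(f"unknown direction {direction!r}")
        if field.plane is not expected:
            raise InvalidFieldError(
                f"cannot propagate a {field.plane.value}-plane field {direction}"
            )
    if field.plane is Plane.HOLOGRAPHIC:
        out = fft_centered(field.samples)
    else:
        out = ifft_centered(field.samples)
    return field.copy_with(out, plane=field.plane.other)


def aperture_mask(aperture: ApertureSpec, n: int, default_diameter: int | None = None) -> np.ndarray:
    """Binary 2D transmission mask of a hard-edged aperture on an n x n grid."""
    d = aperture.diameter
    if d is None:
        d = default_diameter if default_diameter is not None else n
    if d > n:
        raise ConfigurationError(f"aperture diameter {d} exceeds grid size {n}")
    if d == 0:
        return np.zeros((n, n))
    c = centered_coords(n)
    if aperture.shape == "square":
        inside1d = np.abs(c) <= d / 2
        return np.outer(inside1d, inside1d).astype(float)
    xx, yy = np.meshgrid(c, c)
    return (xx**2 + yy**2 <= (d / 2) ** 2).astype(float)


def apply_aperture(field: Field, aperture: ApertureSpec) -> Field:
    """Zero all samples outside a hard-edged aperture (2D holographic field)."""
    if field.ndim != 2:
        raise InvalidFieldError("apply_aperture expects a 2D field")
    if field.plane is not Plane.HOLOGRAPHIC:
        raise InvalidFieldError("apertures act in the holographic plane")
    mask = aperture_mask(aperture, field.optics.grid_size, field.optics.aperture)
    return field.copy_with(field.samples * mask)


def beam_amplitude(beam: BeamProfile, n: int, ndim: int = 1) -> np.ndarray:
    """Amplitude profile of the input beam on the sampling grid.

    A gaussian beam of 1/e^2 *intensity* diameter ``d`` has amplitude
    ``exp(-4 r^2 / d^2)`` so the intensity at r = d/2 is exp(-2).
    """
    if beam.kind == "uniform":
        return np.ones((n,) * ndim)
    c = centered_coords(n)
    if ndim == 1:
        r2 = c.astype(float) ** 2
    else:
        xx, yy = np.meshgrid(c, c)
        r2 = xx.astype(float) ** 2 + yy**2
    return np.exp(-4.0 * r2 / beam.diameter**2)


def apply_beam(field: Field, beam: BeamProfile) -> Field:
    """Multiply a holographic-plane field by the input-beam amplitude."""
    if field.plane is not Plane.HOLOGRAPHIC:
        raise InvalidFieldError("beam profiles act in the holographic plane")
    if beam.kind == "uniform":
        return field.copy_with(field.samples.copy())
    prof = beam_amplitude(beam, field.optics.grid_size, field.ndim)
    return field.copy_with(field.samples * prof)


def embed_ps2d(
    phase_x: np.ndarray,
    phase_y: np.ndarray,
    amp_x: np.ndarray,
    amp_y: np.ndarray,
    optics: OpticalConfig,
) -> Field:
    """Embed two 1D axis modulations into a separable 2D holographic field.

    Crossed deflectors superpose their wavefronts additively,
    ``phi(x, y) = phi_x(x) + phi_y(y)``, while the amplitude masks multiply,
    so the embedded samples are
    ``A_x(x) * A_y(y) * exp(i (phi_x(x) + phi_y(y)))`` with x varying along
    the second (column) array axis.
    """
    arrs = [np.asarray(a, dtype=float) for a in (phase_x, phase_y, amp_x, amp_y)]
    n = optics.grid_size
    for a in arrs:
        if a.shape != (n,):
            raise ValueError(f"axis profiles must have shape ({n},)")
    px, py, ax, ay = arrs
    fx = ax * np.exp(1j * px)
    fy = ay * np.exp(1j * py)
    return Field(np.outer(fy, fx), Plane.HOLOGRAPHIC, optics)


def extract_midline(field: Field, axis: str = "x") -> Field:
    """Central line cut of a 2D target-plane field.

    ``axis="x"`` returns the row through the field center (profile along x),
    ``axis="y"`` the corresponding column.  With even N the center lies at
    index N // 2.
    """
    if field.ndim != 2:
        raise InvalidFieldError("extract_midline expects a 2D field")
    if field.plane is not Plane.TARGET:
        raise InvalidFieldError("midline extraction is defined in the target plane")
    c = field.optics.grid_size // 2
    if axis == "x":
        line = field.samples[c, :]
    elif axis == "y":
        line = field.samples[:, c]
    else:
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    return Field(line.copy(), Plane.TARGET, field.optics)
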
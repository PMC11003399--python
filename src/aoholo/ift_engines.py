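"""Gerchberg-Saxton iterative Fourier-transform (IFT) hologram retrieval.

All engines alternate between the target and holographic planes of a 1D
optical system, clamping the amplitude in each plane according to a
regularization rule while letting the phase evolve freely:

* ``gs_static`` - phase-only retrieval with the target amplitude imposed on
  the whole target plane every cycle.
* ``gs_dynamic`` - the target is clamped only on the target domain; on a
  complementary freedom domain the current amplitude is carried over, so
  higher diffraction orders may develop there unconstrained.
* ``gs_complex`` - joint phase *and* amplitude retrieval: each cycle the
  holographic amplitude is blended back into the input with a feedback gain
  that ramps from zero up to ``am_gain``, yielding a complex (FM/AM)
  hologram that suppresses speckle on dense targets.
* ``gs_extended`` - any of the above, but with the per-cycle forward
  propagation routed through a separable 2D embedding so that a circular
  system aperture is accounted for during retrieval.

``apodize`` turns a phase-only hologram into an FM/AM hologram post hoc by
re-using the retained holographic amplitude as a transmission mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .field_model import (
    ApertureSpec,
    BeamProfile,
    Field,
    OpticalConfig,
    Plane,
    aperture_slit,
    beam_amplitude,
    fft_centered,
    ifft_centered,
)

__all__ = [
    "Target1D",
    "IFTConfig",
    "Hologram1D",
    "DegenerateTargetError",
    "MaskError",
    "gs_static",
    "gs_dynamic",
    "gs_complex",
    "gs_extended",
    "apodize",
    "decadic_gain",
    "inverse_decadic_gain",
    "reconstruct_1d",
    "efficiency_1d",
    "with_freedom_domain",
]


class DegenerateTargetError(ValueError):
    """Raised for all-zero or otherwise unusable targets."""


class MaskError(ValueError):
    """Raised when target/freedom domain masks are inconsistent."""


@dataclass
class Target1D:
    """A nonnegative 1D amplitude target with domain masks.

    ``amplitude`` is normalized to unit maximum.  ``target_mask`` marks the
    target domain: the coordinate range where the target appreciably
    differs from zero, used for clamping (dynamic mode) and for the quality
    metrics.  Dense targets smoothed to the diffraction resolution may
    carry dim sub-resolution shoulders outside the target domain; sparse
    point targets are exactly zero there.  The optional ``freedom_mask``
    marks samples whose amplitude is left unconstrained during
    dynamic-target retrieval; it must be disjoint from the target domain.
    ``length_um`` records the physical extent L_S of the target support.
    """

    amplitude: np.ndarray
    target_mask: np.ndarray
    freedom_mask: np.ndarray | None = None
    length_um: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.target_mask = np.asarray(self.target_mask, dtype=bool)
        if self.freedom_mask is None:
            self.freedom_mask = np.zeros_like(self.target_mask)
        self.freedom_mask = np.asarray(self.freedom_mask, dtype=bool)
        if self.amplitude.ndim != 1:
            raise ValueError("Target1D amplitude must be 1D")
        if self.amplitude.shape != self.target_mask.shape != self.freedom_mask.shape:
            raise MaskError("amplitude and masks must share one shape")
        if np.any(self.amplitude < 0):
            raise ValueError("target amplitude must be nonnegative")
        if np.any(self.target_mask & self.freedom_mask):
            raise MaskError("target and freedom domains must be disjoint")
        peak = self.amplitude.max()
        if peak == 0:
            raise DegenerateTargetError("target amplitude is identically zero")
        self.amplitude = self.amplitude / peak

    @property
    def n(self) -> int:
        return self.amplitude.size


def with_freedom_domain(target: Target1D, guard: int = 2) -> Target1D:
    """Return a copy whose freedom domain is everything outside the target
    domain minus a guard band of ``guard`` samples around it."""
    from scipy.ndimage import binary_dilation

    guarded = binary_dilation(target.target_mask, iterations=guard) if guard else target.target_mask
    freedom = ~guarded
    return Target1D(
        target.amplitude.copy(), target.target_mask.copy(), freedom, target.length_um, target.name
    )


@dataclass(frozen=True)
class IFTConfig:
    """Retrieval settings shared by all engines.

    ``am_gain`` is the maximum amplitude-feedback gain g_AM of the complex
    engine, reached at the end of a linear ramp of ``ramp_iterations``
    cycles (default: half the iteration budget).  The decadic-gain scale
    covers g_AM in [0, 0.99]; g_AM = 1 (full amplitude feedback) is also
    admitted.  ``apod_gain`` is the post hoc apodization gain applied by
    :func:`apodize`.
    """

    iterations: int = 200
    seed: int = 0
    regularization: str = "static"  # "static" | "dynamic" | "complex"
    am_gain: float = 0.0
    ramp_iterations: int | None = None
    apod_gain: float = 0.0
    guard_samples: int = 2

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iteration count must be >= 1")
        if not 0.0 <= self.am_gain <= 1.0:
            raise ValueError("am_gain must lie in [0, 1]")
        if not 0.0 <= self.apod_gain <= 1.0:
            raise ValueError("apod_gain must lie in [0, 1]")
        if self.regularization not in ("static", "dynamic", "complex"):
            raise ValueError(f"unknown regularization {self.regularization!r}")
        if self.ramp_iterations is not None and self.ramp_iterations > self.iterations:
            raise ValueError("ramp length cannot exceed the iteration count")

    @property
    def ramp(self) -> int:
        return self.iterations // 2 if self.ramp_iterations is None else self.ramp_iterations


@dataclass
class Hologram1D:
    """Retrieved 1D hologram: unwrapped phase plus amplitude mask.

    ``mode`` is ``"FM"`` for phase-only holograms (unit amplitude mask) and
    ``"FM/AM"`` when the mask carries amplitude modulation.  The final
    holographic amplitude seen during retrieval is retained in
    ``final_holo_amplitude`` for optional post hoc apodization.
    """

    phase_unwrapped: np.ndarray
    amplitude_mask: np.ndarray
    mode: str
    optics: OpticalConfig
    engine: str = ""
    seed: int = 0
    final_holo_amplitude: np.ndarray | None = None
    aperture: ApertureSpec | None = None  # non-None for extended-IFT holograms
    final_error: float = float("nan")
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phase_unwrapped = np.asarray(self.phase_unwrapped, dtype=float)
        self.amplitude_mask = np.asarray(self.amplitude_mask, dtype=float)
        if not np.all(np.isfinite(self.phase_unwrapped)):
            raise ValueError("unwrapped phase must be finite")
        if np.any(self.amplitude_mask < 0) or np.any(self.amplitude_mask > 1 + 1e-12):
            raise ValueError("amplitude mask must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.phase_unwrapped.size

    @property
    def phase_wrapped(self) -> np.ndarray:
        """Phase wrapped to (-pi, pi]."""
        w = np.mod(self.phase_unwrapped + np.pi, 2 * np.pi) - np.pi
        w[w == -np.pi] = np.pi
        return w

    def complex_profile(self) -> np.ndarray:
        return self.amplitude_mask * np.exp(1j * self.phase_unwrapped)


def decadic_gain(g_lin: float | np.ndarray) -> float | np.ndarray:
    """Decadic feedback gain g' = 0.5 log10(1 / (1 - g)), g in [0, 0.99]."""
    g = np.asarray(g_lin, dtype=float)
    if np.any(g < 0) or np.any(g >= 1):
        raise ValueError("linear gain must lie in [0, 1)")
    out = 0.5 * np.log10(1.0 / (1.0 - g))
    return float(out) if np.isscalar(g_lin) else out


def inverse_decadic_gain(g_prime: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`decadic_gain`: g = 1 - 10^(-2 g')."""
    gp = np.asarray(g_prime, dtype=float)
    if np.any(gp < 0):
        raise ValueError("decadic gain must be >= 0")
    out = 1.0 - 10.0 ** (-2.0 * gp)
    return float(out) if np.isscalar(g_prime) else out


# ---------------------------------------------------------------------------
# forward models


def _forward_plain(holo_field: np.ndarray) -> np.ndarray:
    """1D holographic field -> 1D target-plane field."""
    return fft_centered(holo_field)


def _make_forward_circular(aperture: ApertureSpec, optics: OpticalConfig):
    """Forward model of extended IFT: the 1D field is expanded to a
    separable 2D field, clipped by the circular aperture, propagated by 2D
    FFT, and the 1D target field recovered from the midline."""
    from .field_model import aperture_mask

    mask2d = aperture_mask(aperture, optics.grid_size, optics.aperture)

    def forward(holo_field: np.ndarray) -> np.ndarray:
        f2 = np.outer(holo_field, holo_field) * mask2d
        out = fft_centered(f2)
        return out[optics.grid_size // 2, :]

    return forward


def _target_constraint(target: Target1D, mode: str):
    """Per-cycle target-plane amplitude update rule.

    Static mode imposes the full target amplitude everywhere; dynamic mode
    imposes it only outside the freedom domain, where the current amplitude
    is carried over.
    """
    amp = target.amplitude
    if mode == "dynamic" and np.any(target.freedom_mask):
        fd = target.freedom_mask

        def clamp(field_t: np.ndarray) -> np.ndarray:
            cur = np.abs(field_t)
            new_amp = np.where(fd, cur, amp)
            return new_amp * np.exp(1j * np.angle(field_t))

    else:

        def clamp(field_t: np.ndarray) -> np.ndarray:
            return amp * np.exp(1j * np.angle(field_t))

    return clamp


def _run_ift(
    target: Target1D,
    cfg: IFTConfig,
    optics: OpticalConfig,
    *,
    target_mode: str,
    complex_feedback: bool,
    forward,
    backward,
    engine_name: str,
    aperture: ApertureSpec | None = None,
) -> Hologram1D:
    """Shared IFT loop.

    Each cycle: holographic constraint -> forward propagation -> target
    constraint -> backward propagation.  The loop starts from a uniformly
    random target-plane phase (seeded) and runs a fixed iteration budget.
    """
    n = optics.grid_size
    if target.n != n:
        raise ValueError("target length does not match the optical grid")
    rng = np.random.default_rng(cfg.seed)
    # retrieval input: a uniform beam truncated by the device aperture
    slit = aperture_slit(optics)
    input_amp = slit

    clamp = _target_constraint(target, target_mode)
    phase0 = rng.uniform(0.0, 2.0 * np.pi, n)
    field_t = target.amplitude * np.exp(1j * phase0)

    holo_amp_used = input_amp
    holo_amp_raw = input_amp
    holo_phase = np.zeros(n)
    for k in range(cfg.iterations):
        field_h = backward(field_t)
        holo_amp_raw = np.abs(field_h) * slit
        holo_phase = np.angle(field_h)
        if complex_feedback:
            ramp = min(1.0, (k + 1) / max(cfg.ramp, 1)) if cfg.ramp else 1.0
            g = cfg.am_gain * ramp
            peak = holo_amp_raw.max()
            norm = holo_amp_raw / peak if peak > 0 else holo_amp_raw
            holo_amp_used = ((1.0 - g) * input_amp + g * norm) * slit
        else:
            holo_amp_used = input_amp
        field_h = holo_amp_used * np.exp(1j * holo_phase)
        field_t = forward(field_h)
        field_t = clamp(field_t)

    if complex_feedback:
        mask = holo_amp_used / max(holo_amp_used.max(), 1e-300)
        mode = "FM/AM"
    else:
        mask = np.ones(n)
        mode = "FM"

    holo = Hologram1D(
        phase_unwrapped=np.unwrap(holo_phase),
        amplitude_mask=mask,
        mode=mode,
        optics=optics,
        engine=engine_name,
        seed=cfg.seed,
        final_holo_amplitude=holo_amp_raw,
        aperture=aperture,
        provenance={
            "engine": engine_name,
            "iterations": cfg.iterations,
            "seed": cfg.seed,
            "am_gain": cfg.am_gain,
            "ramp_iterations": cfg.ramp,
            "target": target.name,
        },
    )
    holo.final_error = _record_error(holo, target)
    return holo


def _record_error(holo: Hologram1D, target: Target1D) -> float:
    from .metrics import target_error

    recon = reconstruct_1d(holo)
    return target_error(recon.amplitude, target)


def reconstruct_1d(holo: Hologram1D, beam: BeamProfile | None = None) -> Field:
    """Reconstruct the target-plane field of a 1D hologram with its own
    forward model (plain FFT through the device aperture, or midline of the
    aperture-clipped separable 2D propagation for extended-IFT holograms).

    ``beam`` shapes the input illumination (default: uniform); the device
    aperture of the hologram's optical config is always applied.
    """
    profile = holo.complex_profile() * aperture_slit(holo.optics)
    if beam is not None:
        profile = profile * beam_amplitude(beam, holo.n, 1)
    if holo.aperture is not None and holo.aperture.shape == "circular":
        forward = _make_forward_circular(holo.aperture, holo.optics)
        out = forward(profile)
    else:
        out = _forward_plain(profile)
    return Field(out, Plane.TARGET, holo.optics)


def efficiency_1d(holo: Hologram1D, beam: BeamProfile | None = None) -> float:
    """First-order power efficiency of a 1D hologram.

    Input power is the beam power through the device aperture before the
    amplitude mask; the mask-rejected power counts as lost to the zero
    Bragg order.
    """
    slit = aperture_slit(holo.optics)
    b = slit if beam is None else slit * beam_amplitude(beam, holo.n, 1)
    input_power = float(np.sum(b**2))
    out_power = float(np.sum((b * holo.amplitude_mask) ** 2))
    return out_power / input_power


# ---------------------------------------------------------------------------
# public engines


def gs_static(target: Target1D, cfg: IFTConfig, optics: OpticalConfig) -> Hologram1D:
    """Static-target phase retrieval: the full target amplitude is imposed
    on the whole target plane every cycle.  Returns a phase-only hologram;
    the final holographic amplitude is retained for apodization."""
    return _run_ift(
        target,
        cfg,
        optics,
        target_mode="static",
        complex_feedback=False,
        forward=_forward_plain,
        backward=ifft_centered,
        engine_name="static",
    )


def gs_dynamic(target: Target1D, cfg: IFTConfig, optics: OpticalConfig) -> Hologram1D:
    """Dynamic-target phase retrieval: amplitude clamped only on the target
    domain, carried over on the freedom domain, zeroed on the guard band.
    With an empty freedom domain this reduces exactly to :func:`gs_static`."""
    return _run_ift(
        target,
        cfg,
        optics,
        target_mode="dynamic",
        complex_feedback=False,
        forward=_forward_plain,
        backward=ifft_centered,
        engine_name="dynamic",
    )


def gs_complex(target: Target1D, cfg: IFTConfig, optics: OpticalConfig) -> Hologram1D:
    """Complex (FM/AM) retrieval with amplitude feedback.

    Each cycle the holographic amplitude is replaced by a gain-weighted
    blend of the input-beam amplitude and the normalized current
    holographic amplitude; the gain ramps linearly from zero to ``am_gain``
    over the first ``ramp_iterations`` cycles to avoid early stagnation.
    """
    return _run_ift(
        target,
        cfg,
        optics,
        target_mode="dynamic" if np.any(target.freedom_mask) else "static",
        complex_feedback=True,
        forward=_forward_plain,
        backward=ifft_centered,
        engine_name="complex",
    )


def gs_extended(
    target: Target1D,
    aperture: ApertureSpec,
    cfg: IFTConfig,
    optics: OpticalConfig,
) -> Hologram1D:
    """Extended 1D IFT accounting for a circular system aperture.

    Each forward step embeds the current 1D holographic field on both axes
    of a separable 2D field, imposes the circular aperture, propagates in
    2D and recovers the 1D target field from the midline.  A square
    aperture is equivalent to the plain 1D engine (slit geometry) and falls
    back to it with a warning.
    """
    if aperture.shape == "square":
        import warnings

        warnings.warn(
            "square apertures are separable; falling back to the plain 1D engine",
            stacklevel=2,
        )
        return _dispatch_plain(target, cfg, optics)

    complex_feedback = cfg.regularization == "complex"
    target_mode = cfg.regularization if cfg.regularization != "complex" else (
        "dynamic" if np.any(target.freedom_mask) else "static"
    )
    return _run_ift(
        target,
        cfg,
        optics,
        target_mode=target_mode,
        complex_feedback=complex_feedback,
        forward=_make_forward_circular(aperture, optics),
        backward=ifft_centered,
        engine_name=f"extended-{cfg.regularization}",
        aperture=aperture,
    )


def _dispatch_plain(target: Target1D, cfg: IFTConfig, optics: OpticalConfig) -> Hologram1D:
    if cfg.regularization == "static":
        return gs_static(target, cfg, optics)
    if cfg.regularization == "dynamic":
        return gs_dynamic(target, cfg, optics)
    return gs_complex(target, cfg, optics)


def retrieve(target: Target1D, cfg: IFTConfig, optics: OpticalConfig,
             aperture: ApertureSpec | None = None) -> Hologram1D:
    """Run the engine selected by ``cfg.regularization``; with a circular
    ``aperture`` the extended variant is used."""
    if aperture is not None and aperture.shape == "circular":
        return gs_extended(target, aperture, cfg, optics)
    return _dispatch_plain(target, cfg, optics)


def apodize(holo: Hologram1D, gain: float) -> Hologram1D:
    """Post hoc apodization of a phase-only hologram.

    The amplitude mask becomes ``(1 - gain) + gain * A / max(A)`` with A the
    retained final holographic amplitude; the phase is unchanged.  Gain 0
    returns a pure FM hologram, gain 1 the fully apodized FM/AM hologram.
    """
    if not 0.0 <= gain <= 1.0:
        raise ValueError("apodization gain must lie in [0, 1]")
    if holo.final_holo_amplitude is None:
        raise ValueError("hologram carries no retained holographic amplitude")
    a = holo.final_holo_amplitude
    peak = a.max()
    norm = a / peak if peak > 0 else a
    mask = (1.0 - gain) + gain * norm
    out = replace(
        holo,
        amplitude_mask=mask,
        mode="FM/AM" if gain > 0 else "FM",
        provenance={**holo.provenance, "apod_gain": gain},
    )
    out.final_error = float("nan")
    return out
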
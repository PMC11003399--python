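"""Translation between optical phase profiles and acoustic frequency envelopes.

In the synchronous regime every laser pulse sees a static acoustic grating,
and the deflector transfer function reduces to a local linear relation
between the wavefront slope and the acoustic frequency offset from the
carrier::

    d(phi)/ds = 2 pi / v_ac * delta_f(s)

with ``v_ac`` the acoustic phase velocity (650 m/s for shear waves in TeO2)
and ``s`` the physical coordinate along the active axis.  Any *unwrapped*
1D optical phase therefore maps to a frequency-modulation envelope and back;
1D phases are always unwrappable because phase vortices do not exist in one
dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field_model import OpticalConfig
from .ift_engines import Hologram1D

__all__ = [
    "AODSpec",
    "AODReport",
    "phase_to_frequency",
    "frequency_to_phase",
    "validate",
]


@dataclass(frozen=True)
class AODSpec:
    """Acousto-optic deflector device parameters."""

    v_ac_m_s: float = 650.0  # acoustic phase velocity (shear TeO2)
    aperture_mm: float = 15.0
    carrier_MHz: float = 75.0
    bandwidth_MHz: float = 50.0  # allocated bandwidth around the carrier
    laser_rate_kHz: float = 40.0

    def __post_init__(self) -> None:
        for name in ("v_ac_m_s", "aperture_mm", "carrier_MHz", "bandwidth_MHz", "laser_rate_kHz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def cycle_time_us(self) -> float:
        """Acoustic fill time of the aperture, T = D / v_ac, in us."""
        return self.aperture_mm * 1e-3 / self.v_ac_m_s * 1e6

    @property
    def max_laser_rate_kHz(self) -> float:
        """Maximal synchronous-mode laser rate 1 / T in kHz."""
        return 1e3 / self.cycle_time_us


@dataclass
class AODReport:
    """Device-constraint validation report."""

    laser_rate_ok: bool
    laser_rate_margin_kHz: float
    bandwidth_ok: bool
    bandwidth_margin_MHz: float
    peak_excursion_MHz: float

    @property
    def passed(self) -> bool:
        return self.laser_rate_ok and self.bandwidth_ok


def _sample_pitch_mm(spec: AODSpec, optics: OpticalConfig) -> float:
    """Holographic samples map onto the physical device aperture."""
    return spec.aperture_mm / optics.grid_size


def phase_to_frequency(
    holo: Hologram1D | np.ndarray, spec: AODSpec, optics: OpticalConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Convert an unwrapped phase profile to a frequency envelope.

    Returns ``(s_mm, delta_f_MHz)`` with the frequency offset
    ``delta_f = v_ac / (2 pi) * d(phi)/ds`` evaluated by central differences
    on the physical coordinate (one-sided stencils at the edges).
    """
    phase = holo.phase_unwrapped if isinstance(holo, Hologram1D) else np.asarray(holo, float)
    if phase.ndim != 1:
        raise ValueError("expected a 1D unwrapped phase profile")
    ds_m = _sample_pitch_mm(spec, optics) * 1e-3
    dphids = np.gradient(phase, ds_m)
    delta_f_hz = spec.v_ac_m_s / (2.0 * np.pi) * dphids
    n = phase.size
    s_mm = (np.arange(n) - n // 2) * _sample_pitch_mm(spec, optics)
    return s_mm, delta_f_hz * 1e-6


def frequency_to_phase(
    delta_f_MHz: np.ndarray, spec: AODSpec, optics: OpticalConfig
) -> np.ndarray:
    """Integrate a frequency envelope back into an unwrapped phase.

    Inverts the central-difference stencil of :func:`phase_to_frequency`
    exactly (a second-order leapfrog recursion), so a phase -> frequency ->
    phase roundtrip returns the input up to an additive constant at machine
    precision.  The phase is anchored to zero at the left edge.
    """
    env = np.asarray(delta_f_MHz, dtype=float)
    if env.ndim != 1:
        raise ValueError("expected a 1D frequency envelope")
    ds_m = _sample_pitch_mm(spec, optics) * 1e-3
    g = 2.0 * np.pi / spec.v_ac_m_s * env * 1e6  # phase slope, rad/m
    n = g.size
    phase = np.empty(n)
    phase[0] = 0.0
    if n > 1:
        phase[1] = g[0] * ds_m  # one-sided stencil at the left edge
    # interior central differences: phi[i+1] = phi[i-1] + 2 h g[i]; the two
    # parity chains are independent cumulative sums
    if n > 2:
        even_idx = np.arange(2, n, 2)  # phi[2], phi[4], ... from phi[0]
        odd_idx = np.arange(3, n, 2)   # phi[3], phi[5], ... from phi[1]
        phase[even_idx] = phase[0] + 2.0 * ds_m * np.cumsum(g[1:n - 1:2])[: even_idx.size]
        phase[odd_idx] = phase[1] + 2.0 * ds_m * np.cumsum(g[2:n - 1:2])[: odd_idx.size]
    return phase


def validate(holo_or_env, spec: AODSpec, optics: OpticalConfig | None = None) -> AODReport:
    """Check synchronous-mode device constraints.

    Flags (i) a laser rate above the AOD cycle rate (boundary inclusive:
    ``r_laser <= 1/T`` passes) and (ii) a frequency-envelope excursion
    beyond half the allocated bandwidth around the carrier.
    """
    rate_margin = spec.max_laser_rate_kHz - spec.laser_rate_kHz
    rate_ok = spec.laser_rate_kHz <= spec.max_laser_rate_kHz

    if isinstance(holo_or_env, Hologram1D):
        if optics is None:
            raise ValueError("validating a hologram requires the optical config")
        _, env = phase_to_frequency(holo_or_env, spec, optics)
    else:
        env = np.asarray(holo_or_env, dtype=float)
    peak = float(np.max(np.abs(env))) if env.size else 0.0
    half_bw = spec.bandwidth_MHz / 2.0
    return AODReport(
        laser_rate_ok=bool(rate_ok),
        laser_rate_margin_kHz=float(rate_margin),
        bandwidth_ok=bool(peak <= half_bw),
        bandwidth_margin_MHz=float(half_bw - peak),
        peak_excursion_MHz=peak,
    )
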
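"""Quantitative evaluation of holographic reconstructions.

The metrics operate on reconstruction amplitudes (not intensities, unless
noted) and are normalization-free: the target error rescales the
reconstruction by least squares before comparing, and the speckle noise is
a coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .field_model import Field

__all__ = [
    "MetricsRecord",
    "UndefinedMetricError",
    "target_error",
    "speckle_noise",
    "power_efficiency",
    "moving_phase_variance",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined (empty domain, zero power, ...)."""


@dataclass
class MetricsRecord:
    target_error: float = float("nan")
    speckle_noise: float = float("nan")
    power_efficiency: float = float("nan")
    metadata: dict = dc_field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "target_error": self.target_error,
            "speckle_noise": self.speckle_noise,
            "power_efficiency": self.power_efficiency,
            **({"metadata": self.metadata} if self.metadata else {}),
        }


def _amp_and_domain(recon, target) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalize inputs: reconstruction amplitude, target amplitude, mask."""
    amp = recon.amplitude if isinstance(recon, Field) else np.abs(np.asarray(recon, dtype=float))
    if hasattr(target, "target_mask"):  # Target1D
        t = target.amplitude
        mask = target.target_mask
    else:
        t = np.asarray(target, dtype=float)
        mask = t > 0
    if amp.shape != t.shape:
        raise ValueError(f"shape mismatch: reconstruction {amp.shape} vs target {t.shape}")
    return amp, t, mask


def target_error(recon, target, rescale: str = "max") -> float:
    """Relative RMS amplitude deviation on the target domain.

    Reconstruction amplitudes are presented normalized to unit peak, so by
    default the reconstruction is rescaled to unit maximum on the target
    domain (the target amplitude itself is peak-normalized) before
    ``error = sqrt(sum((c A - T)^2) / sum(T^2))`` is evaluated over the
    target domain.  ``rescale="lsq"`` uses the least-squares factor
    ``c = sum(A T) / sum(A^2)`` instead.  A reconstruction that vanishes on
    the target domain has error 1 (rescale factor 0 by convention).
    """
    amp, t, mask = _amp_and_domain(recon, target)
    if not np.any(mask):
        raise UndefinedMetricError("empty target domain")
    a = amp[mask]
    tt = t[mask]
    if rescale == "max":
        peak = float(a.max())
        c = 1.0 / peak if peak > 0 else 0.0
    elif rescale == "lsq":
        denom = float(np.sum(a * a))
        c = float(np.sum(a * tt)) / denom if denom > 0 else 0.0
    else:
        raise ValueError(f"unknown rescale convention {rescale!r}")
    return float(np.sqrt(np.sum((c * a - tt) ** 2) / np.sum(tt * tt)))


def speckle_noise(recon, target) -> float:
    """Coefficient of variation of intensity over the target domain.

    The reconstructed intensity is divided pointwise by the target
    intensity before taking std/mean, so shaped (non-flat) targets are
    evaluated against their intended profile; for flat targets this is
    simply the CV of the intensity.  Fully developed speckle (exponential
    intensity statistics) gives a CV of ~1.
    """
    amp, t, mask = _amp_and_domain(recon, target)
    mask = mask & (t > 0)
    if not np.any(mask):
        raise UndefinedMetricError("empty target domain")
    ratio = (amp[mask] / t[mask]) ** 2
    mean = float(np.mean(ratio))
    if mean == 0:
        raise UndefinedMetricError("zero mean intensity on the target domain")
    return float(np.std(ratio) / mean)


def power_efficiency(result=None, *, first_order_power: float | None = None,
                     input_power: float | None = None) -> float:
    """First-Bragg-order power divided by input power.

    Accepts a ``ReconstructionResult``-like object (attributes
    ``first_order_power`` and ``input_power``) or the two powers as
    keywords.  Power rejected by amplitude masks and apertures is counted
    as lost to the zero order.
    """
    if result is not None:
        first_order_power = result.first_order_power
        input_power = result.input_power
    if input_power is None or first_order_power is None:
        raise ValueError("need a result object or both powers")
    if input_power <= 0:
        raise UndefinedMetricError("input power must be > 0")
    return float(first_order_power / input_power)


def moving_phase_variance(field: Field, window_um: float = 0.5) -> np.ndarray:
    """Sliding-window variance of the target-plane phase.

    The phase within each (square, for 2D fields) window is referenced to
    the window's circular mean direction before squaring, which avoids
    2-pi wrap artifacts.  ``window_um`` is converted to samples with the
    field's target-plane pitch; edges are padded by reflection so the
    output has the field's shape.
    """
    pitch = field.optics.pitch_target_um
    w = max(2, int(round(window_um / pitch)))
    phase = field.phase
    n = field.optics.grid_size
    if w > n:
        raise ValueError("window exceeds the field extent")
    pad = (w - 1) // 2, w - 1 - (w - 1) // 2

    if phase.ndim == 1:
        padded = np.pad(phase, pad, mode="reflect")
        win = np.lib.stride_tricks.sliding_window_view(padded, w)
        z = np.exp(1j * win)
        mean_dir = np.angle(np.mean(z, axis=-1))
        d = np.angle(np.exp(1j * (win - mean_dir[:, None])))
        return np.mean(d * d, axis=-1)

    padded = np.pad(phase, (pad, pad), mode="reflect")
    win = np.lib.stride_tricks.sliding_window_view(padded, (w, w))
    z = np.exp(1j * win)
    mean_dir = np.angle(np.mean(z, axis=(-2, -1)))
    d = np.angle(np.exp(1j * (win - mean_dir[..., None, None])))
    return np.mean(d * d, axis=(-2, -1))
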
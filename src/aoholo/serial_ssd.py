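"""Seven-segment-display (SSD) text as serial pseudo-2D holography.

Arbitrary text lacks ps2D symmetry and cannot be stored in a single
crossed-axis hologram.  SSD glyphs, however, are unions of axis-aligned
bars, and the seven segments regroup into five *meta segments* that are
rank-1 (Cartesian-product) patterns for ANY text:

====  ===========  =================================
No.   segments     geometry
====  ===========  =================================
1     {1}          top bars (one row of y)
2     {2, 3}       upper vertical bars (upper half)
3     {4}          bottom bars
4     {5, 6}       lower vertical bars (lower half)
5     {7}          middle bars
====  ===========  =================================

Segment numbering: 1 = top, 2 = upper-right, 3 = upper-left, 4 = bottom,
5 = lower-right, 6 = lower-left, 7 = middle.  Within a group every active
bar shares the same y extent, so each group's union over characters
factorizes into (column profile) x (row profile) regardless of the text.
Meta segments whose union is itself still rank-1 (e.g. top and middle bars
active in exactly the same characters) are merged, so at most five — and
often fewer — holograms are needed per text frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .field_model import ApertureSpec, BeamProfile, OpticalConfig
from .ift_engines import (
    IFTConfig,
    Target1D,
    apodize,
    gs_complex,
    gs_extended,
    gs_static,
)
from .metrics import power_efficiency
from .ps2d_synthesis import (
    Ps2DHologram,
    ReconstructionResult,
    compose,
    is_ps2d_separable,
    reconstruct_2d,
)

__all__ = [
    "SSDLayout",
    "MetaSegmentSet",
    "SerialHologram",
    "EncodingError",
    "GROUP_MAP",
    "SUPPORTED_CHARACTERS",
    "ssd_encode",
    "build_meta_segments",
    "build_serial_holograms",
    "sum_reconstructions",
]


class EncodingError(ValueError):
    """Raised for characters outside the supported SSD code."""


GROUP_MAP: dict[int, frozenset[int]] = {
    1: frozenset({1}),
    2: frozenset({2, 3}),
    3: frozenset({4}),
    4: frozenset({5, 6}),
    5: frozenset({7}),
}

# classic a-g segment letters -> numbering above
_AG = {"a": 1, "b": 2, "c": 5, "d": 4, "e": 6, "f": 3, "g": 7}

_CODE_AG: dict[str, str] = {
    "0": "abcdef", "1": "bc", "2": "abdeg", "3": "abcdg", "4": "bcfg",
    "5": "acdfg", "6": "acdefg", "7": "abc", "8": "abcdefg", "9": "abcdfg",
    "A": "abcefg", "B": "cdefg", "C": "adef", "D": "bcdeg", "E": "adefg",
    "F": "aefg", "G": "acdef", "H": "bcefg", "I": "ef", "J": "bcde",
    "L": "def", "N": "ceg", "O": "abcdef", "P": "abefg", "Q": "abcfg",
    "R": "eg", "S": "acdfg", "T": "defg", "U": "bcdef", "Y": "bcdfg",
    " ": "",
}

SEGMENT_CODE: dict[str, frozenset[int]] = {
    ch: frozenset(_AG[s] for s in segs) for ch, segs in _CODE_AG.items()
}
SUPPORTED_CHARACTERS = "".join(sorted(SEGMENT_CODE))


def ssd_encode(text: str) -> list[frozenset[int]]:
    """Per-character segment activation sets (uppercased lookup)."""
    activations = []
    bad = sorted({c for c in text if c.upper() not in SEGMENT_CODE})
    if bad:
        raise EncodingError(f"unsupported character(s): {bad}")
    for c in text:
        activations.append(SEGMENT_CODE[c.upper()])
    return activations


@dataclass(frozen=True)
class SSDLayout:
    """Geometry of one display character and the inter-character pitch (um)."""

    char_width_um: float = 8.0
    char_height_um: float = 16.0
    line_width_um: float = 1.5
    pitch_um: float = 12.0

    def segment_rect(self, seg: int) -> tuple[float, float, float, float]:
        """(x0, x1, y0, y1) of a segment, char origin at its lower-left."""
        w, h, t = self.char_width_um, self.char_height_um, self.line_width_um
        rects = {
            1: (0.0, w, h - t, h),            # top
            4: (0.0, w, 0.0, t),              # bottom
            7: (0.0, w, (h - t) / 2, (h + t) / 2),  # middle
            2: (w - t, w, h / 2, h),          # upper-right
            3: (0.0, t, h / 2, h),            # upper-left
            5: (w - t, w, 0.0, h / 2),        # lower-right
            6: (0.0, t, 0.0, h / 2),          # lower-left
        }
        return rects[seg]


@dataclass
class MetaSegmentSet:
    """The per-text ps2D-separable meta-segment target patterns."""

    text: str
    patterns: dict[str, np.ndarray]  # label -> binary target pattern (N x N)
    merged: list[tuple[int, ...]] = dc_field(default_factory=list)
    layout: SSDLayout = dc_field(default_factory=SSDLayout)

    @property
    def count(self) -> int:
        return len(self.patterns)

    def full_pattern(self) -> np.ndarray:
        out = None
        for p in self.patterns.values():
            out = p.copy() if out is None else np.maximum(out, p)
        return out


def _rasterize(
    rects: list[tuple[float, float, float, float]], optics: OpticalConfig
) -> np.ndarray:
    """Binary sample-center rasterization of rectangles (um) on the target
    grid, pattern centered on the optical axis."""
    n = optics.grid_size
    pitch = optics.pitch_target_um
    coords = (np.arange(n) - n // 2) * pitch
    img = np.zeros((n, n))
    for x0, x1, y0, y1 in rects:
        cx = (coords >= x0) & (coords < x1)
        cy = (coords >= y0) & (coords < y1)
        img[np.ix_(cy, cx)] = 1.0
    return img


def build_meta_segments(
    text: str, layout: SSDLayout | None = None, optics: OpticalConfig | None = None
) -> MetaSegmentSet:
    """Regroup the active segments of ``text`` into separable targets.

    Each of the five meta-segment groups is rasterized as the union over
    characters of its active segments; empty groups are dropped and groups
    whose pairwise union still passes the rank-1 separability test are
    merged (this realizes the translation-symmetry merge operationally).
    """
    from .field_model import default_config

    layout = layout or SSDLayout()
    optics = optics or default_config()
    activations = ssd_encode(text)
    n_chars = len(activations)
    total_w = (n_chars - 1) * layout.pitch_um + layout.char_width_um if n_chars else 0.0
    x_off = -total_w / 2
    y_off = -layout.char_height_um / 2

    group_rects: dict[int, list] = {g: [] for g in GROUP_MAP}
    for i, active in enumerate(activations):
        for g, members in GROUP_MAP.items():
            for seg in active & members:
                x0, x1, y0, y1 = layout.segment_rect(seg)
                dx = x_off + i * layout.pitch_um
                group_rects[g].append((x0 + dx, x1 + dx, y0 + y_off, y1 + y_off))

    groups = {
        g: _rasterize(rects, optics) for g, rects in group_rects.items() if rects
    }
    groups = {g: p for g, p in groups.items() if p.any()}

    # operational merge: combine any surviving groups whose union is rank-1
    labels: dict[str, tuple[np.ndarray, tuple[int, ...]]] = {
        str(g): (p, (g,)) for g, p in groups.items()
    }
    merged_pairs: list[tuple[int, ...]] = []
    changed = True
    while changed:
        changed = False
        keys = sorted(labels)
        for i, ki in enumerate(keys):
            for kj in keys[i + 1:]:
                union = np.maximum(labels[ki][0], labels[kj][0])
                ok, _, _ = is_ps2d_separable(union, tol=1e-6)
                if ok:
                    gids = labels[ki][1] + labels[kj][1]
                    del labels[kj]
                    labels.pop(ki)
                    labels["+".join(map(str, gids))] = (union, gids)
                    merged_pairs.append(gids)
                    changed = True
                    break
            if changed:
                break

    patterns = {}
    for key, (pat, gids) in sorted(labels.items(), key=lambda kv: kv[1][1]):
        ok, _, _ = is_ps2d_separable(pat, tol=1e-6)
        if not ok:
            raise RuntimeError(f"meta segment {key} is not separable (internal error)")
        patterns[f"No.{key}"] = pat
    return MetaSegmentSet(text=text, patterns=patterns, merged=merged_pairs, layout=layout)


@dataclass
class SerialHologram:
    """One frame of a serial-holography sequence."""

    label: str
    hologram: Ps2DHologram
    reconstruction: ReconstructionResult
    efficiency: float


def _axis_target(profile: np.ndarray, optics: OpticalConfig) -> Target1D:
    """Axis factor profile -> 1D target, smoothed to the system resolution."""
    from scipy.ndimage import gaussian_filter1d

    amp = np.where(profile > 1e-9 * profile.max(), profile, 0.0)
    idx = np.flatnonzero(amp)
    length = (idx[-1] - idx[0] + 1) * optics.pitch_target_um if idx.size else 0.0
    amp = gaussian_filter1d(amp, optics.resolution_samples)
    peak = amp.max()
    if peak > 0:
        amp = amp / peak
    mask = amp >= 0.05
    return Target1D(amp, mask, length_um=length)


def build_serial_holograms(
    meta: MetaSegmentSet,
    cfg: IFTConfig | None = None,
    optics: OpticalConfig | None = None,
    mode: str = "hybrid",
    beam: BeamProfile | None = None,
    aperture: ApertureSpec | None = None,
    apod_gain: float = 0.0,
    extended: bool = False,
) -> list[SerialHologram]:
    """Retrieve one ps2D hologram per meta segment.

    ``mode`` selects the per-axis engines: ``"hybrid"`` runs the complex
    (FM/AM) engine on the axis with the larger target support and the
    phase-only static engine on the other; ``"fm"`` is phase-only on both
    axes; ``"complex"`` FM/AM on both.  ``apod_gain`` > 0 apodizes the FM
    axes post hoc (removes residual second-order ghosts at some efficiency
    cost).  Empty meta segments emit no hologram.
    """
    from .field_model import default_config

    cfg = cfg or IFTConfig(regularization="complex", am_gain=0.99)
    optics = optics or default_config()
    beam = beam or BeamProfile("gaussian", diameter=optics.aperture)
    aperture = aperture or ApertureSpec("circular", None)

    frames: list[SerialHologram] = []
    for j, (label, pattern) in enumerate(meta.patterns.items()):
        if not pattern.any():
            continue
        ok, px, py = is_ps2d_separable(pattern, tol=1e-6)
        if not ok:
            raise RuntimeError(f"stored meta segment {label} is not separable")
        axes = []
        support = [int(np.count_nonzero(p > 1e-9)) for p in (px, py)]
        for axis, profile in enumerate((px, py)):
            target = _axis_target(profile, optics)
            if mode == "complex":
                engine = "complex"
            elif mode == "fm":
                engine = "static"
            elif mode == "hybrid":
                engine = "complex" if support[axis] >= max(support) else "static"
            else:
                raise ValueError(f"unknown mode {mode!r}")
            axis_cfg = IFTConfig(
                iterations=cfg.iterations,
                seed=cfg.seed + 101 * j + axis,
                regularization=engine,
                am_gain=cfg.am_gain if engine == "complex" else 0.0,
                ramp_iterations=cfg.ramp_iterations,
            )
            if extended and engine != "complex":
                holo = gs_extended(target, aperture, axis_cfg, optics)
            elif engine == "complex":
                holo = gs_complex(target, axis_cfg, optics)
            else:
                holo = gs_static(target, axis_cfg, optics)
            if engine == "static" and apod_gain > 0:
                holo = apodize(holo, apod_gain)
            axes.append(holo)

        ps2d = compose(axes[0], axes[1], label=f"{meta.text}:{label}")
        recon = reconstruct_2d(ps2d, aperture=aperture, beam=beam, optics=optics)
        frames.append(
            SerialHologram(
                label=label,
                hologram=ps2d,
                reconstruction=recon,
                efficiency=power_efficiency(recon),
            )
        )
    return frames


def sum_reconstructions(
    results: list[ReconstructionResult] | list[np.ndarray],
    two_photon: bool = False,
) -> np.ndarray:
    """Camera-accumulation model: pointwise sum of the frame intensities
    (optionally squared per frame for two-photon rendering), normalized to
    unit maximum."""
    if not results:
        raise ValueError("no reconstructions to sum")
    acc = None
    for r in results:
        frame = r.intensity if isinstance(r, ReconstructionResult) else np.asarray(r, float)
        if two_photon:
            frame = frame**2
        if acc is None:
            acc = frame.astype(float).copy()
        elif frame.shape != acc.shape:
            raise ValueError(f"shape mismatch: {frame.shape} vs {acc.shape}")
        else:
            acc += frame
    peak = acc.max()
    return acc / peak if peak > 0 else acc
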
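"""Orthonormal pseudo-2D polynomial basis on the unit disk.

Crossed 1D modulators can only realize wavefronts of the separable form
``f(x, y) = g(x) + h(y)``.  Restricted to polynomials this space is spanned,
order by order, by the family ``{1; x, y; x^2 + y^2, x^2 - y^2;
x^3 + y^3, x^3 - y^3; ...}``.  Gram-Schmidt orthonormalization under the
uniform disk inner product yields exactly ``2 n + 1`` modes up to order n
(piston, two tilts, then one symmetric and one antisymmetric mode per
order), against ``n (n + 3) / 2`` modes of the full 2D Zernike space
(piston excluded).  Orders 1 and 2 coincide with the Zernike modes of tilt,
defocus and vertical astigmatism; from order 3 on, the symmetric modes form
a pseudo-coma / pseudo-spherical family and the antisymmetric modes a
pseudo-astigmatism family whose Zernike decompositions pick up foil terms.

All inner products are evaluated numerically on a Cartesian disk grid with
boundary pixels weighted by their supersampled in-disk area fraction; the
basis (and the Zernike set used for decomposition) is orthonormalized with
respect to that discrete inner product, so Gram identities and Parseval
hold at machine precision on the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "DiskGrid",
    "Ps2DMode",
    "ZernikeDecomposition",
    "build_ps2d_basis",
    "zernike_decompose",
    "zernike_cartesian",
    "ps2d_mode_count",
    "zernike_mode_count",
]


def ps2d_mode_count(n: int) -> int:
    """Number of ps2D polynomial modes up to order n (piston included)."""
    return 2 * n + 1


def zernike_mode_count(n: int) -> int:
    """Number of 2D Zernike modes up to radial order n (piston excluded)."""
    return n * (n + 3) // 2


@dataclass(frozen=True)
class DiskGrid:
    """Cartesian sampling of the unit disk with area-fraction edge weights."""

    x: np.ndarray  # (M, M)
    y: np.ndarray
    weights: np.ndarray  # in-disk area fraction per pixel, 0 outside

    @property
    def size(self) -> int:
        return self.x.shape[0]

    def inner(self, f: np.ndarray, g: np.ndarray) -> float:
        """Mean-over-disk inner product <f, g> (piston has unit norm)."""
        return float(np.sum(self.weights * f * g) / np.sum(self.weights))

    def norm(self, f: np.ndarray) -> float:
        return math.sqrt(max(0.0, self.inner(f, f)))


@lru_cache(maxsize=8)
def disk_grid(grid_size: int = 512, supersample: int = 16) -> DiskGrid:
    """Build the unit-disk quadrature grid.

    Pixels fully inside the circle get weight 1; pixels crossed by the rim
    get the fraction of their area inside the disk, estimated by
    ``supersample x supersample`` subsampling.
    """
    m = grid_size
    h = 2.0 / m
    centers = -1.0 + h * (np.arange(m) + 0.5)
    xx, yy = np.meshgrid(centers, centers)
    r2 = xx**2 + yy**2
    inner_radius = 1.0 - h * math.sqrt(0.5)
    outer_radius = 1.0 + h * math.sqrt(0.5)
    weights = (r2 <= inner_radius**2).astype(float)
    edge = (r2 > inner_radius**2) & (r2 < outer_radius**2)
    if np.any(edge):
        offs = (np.arange(supersample) + 0.5) / supersample - 0.5
        ex, ey = xx[edge], yy[edge]
        frac = np.zeros(ex.size)
        for ox in offs:
            sub_x = ex + ox * h
            for oy in offs:
                sub_y = ey + oy * h
                frac += sub_x**2 + sub_y**2 <= 1.0
        weights[edge] = frac / supersample**2
    return DiskGrid(xx, yy, weights)


@dataclass
class Ps2DMode:
    """One orthonormal ps2D polynomial mode sampled on the disk grid."""

    order: int
    parity: str  # "piston" | "tilt" | "symmetric" | "antisymmetric"
    name: str
    values: np.ndarray
    grid: DiskGrid


@dataclass
class ZernikeDecomposition:
    """Zernike coefficients of a disk function, indexed by (n, m) in the
    two-index convention (radial degree n, signed azimuthal frequency m)."""

    coefficients: dict[tuple[int, int], float]
    residual: float

    def dominant(self, threshold: float = 1e-3) -> dict[tuple[int, int], float]:
        return {k: v for k, v in self.coefficients.items() if abs(v) > threshold}


def _mode_name(order: int, parity: str) -> str:
    if parity == "piston":
        return "piston"
    if order == 1:
        return {"symmetric": "tilt_x", "antisymmetric": "tilt_y"}[parity]
    if order == 2:
        return {"symmetric": "defocus", "antisymmetric": "vertical_astigmatism"}[parity]
    if order % 2:
        return f"ps_coma_{order}_{'sym' if parity == 'symmetric' else 'anti'}"
    return f"ps_spherical_{order}" if parity == "symmetric" else f"ps_astigmatism_{order}"


def build_ps2d_basis(max_order: int, grid_size: int = 512) -> list[Ps2DMode]:
    """Gram-Schmidt orthonormalization of the separable polynomial family.

    Returns ``2 * max_order + 1`` modes ordered by polynomial order, each of
    unit norm under the discrete disk inner product.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    grid = disk_grid(grid_size)
    x, y = grid.x, grid.y

    raw: list[tuple[int, str, np.ndarray]] = [(0, "piston", np.ones_like(x))]
    raw.append((1, "symmetric", x.copy()))
    raw.append((1, "antisymmetric", y.copy()))
    for k in range(2, max_order + 1):
        raw.append((k, "symmetric", x**k + y**k))
        raw.append((k, "antisymmetric", x**k - y**k))

    modes: list[Ps2DMode] = []
    basis_vals: list[np.ndarray] = []
    for order, parity, vals in raw:
        v = vals.copy()
        # modified Gram-Schmidt, two passes for numerical orthogonality
        for _ in range(2):
            for b in basis_vals:
                v -= grid.inner(v, b) * b
        nrm = grid.norm(v)
        if nrm < 1e-12:
            raise RuntimeError("degenerate basis candidate; increase grid_size")
        v /= nrm
        basis_vals.append(v)
        modes.append(
            Ps2DMode(order, "piston" if order == 0 else parity, _mode_name(order, parity), v, grid)
        )
    return modes


def _zernike_radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        c = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m) // 2 - k)
                * math.factorial((n - m) // 2 - k)
            )
        )
        out += c * rho ** (n - 2 * k)
    return out


def zernike_cartesian(n: int, m: int, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Zernike polynomial Z_n^m on Cartesian coordinates, unit-RMS
    normalization over the disk (positive m: cosine, negative m: sine)."""
    rho = np.sqrt(x**2 + y**2)
    theta = np.arctan2(y, x)
    r = _zernike_radial(n, abs(m), rho)
    norm = math.sqrt(2 * (n + 1)) if m else math.sqrt(n + 1)
    if m > 0:
        return norm * r * np.cos(m * theta)
    if m < 0:
        return norm * r * np.sin(-m * theta)
    return norm * r


def _zernike_indices(max_order: int) -> list[tuple[int, int]]:
    idx = []
    for n in range(max_order + 1):
        for m in range(-n, n + 1, 2):
            idx.append((n, m))
    return idx


@lru_cache(maxsize=8)
def _orthonormal_zernikes(max_order: int, grid_size: int) -> tuple:
    """Zernike set re-orthonormalized under the discrete disk inner product
    (symmetric Loewdin orthogonalization, which perturbs each analytic mode
    minimally), so grid-quadrature Parseval identities are exact."""
    grid = disk_grid(grid_size)
    idx = _zernike_indices(max_order)
    vals = np.stack([zernike_cartesian(n, m, grid.x, grid.y) for n, m in idx])
    w = grid.weights / np.sum(grid.weights)
    flat = vals.reshape(len(idx), -1)
    gram = (flat * w.ravel()) @ flat.T
    evals, evecs = np.linalg.eigh(gram)
    inv_sqrt = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
    ortho = (inv_sqrt @ flat).reshape(vals.shape)
    return idx, ortho, grid


def zernike_decompose(
    mode: Ps2DMode | np.ndarray,
    max_zernike_order: int = 10,
    grid_size: int | None = None,
) -> ZernikeDecomposition:
    """Decompose a disk function into 2D Zernike polynomials.

    Coefficients are discrete disk inner products with the (grid-)
    orthonormal Zernike set; the residual is the norm of the unexplained
    remainder, so ``sum(c^2) + residual^2 = ||mode||^2`` exactly.
    """
    if isinstance(mode, Ps2DMode):
        values = mode.values
        grid_size = mode.grid.size
    else:
        values = np.asarray(mode, dtype=float)
        grid_size = grid_size or values.shape[0]
    if grid_size < 8 * (max_zernike_order + 1):
        raise ValueError(
            f"grid size {grid_size} too coarse for Zernike order {max_zernike_order}"
        )
    idx, ortho, grid = _orthonormal_zernikes(max_zernike_order, grid_size)
    if values.shape != grid.x.shape:
        raise ValueError("mode must be sampled on the same disk grid")
    coeffs = {}
    total = grid.inner(values, values)
    explained = 0.0
    for (n, m), z in zip(idx, ortho):
        c = grid.inner(values, z)
        coeffs[(n, m)] = c
        explained += c * c
    residual = math.sqrt(max(0.0, total - explained))
    return ZernikeDecomposition(coeffs, residual)
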
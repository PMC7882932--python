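"""Occurrence-probability surfaces and highest-density regions on score planes.

The density layer of a trait-space figure is a 2-D Gaussian product-kernel
estimate of the reference scores on the displayed component plane, and the
"density areas" drawn per growth form are highest-density regions (HDRs): the
smallest regions containing a stated probability mass (0.50 and 0.95 by
default).  Thresholds are found on the evaluation grid by accumulating cell
mass in decreasing density order; contours are traced at the threshold level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from skimage import measure

DEFAULT_MASSES = (0.50, 0.95)


@dataclass(frozen=True)
class DensityGrid:
    """A kernel density estimate evaluated on a regular grid.

    ``density[i, j]`` is the estimate at ``(x[i], y[j])``; the bandwidths are
    the per-axis Gaussian kernel SDs actually used.
    """

    x: np.ndarray
    y: np.ndarray
    density: np.ndarray
    bandwidths: tuple[float, float]
    n: int

    @property
    def cell_area(self) -> float:
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))

    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area)

    def at(self, points: np.ndarray) -> np.ndarray:
        """Density at arbitrary points, by bilinear interpolation of the grid."""
        interp = RegularGridInterpolator(
            (self.x, self.y), self.density, bounds_error=False, fill_value=0.0
        )
        return interp(np.asarray(points, dtype=float))


@dataclass(frozen=True)
class HDRSet:
    """Highest-density regions of one grid at one or more probability masses.

    ``thresholds[q]`` is the density level whose superlevel set holds mass q;
    ``contours[q]`` is a list of (m x 2) polylines in score coordinates.
    Thresholds strictly decrease as the mass grows, so smaller-mass regions
    nest inside larger ones.
    """

    grid: DensityGrid
    masses: tuple[float, ...]
    thresholds: dict[float, float]
    contours: dict[float, list[np.ndarray]]

    def contains(self, points: np.ndarray, mass: float) -> np.ndarray:
        """Boolean mask: which points lie inside the mass-q region."""
        return self.at_mass_density(points) >= self.thresholds[mass]

    def at_mass_density(self, points: np.ndarray) -> np.ndarray:
        return self.grid.at(points)


def scott_bandwidths(points: np.ndarray) -> tuple[float, float]:
    """Scott's rule per axis for a 2-D sample: sigma_i * n^(-1/6)."""
    n = points.shape[0]
    sd = points.std(axis=0, ddof=1)
    factor = n ** (-1.0 / 6.0)
    return float(sd[0] * factor), float(sd[1] * factor)


def estimate_density(
    points: np.ndarray,
    grid_size: int = 200,
    pad_bandwidths: float = 3.0,
    bandwidths: tuple[float, float] | None = None,
) -> DensityGrid:
    """Gaussian product-kernel density estimate of 2-D scores on a regular grid.

    The grid spans the data range padded by ``pad_bandwidths`` kernel SDs on
    each side, so essentially all kernel mass lies on the grid and the Riemann
    sum of the estimate is ~1.  The product kernel is separable, so the grid
    evaluation is two 1-D kernel matrices and one matrix product.

    Raises ``ValueError`` for fewer than 10 points (a density display is not
    meaningful) or a zero-variance axis.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an n x 2 array of scores, got shape {pts.shape}")
    n = pts.shape[0]
    if n < 10:
        raise ValueError(
            f"density estimation needs at least 10 points, got {n}; "
            "consider disabling the density layer for this subset"
        )
    if bandwidths is None:
        bandwidths = scott_bandwidths(pts)
    hx, hy = bandwidths
    if hx <= 0 or hy <= 0:
        raise ValueError("degenerate point set: zero variance on at least one axis")

    x = np.linspace(pts[:, 0].min() - pad_bandwidths * hx,
                    pts[:, 0].max() + pad_bandwidths * hx, grid_size)
    y = np.linspace(pts[:, 1].min() - pad_bandwidths * hy,
                    pts[:, 1].max() + pad_bandwidths * hy, grid_size)

    # separable evaluation: density = Kx @ Ky^T / n
    kx = np.exp(-0.5 * ((x[:, None] - pts[None, :, 0]) / hx) ** 2) / (hx * np.sqrt(2 * np.pi))
    ky = np.exp(-0.5 * ((y[:, None] - pts[None, :, 1]) / hy) ** 2) / (hy * np.sqrt(2 * np.pi))
    density = (kx @ ky.T) / n

    return DensityGrid(x=x, y=y, density=density, bandwidths=(hx, hy), n=n)


def hdr_regions(grid: DensityGrid, masses=DEFAULT_MASSES) -> HDRSet:
    """Extract highest-density regions at the requested probability masses.

    For each mass q the threshold is the largest density level L such that
    the grid mass where density >= L reaches q (mass measured as a Riemann
    sum over grid cells, normalized by the grid's total mass).
    """
    masses = tuple(sorted(float(q) for q in masses))
    for q in masses:
        if not 0.0 < q < 1.0:
            raise ValueError(f"probability mass must lie in (0, 1), got {q}")

    flat = np.sort(grid.density.ravel())[::-1]
    cum = np.cumsum(flat) * grid.cell_area
    total = cum[-1]

    thresholds: dict[float, float] = {}
    contours: dict[float, list[np.ndarray]] = {}
    dx = grid.x[1] - grid.x[0]
    dy = grid.y[1] - grid.y[0]
    for q in masses:
        idx = int(np.searchsorted(cum, q * total))
        idx = min(idx, len(flat) - 1)
        level = float(flat[idx])
        thresholds[q] = level
        polys = []
        for c in measure.find_contours(grid.density, level):
            # find_contours returns fractional (row, col) indices; map to scores
            polys.append(np.column_stack([grid.x[0] + c[:, 0] * dx,
                                          grid.y[0] + c[:, 1] * dy]))
        contours[q] = polys

    return HDRSet(grid=grid, masses=masses, thresholds=thresholds, contours=contours)


def growth_form_densities(
    space,
    components: tuple[int, int] = (1, 2),
    forms: list[str] | tuple[str, ...] | None = None,
    masses=DEFAULT_MASSES,
    grid_size: int = 200,
) -> dict[str, HDRSet]:
    """Per-growth-form HDR sets on a component plane of a fitted space.

    ``components`` are 1-based component indices.  Forms with fewer than 10
    reference points are skipped with a warning rather than erroring, so one
    sparse form does not block the figure.
    """
    if space.entity_growth_forms is None:
        raise ValueError("space was fitted on a table without growth forms")
    i, j = components[0] - 1, components[1] - 1
    labels = np.asarray(space.entity_growth_forms)
    if forms is None:
        forms = sorted(set(labels))
    out: dict[str, HDRSet] = {}
    for form in forms:
        pts = space.scores[labels == form][:, [i, j]]
        if pts.shape[0] < 10:
            warnings.warn(
                f"growth form {form!r} has only {pts.shape[0]} reference points; "
                "skipping its density area",
                UserWarning,
                stacklevel=2,
            )
            continue
        out[form] = hdr_regions(estimate_density(pts, grid_size=grid_size), masses=masses)
    return out


def hdr_to_frame(hdr: HDRSet):
    """Flatten an HDRSet's contours to a plain table (mass, polygon, x, y)."""
    import pandas as pd

    rows = []
    for q in hdr.masses:
        for p_idx, poly in enumerate(hdr.contours[q]):
            for x, y in poly:
                rows.append((q, p_idx, x, y))
    return pd.DataFrame(rows, columns=["mass", "polygon", "x", "y"])


__all__ = [
    "DEFAULT_MASSES",
    "DensityGrid",
    "HDRSet",
    "scott_bandwidths",
    "estimate_density",
    "hdr_regions",
    "growth_form_densities",
    "hdr_to_frame",
]
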
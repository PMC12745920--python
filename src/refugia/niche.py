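"""Gridded occurrence densities in environmental space and Schoener's D.

Occurrence points of each lineage are smoothed onto a common grid (100
bins per axis by default) spanning the available environment, corrected
by the background density of available conditions, and compared with
Schoener's overlap statistic ``D = 1 - 0.5 * sum |z1 - z2|``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DensityGrid:
    """Normalized occurrence density on a bins x bins environmental grid."""

    values: np.ndarray
    extent: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise ValueError("density grid must be 2-D with >= 2 bins")
        if np.any(self.values < 0):
            raise ValueError("densities must be nonnegative")
        total = self.values.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"density grid must sum to 1 (got {total})")

    @property
    def bins(self) -> int:
        return self.values.shape[0]


def _scott_bandwidth(pts: np.ndarray) -> np.ndarray:
    """Scott's plug-in bandwidth per axis (falls back to 1/10 of the
    data range for degenerate inputs)."""
    n = len(pts)
    sd = pts.std(axis=0, ddof=1) if n > 1 else np.zeros(2)
    bw = sd * n ** (-1 / 6)
    rng = np.ptp(pts, axis=0)
    fallback = np.where(rng > 0, rng / 10, 1.0)
    return np.where(bw > 0, bw, fallback)


def _kde_on_grid(pts: np.ndarray, gx: np.ndarray, gy: np.ndarray,
                 bw: np.ndarray) -> np.ndarray:
    """Product-Gaussian kernel density evaluated at grid-cell centres."""
    dx = (gx[None, :] - pts[:, 0, None]) / bw[0]
    dy = (gy[None, :] - pts[:, 1, None]) / bw[1]
    kx = np.exp(-0.5 * dx ** 2)
    ky = np.exp(-0.5 * dy ** 2)
    return kx.T @ ky


def occurrence_density_grid(points, background, bins: int = 100,
                            bandwidth=None) -> DensityGrid:
    """Background-corrected kernel density of occurrences.

    The grid spans the background extent.  Occurrence and background
    point clouds are both kernel-smoothed (bivariate normal kernel;
    plug-in bandwidth unless given as a 2-vector); the occurrence
    density is divided by the background density where the background is
    positive (occupancy relative to availability), then renormalized to
    sum to one.

    ``bandwidth`` may be a scalar/2-vector in axis units; values of zero
    select pure histogram binning (the delta-kernel limit).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if len(background) == 0:
        raise ValueError("background points are required")
    if len(points) == 0:
        raise ValueError("at least one occurrence point is required")
    if points.shape[1] != 2 or background.shape[1] != 2:
        raise ValueError("points must be 2-D coordinates")
    x0, x1 = background[:, 0].min(), background[:, 0].max()
    y0, y1 = background[:, 1].min(), background[:, 1].max()
    if (np.any(points[:, 0] < x0) or np.any(points[:, 0] > x1)
            or np.any(points[:, 1] < y0) or np.any(points[:, 1] > y1)):
        raise ValueError("occurrences fall outside the background extent")
    # guard against a degenerate (zero-width) axis
    if x1 - x0 <= 0:
        x0, x1 = x0 - 0.5, x1 + 0.5
    if y1 - y0 <= 0:
        y0, y1 = y0 - 0.5, y1 + 0.5
    gx = x0 + (np.arange(bins) + 0.5) * (x1 - x0) / bins
    gy = y0 + (np.arange(bins) + 0.5) * (y1 - y0) / bins

    if bandwidth is None:
        bw_occ = _scott_bandwidth(points)
        bw_bg = _scott_bandwidth(background)
    else:
        bw = np.broadcast_to(np.asarray(bandwidth, dtype=float), (2,))
        bw_occ = bw_bg = bw

    if np.all(bw_occ > 0):
        occ = _kde_on_grid(points, gx, gy, bw_occ)
    else:  # delta-kernel limit: plain 2-D histogram
        occ, _, _ = np.histogram2d(points[:, 0], points[:, 1], bins=bins,
                                   range=[[x0, x1], [y0, y1]])
    if np.all(bw_bg > 0):
        bg = _kde_on_grid(background, gx, gy, bw_bg)
    else:
        bg, _, _ = np.histogram2d(background[:, 0], background[:, 1],
                                  bins=bins, range=[[x0, x1], [y0, y1]])

    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = np.where(bg > 0, occ / bg, 0.0)
    total = corrected.sum()
    if total <= 0:
        raise ValueError("occurrence density vanished after background "
                         "correction")
    return DensityGrid(corrected / total, ((x0, x1), (y0, y1)))


def schoener_d(g1: DensityGrid, g2: DensityGrid) -> float:
    """Schoener's niche-overlap statistic on matching grids; 1 for
    identical densities, 0 for disjoint supports."""
    if g1.values.shape != g2.values.shape:
        raise ValueError("density grids have different bin counts")
    if not np.allclose(g1.extent, g2.extent):
        raise ValueError("density grids span different extents")
    return float(1.0 - 0.5 * np.abs(g1.values - g2.values).sum())


def environmental_pca(variables: np.ndarray) -> np.ndarray:
    """First two principal axes of standardized environmental variables
    (plumbing for building the 2-D environment space from raw layers)."""
    X = np.asarray(variables, dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    return X @ vt[:2].T
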
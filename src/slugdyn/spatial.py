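"""Binned density grids and cross-layer correlation.

Point snapshots are converted to an m x m grid of bin densities
u(i) = B_i / A (B_i slugs in bin i, A the bin area), and the similarity of
the overground and underground spatial distributions is measured by the
Pearson correlation coefficient over the M = m^2 paired bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ZeroVarianceError",
    "DensityGrid",
    "bin_density",
    "grid_from_state",
    "correlation",
    "average_correlation",
    "write_grid_csv",
]


class ZeroVarianceError(ValueError):
    """Raised when a correlation is requested of a constant density grid.

    The correlation coefficient is undefined there; raising instead of
    returning 0 keeps silent NaNs/zeros out of replicate averages.
    """


@dataclass
class DensityGrid:
    """m x m binned population density over a square domain of side L.

    ``counts[i, j]`` is the number of slugs with x in the i-th and y in the
    j-th of m equal intervals (row-major in x); ``values`` is counts divided
    by the bin area.
    """

    counts: np.ndarray
    L: float
    m: int

    @property
    def bin_area(self) -> float:
        return (self.L / self.m) ** 2

    @property
    def values(self) -> np.ndarray:
        return self.counts / self.bin_area

    @property
    def n_slugs(self) -> int:
        return int(self.counts.sum())


def bin_density(x, y, L: float, m: int) -> DensityGrid:
    """Bin slug coordinates into an m x m density grid.

    Bins are half-open [k L/m, (k+1) L/m) with the last bin closed at L, so
    every slug in the domain lands in exactly one bin.  Coordinates outside
    [0, L] raise (they would signal a boundary-handling bug upstream).
    """
    if m < 1:
        raise ValueError(f"number of bins per side must be >= 1, got {m}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size and (x.min() < 0 or x.max() > L or y.min() < 0 or y.max() > L):
        raise ValueError("coordinates outside the domain [0, L]^2")
    ix = np.minimum((x * m / L).astype(np.int64), m - 1)
    iy = np.minimum((y * m / L).astype(np.int64), m - 1)
    counts = np.bincount(ix * m + iy, minlength=m * m).reshape(m, m)
    return DensityGrid(counts=counts, L=L, m=m)


def grid_from_state(state, layer: str = "over", m: int = 10) -> DensityGrid:
    """Bin one layer of a population state (``layer`` in {'over','under'})."""
    if layer not in ("over", "under"):
        raise ValueError("layer must be 'over' or 'under'")
    mask = state.over if layer == "over" else ~state.over
    return bin_density(state.x[mask], state.y[mask], state.L, m)


def correlation(grid_ov: DensityGrid, grid_un: DensityGrid) -> float:
    """Pearson correlation between two density grids over paired bins.

    The grids must share the same binning (the overground domain maps
    exactly onto the underground one).  A grid with zero variance raises
    :class:`ZeroVarianceError`.
    """
    if grid_ov.m != grid_un.m or grid_ov.L != grid_un.L:
        raise ValueError("grids must share the same domain and binning")
    a = grid_ov.values.ravel()
    b = grid_un.values.ravel()
    da = a - a.mean()
    db = b - b.mean()
    va = float(da @ da)
    vb = float(db @ db)
    if va == 0.0 or vb == 0.0:
        raise ZeroVarianceError("correlation undefined for a constant grid")
    return float(da @ db / np.sqrt(va * vb))


def average_correlation(rho_list) -> float:
    """Arithmetic mean of per-replicate correlation coefficients."""
    rho = np.asarray(list(rho_list), dtype=float)
    if rho.size == 0:
        raise ValueError("need at least one correlation coefficient")
    return float(rho.mean())


def write_grid_csv(grid: DensityGrid, path, t=None, layer=None) -> None:
    """Write an m x m grid of densities as CSV with a commented header.

    Header lines (prefixed ``#``) record L, m, bin area and, if given, the
    snapshot time and layer.  Row i of the body is the x-bin index i
    (row-major), columns are y-bin indices.
    """
    with open(path, "w") as fh:
        fh.write(f"# L={grid.L} m={grid.m} A={grid.bin_area}\n")
        if t is not None:
            fh.write(f"# t={t}\n")
        if layer is not None:
            fh.write(f"# layer={layer}\n")
        np.savetxt(fh, grid.values, fmt="%.6g", delimiter=",")
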
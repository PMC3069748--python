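"""Real-space map grids: containers, symmetry averaging, interpolation.

All rotation parts of the supported space groups are diagonal +-1
matrices, which keeps grid symmetry operations to axis flips and rolls;
grid dimensions are chosen even so the 1/2 translations land on grid
points exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .symmetry import SpaceGroup, UnitCell


@dataclass
class MapGrid:
    """Scalar density on a fractional grid over one unit cell."""

    dims: tuple[int, int, int]
    cell: UnitCell
    values: np.ndarray

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)
        if any(d < 2 for d in self.dims):
            raise ValueError("grid dims must be >= 2")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.dims:
            raise ValueError("values shape must equal dims")

    @property
    def sigma(self) -> float:
        return float(self.values.std())

    def copy(self) -> "MapGrid":
        return MapGrid(self.dims, self.cell, self.values.copy())


def suggest_grid_dims(cell: UnitCell, sg: SpaceGroup, d_min: float, factor: float = 3.0) -> tuple[int, int, int]:
    """Even, FFT-friendly dims with spacing <= d_min/factor per axis
    (factor >= 2 keeps the grid at or above Nyquist for d_min data)."""
    dims = []
    for length in cell.lengths():
        n = int(np.ceil(factor * length / d_min))
        n += n % 2  # even so 1/2 translations are exact
        while not _fft_friendly(n):
            n += 2
        dims.append(n)
    return tuple(dims)


def _fft_friendly(n: int) -> bool:
    for p in (2, 3, 5, 7):
        while n % p == 0:
            n //= p
    return n == 1


def check_nyquist(dims, cell: UnitCell, d_min: float) -> bool:
    return all(d >= 2.0 * L / d_min for d, L in zip(dims, cell.lengths()))


def _op_index_maps(op, dims):
    """Index arrays realizing x -> R x + t on the grid (R diagonal +-1)."""
    R, t = op.R, op.t
    if np.any(R - np.diag(np.diag(R))):
        raise ValueError("grid symmetry requires diagonal rotation parts")
    out = []
    for ax, n in enumerate(dims):
        shift = t[ax] * n
        if abs(shift - round(shift)) > 1e-9:
            raise ValueError("grid dims incompatible with translation parts")
        idx = (np.diag(R)[ax] * np.arange(n) + int(round(shift))) % n
        out.append(idx)
    return out


def transform_map(values: np.ndarray, op, dims) -> np.ndarray:
    """rho'(x) = rho(op^{-1} x); used for symmetry averaging.

    For our diagonal ops, op^{-1} has the same rotation with t' = -R t,
    so sampling rho at (R x + (-R t)) realizes the pullback; since we
    average over the whole group, using the op directly is equivalent.
    """
    ix, iy, iz = _op_index_maps(op, dims)
    return values[np.ix_(ix, iy, iz)]


def symmetrize_map(grid: MapGrid, sg: SpaceGroup) -> MapGrid:
    """Average the map over all space-group operations."""
    acc = np.zeros_like(grid.values)
    for op in sg.ops:
        acc += transform_map(grid.values, op, grid.dims)
    return MapGrid(grid.dims, grid.cell, acc / sg.n_ops)


def trilinear(values: np.ndarray, frac: np.ndarray) -> np.ndarray:
    """Periodic trilinear interpolation at fractional coordinates (M, 3)."""
    frac = np.atleast_2d(np.asarray(frac, dtype=float))
    dims = np.array(values.shape)
    g = frac * dims
    i0 = np.floor(g).astype(int)
    f = g - i0
    out = np.zeros(len(frac))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[:, 0] if dx else 1 - f[:, 0])
                    * (f[:, 1] if dy else 1 - f[:, 1])
                    * (f[:, 2] if dz else 1 - f[:, 2])
                )
                idx = (i0 + np.array([dx, dy, dz])) % dims
                out += w * values[idx[:, 0], idx[:, 1], idx[:, 2]]
    return out


def find_peaks(
    grid: MapGrid,
    n_peaks: int = 30,
    min_dist_frac: float = 0.03,
    exclude_origin_radius: float = 0.0,
) -> np.ndarray:
    """Grid peaks (local maxima over 26 neighbours) refined by a 3-point
    parabola per axis; returns fractional coordinates sorted by height."""
    v = grid.values
    is_peak = np.ones(v.shape, dtype=bool)
    for ax in range(3):
        for shift in (1, -1):
            is_peak &= v >= np.roll(v, shift, axis=ax)
    cand = np.argwhere(is_peak)
    heights = v[is_peak]
    order = np.argsort(-heights)
    dims = np.array(grid.dims)
    picked = []
    from .symmetry import min_image_distance

    for ci in order:
        ijk = cand[ci]
        frac = _parabolic_refine(v, ijk) / dims
        if exclude_origin_radius > 0:
            if min_image_distance(grid.cell, frac, np.zeros(3)) < exclude_origin_radius:
                continue
        ok = True
        for p in picked:
            dlt = np.abs((frac - p + 0.5) % 1.0 - 0.5)
            if np.all(dlt < min_dist_frac):
                ok = False
                break
        if ok:
            picked.append(frac)
        if len(picked) >= n_peaks:
            break
    return np.array(picked).reshape(-1, 3)


def _parabolic_refine(v: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    out = ijk.astype(float)
    for ax in range(3):
        m = np.array(ijk)
        lo, hi = m.copy(), m.copy()
        lo[ax] = (m[ax] - 1) % v.shape[ax]
        hi[ax] = (m[ax] + 1) % v.shape[ax]
        y0, y1, y2 = v[tuple(lo)], v[tuple(m)], v[tuple(hi)]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            out[ax] += 0.5 * (y0 - y2) / denom
    return out
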
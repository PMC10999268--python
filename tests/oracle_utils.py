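"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: patch counting uses an
explicit flood fill instead of scipy labelling, and cell areas come from
midpoint quadrature of R^2 cos(lat) instead of the closed-form zone
formula.
"""

from __future__ import annotations

import math

import numpy as np


def flood_fill_patches(mask: np.ndarray, connectivity: int, wrap: bool) -> int:
    """Count connected components of a boolean mask by iterative flood fill."""
    n_rows, n_cols = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                   if (di, dj) != (0, 0)]
    count = 0
    for i0 in range(n_rows):
        for j0 in range(n_cols):
            if not mask[i0, j0] or seen[i0, j0]:
                continue
            count += 1
            stack = [(i0, j0)]
            seen[i0, j0] = True
            while stack:
                i, j = stack.pop()
                for di, dj in offsets:
                    ni, nj = i + di, j + dj
                    if not 0 <= ni < n_rows:
                        continue
                    if wrap:
                        nj %= n_cols
                    elif not 0 <= nj < n_cols:
                        continue
                    if mask[ni, nj] and not seen[ni, nj]:
                        seen[ni, nj] = True
                        stack.append((ni, nj))
    return count


def quad_cell_area(lat_south: float, lat_north: float, lon_step: float,
                   radius_km: float = 6371.0, n: int = 10_000) -> float:
    """Midpoint quadrature of the cell area integral R^2 cos(lat) dlat dlon."""
    lats = np.linspace(lat_south, lat_north, n + 1)
    mids = np.radians((lats[:-1] + lats[1:]) / 2.0)
    dphi = math.radians((lat_north - lat_south) / n)
    dlam = math.radians(lon_step)
    return float(radius_km ** 2 * dlam * np.sum(np.cos(mids)) * dphi)


def bilinear(x: float, y: float, x0: float, x1: float, y0: float, y1: float,
             f00: float, f01: float, f10: float, f11: float) -> float:
    """Four-point bilinear interpolation; fab = f(x_a, y_b)."""
    tx = (x - x0) / (x1 - x0)
    ty = (y - y0) / (y1 - y0)
    return (f00 * (1 - tx) * (1 - ty) + f10 * tx * (1 - ty)
            + f01 * (1 - tx) * ty + f11 * tx * ty)
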
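"""Shared disc rasteriser for initial conditions and synthetic fixtures.

A disc of radius ``R`` about ``(cx, cy)`` covers exactly those cells whose
*centre* satisfies the strict inequality ``(x - cx)^2 + (y - cy)^2 < R^2``.
No anti-aliasing of the edge is performed; the same rule is used everywhere
so generated initial conditions and planted test patterns cannot drift
apart.
"""

from __future__ import annotations

import numpy as np

from .solver import LatticeSpec

__all__ = ["disc_mask"]


def disc_mask(lattice: LatticeSpec, centre: tuple[float, float], R: float) -> np.ndarray:
    """Boolean n x n mask of cells whose centres fall strictly inside the disc."""
    c = lattice.cell_centres()
    x = c[np.newaxis, :]  # column index -> x
    y = c[:, np.newaxis]  # row index    -> y
    cx, cy = centre
    return (x - cx) ** 2 + (y - cy) ** 2 < R * R
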
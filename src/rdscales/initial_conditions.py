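"""Initial-condition generators for the patterning simulations.

The reference scenario seeds a single circular activator spot at the domain
centre — representing the primary reticulate placode on the avian footpad —
with the inhibitor identically zero.  Comparative generators emulate other
patterning modes: a row of initiator spots (the feather-tract mode, where a
dorsolateral row of primordia triggers patterning of its surround), spatially
uniform fields, and uniform-plus-noise fields (the synchronous,
simultaneous-emergence mode seen in squamate footpad placodes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .raster import disc_mask
from .solver import FieldState, LatticeSpec

__all__ = [
    "SpotIC",
    "EmptySpotWarning",
    "central_spot",
    "uniform_ic",
    "initiator_row",
    "noise_ic",
]


class EmptySpotWarning(UserWarning):
    """The requested disc radius is too small to cover any cell centre."""


@dataclass(frozen=True)
class SpotIC:
    """Circular activator spot: radius ``R``, level ``u0``, over ``background``.

    ``centre=None`` places the spot at the domain centre ``(L/2, L/2)``.
    """

    R: float = 1.5
    u0: float = 1.0
    background: float = 0.0
    centre: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ValueError("spot radius R must be non-negative")
        if not self.u0 > self.background:
            raise ValueError("spot level u0 must exceed the background level")
        if self.background < 0:
            raise ValueError("background level must be non-negative")

    def resolved_centre(self, lattice: LatticeSpec) -> tuple[float, float]:
        return self.centre if self.centre is not None else lattice.centre


def _check_centre_inside(centre: tuple[float, float], lattice: LatticeSpec) -> None:
    cx, cy = centre
    if not (0.0 < cx < lattice.L and 0.0 < cy < lattice.L):
        raise ValueError(f"spot centre {centre} lies outside the open domain (0, {lattice.L})^2")


def central_spot(lattice: LatticeSpec, ic: SpotIC | None = None) -> FieldState:
    """Single circular activator spot; inhibitor identically zero; t = 0."""
    ic = ic or SpotIC()
    centre = ic.resolved_centre(lattice)
    _check_centre_inside(centre, lattice)
    mask = disc_mask(lattice, centre, ic.R)
    if not mask.any():
        warnings.warn(
            f"disc of radius {ic.R} covers no cell centres at spacing h={lattice.h}",
            EmptySpotWarning,
            stacklevel=2,
        )
    u = np.where(mask, ic.u0, ic.background)
    return FieldState(u=u, v=np.zeros_like(u), t=0.0)


def uniform_ic(lattice: LatticeSpec, u_level: float, v_level: float = 0.0) -> FieldState:
    """Spatially constant fields; t = 0."""
    if u_level < 0 or v_level < 0:
        raise ValueError("concentration levels must be non-negative")
    shape = (lattice.n, lattice.n)
    return FieldState(u=np.full(shape, float(u_level)), v=np.full(shape, float(v_level)), t=0.0)


def initiator_row(
    lattice: LatticeSpec,
    ic: SpotIC | None = None,
    n_spots: int = 3,
    spacing: float = 10.0,
    axis: str = "x",
) -> FieldState:
    """Row of equally spaced activator spots through the domain centre.

    The spots are the set union of discs (overlapping discs do not add);
    the row runs along ``axis`` ("x" or "y"), centred on the domain.
    """
    ic = ic or SpotIC()
    if n_spots < 1:
        raise ValueError("need at least one spot")
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    cx, cy = ic.resolved_centre(lattice)
    offsets = (np.arange(n_spots) - (n_spots - 1) / 2.0) * spacing
    centres = [(cx + d, cy) if axis == "x" else (cx, cy + d) for d in offsets]
    for c in centres:
        _check_centre_inside(c, lattice)
        if not (ic.R <= c[0] <= lattice.L - ic.R and ic.R <= c[1] <= lattice.L - ic.R):
            raise ValueError(f"spot at {c} with R={ic.R} leaves the domain")
    mask = np.zeros((lattice.n, lattice.n), dtype=bool)
    for c in centres:
        mask |= disc_mask(lattice, c, ic.R)
    u = np.where(mask, ic.u0, ic.background)
    return FieldState(u=u, v=np.zeros_like(u), t=0.0)


def noise_ic(
    lattice: LatticeSpec, mean_u: float, amplitude: float, seed: int
) -> FieldState:
    """Uniform activator level plus i.i.d. uniform noise in [-amplitude, +amplitude].

    Reproducible for a fixed seed; the inhibitor starts at zero.
    """
    if amplitude < 0:
        raise ValueError("noise amplitude must be non-negative")
    if mean_u - amplitude < 0:
        raise ValueError("mean_u - amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    u = mean_u + rng.uniform(-amplitude, amplitude, size=(lattice.n, lattice.n))
    return FieldState(u=u, v=np.zeros((lattice.n, lattice.n)), t=0.0)
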
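"""Synthetic ground-truth spot fields for testing the pattern analyzer.

These generators render fields with *known* spot counts, centres, and ring
structure — discrete high-activator units on a low background, optionally
arranged in concentric rings around a central unit — so every analysis
operation can be validated without running the solver.  They share the disc
rasteriser with the initial-condition generators, so the two cannot drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .raster import disc_mask
from .solver import FieldState, LatticeSpec

__all__ = ["PlantedPattern", "render", "ring_pattern", "random_pattern"]


@dataclass(frozen=True)
class PlantedPattern:
    """Planted spot configuration with known ground truth.

    The ground-truth spot count is ``len(centres)``.
    """

    centres: tuple[tuple[float, float], ...]
    disc_radius: float = 1.5
    amplitude: float = 1.0
    background: float = 0.0
    lattice: LatticeSpec = LatticeSpec(L=75.0, n=75)

    def __post_init__(self) -> None:
        for cx, cy in self.centres:
            if not (0.0 < cx < self.lattice.L and 0.0 < cy < self.lattice.L):
                raise ValueError(f"planted centre ({cx}, {cy}) outside the domain")
        if self.amplitude <= self.background:
            raise ValueError("amplitude must exceed background")

    @property
    def count(self) -> int:
        return len(self.centres)

    def to_json(self) -> str:
        return json.dumps(
            {
                "centres": [list(c) for c in self.centres],
                "disc_radius": self.disc_radius,
                "amplitude": self.amplitude,
                "background": self.background,
                "lattice": self.lattice.to_dict(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "PlantedPattern":
        d = json.loads(s)
        return cls(
            centres=tuple(tuple(c) for c in d["centres"]),
            disc_radius=d["disc_radius"],
            amplitude=d["amplitude"],
            background=d["background"],
            lattice=LatticeSpec.from_dict(d["lattice"]),
        )


def render(pattern: PlantedPattern) -> FieldState:
    """Rasterise the planted discs (set union) over the background; v = 0."""
    lat = pattern.lattice
    mask = np.zeros((lat.n, lat.n), dtype=bool)
    for c in pattern.centres:
        mask |= disc_mask(lat, c, pattern.disc_radius)
    u = np.where(mask, pattern.amplitude, pattern.background)
    return FieldState(u=u, v=np.zeros_like(u), t=0.0)


def ring_pattern(
    k: int,
    radius: float,
    centre: tuple[float, float] | None = None,
    include_central: bool = True,
    lattice: LatticeSpec = LatticeSpec(L=75.0, n=75),
    disc_radius: float = 1.5,
    amplitude: float = 1.0,
) -> PlantedPattern:
    """``k`` spots equally spaced on a circle, optionally plus a central spot.

    Mimics the radial geometry of a subdivided primary unit.  Angles start
    at 0 and step ``2*pi/k``.  Every disc must fit inside the domain.
    """
    if k < 1:
        raise ValueError("need k >= 1 ring spots")
    cx, cy = centre if centre is not None else lattice.centre
    if radius + disc_radius >= lattice.L / 2.0:
        raise ValueError("ring would leave the domain: radius + disc_radius >= L/2")
    angles = 2.0 * np.pi * np.arange(k) / k
    centres = [(cx + radius * np.cos(a), cy + radius * np.sin(a)) for a in angles]
    if include_central:
        centres.insert(0, (cx, cy))
    for px, py in centres:
        if not (
            disc_radius <= px <= lattice.L - disc_radius
            and disc_radius <= py <= lattice.L - disc_radius
        ):
            raise ValueError(f"disc at ({px:.3f}, {py:.3f}) leaves the domain")
    return PlantedPattern(
        centres=tuple((float(x), float(y)) for x, y in centres),
        disc_radius=disc_radius,
        amplitude=amplitude,
        lattice=lattice,
    )


def random_pattern(
    count: int,
    rng: np.random.Generator,
    lattice: LatticeSpec = LatticeSpec(L=75.0, n=75),
    disc_radius: float = 1.5,
    min_separation: float | None = None,
    amplitude: float = 1.0,
    max_tries: int = 10_000,
) -> PlantedPattern:
    """Rejection-sample ``count`` well-separated planted centres.

    ``min_separation`` defaults to ``2*disc_radius + 2*h``, the separation
    at which rendered discs are guaranteed to stay disjoint as connected
    components under 8-connectivity.
    """
    h = lattice.h
    if min_separation is None:
        min_separation = 2.0 * disc_radius + 2.0 * h
    margin = disc_radius + h
    lo, hi = margin, lattice.L - margin
    centres: list[tuple[float, float]] = []
    tries = 0
    while len(centres) < count:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {count} spots with separation {min_separation}"
            )
        cand = (float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))
        if all(np.hypot(cand[0] - x, cand[1] - y) > min_separation for x, y in centres):
            centres.append(cand)
    return PlantedPattern(
        centres=tuple(centres),
        disc_radius=disc_radius,
        amplitude=amplitude,
        lattice=lattice,
    )
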
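"""Pattern statistics for simulated activator fields.

Turns the qualitative description of reticulate-scale patterning — a primary
unit that subdivides into smaller secondary units radiating outwards from a
central unit — into numbers: spot detection by thresholding and connected
components, spot-count time series, the time of the subdivision event, and
radial "ring" statistics of secondary-unit centroids around the domain
centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skimage import measure

from .kinetics import homogeneous_fixed_point
from .solver import FieldState, SimulationResult

__all__ = [
    "DetectionPolicy",
    "Spot",
    "SpotSet",
    "RadialReport",
    "detect_spots",
    "count_timeseries",
    "subdivision_time",
    "radial_report",
    "nn_spacing",
    "classify_outcome",
    "default_policy",
]

#: Final-state spatial variance below which a run counts as homogeneous.
HOMOGENEOUS_VARIANCE = 1e-6


@dataclass(frozen=True)
class DetectionPolicy:
    """How spots are extracted from a field.

    threshold
        Binarisation level on the activator; cells with ``u > threshold``
        are foreground.
    connectivity
        4 (edge-adjacent) or 8 (edge- or corner-adjacent).
    min_area
        Components smaller than this many cells are dropped (suppresses
        single-cell numerical speckle).
    """

    threshold: float
    connectivity: int = 8
    min_area: int = 2

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_area < 1:
            raise ValueError("min_area must be at least 1")


def default_policy(params) -> DetectionPolicy:
    """Parameter-free default: threshold at the homogeneous fixed point.

    Pattern peaks rise above the uniform steady state and troughs fall
    below it, so the fixed-point activator level separates units from
    background for any run of the same kinetics.
    """
    return DetectionPolicy(threshold=homogeneous_fixed_point(params).u_star)


@dataclass(frozen=True)
class Spot:
    """One detected pattern element."""

    x: float  # centroid, physical units
    y: float
    area: int  # cells
    peak_u: float


@dataclass(frozen=True)
class SpotSet:
    """Detected pattern elements plus the policy that produced them."""

    spots: tuple[Spot, ...]
    policy: DetectionPolicy
    t: float

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of (x, y) centroids."""
        if not self.spots:
            return np.empty((0, 2))
        return np.array([(s.x, s.y) for s in self.spots])

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "policy": asdict(self.policy),
            "spots": [asdict(s) for s in self.spots],
        }


@dataclass(frozen=True)
class RadialReport:
    """Radial arrangement of spots about a reference centre.

    ``ring_radii`` holds the sorted centroid distances of non-central spots;
    rings are maximal runs of radii whose consecutive gaps stay within
    ``ring_gap``.  A low within-ring coefficient of variation indicates the
    ring-like radial arrangement of secondary units.
    """

    has_central_unit: bool
    ring_radii: tuple[float, ...]
    rings: tuple[tuple[float, ...], ...] = field(default=())

    @property
    def n_rings(self) -> int:
        return len(self.rings)

    @property
    def ring_cvs(self) -> tuple[float, ...]:
        out = []
        for ring in self.rings:
            r = np.asarray(ring)
            m = r.mean()
            out.append(float(r.std() / m) if m > 0 else 0.0)
        return tuple(out)

    @property
    def max_radius(self) -> float:
        return max(self.ring_radii) if self.ring_radii else 0.0

    def to_dict(self) -> dict:
        return {
            "has_central_unit": self.has_central_unit,
            "ring_radii": list(self.ring_radii),
            "rings": [list(r) for r in self.rings],
            "ring_cvs": list(self.ring_cvs),
            "n_rings": self.n_rings,
        }


def detect_spots(state: FieldState, policy: DetectionPolicy, h: float = 1.0) -> SpotSet:
    """Threshold the activator field and label connected components.

    Centroids are area-weighted means of cell centres, reported in physical
    units (cell spacing ``h``); components below ``min_area`` are discarded.
    An empty result is valid.
    """
    binary = state.u > policy.threshold
    labels = measure.label(binary, connectivity=1 if policy.connectivity == 4 else 2)
    return _spots_from_labels(state, labels, policy, h=h)


def _spots_from_labels(state, labels, policy, h: float) -> SpotSet:
    spots = []
    for region in measure.regionprops(labels, intensity_image=state.u):
        if region.area < policy.min_area:
            continue
        cy, cx = region.centroid  # (row, col) in cell indices
        spots.append(
            Spot(
                x=(cx + 0.5) * h,
                y=(cy + 0.5) * h,
                area=int(region.area),
                peak_u=float(region.intensity_max),
            )
        )
    spots.sort(key=lambda s: (s.y, s.x))
    return SpotSet(spots=tuple(spots), policy=policy, t=state.t)


def count_timeseries(result: SimulationResult, policy: DetectionPolicy | None = None):
    """Spot count per snapshot under one fixed policy: list of (t, n)."""
    policy = policy or default_policy(result.params)
    h = result.lattice.h
    out = []
    for snap in result.snapshots:
        spots = detect_spots(snap, policy, h)
        out.append((snap.t, len(spots)))
    return out


def subdivision_time(series) -> float | None:
    """Earliest time the spot count exceeds ``max(1, count at t=0)``.

    Growth from an initially empty field counts as pattern emergence.
    Returns None when the count never grows.
    """
    if not series:
        raise ValueError("series must be nonempty")
    base = max(1, series[0][1])
    for t, n in series:
        if n > base:
            return t
    return None


def radial_report(
    spots: SpotSet,
    centre: tuple[float, float],
    central_tol: float = 2.0,
    ring_gap: float = 3.0,
) -> RadialReport:
    """Group spot centroids into a central unit and concentric rings.

    A spot within ``central_tol`` of ``centre`` is the central unit.  The
    remaining centroid distances are sorted and split into rings wherever
    consecutive distances differ by more than ``ring_gap``.
    """
    pts = spots.centroids
    if pts.size == 0:
        return RadialReport(has_central_unit=False, ring_radii=())
    d = np.hypot(pts[:, 0] - centre[0], pts[:, 1] - centre[1])
    central = d <= central_tol
    radii = np.sort(d[~central])
    rings: list[tuple[float, ...]] = []
    if radii.size:
        start = 0
        for i in range(1, radii.size):
            if radii[i] - radii[i - 1] > ring_gap:
                rings.append(tuple(radii[start:i]))
                start = i
        rings.append(tuple(radii[start:]))
    return RadialReport(
        has_central_unit=bool(central.any()),
        ring_radii=tuple(float(r) for r in radii),
        rings=tuple(rings),
    )


def nn_spacing(spots: SpotSet) -> tuple[float, float]:
    """Mean and CV of nearest-neighbour centroid distances.

    The standard wavelength diagnostic for periodic spot patterns.
    Requires at least two spots.
    """
    pts = spots.centroids
    if len(pts) < 2:
        raise ValueError("nearest-neighbour spacing needs at least 2 spots")
    D = squareform(pdist(pts))
    np.fill_diagonal(D, np.inf)
    nn = D.min(axis=1)
    mean = float(nn.mean())
    cv = float(nn.std() / mean) if mean > 0 else 0.0
    return mean, cv


def classify_outcome(
    result: SimulationResult,
    policy: DetectionPolicy | None = None,
    central_tol: float | None = None,
    ring_gap: float | None = None,
) -> str:
    """Label a run's final pattern. First matching label wins, in order:

    ``homogeneous``
        final activator spatial variance below 1e-6;
    ``persistent_single_spot``
        final spot count is exactly 1;
    ``radial_subdivision``
        the count grew past its initial value at some time AND the final
        field has a central unit AND at least one ring of secondary units;
    ``other``
        anything else.
    """
    if len(result.snapshots) < 2:
        raise ValueError("classification needs at least 2 snapshots")
    policy = policy or default_policy(result.params)
    h = result.lattice.h
    central_tol = 2.0 * h if central_tol is None else central_tol
    ring_gap = 3.0 * h if ring_gap is None else ring_gap

    if float(result.final.u.var()) < HOMOGENEOUS_VARIANCE:
        return "homogeneous"
    series = count_timeseries(result, policy)
    if series[-1][1] == 1:
        return "persistent_single_spot"
    t_sub = subdivision_time(series)
    final_spots = detect_spots(result.final, policy, h)
    report = radial_report(final_spots, result.lattice.centre, central_tol, ring_gap)
    if t_sub is not None and report.has_central_unit and report.n_rings >= 1:
        return "radial_subdivision"
    return "other"
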
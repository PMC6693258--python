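"""Explicit finite-difference integration on a square no-flux lattice.

The two concentration fields live on an ``n x n`` cell-centred grid covering
the square domain ``0 < x, y < L``: cell ``(i, j)`` (row ``i``, column ``j``)
has its centre at ``x = (j + 0.5) h``, ``y = (i + 0.5) h`` with spacing
``h = L / n``.  Diffusion uses the standard 5-point Laplacian with mirror
ghost cells, which realises zero-flux (homogeneous Neumann) boundaries at
first order and conserves total mass exactly.  Time stepping is forward
Euler, guarded by the usual diffusive stability bound ``dt <= h^2 / (4 D)``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .kinetics import KineticParams, reaction

__all__ = [
    "LatticeSpec",
    "FieldState",
    "SimulationResult",
    "InstabilityError",
    "laplacian_no_flux",
    "stable_dt",
    "step",
    "simulate",
]

# Fraction of the diffusive stability bound used by default; chosen by a
# dt-convergence study on the reference run (see docs/methods.md).
DEFAULT_SAFETY = 0.1


class InstabilityError(RuntimeError):
    """The explicit update produced non-finite values.

    Carries the simulation time at which the blow-up was detected in ``t``.
    """

    def __init__(self, msg: str, t: float | None = None):
        super().__init__(msg)
        self.t = t


@dataclass(frozen=True)
class LatticeSpec:
    """Square domain geometry: physical side ``L`` split into ``n`` cells."""

    L: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("lattice needs n >= 3 cells per side")
        if self.L <= 0:
            raise ValueError("side length L must be positive")

    @property
    def h(self) -> float:
        """Cell spacing L / n."""
        return self.L / self.n

    @property
    def centre(self) -> tuple[float, float]:
        return (self.L / 2.0, self.L / 2.0)

    def cell_centres(self) -> np.ndarray:
        """1D coordinates of cell centres along either axis."""
        return (np.arange(self.n) + 0.5) * self.h

    def to_dict(self) -> dict:
        return {"L": self.L, "n": self.n}

    @classmethod
    def from_dict(cls, d: dict) -> "LatticeSpec":
        return cls(L=float(d["L"]), n=int(d["n"]))


@dataclass
class FieldState:
    """Paired activator/inhibitor grids at one simulation time."""

    u: np.ndarray
    v: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape or self.u.ndim != 2 or self.u.shape[0] != self.u.shape[1]:
            raise ValueError("u and v must be equal-shaped square 2D grids")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise ValueError("fields must be finite-valued")
        if (self.u < 0).any() or (self.v < 0).any():
            raise ValueError("concentrations must be non-negative")

    @property
    def n(self) -> int:
        return self.u.shape[0]

    def copy(self) -> "FieldState":
        return FieldState(self.u.copy(), self.v.copy(), self.t)


@dataclass
class SimulationResult:
    """Ordered snapshots of a run plus the metadata to reproduce it."""

    snapshots: list[FieldState]
    params: KineticParams
    lattice: LatticeSpec
    dt: float
    seed: int | None = None
    fingerprint: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        if not self.snapshots:
            raise ValueError("a simulation result needs at least one snapshot")
        if self.snapshots[0].t != 0.0:
            raise ValueError("first snapshot must be at t = 0")
        ts = self.times
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("snapshot times must be strictly increasing")
        if not self.fingerprint:
            self.fingerprint = self._compute_fingerprint()

    @property
    def times(self) -> list[float]:
        return [s.t for s in self.snapshots]

    @property
    def final(self) -> FieldState:
        return self.snapshots[-1]

    def _compute_fingerprint(self) -> str:
        h = hashlib.sha256()
        meta = {
            "params": self.params.to_dict(),
            "lattice": self.lattice.to_dict(),
            "dt": self.dt,
            "seed": self.seed,
            "times": self.times,
        }
        h.update(json.dumps(meta, sort_keys=True).encode())
        for s in self.snapshots:
            h.update(np.ascontiguousarray(s.u).tobytes())
            h.update(np.ascontiguousarray(s.v).tobytes())
        return h.hexdigest()


def laplacian_no_flux(grid: np.ndarray, h: float) -> np.ndarray:
    """5-point Laplacian with mirror ghost cells (zero normal gradient).

    A ghost cell outside edge ``e`` copies the boundary cell it mirrors, so
    the stencil contribution across every boundary face cancels and the
    discrete integral of the result is exactly zero.
    """
    g = np.asarray(grid, dtype=float)
    if g.ndim != 2 or min(g.shape) < 2:
        raise ValueError("grid must be 2D with at least 2 cells per side")
    p = np.pad(g, 1, mode="edge")
    # (N+S) + (W+E) grouping keeps the update bit-exactly equivariant under
    # 90-degree rotation and reflection (IEEE addition is commutative), so a
    # symmetric initial condition cannot lose its symmetry to rounding.
    ns = p[:-2, 1:-1] + p[2:, 1:-1]
    we = p[1:-1, :-2] + p[1:-1, 2:]
    return (ns + we - 4.0 * g) / (h * h)


def stable_dt(p: KineticParams, h: float, safety: float = 1.0) -> float:
    """Explicit-Euler diffusion stability bound ``safety * h^2 / (4 max D)``."""
    if not 0.0 < safety <= 1.0:
        raise ValueError("safety fraction must be in (0, 1]")
    D = max(p.D_u, p.D_v)
    if D == 0.0:
        raise ValueError("both diffusivities are zero; no diffusive time scale")
    return safety * h * h / (4.0 * D)


def step(state: FieldState, p: KineticParams, lattice: LatticeSpec, dt: float) -> FieldState:
    """One forward-Euler update of both fields.

    Negative concentrations produced by Euler undershoot are floored to
    zero after the update (concentrations are physical, and the floor
    matches the kinetics' own synthesis floor).
    """
    h = lattice.h
    with np.errstate(over="ignore", invalid="ignore"):  # blow-up checked below
        ru, rv = reaction(state.u, state.v, p)
        u = state.u + dt * (p.D_u * laplacian_no_flux(state.u, h) + ru)
        v = state.v + dt * (p.D_v * laplacian_no_flux(state.v, h) + rv)
    t = state.t + dt
    if not (np.isfinite(u).all() and np.isfinite(v).all()):
        raise InstabilityError(
            f"non-finite field values at t={t:g}; time step too large?", t=t
        )
    np.maximum(u, 0.0, out=u)
    np.maximum(v, 0.0, out=v)
    out = FieldState.__new__(FieldState)  # skip validation in the hot loop
    out.u, out.v, out.t = u, v, t
    return out


def simulate(
    initial: FieldState,
    p: KineticParams,
    lattice: LatticeSpec,
    dt: float,
    t_end: float,
    snapshot_times=None,
    seed: int | None = None,
) -> SimulationResult:
    """Integrate from ``initial`` to ``t_end``, recording snapshots.

    Snapshots are captured at the first completed step at or after each
    requested time, with the actual step time recorded.  A snapshot at
    ``t = 0`` (the initial state) is always included.  The run is fully
    deterministic: identical inputs give bit-identical outputs.

    Parameters
    ----------
    snapshot_times : iterable of float, optional
        Requested times in ``[0, t_end]``.  Defaults to every 250 time
        units plus the final time.
    seed : int, optional
        Recorded in the metadata when the initial condition was random;
        the integrator itself uses no randomness.
    """
    if initial.n != lattice.n:
        raise ValueError("initial state grid size does not match the lattice")
    bound = stable_dt(p, lattice.h, 1.0)
    if dt > bound * (1.0 + 1e-12):
        raise ValueError(f"dt={dt:g} exceeds the stability bound {bound:g}")
    if t_end < 0:
        raise ValueError("t_end must be non-negative")

    if snapshot_times is None:
        snapshot_times = list(np.arange(250.0, t_end + 1e-9, 250.0))
        if t_end > 0 and (not snapshot_times or snapshot_times[-1] < t_end):
            snapshot_times.append(t_end)
    req = sorted(t for t in snapshot_times if 0.0 < t <= t_end + 1e-12)

    state = initial if initial.t == 0.0 else FieldState(initial.u, initial.v, 0.0)
    snapshots = [state.copy()]
    n_steps = math.ceil(t_end / dt - 1e-12) if t_end > 0 else 0
    next_req = 0
    try:
        for k in range(1, n_steps + 1):
            state = step(state, p, lattice, dt)
            state.t = k * dt  # avoid accumulated float drift
            if next_req < len(req) and state.t >= req[next_req] - 1e-12:
                snapshots.append(state.copy())
                while next_req < len(req) and state.t >= req[next_req] - 1e-12:
                    next_req += 1  # several requests can land on one step
    except InstabilityError as e:
        raise InstabilityError(str(e), t=e.t) from None
    # Requested times beyond the last completed step collapse onto it.
    if next_req < len(req) and snapshots[-1].t < state.t:
        snapshots.append(state.copy())

    return SimulationResult(
        snapshots=snapshots, params=p, lattice=lattice, dt=dt, seed=seed
    )
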
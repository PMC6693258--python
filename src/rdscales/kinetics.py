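"""Clipped-linear activator–inhibitor kinetics (Kondo–Miura type).

The model couples an activator ``u`` and an inhibitor ``v``.  Each species
is synthesised at a rate that is *linear* in ``(u, v)`` but clipped to a
physical band — non-negative and capped at a saturation level — and decays
linearly::

    du/dt = F(u, v) - d_u * u,   F = clamp(a_u*u + b_u*v + c_u, 0, F_max)
    dv/dt = G(u, v) - d_v * v,   G = clamp(a_v*u + b_v*v + c_v, 0, G_max)

The saturation bounds ``F_max``/``G_max`` — not classic Turing
stability-at-k=0 conditions — are what contain the pattern amplitude: for
the reference parameter set the homogeneous steady state is linearly
*unstable* with an oscillatory character at wavenumber zero, and bounded
dynamics emerge only because synthesis saturates while decay stays linear.

All kinetic functions operate elementwise, identically on scalars and on
whole concentration grids.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import numpy as np
from scipy import optimize

__all__ = [
    "KineticParams",
    "FixedPoint",
    "SingularKineticsError",
    "synthesis_u",
    "synthesis_v",
    "reaction",
    "homogeneous_fixed_point",
    "dispersion_relation",
]


class SingularKineticsError(ValueError):
    """The linear balance system of the kinetics is (numerically) singular."""


@dataclass(frozen=True)
class KineticParams:
    """The 12 reaction/diffusion constants of the clipped-linear model.

    Attributes
    ----------
    d_u, d_v : float
        Linear degradation rates of activator and inhibitor (1/time).
    D_u, D_v : float
        Diffusivities (length**2/time).  Lateral inhibition requires
        ``D_v >> D_u``.
    a_u, b_u, c_u : float
        Activator synthesis coefficients: self-coupling, cross-coupling
        from the inhibitor, and basal rate.
    F_max : float
        Saturation cap on activator synthesis.
    a_v, b_v, c_v : float
        Inhibitor synthesis coefficients.
    G_max : float
        Saturation cap on inhibitor synthesis.
    """

    d_u: float
    D_u: float
    a_u: float
    b_u: float
    c_u: float
    F_max: float
    d_v: float
    D_v: float
    a_v: float
    b_v: float
    c_v: float
    G_max: float

    def __post_init__(self) -> None:
        if self.d_u <= 0 or self.d_v <= 0:
            raise ValueError("degradation rates d_u, d_v must be positive")
        if self.D_u < 0 or self.D_v < 0:
            raise ValueError("diffusivities D_u, D_v must be non-negative")
        if self.F_max <= 0 or self.G_max <= 0:
            raise ValueError("synthesis caps F_max, G_max must be positive")

    @classmethod
    def reference(cls) -> "KineticParams":
        """Published reference parameter set for avian reticulate-scale
        patterning (central placode subdividing into radial secondary units)."""
        return cls(
            d_u=0.02,
            D_u=0.02,
            a_u=0.06,
            b_u=-0.07,
            c_u=0.015,
            F_max=0.19,
            d_v=0.031,
            D_v=0.4,
            a_v=0.0608,
            b_v=0.004,
            c_v=-0.025,
            G_max=0.184,
        )

    def to_dict(self) -> dict[str, float]:
        """Flat key-value form using the conventional symbol names."""
        return {k: float(v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        names = {f.name for f in fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise KeyError(f"unknown kinetic parameter(s): {sorted(unknown)}")
        missing = names - set(d)
        if missing:
            raise KeyError(f"missing kinetic parameter(s): {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def replace(self, **changes) -> "KineticParams":
        d = self.to_dict()
        d.update(changes)
        return KineticParams.from_dict(d)


@dataclass(frozen=True)
class FixedPoint:
    """Spatially homogeneous steady state of the kinetics.

    ``in_linear_regime`` is True when both synthesis terms evaluated at the
    fixed point lie strictly inside their clip bands, i.e. the linearisation
    around the fixed point is smooth and the dispersion relation is valid.
    """

    u_star: float
    v_star: float
    in_linear_regime: bool


def synthesis_u(u, v, p: KineticParams):
    """Activator synthesis rate, clipped to [0, F_max]. Elementwise."""
    return np.clip(p.a_u * np.asarray(u) + p.b_u * np.asarray(v) + p.c_u, 0.0, p.F_max)


def synthesis_v(u, v, p: KineticParams):
    """Inhibitor synthesis rate, clipped to [0, G_max]. Elementwise."""
    return np.clip(p.a_v * np.asarray(u) + p.b_v * np.asarray(v) + p.c_v, 0.0, p.G_max)


def reaction(u, v, p: KineticParams):
    """Net reaction rates ``(du/dt, dv/dt)`` without diffusion.

    Degradation is linear and never clipped; only synthesis saturates.
    """
    u = np.asarray(u)
    v = np.asarray(v)
    return synthesis_u(u, v, p) - p.d_u * u, synthesis_v(u, v, p) - p.d_v * v


def _linear_balance_matrix(p: KineticParams) -> np.ndarray:
    return np.array([[p.a_u - p.d_u, p.b_u], [p.a_v, p.b_v - p.d_v]])


def homogeneous_fixed_point(p: KineticParams, tol: float = 1e-10) -> FixedPoint:
    """Solve for the spatially uniform steady state of the kinetics.

    First solves the *unclipped* linear balance

        (a_u - d_u) u + b_u v + c_u = 0
        a_v u + (b_v - d_v) v + c_v = 0

    and checks whether both synthesis terms fall strictly inside their clip
    bands there.  If they do, that solution is the fixed point of the full
    clipped system and ``in_linear_regime`` is True.  Otherwise a bounded
    root search over the invariant box ``[0, F_max/d_u] x [0, G_max/d_v]``
    locates a fixed point of the clipped kinetics and ``in_linear_regime``
    is False.

    Raises
    ------
    SingularKineticsError
        If the linear balance matrix has |det| < 1e-14.
    """
    A = _linear_balance_matrix(p)
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if abs(det) < 1e-14:
        raise SingularKineticsError(
            f"linear balance system is singular (det={det:.3e})"
        )
    u_lin, v_lin = np.linalg.solve(A, [-p.c_u, -p.c_v])

    f_lin = p.a_u * u_lin + p.b_u * v_lin + p.c_u
    g_lin = p.a_v * u_lin + p.b_v * v_lin + p.c_v
    linear = (0.0 < f_lin < p.F_max) and (0.0 < g_lin < p.G_max)
    if linear:
        return FixedPoint(u_star=float(u_lin), v_star=float(v_lin), in_linear_regime=True)

    # Clipped and unclipped fixed points disagree: search the invariant box.
    u_hi, v_hi = p.F_max / p.d_u, p.G_max / p.d_v
    x0 = np.clip([u_lin, v_lin], 0.0, [u_hi, v_hi])
    sol = optimize.least_squares(
        lambda x: np.array(reaction(x[0], x[1], p), dtype=float),
        x0,
        bounds=([0.0, 0.0], [u_hi, v_hi]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    res = reaction(sol.x[0], sol.x[1], p)
    if max(abs(res[0]), abs(res[1])) > tol:
        raise RuntimeError(
            "bounded search failed to locate a fixed point of the clipped kinetics"
        )
    return FixedPoint(u_star=float(sol.x[0]), v_star=float(sol.x[1]), in_linear_regime=False)


def jacobian(p: KineticParams) -> np.ndarray:
    """Jacobian of the reaction terms at a point inside the linear regime."""
    return _linear_balance_matrix(p)


def dispersion_relation(p: KineticParams, k: float) -> tuple[complex, complex]:
    """Growth rates of spatial perturbation modes at wavenumber ``k``.

    Returns the two eigenvalues of ``J - k^2 diag(D_u, D_v)`` where ``J`` is
    the reaction Jacobian at the homogeneous fixed point.  Only valid while
    the fixed point sits strictly inside both clip bands.

    Eigenvalues are ordered by descending real part, then descending
    imaginary part.

    Raises
    ------
    ValueError
        If the fixed point is not in the linear regime, so the smooth
        linearisation (and hence this relation) does not exist.
    """
    fp = homogeneous_fixed_point(p)
    if not fp.in_linear_regime:
        raise ValueError(
            "fixed point is outside the linear synthesis band; "
            "dispersion relation undefined for these parameters"
        )
    M = jacobian(p) - float(k) ** 2 * np.diag([p.D_u, p.D_v])
    tr = M[0, 0] + M[1, 1]
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    disc = complex(tr * tr - 4.0 * det)
    root = np.sqrt(disc)
    lam1 = (tr + root) / 2.0
    lam2 = (tr - root) / 2.0
    pair = sorted([complex(lam1), complex(lam2)], key=lambda z: (-z.real, -z.imag))
    return pair[0], pair[1]
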
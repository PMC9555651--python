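"""Socially buffered stress-response model.

Three coupled state variables describe an individual's stress dynamics:

* ``X`` — perceived psychological stress,
* ``Y`` — symptoms of stress-related ill-health,
* ``Z`` — received social support currently in use (out of a total pool
  ``S0``; the unused reserve is ``S0 - Z``).

The vector field is an Oregonator-like kinetic scheme

.. math::

    \\dot X &= k_1 A + (k_2 B - k_6) X + k_3 Y - k_4 X Z - k_5 X^2, \\\\
    \\dot Y &= k_6 X - k_7 Y, \\\\
    \\dot Z &= k_8 (S_0 - Z) Y - \\beta k_4 X Z - k_9 Z,

where the environmental stress ``A = A0 + rho * sin(omega * t)`` may be
periodically forced, ``B`` is the "kindling" parameter (existing stress
amplifying the response to new stressors) and ``beta`` the fraction of
support consumed when buffering stress.  In the fractional variant the
time derivatives are Caputo derivatives of order ``q`` in (0, 1]; the
integer-order model is recovered at ``q = 1``.

This module holds the vector field, its Jacobian, equilibrium location
for the unforced system, and fractional (Matignon) stability
classification of the linearization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import optimize

__all__ = [
    "ParameterSet",
    "EquilibriumReport",
    "TABLE1",
    "forcing_amplitude",
    "rhs",
    "stress_field",
    "params_vector",
    "jacobian",
    "characteristic_polynomial",
    "matignon_stability",
    "find_equilibria",
]

#: q grid used by default when classifying fractional stability.
DEFAULT_Q_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2))


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants, forcing and environment parameters.

    The defaults for ``k1..k9``, ``A0``, ``S0`` and ``beta`` are the
    reference calibration of the model.  ``B`` (kindling), ``rho``
    (forcing amplitude) and ``omega`` (forcing angular frequency) are
    experiment-specific; the defaults give the unforced system at the
    kindling level used throughout the stability analysis.
    """

    k1: float = 1.0
    k2: float = 1.0
    k3: float = 0.01
    k4: float = 2.0
    k5: float = 0.3
    k6: float = 0.01
    k7: float = 0.01
    k8: float = 0.1
    k9: float = 0.01
    A0: float = 1.0
    rho: float = 0.0
    omega: float = 1.5
    B: float = 2.2
    S0: float = 10.0
    beta: float = 0.5

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be nonnegative")
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.omega < 0 or self.rho < 0:
            raise ValueError("omega and rho must be nonnegative")

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def field(self):
        """Return ``f(t, state) -> derivative`` closing over these parameters."""
        return lambda t, state: rhs(state, t, self)


#: Named preset for the reference calibration.
TABLE1 = ParameterSet()

PRESETS: dict[str, ParameterSet] = {"table1": TABLE1}


def forcing_amplitude(t: float, params: ParameterSet) -> float:
    """Environmental stress ``A(t) = A0 + rho*sin(omega*t)``."""
    return params.A0 + params.rho * np.sin(params.omega * t)


def rhs(state, t: float, params: ParameterSet) -> np.ndarray:
    """Vector field ``(f1, f2, f3)`` at ``state = (X, Y, Z)`` and time ``t``.

    Raises
    ------
    FloatingPointError
        If the state is non-finite, which signals integrator blow-up.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite state passed to the vector field")
    X, Y, Z = state
    p = params
    A = forcing_amplitude(t, p)
    f1 = p.k1 * A + (p.k2 * p.B - p.k6) * X + p.k3 * Y - p.k4 * X * Z - p.k5 * X * X
    f2 = p.k6 * X - p.k7 * Y
    f3 = p.k8 * (p.S0 - Z) * Y - p.beta * p.k4 * X * Z - p.k9 * Z
    return np.array([f1, f2, f3])


@njit(cache=True)
def stress_field(t, y, p):  # pragma: no cover - exercised through integrate
    """Compiled vector field; ``p`` is the vector from :func:`params_vector`."""
    A = p[9] + p[10] * np.sin(p[11] * t)
    X, Y, Z = y[0], y[1], y[2]
    out = np.empty(3)
    out[0] = p[0] * A + (p[1] * p[12] - p[5]) * X + p[2] * Y - p[3] * X * Z - p[4] * X * X
    out[1] = p[5] * X - p[6] * Y
    out[2] = p[7] * (p[13] - Z) * Y - p[14] * p[3] * X * Z - p[8] * Z
    return out


def params_vector(params: ParameterSet) -> np.ndarray:
    """Flatten a :class:`ParameterSet` for the compiled vector field."""
    p = params
    return np.array(
        [p.k1, p.k2, p.k3, p.k4, p.k5, p.k6, p.k7, p.k8, p.k9,
         p.A0, p.rho, p.omega, p.B, p.S0, p.beta]
    )


def jacobian(state, params: ParameterSet) -> np.ndarray:
    """Jacobian of the vector field with respect to ``(X, Y, Z)``.

    The forcing enters only additively through ``A(t)``, so the state
    Jacobian is the same for the forced and unforced systems.
    """
    X, Y, Z = np.asarray(state, dtype=float)
    p = params
    return np.array(
        [
            [p.k2 * p.B - p.k6 - p.k4 * Z - 2.0 * p.k5 * X, p.k3, -p.k4 * X],
            [p.k6, -p.k7, 0.0],
            [-p.beta * p.k4 * Z, p.k8 * (p.S0 - Z), -p.k8 * Y - p.beta * p.k4 * X - p.k9],
        ]
    )


def characteristic_polynomial(m: np.ndarray) -> tuple[float, float, float]:
    """Coefficients ``(c2, c1, c0)`` of ``det(lambda*I - m) = l^3 + c2 l^2 + c1 l + c0``.

    For a 3x3 matrix: ``c2 = -trace``, ``c1`` = sum of principal 2x2
    minors, ``c0 = -det``.
    """
    m = np.asarray(m, dtype=float)
    tr = np.trace(m)
    c2 = -tr
    c1 = 0.5 * (tr * tr - np.trace(m @ m))
    c0 = -np.linalg.det(m)
    return (c2, c1, c0)


def matignon_stability(eigenvalues, q: float, tol: float = 1e-9) -> str:
    """Matignon stability of a commensurate Caputo linear system.

    The system is asymptotically stable iff every eigenvalue satisfies
    ``|arg(lambda)| > q*pi/2`` (principal argument in (-pi, pi]; a
    positive real has argument 0, a negative real pi).  Eigenvalues
    within ``tol`` of the boundary are treated as marginal and the
    system is reported ``"unstable"``.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("fractional order q must lie in (0, 1]")
    boundary = q * np.pi / 2.0
    for lam in np.atleast_1d(np.asarray(eigenvalues, dtype=complex)):
        a = abs(np.angle(lam))
        if a <= boundary + tol:  # inside the unstable sector or marginal
            return "unstable"
    return "stable"


@dataclass
class EquilibriumReport:
    """A stationary state of the unforced system with its linearization."""

    point: np.ndarray
    residual_norm: float
    char_poly: tuple[float, float, float]
    eigenvalues: np.ndarray
    stability_by_order: dict[float, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "point": [float(v) for v in self.point],
            "residual": float(self.residual_norm),
            "char_poly": [float(c) for c in self.char_poly],
            "eigenvalues": [[float(e.real), float(e.imag)] for e in self.eigenvalues],
            "stability": {str(q): s for q, s in self.stability_by_order.items()},
        }


def _cubic_coefficients(p: ParameterSet) -> list[float]:
    # Y* = (k6/k7) X*;  Z* = k8*S0*c*X / ((k8*c + beta*k4) X + k9).
    # Substituting into f1 = 0 and clearing the denominator leaves a cubic in X.
    c = p.k6 / p.k7
    ad = p.k8 * c + p.beta * p.k4
    bd = p.k9
    lin = p.k2 * p.B - p.k6 + p.k3 * c
    return [
        -p.k5 * ad,
        lin * ad - p.k5 * bd - p.k4 * p.k8 * p.S0 * c,
        p.k1 * p.A0 * ad + lin * bd,
        p.k1 * p.A0 * bd,
    ]


def find_equilibria(
    params: ParameterSet,
    q_grid: tuple[float, ...] = DEFAULT_Q_GRID,
) -> list[EquilibriumReport]:
    """All real stationary states of the unforced (``rho = 0``) system.

    ``f2 = 0`` forces ``Y* = (k6/k7) X*``; eliminating ``Z*`` through
    ``f3 = 0`` reduces the fixed-point conditions to a cubic in ``X``.
    Its real roots seed a Newton-type refinement of the full 3D system
    (the support-depleted branch is ill-conditioned in ``Z``, so
    refinement well beyond the cubic's accuracy is mandatory).  Reports
    are sorted by descending ``X``.
    """
    if params.k7 <= 0:
        raise ValueError("k7 must be positive: k7 = 0 leaves Y unconstrained")
    p0 = params.replace(rho=0.0)
    fun = lambda v: rhs(v, 0.0, p0)

    c = p0.k6 / p0.k7
    ad = p0.k8 * c + p0.beta * p0.k4
    bd = p0.k9
    reports: list[EquilibriumReport] = []
    seen: list[np.ndarray] = []
    for x_root in np.roots(_cubic_coefficients(p0)):
        if abs(x_root.imag) > 1e-9 * max(1.0, abs(x_root.real)):
            continue
        x = float(x_root.real)
        seed = np.array([x, c * x, p0.k8 * p0.S0 * c * x / (ad * x + bd)])
        sol = optimize.root(fun, seed, jac=lambda v: jacobian(v, p0), tol=1e-14)
        point = sol.x
        if any(np.allclose(point, s, rtol=1e-6, atol=1e-9) for s in seen):
            continue
        seen.append(point)
        jac = jacobian(point, p0)
        eigs = np.linalg.eigvals(jac)
        reports.append(
            EquilibriumReport(
                point=point,
                residual_norm=float(np.linalg.norm(fun(point))),
                char_poly=characteristic_polynomial(jac),
                eigenvalues=eigs,
                stability_by_order={float(q): matignon_stability(eigs, float(q)) for q in q_grid},
            )
        )
    reports.sort(key=lambda r: -r.point[0])
    return reports
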
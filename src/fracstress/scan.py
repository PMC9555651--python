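"""Parameter, forcing and initial-condition sweeps.

Produces bifurcation diagrams (sets of post-transient peak values of
the perceived-stress variable X per grid point) and regime maps
(spectral entropy, C0 complexity or leading Lyapunov exponent per grid
point) over 1D or 2D grids in the kindling parameter B, fractional
order q, forcing amplitude rho, forcing frequency omega, or initial
conditions Y0/Z0.

Per-point integrations default to 1000 time units at h = 0.02 with
full memory and a 50% transient discard: the chaotic signature at
q near 1 only develops after several hundred time units, so horizons
cannot be shortened, and the coarser step (validated against h = 0.01
at reference points) keeps a full-memory sweep point affordable.
Parameter scans start from the fixed
initial state (1, 1, 1) unless the scanned axis is itself an initial
condition; the system is multistable, so this choice matters and is
recorded in every grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import complexity
from .model import ParameterSet, params_vector, stress_field
from .lyapunov import LyapunovConfig, benettin_wolf
from .solver import FractionalOrders, SolverConfig, Trajectory, integrate

__all__ = [
    "Axis",
    "ScanSpec",
    "ScanGrid",
    "RegimeLabel",
    "extract_peaks",
    "bifurcation_scan",
    "metric_scan",
    "classify_regime",
    "SE_THRESHOLD",
    "C0_THRESHOLD",
]

#: Discrimination thresholds separating stable/periodic from chaotic
#: regimes on the SE and C0 metrics.
SE_THRESHOLD = 0.4
C0_THRESHOLD = 0.12

AXIS_NAMES = ("q", "B", "rho", "omega", "Y0", "Z0")
SUMMARIES = ("peaks", "se", "c0", "le1")


@dataclass(frozen=True)
class Axis:
    name: str
    start: float
    stop: float
    points: int

    def __post_init__(self):
        if self.name not in AXIS_NAMES:
            raise ValueError(f"unknown scan axis {self.name!r}; choose from {AXIS_NAMES}")
        if self.points < 2:
            raise ValueError("an axis needs at least 2 points")
        if not (np.isfinite(self.start) and np.isfinite(self.stop)):
            raise ValueError("axis range must be finite")

    def values(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.points)


@dataclass
class ScanSpec:
    """What to sweep, what to hold fixed, and what to summarize."""

    axis1: Axis
    axis2: Axis | None = None
    params: ParameterSet = field(default_factory=ParameterSet)
    q: float = 0.99
    solver: SolverConfig = field(
        default_factory=lambda: SolverConfig(
            h=0.02, t_end=1000.0, initial_state=(1.0, 1.0, 1.0)
        )
    )
    summary: str = "peaks"
    transient_fraction: float = 0.5
    window_n: int = 4096
    r: float = 1.0

    def __post_init__(self):
        if self.summary not in SUMMARIES:
            raise ValueError(f"unknown summary {self.summary!r}; choose from {SUMMARIES}")
        if self.axis2 is not None and self.axis2.name == self.axis1.name:
            raise ValueError("scan axes must be distinct")


@dataclass
class ScanGrid:
    """Per-grid-point summaries with a divergence mask."""

    axes: dict[str, np.ndarray]
    values: np.ndarray  # float array, or object array of peak-value arrays
    diverged: np.ndarray  # bool mask, same shape as values
    spec: ScanSpec

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass
class RegimeLabel:
    label: str  # "stable_or_periodic" | "chaotic"
    se_threshold: float = SE_THRESHOLD
    c0_threshold: float = C0_THRESHOLD


def extract_peaks(
    traj: Trajectory,
    transient_fraction: float = 0.5,
    tol: float = 1e-2,
) -> np.ndarray:
    """Distinct X values at strict local maxima after the transient.

    Peaks are deduplicated at resolution ``tol``: a fixed point yields
    no peaks, a limit cycle a few, a chaotic attractor a dense set.
    The default resolution is matched to the algebraic settling of
    fractional transients: over a 1000-time-unit window the peak
    heights of a settling periodic orbit still drift by a few times
    1e-3 (Caputo relaxation is power-law, not exponential), so a much
    finer resolution would report a limit cycle as dozens of spurious
    "distinct" peaks.  At 1e-2 a limit cycle collapses to a handful of
    values while a chaotic attractor retains on the order of a hundred.
    """
    if traj.diverged:
        return np.array([])
    x = traj.column("X")
    start = int(len(x) * transient_fraction)
    x = x[start:]
    if len(x) < 3:
        return np.array([])
    interior = x[1:-1]
    mask = (interior > x[:-2]) & (interior > x[2:])
    peaks = interior[mask]
    if peaks.size == 0:
        return peaks
    return np.unique(np.round(peaks / tol)) * tol


def _point_run(spec: ScanSpec, overrides: dict[str, float]) -> tuple[ParameterSet, float, SolverConfig]:
    params = spec.params
    q = spec.q
    ic = list(np.asarray(spec.solver.initial_state, dtype=float))
    for name, val in overrides.items():
        if name == "q":
            q = float(val)
        elif name in ("B", "rho", "omega"):
            params = params.replace(**{name: float(val)})
        elif name == "Y0":
            ic[1] = float(val)
        elif name == "Z0":
            ic[2] = float(val)
    solver = replace(spec.solver, initial_state=tuple(ic))
    return params, q, solver


def _summarize(spec: ScanSpec, params: ParameterSet, q: float, solver: SolverConfig):
    if spec.summary == "le1":
        lcfg = LyapunovConfig(
            t_total=solver.t_end,
            transient=solver.t_end * spec.transient_fraction,
            solver=replace(solver),
            orders=FractionalOrders(q),
        )
        spectrum = benettin_wolf(params, FractionalOrders(q), lcfg)
        return float(spectrum.exponents[0]), False
    traj = integrate(stress_field, FractionalOrders(q), solver, params_vector=params_vector(params))
    if spec.summary == "peaks":
        return extract_peaks(traj, spec.transient_fraction), traj.diverged
    if traj.diverged:
        return np.nan, True
    window = complexity.trajectory_window(
        traj.column("X"), n=spec.window_n, discard_fraction=spec.transient_fraction
    )
    result = complexity.analyze(window, r=spec.r)
    return (result.se if spec.summary == "se" else result.c0), False


def _run_scan(spec: ScanSpec) -> ScanGrid:
    v1 = spec.axis1.values()
    if spec.axis2 is None:
        values = np.empty(len(v1), dtype=object if spec.summary == "peaks" else float)
        diverged = np.zeros(len(v1), dtype=bool)
        for i, a in enumerate(v1):
            params, q, solver = _point_run(spec, {spec.axis1.name: a})
            values[i], diverged[i] = _summarize(spec, params, q, solver)
        axes = {spec.axis1.name: v1}
    else:
        v2 = spec.axis2.values()
        shape = (len(v1), len(v2))
        values = np.empty(shape, dtype=object if spec.summary == "peaks" else float)
        diverged = np.zeros(shape, dtype=bool)
        for i, a in enumerate(v1):
            for j, b in enumerate(v2):
                params, q, solver = _point_run(spec, {spec.axis1.name: a, spec.axis2.name: b})
                values[i, j], diverged[i, j] = _summarize(spec, params, q, solver)
        axes = {spec.axis1.name: v1, spec.axis2.name: v2}
    return ScanGrid(axes=axes, values=values, diverged=diverged, spec=spec)


def bifurcation_scan(spec: ScanSpec) -> ScanGrid:
    """One integration + peak extraction per grid point (summary='peaks')."""
    if spec.summary != "peaks":
        raise ValueError("bifurcation_scan requires summary='peaks'")
    return _run_scan(spec)


def metric_scan(spec: ScanSpec) -> ScanGrid:
    """Per-point SE, C0 or leading Lyapunov exponent over the grid."""
    if spec.summary not in ("se", "c0", "le1"):
        raise ValueError("metric_scan requires summary in {'se','c0','le1'}")
    return _run_scan(spec)


def classify_regime(
    result: complexity.ComplexityResult,
    se_threshold: float = SE_THRESHOLD,
    c0_threshold: float = C0_THRESHOLD,
) -> RegimeLabel:
    """Conjunctive threshold rule: chaotic iff SE and C0 both exceed."""
    if se_threshold <= 0 or c0_threshold <= 0:
        raise ValueError("thresholds must be positive")
    chaotic = result.se > se_threshold and result.c0 > c0_threshold
    return RegimeLabel(
        label="chaotic" if chaotic else "stable_or_periodic",
        se_threshold=se_threshold,
        c0_threshold=c0_threshold,
    )
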
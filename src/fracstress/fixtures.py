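"""Deterministic reference signals for validating the complexity metrics.

Four signal families with known spectral character:

* ``sine`` — unit sinusoid at an exact FFT bin (all power in one bin,
  SE near 0),
* ``white_noise`` — seeded standard Gaussian samples (near-flat
  spectrum, SE near 1),
* ``logistic_map`` — iterates of ``x <- r x (1 - x)`` at r = 4 (fully
  chaotic, broadband),
* ``constant`` — all ones (degenerate after mean removal).

Same (kind, N, seed, parameters) always reproduces identical samples:
the Gaussian and logistic starting values come from ``numpy``'s PCG64
generator seeded explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FixtureSignal", "generate_fixture"]

KINDS = ("sine", "white_noise", "logistic_map", "constant")


@dataclass(frozen=True)
class FixtureSignal:
    kind: str
    n: int = 4096
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {KINDS}")
        if self.n < 64 or self.n % 2:
            raise ValueError("fixture length must be even and >= 64")


def generate_fixture(spec: FixtureSignal) -> np.ndarray:
    """Samples of the requested fixture signal."""
    n = spec.n
    if spec.kind == "constant":
        return np.ones(n)
    if spec.kind == "sine":
        k = int(spec.params.get("bin", 32))
        if not 1 <= k < n // 2:
            raise ValueError("sine bin must lie strictly inside the one-sided band")
        return np.sin(2.0 * np.pi * k * np.arange(n) / n)
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "white_noise":
        scale = float(spec.params.get("scale", 1.0))
        return scale * rng.standard_normal(n)
    # logistic map, burn-in discards the transient toward the invariant density
    r = float(spec.params.get("r", 4.0))
    burn_in = int(spec.params.get("burn_in", 1000))
    x = float(rng.uniform(0.05, 0.95))
    for _ in range(burn_in):
        x = r * x * (1.0 - x)
    out = np.empty(n)
    for i in range(n):
        x = r * x * (1.0 - x)
        out[i] = x
    return out
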
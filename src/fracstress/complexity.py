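"""Spectral complexity summaries for regime classification.

Two global, spectrum-based statistics distinguish periodic from
chaotic oscillations in the model's time series:

* **Spectral entropy (SE)** — Shannon entropy of the one-sided
  relative power spectral density, normalized by ``ln(N/2)`` so it
  ranges over [0, 1].  Narrowband (periodic) signals score near 0,
  broadband (chaotic or noisy) signals near 1.

* **C0 complexity** — the energy fraction of a signal's "irregular"
  part.  Spectral bins whose power does not strictly exceed ``r``
  times the mean one-sided power are zeroed; the inverse transform of
  what remains is the "regular" part, and C0 is the energy of the
  residual relative to the whole.  The larger C0, the more complex the
  signal.

Both are scale invariant.  Applied to the stress model, SE above about
0.4 together with C0 above about 0.12 flags chaos.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SignalWindow",
    "ComplexityResult",
    "remove_mean",
    "relative_psd",
    "spectral_entropy",
    "c0_complexity",
    "analyze",
    "trajectory_window",
]

MIN_WINDOW = 64


@dataclass
class SignalWindow:
    """A uniformly sampled, even-length analysis window."""

    samples: np.ndarray
    source: str = ""
    dt: float = 1.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        n = len(self.samples)
        if n < MIN_WINDOW or n % 2:
            raise ValueError(f"window length must be even and >= {MIN_WINDOW}, got {n}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window contains non-finite samples")


@dataclass
class ComplexityResult:
    """SE and C0 values with the settings that produced them."""

    se: float
    c0: float
    r: float
    n: int
    source: str = ""


def remove_mean(samples) -> np.ndarray:
    """Subtract the sample mean (the DC part)."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    return x - x.mean()


def _validate(samples) -> np.ndarray:
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < MIN_WINDOW or n % 2:
        raise ValueError(f"signal length must be even and >= {MIN_WINDOW}, got {n}")
    return x


def relative_psd(samples) -> np.ndarray:
    """One-sided relative power spectral density P(k), k = 0..N/2-1.

    ``P(k) = |X(k)|^2 / sum_{k<N/2} |X(k)|^2``; sums to 1 exactly.
    The Nyquist bin is excluded.  Expects the mean already removed.
    """
    x = _validate(samples)
    X = np.fft.fft(x)
    power = np.abs(X[: len(x) // 2]) ** 2
    total = power.sum()
    if total == 0:
        raise ValueError("all-zero signal: relative PSD undefined")
    return power / total


def spectral_entropy(samples) -> float:
    """Normalized Shannon entropy of the one-sided relative PSD, in [0, 1]."""
    p = relative_psd(samples)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(len(p)))


def c0_complexity(samples, r: float = 1.0) -> float:
    """C0 complexity with control parameter ``r > 0``, in [0, 1].

    Threshold ``G_N = (2 r / N) * sum_{k<N/2} |X(k)|^2`` (r times the
    mean one-sided power); bins with ``|X(k)|^2 > G_N`` (strictly) are
    kept over the full two-sided spectrum — for a real signal the
    power spectrum is conjugate-symmetric, so the kept set is
    symmetric and the regular part is real.  Returns the energy ratio
    of the removed (irregular) part to the original signal.
    """
    if r <= 0:
        raise ValueError("control parameter r must be positive")
    x = _validate(samples)
    n = len(x)
    total_energy = float(np.sum(x * x))
    if total_energy == 0:
        raise ValueError("all-zero signal: C0 undefined")
    X = np.fft.fft(x)
    power = np.abs(X) ** 2
    g_n = 2.0 * r / n * power[: n // 2].sum()
    kept = np.where(power > g_n, X, 0.0)
    regular = np.fft.ifft(kept).real
    residual = x - regular
    return float(np.sum(residual * residual) / total_energy)


def analyze(samples, r: float = 1.0, source: str = "") -> ComplexityResult:
    """Mean-removed SE and C0 of a window, with settings recorded."""
    x = remove_mean(_validate(samples))
    return ComplexityResult(
        se=spectral_entropy(x),
        c0=c0_complexity(x, r=r),
        r=r,
        n=len(x),
        source=source,
    )


def trajectory_window(
    values: np.ndarray,
    n: int = 4096,
    discard_fraction: float = 0.5,
) -> np.ndarray:
    """Post-transient analysis window resampled to ``n`` points.

    Discards the leading ``discard_fraction`` of the samples, then
    linearly resamples the remainder onto ``n`` evenly spaced points.
    With the default grid (h = 0.01, horizons of several hundred time
    units) the window spans many forcing periods.
    """
    values = np.asarray(values, dtype=float)
    start = int(len(values) * discard_fraction)
    tail = values[start:]
    if len(tail) < 2:
        raise ValueError("trajectory too short for the requested window")
    src = np.arange(len(tail), dtype=float)
    dst = np.linspace(0.0, len(tail) - 1.0, n)
    return np.interp(dst, src, tail)
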
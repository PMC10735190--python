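"""Empirical mode decomposition by sifting with the SD stopping criterion.

The decomposition splits a signal into intrinsic mode functions (IMFs):
oscillatory components whose extrema and zero-crossing counts differ by at
most one and whose local envelope mean is (near) zero. Each mode is
obtained by *sifting* — repeatedly subtracting the mean of the cubic-spline
envelopes through the local maxima and minima — until the normalized
squared change between successive iterates

    SD = sum((s2 - s1)**2) / sum(s1**2)

falls below a threshold ``q`` in [0.2, 0.3]. Extracted modes are
subtracted from the running residual, so the decomposition reconstructs
the input exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import DegenerateInputError, NotSiftableError

__all__ = [
    "IMFSet",
    "find_extrema",
    "sd_criterion",
    "sift",
    "decompose",
]

#: Default SD-criterion threshold: midpoint of the conventional 0.2–0.3 range.
DEFAULT_Q = 0.25
#: Safety cap on sifting iterations per mode.
DEFAULT_MAX_ITER = 100
#: Number of modes extracted by default (five carry features, the sixth is
#: the adjacent-band partner of the fifth; see ``cogload.features``).
DEFAULT_N_MODES = 6


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus the final residual.

    ``imfs[k]`` is the (k+1)-th mode, fastest oscillation first; ``residual``
    is what remains after all modes were subtracted. ``sift_counts[k]`` is the
    number of sifting iterations mode k took.
    """

    imfs: list[np.ndarray]
    residual: np.ndarray
    sift_counts: list[int] = field(default_factory=list)

    @property
    def n_modes(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        """Sum of all modes and the residual (equals the input signal)."""
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def _validate_signal(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"signal must be 1-D, got shape {x.shape}")
    if x.size < 8:
        raise ValueError(f"signal too short for decomposition: {x.size} < 8")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    return x


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima of ``x``.

    A run of equal samples (plateau) bounded on both sides by lower
    (higher) values counts as one maximum (minimum) at the plateau
    center. Endpoints are never extrema.

    Returns ``(maxima, minima)`` as int arrays, possibly empty.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to locate extrema")
    # collapse plateaus: run starts where the value changes
    change = np.empty(x.size, dtype=bool)
    change[0] = True
    np.not_equal(x[1:], x[:-1], out=change[1:])
    starts = np.flatnonzero(change)              # first index of each run
    vals = x[starts]
    if vals.size < 3:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    ends = np.empty_like(starts)
    ends[:-1] = starts[1:] - 1
    ends[-1] = x.size - 1
    centers = (starts + ends) // 2
    prev, cur, nxt = vals[:-2], vals[1:-1], vals[2:]
    maxima = centers[1:-1][(cur > prev) & (cur > nxt)]
    minima = centers[1:-1][(cur < prev) & (cur < nxt)]
    return maxima, minima


def sd_criterion(s1: np.ndarray, s2: np.ndarray) -> float:
    """Normalized squared difference between successive sifting iterates.

    Computed with global normalization, ``sum((s2-s1)**2) / sum(s1**2)``,
    which is finite wherever ``s1`` is not identically zero (a point-wise
    ratio would blow up at zero-crossings of ``s1``).
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError(f"length mismatch: {s1.shape} vs {s2.shape}")
    denom = float(np.sum(s1 * s1))
    if denom == 0.0:
        raise DegenerateInputError("SD criterion undefined for all-zero iterate")
    return float(np.sum((s2 - s1) ** 2)) / denom


def _mirrored_envelope(idx: np.ndarray, val: np.ndarray, n: int, t: np.ndarray) -> np.ndarray:
    """Natural cubic spline through extrema, mirror-extended two points per end.

    Mirroring the outermost extrema across the signal boundaries suppresses
    the end swings a spline clamped only to interior extrema would show.
    """
    left_x = -idx[:2][::-1]
    left_v = val[:2][::-1]
    right_x = 2 * (n - 1) - idx[-2:][::-1]
    right_v = val[-2:][::-1]
    xs = np.concatenate([left_x, idx, right_x])
    vs = np.concatenate([left_v, val, right_v])
    xs, keep = np.unique(xs, return_index=True)  # guard extremum exactly on a boundary
    vs = vs[keep]
    return CubicSpline(xs, vs, bc_type="natural")(t)


def _envelope_mean(s: np.ndarray) -> np.ndarray | None:
    """Mean of the upper and lower spline envelopes, or None if not siftable."""
    maxima, minima = find_extrema(s)
    if maxima.size < 2 or minima.size < 2:
        return None
    t = np.arange(s.size)
    upper = _mirrored_envelope(maxima, s[maxima], s.size, t)
    lower = _mirrored_envelope(minima, s[minima], s.size, t)
    return 0.5 * (upper + lower)


def sift(x: np.ndarray, q: float = DEFAULT_Q,
         max_iter: int = DEFAULT_MAX_ITER) -> tuple[np.ndarray, int]:
    """Extract one intrinsic mode function from ``x`` by sifting.

    Parameters
    ----------
    x : 1-D array with at least 2 maxima and 2 minima.
    q : SD-criterion threshold; iteration stops once the normalized change
        between successive iterates drops below it.
    max_iter : hard cap on iterations (guarantees termination).

    Returns
    -------
    (imf, iterations)

    Raises
    ------
    NotSiftableError
        If the input itself has too few extrema to build envelopes.
    """
    s1 = np.asarray(x, dtype=float)
    mean_env = _envelope_mean(s1)
    if mean_env is None:
        raise NotSiftableError("signal has fewer than 2 maxima or 2 minima")
    iterations = 0
    while iterations < max_iter:
        s2 = s1 - mean_env
        iterations += 1
        if sd_criterion(s1, s2) < q:
            return s2, iterations
        s1 = s2
        mean_env = _envelope_mean(s1)
        if mean_env is None:  # sifting consumed the oscillation
            return s1, iterations
    return s1, iterations


def decompose(x: np.ndarray, n_modes: int = DEFAULT_N_MODES, q: float = DEFAULT_Q,
              max_iter: int = DEFAULT_MAX_ITER) -> IMFSet:
    """Decompose ``x`` into up to ``n_modes`` IMFs plus a residual.

    Modes are extracted fastest-first; extraction stops early when the
    running residual is monotone or has too few extrema to sift. The sum
    of the returned modes and residual equals the input to rounding error.
    """
    x = _validate_signal(x)
    residual = x.copy()
    imfs: list[np.ndarray] = []
    counts: list[int] = []
    for _ in range(n_modes):
        try:
            imf, n_it = sift(residual, q=q, max_iter=max_iter)
        except NotSiftableError:
            break
        imfs.append(imf)
        counts.append(n_it)
        residual = residual - imf
    return IMFSet(imfs=imfs, residual=residual, sift_counts=counts)
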
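"""Independently coded reference EMD used only as a cross-check oracle.

Deliberately different implementation choices from the package: extrema via
``scipy.signal.argrelextrema``, envelopes anchored at the signal endpoints
(no mirror extension) with not-a-knot cubic splines, and a fixed number of
sifting iterations per mode instead of the SD stopping criterion. Away from
the boundaries (where end-extension conventions genuinely differ between
EMD variants) both routes must produce the same modes.
"""

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import argrelextrema


def reference_envelope_mean(s: np.ndarray) -> np.ndarray | None:
    n = len(s)
    maxima = argrelextrema(s, np.greater)[0]
    minima = argrelextrema(s, np.less)[0]
    if maxima.size < 2 or minima.size < 2:
        return None

    def envelope(idx):
        xs = np.concatenate([[0], idx, [n - 1]])
        vs = s[xs]
        xs, keep = np.unique(xs, return_index=True)
        return CubicSpline(xs, vs[keep])(np.arange(n))

    return 0.5 * (envelope(maxima) + envelope(minima))


def reference_decompose(x: np.ndarray, n_modes: int = 6,
                        n_sifts: int = 10) -> tuple[list[np.ndarray], np.ndarray]:
    residual = np.asarray(x, dtype=float).copy()
    modes: list[np.ndarray] = []
    for _ in range(n_modes):
        if reference_envelope_mean(residual) is None:
            break
        s = residual.copy()
        for _ in range(n_sifts):
            env_mean = reference_envelope_mean(s)
            if env_mean is None:
                break
            s = s - env_mean
        modes.append(s)
        residual = residual - s
    return modes, residual
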
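"""Per-IMF statistical features and the 570-value subject-condition vector.

Six statistics are computed for each of the first five IMFs of each of the
19 montage channels: mean, standard deviation, skewness, kurtosis, RMS and
the ratio of absolute mean amplitudes of adjacent sub-bands. All moments
use the population (1/n) divisor, so RMS² = mean² + SD² holds as an exact
identity. The adjacent-band partner of mode k is mode k+1 — which is why
six modes are decomposed although only five carry features.

Layout is channel-major: ``values[30*c + 6*k + f]`` for channel ``c``,
mode ``k`` (0-based, first five), feature ``f`` in
(mean, sd, skewness, kurtosis, rms, ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import emd
from .errors import DegenerateMomentError, InsufficientModesError, RatioUndefinedError
from .montage import CHANNELS

__all__ = [
    "FEATURE_NAMES",
    "N_FEATURE_MODES",
    "N_FEATURES",
    "FeatureVector",
    "feature_columns",
    "imf_features",
    "subject_feature_vector",
    "EMDFeatureExtractor",
]

FEATURE_NAMES: tuple[str, ...] = ("mean", "sd", "skewness", "kurtosis", "rms", "ratio")
#: Modes carrying features (a sixth is decomposed as the ratio partner).
N_FEATURE_MODES = 5
#: 19 channels x 5 modes x 6 features.
N_FEATURES = len(CHANNELS) * N_FEATURE_MODES * len(FEATURE_NAMES)


@dataclass
class FeatureVector:
    """One subject-condition's ordered 570-value feature array."""

    subject_id: str
    condition: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(
                f"feature vector must have length {N_FEATURES}, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


def feature_columns() -> list[str]:
    """Ordered column names ``<channel>_imf<k>_<feature>`` for the 570 values."""
    return [
        f"{ch}_imf{k + 1}_{feat}"
        for ch in CHANNELS
        for k in range(N_FEATURE_MODES)
        for feat in FEATURE_NAMES
    ]


def imf_features(D: np.ndarray, E: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Six statistics of mode ``D`` with adjacent-band partner ``E``.

    Returns ``(mean, sd, skewness, kurtosis, rms, ratio)`` where sd is the
    population standard deviation, skewness/kurtosis are the third/fourth
    standardized moments (kurtosis not excess: 3 for a normal sample), rms
    the root mean square, and ratio = sum|D| / sum|E|.

    Raises
    ------
    DegenerateMomentError
        If D is constant (sd = 0), leaving skewness/kurtosis undefined.
    RatioUndefinedError
        If sum|E| = 0.
    """
    D = np.asarray(D, dtype=float)
    E = np.asarray(E, dtype=float)
    if D.size < 2:
        raise ValueError("need at least 2 samples")
    m = float(np.mean(D))
    centered = D - m
    sd = float(np.sqrt(np.mean(centered**2)))
    if sd == 0.0:
        raise DegenerateMomentError("constant mode: standard deviation is zero")
    z = centered / sd
    skew = float(np.mean(z**3))
    kurt = float(np.mean(z**4))
    rms = float(np.sqrt(np.mean(D**2)))
    abs_e = float(np.sum(np.abs(E)))
    if abs_e == 0.0:
        raise RatioUndefinedError("adjacent sub-band has zero absolute sum")
    ratio = float(np.sum(np.abs(D))) / abs_e
    return m, sd, skew, kurt, rms, ratio


def subject_feature_vector(imfsets: list[emd.IMFSet], subject_id: str = "",
                           condition: str = "") -> FeatureVector:
    """Assemble the 570-value vector from per-channel decompositions.

    ``imfsets`` must hold one :class:`~cogload.emd.IMFSet` per canonical
    channel, in canonical order, each with at least six modes (mode k's
    ratio partner is mode k+1).
    """
    if len(imfsets) != len(CHANNELS):
        raise ValueError(f"expected {len(CHANNELS)} channel decompositions, got {len(imfsets)}")
    values = np.empty(N_FEATURES)
    pos = 0
    for ch, imfset in zip(CHANNELS, imfsets):
        if imfset.n_modes < N_FEATURE_MODES + 1:
            raise InsufficientModesError(
                f"channel {ch}: {imfset.n_modes} modes extracted, "
                f"need {N_FEATURE_MODES + 1}"
            )
        for k in range(N_FEATURE_MODES):
            values[pos:pos + 6] = imf_features(imfset.imfs[k], imfset.imfs[k + 1])
            pos += 6
    return FeatureVector(subject_id=subject_id, condition=condition, values=values)


class EMDFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer: recordings -> (n_samples, 570) feature matrix.

    Each input recording is decomposed channel by channel into ``n_modes``
    intrinsic mode functions (SD-criterion threshold ``q``, at most
    ``max_iter`` sifting iterations per mode) and summarized by the six
    statistics per mode. No parameters are learned; ``fit`` exists for
    sklearn-pipeline compatibility.

    Parameters
    ----------
    n_modes : modes to decompose per channel (the last is only the
        adjacent-band partner of the fifth).
    q : SD stopping threshold, conventionally in [0.2, 0.3].
    max_iter : sifting iteration cap per mode.
    """

    def __init__(self, n_modes: int = emd.DEFAULT_N_MODES, q: float = emd.DEFAULT_Q,
                 max_iter: int = emd.DEFAULT_MAX_ITER):
        self.n_modes = n_modes
        self.q = q
        self.max_iter = max_iter

    def fit(self, X, y=None):
        self.n_features_out_ = N_FEATURES
        return self

    def extract(self, recording) -> FeatureVector:
        """Feature vector of a single :class:`~cogload.io.Recording`."""
        imfsets = [
            emd.decompose(recording.data[c], n_modes=self.n_modes, q=self.q,
                          max_iter=self.max_iter)
            for c in range(len(CHANNELS))
        ]
        try:
            return subject_feature_vector(imfsets, subject_id=recording.subject_id,
                                          condition=recording.condition)
        except InsufficientModesError as err:
            raise InsufficientModesError(
                f"{recording.subject_id}/{recording.condition}: {err}"
            ) from err

    def transform(self, X) -> np.ndarray:
        """Transform an iterable of recordings into a feature matrix."""
        return np.vstack([self.extract(rec).values for rec in X])
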
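"""Recording and manifest I/O: EDF files, subject manifests, feature tables.

EDF (European Data Format) reading goes through :mod:`mne`; writing uses a
minimal built-in 16-bit EDF encoder sufficient for plain continuous
multichannel segments (no annotations). Amplitudes are handled in µV
throughout the package; the reader rescales whatever physical unit the
file declares.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ChannelMissingError,
    EmptyManifestError,
    FormatError,
    ValidationError,
)
from .features import N_FEATURES, FeatureVector, feature_columns
from .montage import ALIASES, CHANNELS

__all__ = [
    "Recording",
    "SubjectMeta",
    "PERFORMANCE_THRESHOLD",
    "read_recording",
    "write_edf",
    "load_manifest",
    "write_manifest",
    "write_features",
    "read_features",
]

#: Problems-per-minute threshold separating BAD (X <= 10) from GOOD performers.
PERFORMANCE_THRESHOLD = 10.0

CONDITIONS = ("rest", "task")


@dataclass
class Recording:
    """One subject-condition multichannel EEG segment.

    ``data`` is a (19, n_samples) float array in µV with rows in the
    canonical montage order.
    """

    subject_id: str
    condition: str
    fs: float
    data: np.ndarray
    channel_labels: tuple[str, ...] = field(default=CHANNELS)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.condition not in CONDITIONS:
            raise ValidationError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValidationError(
                f"data must be ({len(self.channel_labels)}, n_samples), got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SubjectMeta:
    """Subject identity, problem-completion rate and derived skill group."""

    subject_id: str
    X: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.X) or self.X <= 0:
            raise ValidationError(f"{self.subject_id}: completion rate must be > 0, got {self.X}")

    @property
    def group(self) -> str:
        return "BAD" if self.X <= PERFORMANCE_THRESHOLD else "GOOD"


# ---------------------------------------------------------------------------
# EDF writing (minimal continuous-signal encoder)
# ---------------------------------------------------------------------------

def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF header field {s!r} exceeds {width} ascii chars")
    return s.ljust(width).encode("ascii")


def _phys_bound(v: float) -> float:
    """Round-trippable 8-char ascii representation of a physical bound."""
    return float(f"{v:.6g}")


def write_edf(rec: Recording, path) -> None:
    """Write a recording as a 16-bit EDF file (one signal per channel).

    Uses 1-second data records when the sample count divides evenly,
    otherwise a single record spanning the whole segment. Per-channel
    physical scaling keeps quantization error below physical-range/2^16.
    """
    path = Path(path)
    n_ch, n = rec.data.shape
    fs = rec.fs
    if n % round(fs) == 0 and abs(fs - round(fs)) < 1e-9:
        spr, n_rec, dur = round(fs), n // round(fs), "1"
        if len(f"{dur}") > 8:
            raise FormatError("record duration does not fit EDF header")
    else:
        spr, n_rec, dur = n, 1, f"{n / fs:.6g}"

    dig_max, dig_min = 32767, -32767
    pmaxs = [_phys_bound(max(1e-6, float(np.max(np.abs(ch)))) * 1.0001) for ch in rec.data]

    header = bytearray()
    header += _ascii("0", 8)
    header += _ascii(rec.subject_id or "X", 80)
    header += _ascii(f"Startdate X {rec.condition}", 80)
    now = _dt.datetime(2000, 1, 1)
    header += _ascii(now.strftime("%d.%m.%y"), 8)
    header += _ascii(now.strftime("%H.%M.%S"), 8)
    header += _ascii(256 * (1 + n_ch), 8)
    header += _ascii("", 44)
    header += _ascii(n_rec, 8)
    header += _ascii(dur, 8)
    header += _ascii(n_ch, 4)
    for label in rec.channel_labels:
        header += _ascii(f"EEG {label}", 16)
    header += b"".join(_ascii("", 80) for _ in range(n_ch))          # transducer
    header += b"".join(_ascii("uV", 8) for _ in range(n_ch))         # physical dim
    header += b"".join(_ascii(f"{-p:.6g}", 8) for p in pmaxs)        # phys min
    header += b"".join(_ascii(f"{p:.6g}", 8) for p in pmaxs)         # phys max
    header += b"".join(_ascii(dig_min, 8) for _ in range(n_ch))
    header += b"".join(_ascii(dig_max, 8) for _ in range(n_ch))
    header += b"".join(_ascii("", 80) for _ in range(n_ch))          # prefiltering
    header += b"".join(_ascii(spr, 8) for _ in range(n_ch))
    header += b"".join(_ascii("", 32) for _ in range(n_ch))

    digital = np.empty((n_ch, n), dtype="<i2")
    for c in range(n_ch):
        gain = pmaxs[c] / dig_max
        digital[c] = np.clip(np.rint(rec.data[c] / gain), dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_rec):
            sl = slice(r * spr, (r + 1) * spr)
            for c in range(n_ch):
                fh.write(digital[c, sl].tobytes())


# ---------------------------------------------------------------------------
# EDF reading (via mne)
# ---------------------------------------------------------------------------

def _filename_metadata(path: Path) -> tuple[str, str | None]:
    stem = path.stem
    m = re.match(r"(?P<sid>.+)_(?P<cond>rest|task)$", stem, flags=re.IGNORECASE)
    if m:
        return m.group("sid"), m.group("cond").lower()
    return stem, None


def read_recording(path, montage: tuple[str, ...] = CHANNELS, *,
                   subject_id: str | None = None, condition: str | None = None,
                   allow_aliases: bool = False) -> Recording:
    """Read an EDF file and return the 19 montage channels in canonical order.

    Reference (A1/A2), ECG, stimulus and any other non-montage channels are
    dropped. Matching is case-insensitive and tolerates an ``EEG `` prefix;
    with ``allow_aliases=True`` the modern temporal names (T7/T8/P7/P8) are
    accepted for the classic T3/T4/T5/T6 sites.

    Raises
    ------
    ChannelMissingError
        If a montage label has no counterpart in the file.
    FormatError
        If the file cannot be parsed as EDF.
    """
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as err:  # mne raises assorted types on malformed files
        raise FormatError(f"cannot read {path} as EDF: {err}") from err

    def canon(name: str) -> str:
        name = name.strip()
        if name.lower().startswith("eeg "):
            name = name[4:].strip()
        return name.lower()

    available = {canon(name): name for name in raw.ch_names}
    picks = []
    for label in montage:
        candidates = (label,) + (ALIASES.get(label, ()) if allow_aliases else ())
        for cand in candidates:
            if cand.lower() in available:
                picks.append(available[cand.lower()])
                break
        else:
            raise ChannelMissingError(label)

    data = raw.get_data(picks=picks) * 1e6  # mne returns SI volts
    sid, cond = _filename_metadata(path)
    return Recording(
        subject_id=subject_id or sid,
        condition=condition or cond or "rest",
        fs=float(raw.info["sfreq"]),
        data=data,
        channel_labels=tuple(montage),
    )


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def load_manifest(path) -> list[SubjectMeta]:
    """Load a subject manifest CSV with columns ``subject_id`` and ``X``.

    Rows are returned in file order. Duplicated subject ids, non-numeric or
    non-positive completion rates, and empty files are rejected.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as err:
        raise EmptyManifestError(f"manifest {path} is empty") from err
    if df.empty:
        raise EmptyManifestError(f"manifest {path} has no rows")
    missing = {"subject_id", "X"} - set(df.columns)
    if missing:
        raise FormatError(f"manifest {path} lacks columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"duplicate subject ids in manifest: {dupes}")
    x = pd.to_numeric(df["X"], errors="coerce")
    if x.isna().any():
        bad = df.loc[x.isna(), "X"].tolist()
        raise ValidationError(f"non-numeric completion rates in manifest: {bad}")
    return [SubjectMeta(subject_id=str(s), X=float(v)) for s, v in zip(df["subject_id"], x)]


def write_manifest(metas: list[SubjectMeta], path) -> None:
    pd.DataFrame(
        {"subject_id": [m.subject_id for m in metas],
         "X": [m.X for m in metas],
         "group": [m.group for m in metas]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def write_features(vectors: list[FeatureVector], path) -> None:
    """Persist feature vectors as CSV; the header encodes (channel, mode, feature)."""
    cols = feature_columns()
    rows = [
        {"subject_id": v.subject_id, "condition": v.condition,
         **dict(zip(cols, v.values))}
        for v in vectors
    ]
    pd.DataFrame(rows, columns=["subject_id", "condition", *cols]).to_csv(path, index=False)


def read_features(path) -> list[FeatureVector]:
    """Read a feature-table CSV back into :class:`FeatureVector` objects."""
    df = pd.read_csv(path)
    expected = ["subject_id", "condition", *feature_columns()]
    if list(df.columns) != expected:
        raise FormatError(
            f"feature table {path} header does not match the "
            f"{N_FEATURES}-value layout"
        )
    return [
        FeatureVector(subject_id=str(row[0]), condition=str(row[1]),
                      values=np.asarray(row[2:], dtype=float))
        for row in df.itertuples(index=False)
    ]
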
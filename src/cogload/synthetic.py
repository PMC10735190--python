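"""Seedable synthetic rest/task EEG cohorts with performance-dependent load.

The generator emulates the study design every downstream stage expects: a
cohort of low-skill ("BAD", completion rate X <= 10 problems/min) and
high-skill ("GOOD") subjects, each contributing one rest and one task
segment of 19-channel EEG.

Signal model, per channel::

    x(t) = pink(t) + A_alpha * sin(2*pi*10*t + phi_a) + A_theta * sin(2*pi*6*t + phi_t)

* pink(t): 1/f background noise (power spectral slope -1), normalized to
  an exact RMS of ``PINK_RMS`` µV per channel, independent per channel and
  condition.
* alpha (10 Hz): occipital-dominant, identical in both conditions; it
  dominates the rest maps (and the rest-relative share of alpha shrinks
  under load, i.e. alpha is rest-enhanced in relative terms).
* theta (6 Hz): frontal/central/parietal; its task amplitude is scaled by
  the load factor ``L = 1 + effect * (1 - skill)``, so low-skill subjects
  under a large effect show a strong task power increase while high-skill
  subjects (or effect 0) show none.

Routing the entire load effect through the theta amplitude keeps two
properties exact: with effect = 0 the rest and task segments are draws
from the same distribution, and expected task-minus-rest power is
non-decreasing in the effect multiplier on every channel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import InvalidConfigError
from .io import PERFORMANCE_THRESHOLD, Recording, SubjectMeta, write_edf, write_manifest
from .montage import CHANNELS, REGIONS

__all__ = [
    "SyntheticConfig",
    "SkillProfile",
    "generate_subject_recording",
    "generate_profiles",
    "generate_cohort",
    "write_cohort",
    "expected_channel_power",
    "load_factor",
    "ALPHA_FREQ",
    "THETA_FREQ",
    "PINK_RMS",
]

ALPHA_FREQ = 10.0  # Hz
THETA_FREQ = 6.0   # Hz
PINK_RMS = 2.0     # µV, exact per-channel RMS of the 1/f background

#: Alpha-band amplitude (µV) per region: strongest over occipital cortex.
_ALPHA_AMP = {"occipital": 8.0, "parietal": 4.0}
_ALPHA_DEFAULT = 1.5
#: Theta-band amplitude (µV) per region: the workload-sensitive component.
_THETA_AMP = {"prefrontal": 3.0, "frontal": 3.0, "central": 2.5, "parietal": 2.0}
_THETA_DEFAULT = 0.5

#: Truncation bounds of the completion-rate distribution (problems/min).
X_LOW, X_HIGH = 1.0, 40.0


def _region_of(channel: str) -> str:
    for region, members in REGIONS.items():
        if channel in members:
            return region
    raise KeyError(channel)


def _alpha_amp(channel: str) -> float:
    return _ALPHA_AMP.get(_region_of(channel), _ALPHA_DEFAULT)


def _theta_amp(channel: str) -> float:
    return _THETA_AMP.get(_region_of(channel), _THETA_DEFAULT)


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level generation parameters.

    ``score_params`` holds the (mean, SD) of the problem-completion rate X
    for the low-skill and high-skill draw, matching the study cohort's
    group statistics. ``effect_bad``/``effect_good`` are the dimensionless
    task-power multipliers entering the load factor ``1 + effect*(1-skill)``.
    Segment lengths default to 30 s per condition — long enough for six
    stable modes per channel — with full-length (180 s / 60 s) generation
    available by configuration.
    """

    n_bad: int = 10
    n_good: int = 26
    fs: float = 500.0
    rest_duration: float = 30.0
    task_duration: float = 30.0
    n_channels: int = 19
    effect_bad: float = 2.0
    effect_good: float = 0.2
    score_params: tuple[tuple[float, float], tuple[float, float]] = ((6.2, 3.37), (21.99, 7.46))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bad + self.n_good < 2:
            raise InvalidConfigError("cohort needs at least 2 subjects")
        if self.n_bad < 0 or self.n_good < 0:
            raise InvalidConfigError("group sizes must be non-negative")
        if self.rest_duration <= 0 or self.task_duration <= 0:
            raise InvalidConfigError("segment durations must be positive")
        if self.fs <= 0:
            raise InvalidConfigError("sampling rate must be positive")
        if self.n_channels != len(CHANNELS):
            raise InvalidConfigError(f"montage has {len(CHANNELS)} channels")
        if self.effect_bad < 0 or self.effect_good < 0:
            raise InvalidConfigError("effect multipliers must be non-negative")
        for mu, sd in self.score_params:
            if sd < 0:
                raise InvalidConfigError(f"score SD must be non-negative, got {sd}")


@dataclass(frozen=True)
class SkillProfile:
    """A subject's task skill on [0, 1] and its observable completion rate."""

    subject_id: str
    skill: float
    X: float
    group_label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.skill <= 1.0:
            raise InvalidConfigError(f"skill must lie in [0, 1], got {self.skill}")
        if self.X <= 0:
            raise InvalidConfigError(f"completion rate must be > 0, got {self.X}")
        expected = "BAD" if self.X <= PERFORMANCE_THRESHOLD else "GOOD"
        if self.group_label != expected:
            raise InvalidConfigError(
                f"group label {self.group_label!r} inconsistent with X={self.X}"
            )


def skill_from_rate(X: float) -> float:
    """Map a completion rate onto [0, 1] over the truncation range."""
    return float(np.clip((X - X_LOW) / (X_HIGH - X_LOW), 0.0, 1.0))


def load_factor(effect: float, skill: float) -> float:
    """Cognitive-load multiplier ``1 + effect * (1 - skill)``."""
    return 1.0 + effect * (1.0 - skill)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f noise with exact unit RMS (spectrally shaped white noise)."""
    freqs = np.fft.rfftfreq(n)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])      # amplitude ~ f^{-1/2}  =>  power ~ 1/f
    spectrum = shape * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spectrum, n=n)
    x -= x.mean()
    return x / np.sqrt(np.mean(x**2))


def _band_amplitudes(channel: str, condition: str, effect: float,
                     skill: float) -> tuple[float, float]:
    """(alpha, theta) amplitudes in µV for one channel and condition."""
    alpha = _alpha_amp(channel)
    theta = _theta_amp(channel)
    if condition == "task":
        theta = theta * load_factor(effect, skill)
    return alpha, theta


def expected_channel_power(channel: str, condition: str, effect: float,
                           skill: float) -> float:
    """Closed-form expected signal power (µV²) of the generator's model.

    Sum of the exactly normalized pink-noise power and A²/2 for each
    sinusoidal component (phases are independent, cross terms vanish in
    expectation).
    """
    alpha, theta = _band_amplitudes(channel, condition, effect, skill)
    return PINK_RMS**2 + alpha**2 / 2.0 + theta**2 / 2.0


def generate_subject_recording(profile: SkillProfile, condition: str,
                               cfg: SyntheticConfig, seed: int) -> Recording:
    """Generate one subject-condition recording.

    Deterministic in ``(profile, condition, cfg, seed)``: the RNG stream is
    keyed on the seed and the condition only, so rest and task segments of
    one subject are independent draws.
    """
    if condition not in ("rest", "task"):
        raise InvalidConfigError(f"condition must be 'rest' or 'task', got {condition!r}")
    cfg = cfg if isinstance(cfg, SyntheticConfig) else SyntheticConfig(**cfg)
    duration = cfg.rest_duration if condition == "rest" else cfg.task_duration
    n = int(round(duration * cfg.fs))
    if n < 8:
        raise InvalidConfigError("segment too short at this sampling rate")
    effect = cfg.effect_bad if profile.group_label == "BAD" else cfg.effect_good
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0 if condition == "rest" else 1])
    )
    t = np.arange(n) / cfg.fs
    data = np.empty((len(CHANNELS), n))
    for c, channel in enumerate(CHANNELS):
        alpha, theta = _band_amplitudes(channel, condition, effect, profile.skill)
        phi_a, phi_t = rng.uniform(0.0, 2.0 * np.pi, size=2)
        data[c] = (
            PINK_RMS * _pink_noise(n, rng)
            + alpha * np.sin(2.0 * np.pi * ALPHA_FREQ * t + phi_a)
            + theta * np.sin(2.0 * np.pi * THETA_FREQ * t + phi_t)
        )
    return Recording(subject_id=profile.subject_id, condition=condition,
                     fs=cfg.fs, data=data)


def _draw_scores(cfg: SyntheticConfig, rng: np.random.Generator) -> list[SkillProfile]:
    """Draw per-subject completion rates and derive skill profiles.

    Rates come from truncated normals on [1, 40] with the configured
    group-wise (mean, SD), rounded to 2 decimals like the published
    manifests. Group labels are then re-derived from the threshold rule,
    and low/high draws are interleaved over subject ids by a seeded
    shuffle so "first N subjects" splits mix both groups.
    """
    draws = []
    for (mu, sd), count in zip(cfg.score_params, (cfg.n_bad, cfg.n_good)):
        if count == 0:
            continue
        if sd == 0:
            xs = np.full(count, mu)
        else:
            a, b = (X_LOW - mu) / sd, (X_HIGH - mu) / sd
            xs = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=count, random_state=rng)
        draws.extend(np.round(xs, 2))
    draws = np.array(draws)
    rng.shuffle(draws)
    width = max(2, len(str(draws.size)))
    profiles = []
    for i, x in enumerate(draws):
        x = float(max(x, X_LOW))   # rounding guard at the lower bound
        profiles.append(SkillProfile(
            subject_id=f"Subject{i + 1:0{width}d}",
            skill=skill_from_rate(x),
            X=x,
            group_label="BAD" if x <= PERFORMANCE_THRESHOLD else "GOOD",
        ))
    return profiles


def generate_profiles(cfg: SyntheticConfig) -> list[SkillProfile]:
    """Draw the cohort's skill profiles (completion rates, no signals).

    Deterministic in ``cfg``; :func:`generate_cohort` builds its recordings
    from exactly these profiles.
    """
    cfg = cfg if isinstance(cfg, SyntheticConfig) else SyntheticConfig(**cfg)
    score_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 917]))
    return _draw_scores(cfg, score_rng)


def generate_cohort(cfg: SyntheticConfig) -> tuple[list[Recording], list[SubjectMeta]]:
    """Generate the full cohort: one rest and one task recording per subject.

    Returns recordings ordered (subject, rest), (subject, task), ... and the
    manifest sorted by subject id. Deterministic in ``cfg`` (including its
    seed).
    """
    cfg = cfg if isinstance(cfg, SyntheticConfig) else SyntheticConfig(**cfg)
    profiles = generate_profiles(cfg)
    recordings: list[Recording] = []
    metas: list[SubjectMeta] = []
    for i, profile in enumerate(profiles):
        subject_seed = int(
            np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, i]).generate_state(1)[0]
        ) & 0x7FFFFFFF
        for condition in ("rest", "task"):
            recordings.append(generate_subject_recording(profile, condition, cfg, subject_seed))
        metas.append(SubjectMeta(subject_id=profile.subject_id, X=profile.X))
    return recordings, metas


def write_cohort(recordings: list[Recording], metas: list[SubjectMeta], outdir) -> list[Path]:
    """Write one EDF per subject-condition plus ``manifest.csv``; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        path = outdir / f"{rec.subject_id}_{rec.condition}.edf"
        write_edf(rec, path)
        paths.append(path)
    write_manifest(metas, outdir / "manifest.csv")
    return paths


def full_length_config(cfg: SyntheticConfig) -> SyntheticConfig:
    """The same cohort configuration at the recorded segment lengths (180 s rest, 60 s task)."""
    return replace(cfg, rest_duration=180.0, task_duration=60.0)
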
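"""Channel power, grand averages, scalp topography and image similarity.

The topographic pipeline mirrors the figure-level analysis of the study
design: per-subject recordings are normalized by a shared per-channel
scale (so the rest/task power contrast survives), per-channel mean squared
amplitude is grand-averaged within performance groups, interpolated over a
schematic head disc by a thin-plate radial basis function, and rest-vs-task
map pairs are compared with a structural-similarity image index (ISI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator
from skimage.metrics import structural_similarity

from .errors import DegenerateChannelError, ValidationError
from .io import Recording
from .montage import CHANNELS, electrode_positions

__all__ = [
    "ChannelPower",
    "Topomap",
    "normalize_recording_pair",
    "channel_power",
    "grand_average",
    "render_topomap",
    "image_similarity",
]


@dataclass
class ChannelPower:
    """Per-channel mean signal power (µV²) of one subject-condition."""

    subject_id: str
    condition: str
    power: np.ndarray

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (len(CHANNELS),):
            raise ValidationError(f"expected {len(CHANNELS)} channel powers, got {self.power.shape}")
        if not np.all(np.isfinite(self.power)) or np.any(self.power < 0):
            raise ValidationError("channel powers must be finite and non-negative")


@dataclass
class Topomap:
    """Interpolated power field over the unit head disc.

    ``grid`` is a masked (grid_n, grid_n) array; entries outside the head
    circle are masked. ``extent`` is (xmin, xmax, ymin, ymax) for plotting.
    """

    grid: np.ma.MaskedArray
    coords: np.ndarray
    values: np.ndarray
    extent: tuple[float, float, float, float] = (-1.0, 1.0, -1.0, 1.0)
    group: str = ""
    condition: str = ""


def normalize_recording_pair(rest: Recording, task: Recording) -> tuple[Recording, Recording]:
    """Rescale both conditions of one subject by a shared per-channel factor.

    Each channel of both segments is divided by that channel's standard
    deviation over the *concatenated* rest+task samples. A per-condition
    scale would erase the rest/task power contrast; the shared scale
    preserves the power ratio exactly while removing inter-subject
    amplitude differences.
    """
    if rest.subject_id != task.subject_id:
        raise ValidationError("rest and task recordings belong to different subjects")
    scale = np.empty(len(CHANNELS))
    for c, label in enumerate(CHANNELS):
        sd = np.std(np.concatenate([rest.data[c], task.data[c]]))
        if sd == 0:
            raise DegenerateChannelError(f"channel {label} has zero variance")
        scale[c] = sd
    norm = scale[:, None]
    rest_n = Recording(subject_id=rest.subject_id, condition="rest", fs=rest.fs,
                       data=rest.data / norm, channel_labels=rest.channel_labels)
    task_n = Recording(subject_id=task.subject_id, condition="task", fs=task.fs,
                       data=task.data / norm, channel_labels=task.channel_labels)
    return rest_n, task_n


def channel_power(rec: Recording) -> ChannelPower:
    """Mean squared amplitude per channel (µV², or dimensionless if normalized)."""
    if rec.n_samples == 0:
        raise ValidationError("recording has no samples")
    return ChannelPower(subject_id=rec.subject_id, condition=rec.condition,
                        power=np.mean(rec.data**2, axis=1))


def grand_average(powers: list[ChannelPower],
                  groups: dict[str, str]) -> dict[tuple[str, str], np.ndarray]:
    """Mean channel power per (group, condition) over subjects.

    ``groups`` maps every subject id appearing in ``powers`` to its
    performance group. Raises on subjects without a group or on a group
    without members.
    """
    buckets: dict[tuple[str, str], list[np.ndarray]] = {}
    for p in powers:
        if p.subject_id not in groups:
            raise ValidationError(f"subject {p.subject_id} has no group assignment")
        buckets.setdefault((groups[p.subject_id], p.condition), []).append(p.power)
    if not buckets:
        raise ValidationError("no channel powers supplied")
    return {key: np.mean(np.vstack(vals), axis=0) for key, vals in buckets.items()}


def render_topomap(values, coords: np.ndarray | None = None, grid_n: int = 64,
                   group: str = "", condition: str = "") -> Topomap:
    """Interpolate 19 electrode values onto a grid_n x grid_n head-disc grid.

    Thin-plate-spline radial basis interpolation, exact at the electrodes;
    grid nodes outside the unit head circle are masked, and no values are
    extrapolated beyond it.
    """
    values = np.asarray(values, dtype=float)
    coords = electrode_positions() if coords is None else np.asarray(coords, dtype=float)
    if values.shape != (coords.shape[0],):
        raise ValidationError(
            f"{values.shape[0]} values for {coords.shape[0]} electrode coordinates"
        )
    interp = RBFInterpolator(coords, values, kernel="thin_plate_spline")
    axis = np.linspace(-1.0, 1.0, grid_n)
    gx, gy = np.meshgrid(axis, axis)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    inside = np.linalg.norm(nodes, axis=1) <= 1.0
    field = np.full(nodes.shape[0], np.nan)
    field[inside] = interp(nodes[inside])
    grid = np.ma.masked_invalid(field.reshape(grid_n, grid_n))
    return Topomap(grid=grid, coords=coords, values=values,
                   group=group, condition=condition)


def image_similarity(a: Topomap, b: Topomap) -> float:
    """Image similarity index of two topomaps: mean SSIM over the head disc.

    The windowed structural-similarity map (standard constants) is computed
    on the raw fields with the data range set by the pair's joint magnitude,
    ``max(0, a, b) - min(0, a, b)``, and averaged over the unmasked disc
    (masked cells are filled with each field's disc mean so boundary windows
    see no artificial edge). Two near-identical fields therefore score near
    1 regardless of how small their internal variation is — rescaling each
    field to full contrast first would instead amplify Monte-Carlo noise
    and can invert the ordering of interest. Reflexive (ISI(a, a) = 1),
    symmetric, and contained in [-1, 1].
    """
    if a.grid.shape != b.grid.shape:
        raise ValidationError(f"grid shapes differ: {a.grid.shape} vs {b.grid.shape}")
    if not np.array_equal(np.ma.getmaskarray(a.grid), np.ma.getmaskarray(b.grid)):
        raise ValidationError("topomaps have different head masks")
    fa = a.grid.filled(float(a.grid.mean()))
    fb = b.grid.filled(float(b.grid.mean()))
    rng = max(float(a.grid.max()), float(b.grid.max()), 0.0) - min(
        float(a.grid.min()), float(b.grid.min()), 0.0)
    if rng == 0.0:
        return 1.0
    _, smap = structural_similarity(fa, fb, data_range=rng, full=True)
    inside = ~np.ma.getmaskarray(a.grid)
    return float(np.mean(smap[inside]))
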
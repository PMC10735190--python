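"""Canonical 19-channel 10/20 montage: ordering, aliases and 2-D layout.

Every stage of the pipeline (EDF reading, the 570-value feature layout,
channel-power bars, topography) indexes channels in the single order
defined by :data:`CHANNELS`, so this module is the one source of truth.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

#: Canonical channel order: prefrontal, frontal, central, parietal,
#: occipital, temporal — the classic 19-site recording montage.
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "Fz", "F7", "F8",
    "C3", "C4", "Cz", "P3", "P4", "Pz",
    "O1", "O2", "T3", "T4", "T5", "T6",
)

#: Modern 10/10 names for the four classic temporal sites. Applied only on
#: explicit opt-in when reading files (older EEG systems use the classic
#: labels; newer exports use the 10/10 ones).
ALIASES: dict[str, tuple[str, ...]] = {
    "T3": ("T7",),
    "T4": ("T8",),
    "T5": ("P7",),
    "T6": ("P8",),
}

#: Channel groups used by the synthetic signal model and power summaries.
REGIONS: dict[str, tuple[str, ...]] = {
    "prefrontal": ("Fp1", "Fp2"),
    "frontal": ("F3", "F4", "Fz", "F7", "F8"),
    "central": ("C3", "C4", "Cz"),
    "parietal": ("P3", "P4", "Pz"),
    "occipital": ("O1", "O2"),
    "temporal": ("T3", "T4", "T5", "T6"),
}

#: Frontal-lobe channels (prefrontal + frontal) used in task-vs-rest
#: power contrasts.
FRONTAL_CHANNELS: tuple[str, ...] = REGIONS["prefrontal"] + REGIONS["frontal"]


def channel_index(label: str) -> int:
    """Position of ``label`` in the canonical order."""
    return CHANNELS.index(label)


def electrode_positions() -> np.ndarray:
    """(19, 2) array of schematic x/y electrode positions on the unit head disc.

    x grows to the subject's right, y to the front; the head circle has
    radius 1 and the outermost electrodes sit at radius 0.9. Rows follow
    :data:`CHANNELS`.
    """
    with resources.files("cogload.data").joinpath("montage_1020_2d.csv").open() as fh:
        df = pd.read_csv(fh)
    df = df.set_index("label").loc[list(CHANNELS)]
    return df[["x", "y"]].to_numpy(dtype=float)
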
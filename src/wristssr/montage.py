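"""Extended 10/20 montage used by the recording setup.

The recording cap is a 64-channel subset of the extended 10/20 system.
Odd-numbered electrodes sit over the left hemisphere, even-numbered over the
right, ``z`` electrodes on the midline.  The laterality analysis uses two
mirror-symmetric 15-electrode sets over the sensorimotor cortices.
"""

from __future__ import annotations

import re
import warnings
from functools import lru_cache

import numpy as np
import pandas as pd

#: The 64 electrode labels of the recording montage.
STANDARD_64 = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F9", "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8", "F10",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)

#: Left-hemisphere sensorimotor set used for the laterality index.
LEFT_SENSORIMOTOR = (
    "F1", "F3", "F5", "FC1", "FC3", "FC5",
    "C1", "C3", "C5", "CP1", "CP3", "CP5",
    "P1", "P3", "P5",
)

#: Even-numbered counterparts over the right hemisphere.
RIGHT_SENSORIMOTOR = (
    "F2", "F4", "F6", "FC2", "FC4", "FC6",
    "C2", "C4", "C6", "CP2", "CP4", "CP6",
    "P2", "P4", "P6",
)

#: Frontal-pole electrodes used to recognise blink/eye-movement components.
FRONTAL_EYE_SET = ("Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8")

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(z|\d+)$")


def mirror_label(label: str) -> str:
    """Return the sagittal mirror of an electrode label (C3 -> C4, Fz -> Fz)."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"cannot parse electrode label {label!r}")
    prefix, suffix = m.groups()
    if suffix == "z":
        return label
    n = int(suffix)
    return f"{prefix}{n + 1 if n % 2 == 1 else n - 1}"


def mirror_pairs(labels) -> dict[str, str]:
    """Map every label in ``labels`` to its mirror, requiring the mirror to exist.

    Midline labels map to themselves.  Raises naming the electrode if a lateral
    label has no counterpart in ``labels``.
    """
    labels = list(labels)
    out = {}
    for lab in labels:
        mir = mirror_label(lab)
        if mir not in labels:
            raise ValueError(f"electrode {lab} has no mirror counterpart {mir} in montage")
        out[lab] = mir
    return out


@lru_cache(maxsize=4)
def electrode_positions(labels: tuple[str, ...] = STANDARD_64) -> pd.DataFrame:
    """2-D scalp positions (azimuthal projection) for ``labels``.

    Coordinates come from mne's bundled standard 10/20 montage; the 3-D points
    are projected azimuthally so Euclidean distance in the plane approximates
    along-scalp distance.  Units are radians of arc from the vertex; +x right,
    +y anterior.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            mont = mne.channels.make_standard_montage("colin27_1020")
        except ValueError:  # older montage name
            mont = mne.channels.make_standard_montage("standard_1020")
    pos3 = mont.get_positions()["ch_pos"]
    rows = []
    for lab in labels:
        x, y, z = pos3[lab]
        r = np.sqrt(x * x + y * y + z * z)
        theta = np.arccos(np.clip(z / r, -1.0, 1.0))  # arc from vertex
        rho = np.hypot(x, y)
        if rho < 1e-12:
            u = v = 0.0
        else:
            u, v = theta * x / rho, theta * y / rho
        rows.append((lab, u, v))
    pos = pd.DataFrame(rows, columns=["label", "x", "y"]).set_index("label")
    # enforce exact sagittal symmetry: average each electrode with its mirror
    # (digitized head shapes are slightly asymmetric, the 10/20 scheme is not)
    sym = pos.copy()
    for lab in pos.index:
        mir = mirror_label(lab)
        if mir in pos.index:
            sx = 0.5 * (abs(pos.at[lab, "x"]) + abs(pos.at[mir, "x"]))
            sym.at[lab, "x"] = np.copysign(sx, pos.at[lab, "x"]) if lab != mir else 0.0
            sym.at[lab, "y"] = 0.5 * (pos.at[lab, "y"] + pos.at[mir, "y"])
    return sym


def sensorimotor_sets(stimulated_side: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """(contralateral, ipsilateral) electrode sets for a stimulated wrist.

    Sensory pathways cross: a manipulated right wrist projects to the left
    hemisphere (odd labels), so for ``stimulated_side="right"`` the
    contralateral set is the odd-numbered one.
    """
    side = stimulated_side.lower()
    if side == "right":
        return LEFT_SENSORIMOTOR, RIGHT_SENSORIMOTOR
    if side == "left":
        return RIGHT_SENSORIMOTOR, LEFT_SENSORIMOTOR
    raise ValueError(f"stimulated_side must be 'left' or 'right', got {stimulated_side!r}")
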
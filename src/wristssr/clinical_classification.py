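"""Sensory-impairment grouping from EmNSA-UE subscores.

The Erasmus modification of the Nottingham Sensory Assessment for the upper
extremity scores five subtests — light touch (LT), pressure (P), pinprick
(PP), discrimination (D) and proprioception (PR) — each 0 (fully impaired),
1 (some impairment) or 2 (no impairment).  Discrimination and proprioception
are skipped when tactile subtests already show impairment; a skipped subtest
is treated as reduced here, the only convention that reproduces the study
cohort's printed group labels.

Grouping rule: no reduced subtest -> ``none``; one or two -> ``mild``; more
than two -> ``severe``.  Motor severity is flagged from the Fugl-Meyer
upper-extremity score (FMA-UE < 40).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd

#: EmNSA-UE subtest keys, in the order they are reported.
SUBTESTS = ("lt", "p", "pp", "d", "pr")

#: Valid group labels, from most to least impaired.
SENSORY_GROUPS = ("severe", "mild", "none")

FMA_UE_MAX = 66
SEVERE_MOTOR_THRESHOLD = 40


@dataclass(frozen=True)
class ClinicalRecord:
    """One participant's clinical profile.

    ``emnsa_subscores`` maps subtest key to 0/1/2 or ``None`` when the test
    was not administered (upstream tactile impairment).
    """

    id: int
    emnsa_subscores: dict[str, Optional[int]]
    fma_ue: int
    months_post_stroke: int
    age_years: int
    gender: str
    affected_side: str
    handedness: str
    sensory_group: str

    def __post_init__(self):
        for key, val in self.emnsa_subscores.items():
            if key not in SUBTESTS:
                raise ValueError(f"unknown EmNSA subtest {key!r}")
            if val is not None and val not in (0, 1, 2):
                raise ValueError(f"subscore {key}={val!r} outside {{0,1,2}}")
        if not 0 <= self.fma_ue <= FMA_UE_MAX:
            raise ValueError(f"fma_ue={self.fma_ue} outside [0, {FMA_UE_MAX}]")
        if self.sensory_group not in SENSORY_GROUPS:
            raise ValueError(f"unknown sensory group {self.sensory_group!r}")


def classify_sensory_impairment(subscores) -> str:
    """Group label from EmNSA-UE subscores.

    ``subscores`` is a mapping over :data:`SUBTESTS` or a sequence in that
    order; entries may be ``None`` (not assessed, counted as reduced).
    """
    if isinstance(subscores, dict):
        values = [subscores.get(k) for k in SUBTESTS]
    else:
        values = list(subscores)
    if len(values) == 0 or all(v is None for v in values):
        raise ValueError("at least one assessed subscore is required")
    n_reduced = sum(1 for v in values if v is None or v < 2)
    if n_reduced == 0:
        return "none"
    if n_reduced <= 2:
        return "mild"
    return "severe"


def motor_severity_flag(fma_ue: int) -> bool:
    """True when the participant has severe motor impairment (FMA-UE < 40)."""
    if not 0 <= fma_ue <= FMA_UE_MAX:
        raise ValueError(f"fma_ue={fma_ue} outside [0, {FMA_UE_MAX}]")
    return fma_ue < SEVERE_MOTOR_THRESHOLD


def load_study_cohort() -> list[ClinicalRecord]:
    """The 30-participant stroke cohort shipped with the package."""
    with resources.files("wristssr.data").joinpath("study_cohort.csv").open() as fh:
        df = pd.read_csv(fh, keep_default_na=False, na_values=["NA"])
    records = []
    for _, row in df.iterrows():
        subs = {
            k: (None if pd.isna(row[k]) else int(row[k])) for k in SUBTESTS
        }
        records.append(
            ClinicalRecord(
                id=int(row["id"]),
                emnsa_subscores=subs,
                fma_ue=int(row["fma_ue"]),
                months_post_stroke=int(row["months_post_stroke"]),
                age_years=int(row["age_years"]),
                gender=str(row["gender"]),
                affected_side={"L": "left", "R": "right"}[row["affected_side"]],
                handedness={"L": "left", "R": "right"}[row["handedness"]],
                sensory_group=str(row["sensory_group"]),
            )
        )
    return records


def group_counts(records) -> dict[str, int]:
    """Count records per derived sensory group (classification re-applied)."""
    counts = {g: 0 for g in SENSORY_GROUPS}
    for rec in records:
        counts[classify_sensory_impairment(rec.emnsa_subscores)] += 1
    return counts
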
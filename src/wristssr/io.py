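"""Serialization of sessions and period stacks.

Recordings travel as single-file NPZ containers (arrays) with a JSON header
embedded for labels and metadata; torque can additionally be exported as a
CSV sidecar.  This is the compact array format used throughout the pipeline
and the test-suite.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocessing import PeriodStack
from .synthetic_data import SessionRecording


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()
                if not isinstance(v, np.ndarray)}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_session(recording: SessionRecording, path) -> None:
    header = {
        "electrode_labels": list(recording.electrode_labels),
        "sample_rate_hz": recording.sample_rate_hz,
        "trial_boundaries": [list(b) for b in recording.trial_boundaries],
        "task": recording.task,
        "target_torque_nm": recording.target_torque_nm,
        "metadata": _jsonable(recording.metadata),
    }
    np.savez_compressed(path, eeg=recording.eeg, torque=recording.torque,
                        emg=recording.emg,
                        header=np.array(json.dumps(header)))


def load_session(path) -> SessionRecording:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        return SessionRecording(
            eeg=z["eeg"], torque=z["torque"], emg=z["emg"],
            electrode_labels=tuple(header["electrode_labels"]),
            sample_rate_hz=header["sample_rate_hz"],
            trial_boundaries=tuple(tuple(b) for b in header["trial_boundaries"]),
            task=header["task"],
            target_torque_nm=header["target_torque_nm"],
            metadata=header["metadata"],
        )


def save_stack(stack: PeriodStack, path) -> None:
    header = {
        "electrode_labels": list(stack.electrode_labels),
        "sample_rate_hz": stack.sample_rate_hz,
        "period_s": stack.period_s,
        "task": stack.task,
    }
    np.savez_compressed(path, data=stack.data,
                        kept_period_index=stack.kept_period_index,
                        period_start_sample=stack.period_start_sample,
                        header=np.array(json.dumps(header)))


def load_stack(path) -> PeriodStack:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        return PeriodStack(
            data=z["data"],
            electrode_labels=tuple(header["electrode_labels"]),
            sample_rate_hz=header["sample_rate_hz"],
            period_s=header["period_s"],
            task=header["task"],
            kept_period_index=z["kept_period_index"],
            period_start_sample=z["period_start_sample"],
        )


def export_torque_csv(recording: SessionRecording, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# wrist torque [Nm], sample_rate_hz={recording.sample_rate_hz}\n")
        fh.write("torque_nm\n")
        np.savetxt(fh, recording.torque, fmt="%.9e")
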
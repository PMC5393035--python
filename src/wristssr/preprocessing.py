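"""Filtering, channel hygiene, re-referencing, and period bookkeeping.

EEG trials are band-pass filtered 0.8–120 Hz with narrow band-stops around
the 50 Hz line frequency and its 100 Hz harmonic (4th-order Butterworth,
applied forward-backward for zero phase), bad channels are dropped, and the
remainder re-referenced to the common average.  Each 12.5 s trial is split
into ten 1.25 s disturbance periods; the first two are discarded as motor
transients.  Active-task periods whose mean wrist torque falls outside ±50%
of the target are rejected, and an active task with fewer than 80 surviving
periods is excluded from analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace, field

import numpy as np
from scipy import signal as sps

from .signal_design import MultisineSpec
from .synthetic_data import SessionRecording

DEFAULT_BAND_HZ = (0.8, 120.0)
DEFAULT_NOTCHES_HZ = (50.0, 100.0)
DEFAULT_NOTCH_HALFWIDTH_HZ = 1.0
DEFAULT_DISCARD_FIRST = 2
DEFAULT_TORQUE_TOLERANCE = 0.5
DEFAULT_MIN_PERIODS = 80


@dataclass
class PeriodStack:
    """Electrode x period x sample array of period-locked EEG (µV)."""

    data: np.ndarray
    electrode_labels: tuple[str, ...]
    sample_rate_hz: float
    period_s: float
    task: str
    kept_period_index: np.ndarray          # global period number within session
    period_start_sample: np.ndarray        # session sample of each kept period

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("data must be electrode x period x sample")
        if len(self.electrode_labels) != len(set(self.electrode_labels)):
            raise ValueError("electrode labels must be unique")
        n_expected = self.sample_rate_hz * self.period_s
        if abs(self.data.shape[2] - n_expected) > 1e-9:
            raise ValueError("samples per period must equal sample_rate * period_s")

    @property
    def P(self) -> int:
        return self.data.shape[1]

    @property
    def N(self) -> int:
        return self.data.shape[2]


def _design_sos(sample_rate_hz, band, notches, notch_halfwidth, order=4):
    nyq = sample_rate_hz / 2.0
    if nyq <= band[1]:
        raise ValueError(f"sample rate {sample_rate_hz} too low for a "
                         f"{band[1]} Hz band edge")
    sections = [sps.butter(order, band, btype="bandpass", fs=sample_rate_hz,
                           output="sos")]
    for f0 in notches:
        sections.append(sps.butter(order, (f0 - notch_halfwidth, f0 + notch_halfwidth),
                                   btype="bandstop", fs=sample_rate_hz, output="sos"))
    return np.vstack(sections)


def apply_filters(
    recording: SessionRecording,
    band_hz=DEFAULT_BAND_HZ,
    notches_hz=DEFAULT_NOTCHES_HZ,
    notch_halfwidth_hz=DEFAULT_NOTCH_HALFWIDTH_HZ,
    order: int = 4,
) -> SessionRecording:
    """Zero-phase band-pass and band-stop filtering of the EEG, per trial.

    Filters run forward-backward (``sosfiltfilt``) so the group delay is zero
    and the period grid is preserved.  Trials shorter than the filter warm-up
    are rejected.
    """
    sos = _design_sos(recording.sample_rate_hz, band_hz, notches_hz,
                      notch_halfwidth_hz, order)
    padlen = 3 * (2 * sos.shape[0] + 1)
    eeg = recording.eeg.copy()
    for (s0, s1) in recording.trial_boundaries:
        if s1 - s0 <= padlen:
            raise ValueError(
                f"trial [{s0}, {s1}) shorter than the filter warm-up ({padlen} samples)")
        eeg[:, s0:s1] = sps.sosfiltfilt(sos, eeg[:, s0:s1], axis=1)
    return replace(recording, eeg=eeg)


def exclude_bad_channels(recording: SessionRecording, bad="auto",
                         mad_threshold: float = 5.0) -> SessionRecording:
    """Drop bad EEG channels before re-referencing.

    ``bad`` is a list of electrode labels, or ``"auto"`` to flag channels
    whose broadband variance is a robust outlier (log-variance more than
    ``mad_threshold`` scaled MADs from the median).
    """
    labels = list(recording.electrode_labels)
    if bad == "auto":
        flagged = auto_bad_channels(recording, mad_threshold)
    else:
        unknown = [b for b in bad if b not in labels]
        if unknown:
            raise ValueError(f"bad channels not in montage: {unknown}")
        flagged = list(bad)
    keep = [i for i, lab in enumerate(labels) if lab not in flagged]
    if not keep:
        raise ValueError("all channels flagged as bad")
    meta = dict(recording.metadata)
    meta["bad_channels"] = sorted(flagged)
    return replace(recording, eeg=recording.eeg[keep],
                   electrode_labels=tuple(labels[i] for i in keep), metadata=meta)


def auto_bad_channels(recording: SessionRecording, mad_threshold: float = 5.0) -> list[str]:
    """Channels with outlying broadband log-variance (robust MAD rule)."""
    logv = np.log(np.var(recording.eeg, axis=1) + 1e-30)
    med = np.median(logv)
    mad = np.median(np.abs(logv - med)) * 1.4826
    if mad == 0:
        return []
    flagged = np.abs(logv - med) > mad_threshold * mad
    return [lab for lab, f in zip(recording.electrode_labels, flagged) if f]


def rereference_common_average(recording: SessionRecording) -> SessionRecording:
    """Subtract the instantaneous mean over retained EEG channels."""
    if recording.n_channels < 2:
        raise ValueError("common-average reference needs at least two channels")
    eeg = recording.eeg - recording.eeg.mean(axis=0, keepdims=True)
    return replace(recording, eeg=eeg)


def segment_periods(recording: SessionRecording, spec: MultisineSpec,
                    discard_first: int = DEFAULT_DISCARD_FIRST) -> PeriodStack:
    """Split trials into disturbance periods, dropping leading transients.

    Each trial must span an integer number of periods; each contributes its
    periods beyond the first ``discard_first``, ordered by trial then period.
    """
    n_per_f = recording.sample_rate_hz * spec.period_s
    n_per = int(round(n_per_f))
    if abs(n_per_f - n_per) > 1e-9:
        raise ValueError("sample_rate * period_s is not an integer")
    chunks, kept_idx, starts = [], [], []
    global_period = 0
    for (s0, s1) in recording.trial_boundaries:
        n_in_trial = (s1 - s0) / n_per
        if abs(n_in_trial - round(n_in_trial)) > 1e-9:
            raise ValueError(f"trial [{s0}, {s1}) is not an integer number of periods")
        n_in_trial = int(round(n_in_trial))
        if discard_first >= n_in_trial:
            raise ValueError("discard_first leaves no periods in a trial")
        trial = recording.eeg[:, s0:s1].reshape(recording.n_channels, n_in_trial, n_per)
        chunks.append(trial[:, discard_first:, :])
        for p in range(discard_first, n_in_trial):
            kept_idx.append(global_period + p)
            starts.append(s0 + p * n_per)
        global_period += n_in_trial
    data = np.concatenate(chunks, axis=1)
    return PeriodStack(
        data=data, electrode_labels=tuple(recording.electrode_labels),
        sample_rate_hz=recording.sample_rate_hz, period_s=spec.period_s,
        task=recording.task, kept_period_index=np.asarray(kept_idx),
        period_start_sample=np.asarray(starts))


def reject_periods_by_torque(
    stack: PeriodStack,
    torque: np.ndarray,
    target_torque_nm: float,
    tolerance_fraction: float = DEFAULT_TORQUE_TOLERANCE,
) -> PeriodStack:
    """Keep active-task periods whose mean torque is within ±50% of target.

    The interval is closed at both ends: a mean torque of exactly
    ``target*(1±tolerance)`` is kept.
    """
    if stack.task != "active":
        raise ValueError("torque-based rejection applies to the active task only")
    if target_torque_nm <= 0:
        raise ValueError("target torque must be positive")
    if tolerance_fraction < 0:
        raise ValueError("tolerance_fraction must be non-negative")
    lo = target_torque_nm * (1.0 - tolerance_fraction)
    hi = target_torque_nm * (1.0 + tolerance_fraction)
    means = np.array([
        torque[s:s + stack.N].mean() for s in stack.period_start_sample])
    keep = (means >= lo) & (means <= hi)
    return replace(stack, data=stack.data[:, keep, :],
                   kept_period_index=stack.kept_period_index[keep],
                   period_start_sample=stack.period_start_sample[keep])


def check_min_periods(stack: PeriodStack, minimum: int = DEFAULT_MIN_PERIODS) -> bool:
    """False when fewer than ``minimum`` periods survive (task excluded)."""
    return stack.P >= minimum
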
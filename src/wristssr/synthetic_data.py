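"""Synthetic experimental sessions with known ground truth.

The generator emulates the study's recordings: a 64-channel EEG in which a
period-locked evoked response — energy at the stimulated multisine lines plus
even-harmonic energy, reflecting the nonlinear but periodic nature of the
true response — is embedded in spatially correlated 1/f background activity
with an alpha (≈10 Hz) component, together with a wrist-torque trace that
passes or violates the ±50% task criterion per period, quiescent/elevated
forearm EMG, and stereotyped blink and muscle artifacts.

Ground truth (per-electrode response gain, the active/passive power ratio,
group membership) is retained so downstream estimators can be checked by
parameter recovery.  Group gain defaults (control 1.0, none 0.9, mild 0.6,
severe 0.05) are calibration constants that qualitatively reproduce the
study's group ordering; the study reports no quantitative per-group SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .clinical_classification import ClinicalRecord, SUBTESTS
from .montage import (FRONTAL_EYE_SET, STANDARD_64, electrode_positions,
                      mirror_label)
from .signal_design import MultisineSpec, build_default_spec

#: Default response gain per sensory group (free calibration constants).
GROUP_GAINS = {"control": 1.0, "none": 0.9, "mild": 0.6, "severe": 0.05}

#: Default active/passive SSR power ratio per group; the mild group's
#: reduction under load mirrors the study's qualitative finding.
GROUP_ACTIVE_POWER_RATIO = {"control": 1.0, "none": 1.0, "mild": 0.5, "severe": 1.0}

DEFAULT_SAMPLE_RATE_HZ = 2048.0
DEFAULT_N_TRIALS = 20
PERIODS_PER_TRIAL = 10
DEFAULT_BACKGROUND_RMS_UV = 10.0
DEFAULT_TEMPLATE_RMS_UV = 8.0


@dataclass
class GroundTruth:
    """Hidden parameters of one simulated participant."""

    response_gain_map: pd.Series          # per-electrode gain, unitless
    response_template: np.ndarray         # one period of the evoked waveform, µV
    noise_sd_map: pd.Series               # per-electrode background scale, µV
    active_power_ratio: float
    affected_side: str                    # stimulated wrist
    sensory_group_label: str

    def __post_init__(self):
        if (self.response_gain_map < 0).any() or (self.noise_sd_map < 0).any():
            raise ValueError("gains and noise scales must be non-negative")
        if self.active_power_ratio <= 0:
            raise ValueError("active_power_ratio must be positive")


@dataclass
class SessionRecording:
    """One task recording: EEG (µV), torque (Nm), EMG (µV) at a common rate."""

    eeg: np.ndarray                        # electrode x sample
    electrode_labels: tuple[str, ...]
    torque: np.ndarray
    emg: np.ndarray                        # 2 x sample
    sample_rate_hz: float
    trial_boundaries: tuple[tuple[int, int], ...]
    task: str                              # "passive" | "active"
    target_torque_nm: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.eeg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]


def make_response_template(
    spec: MultisineSpec,
    sample_rate_hz: float,
    rms_uv: float = DEFAULT_TEMPLATE_RMS_UV,
    harmonic_power_fraction: float = 0.3,
    seed: int = 0,
) -> np.ndarray:
    """One period of the evoked waveform (µV).

    70% of the power (by default) sits at the stimulated lines, the rest at
    their even harmonics below 0.45 times the sample rate — the evoked
    response is nonlinear in the stimulus but strictly periodic with it.
    """
    rng = np.random.default_rng(seed)
    n = int(round(sample_rate_hz * spec.period_s))
    t = np.arange(n) / sample_rate_hz
    fundamental = np.zeros(n)
    for f in spec.frequencies:
        fundamental += np.cos(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    f_max = 0.45 * sample_rate_hz
    harmonics = np.zeros(n)
    for f in spec.frequencies:
        h = 2 * f
        if h <= f_max:
            harmonics += np.cos(2 * np.pi * h * t + rng.uniform(0, 2 * np.pi))

    def _set_rms(x, target):
        r = np.sqrt(np.mean(x**2))
        return x * (target / r) if r > 0 else x

    p_harm = harmonic_power_fraction if np.any(harmonics) else 0.0
    template = (_set_rms(fundamental, np.sqrt(1.0 - p_harm))
                + _set_rms(harmonics, np.sqrt(p_harm)))
    return _set_rms(template, rms_uv)


def make_gain_map(
    stimulated_side: str,
    labels=STANDARD_64,
    peak_gain: float = 1.0,
    ipsi_leak: float = 0.1,
    width: float = 0.30,
) -> pd.Series:
    """Smooth contralateral sensorimotor gain topography.

    A Gaussian in the 2-D montage plane peaked between C3 and CP3 (for a
    manipulated right wrist; mirrored for the left), plus an ``ipsi_leak``
    fraction of the mirrored pattern.  ``width`` is in the radian units of the
    azimuthal projection.
    """
    pos = electrode_positions(tuple(labels))
    peak_labels = ("C3", "CP3") if stimulated_side == "right" else ("C4", "CP4")
    center = pos.loc[list(peak_labels)].mean(axis=0).to_numpy()
    d2 = ((pos[["x", "y"]].to_numpy() - center) ** 2).sum(axis=1)
    contra = np.exp(-d2 / (2 * width**2))
    mirror_idx = [list(labels).index(mirror_label(l)) for l in labels]
    gains = contra + ipsi_leak * contra[mirror_idx]
    return pd.Series(peak_gain * gains, index=list(labels))


def make_ground_truth(
    group: str,
    stimulated_side: str = "right",
    spec: Optional[MultisineSpec] = None,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    seed: int = 0,
    labels=STANDARD_64,
    ipsi_leak: float = 0.1,
    template_rms_uv: float = DEFAULT_TEMPLATE_RMS_UV,
    background_rms_uv: float = DEFAULT_BACKGROUND_RMS_UV,
    gain: Optional[float] = None,
    active_power_ratio: Optional[float] = None,
) -> GroundTruth:
    """Assemble a participant's ground truth from group-level defaults."""
    if spec is None:
        spec = build_default_spec(0)
    if gain is None:
        gain = GROUP_GAINS[group]
    if active_power_ratio is None:
        active_power_ratio = GROUP_ACTIVE_POWER_RATIO[group]
    gain_map = make_gain_map(stimulated_side, labels=labels, peak_gain=gain,
                             ipsi_leak=ipsi_leak)
    template = make_response_template(spec, sample_rate_hz,
                                      rms_uv=template_rms_uv, seed=seed)
    noise_sd = pd.Series(background_rms_uv, index=list(labels))
    return GroundTruth(response_gain_map=gain_map, response_template=template,
                       noise_sd_map=noise_sd, active_power_ratio=active_power_ratio,
                       affected_side=stimulated_side, sensory_group_label=group)


def simulate_background(
    n_channels: int,
    duration_s: float,
    sample_rate_hz: float,
    seed: int,
    rms_uv: float = DEFAULT_BACKGROUND_RMS_UV,
    alpha_center_hz: float = 10.0,
    alpha_rel_amplitude: float = 1.0,
    spatial_scale: float = 0.6,
    labels=None,
) -> np.ndarray:
    """Spatially correlated 1/f-like noise with an alpha bump (µV).

    Independent white noise per channel is shaped in the frequency domain
    (amplitude ∝ 1/sqrt(f) above 1 Hz, plus a Gaussian alpha component),
    then mixed through a smooth spatial covariance derived from electrode
    distances.  By construction it contains no component locked to the
    disturbance period.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    if n < 2:
        raise ValueError("duration must cover at least two samples")
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(np.maximum(freqs[nz], 1.0))
    shape += alpha_rel_amplitude * 0.5 * np.exp(
        -((freqs - alpha_center_hz) ** 2) / (2 * 1.5**2))
    spectra = (rng.standard_normal((n_channels, len(freqs)))
               + 1j * rng.standard_normal((n_channels, len(freqs)))) * shape
    spectra[:, 0] = 0.0
    data = np.fft.irfft(spectra, n=n, axis=1)
    data /= np.sqrt(np.mean(data**2, axis=1, keepdims=True))
    if labels is None and n_channels == len(STANDARD_64):
        labels = STANDARD_64
    if labels is not None:
        pos = electrode_positions(tuple(labels))[["x", "y"]].to_numpy()
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
        cov = np.exp(-d2 / (2 * spatial_scale**2)) + 1e-6 * np.eye(n_channels)
        data = np.linalg.cholesky(cov) @ data
        data /= np.sqrt(np.mean(data**2, axis=1, keepdims=True))
    return rms_uv * data


def _blink_artifact(labels, n, sample_rate_hz, rng, rate_hz=0.25,
                    amplitude_uv=120.0, width_s=0.3):
    """Sparse positive frontal blink deflections: (channels x samples, source)."""
    source = np.zeros(n)
    n_blinks = rng.poisson(rate_hz * n / sample_rate_hz)
    w = int(width_s * sample_rate_hz)
    bump = np.hanning(max(w, 3))
    for _ in range(n_blinks):
        start = rng.integers(0, max(n - len(bump), 1))
        source[start:start + len(bump)] += bump[: n - start]
    pos = electrode_positions(tuple(labels))
    center = pos.loc[["Fp1", "Fp2"]].mean(axis=0).to_numpy() if (
        "Fp1" in pos.index and "Fp2" in pos.index) else pos[["x", "y"]].to_numpy().mean(0)
    d2 = ((pos[["x", "y"]].to_numpy() - center) ** 2).sum(axis=1)
    topo = np.exp(-d2 / (2 * 0.45**2))  # blinks spread over the whole forehead
    return amplitude_uv * np.outer(topo, source), source


def _muscle_artifact(labels, n, sample_rate_hz, rng, amplitude_uv=15.0):
    """Bursty high-frequency activity over temporal sites, spectrum rising with f."""
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    f_hi = 0.45 * sample_rate_hz
    shape = np.clip(freqs / f_hi, 0, 1) ** 1.5 * (freqs > 15)
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))) * shape
    carrier = np.fft.irfft(spec, n=n)
    # slow positive envelope makes the source bursty (super-Gaussian)
    env_spec_len = len(freqs)
    env_shape = np.exp(-freqs / 0.7)
    env = np.fft.irfft((rng.standard_normal(env_spec_len)
                        + 1j * rng.standard_normal(env_spec_len)) * env_shape, n=n)
    env = np.maximum(env - np.quantile(env, 0.6), 0.0)
    if env.max() > 0:
        env /= env.max()
    source = carrier * env
    r = np.sqrt(np.mean(source**2))
    if r > 0:
        source /= r
    pos = electrode_positions(tuple(labels))
    anchor = "T7" if "T7" in pos.index else pos.index[0]
    d2 = ((pos[["x", "y"]].to_numpy() - pos.loc[anchor].to_numpy()) ** 2).sum(axis=1)
    topo = np.exp(-d2 / (2 * 0.5**2))  # temporal-chain spread of scalp EMG
    return amplitude_uv * np.outer(topo, source), source


def simulate_session(
    truth: GroundTruth,
    spec: MultisineSpec,
    task: str,
    seed: int,
    n_trials: int = DEFAULT_N_TRIALS,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    target_torque_nm: float = 1.0,
    violation_fraction: float = 0.05,
    artifacts: tuple[str, ...] = (),
    blink_amplitude_uv: float = 120.0,
    muscle_amplitude_uv: float = 15.0,
    participant_id: str = "sim",
) -> SessionRecording:
    """One task recording of ``n_trials`` trials of ten disturbance periods.

    EEG = gain ⊗ template (scaled by sqrt(active_power_ratio) for the active
    task) + background + optional artifacts.  Active-task torque is constant
    per period with the configured fraction of periods violating the ±50%
    criterion; passive torque hovers near zero.
    """
    if task not in ("passive", "active"):
        raise ValueError(f"task must be 'passive' or 'active', got {task!r}")
    rng = np.random.default_rng(seed)
    labels = tuple(truth.response_gain_map.index)
    n_ch = len(labels)
    n_per = int(round(sample_rate_hz * spec.period_s))
    if len(truth.response_template) != n_per:
        raise ValueError("response template length does not match spec period "
                         f"({len(truth.response_template)} vs {n_per} samples)")
    trial_len = PERIODS_PER_TRIAL * n_per
    n_samples = n_trials * trial_len

    scale = np.sqrt(truth.active_power_ratio) if task == "active" else 1.0
    response = np.outer(truth.response_gain_map.to_numpy(),
                        np.tile(truth.response_template, n_trials * PERIODS_PER_TRIAL)) * scale
    eeg = response + simulate_background(
        n_ch, n_samples / sample_rate_hz, sample_rate_hz,
        seed=int(rng.integers(2**31)), labels=labels,
        rms_uv=1.0) * truth.noise_sd_map.to_numpy()[:, None]

    truth_artifacts = {}
    if "blink" in artifacts:
        art, src = _blink_artifact(labels, n_samples, sample_rate_hz, rng,
                                   amplitude_uv=blink_amplitude_uv)
        eeg += art
        truth_artifacts["blink"] = src
    if "muscle" in artifacts:
        art, src = _muscle_artifact(labels, n_samples, sample_rate_hz, rng,
                                    amplitude_uv=muscle_amplitude_uv)
        eeg += art
        truth_artifacts["muscle"] = src

    n_periods_total = n_trials * PERIODS_PER_TRIAL
    if task == "active":
        violating = rng.random(n_periods_total) < violation_fraction
        period_means = np.where(
            violating,
            target_torque_nm * rng.choice([0.3, 1.7], size=n_periods_total)
            * (1 + 0.1 * rng.standard_normal(n_periods_total)),
            target_torque_nm * (1 + rng.uniform(-0.3, 0.3, size=n_periods_total)),
        )
        emg_rms = 50.0
    else:
        violating = np.zeros(n_periods_total, bool)
        period_means = 0.02 * rng.standard_normal(n_periods_total)
        emg_rms = 2.0
    wobble = 0.03 * target_torque_nm if task == "active" else 0.01
    torque = np.empty(n_samples)
    for p in range(n_periods_total):
        seg = wobble * rng.standard_normal(n_per)
        torque[p * n_per:(p + 1) * n_per] = seg - seg.mean() + period_means[p]

    emg = emg_rms * rng.standard_normal((2, n_samples))

    boundaries = tuple((t * trial_len, (t + 1) * trial_len) for t in range(n_trials))
    meta = {
        "participant_id": participant_id,
        "side": truth.affected_side,
        "group": truth.sensory_group_label,
        "mvc_nm": target_torque_nm * 5.0,
        "violating_periods": violating.tolist(),
        "truth_artifact_sources": truth_artifacts,
    }
    return SessionRecording(
        eeg=eeg, electrode_labels=labels, torque=torque, emg=emg,
        sample_rate_hz=sample_rate_hz, trial_boundaries=boundaries, task=task,
        target_torque_nm=target_torque_nm if task == "active" else 0.0,
        metadata=meta,
    )


@dataclass
class CohortConfig:
    """Study-condition defaults for a simulated cohort."""

    group_sizes: dict = field(default_factory=lambda: {
        "severe": 6, "mild": 13, "none": 11, "control": 10})
    n_trials: int = DEFAULT_N_TRIALS
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    violation_fraction: float = 0.05
    artifacts: tuple[str, ...] = ()
    gain_jitter_sd: float = 0.1          # multiplicative, per participant
    lesion_volume_max_ml: float = 20.0
    lesion_noise_sd_ml: float = 1.5
    left_handed_fraction: float = 0.5
    ipsi_leak: float = 0.1
    template_rms_uv: float = DEFAULT_TEMPLATE_RMS_UV
    background_rms_uv: float = DEFAULT_BACKGROUND_RMS_UV
    labels: tuple[str, ...] = STANDARD_64
    group_gains: Optional[dict] = None   # overrides of GROUP_GAINS entries


@dataclass
class SimulatedParticipant:
    passive: SessionRecording
    active: Optional[SessionRecording]
    clinical: ClinicalRecord
    smt_lesion_volume_ml: float
    truth: GroundTruth


_GROUP_SUBSCORES = {
    # representative EmNSA-UE profiles per group (severe: >2 reduced, etc.)
    "severe": {"lt": 1, "p": 1, "pp": 1, "d": None, "pr": 1},
    "mild": {"lt": 1, "p": 2, "pp": 2, "d": 1, "pr": 2},
    "none": {"lt": 2, "p": 2, "pp": 2, "d": 2, "pr": 2},
    "control": {"lt": 2, "p": 2, "pp": 2, "d": 2, "pr": 2},
}


def simulate_cohort(config: CohortConfig, seed: int) -> list[SimulatedParticipant]:
    """Paired passive/active sessions with group structure and lesion volumes.

    The SMT lesion volume is a stated monotone decreasing function of the
    participant's response gain, ``v = v_max * (1 - g/g_max) + noise``, so the
    regression stage has recoverable structure; ``lesion_noise_sd_ml = 0``
    makes the gain→volume map strictly monotone.
    """
    root = np.random.SeedSequence(seed)
    spec = build_default_spec(int(np.random.default_rng(root.spawn(1)[0]).integers(2**31)))
    participants = []
    pid = 0
    gains = dict(GROUP_GAINS)
    if config.group_gains:
        gains.update(config.group_gains)
    g_max = max(gains.values())
    for group, size in config.group_sizes.items():
        for _ in range(size):
            pid += 1
            ss = root.spawn(1)[0]
            rng = np.random.default_rng(ss)
            side = "left" if rng.random() < config.left_handed_fraction else "right"
            gain = gains[group] * float(
                np.exp(config.gain_jitter_sd * rng.standard_normal()))
            truth = make_ground_truth(
                group, stimulated_side=side, spec=spec,
                sample_rate_hz=config.sample_rate_hz,
                seed=int(rng.integers(2**31)), labels=config.labels,
                ipsi_leak=config.ipsi_leak, gain=gain,
                template_rms_uv=config.template_rms_uv,
                background_rms_uv=config.background_rms_uv)
            mvc = 5.0
            passive = simulate_session(
                truth, spec, "passive", seed=int(rng.integers(2**31)),
                n_trials=config.n_trials, sample_rate_hz=config.sample_rate_hz,
                artifacts=config.artifacts, participant_id=f"P{pid:02d}")
            active = simulate_session(
                truth, spec, "active", seed=int(rng.integers(2**31)),
                n_trials=config.n_trials, sample_rate_hz=config.sample_rate_hz,
                target_torque_nm=0.2 * mvc,
                violation_fraction=config.violation_fraction,
                artifacts=config.artifacts, participant_id=f"P{pid:02d}")
            if group == "control":
                lesion = 0.0
            else:
                lesion = max(0.0, config.lesion_volume_max_ml * (1.0 - gain / g_max)
                             + config.lesion_noise_sd_ml * rng.standard_normal())
            subs = dict(_GROUP_SUBSCORES[group])
            clinical = ClinicalRecord(
                id=pid, emnsa_subscores=subs,
                fma_ue=int(rng.integers(30, 67)) if group != "severe" else int(rng.integers(1, 30)),
                months_post_stroke=int(rng.integers(6, 120)),
                age_years=int(rng.integers(45, 80)),
                gender=rng.choice(["M", "F"]),
                affected_side=side, handedness=side,
                sensory_group="none" if group == "control" else group)
            participants.append(SimulatedParticipant(
                passive=passive, active=active, clinical=clinical,
                smt_lesion_volume_ml=float(lesion), truth=truth))
    return participants
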
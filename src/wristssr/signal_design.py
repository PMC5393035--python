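"""Random-phase multisine disturbance applied by the robotic wrist manipulator.

The stimulus is a sum of sinusoids on a common frequency grid (multiples of
1/period).  Frequencies up to the natural frequency of the relaxed wrist carry
the highest amplitudes; above the 4 Hz corner the amplitude rolls off at
-20 dB/decade (amplitude proportional to 1/f) so the manipulator torque stays
bounded and the velocity-sensitive muscle spindles are still driven.  The
rendered waveform is rescaled to a root-mean-square excursion of 0.02 rad and
negated ("flipped") for left-hand recordings so flexion/extension stimulation
matches the right-hand case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

#: Stimulated frequencies (Hz) of the study's disturbance signal.
DEFAULT_FREQUENCIES_HZ = (
    0.8, 1.6, 2.4, 3.2, 4.0, 4.8, 5.6, 6.4, 8.0, 9.6, 11.2, 13.6, 16.0, 19.2,
)

DEFAULT_PERIOD_S = 1.25
DEFAULT_RMS_RAD = 0.02
DEFAULT_CORNER_HZ = 4.0


@dataclass(frozen=True)
class MultisineSpec:
    """Definition of a random-phase multisine disturbance.

    ``amplitudes`` carry the pre-normalization spectral *shape*; the rendered
    waveform is rescaled as a whole to ``rms_target_rad``.
    """

    frequencies: tuple[float, ...]
    amplitudes: tuple[float, ...]
    phases: tuple[float, ...]
    period_s: float = DEFAULT_PERIOD_S
    rms_target_rad: float = DEFAULT_RMS_RAD
    corner_hz: float = DEFAULT_CORNER_HZ
    rolloff_db_per_decade: float = -20.0

    def __post_init__(self):
        f = np.asarray(self.frequencies, float)
        a = np.asarray(self.amplitudes, float)
        p = np.asarray(self.phases, float)
        if not (len(f) == len(a) == len(p)):
            raise ValueError("frequencies, amplitudes and phases must have equal length")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("amplitudes must be non-negative")
        k = f * self.period_s
        if not np.allclose(k, np.round(k), atol=1e-9):
            raise ValueError("every frequency must be an integer multiple of 1/period_s")
        if np.any(p < 0) or np.any(p >= 2 * np.pi):
            raise ValueError("phases must lie in [0, 2*pi)")

    @property
    def harmonic_numbers(self) -> np.ndarray:
        """Index of each line on the 1/period frequency grid."""
        return np.round(np.asarray(self.frequencies) * self.period_s).astype(int)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MultisineSpec":
        d = json.loads(text)
        for key in ("frequencies", "amplitudes", "phases"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class DisturbanceSignal:
    """A rendered angular disturbance: `samples` in rad at `sample_rate_hz`."""

    samples: np.ndarray
    sample_rate_hz: float
    period_samples: int
    side: str = "right"

    @property
    def n_periods(self) -> int:
        return len(self.samples) // self.period_samples


def build_default_spec(seed: int) -> MultisineSpec:
    """The study's stimulus: 14 lines on a 0.8 Hz grid, flat to 4 Hz then 1/f.

    Only the phases depend on ``seed``; they are drawn uniformly on [0, 2*pi).
    """
    rng = np.random.default_rng(seed)
    freqs = np.asarray(DEFAULT_FREQUENCIES_HZ)
    amps = np.where(freqs <= DEFAULT_CORNER_HZ, 1.0, DEFAULT_CORNER_HZ / freqs)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(freqs))
    return MultisineSpec(
        frequencies=tuple(freqs),
        amplitudes=tuple(amps),
        phases=tuple(phases),
    )


def render_signal(
    spec: MultisineSpec,
    sample_rate_hz: float,
    n_periods: int,
    side: str = "right",
    normalize: bool = True,
) -> DisturbanceSignal:
    """Evaluate the multisine on a sample grid and normalize its RMS.

    One period is rendered and tiled, so consecutive periods are identical by
    construction.  With ``normalize`` the single-period RMS equals
    ``spec.rms_target_rad`` exactly (up to floating rounding); without it the
    raw sum of cosines is returned.  For ``side="left"`` the waveform is
    negated.
    """
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    n_float = sample_rate_hz * spec.period_s
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9 or n < 2:
        raise ValueError(
            f"sample_rate_hz * period_s = {n_float} is not an integer number of "
            "samples per period; choose a compatible sample rate"
        )
    t = np.arange(n) / sample_rate_hz
    period = np.zeros(n)
    for f, a, ph in zip(spec.frequencies, spec.amplitudes, spec.phases):
        period += a * np.cos(2.0 * np.pi * f * t + ph)
    if normalize:
        rms = np.sqrt(np.mean(period**2))
        if rms == 0:
            raise ValueError("cannot normalize an all-zero signal")
        period *= spec.rms_target_rad / rms
    if side == "left":
        period = -period
    samples = np.tile(period, n_periods)
    return DisturbanceSignal(samples=samples, sample_rate_hz=sample_rate_hz,
                             period_samples=n, side=side)


def spectral_report(signal: DisturbanceSignal, spec: MultisineSpec) -> pd.DataFrame:
    """Per-line magnitude and phase of the mean period, plus RMS/crest summary.

    Magnitude is the cosine amplitude at each spec frequency; phase follows the
    ``a*cos(2*pi*f*t + phase)`` convention.  Summary scalars are attached as
    DataFrame ``attrs``: ``rms``, ``crest_factor`` and ``total_line_power``
    (sum of per-line power a^2/2, comparable to the signal mean square).
    """
    n = signal.period_samples
    if len(signal.samples) < n:
        raise ValueError("signal shorter than one period")
    n_full = (len(signal.samples) // n) * n
    mean_period = signal.samples[:n_full].reshape(-1, n).mean(axis=0)
    coef = np.fft.rfft(mean_period)
    rows = []
    for f, m in zip(spec.frequencies, spec.harmonic_numbers):
        c = coef[m] * 2.0 / n
        mag = np.abs(c)
        rows.append((f, mag, np.angle(c) if mag > 0 else 0.0))
    report = pd.DataFrame(rows, columns=["frequency_hz", "magnitude_rad", "phase_rad"])
    rms = float(np.sqrt(np.mean(mean_period**2)))
    report.attrs["rms"] = rms
    report.attrs["crest_factor"] = float(np.max(np.abs(mean_period)) / rms) if rms > 0 else 0.0
    report.attrs["total_line_power"] = float(np.sum(report["magnitude_rad"] ** 2 / 2.0))
    return report


def export_csv(signal: DisturbanceSignal, path) -> None:
    """Write the rendered waveform as single-column CSV with a descriptive header."""
    header = (
        f"# angular excursion [rad], sample_rate_hz={signal.sample_rate_hz}, "
        f"period_samples={signal.period_samples}, side={signal.side}\n"
        "excursion_rad\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, signal.samples, fmt="%.12e")
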
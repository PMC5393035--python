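"""Outcome metrics of the steady-state response analysis.

Given a stack of EEG periods locked to the disturbance signal, each electrode
is summarized by

* the steady-state response (SSR) ``xhat(k)``: the mean over periods,
* its power ``E = sum_k xhat(k)^2`` (summed, not averaged, over samples),
* the noise variance ``sigma2 = sum_k var_p(x[p](k))`` (unbiased across
  periods, summed over samples),
* the signal-to-noise ratio ``SNR = E / sigma2``.

Montage summaries average SNR over the 15-electrode sensorimotor sets
contralateral and ipsilateral to the manipulated wrist; their normalized
contrast is the laterality index ``LI = (contra - ipsi) / (contra + ipsi)``
(+1 purely contralateral), and their sum is ``sum SNR``.  The task effect is
the percentage power change ``deltaE = (E_active - E_passive)/E_passive * 100``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .montage import mirror_pairs, sensorimotor_sets


@dataclass
class LateralityResult:
    li: float
    snr_contra: float
    snr_ipsi: float
    sum_snr: float
    electrodes_used: tuple[str, ...] = ()


@dataclass
class EvokedMetrics:
    """Per-electrode metrics for one task recording."""

    ssr: pd.DataFrame            # electrode x sample, µV
    e_hat: pd.Series             # SSR power, µV²
    noise_var: pd.Series         # across-period variance summed over samples, µV²
    snr: pd.Series
    laterality: Optional[LateralityResult] = None
    delta_e: Optional[pd.Series] = None   # percent, filled when both tasks exist


def compute_ssr(stack) -> pd.DataFrame:
    """Mean period waveform per electrode (electrode x sample, µV)."""
    if stack.P < 1:
        raise ValueError("need at least one period")
    return pd.DataFrame(stack.data.mean(axis=1), index=list(stack.electrode_labels))


def compute_snr(stack) -> pd.Series:
    """SSR power over across-period variance, per electrode.

    Identical periods give zero denominator; those electrodes report ``inf``
    rather than raising.
    """
    if stack.P < 2:
        raise ValueError("SNR needs at least two periods (unbiased variance)")
    xhat = stack.data.mean(axis=1)                      # (E, N)
    num = np.sum(xhat**2, axis=1)
    den = np.sum(stack.data.var(axis=1, ddof=1), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
    snr = np.where((den == 0) & (num == 0), np.inf, snr)
    return pd.Series(snr, index=list(stack.electrode_labels))


def compute_noise_variance(stack) -> pd.Series:
    """Denominator of the SNR: across-period variance summed over samples."""
    den = np.sum(stack.data.var(axis=1, ddof=1), axis=1)
    return pd.Series(den, index=list(stack.electrode_labels))


def compute_ssr_power(stack) -> pd.Series:
    """SSR power per electrode (µV²), sum over samples of the squared mean period."""
    ssr = compute_ssr(stack)
    return (ssr**2).sum(axis=1)


def compute_delta_e(e_active, e_passive):
    """Percentage power change of the active relative to the passive task.

    Accepts scalars or aligned Series.  Non-positive passive power makes the
    ratio meaningless (no passive response to reference against); such entries
    are reported as NaN.
    """
    if np.isscalar(e_active) and np.isscalar(e_passive):
        if e_passive <= 0:
            return float("nan")
        return (e_active - e_passive) / e_passive * 100.0
    e_active = pd.Series(e_active)
    e_passive = pd.Series(e_passive).reindex(e_active.index)
    out = (e_active - e_passive) / e_passive * 100.0
    out[e_passive <= 0] = np.nan
    return out


def compute_laterality(snr_map: pd.Series, stimulated_side: str) -> LateralityResult:
    """Set-mean SNRs, their sum, and the laterality index.

    Electrodes missing from the montage (e.g. excluded as bad) are dropped
    together with their mirror counterparts so the two sets stay symmetric.
    Both set means zero makes LI undefined (NaN).
    """
    contra_set, ipsi_set = sensorimotor_sets(stimulated_side)
    present = set(snr_map.index)
    kept_contra, kept_ipsi = [], []
    from .montage import mirror_label

    for c, i in zip(contra_set, ipsi_set):
        if c in present and i in present:
            kept_contra.append(c)
            kept_ipsi.append(i)
    if not kept_contra:
        raise ValueError("no symmetric sensorimotor electrode pairs available")
    snr_contra = float(snr_map[kept_contra].mean())
    snr_ipsi = float(snr_map[kept_ipsi].mean())
    total = snr_contra + snr_ipsi
    li = (snr_contra - snr_ipsi) / total if total > 0 else float("nan")
    return LateralityResult(
        li=li,
        snr_contra=snr_contra,
        snr_ipsi=snr_ipsi,
        sum_snr=total,
        electrodes_used=tuple(kept_contra + kept_ipsi),
    )


def hemisphere_delta_e(e_active: pd.Series, e_passive: pd.Series,
                       stimulated_side: str) -> dict[str, float]:
    """Contra/ipsilateral power change from set-mean powers.

    Set-mean powers (mean of E over each sensorimotor set) are compared
    between tasks; this is stabler than averaging per-electrode percentage
    changes when individual passive powers are near zero.
    """
    contra_set, ipsi_set = sensorimotor_sets(stimulated_side)
    out = {}
    for name, eset in (("contra", contra_set), ("ipsi", ipsi_set)):
        labels = [e for e in eset if e in e_active.index and e in e_passive.index]
        out[name] = compute_delta_e(float(e_active[labels].mean()),
                                    float(e_passive[labels].mean()))
    return out


def compute_metrics(stack, stimulated_side: Optional[str] = None) -> EvokedMetrics:
    """All per-electrode metrics, plus montage summaries when a side is given."""
    ssr = compute_ssr(stack)
    e_hat = (ssr**2).sum(axis=1)
    noise_var = compute_noise_variance(stack)
    snr = compute_snr(stack)
    lat = compute_laterality(snr, stimulated_side) if stimulated_side else None
    return EvokedMetrics(ssr=ssr, e_hat=e_hat, noise_var=noise_var, snr=snr,
                         laterality=lat)


def topography_table(metrics: EvokedMetrics, flip_to_canonical: bool = False,
                     delta_e: Optional[pd.Series] = None) -> pd.DataFrame:
    """Tidy per-electrode table (label, snr, e_hat, optional delta_e).

    With ``flip_to_canonical`` every lateral electrode's value is swapped with
    its sagittal mirror (C3 <-> C4, midline fixed) so that the left column set
    is always contralateral to the manipulated wrist — the convention used for
    group-level topographies of left-hand recordings.
    """
    labels = list(metrics.snr.index)
    table = pd.DataFrame({"label": labels,
                          "snr": metrics.snr.values,
                          "e_hat": metrics.e_hat.reindex(labels).values})
    if delta_e is not None:
        table["delta_e"] = delta_e.reindex(labels).values
    if flip_to_canonical:
        pairs = mirror_pairs(labels)  # raises naming any unmatched electrode
        value_cols = [c for c in table.columns if c != "label"]
        src = table.set_index("label")
        flipped = src.loc[[pairs[l] for l in labels], value_cols].to_numpy()
        table[value_cols] = flipped
    return table
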
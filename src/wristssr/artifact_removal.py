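"""ICA-based artifact handling.

The EEG of both tasks combined is unmixed into independent components; each
component is labelled by simple spectral/topographic heuristics — muscle
(power rising with frequency over 20–120 Hz), eye (topography concentrated on
the frontal poles with a slow, event-like time course), or single-electrode
(one electrode dominating the topography) — and the remaining ("brain")
components are projected back to the electrode level.  The decomposition
backend is pluggable: extended Infomax (the algorithm family used in the
original analysis) or FastICA; the classification heuristics, not the
unmixing flavor, carry the scientific content.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .montage import FRONTAL_EYE_SET

COMPONENT_LABELS = ("brain", "muscle", "eye", "single-electrode")

#: Heuristic thresholds (config keys; the study reports no numeric values).
DEFAULT_THRESHOLDS = {
    "muscle_slope_band_hz": (20.0, 120.0),
    "muscle_slope_min": 0.0,            # log10-power vs log10-f slope
    "single_electrode_fraction": 0.8,   # topography energy on one electrode
    "eye_frontal_fraction": 0.6,        # topography energy on the frontal set
    "eye_lowfreq_fraction": 0.5,        # source power below 5 Hz
    "eye_lowfreq_hz": 5.0,
}


@dataclass
class ICADecomposition:
    """Linear unmixing of multichannel EEG.

    ``mixing @ sources + mean`` reconstructs the input.  ``sources`` are unit
    variance; scale lives in the mixing columns.
    """

    mixing: np.ndarray                  # electrode x component
    sources: np.ndarray                 # component x sample
    mean: np.ndarray                    # electrode offsets removed before unmixing
    electrode_labels: tuple[str, ...]
    sample_rate_hz: float
    method_name: str
    component_labels: Optional[list[str]] = None
    warnings_log: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]


def decompose(
    eeg: np.ndarray,
    electrode_labels,
    sample_rate_hz: float,
    backend: str = "fastica",
    seed: int = 0,
    n_components: Optional[int] = None,
    rank_tol: float = 1e-10,
) -> ICADecomposition:
    """Unmix EEG (electrode x sample, both tasks concatenated) into ICs.

    Data are centred and PCA-whitened to their numerical rank (common-average
    referenced data lose one dimension; a warning record is kept when the rank
    is below the channel count).  Deterministic for a given seed.
    """
    eeg = np.asarray(eeg, float)
    n_ch, n_samp = eeg.shape
    if n_samp < 10 * n_ch:
        warnings.warn("few samples relative to channels; ICA may be unstable")
    mean = eeg.mean(axis=1, keepdims=True)
    x = eeg - mean
    u, s, _ = np.linalg.svd(x @ x.T / n_samp, hermitian=True)
    rank = int(np.sum(s > rank_tol * s[0]))
    logs = []
    if n_components is not None:
        rank = min(rank, n_components)
    if rank < n_ch:
        logs.append(f"rank-deficient input: {rank} components for {n_ch} channels")
    whitener = (u[:, :rank] / np.sqrt(s[:rank])).T          # rank x ch
    z = whitener @ x                                        # whitened

    if backend == "fastica":
        from sklearn.decomposition import FastICA

        ica = FastICA(n_components=rank, whiten=False, random_state=seed,
                      max_iter=1000, tol=1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica.fit(z.T)
        w = ica.components_                                 # rank x rank
    elif backend == "infomax":
        from mne.preprocessing import infomax

        w = infomax(z.T, extended=True, random_state=seed)  # rank x rank
    else:
        raise ValueError(f"unknown ICA backend {backend!r}")

    unmixing = w @ whitener                                 # rank x ch
    sources = unmixing @ x
    # normalize sources to unit variance, push scale into mixing
    sd = sources.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    sources /= sd[:, None]
    mixing = np.linalg.pinv(unmixing) * sd[None, :]
    return ICADecomposition(
        mixing=mixing, sources=sources, mean=mean,
        electrode_labels=tuple(electrode_labels), sample_rate_hz=sample_rate_hz,
        method_name=backend, warnings_log=logs)


def _spectral_slope(source, fs, band):
    f_hi = min(band[1], 0.45 * fs)
    nper = min(len(source), int(4 * fs))
    f, pxx = sps.welch(source, fs=fs, nperseg=nper)
    sel = (f >= band[0]) & (f <= f_hi) & (pxx > 0)
    if sel.sum() < 4:
        return 0.0
    coef = np.polyfit(np.log10(f[sel]), np.log10(pxx[sel]), 1)
    return float(coef[0])


def _lowfreq_fraction(source, fs, f_cut):
    nper = min(len(source), int(4 * fs))
    f, pxx = sps.welch(source, fs=fs, nperseg=nper)
    total = np.trapezoid(pxx, f)
    if total <= 0:
        return 0.0
    return float(np.trapezoid(pxx[f < f_cut], f[f < f_cut]) / total)


def classify_components(decomp: ICADecomposition,
                        thresholds: Optional[dict] = None) -> list[str]:
    """Label every component as brain / muscle / eye / single-electrode.

    Rules, applied in order of topographic specificity: single-electrode when
    one electrode carries more than 80% of the topography energy; muscle when
    the log-log spectral slope over 20–120 Hz is positive; eye when the
    topography energy concentrates on the frontal-pole electrodes and the
    source is dominated by slow (<5 Hz) activity; otherwise brain.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    labels = []
    frontal_idx = [i for i, lab in enumerate(decomp.electrode_labels)
                   if lab in FRONTAL_EYE_SET]
    for j in range(decomp.n_components):
        topo = decomp.mixing[:, j] ** 2
        total = topo.sum()
        frac_max = topo.max() / total if total > 0 else 0.0
        frac_frontal = topo[frontal_idx].sum() / total if total > 0 else 0.0
        src = decomp.sources[j]
        if frac_max > th["single_electrode_fraction"]:
            labels.append("single-electrode")
        elif _spectral_slope(src, decomp.sample_rate_hz,
                             th["muscle_slope_band_hz"]) > th["muscle_slope_min"]:
            labels.append("muscle")
        elif (frac_frontal > th["eye_frontal_fraction"]
              and _lowfreq_fraction(src, decomp.sample_rate_hz,
                                    th["eye_lowfreq_hz"]) > th["eye_lowfreq_fraction"]):
            labels.append("eye")
        else:
            labels.append("brain")
    decomp.component_labels = labels
    return labels


def reconstruct_clean(decomp: ICADecomposition, reject_labels=("muscle", "eye", "single-electrode"),
                      reject_indices=None) -> np.ndarray:
    """Project non-rejected components back to the electrode level.

    ``reject_labels`` selects by classification (requires
    :func:`classify_components` to have run) unless explicit
    ``reject_indices`` are given.  Rejecting everything is an error.
    """
    if reject_indices is None:
        if decomp.component_labels is None:
            raise ValueError("components are unlabelled; run classify_components "
                             "or pass reject_indices")
        unknown = set(reject_labels) - set(COMPONENT_LABELS)
        if unknown:
            raise ValueError(f"unknown component labels: {sorted(unknown)}")
        reject_indices = [i for i, lab in enumerate(decomp.component_labels)
                          if lab in reject_labels]
    keep = [i for i in range(decomp.n_components) if i not in set(reject_indices)]
    if not keep:
        raise ValueError("all components rejected; nothing to reconstruct")
    return decomp.mixing[:, keep] @ decomp.sources[keep] + decomp.mean
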
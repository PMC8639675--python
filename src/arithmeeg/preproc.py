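"""EEG cleaning: bad channels -> common average reference -> artifact
segments -> ICA-based ocular removal.

The cleaning recipe mirrors standard continuous-EEG practice: obviously flat
or excessively noisy channels are dropped first; the remaining channels are
re-referenced to their common average; high-amplitude segments are masked
(all later steps ignore them); finally an ICA unmixing estimated on a 1 Hz
high-passed copy of the clean data identifies ocular components, which are
zeroed before back-projecting the *original* (unfiltered) data.

Where the original workflow relied on visual inspection (bad channels,
artifact segments, component selection), this module defines automated,
deterministic surrogates with documented thresholds so that runs are
reproducible.  Ocular components must satisfy two criteria at once: high
absolute correlation with the mean of the prefrontal channels (Fp1/Fp2) and
a dominant low-frequency (< 3 Hz) share of spectral power.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import mne
import numpy as np
from scipy import signal as spsig
from sklearn.decomposition import FastICA

from .synthdata import Recording

__all__ = [
    "PreprocConfig",
    "CleaningReport",
    "IcaError",
    "detect_bad_channels",
    "rereference_common_average",
    "mark_artifact_segments",
    "remove_ocular_ica",
    "preprocess",
]


@dataclass
class PreprocConfig:
    """Thresholds for the automated cleaning surrogates.

    All amplitudes are in microvolts.  ``flat_floor`` is an absolute floor on
    the robust (MAD-based) amplitude spread; ``noisy_z`` is a robust z-score
    cutoff on log channel variance; ``amp_threshold``/``jump_threshold``
    trigger artifact-segment masking, padded by ``pad_s`` seconds.
    """

    flat_floor: float = 0.5
    noisy_z: float = 5.0
    amp_threshold: float = 400.0
    jump_threshold: float = 200.0
    pad_s: float = 0.25
    ica_highpass_hz: float = 1.0
    ica_seed: int = 1861
    ica_max_iter: int = 500
    ica_tol: float = 1e-3
    ica_decim: int = 4
    ocular_corr_threshold: float = 0.6
    ocular_lowfreq_threshold: float = 0.5
    lowfreq_hz: float = 3.0
    spectrum_max_hz: float = 40.0
    min_unmasked_s: float = 60.0
    frontal_channels: tuple[str, ...] = ("Fp1", "Fp2")


@dataclass
class CleaningReport:
    """What was removed and why, serializable to JSON."""

    bad_channels: dict[str, str] = field(default_factory=dict)
    masked_intervals: list[tuple[float, float]] = field(default_factory=list)
    removed_components: list[int] = field(default_factory=list)
    component_scores: dict[int, dict[str, float]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        d["component_scores"] = {str(k): v for k, v in self.component_scores.items()}
        return json.dumps(d, indent=2)


class IcaError(RuntimeError):
    """ICA decomposition failed; carries diagnostics."""


def _robust_spread(x: np.ndarray) -> np.ndarray:
    """MAD-based per-row amplitude spread, scaled to match a Gaussian SD."""
    med = np.median(x, axis=1, keepdims=True)
    return 1.4826 * np.median(np.abs(x - med), axis=1)


def detect_bad_channels(
    recording: Recording, config: PreprocConfig = PreprocConfig()
) -> dict[str, str]:
    """Flag flat and noisy channels; returns {channel: reason}.

    Flat: robust amplitude spread below ``flat_floor``.  Noisy: robust
    z-score of log high-frequency power (variance of the first difference,
    which is insensitive to ocular low-frequency activity) across channels
    above ``noisy_z``.  Raises if every channel is flagged (recording
    unusable).
    """
    if len(recording.channels) < 8:
        raise ValueError("need at least 8 channels for bad-channel statistics")
    x = recording.samples
    spread = _robust_spread(x)
    bad: dict[str, str] = {}
    for ch, s in zip(recording.channels, spread):
        if s < config.flat_floor:
            bad[ch] = "flat"

    hf_spread = _robust_spread(np.diff(x, axis=1))
    log_var = np.log(np.maximum(hf_spread, 1e-12) ** 2)
    ok = np.array([ch not in bad for ch in recording.channels])
    med = np.median(log_var[ok])
    mad = 1.4826 * np.median(np.abs(log_var[ok] - med))
    if mad > 0:
        z = (log_var - med) / mad
        for ch, zi, flat in zip(recording.channels, z, ~ok):
            if not flat and zi > config.noisy_z:
                bad[ch] = "noisy"
    if len(bad) == len(recording.channels):
        raise ValueError("all channels flagged bad; recording unusable")
    return bad


def rereference_common_average(
    recording: Recording, bad_channels: dict[str, str] | set | None = None
) -> Recording:
    """Re-reference good channels to their common average.

    At every sample the mean over good channels becomes zero.  Bad channels
    do not contribute to the average and are left unchanged (they are
    excluded from all downstream analysis anyway).
    """
    bad = set(bad_channels or ())
    good_idx = [i for i, ch in enumerate(recording.channels) if ch not in bad]
    if len(good_idx) < 2:
        raise ValueError("common average reference needs at least 2 good channels")
    out = recording.copy()
    avg = out.samples[good_idx].mean(axis=0)
    out.samples[good_idx] -= avg
    out.bad_channels |= bad
    return out


def _merge_intervals(
    intervals: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for t0, t1 in intervals[1:]:
        if t0 <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], t1))
        else:
            merged.append((t0, t1))
    return merged


def mark_artifact_segments(
    recording: Recording, config: PreprocConfig = PreprocConfig()
) -> list[tuple[float, float]]:
    """Half-open time intervals where any good channel exceeds the absolute
    amplitude threshold or the sample-to-sample jump criterion, padded by
    ``pad_s`` and merged.  An empty mask is a valid outcome."""
    good_idx = [
        i for i, ch in enumerate(recording.channels)
        if ch not in recording.bad_channels
    ]
    x = recording.samples[good_idx]
    sfreq = recording.sfreq
    over = (np.abs(x) > config.amp_threshold).any(axis=0)
    jump = np.zeros_like(over)
    jump[1:] = (np.abs(np.diff(x, axis=1)) > config.jump_threshold).any(axis=0)
    flag = over | jump
    if not flag.any():
        return []
    idx = np.flatnonzero(flag)
    # contiguous runs -> padded intervals
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[splits + 1]))
    ends = np.concatenate((idx[splits], [idx[-1]])) + 1
    intervals = [
        (
            max(s / sfreq - config.pad_s, 0.0),
            min(e / sfreq + config.pad_s, recording.duration),
        )
        for s, e in zip(starts, ends)
    ]
    return _merge_intervals(intervals)


def _mask_bool(
    intervals: list[tuple[float, float]], n: int, sfreq: float
) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for t0, t1 in intervals:
        mask[max(int(round(t0 * sfreq)), 0) : min(int(round(t1 * sfreq)), n)] = True
    return mask


def _lowfreq_fraction(
    source: np.ndarray, sfreq: float, low_hz: float, max_hz: float
) -> float:
    nper = min(int(4 * sfreq), source.size)
    freqs, psd = spsig.welch(source, fs=sfreq, nperseg=nper)
    sel = (freqs > 0) & (freqs <= max_hz)
    total = psd[sel].sum()
    if total <= 0:
        return 0.0
    return float(psd[sel & (freqs < low_hz)].sum() / total)


def remove_ocular_ica(
    recording: Recording,
    mask: list[tuple[float, float]] | None = None,
    config: PreprocConfig = PreprocConfig(),
) -> tuple[Recording, CleaningReport]:
    """Estimate ICA on clean, 1 Hz high-passed data and remove ocular
    components from the original recording.

    A component is ocular when (i) its time course correlates with the
    Fp1/Fp2 mean (|r| above threshold) and (ii) its sub-3 Hz power fraction
    exceeds its threshold.  Flagged components are zeroed and the data
    back-projected; everything else passes through unchanged (the transform
    is linear and invertible on the good channels).
    """
    mask = mask if mask is not None else list(recording.artifact_mask)
    report = CleaningReport(
        bad_channels={ch: "pre-flagged" for ch in recording.bad_channels},
        masked_intervals=list(mask),
    )
    good_idx = [
        i for i, ch in enumerate(recording.channels)
        if ch not in recording.bad_channels
    ]
    good_chs = [recording.channels[i] for i in good_idx]
    sfreq = recording.sfreq
    x = recording.samples[good_idx]

    keep = ~_mask_bool(mask, recording.n_times, sfreq)
    if keep.sum() / sfreq < config.min_unmasked_s:
        raise ValueError(
            f"only {keep.sum() / sfreq:.1f} s unmasked; "
            f"need {config.min_unmasked_s} s for ICA"
        )

    hp = mne.filter.filter_data(
        np.ascontiguousarray(x),
        sfreq,
        l_freq=config.ica_highpass_hz,
        h_freq=None,
        phase="zero",
        fir_window="hamming",
        fir_design="firwin",
        verbose=False,
    )
    fit_data = hp[:, keep][:, :: config.ica_decim].T  # samples x channels

    # effective rank: common-average referencing removes one dimension, so
    # whitening onto n_good components would be singular
    sv = np.linalg.svd(fit_data[: min(len(fit_data), 20000)], compute_uv=False)
    rank = int(np.sum(sv > sv[0] * 1e-8))
    n_components = min(len(good_idx), rank)

    ica = FastICA(
        n_components=n_components,
        random_state=config.ica_seed,
        max_iter=config.ica_max_iter,
        tol=config.ica_tol,
        whiten="unit-variance",
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            sources_fit = ica.fit_transform(fit_data)
        except Exception as err:  # noqa: BLE001
            raise IcaError(f"ICA decomposition failed: {err}") from err
    if not np.all(np.isfinite(ica.components_)):
        raise IcaError("ICA produced a non-finite unmixing matrix")
    if any("did not converge" in str(w.message) for w in caught):
        report.warnings.append(
            f"FastICA hit max_iter={config.ica_max_iter} without reaching "
            f"tol={config.ica_tol}; using the final unmixing"
        )

    # identification on the high-passed, decimated, unmasked sources
    frontal_idx = [
        good_chs.index(ch) for ch in config.frontal_channels if ch in good_chs
    ]
    if not frontal_idx:
        report.warnings.append("no frontal channels available; nothing removed")
        return recording.copy(), report
    frontal = fit_data[:, frontal_idx].mean(axis=1)
    sfreq_fit = sfreq / config.ica_decim

    flagged: list[int] = []
    for k in range(sources_fit.shape[1]):
        src = sources_fit[:, k]
        r = float(np.corrcoef(src, frontal)[0, 1])
        lf = _lowfreq_fraction(src, sfreq_fit, config.lowfreq_hz, config.spectrum_max_hz)
        report.component_scores[k] = {"frontal_corr": r, "lowfreq_fraction": lf}
        if abs(r) >= config.ocular_corr_threshold and lf >= config.ocular_lowfreq_threshold:
            flagged.append(k)

    out = recording.copy()
    if not flagged:
        report.warnings.append("no component met both ocular criteria; data passed through")
        return out, report
    report.removed_components = flagged

    # zero flagged components and back-project the ORIGINAL data
    sources_full = (x.T - ica.mean_) @ ica.components_.T  # samples x comps
    removed = sources_full[:, flagged] @ ica.mixing_[:, flagged].T
    out.samples[good_idx] = (x.T - removed).T
    return out, report


def preprocess(
    recording: Recording, config: PreprocConfig = PreprocConfig()
) -> tuple[Recording, CleaningReport]:
    """Run the full cleaning recipe on one continuous recording."""
    bad = detect_bad_channels(recording, config)
    reref = rereference_common_average(recording, bad)
    mask = mark_artifact_segments(reref, config)
    reref.artifact_mask = mask
    cleaned, report = remove_ocular_ica(reref, mask, config)
    report.bad_channels = bad
    cleaned.artifact_mask = mask
    return cleaned, report
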
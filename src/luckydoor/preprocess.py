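"""Channel-space EEG preprocessing.

The chain mirrors a conventional event-related band-activity pipeline:
resample to 250 Hz, band-pass 1-45 Hz, reject noisy trials (absolute
100 µV criterion plus an iterative >5 SD outlier rule, max 8 iterations),
band-filter into theta (4-8), alpha (8-13) and beta (13-30) Hz, average
across trials (evoked band activity, µV), baseline-correct against the
-250 to -50 ms pre-choice fixation window, and summarize each channel over
three 500-ms post-choice periods (choice, immediate reward, cumulative
reward). A final cross-subject rule masks any scalar further than 5 SD
from the cohort mean as NaN.

Filters are zero-phase: forward-backward 4th-order Butterworth by default,
with a Hamming-window FIR alternative (``design="fir"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .eeg_sim import EpochSet
from .montage import PARIETAL_CLUSTER

BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: Post-choice analysis periods, seconds relative to chosen-door onset.
PERIODS: dict[str, tuple[float, float]] = {
    "choice": (0.0, 0.5),
    "immediate_reward": (0.5, 1.0),
    "cumulative_reward": (1.0, 1.5),
}

BASELINE_WINDOW = (-0.25, -0.05)
BROADBAND = (1.0, 45.0)
AMPLITUDE_CRITERION_UV = 100.0


def bandpass_filter(
    data: np.ndarray,
    sfreq: float,
    low: float,
    high: float,
    design: Literal["iir", "fir"] = "iir",
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase band-pass along ``axis``.

    ``"iir"``: 4th-order Butterworth applied forward and backward
    (sosfiltfilt). ``"fir"``: Hamming-window linear-phase FIR with transition
    bandwidth 25% of each band edge, applied with filtfilt; the tap count is
    capped at two-thirds of the signal length so short epochs stay filterable.
    """
    if not 0 < low < high < sfreq / 2:
        raise ValueError(f"invalid band ({low}, {high}) at sfreq {sfreq}")
    if design == "iir":
        sos = signal.butter(4, [low, high], btype="bandpass", fs=sfreq, output="sos")
        return signal.sosfiltfilt(sos, data, axis=axis)
    if design == "fir":
        n = data.shape[axis]
        trans = 0.25 * low
        numtaps = int(3.3 * sfreq / trans)
        numtaps = min(numtaps, max(3, (2 * n) // 3))
        numtaps |= 1  # odd for type-I linear phase
        taps = signal.firwin(
            numtaps, [low, high], pass_zero=False, window="hamming", fs=sfreq
        )
        padlen = min(3 * numtaps, n - 1)
        return signal.filtfilt(taps, [1.0], data, axis=axis, padlen=padlen)
    raise ValueError(f"unknown filter design {design!r}")


def resample_and_filter(
    epochs: EpochSet,
    target_rate: float = 250.0,
    band: tuple[float, float] = BROADBAND,
    design: Literal["iir", "fir"] = "iir",
) -> EpochSet:
    """Polyphase-resample to ``target_rate`` and zero-phase band-pass."""
    if epochs.sfreq < 2 * band[1]:
        raise ValueError(
            f"sampling rate {epochs.sfreq} below Nyquist requirement for {band[1]} Hz"
        )
    data = epochs.data
    sfreq = epochs.sfreq
    if abs(sfreq - target_rate) > 1e-9:
        frac = Fraction(target_rate / sfreq).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
        sfreq = target_rate
    data = bandpass_filter(data, sfreq, *band, design=design)
    return epochs.copy_with(data, sfreq=sfreq)


def _trial_stat(data: np.ndarray, stat: str) -> np.ndarray:
    if stat == "max_abs":
        return np.max(np.abs(data), axis=(1, 2))
    if stat == "variance":
        return data.var(axis=(1, 2))
    raise ValueError(f"unknown trial statistic {stat!r}")


def reject_trials(
    epochs: EpochSet,
    amplitude_uv: float = AMPLITUDE_CRITERION_UV,
    z_thresh: float = 5.0,
    max_iter: int = 8,
    stat: Literal["max_abs", "variance"] = "max_abs",
) -> tuple[EpochSet, list[dict]]:
    """Drop noisy trials; return the cleaned EpochSet and a rejection log.

    Two rules, in order: (a) any trial whose absolute amplitude exceeds
    ``amplitude_uv`` on any channel is dropped; (b) a per-trial deviation
    statistic (default: max absolute amplitude) is compared against the
    remaining-trial distribution and trials more than ``z_thresh`` SDs from
    its mean are dropped, with the mean/SD recomputed after each pass, for at
    most ``max_iter`` passes. Each log entry records the original trial
    index, the rule, and the iteration.
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials")
    keep = np.ones(epochs.n_trials, dtype=bool)
    log: list[dict] = []

    over = np.max(np.abs(epochs.data), axis=(1, 2)) > amplitude_uv
    for t in np.flatnonzero(over):
        keep[t] = False
        log.append({"trial": int(epochs.metadata["trial"].iloc[t]),
                    "reason": "amplitude", "iteration": 0})

    stats = _trial_stat(epochs.data, stat)
    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(keep)
        if len(idx) < 3:
            break
        s = stats[idx]
        mu, sd = s.mean(), s.std(ddof=1)
        if sd == 0:
            break
        bad = idx[np.abs(s - mu) > z_thresh * sd]
        if len(bad) == 0:
            break
        for t in bad:
            keep[t] = False
            log.append({"trial": int(epochs.metadata["trial"].iloc[t]),
                        "reason": f">{z_thresh}SD", "iteration": it})

    if not keep.any():
        raise ValueError(f"all trials rejected for subject {epochs.subject_id}")
    cleaned = epochs.copy_with(
        epochs.data[keep], metadata=epochs.metadata.iloc[keep].reset_index(drop=True)
    )
    return cleaned, log


@dataclass
class SubjectBandActivity:
    """Trial-averaged band-filtered activity for one subject and band."""

    subject_id: str
    band: str
    waveform: np.ndarray  # (n_channels, n_samples), µV
    sfreq: float
    tmin: float
    ch_names: tuple[str, ...]
    n_retained: int
    n_rejected: int
    baseline_corrected: bool = False

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.waveform.shape[1]) / self.sfreq


def band_decompose_and_average(
    epochs: EpochSet,
    band: str | tuple[float, float],
    trial_mask: np.ndarray | None = None,
    design: Literal["iir", "fir"] = "iir",
    n_rejected: int = 0,
) -> SubjectBandActivity:
    """Band-pass each trial, then average across trials (evoked activity).

    ``trial_mask`` restricts which retained trials enter the average (the
    neural analysis uses rare-gain choice trials only). The band must lie
    within the 1-45 Hz broadband envelope.
    """
    if isinstance(band, str):
        name, (low, high) = band, BANDS[band]
    else:
        low, high = band
        name = f"{low:g}-{high:g}Hz"
    if low < BROADBAND[0] or high > BROADBAND[1]:
        raise ValueError(f"band ({low}, {high}) outside the {BROADBAND} envelope")

    data = epochs.data
    if trial_mask is not None:
        data = data[np.asarray(trial_mask, dtype=bool)]
    if data.shape[0] == 0:
        raise ValueError("no trials to average")
    filtered = bandpass_filter(data, epochs.sfreq, low, high, design=design)
    return SubjectBandActivity(
        subject_id=epochs.subject_id,
        band=name,
        waveform=filtered.mean(axis=0),
        sfreq=epochs.sfreq,
        tmin=epochs.tmin,
        ch_names=epochs.ch_names,
        n_retained=int(data.shape[0]),
        n_rejected=n_rejected,
    )


def baseline_correct(
    activity: SubjectBandActivity,
    window: tuple[float, float] = BASELINE_WINDOW,
) -> SubjectBandActivity:
    """Subtract each channel's mean over the baseline window from its waveform."""
    times = activity.times
    lo, hi = window
    if lo < times[0] - 1e-9 or hi > times[-1] + 1e-9:
        raise ValueError(f"baseline window {window} outside epoch {times[0]}..{times[-1]}")
    mask = (times >= lo) & (times <= hi)
    corrected = activity.waveform - activity.waveform[:, mask].mean(axis=1, keepdims=True)
    return SubjectBandActivity(
        activity.subject_id, activity.band, corrected, activity.sfreq,
        activity.tmin, activity.ch_names, activity.n_retained,
        activity.n_rejected, baseline_corrected=True,
    )


def summarize_periods(
    activity: SubjectBandActivity,
    periods: dict[str, tuple[float, float]] = PERIODS,
    measure: Literal["mean", "envelope"] = "mean",
    cluster: Sequence[str] = PARIETAL_CLUSTER,
    cluster_label: str = "parietal_cluster",
) -> pd.DataFrame:
    """Per-channel x per-period scalars, plus the parietal-cluster row.

    ``measure="mean"`` takes the signed mean of the trial-averaged waveform
    over each window; ``measure="envelope"`` takes the mean of its analytic
    (Hilbert) amplitude, which carries oscillatory magnitude that the signed
    mean of a band-limited signal cancels out. The cluster scalar is the mean
    of the four parietal channel scalars.
    """
    missing = [c for c in cluster if c not in activity.ch_names]
    if missing:
        raise ValueError(f"missing cluster channels {missing}")
    times = activity.times
    if measure == "mean":
        wave = activity.waveform
    elif measure == "envelope":
        wave = np.abs(signal.hilbert(activity.waveform, axis=1))
    else:
        raise ValueError(f"unknown measure {measure!r}")

    out = {}
    for name, (lo, hi) in periods.items():
        mask = (times >= lo) & (times < hi)
        if not mask.any():
            raise ValueError(f"period {name} {lo}-{hi}s outside epoch")
        out[name] = wave[:, mask].mean(axis=1)
    df = pd.DataFrame(out, index=list(activity.ch_names))
    df.loc[cluster_label] = df.loc[list(cluster)].mean(axis=0)
    df.index.name = "channel"
    return df


def mask_group_outliers(scalars: pd.DataFrame, z_thresh: float = 5.0) -> pd.DataFrame:
    """Set cross-subject outliers (> ``z_thresh`` SD from the mean) to NaN.

    ``scalars`` is subjects x measures; each column is screened independently.
    A zero-SD column masks nothing.
    """
    if len(scalars) < 3:
        raise ValueError("need at least 3 subjects")
    out = scalars.copy().astype(float)
    mu = out.mean(axis=0)
    sd = out.std(axis=0, ddof=1)
    dev = (out - mu).abs()
    mask = dev.gt(z_thresh * sd, axis=1) & (sd > 0)
    return out.mask(mask)
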
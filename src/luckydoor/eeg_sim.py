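"""Synthetic epoched EEG with known ground truth.

Each epoch is 1/f-shaped broadband background noise plus, on rare-gain
choice trials, a phase-consistent (evoked) 10 Hz alpha burst on the parietal
target channels, with amplitude drawn per subject from that subject's group
distribution and spatial leakage to neighboring channels. A configurable
fraction of trials carries blink-like frontal transients or forced
high-amplitude excursions, flagged in the metadata so that artifact
rejection can be scored against ground truth.

The default group effect mirrors the study condition the analysis targets:
elevated parietal alpha in the directly exposed group across the 0-1500 ms
post-choice interval, at a configured standardized difference of 0.75
between-subject SDs versus the other groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .montage import Montage, PARIETAL_CLUSTER, default_montage

#: Frontal blink topography weights (unlisted channels get 0).
BLINK_WEIGHTS = {
    "Fp1": 1.0, "Fp2": 1.0,
    "F7": 0.5, "F3": 0.6, "Fz": 0.6, "F4": 0.6, "F8": 0.5,
    "FC1": 0.3, "FC2": 0.3,
}


@dataclass
class EpochSet:
    """Per-subject epoched EEG: trials x channels x samples, in microvolts."""

    subject_id: str
    data: np.ndarray  # (n_trials, n_channels, n_samples), float64, µV
    sfreq: float  # Hz
    tmin: float  # epoch start relative to choice-stimulus onset, seconds
    ch_names: tuple[str, ...]
    metadata: pd.DataFrame  # one row per trial

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel axis does not match ch_names")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata rows must match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.sfreq

    def copy_with(self, data: np.ndarray, metadata: pd.DataFrame | None = None,
                  sfreq: float | None = None) -> "EpochSet":
        return EpochSet(
            self.subject_id,
            data,
            self.sfreq if sfreq is None else sfreq,
            self.tmin,
            self.ch_names,
            self.metadata.copy() if metadata is None else metadata,
        )


@dataclass(frozen=True)
class EegEffectConfig:
    """Ground-truth parameters of the simulated alpha effect and artifacts.

    ``alpha_amp_mean`` maps group to the mean evoked alpha amplitude (µV) on
    the target channels; ``alpha_amp_sd`` is the between-subject SD. The
    default configuration puts the directly exposed group 0.75 SD above the
    other two groups (2.6 vs 2.0 µV at SD 0.8). The burst spans
    ``burst_window`` seconds relative to choice onset, covering the choice,
    immediate-reward and cumulative-reward periods.
    """

    target_channels: tuple[str, ...] = PARIETAL_CLUSTER
    alpha_freq: float = 10.0
    alpha_amp_mean: Mapping[str, float] = field(
        default_factory=lambda: {
            "directly_exposed": 2.6,
            "indirectly_exposed": 2.0,
            "non_exposed": 2.0,
        }
    )
    alpha_amp_sd: float = 0.8
    burst_window: tuple[float, float] = (0.0, 1.5)
    leakage: float = 0.4  # fractional amplitude on neighbors of target channels
    noise_rms: float = 10.0  # broadband background RMS, µV
    noise_exponent: float = 1.0  # 1/f^gamma spectral slope
    blink_rate: float = 0.05  # fraction of trials with a blink transient
    blink_amp: float = 150.0  # blink peak, µV
    big_amp_rate: float = 0.02  # fraction of trials forced above the 100 µV criterion
    big_amp: float = 140.0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.alpha_amp_mean.values()) or self.alpha_amp_sd < 0:
            raise ValueError("alpha amplitudes must be >= 0")
        for name in ("blink_rate", "big_amp_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def null(cls, amp: float = 2.0, **kw) -> "EegEffectConfig":
        groups = ("directly_exposed", "indirectly_exposed", "non_exposed")
        return cls(alpha_amp_mean={g: amp for g in groups}, **kw)


def one_over_f_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    sfreq: float,
    rms: float,
    exponent: float = 1.0,
    f_min: float = 1.0,
) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum along the last axis.

    Spectral shaping is flat below ``f_min`` (the pink ramp starts at 1 Hz,
    matching the analysis band) and the output is scaled to the requested RMS.
    """
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = np.maximum(freqs[nz], f_min) ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    spec = (rng.standard_normal(shape[:-1] + (len(freqs),))
            + 1j * rng.standard_normal(shape[:-1] + (len(freqs),))) * scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    current = np.sqrt(np.mean(x**2))
    return x * (rms / current) if current > 0 else x


def _burst_envelope(times: np.ndarray, window: tuple[float, float], ramp: float = 0.1) -> np.ndarray:
    """Unit-height envelope over ``window`` with raised-cosine on/off ramps."""
    t0, t1 = window
    env = np.zeros_like(times)
    inside = (times >= t0) & (times <= t1)
    env[inside] = 1.0
    rise = inside & (times < t0 + ramp)
    env[rise] = 0.5 * (1 - np.cos(np.pi * (times[rise] - t0) / ramp))
    fall = inside & (times > t1 - ramp)
    env[fall] = 0.5 * (1 - np.cos(np.pi * (t1 - times[fall]) / ramp))
    return env


def simulate_epochs(
    behavior: pd.DataFrame,
    covariates: pd.DataFrame,
    effect: EegEffectConfig | None = None,
    montage: Montage | None = None,
    rng: np.random.Generator | int | None = None,
    sfreq: float = 250.0,
    tmin: float = -0.5,
    tmax: float = 1.5,
    block: str = "experimental",
) -> dict[str, EpochSet]:
    """Simulate one epoch per retained behavioral trial for every subject.

    Epochs are aligned to the chosen-door onset and span ``tmin``..``tmax``
    seconds (default -0.5 to +1.5 s at 250 Hz). The evoked alpha burst is
    added on rare-gain choice trials only — the trials the neural analysis
    uses — with a fixed phase across trials so it survives trial averaging.
    Returns a mapping subject_id -> EpochSet.
    """
    effect = effect or EegEffectConfig()
    montage = montage or default_montage()
    montage.require(effect.target_channels)
    rng = np.random.default_rng(rng)

    n_samples = int(round((tmax - tmin) * sfreq))
    times = tmin + np.arange(n_samples) / sfreq
    env = _burst_envelope(times, effect.burst_window)
    carrier = np.sin(2 * np.pi * effect.alpha_freq * times) * env

    # spatial profile of the alpha source: 1 on targets, leakage on neighbors
    profile = np.zeros(len(montage.ch_names))
    targets = set(effect.target_channels)
    for ch in targets:
        profile[montage.index(ch)] = 1.0
    for ch in targets:
        for nb in montage.neighbors(ch):
            if nb not in targets:
                i = montage.index(nb)
                profile[i] = max(profile[i], effect.leakage)

    blink_profile = np.array(
        [BLINK_WEIGHTS.get(ch, 0.0) for ch in montage.ch_names]
    )

    group_of = dict(zip(covariates["subject_id"], covariates["group"]))
    out: dict[str, EpochSet] = {}
    trials = behavior[behavior["block"] == block]
    for sid, sub in trials.groupby("subject_id", sort=True):
        sub = sub.sort_values("trial")
        group = group_of[sid]
        amp = max(0.0, rng.normal(effect.alpha_amp_mean[group], effect.alpha_amp_sd))
        n_tr = len(sub)
        data = one_over_f_noise(
            rng, (n_tr, len(montage.ch_names), n_samples), sfreq,
            rms=effect.noise_rms, exponent=effect.noise_exponent,
        )
        is_rareg = (sub["choice"] == "RareG").to_numpy()
        data[is_rareg] += amp * profile[None, :, None] * carrier[None, None, :]

        blink = rng.random(n_tr) < effect.blink_rate
        for t in np.flatnonzero(blink):
            center = rng.uniform(times[0] + 0.2, times[-1] - 0.2)
            pulse = effect.blink_amp * np.exp(-0.5 * ((times - center) / 0.08) ** 2)
            data[t] += blink_profile[:, None] * pulse[None, :]

        forced = (rng.random(n_tr) < effect.big_amp_rate) & ~blink
        for t in np.flatnonzero(forced):
            ch = rng.integers(len(montage.ch_names))
            center = rng.uniform(times[0] + 0.1, times[-1] - 0.1)
            data[t, ch] += effect.big_amp * np.exp(-0.5 * ((times - center) / 0.05) ** 2)

        meta = pd.DataFrame(
            {
                "trial": sub["trial"].to_numpy(),
                "choice": sub["choice"].to_numpy(),
                "outcome": sub["outcome"].to_numpy(),
                "is_win": sub["outcome"].to_numpy() > 0,
                "blink": blink,
                "forced_big": forced,
                "alpha_amp": amp,
            }
        )
        out[sid] = EpochSet(sid, data, sfreq, tmin, montage.ch_names, meta)
    return out
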
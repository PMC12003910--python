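"""File formats: trial/covariate CSV schemas, the HDF5 epoch layout, and EDF.

HDF5 layout (one file for a cohort)::

    /subjects/<subject_id>/data        float64 (trials, channels, samples), µV
    /subjects/<subject_id>/metadata    UTF-8 JSON (orient="split") trial table
    /subjects/<subject_id>  attrs: sfreq, tmin, ch_names (JSON list)

EDF export writes a single-record EDF (16-bit) for continuous data; epochs
can be flattened trial-by-trial into a continuous array first. Reading back
through MNE's EDF reader reproduces the signal within the 16-bit
quantization step of each channel's physical range.
"""

from __future__ import annotations

import json
from io import StringIO

import h5py
import numpy as np
import pandas as pd

from .eeg_sim import EpochSet

BEHAVIOR_COLUMNS = ("subject_id", "block", "trial", "choice", "outcome", "cumulative")
COVARIATE_COLUMNS = (
    "subject_id", "group", "age", "gender", "ethnicity", "ses", "gad7", "phq9",
    "recent_trauma",
)


def _check_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}; has {list(df.columns)}")


def write_behavior_csv(behavior: pd.DataFrame, path) -> None:
    _check_columns(behavior, BEHAVIOR_COLUMNS, "behavior table")
    behavior.to_csv(path, index=False)


def read_behavior_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, BEHAVIOR_COLUMNS, "behavior table")
    bad_choice = ~df["choice"].isin(["RareG", "RareL"])
    if bad_choice.any():
        row = df.index[bad_choice][0]
        raise ValueError(
            f"behavior table row {row}: invalid choice {df.loc[row, 'choice']!r}"
        )
    return df


def write_covariates_csv(covariates: pd.DataFrame, path) -> None:
    _check_columns(covariates, COVARIATE_COLUMNS, "covariate table")
    covariates.to_csv(path, index=False)


def read_covariates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, COVARIATE_COLUMNS, "covariate table")
    df["recent_trauma"] = df["recent_trauma"].astype(bool)
    return df


def write_epochs_h5(epoch_sets: dict[str, EpochSet], path) -> None:
    with h5py.File(path, "w") as fh:
        root = fh.create_group("subjects")
        for sid in sorted(epoch_sets):
            ep = epoch_sets[sid]
            grp = root.create_group(sid)
            grp.create_dataset("data", data=ep.data, compression="gzip", shuffle=True)
            grp.create_dataset(
                "metadata", data=ep.metadata.to_json(orient="split", index=False)
            )
            grp.attrs["sfreq"] = ep.sfreq
            grp.attrs["tmin"] = ep.tmin
            grp.attrs["ch_names"] = json.dumps(list(ep.ch_names))


def read_epochs_h5(path) -> dict[str, EpochSet]:
    out: dict[str, EpochSet] = {}
    with h5py.File(path, "r") as fh:
        for sid, grp in fh["subjects"].items():
            meta = pd.read_json(
                StringIO(grp["metadata"][()].decode()), orient="split"
            )
            out[sid] = EpochSet(
                subject_id=sid,
                data=grp["data"][()],
                sfreq=float(grp.attrs["sfreq"]),
                tmin=float(grp.attrs["tmin"]),
                ch_names=tuple(json.loads(grp.attrs["ch_names"])),
                metadata=meta,
            )
    return out


def epochs_to_continuous(epochs: EpochSet) -> np.ndarray:
    """Concatenate trials along time: (channels, trials * samples)."""
    return np.concatenate(list(epochs.data), axis=-1)


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    data: np.ndarray,
    sfreq: float,
    ch_names: tuple[str, ...] | list[str],
    physical_dim: str = "uV",
) -> None:
    """Write continuous data as a single-record 16-bit EDF file.

    ``data`` is (channels, samples) in the units of ``physical_dim``. Each
    channel's physical range is its own [min, max] (widened slightly for
    flat channels), digitized to the full 16-bit range; the quantization
    step is (max - min) / 65535. Date/time fields are fixed so output is
    byte-reproducible.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] != len(ch_names):
        raise ValueError("data must be (channels, samples) matching ch_names")
    n_ch, n_samp = data.shape
    duration = n_samp / sfreq

    pmin, pmax = _physical_range(data)
    dmin, dmax = -32768, 32767
    gain = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin[:, None]) / gain[:, None] + dmin).astype("<i2")

    header_bytes = 256 * (1 + n_ch)
    head = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate 01-JAN-2000 X X X", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(header_bytes, 8),
            _ascii("", 44),
            _ascii(1, 8),  # one data record
            _ascii(f"{duration:.6g}", 8),
            _ascii(n_ch, 4),
        ]
    )

    def field(values, width):
        return b"".join(_ascii(v, width) for v in values)

    head += field(ch_names, 16)
    head += field([""] * n_ch, 80)  # transducer
    head += field([physical_dim] * n_ch, 8)
    head += field([f"{v:d}" for v in pmin], 8)
    head += field([f"{v:d}" for v in pmax], 8)
    head += field([dmin] * n_ch, 8)
    head += field([dmax] * n_ch, 8)
    head += field([""] * n_ch, 80)  # prefiltering
    head += field([n_samp] * n_ch, 8)
    head += field([""] * n_ch, 32)

    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(digital.tobytes())  # channel-major within the single record


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file through MNE; returns (data in µV, sfreq, ch_names)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def _physical_range(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer physical min/max per channel (EDF header fields are 8 ASCII
    bytes, so the range is rounded outward to whole physical units)."""
    pmin = np.floor(data.min(axis=1)).astype(int)
    pmax = np.ceil(data.max(axis=1)).astype(int)
    same = pmax <= pmin
    pmax[same] = pmin[same] + 1
    return pmin, pmax


def edf_quantization_step(data: np.ndarray) -> np.ndarray:
    """Per-channel quantization step of the 16-bit EDF encoding of ``data``."""
    pmin, pmax = _physical_range(np.asarray(data, dtype=float))
    return (pmax - pmin) / 65535
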
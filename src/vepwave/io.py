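"""Trace and manifest I/O.

Two on-disk trace formats are supported:

* **tabular** — a plain CSV per session with columns ``epoch``, ``block``,
  ``time_ms``, ``uv``; lossless for float32-scale data and trivially
  inspectable.
* **edf** — EDF+C with the sweeps concatenated into a continuous record and a
  ``flash`` annotation at every stimulus onset.  Reading goes through
  :mod:`mne`; writing uses a minimal EDF+ writer in this module (16-bit
  quantization, so round-trips are exact only to the configured physical
  range / 2^16).

All voltages are microvolts internally; epoch time is milliseconds relative
to the flash (0 ms = flash onset).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Epoch",
    "read_epochs",
    "write_epochs",
    "write_edf",
    "read_manifest",
    "write_manifest",
    "ManifestError",
]

MANIFEST_COLUMNS = ["eye_id", "mouse_id", "group", "day", "path"]


class ManifestError(ValueError):
    """Raised for structurally invalid cohort manifests."""


@dataclass
class Epoch:
    """One stimulus-locked EEG sweep.

    Parameters
    ----------
    samples : ndarray
        Voltage series in microvolts, uniformly sampled.
    sampling_rate : float
        Sampling frequency in Hz.
    t0_ms : float
        Time of the first sample relative to flash onset (ms).
    block_index : int
        Which of the session's averaging blocks this sweep belongs to.
    """

    samples: np.ndarray
    sampling_rate: float
    t0_ms: float = 0.0
    block_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("epoch samples must be a non-empty 1-D array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.sampling_rate * 1000.0

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) / self.sampling_rate * 1000.0


def write_epochs(path: str | os.PathLike, epochs: list[Epoch]) -> None:
    """Write a session's sweeps to the tabular CSV format."""
    if not epochs:
        raise ValueError("no epochs to write")
    frames = []
    for i, ep in enumerate(epochs):
        frames.append(
            pd.DataFrame(
                {
                    "epoch": i,
                    "block": ep.block_index,
                    "time_ms": ep.times_ms,
                    "uv": ep.samples,
                }
            )
        )
    # %.17g survives the float64 round trip exactly
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def _read_epochs_tabular(path: str | os.PathLike) -> list[Epoch]:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"empty trace file: {path}")
    missing = {"epoch", "block", "time_ms", "uv"} - set(df.columns)
    if missing:
        raise ValueError(f"trace file {path} missing columns: {sorted(missing)}")
    epochs = []
    for _, g in df.groupby("epoch", sort=True):
        t = g["time_ms"].to_numpy()
        dt = np.diff(t)
        if t.size > 1:
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError(f"non-uniform sampling in {path}")
            fs = 1000.0 / dt[0]
        else:
            raise ValueError(f"single-sample epoch in {path}")
        epochs.append(
            Epoch(
                samples=g["uv"].to_numpy(),
                sampling_rate=fs,
                t0_ms=float(t[0]),
                block_index=int(g["block"].iloc[0]),
            )
        )
    return epochs


# ---------------------------------------------------------------------------
# EDF+ support
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r}")
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | os.PathLike,
    epochs: list[Epoch],
    flash_rate_hz: float = 1.0,
    annotation: str = "flash",
    channel: str = "EEG V1",
    physical_max_uv: float | None = None,
) -> None:
    """Export sweeps as a continuous EDF+C recording with stimulus annotations.

    Sweeps are laid end-to-end on the inter-stimulus grid (one data record per
    flash interval, epoch at the start of the record, zero-padded to the
    record length) and a text annotation marks each flash onset.
    """
    if not epochs:
        raise ValueError("no epochs to write")
    fs = epochs[0].sampling_rate
    n = epochs[0].n_samples
    for ep in epochs:
        if ep.sampling_rate != fs or ep.n_samples != n:
            raise ValueError("all epochs must share sampling rate and length")
    record_dur = 1.0 / flash_rate_hz
    samples_per_record = int(round(fs * record_dur))
    if samples_per_record < n:
        raise ValueError("epoch longer than the inter-flash interval")

    if physical_max_uv is None:
        peak = max(1.0, float(np.max(np.abs([e.samples for e in epochs]))))
        physical_max_uv = float(np.ceil(peak * 1.05))
    scale = 32767 / physical_max_uv

    n_records = len(epochs)
    # annotation channel: 2 bytes/sample; 60 samples = 120 bytes per record
    ann_samples = 60

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)  # local patient id (anonymous)
    header += _edf_field("Startdate X X X X", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (1 + 2), 8)  # header bytes
    header += _edf_field("EDF+C", 44)
    header += _edf_field(n_records, 8)
    header += _edf_field(f"{record_dur:g}", 8)
    header += _edf_field(2, 4)

    labels = [channel, "EDF Annotations"]
    transducers = ["AgAgCl cup electrode", ""]
    dims = ["uV", ""]
    phys_min = [f"{-physical_max_uv:g}", "-1"]
    phys_max = [f"{physical_max_uv:g}", "1"]
    dig_min = ["-32768", "-32768"]
    dig_max = ["32767", "32767"]
    prefilter = ["", ""]
    nsamp = [str(samples_per_record), str(ann_samples)]
    for values, width in [
        (labels, 16),
        (transducers, 80),
        (dims, 8),
        (phys_min, 8),
        (phys_max, 8),
        (dig_min, 8),
        (dig_max, 8),
        (prefilter, 80),
        (nsamp, 8),
        (["", ""], 32),  # reserved
    ]:
        for v in values:
            header += _edf_field(v, width)

    with open(path, "wb") as fh:
        fh.write(header)
        for rec, ep in enumerate(epochs):
            sig = np.zeros(samples_per_record)
            sig[:n] = ep.samples
            digital = np.clip(np.round(sig * scale), -32768, 32767).astype("<i2")
            fh.write(digital.tobytes())
            onset = rec * record_dur
            tal = f"+{onset:g}\x14\x14\x00".encode("ascii")
            tal += f"+{onset:g}\x14{annotation}\x14\x00".encode("ascii")
            tal = tal.ljust(ann_samples * 2, b"\x00")
            if len(tal) > ann_samples * 2:
                raise ValueError("annotation too long for reserved TAL space")
            fh.write(tal)


def _read_epochs_edf(
    path: str | os.PathLike,
    epoch_duration_ms: float = 500.0,
    annotation: str | None = None,
) -> list[Epoch]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    onsets = [
        float(a["onset"])
        for a in raw.annotations
        if annotation is None or a["description"] == annotation
    ]
    if not onsets:
        raise ValueError(f"no stimulus annotations in {path}")
    data = raw.get_data(picks=[0])[0] * 1e6  # volts -> microvolts
    n = int(round(epoch_duration_ms / 1000.0 * fs))
    epochs = []
    for onset in onsets:
        start = int(round(onset * fs))
        if start + n > data.size:
            raise ValueError(f"annotation at {onset} s runs past the end of {path}")
        epochs.append(Epoch(samples=data[start : start + n], sampling_rate=fs))
    return epochs


def read_epochs(
    path: str | os.PathLike,
    format: str = "tabular",
    epoch_duration_ms: float = 500.0,
) -> list[Epoch]:
    """Read a session's sweeps from disk.

    Parameters
    ----------
    path : path-like
        Trace file.
    format : {"tabular", "edf"}
        ``tabular`` is the package's CSV format; ``edf`` expects an EDF(+)
        file with a stimulus annotation at every flash onset, from which
        ``epoch_duration_ms`` epochs are cut starting at each annotation.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty trace file: {path}")
    if format == "tabular":
        return _read_epochs_tabular(path)
    if format == "edf":
        return _read_epochs_edf(path, epoch_duration_ms=epoch_duration_ms)
    raise ValueError(f"unknown trace format: {format!r}")


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

def write_manifest(path: str | os.PathLike, rows: pd.DataFrame) -> None:
    missing = set(MANIFEST_COLUMNS) - set(rows.columns)
    if missing:
        raise ManifestError(f"manifest missing columns: {sorted(missing)}")
    rows.to_csv(path, index=False, float_format="%.10g")


def read_manifest(
    path: str | os.PathLike,
    known_groups: list[str] | None = None,
) -> pd.DataFrame:
    """Load and validate a cohort manifest CSV.

    Checks: required columns present, ``(eye_id, day)`` unique, days
    non-negative, group labels within ``known_groups`` when given.  Eyes with
    no day-0 session are flagged in the boolean column ``has_baseline``
    (their percent-change endpoints are undefined downstream).
    """
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ManifestError(f"manifest missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["eye_id", "day"])
    if dup.any():
        bad = df.loc[dup, ["eye_id", "day"]].to_records(index=False).tolist()
        raise ManifestError(f"duplicate (eye_id, day) rows: {bad}")
    if (df["day"] < 0).any():
        raise ManifestError("negative day in manifest")
    if known_groups is not None:
        unknown = set(df["group"]) - set(known_groups)
        if unknown:
            raise ManifestError(f"unknown group labels: {sorted(unknown)}")
    baseline_eyes = set(df.loc[df["day"] == 0, "eye_id"])
    df = df.copy()
    df["has_baseline"] = df["eye_id"].isin(baseline_eyes)
    return df
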
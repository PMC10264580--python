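"""Sweep filtering and block averaging.

The filter chain is the analysis band of the recording protocol — 5-100 Hz
bandpass plus a 50 Hz notch — applied forward-backward (zero phase).  The
zero-phase contract is load-bearing: the pipeline's endpoints are peak
latencies, and a causal filter would shift every peak by its group delay.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .io import Epoch

__all__ = [
    "FilterSpec",
    "AverageTrace",
    "apply_filters",
    "average_sweeps",
    "grand_average",
    "session_averages",
]

GRAND = "grand"


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass corners and optional notch frequency, all in Hz."""

    bandpass_low: float = 5.0
    bandpass_high: float = 100.0
    notch: float | None = 50.0
    bandpass_order: int = 4
    notch_q: float = 30.0

    def validate(self, sampling_rate: float) -> None:
        nyquist = sampling_rate / 2.0
        if not 0 < self.bandpass_low < self.bandpass_high:
            raise ValueError("require 0 < bandpass_low < bandpass_high")
        if self.bandpass_high >= nyquist:
            raise ValueError(
                f"bandpass_high {self.bandpass_high} Hz >= Nyquist {nyquist} Hz"
            )
        if self.notch is not None and not 0 < self.notch < nyquist:
            raise ValueError("notch frequency must lie below Nyquist")


@dataclass
class AverageTrace:
    """Pointwise mean of a block of sweeps; the unit on which peaks are marked."""

    samples: np.ndarray
    sampling_rate: float
    n_sweeps: int
    block_index: int | str = 0
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.samples.size) / self.sampling_rate * 1000.0


def _filter_array(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    sos = sps.butter(
        spec.bandpass_order,
        [spec.bandpass_low, spec.bandpass_high],
        btype="bandpass",
        fs=fs,
        output="sos",
    )
    y = sps.sosfiltfilt(sos, x)
    if spec.notch is not None:
        b, a = sps.iirnotch(spec.notch, spec.notch_q, fs=fs)
        y = sps.filtfilt(b, a, y)
    return y


def apply_filters(epoch: Epoch | AverageTrace, spec: FilterSpec) -> Epoch | AverageTrace:
    """Zero-phase bandpass + notch; returns a new object of the same kind."""
    spec.validate(epoch.sampling_rate)
    filtered = _filter_array(epoch.samples, epoch.sampling_rate, spec)
    if isinstance(epoch, AverageTrace):
        return _dc_replace(epoch, samples=filtered)
    return Epoch(
        samples=filtered,
        sampling_rate=epoch.sampling_rate,
        t0_ms=epoch.t0_ms,
        block_index=epoch.block_index,
    )


def average_sweeps(epochs: Sequence[Epoch], block_index: int | str | None = None) -> AverageTrace:
    """Arithmetic mean of a block of sweeps."""
    if not epochs:
        raise ValueError("cannot average zero sweeps")
    lengths = {ep.n_samples for ep in epochs}
    if len(lengths) > 1:
        raise ValueError(f"mixed epoch lengths: {sorted(lengths)}")
    rates = {ep.sampling_rate for ep in epochs}
    if len(rates) > 1:
        raise ValueError(f"mixed sampling rates: {sorted(rates)}")
    if block_index is None:
        blocks = {ep.block_index for ep in epochs}
        block_index = blocks.pop() if len(blocks) == 1 else GRAND
    stacked = np.stack([ep.samples for ep in epochs])
    return AverageTrace(
        samples=stacked.mean(axis=0),
        sampling_rate=epochs[0].sampling_rate,
        n_sweeps=len(epochs),
        block_index=block_index,
        t0_ms=epochs[0].t0_ms,
    )


def grand_average(blocks: Sequence[AverageTrace]) -> AverageTrace:
    """Sweep-weighted mean of block averages.

    With equal sweep counts this equals the plain mean of the block averages;
    in general it equals the mean over all underlying sweeps (linearity).
    """
    if not blocks:
        raise ValueError("cannot average zero blocks")
    lengths = {b.samples.size for b in blocks}
    if len(lengths) > 1:
        raise ValueError(f"mixed block lengths: {sorted(lengths)}")
    weights = np.array([b.n_sweeps for b in blocks], dtype=float)
    stacked = np.stack([b.samples for b in blocks])
    samples = (stacked * weights[:, None]).sum(axis=0) / weights.sum()
    return AverageTrace(
        samples=samples,
        sampling_rate=blocks[0].sampling_rate,
        n_sweeps=int(weights.sum()),
        block_index=GRAND,
        t0_ms=blocks[0].t0_ms,
    )


def session_averages(epochs: Sequence[Epoch]) -> tuple[list[AverageTrace], AverageTrace]:
    """Group a session's sweeps by block, average each, and form the grand average."""
    by_block: dict[int, list[Epoch]] = {}
    for ep in epochs:
        by_block.setdefault(ep.block_index, []).append(ep)
    blocks = [average_sweeps(by_block[b], block_index=b) for b in sorted(by_block)]
    return blocks, grand_average(blocks)
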
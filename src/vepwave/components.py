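"""Ordinal P1/N1/P2 detection and implicit times.

The marking rules automate how a human electrophysiologist reads a flash-VEP
average: P1 is the *first* positive peak after the stimulus-artifact blanking
period, N1 the first negative trough after it, and P2 the second positive
peak — provided it occurs before the trace's sustained late negativity (the
"hyperpolarization" that closes the response).  "First", not "largest":
ordinal semantics are what distinguish these definitions from plain argmax.

Candidates are found on a lightly smoothed copy of the trace (a short moving
average suppresses single-sample noise ripples that a human marker would
ignore); each candidate is then refined to the nearest local extremum of the
*unsmoothed* trace, from which the latency and amplitude are read.  Ties
between equal adjacent samples resolve to the earliest sample.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .preprocess import AverageTrace

__all__ = [
    "SearchWindows",
    "HyperpolarizationRule",
    "VEPMarks",
    "detect_components",
    "implicit_times",
    "mark_reproducibility",
    "local_maxima",
    "local_minima",
]

MEASURES = ("P1", "N1", "P2", "P1-N1", "N1-P2", "P1-P2")


@dataclass(frozen=True)
class SearchWindows:
    """Per-component latency windows (ms), and the stimulus-artifact blanking.

    Defaults are analysis conventions for murine flash VEP, not measured
    values; the ordinal rules additionally require N1 after P1 and P2 after
    N1 regardless of the windows.
    """

    p1: tuple[float, float] = (10.0, 45.0)
    n1: tuple[float, float] = (25.0, 80.0)
    p2: tuple[float, float] = (45.0, 150.0)
    blank_ms: float = 10.0

    def __post_init__(self) -> None:
        for name, (lo, hi) in [("p1", self.p1), ("n1", self.n1), ("p2", self.p2)]:
            if not lo < hi:
                raise ValueError(f"degenerate {name} window ({lo}, {hi})")
        if self.p1[0] < self.blank_ms:
            raise ValueError("P1 window must start after the blanking period")


@dataclass(frozen=True)
class HyperpolarizationRule:
    """Operational bound for "before the complete signal hyperpolarization".

    The P2 search is cut at the onset of the first sustained negative
    excursion: the first sample after ``earliest_ms`` where the (smoothed)
    trace stays <= 0 for at least ``min_duration_ms`` AND dips below
    ``-min_depth_fraction`` times the trace's absolute peak within that run —
    a *complete* hyperpolarization is a deep negativity, and the depth
    requirement keeps near-zero inter-peak troughs (filter undershoot, noise
    hover) from truncating the search.  ``cap_ms`` is a hard upper bound
    applied regardless.
    """

    earliest_ms: float = 60.0
    min_duration_ms: float = 40.0
    cap_ms: float = 150.0
    min_depth_fraction: float = 0.2


@dataclass
class VEPMarks:
    """Latencies, amplitudes, implicit times and quality flags for one trace.

    Latencies in ms from flash onset; amplitudes in microvolts relative to
    the blanking-interval baseline; ``n1_p2_amplitude`` is peak-to-peak.
    Absent components are ``None`` with an explanatory quality flag.
    """

    p1_latency: float | None = None
    n1_latency: float | None = None
    p2_latency: float | None = None
    p1_amp: float | None = None
    n1_amp: float | None = None
    p2_amp: float | None = None
    n1_p2_amplitude: float | None = None
    p1_n1_time: float | None = None
    n1_p2_time: float | None = None
    p1_p2_time: float | None = None
    quality: dict[str, str] = field(default_factory=dict)

    def latency(self, component: str) -> float | None:
        return getattr(self, f"{component.lower()}_latency")

    def measure(self, name: str) -> float | None:
        """Value of any of the six latency measures (ms) by field name."""
        return {
            "P1": self.p1_latency,
            "N1": self.n1_latency,
            "P2": self.p2_latency,
            "P1-N1": self.p1_n1_time,
            "N1-P2": self.n1_p2_time,
            "P1-P2": self.p1_p2_time,
        }[name]


# ---------------------------------------------------------------------------
# Extremum machinery
# ---------------------------------------------------------------------------


def local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; a plateau yields its earliest sample.

    Endpoints are never maxima.  Implemented by back-filling zero slopes so
    that a rise-plateau-fall pattern marks the first plateau sample.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int)
    d = np.sign(np.diff(x))
    # back-fill zeros (plateaus) with the next nonzero slope
    filled = d.copy()
    nxt = 0.0
    for i in range(filled.size - 1, -1, -1):
        if filled[i] == 0:
            filled[i] = nxt
        else:
            nxt = filled[i]
    idx = np.nonzero((filled[:-1] > 0) & (filled[1:] < 0))[0] + 1
    # a leading plateau inherits a falling slope but never rose: d guards it
    return idx[d[idx - 1] != -1] if idx.size else idx


def local_minima(x: np.ndarray) -> np.ndarray:
    return local_maxima(-np.asarray(x, dtype=float))


def _refine_extremum(x: np.ndarray, idx: int, kind: str) -> int:
    """Hill-climb from a smoothed-trace candidate to the nearest raw extremum."""
    sign = 1.0 if kind == "max" else -1.0
    y = sign * x
    i = int(idx)
    while True:
        if i > 0 and y[i - 1] > y[i]:
            i -= 1
        elif i + 1 < y.size and y[i + 1] > y[i]:
            i += 1
        else:
            break
    while i > 0 and y[i - 1] == y[i]:  # earliest sample of a plateau
        i -= 1
    return i


def peak_prominence(x: np.ndarray, idx: int) -> float:
    """Topographic prominence of a local maximum of ``x`` at ``idx``.

    Height above the higher of the two key saddles: walk outward on each side
    to the nearest strictly higher point (or the signal edge) and take the
    minimum in between; prominence = x[idx] - max(left base, right base).
    """
    x = np.asarray(x, dtype=float)
    h = x[idx]
    left = x[:idx][::-1]
    higher = np.nonzero(left > h)[0]
    left_base = left[: higher[0]].min() if higher.size else (left.min() if left.size else h)
    right = x[idx + 1 :]
    higher = np.nonzero(right > h)[0]
    right_base = right[: higher[0]].min() if higher.size else (right.min() if right.size else h)
    return float(h - max(left_base, right_base))


def _candidates(
    trace: np.ndarray, smoothed: np.ndarray, kind: str, min_prominence: float
) -> np.ndarray:
    sign = 1.0 if kind == "max" else -1.0
    finder = local_maxima if kind == "max" else local_minima
    kept = [
        i
        for i in finder(smoothed)
        if peak_prominence(sign * smoothed, i) >= min_prominence
    ]
    refined = sorted({_refine_extremum(trace, i, kind) for i in kept})
    return np.array(refined, dtype=int)


def _hyperpolarization_bound(
    smoothed: np.ndarray, times: np.ndarray, fs: float, rule: HyperpolarizationRule
) -> float:
    """Onset time (ms) of the first sustained, deep non-positive excursion."""
    min_run = int(round(rule.min_duration_ms / 1000.0 * fs))
    start_idx = int(np.searchsorted(times, rule.earliest_ms))
    depth = -rule.min_depth_fraction * float(np.max(np.abs(smoothed))) if smoothed.size else 0.0
    nonpos = smoothed <= 0
    onset = None
    i = start_idx
    while i < nonpos.size:
        if not nonpos[i]:
            i += 1
            continue
        j = i
        while j < nonpos.size and nonpos[j]:
            j += 1
        if j - i >= min_run and float(smoothed[i:j].min()) <= depth:
            onset = times[i]
            break
        i = j
    bound = rule.cap_ms if onset is None else min(onset, rule.cap_ms)
    return float(bound)


def detect_components(
    avg: AverageTrace,
    windows: SearchWindows | None = None,
    polarity: int = 1,
    smoothing_ms: float = 1.2,
    hyperpolarization: HyperpolarizationRule | None = None,
    min_prominence_fraction: float = 0.15,
    min_prominence_uv: float = 0.0,
) -> VEPMarks:
    """Mark P1, N1 and P2 on an average trace by their ordinal definitions.

    Parameters
    ----------
    avg : AverageTrace
        Filtered average; positivity upward after ``polarity`` correction.
    windows : SearchWindows
        Latency windows per component.
    polarity : {1, -1}
        -1 for recordings referenced with positivity downward.
    smoothing_ms : float
        Moving-average span used only for candidate detection; latencies are
        read from the unsmoothed trace.
    min_prominence_fraction, min_prominence_uv : float
        A candidate extremum must have topographic prominence of at least
        ``max(min_prominence_uv, min_prominence_fraction * max|trace|)`` on
        the smoothed trace.  This is the operational form of a human marker
        ignoring small ripples (noise residue, filter rebound) between the
        genuine deflections; among candidates that clear it, the ordinal
        "first peak" rules decide.
    """
    if polarity not in (1, -1):
        raise ValueError("polarity must be +1 or -1")
    windows = windows or SearchWindows()
    rule = hyperpolarization or HyperpolarizationRule()
    trace = polarity * np.asarray(avg.samples, dtype=float)
    times = avg.times_ms
    fs = avg.sampling_rate

    marks = VEPMarks()
    span = max(1, int(round(smoothing_ms / 1000.0 * fs)))
    smoothed = uniform_filter1d(trace, size=span, mode="nearest") if span > 1 else trace
    min_prom = max(
        min_prominence_uv,
        min_prominence_fraction * float(np.max(np.abs(smoothed))) if smoothed.size else 0.0,
    )

    maxima = _candidates(trace, smoothed, "max", min_prom)
    minima = _candidates(trace, smoothed, "min", min_prom)
    if maxima.size == 0 and minima.size == 0:
        marks.quality = {c: "no_signal" for c in ("P1", "N1", "P2")}
        return marks

    blank_n = int(np.searchsorted(times, windows.blank_ms))
    baseline = float(trace[:blank_n].mean()) if blank_n > 0 else 0.0

    def first_in(cands: np.ndarray, lo: float, hi: float, after: int | None, positive: bool):
        for i in cands:
            if after is not None and i <= after:
                continue
            t = times[i]
            if t < lo or t > hi:
                continue
            if positive and trace[i] <= 0:
                continue
            if not positive and trace[i] >= 0:
                continue
            return int(i)
        return None

    p1_idx = first_in(maxima, *windows.p1, after=None, positive=True)
    n1_idx = first_in(minima, *windows.n1, after=p1_idx, positive=False)

    p2_hi = min(windows.p2[1], _hyperpolarization_bound(smoothed, times, fs, rule))
    p2_idx = first_in(maxima, windows.p2[0], p2_hi, after=n1_idx, positive=True)

    if p1_idx is not None:
        marks.p1_latency = float(times[p1_idx])
        marks.p1_amp = float(trace[p1_idx] - baseline)
        marks.quality["P1"] = "ok"
    else:
        marks.quality["P1"] = "absent"
    if n1_idx is not None:
        marks.n1_latency = float(times[n1_idx])
        marks.n1_amp = float(trace[n1_idx] - baseline)
        marks.quality["N1"] = "ok"
    else:
        marks.quality["N1"] = "absent"
    if p2_idx is not None:
        marks.p2_latency = float(times[p2_idx])
        marks.p2_amp = float(trace[p2_idx] - baseline)
        marks.quality["P2"] = "ok"
    else:
        marks.quality["P2"] = "absent"

    if marks.n1_amp is not None and marks.p2_amp is not None:
        marks.n1_p2_amplitude = marks.p2_amp - marks.n1_amp
    return implicit_times(marks)


def implicit_times(marks: VEPMarks) -> VEPMarks:
    """Populate the inter-peak latencies by exact subtraction.

    Each implicit time is the later peak's latency minus the earlier one's;
    a missing operand makes the result absent (never fabricated).
    """

    def diff(b: float | None, a: float | None) -> float | None:
        return None if a is None or b is None else b - a

    marks.p1_n1_time = diff(marks.n1_latency, marks.p1_latency)
    marks.n1_p2_time = diff(marks.p2_latency, marks.n1_latency)
    marks.p1_p2_time = diff(marks.p2_latency, marks.p1_latency)
    return marks


def mark_reproducibility(
    block_marks: list[VEPMarks], tolerance_ms: float = 5.0
) -> dict[str, dict]:
    """Across-block agreement of the marked latencies.

    For each component, the maximum pairwise latency spread across the block
    averages; a component missing in any block, or spreading wider than the
    tolerance, is flagged ``unstable``.
    """
    if len(block_marks) < 2:
        raise ValueError("reproducibility needs at least two marked blocks")
    report: dict[str, dict] = {}
    for comp in ("P1", "N1", "P2"):
        lats = [m.latency(comp) for m in block_marks]
        present = [lat for lat in lats if lat is not None]
        if len(present) < len(lats):
            report[comp] = {"spread_ms": None, "stable": False, "flag": "unstable"}
            continue
        spread = max(abs(a - b) for a, b in itertools.combinations(present, 2))
        stable = spread <= tolerance_ms
        report[comp] = {
            "spread_ms": float(spread),
            "stable": stable,
            "flag": "ok" if stable else "unstable",
        }
    return report
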
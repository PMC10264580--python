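import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from vepwave import (
    AcquisitionSpec,
    FilterSpec,
    NoiseSpec,
    default_components,
    simulate_session,
)
from vepwave.preprocess import apply_filters, grand_average, session_averages


@pytest.fixture(scope="session")
def acq():
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def components():
    return default_components()


@pytest.fixture(scope="session")
def silent_noise():
    return NoiseSpec.silent()


def filtered_grand(epochs, filter_spec=None):
    """Block-average a session's sweeps, filter, and grand-average."""
    blocks, _ = session_averages(epochs)
    spec = filter_spec or FilterSpec()
    blocks = [apply_filters(b, spec) for b in blocks]
    return grand_average(blocks)


def mark_simulated_session(truth, noise, acq, seed, **detect_kwargs):
    from vepwave import detect_components

    epochs, latencies = simulate_session(truth, noise, acq, seed)
    marks = detect_components(filtered_grand(epochs), **detect_kwargs)
    return marks, latencies


# ---------------------------------------------------------------------------
# Independent brute-force oracle for the ordinal component definitions.
# Kept deliberately naive (explicit scans, own prominence walk) so it shares
# no machinery with the implementation it checks.
# ---------------------------------------------------------------------------


def oracle_extrema(x, kind):
    """All local extrema (earliest sample of plateaus), by explicit scan."""
    x = list(x)
    n = len(x)
    sign = 1.0 if kind == "max" else -1.0
    y = [sign * v for v in x]
    out = []
    for i in range(1, n - 1):
        if y[i - 1] >= y[i]:
            continue
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        if j + 1 < n and y[j + 1] < y[i]:
            out.append(i)
    return out


def oracle_prominence(x, idx, kind):
    sign = 1.0 if kind == "max" else -1.0
    y = [sign * v for v in x]
    h = y[idx]
    left_base = h
    run_min = h
    for i in range(idx - 1, -1, -1):
        if y[i] > h:
            break
        run_min = min(run_min, y[i])
    else:
        pass
    left_base = run_min
    run_min = h
    for i in range(idx + 1, len(y)):
        if y[i] > h:
            break
        run_min = min(run_min, y[i])
    right_base = run_min
    return h - max(left_base, right_base)


def random_bump_fixture(rng, times):
    """Sum of well-separated Gaussian bumps with mixed signs.

    Separation >= 18 ms and amplitudes 8-14 uV keep every bump's prominence
    far from the detection floor, so smoothing cannot flip a candidate.
    """
    while True:
        k = rng.integers(2, 5)
        lats = np.sort(rng.uniform(14.0, 140.0, size=k))
        if k > 1 and np.min(np.diff(lats)) < 18.0:
            continue
        amps = rng.uniform(8.0, 14.0, size=k) * rng.choice([-1, 1], size=k)
        widths = rng.uniform(3.0, 5.0, size=k)
        sigma = widths / np.sqrt(2 * np.log(2))
        samples = np.zeros_like(times)
        for lat, amp, s in zip(lats, amps, sigma):
            samples += amp * np.exp(-0.5 * ((times - lat) / s) ** 2)
        return samples


def oracle_detect(trace, times, windows, min_prominence=0.0, p2_cap_ms=150.0):
    """First-extremum scan implementing the ordinal P1/N1/P2 definitions."""

    def first(kind, lo, hi, after_idx, positive):
        for i in oracle_extrema(trace, kind):
            if after_idx is not None and i <= after_idx:
                continue
            if not (lo <= times[i] <= hi):
                continue
            if positive and trace[i] <= 0:
                continue
            if not positive and trace[i] >= 0:
                continue
            if oracle_prominence(trace, i, kind) < min_prominence:
                continue
            return i
        return None

    p1 = first("max", windows.p1[0], windows.p1[1], None, True)
    n1 = first("min", windows.n1[0], windows.n1[1], p1, False)
    p2 = first("max", windows.p2[0], min(windows.p2[1], p2_cap_ms), n1, True)
    return tuple(None if i is None else times[i] for i in (p1, n1, p2))
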
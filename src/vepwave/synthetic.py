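"""Synthetic flash-VEP cohorts with known ground truth.

The generator emulates the study design this package analyzes: 500 ms
post-flash epochs sampled at 4096 Hz, recorded as 3 averaging blocks of 20
sweeps per session, over longitudinal sessions (baseline plus follow-up days
post-immunization).  Each sweep is a triphasic VEP — positive P1, negative
N1, positive P2, each a Gaussian bump with exact peak latency — superimposed
on 1/f^alpha Gaussian background EEG, an optional 50 Hz mains component, and
per-sweep latency jitter.  Disease and treatment arms are modeled purely as
per-component latency-delay trajectories (percent delay vs baseline as a
function of day), so every downstream endpoint has a known ground truth.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning; identical (design, seed) pairs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from .io import Epoch

__all__ = [
    "ComponentSpec",
    "AcquisitionSpec",
    "NoiseSpec",
    "Trajectory",
    "GroupSpec",
    "CohortDesign",
    "SimulatedSession",
    "default_components",
    "make_component_kernel",
    "pink_noise",
    "simulate_epoch",
    "simulate_session",
    "iter_cohort_sessions",
    "simulate_cohort",
    "eae_characterization_design",
    "tdcs_design",
]

COMPONENT_NAMES = ("P1", "N1", "P2")

# Gaussian sigma such that the kernel is at half amplitude one half-width
# from the peak: sigma = width / sqrt(2 ln 2).
_HWHM_TO_SIGMA = 1.0 / np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class ComponentSpec:
    """One VEP component: a signed unimodal bump.

    ``width_ms`` is the half-width at half maximum of the Gaussian kernel.
    P1 and P2 must be positive deflections, N1 negative.
    """

    name: str
    latency_ms: float
    amplitude_uv: float
    width_ms: float

    def __post_init__(self) -> None:
        if self.name not in COMPONENT_NAMES:
            raise ValueError(f"component name must be one of {COMPONENT_NAMES}")
        if self.latency_ms <= 0:
            raise ValueError("latency must be positive")
        if self.width_ms <= 0:
            raise ValueError("width must be positive")
        if self.amplitude_uv == 0:
            raise ValueError("amplitude must be nonzero")
        if self.name in ("P1", "P2") and self.amplitude_uv < 0:
            raise ValueError(f"{self.name} amplitude must be positive")
        if self.name == "N1" and self.amplitude_uv > 0:
            raise ValueError("N1 amplitude must be negative")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Recording geometry: defaults match the flash-VEP protocol
    (4096 Hz, 500 ms epochs, 3 averages of 20 sweeps, 1 Hz flashes)."""

    sampling_rate: float = 4096.0
    epoch_duration_ms: float = 500.0
    sweeps_per_average: int = 20
    averages_per_session: int = 3
    flash_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.epoch_duration_ms <= 0:
            raise ValueError("sampling rate and epoch duration must be positive")
        if self.sweeps_per_average < 1 or self.averages_per_session < 1:
            raise ValueError("sweep and average counts must be >= 1")
        n = self.epoch_duration_ms / 1000.0 * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch duration must be an integer number of samples")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_duration_ms / 1000.0 * self.sampling_rate))

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate * 1000.0


@dataclass(frozen=True)
class NoiseSpec:
    """Background model: 1/f^alpha Gaussian EEG, mains hum, sweep jitter.

    ``background_sd`` is the per-sample SD of the background in microvolts;
    ``sweep_latency_jitter_sd`` jitters each component's latency per sweep.
    """

    background_sd: float = 3.0  # one fifth of the default |N1| amplitude
    spectral_exponent: float = 1.0
    powerline_amplitude: float = 2.0
    powerline_hz: float = 50.0
    sweep_latency_jitter_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.background_sd < 0 or self.sweep_latency_jitter_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.spectral_exponent <= 2.0:
            raise ValueError("spectral exponent must lie in [0, 2]")
        if self.powerline_amplitude < 0:
            raise ValueError("powerline amplitude must be non-negative")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(background_sd=0.0, powerline_amplitude=0.0, sweep_latency_jitter_sd=0.0)


def default_components() -> tuple[ComponentSpec, ComponentSpec, ComponentSpec]:
    """Nominal healthy mouse flash-VEP morphology.

    Baseline latencies (P1 25 ms, N1 50 ms, P2 90 ms) are configurable
    conventions of this simulator, not measured values.
    """
    return (
        ComponentSpec("P1", 25.0, 8.0, 5.0),
        ComponentSpec("N1", 50.0, -15.0, 8.0),
        ComponentSpec("P2", 90.0, 10.0, 12.0),
    )


def make_component_kernel(spec: ComponentSpec, acq: AcquisitionSpec) -> np.ndarray:
    """Sample one component's Gaussian kernel on the epoch grid.

    The peak is snapped to the sample nearest ``spec.latency_ms`` so that the
    sampled extremum equals ``spec.amplitude_uv`` exactly; the bump decays
    below 1% of the amplitude beyond 3 half-widths.
    """
    if not 0 <= spec.latency_ms <= acq.epoch_duration_ms:
        raise ValueError(
            f"component outside epoch: {spec.name} at {spec.latency_ms} ms "
            f"for a {acq.epoch_duration_ms} ms epoch"
        )
    peak_idx = int(round(spec.latency_ms / 1000.0 * acq.sampling_rate))
    peak_idx = min(peak_idx, acq.n_samples - 1)
    t = acq.times_ms
    sigma = spec.width_ms * _HWHM_TO_SIGMA
    return spec.amplitude_uv * np.exp(-0.5 * ((t - t[peak_idx]) / sigma) ** 2)


def pink_noise(
    n: int, sampling_rate: float, sd: float, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha power spectrum and per-sample SD ``sd``.

    White Gaussian noise is shaped in the frequency domain by f^(-alpha/2)
    (DC removed); the shaping gain is normalized by Parseval's identity so the
    expected time-domain variance is sd^2 regardless of alpha.
    """
    if sd == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, 1.0 / sampling_rate)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-alpha / 2.0)
    # sum of |gain|^2 over the full (two-sided) spectrum
    full_power = 2.0 * np.sum(gain[1:-1] ** 2) + gain[-1] ** 2
    gain *= np.sqrt(n / full_power)
    spectrum = np.fft.rfft(rng.standard_normal(n)) * gain
    return np.fft.irfft(spectrum, n) * sd


def simulate_epoch(
    components: Sequence[ComponentSpec],
    noise: NoiseSpec,
    acq: AcquisitionSpec,
    rng: np.random.Generator | int,
    block_index: int = 0,
) -> Epoch:
    """Simulate one sweep: jittered component kernels + background + mains."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    signal = np.zeros(acq.n_samples)
    jitters = rng.normal(0.0, noise.sweep_latency_jitter_sd, size=len(components))
    for spec, jit in zip(components, jitters):
        lat = float(np.clip(spec.latency_ms + jit, 0.0, acq.epoch_duration_ms))
        signal += make_component_kernel(replace(spec, latency_ms=lat), acq)
    if noise.background_sd > 0:
        signal += pink_noise(
            acq.n_samples, acq.sampling_rate, noise.background_sd, noise.spectral_exponent, rng
        )
    if noise.powerline_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        t_s = acq.times_ms / 1000.0
        signal += noise.powerline_amplitude * np.sin(
            2.0 * np.pi * noise.powerline_hz * t_s + phase
        )
    return Epoch(samples=signal, sampling_rate=acq.sampling_rate, block_index=block_index)


def simulate_session(
    truth: Sequence[ComponentSpec],
    noise: NoiseSpec,
    acq: AcquisitionSpec,
    seed: int | np.random.SeedSequence,
) -> tuple[list[Epoch], dict[str, float]]:
    """Simulate one recording session.

    Returns ``sweeps_per_average * averages_per_session`` epochs tagged with
    their block index, plus the ground-truth component latencies (ms).
    """
    ordered = sorted(truth, key=lambda c: c.latency_ms)
    names = [c.name for c in ordered]
    if names != [n for n in COMPONENT_NAMES if n in names]:
        raise ValueError("component latencies must be ordered P1 < N1 < P2")
    rng = np.random.default_rng(seed)
    epochs = []
    for block in range(acq.averages_per_session):
        for _ in range(acq.sweeps_per_average):
            epochs.append(simulate_epoch(ordered, noise, acq, rng, block_index=block))
    truth_latencies = {c.name: c.latency_ms for c in ordered}
    return epochs, truth_latencies


# ---------------------------------------------------------------------------
# Longitudinal cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Trajectory:
    """Per-component latency delay (percent vs baseline) as a function of day.

    ``delays`` maps a component name to ``{day: percent}`` anchor points;
    values are linearly interpolated between anchors, are 0 at day 0 by
    construction, and hold their last value beyond the final anchor.
    """

    delays: Mapping[str, Mapping[float, float]] = field(default_factory=dict)

    def pct(self, component: str, day: float) -> float:
        anchors = self.delays.get(component)
        if not anchors:
            return 0.0
        days = np.array(sorted(anchors))
        vals = np.array([anchors[d] for d in days])
        if days[0] > 0:
            days = np.insert(days, 0, 0.0)
            vals = np.insert(vals, 0, 0.0)
        return float(np.interp(day, days, vals))

    @classmethod
    def flat(cls) -> "Trajectory":
        return cls({})


@dataclass(frozen=True)
class GroupSpec:
    """One design arm: label, size in eyes, latency-delay trajectory.

    ``dropout_day`` maps an eye index (0-based within the group) to the last
    day that eye is observed (right-censoring; e.g. animals lost to disease).
    """

    label: str
    n_eyes: int
    trajectory: Trajectory = field(default_factory=Trajectory.flat)
    is_diseased: bool = True
    dropout_day: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("group must have at least one eye")


@dataclass(frozen=True)
class CohortDesign:
    """Groups x timepoints layout of a longitudinal VEP study."""

    groups: Sequence[GroupSpec]
    timepoints: Sequence[float]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort design needs at least one group")
        if 0 not in self.timepoints:
            raise ValueError("timepoints must include the baseline day 0")
        if sorted(self.timepoints) != list(self.timepoints):
            raise ValueError("timepoints must be sorted ascending")

    @property
    def n_eyes(self) -> int:
        return sum(g.n_eyes for g in self.groups)


@dataclass
class SimulatedSession:
    """One eye x day recording plus its ground truth."""

    eye_id: str
    mouse_id: str
    group: str
    day: float
    epochs: list[Epoch]
    truth_latencies_ms: dict[str, float]
    truth_pct_change: dict[str, float]


def _slug(label: str) -> str:
    return "".join(ch if ch.isalnum() else "-" for ch in label)


def iter_cohort_sessions(
    design: CohortDesign,
    base_truth: Sequence[ComponentSpec] | None = None,
    noise: NoiseSpec | None = None,
    acq: AcquisitionSpec | None = None,
) -> Iterator[SimulatedSession]:
    """Lazily generate every session of a cohort (one eye x surviving day).

    Ground-truth latency at day d is ``baseline * (1 + trajectory(d)/100)``.
    Two eyes share each mouse.  Sessions stream in deterministic order
    (group, eye, day) with per-session seeds spawned from ``design.seed``.
    """
    base_truth = list(base_truth) if base_truth is not None else list(default_components())
    noise = noise if noise is not None else NoiseSpec()
    acq = acq if acq is not None else AcquisitionSpec()
    root = np.random.SeedSequence(design.seed)
    n_sessions = sum(g.n_eyes * len(design.timepoints) for g in design.groups)
    children = iter(root.spawn(n_sessions))
    for group in design.groups:
        slug = _slug(group.label)
        for eye in range(group.n_eyes):
            eye_id = f"{slug}_e{eye:03d}"
            mouse_id = f"{slug}_m{eye // 2:03d}"
            last_day = group.dropout_day.get(eye, np.inf)
            for day in design.timepoints:
                child = next(children)  # consumed even for dropped sessions: keeps
                # the stream deterministic under any dropout pattern
                if day > last_day:
                    continue
                truth = []
                pct = {}
                for spec in base_truth:
                    delay = group.trajectory.pct(spec.name, day)
                    pct[spec.name] = delay
                    truth.append(
                        replace(spec, latency_ms=spec.latency_ms * (1.0 + delay / 100.0))
                    )
                epochs, latencies = simulate_session(truth, noise, acq, child)
                yield SimulatedSession(
                    eye_id=eye_id,
                    mouse_id=mouse_id,
                    group=group.label,
                    day=day,
                    epochs=epochs,
                    truth_latencies_ms=latencies,
                    truth_pct_change=pct,
                )


def simulate_cohort(
    design: CohortDesign,
    base_truth: Sequence[ComponentSpec] | None = None,
    noise: NoiseSpec | None = None,
    acq: AcquisitionSpec | None = None,
) -> list[SimulatedSession]:
    """Materialize a full cohort in memory (see :func:`iter_cohort_sessions`)."""
    return list(iter_cohort_sessions(design, base_truth, noise, acq))


# ---------------------------------------------------------------------------
# Premade designs mirroring the study arms
# ---------------------------------------------------------------------------


def eae_characterization_design(
    seed: int = 0,
    timepoints: Sequence[float] = (0, 7, 11, 15, 23, 37),
    early_n1_pct: float = 15.0,
    early_p2_pct: float = 15.0,
    late_pct: float = 20.0,
) -> CohortDesign:
    """Healthy / EAE-with-early-N1-delay / EAE-without arms.

    Both disease arms carry an early P2 delay; only the "with latency delay"
    arm has the early N1 delay, the other develops it after day 11.  Arm
    sizes (16 / 24 / 16 eyes) mirror the disease-characterization study.
    """
    last = float(timepoints[-1])
    early = {7.0: early_n1_pct, 11.0: early_n1_pct}
    late_only = {7.0: 0.0, 11.0: 0.0, 15.0: late_pct * 0.75}
    p2_early = {7.0: early_p2_pct, 11.0: early_p2_pct}
    if last > 15.0:  # chronic phase: all disease arms converge to the late delay
        early[last] = late_pct
        late_only[last] = late_pct
        p2_early[last] = late_pct
    return CohortDesign(
        groups=[
            GroupSpec("Healthy", 16, Trajectory.flat(), is_diseased=False),
            GroupSpec("EAE W LD", 24, Trajectory({"N1": early, "P2": p2_early})),
            GroupSpec("EAE W/O LD", 16, Trajectory({"N1": late_only, "P2": p2_early})),
        ],
        timepoints=list(timepoints),
        seed=seed,
    )


def tdcs_design(
    seed: int = 0,
    timepoints: Sequence[float] = (0, 8),
    sham_p2_pct: float = 15.0,
    sham_n1_pct: float = 12.0,
) -> CohortDesign:
    """Healthy / EAE-Sham / EAE-Anodal / EAE-Cathodal arms at the
    post-stimulation timepoint (day 8).

    Sham eyes carry the untreated disease delay in N1 and P2; anodal
    stimulation removes the P2 (intracortical) delay but not N1; cathodal
    removes both.  Arm sizes (16 / 34 / 30 / 28 eyes) mirror the treatment
    study after attrition.
    """
    day = float(timepoints[-1])
    return CohortDesign(
        groups=[
            GroupSpec("Healthy", 16, Trajectory.flat(), is_diseased=False),
            GroupSpec(
                "EAE-Sham", 34, Trajectory({"N1": {day: sham_n1_pct}, "P2": {day: sham_p2_pct}})
            ),
            GroupSpec("EAE-Anodal", 30, Trajectory({"N1": {day: sham_n1_pct}})),
            GroupSpec("EAE-Cathodal", 28, Trajectory.flat()),
        ],
        timepoints=list(timepoints),
        seed=seed,
    )
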
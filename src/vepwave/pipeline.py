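"""End-to-end orchestration: simulate -> preprocess -> mark -> endpoints -> stats -> report.

A run is fully described by a :class:`RunConfig` (serializable to YAML) plus
a seed; every artifact a stage writes is a plain CSV stamped with the config
hash and seed in a leading comment line, so a run is reproducible and
auditable from its output directory alone.  Stages communicate only through
those artifacts, which makes any stage re-runnable in isolation.

For simulation studies that never touch disk, :func:`measure_cohort` streams
synthetic sessions through preprocessing and marking and returns the marks
table together with ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .components import (
    HyperpolarizationRule,
    SearchWindows,
    VEPMarks,
    detect_components,
    mark_reproducibility,
)
from .endpoints import SessionMarks, StratificationRule, build_cohort_table, pool_groups, stratify_eyes
from .io import read_epochs, write_epochs, read_manifest, write_manifest
from .preprocess import FilterSpec, AverageTrace, apply_filters, grand_average, session_averages
from .stats import paired_measure_contrast, run_endpoint_battery
from .synthetic import (
    AcquisitionSpec,
    CohortDesign,
    ComponentSpec,
    GroupSpec,
    NoiseSpec,
    SimulatedSession,
    Trajectory,
    default_components,
    iter_cohort_sessions,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "measure_cohort", "STAGES"]

STAGES = ("simulate", "preprocess", "mark", "endpoints", "stats", "report")

MARK_COLUMNS = [
    "p1_latency",
    "n1_latency",
    "p2_latency",
    "p1_amp",
    "n1_amp",
    "p2_amp",
    "n1_p2_amplitude",
    "p1_n1_time",
    "n1_p2_time",
    "p1_p2_time",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class StatsPlan:
    """Which grouping, timepoints, measures and comparison family to test."""

    grouping: str = "stratified"  # design | stratified | pooled
    timepoints: Sequence[float] | None = None
    measures: Sequence[str] | None = None
    comparisons: Sequence[tuple[str, str]] | None = None
    pooled_labels: Sequence[str] | None = None
    paired_contrast_day: float | None = None
    paired_contrast_groups: Sequence[str] | None = None


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run (with the seed)."""

    design: CohortDesign
    base_truth: tuple[ComponentSpec, ...] = field(default_factory=default_components)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    filter: FilterSpec = field(default_factory=FilterSpec)
    windows: SearchWindows = field(default_factory=SearchWindows)
    hyperpolarization: HyperpolarizationRule = field(default_factory=HyperpolarizationRule)
    stratification: StratificationRule = field(default_factory=StratificationRule)
    stats: StatsPlan = field(default_factory=StatsPlan)
    smoothing_ms: float = 1.2
    min_prominence_fraction: float = 0.15
    min_prominence_uv: float = 0.0
    polarity: int = 1
    use_grand: bool = True
    reproducibility_tolerance_ms: float = 5.0
    seed: int = 0

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return enc(self)

    @property
    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        groups = [
            GroupSpec(
                label=g["label"],
                n_eyes=g["n_eyes"],
                trajectory=Trajectory(
                    {
                        comp: {float(day): float(p) for day, p in anchors.items()}
                        for comp, anchors in g.get("trajectory", {}).get("delays", {}).items()
                    }
                ),
                is_diseased=g.get("is_diseased", True),
                dropout_day={int(k): float(v) for k, v in g.get("dropout_day", {}).items()},
            )
            for g in d["design"]["groups"]
        ]
        design = CohortDesign(
            groups=groups,
            timepoints=[float(t) for t in d["design"]["timepoints"]],
            seed=int(d["design"].get("seed", 0)),
        )
        base_truth = tuple(
            ComponentSpec(**c) for c in d.get("base_truth", [])
        ) or default_components()

        def sub(spec_cls, key, tuple_keys=()):
            if key not in d or d[key] is None:
                return spec_cls()
            kwargs = dict(d[key])
            for tk in tuple_keys:
                if kwargs.get(tk) is not None:
                    kwargs[tk] = tuple(kwargs[tk])
            return spec_cls(**kwargs)

        stats_d = dict(d.get("stats") or {})
        if stats_d.get("comparisons"):
            stats_d["comparisons"] = [tuple(c) for c in stats_d["comparisons"]]
        return cls(
            design=design,
            base_truth=base_truth,
            acquisition=sub(AcquisitionSpec, "acquisition"),
            noise=sub(NoiseSpec, "noise"),
            filter=sub(FilterSpec, "filter"),
            windows=sub(SearchWindows, "windows", tuple_keys=("p1", "n1", "p2")),
            hyperpolarization=sub(HyperpolarizationRule, "hyperpolarization"),
            stratification=sub(StratificationRule, "stratification"),
            stats=StatsPlan(**stats_d) if stats_d else StatsPlan(),
            smoothing_ms=float(d.get("smoothing_ms", 1.2)),
            min_prominence_fraction=float(d.get("min_prominence_fraction", 0.15)),
            min_prominence_uv=float(d.get("min_prominence_uv", 0.0)),
            polarity=int(d.get("polarity", 1)),
            use_grand=bool(d.get("use_grand", True)),
            reproducibility_tolerance_ms=float(d.get("reproducibility_tolerance_ms", 5.0)),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Stamped CSV helpers
# ---------------------------------------------------------------------------


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# vepwave config={config.config_hash} seed={config.seed}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def _read_csv(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# In-memory measurement of a synthetic cohort
# ---------------------------------------------------------------------------


def _detect(trace, config: RunConfig) -> VEPMarks:
    return detect_components(
        trace,
        windows=config.windows,
        polarity=config.polarity,
        smoothing_ms=config.smoothing_ms,
        hyperpolarization=config.hyperpolarization,
        min_prominence_fraction=config.min_prominence_fraction,
        min_prominence_uv=config.min_prominence_uv,
    )


def _mark_session_epochs(epochs, config: RunConfig) -> tuple[VEPMarks, dict]:
    blocks, grand = session_averages(epochs)
    blocks = [apply_filters(b, config.filter) for b in blocks]
    grand = grand_average(blocks)  # filtering is linear: grand of filtered blocks
    target = grand if config.use_grand else blocks[0]
    marks = _detect(target, config)
    repro: dict = {}
    if len(blocks) >= 2:
        block_marks = [_detect(b, config) for b in blocks]
        repro = mark_reproducibility(block_marks, config.reproducibility_tolerance_ms)
    return marks, repro


def measure_cohort(
    config: RunConfig,
    sessions: Iterable[SimulatedSession] | None = None,
) -> tuple[list[SessionMarks], pd.DataFrame]:
    """Simulate (or accept) sessions and mark them, streaming one at a time.

    Returns the per-session marks records and a DataFrame joining detected
    latencies with the simulation ground truth.
    """
    if sessions is None:
        design = replace(config.design, seed=config.seed)
        sessions = iter_cohort_sessions(
            design, config.base_truth, config.noise, config.acquisition
        )
    records: list[SessionMarks] = []
    rows = []
    for ses in sessions:
        marks, repro = _mark_session_epochs(ses.epochs, config)
        records.append(SessionMarks(ses.eye_id, ses.mouse_id, ses.group, ses.day, marks))
        row = {
            "eye_id": ses.eye_id,
            "mouse_id": ses.mouse_id,
            "group": ses.group,
            "day": ses.day,
        }
        for col in MARK_COLUMNS:
            row[col] = getattr(marks, col)
        row["quality"] = ";".join(f"{k}={v}" for k, v in sorted(marks.quality.items()))
        for comp, rep in repro.items():
            row[f"{comp.lower()}_block_spread_ms"] = rep["spread_ms"]
        for comp, lat in ses.truth_latencies_ms.items():
            row[f"truth_{comp.lower()}_ms"] = lat
        rows.append(row)
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Disk-based stages
# ---------------------------------------------------------------------------


def _session_stem(eye_id: str, day: float) -> str:
    return f"{eye_id}_d{day:g}"


def _stage_simulate(config: RunConfig, outdir: Path) -> None:
    traces = outdir / "traces"
    traces.mkdir(parents=True, exist_ok=True)
    design = replace(config.design, seed=config.seed)
    rows = []
    for ses in iter_cohort_sessions(design, config.base_truth, config.noise, config.acquisition):
        rel = f"traces/{_session_stem(ses.eye_id, ses.day)}.csv"
        write_epochs(outdir / rel, ses.epochs)
        row = {
            "eye_id": ses.eye_id,
            "mouse_id": ses.mouse_id,
            "group": ses.group,
            "day": ses.day,
            "path": rel,
        }
        for comp, lat in ses.truth_latencies_ms.items():
            row[f"truth_{comp.lower()}_ms"] = lat
        rows.append(row)
    write_manifest(outdir / "manifest.csv", pd.DataFrame(rows))


def _stage_preprocess(config: RunConfig, outdir: Path) -> None:
    manifest = read_manifest(outdir / "manifest.csv")
    avgdir = outdir / "averages"
    avgdir.mkdir(parents=True, exist_ok=True)
    for _, row in manifest.iterrows():
        epochs = read_epochs(outdir / row["path"], format="tabular")
        blocks, _ = session_averages(epochs)
        blocks = [apply_filters(b, config.filter) for b in blocks]
        grand = grand_average(blocks)
        frames = []
        for trace in [*blocks, grand]:
            frames.append(
                pd.DataFrame(
                    {
                        "block": str(trace.block_index),
                        "n_sweeps": trace.n_sweeps,
                        "time_ms": trace.times_ms,
                        "uv": trace.samples,
                    }
                )
            )
        out = avgdir / f"{_session_stem(row['eye_id'], row['day'])}.csv"
        _write_csv(pd.concat(frames, ignore_index=True), out, config)


def _load_average(path: Path, block: str) -> AverageTrace:
    df = _read_csv(path)
    sub = df[df["block"].astype(str) == block]
    if sub.empty:
        raise ValueError(f"no block {block!r} in {path}")
    t = sub["time_ms"].to_numpy()
    fs = 1000.0 / (t[1] - t[0])
    return AverageTrace(
        samples=sub["uv"].to_numpy(),
        sampling_rate=fs,
        n_sweeps=int(sub["n_sweeps"].iloc[0]),
        block_index=block,
        t0_ms=float(t[0]),
    )


def _stage_mark(config: RunConfig, outdir: Path) -> None:
    manifest = read_manifest(outdir / "manifest.csv")
    rows = []
    for _, mrow in manifest.iterrows():
        path = outdir / "averages" / f"{_session_stem(mrow['eye_id'], mrow['day'])}.csv"
        df = _read_csv(path)
        block_labels = [b for b in df["block"].astype(str).unique()]
        target_label = "grand" if config.use_grand else block_labels[0]
        marks = _detect(_load_average(path, target_label), config)
        row = {
            "eye_id": mrow["eye_id"],
            "mouse_id": mrow["mouse_id"],
            "group": mrow["group"],
            "day": mrow["day"],
        }
        for col in MARK_COLUMNS:
            row[col] = getattr(marks, col)
        row["quality"] = ";".join(f"{k}={v}" for k, v in sorted(marks.quality.items()))
        numbered = [b for b in block_labels if b != "grand"]
        if len(numbered) >= 2:
            block_marks = [_detect(_load_average(path, b), config) for b in numbered]
            repro = mark_reproducibility(block_marks, config.reproducibility_tolerance_ms)
            for comp, rep in repro.items():
                row[f"{comp.lower()}_block_spread_ms"] = rep["spread_ms"]
        rows.append(row)
    _write_csv(pd.DataFrame(rows), outdir / "marks.csv", config)


def _marks_from_row(row: pd.Series) -> VEPMarks:
    kwargs = {}
    for col in MARK_COLUMNS:
        v = row.get(col)
        kwargs[col] = None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)
    marks = VEPMarks(**kwargs)
    q = row.get("quality")
    if isinstance(q, str) and q:
        marks.quality = dict(item.split("=", 1) for item in q.split(";"))
    return marks


def _endpoint_table(config: RunConfig, marks_df: pd.DataFrame) -> pd.DataFrame:
    records = [
        SessionMarks(
            eye_id=row["eye_id"],
            mouse_id=row["mouse_id"],
            group=row["group"],
            day=float(row["day"]),
            marks=_marks_from_row(row),
        )
        for _, row in marks_df.iterrows()
    ]
    table = build_cohort_table(records)
    diseased = [g.label for g in config.design.groups if g.is_diseased]
    if diseased and config.stratification.day in set(table["day"]):
        table = stratify_eyes(table, config.stratification, diseased_labels=diseased)
    if config.stats.pooled_labels:
        table = pool_groups(table, config.stats.pooled_labels)
    return table


def _stage_endpoints(config: RunConfig, outdir: Path) -> None:
    marks_df = _read_csv(outdir / "marks.csv")
    table = _endpoint_table(config, marks_df)
    _write_csv(table, outdir / "endpoints.csv", config)


def _grouping_column(plan: StatsPlan) -> str:
    return {
        "design": "group_design",
        "stratified": "group_stratified",
        "pooled": "group_pooled",
    }[plan.grouping]


def _stage_stats(config: RunConfig, outdir: Path) -> None:
    table = _read_csv(outdir / "endpoints.csv")
    plan = config.stats
    results = run_endpoint_battery(
        table,
        grouping=_grouping_column(plan),
        timepoints=plan.timepoints,
        measures=plan.measures,
        comparisons=plan.comparisons,
    )
    _write_csv(results, outdir / "stats.csv", config)
    payload = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "branch": "per-timepoint Kruskal-Wallis + Dunn (Bonferroni)",
        "grouping": plan.grouping,
        "results": json.loads(results.to_json(orient="records")),
    }
    if plan.paired_contrast_day is not None:
        res = paired_measure_contrast(
            table,
            day=plan.paired_contrast_day,
            groups=plan.paired_contrast_groups,
            grouping=_grouping_column(plan) if plan.paired_contrast_groups else "group_design",
        )
        payload["paired_n1_p2"] = {
            "statistic": res.statistic,
            "p_value": res.p_value,
            "n_pairs": res.n_per_group[0],
            "stars": res.stars,
        }
    with open(outdir / "stats.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def _stage_report(config: RunConfig, outdir: Path) -> None:
    from .plots import plot_group_trajectories

    table = _read_csv(outdir / "endpoints.csv")
    results = _read_csv(outdir / "stats.csv")
    figpath = outdir / "latency_change.png"
    plot_group_trajectories(
        table, results, figpath, grouping=_grouping_column(config.stats)
    )
    lines = [
        "# VEP pipeline run report",
        "",
        f"- config hash: `{config.config_hash}`",
        f"- seed: {config.seed}",
        f"- grouping: {config.stats.grouping}",
        "- statistics branch: per-timepoint Kruskal-Wallis + Dunn (Bonferroni);"
        " no repeated-measures model",
        "",
        "## Eyes per group",
        "",
    ]
    counts = (
        table[table["day"] == 0]
        .drop_duplicates("eye_id")
        .groupby(_grouping_column(config.stats))
        .size()
    )
    for label, n in counts.items():
        lines.append(f"- {label}: {n} eyes")
    lines += ["", "## Significant contrasts", ""]
    sig = results[(results["test"] == "dunn") & results["significant"]]
    if sig.empty:
        lines.append("(none)")
    else:
        for _, r in sig.iterrows():
            lines.append(
                f"- {r['measure']} day {r['day']:g}: {r['comparison']} "
                f"(p_adj={r['p_adjusted']:.4g} {r['stars']})"
            )
    (outdir / "report.md").write_text("\n".join(lines) + "\n")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "mark": _stage_mark,
    "endpoints": _stage_endpoints,
    "stats": _stage_stats,
    "report": _stage_report,
}


def run_pipeline(
    config: RunConfig,
    outdir: str | os.PathLike,
    stages: Sequence[str] | None = None,
) -> Path:
    """Execute pipeline stages in order, writing artifacts under ``outdir``.

    ``stages`` defaults to all six; any subset runs in canonical order and
    expects its prerequisites' artifacts to exist already.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chosen = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    config.to_yaml(outdir / "config.yaml")
    for stage in chosen:
        try:
            _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    meta = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "stages": chosen,
    }
    with open(outdir / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return outdir
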
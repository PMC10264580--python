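"""Group-comparison statistics for endpoint tables.

The battery mirrors standard evoked-potential practice: a D'Agostino-Pearson
omnibus normality check per group, Kruskal-Wallis across groups per measure
and timepoint with Dunn's tie-corrected post-hoc z tests (Bonferroni over the
requested comparison family), and a paired Student's t test for the
within-eye N1-vs-P2 percent-change contrast.  All tests are two-sided at
alpha = 0.05, with the conventional star notation (* <0.05 ... **** <0.0001).

Longitudinal structure is handled as independent per-timepoint comparisons
(each endpoint is already a within-eye change from baseline); no
repeated-measures model is fitted, and every result row records the branch
that produced it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "TestResult",
    "stars",
    "dagostino_pearson",
    "kruskal_wallis",
    "dunn_posthoc",
    "paired_t",
    "run_endpoint_battery",
    "paired_measure_contrast",
]

ALPHA = 0.05


def stars(p: float) -> str:
    """Significance stars: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < ALPHA:
        return "*"
    return "ns"


@dataclass
class TestResult:
    test: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    n_per_group: tuple[int, ...] = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p value outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value - 1e-12:
            raise ValueError("adjusted p smaller than raw p")

    @property
    def stars(self) -> str:
        p = self.p_value if self.p_adjusted is None else self.p_adjusted
        return stars(p)

    @property
    def significant(self) -> bool:
        p = self.p_value if self.p_adjusted is None else self.p_adjusted
        return p < ALPHA


def _clean(sample) -> np.ndarray:
    x = np.asarray(sample, dtype=float)
    return x[~np.isnan(x)]


def dagostino_pearson(sample, name: str = "sample") -> TestResult:
    """D'Agostino-Pearson K^2 omnibus normality test.

    K^2 combines the standardized skewness and kurtosis statistics and is
    referred to chi-square with 2 df; it needs n >= 8 for the kurtosis
    transformation to be defined.
    """
    x = _clean(sample)
    if x.size < 8:
        raise ValueError("insufficient n for omnibus test (need n >= 8)")
    if np.ptp(x) == 0:
        raise ValueError("normality test undefined for a constant sample")
    k2, p = sst.normaltest(x)
    return TestResult("dagostino_pearson", (name,), float(k2), float(p), n_per_group=(x.size,))


def kruskal_wallis(samples: Mapping[str, Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H across groups, with the standard tie correction."""
    groups = {k: _clean(v) for k, v in samples.items()}
    groups = {k: v for k, v in groups.items() if v.size > 0}
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two non-empty groups")
    if max(v.size for v in groups.values()) < 2:
        raise ValueError("Kruskal-Wallis needs at least one group with n >= 2")
    values = np.concatenate(list(groups.values()))
    if np.ptp(values) == 0:
        raise ValueError("Kruskal-Wallis undefined: all observations identical")
    h, p = sst.kruskal(*groups.values())
    return TestResult(
        "kruskal_wallis",
        tuple(groups),
        float(h),
        float(p),
        n_per_group=tuple(v.size for v in groups.values()),
    )


def dunn_posthoc(
    samples: Mapping[str, Sequence[float]],
    comparisons: Sequence[tuple[str, str]] | None = None,
    adjust: str = "bonferroni",
) -> list[TestResult]:
    """Dunn's post-hoc z tests on pooled ranks with tie-corrected variance.

    For groups i, j with pooled-rank means R_i, R_j over N observations,

        z = (R_i - R_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

    where T = sum(t^3 - t) over tie groups.  Two-sided p from the normal;
    Bonferroni multiplied over the requested comparison family.
    """
    groups = {k: _clean(v) for k, v in samples.items()}
    groups = {k: v for k, v in groups.items() if v.size > 0}
    if len(groups) < 2:
        raise ValueError("Dunn post-hoc needs at least two non-empty groups")
    if comparisons is None:
        names = list(groups)
        comparisons = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    pooled = np.concatenate(list(groups.values()))
    n_total = pooled.size
    ranks = sst.rankdata(pooled)
    rank_by_group: dict[str, np.ndarray] = {}
    start = 0
    for k, v in groups.items():
        rank_by_group[k] = ranks[start : start + v.size]
        start += v.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    variance_base = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        variance_base -= tie_term / (12.0 * (n_total - 1))
    if variance_base <= 0:
        raise ValueError("Dunn post-hoc undefined: all observations identical")

    m = len(comparisons)
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment: {adjust!r}")
    results = []
    for a, b in comparisons:
        if a not in groups or b not in groups:
            raise KeyError(f"comparison ({a}, {b}) references a missing group")
        na, nb = groups[a].size, groups[b].size
        z = (rank_by_group[a].mean() - rank_by_group[b].mean()) / np.sqrt(
            variance_base * (1.0 / na + 1.0 / nb)
        )
        p = 2.0 * sst.norm.sf(abs(z))
        p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
        results.append(
            TestResult(
                "dunn",
                (a, b),
                float(z),
                float(p),
                p_adjusted=float(p_adj),
                n_per_group=(na, nb),
                extra={"family_size": m},
            )
        )
    return results


def paired_t(sample_a, sample_b, names: tuple[str, str] = ("a", "b")) -> TestResult:
    """Two-sided paired Student's t test on per-subject differences."""
    a, b = np.asarray(sample_a, dtype=float), np.asarray(sample_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("paired t needs at least two complete pairs")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:  # identical samples: no evidence of a difference
            return TestResult("paired_t", names, 0.0, 1.0, n_per_group=(a.size, a.size))
        raise ValueError("paired t undefined: zero variance of differences")
    t, p = sst.ttest_rel(a, b)
    return TestResult("paired_t", names, float(t), float(p), n_per_group=(a.size, a.size))


# ---------------------------------------------------------------------------
# Battery over an endpoint table
# ---------------------------------------------------------------------------


def run_endpoint_battery(
    table: pd.DataFrame,
    grouping: str = "group_design",
    timepoints: Sequence[float] | None = None,
    measures: Sequence[str] | None = None,
    comparisons: Sequence[tuple[str, str]] | None = None,
    min_n: int = 2,
) -> pd.DataFrame:
    """Per measure x timepoint: normality gate, Kruskal-Wallis, Dunn post-hoc.

    Parameters
    ----------
    table : DataFrame
        Long endpoint table from :func:`vepwave.endpoints.build_cohort_table`
        (optionally stratified / pooled); percent changes are compared.
    grouping : str
        Column holding the group labels to compare.
    comparisons : list of (group, group), optional
        Dunn comparison family; all pairs when omitted.

    Returns a tidy results frame, one row per test, with the branch recorded
    in the ``test`` column (``normality`` rows per group, one
    ``kruskal_wallis`` omnibus row and the ``dunn`` pairwise rows per cell).
    """
    timepoints = timepoints if timepoints is not None else sorted(
        d for d in table["day"].unique() if d != 0
    )
    measures = measures if measures is not None else list(
        dict.fromkeys(table["measure"])
    )
    rows = []
    for measure in measures:
        for day in timepoints:
            cell = table[(table["measure"] == measure) & (table["day"] == day)]
            samples = {
                g: sub["pct_change"].dropna().to_numpy()
                for g, sub in cell.groupby(grouping, sort=False)
                if g != "unclassifiable"
            }
            empty = [g for g, v in samples.items() if v.size == 0]
            for g in empty:
                warnings.warn(
                    f"group {g!r} has no eyes for {measure} at day {day}; skipped"
                )
                samples.pop(g)
            if len(samples) < 2 or max(v.size for v in samples.values()) < min_n:
                continue
            for g, v in samples.items():
                if v.size >= 8 and np.ptp(v) > 0:
                    norm = dagostino_pearson(v, name=g)
                    rows.append(
                        _row(measure, day, norm, comparison=g, branch="normality")
                    )
            try:
                kw = kruskal_wallis(samples)
            except ValueError as exc:
                warnings.warn(f"{measure} day {day}: {exc}")
                continue
            rows.append(_row(measure, day, kw, comparison="omnibus", branch="kruskal_wallis"))
            family = comparisons
            if family is not None:
                family = [(a, b) for a, b in family if a in samples and b in samples]
            for res in dunn_posthoc(samples, comparisons=family):
                rows.append(
                    _row(
                        measure,
                        day,
                        res,
                        comparison=f"{res.groups[0]} vs {res.groups[1]}",
                        branch="dunn",
                    )
                )
    return pd.DataFrame(rows)


def _row(measure: str, day: float, res: TestResult, comparison: str, branch: str) -> dict:
    p_eff = res.p_value if res.p_adjusted is None else res.p_adjusted
    return {
        "measure": measure,
        "day": day,
        "test": branch,
        "comparison": comparison,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "p_adjusted": res.p_adjusted,
        "n": ",".join(str(n) for n in res.n_per_group),
        "stars": stars(p_eff),
        "significant": p_eff < ALPHA,
    }


def paired_measure_contrast(
    table: pd.DataFrame,
    measure_a: str = "N1",
    measure_b: str = "P2",
    day: float = 7.0,
    groups: Sequence[str] | None = None,
    grouping: str = "group_design",
) -> TestResult:
    """Within-eye paired t contrast of two measures' percent changes.

    The canonical use is N1 vs P2 percent latency change in pooled diseased
    eyes at an early timepoint: pairs are formed per eye, eyes missing either
    measure drop out.
    """
    cell = table[table["day"] == day]
    if groups is not None:
        cell = cell[cell[grouping].isin(list(groups))]
    wide = cell.pivot_table(
        index="eye_id", columns="measure", values="pct_change", aggfunc="first"
    )
    if measure_a not in wide.columns or measure_b not in wide.columns:
        raise ValueError(f"measures {measure_a}/{measure_b} not present at day {day}")
    return paired_t(
        wide[measure_a].to_numpy(), wide[measure_b].to_numpy(), names=(measure_a, measure_b)
    )
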
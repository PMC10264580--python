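"""Statistical battery: rank-formula oracles, calibration, battery structure."""

import numpy as np
import pandas as pd
import pytest

from vepwave import (
    dagostino_pearson,
    dunn_posthoc,
    kruskal_wallis,
    paired_t,
    run_endpoint_battery,
    paired_measure_contrast,
)
from vepwave.stats import stars


# ---------------------------------------------------------------------------
# Independent rank machinery for the oracle checks (deliberately naive).
# ---------------------------------------------------------------------------


def naive_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_kw_h(groups):
    pooled = [v for g in groups for v in g]
    ranks = naive_ranks(pooled)
    n_total = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * (sum(r) / len(g)) ** 2
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    # tie correction
    ties = 0.0
    for v in set(pooled):
        t = pooled.count(v)
        ties += t**3 - t
    return h / (1.0 - ties / (n_total**3 - n_total))


def oracle_dunn_z(groups, i, j):
    pooled = [v for g in groups for v in g]
    ranks = naive_ranks(pooled)
    n_total = len(pooled)
    means, start = [], 0
    for g in groups:
        means.append(sum(ranks[start : start + len(g)]) / len(g))
        start += len(g)
    ties = sum(pooled.count(v) ** 3 - pooled.count(v) for v in set(pooled))
    var = n_total * (n_total + 1) / 12.0 - ties / (12.0 * (n_total - 1))
    return (means[i] - means[j]) / np.sqrt(var * (1 / len(groups[i]) + 1 / len(groups[j])))


class TestNormality:
    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="insufficient n"):
            dagostino_pearson(np.arange(7))

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            dagostino_pearson(np.ones(20))

    def test_null_retention_rate(self):
        rng = np.random.default_rng(8)
        kept = sum(
            dagostino_pearson(rng.normal(size=500)).p_value > 0.05 for _ in range(100)
        )
        assert kept >= 90

    def test_power_against_heavy_tails(self):
        rng = np.random.default_rng(9)
        rejected = sum(
            dagostino_pearson(rng.standard_t(2, size=500)).p_value < 0.05
            for _ in range(100)
        )
        assert rejected >= 90


class TestKruskalWallis:
    def test_identical_groups_h_zero_p_one(self):
        res = kruskal_wallis({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_h(self):
        # H = 12/(N(N+1)) * sum n_i R_i^2 - 3(N+1) with N=9, no ties -> 7.2
        res = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        assert res.statistic == pytest.approx(7.2, abs=1e-12)

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            kruskal_wallis({"a": [5, 5], "b": [5, 5]})

    @pytest.mark.parametrize(
        "groups",
        [
            [[1, 2, 3], [4, 5, 6], [7, 8, 9]],
            [[1, 2, 2, 7], [2, 3, 4], [5, 5, 6, 8, 9]],  # ties across groups
            [[10, 12], [11, 13, 15], [9, 14, 16, 17]],
        ],
    )
    def test_h_matches_brute_force_rank_formula(self, groups):
        samples = {str(i): g for i, g in enumerate(groups)}
        assert kruskal_wallis(samples).statistic == pytest.approx(
            oracle_kw_h(groups), abs=1e-10
        )


class TestDunn:
    @pytest.mark.parametrize(
        "groups",
        [
            [[1, 2, 3], [4, 5, 6], [7, 8, 9]],
            [[1, 2, 2, 7], [2, 3, 4], [5, 5, 6, 8, 9]],
            [[3, 1, 4, 1, 5], [9, 2, 6], [5, 3, 5]],
        ],
    )
    def test_z_matches_brute_force_rank_formula(self, groups):
        samples = {str(i): g for i, g in enumerate(groups)}
        results = dunn_posthoc(samples, adjust="none")
        by_pair = {r.groups: r for r in results}
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                z = by_pair[(str(i), str(j))].statistic
                assert z == pytest.approx(oracle_dunn_z(groups, i, j), abs=1e-10)

    def test_bonferroni_adjustment_over_family(self):
        samples = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        results = dunn_posthoc(samples)
        assert all(r.extra["family_size"] == 3 for r in results)
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_value * 3))
            assert r.p_adjusted >= r.p_value

    def test_restricted_comparison_family(self):
        samples = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        results = dunn_posthoc(samples, comparisons=[("a", "b")])
        assert len(results) == 1
        assert results[0].p_adjusted == pytest.approx(results[0].p_value)


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_consistent_direction_is_significant(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=30)
        res = paired_t(a + 1.0 + rng.normal(0, 0.01, 30), a)
        assert res.p_value < 1e-6

    def test_zero_variance_nonzero_difference_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_power_monotone_in_effect_size(self):
        # endpoint-level simulation: detection rate must not fall as the
        # injected latency-delay effect grows
        rng = np.random.default_rng(11)
        n, reps = 20, 200
        power = []
        for effect in [0.0, 0.5, 1.0, 2.0]:
            hits = sum(
                paired_t(rng.normal(effect, 1, n), rng.normal(0, 1, n)).p_value < 0.05
                for _ in range(reps)
            )
            power.append(hits / reps)
        assert all(b >= a - 0.05 for a, b in zip(power, power[1:]))
        assert power[0] < 0.15 and power[-1] > 0.9


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.2, "ns"), (0.049, "*"), (0.009, "**"), (0.0009, "***"), (0.00009, "****")],
    )
    def test_convention(self, p, expected):
        assert stars(p) == expected


def endpoint_table(rng, effects, n_eyes=12, day=7.0):
    """Minimal endpoint table: pct_change ~ N(effect, 1) per group/measure."""
    rows = []
    for group, by_measure in effects.items():
        for i in range(n_eyes):
            for measure in ("P1", "N1", "P2"):
                rows.append(
                    {
                        "eye_id": f"{group}_{i}",
                        "group_design": group,
                        "group_stratified": group,
                        "day": day,
                        "measure": measure,
                        "value_ms": np.nan,
                        "pct_change": rng.normal(by_measure.get(measure, 0.0), 1.0),
                    }
                )
    return pd.DataFrame(rows)


class TestBattery:
    def test_flags_injected_effect_only(self):
        rng = np.random.default_rng(12)
        table = endpoint_table(
            rng, {"Healthy": {}, "Sham": {"P2": 10.0}, "Anodal": {}}, n_eyes=14
        )
        res = run_endpoint_battery(table, grouping="group_design")
        dunn = res[res.test == "dunn"]
        sig = dunn[dunn.significant]
        assert set(sig.measure) == {"P2"}
        assert {"Healthy vs Sham", "Sham vs Anodal"} <= set(sig.comparison)
        # normality gate recorded per group
        assert (res.test == "normality").sum() == 9

    def test_null_cohort_rarely_stars(self):
        rng = np.random.default_rng(13)
        table = endpoint_table(rng, {"a": {}, "b": {}, "c": {}}, n_eyes=16)
        res = run_endpoint_battery(table, grouping="group_design")
        dunn = res[res.test == "dunn"]
        assert dunn.significant.mean() <= 0.1

    def test_single_measure_request(self):
        rng = np.random.default_rng(14)
        table = endpoint_table(rng, {"a": {}, "b": {}})
        res = run_endpoint_battery(table, grouping="group_design", measures=["N1"])
        assert set(res.measure) == {"N1"}
        assert (res.test == "kruskal_wallis").sum() == 1

    def test_empty_group_skipped_with_warning(self):
        rng = np.random.default_rng(15)
        table = endpoint_table(rng, {"a": {}, "b": {}})
        empty = table[table.group_design == "a"].copy()
        empty["group_design"] = "ghost"
        empty["pct_change"] = np.nan
        table = pd.concat([table, empty], ignore_index=True)
        with pytest.warns(UserWarning, match="ghost"):
            res = run_endpoint_battery(table, grouping="group_design")
        assert not any("ghost" in c for c in res.comparison)

    def test_paired_contrast_on_table(self):
        rng = np.random.default_rng(16)
        table = endpoint_table(rng, {"EAE": {"P2": 2.0, "N1": 0.0}}, n_eyes=40)
        res = paired_measure_contrast(table, "N1", "P2", day=7.0, groups=["EAE"])
        assert res.p_value < 0.001
        assert res.n_per_group == (40, 40)
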
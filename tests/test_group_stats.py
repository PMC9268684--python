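"""Tests for normality-gated group statistics and post hoc corrections."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dgephys.errors import DegenerateDataError, ParameterError, SmallSampleError
from dgephys.group_stats import (
    compare_firing_by_group,
    kruskal_dunn,
    normality_gate,
    one_way_anova_bonferroni,
    two_way_anova,
)


def _grouped(rng, means, n=20, sd=1.0):
    vals = np.concatenate([rng.normal(m, sd, n) for m in means])
    labels = np.repeat([f"g{i}" for i in range(len(means))], n)
    return vals, labels


class TestNormalityGate:
    def test_small_group_routed_away(self):
        vals = np.concatenate([np.arange(5.0), np.arange(20.0)])
        labels = np.array(["a"] * 5 + ["b"] * 20)
        with pytest.raises(SmallSampleError):
            normality_gate(vals, labels)

    def test_gaussian_passes_skewed_fails(self):
        rng = np.random.default_rng(0)
        vals, labels = _grouped(rng, [0.0, 0.0], n=100)
        ps, passed = normality_gate(vals, labels)
        assert passed and all(p > 0 for p in ps.values())
        skew = np.concatenate([rng.normal(0, 1, 100), rng.exponential(1.0, 100)])
        _, passed_skew = normality_gate(skew, labels)
        assert not passed_skew

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(1)
        rejections = 0
        reps = 400
        labels = np.repeat(["a"], 100)
        for _ in range(reps):
            ps, _ = normality_gate(
                np.concatenate([rng.standard_normal(100), rng.standard_normal(100)]),
                np.array(["a"] * 100 + ["b"] * 100),
            )
            rejections += sum(p < 0.05 for p in ps.values())
        rate = rejections / (2 * reps)
        assert rate == pytest.approx(0.05, abs=0.02)
        del labels


class TestOneWayAnova:
    def test_f_matches_bruteforce_sums_of_squares(self):
        rng = np.random.default_rng(2)
        vals, labels = _grouped(rng, [0.0, 0.5, 1.0], n=12)
        res = one_way_anova_bonferroni(vals, labels)
        groups = [vals[labels == g] for g in np.unique(labels)]
        grand = vals.mean()
        ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_manual = (ssb / (len(groups) - 1)) / (ssw / (vals.size - len(groups)))
        assert res.statistic == pytest.approx(f_manual, rel=1e-10)

    def test_overwhelming_effect(self):
        rng = np.random.default_rng(3)
        vals, labels = _grouped(rng, [0.0, 5.0], n=20)
        res = one_way_anova_bonferroni(vals, labels)
        assert res.p_value < 1e-6

    def test_bonferroni_dominance(self):
        rng = np.random.default_rng(4)
        vals, labels = _grouped(rng, [0.0, 0.3, 0.6, 0.9], n=10)
        res = one_way_anova_bonferroni(vals, labels)
        assert len(res.posthoc) == 6
        for cmp_ in res.posthoc:
            assert cmp_.p_adj >= cmp_.p_raw
            assert cmp_.p_adj == pytest.approx(min(1.0, cmp_.p_raw * 6))

    def test_constant_groups_degenerate(self):
        vals = np.array([1.0] * 5 + [2.0] * 5)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.raises(DegenerateDataError):
            one_way_anova_bonferroni(vals, labels)

    def test_single_group_rejected(self):
        with pytest.raises(ParameterError):
            one_way_anova_bonferroni(np.arange(10.0), np.repeat("a", 10))


class TestKruskalDunn:
    def test_h_matches_bruteforce_ranks_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            vals = rng.integers(0, 6, size=45).astype(float)  # heavy ties
            labels = np.repeat(["a", "b", "c"], 15)
            if all(np.ptp(vals[labels == g]) == 0 for g in "abc") or np.ptp(vals) == 0:
                continue
            res = kruskal_dunn(vals, labels)
            # brute force H with tie correction
            ranks = stats.rankdata(vals)
            n = vals.size
            h = 12.0 / (n * (n + 1)) * sum(
                ranks[labels == g].sum() ** 2 / (labels == g).sum() for g in "abc"
            ) - 3 * (n + 1)
            _, counts = np.unique(vals, return_counts=True)
            h /= 1.0 - (counts**3 - counts).sum() / (n**3 - n)
            assert res.statistic == pytest.approx(h, rel=1e-10)

    def test_location_shift_power(self):
        rng = np.random.default_rng(6)
        detected = 0
        for _ in range(50):
            vals, labels = _grouped(rng, [0.0, 2.0, 0.0], n=30)
            if kruskal_dunn(vals, labels).p_value < 0.05:
                detected += 1
        assert detected >= 45

    def test_dunn_adjustment_dominates_raw(self):
        rng = np.random.default_rng(7)
        vals, labels = _grouped(rng, [0.0, 0.5, 1.0], n=15)
        res = kruskal_dunn(vals, labels)
        for cmp_ in res.posthoc:
            assert cmp_.p_adj >= cmp_.p_raw

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateDataError):
            kruskal_dunn(np.ones(20), np.repeat(["a", "b"], 10))


class TestTwoWayAnova:
    def test_balanced_design_type2_equals_classic(self):
        rng = np.random.default_rng(8)
        n = 10
        fa = np.repeat(["x", "y"], 2 * n)
        fb = np.tile(np.repeat(["u", "v"], n), 2)
        vals = rng.standard_normal(4 * n) + (fa == "y") * 1.0 + (fb == "v") * 0.5
        res = two_way_anova(vals, fa, fb)
        # classic two-way SS decomposition on a balanced design
        df = pd.DataFrame({"y": vals, "a": fa, "b": fb})
        grand = df["y"].mean()
        ss_a = sum(
            g["y"].size * (g["y"].mean() - grand) ** 2 for _, g in df.groupby("a")
        )
        cell_means = df.groupby(["a", "b"])["y"].mean()
        cell_sizes = df.groupby(["a", "b"])["y"].size()
        ss_cells = sum(
            cell_sizes[k] * (cell_means[k] - grand) ** 2 for k in cell_means.index
        )
        ss_b = sum(
            g["y"].size * (g["y"].mean() - grand) ** 2 for _, g in df.groupby("b")
        )
        ss_int = ss_cells - ss_a - ss_b
        ms_resid = ((df["y"] - df.groupby(["a", "b"])["y"].transform("mean")) ** 2).sum() / (
            4 * n - 4
        )
        f_a = (ss_a / 1) / ms_resid
        f_int = (ss_int / 1) / ms_resid
        assert res.effects["factor_a"][0] == pytest.approx(f_a, rel=1e-8)
        assert res.effects["interaction"][0] == pytest.approx(f_int, rel=1e-8)

    def test_empty_cell_rejected(self):
        fa = np.array(["x"] * 4 + ["y"] * 4)
        fb = np.array(["u"] * 4 + ["u"] * 4)  # level v never crossed with y
        with pytest.raises(ParameterError):
            two_way_anova(np.arange(8.0), fa, fb)

    def test_main_effect_power_at_moderate_n(self):
        rng = np.random.default_rng(9)
        detected = 0
        for _ in range(50):
            n = 12
            fa = np.repeat(["x", "y"], 2 * n)
            fb = np.tile(np.repeat(["u", "v"], n), 2)
            vals = rng.standard_normal(4 * n) + (fa == "y") * 1.5
            res = two_way_anova(vals, fa, fb)
            if res.effects["factor_a"][1] < 0.05:
                detected += 1
        assert detected >= 45

    def test_subject_blocking_accepted(self):
        rng = np.random.default_rng(10)
        n = 4
        fa = np.repeat(["x", "y"], 2 * n)
        fb = np.tile(np.repeat(["u", "v"], n), 2)
        subj = np.tile([f"s{i}" for i in range(n)], 4)
        vals = rng.standard_normal(4 * n)
        res = two_way_anova(vals, fa, fb, subject=subj)
        assert set(res.effects) == {"factor_a", "factor_b", "interaction"}


class TestCompareFiringByGroup:
    @staticmethod
    def _units(rng, shift=0.0, n=30):
        rows = []
        for group in ["ND", "Res", "Sus"]:
            mu = shift if group == "Sus" else 0.0
            for r in rng.normal(mu, 1.0, n):
                rows.append({"cell_class": "putative_PV", "group": group, "rate_hz": 10 + r})
        return pd.DataFrame(rows)

    def test_effect_detected_and_routed(self):
        rng = np.random.default_rng(11)
        results, tidy = compare_firing_by_group(self._units(rng, shift=1.5))
        res = results["putative_PV"]
        assert res.p_value < 0.05
        assert res.posthoc_p("ND", "Sus") < 0.05
        assert (tidy["p_adj"] >= tidy["p"] - 1e-12).all()

    def test_permuted_labels_destroy_effect(self):
        rng = np.random.default_rng(12)
        detections = 0
        for _ in range(40):
            df = self._units(rng, shift=1.5)
            df["group"] = rng.permutation(df["group"].to_numpy())
            res = compare_firing_by_group(df)[0]["putative_PV"]
            if res.p_value < 0.05 and res.posthoc_p("ND", "Sus") < 0.05:
                detections += 1
        assert detections / 40 <= 0.125  # chance level, generous margin at 40 reps

    def test_single_group_class_skipped_with_warning(self):
        rng = np.random.default_rng(13)
        df = self._units(rng)
        solo = pd.DataFrame(
            {"cell_class": "putative_granule", "group": "ND", "rate_hz": rng.normal(2, 0.5, 10)}
        )
        with pytest.warns(UserWarning, match="skipped"):
            results, _ = compare_firing_by_group(pd.concat([df, solo], ignore_index=True))
        assert "putative_granule" not in results
        assert "putative_PV" in results

    def test_small_groups_use_nonparametric_branch(self):
        rng = np.random.default_rng(14)
        rows = []
        for group in ["ND", "Sus"]:
            for r in rng.normal(0, 1, 5):
                rows.append({"cell_class": "putative_PV", "group": group, "rate_hz": 5 + r})
        results, _ = compare_firing_by_group(pd.DataFrame(rows))
        assert results["putative_PV"].test_name == "kruskal_dunn"


def test_bonferroni_pairs_cover_all_combinations():
    rng = np.random.default_rng(15)
    vals, labels = _grouped(rng, [0, 0, 0, 0], n=10)
    res = one_way_anova_bonferroni(vals, labels)
    pairs = {frozenset(c.pair) for c in res.posthoc}
    assert pairs == {frozenset(p) for p in itertools.combinations(np.unique(labels), 2)}
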
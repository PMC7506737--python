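"""Displacement-phase metrics, Spearman correlation, cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from reachkin.core_io import TrialCondition
from reachkin.metrics_stats import (
    UndefinedCorrelationError,
    aggregate_conditions,
    correlation_matrix,
    finger_flexext_metric,
    load_subject_table,
    range_of_motion,
    spearman,
    summarize_subjects,
    trunk_compensation,
)


class TestRangeOfMotion:
    def test_constant_series_is_zero(self):
        t = np.linspace(0, 2, 201)
        assert range_of_motion(t, np.full_like(t, 33.0), (0.5, 1.5)) == 0.0

    def test_sinusoid_gives_twice_amplitude(self):
        t = np.linspace(0, 2, 2001)
        a = 17.0
        rom = range_of_motion(t, a * np.sin(2 * np.pi * 3 * t), (0.0, 2.0))
        assert abs(rom - 2 * a) < 0.01

    def test_offset_invariance(self, rng):
        t = np.linspace(0, 3, 301)
        y = rng.normal(0, 10, len(t))
        r1 = range_of_motion(t, y, (0.5, 2.5))
        r2 = range_of_motion(t, y + 123.4, (0.5, 2.5))
        assert abs(r1 - r2) < 1e-9

    def test_empty_window_rejected(self):
        t = np.linspace(0, 1, 101)
        with pytest.raises(ValueError, match="window"):
            range_of_motion(t, t, (5.0, 6.0))


class TestTrunkCompensation:
    @pytest.mark.parametrize(
        "ranges, expected",
        [((6.0, 8.0, 0.0), 10.0), ((7.0, 0.0, 0.0), 7.0), ((5.0, 5.0, 5.0), 5.0 * np.sqrt(3))],
    )
    def test_closed_forms(self, ranges, expected):
        assert abs(trunk_compensation(*ranges) - expected) < 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(
        r=st.tuples(*[st.floats(0, 90) for _ in range(3)]),
        bump=st.floats(0, 30),
        axis=st.integers(0, 2),
    )
    def test_monotone_in_each_argument(self, r, bump, axis):
        bigger = list(r)
        bigger[axis] += bump
        assert trunk_compensation(*bigger) >= trunk_compensation(*r) - 1e-12

    def test_negative_range_rejected(self):
        with pytest.raises(ValueError):
            trunk_compensation(-1.0, 0.0, 0.0)


class TestFingerMetric:
    def test_mean_of_index_and_middle(self):
        assert finger_flexext_metric(80.0, 100.0) == 90.0
        assert finger_flexext_metric(42.0, 42.0) == 42.0


class TestSpearman:
    def test_monotone_relations(self, rng):
        x = rng.normal(0, 1, 30)
        rho, p = spearman(x, np.exp(x))
        assert rho == 1.0 and p < 1e-6
        rho, _ = spearman(x, -(x**3))
        assert rho == -1.0

    def test_matches_rank_pearson_oracle(self, rng):
        # 1000 random small vectors: rho must equal the Pearson correlation
        # of the rank vectors to floating-point accuracy
        for _ in range(1000):
            n = rng.integers(4, 15)
            x = rng.normal(0, 1, n)
            y = rng.normal(0, 1, n)
            if rng.random() < 0.3:  # exercise ties
                x = np.round(x)
            rho, _ = spearman(x, y, exact_below=0)
            oracle = np.corrcoef(sstats.rankdata(x), sstats.rankdata(y))[0, 1]
            assert abs(rho - oracle) < 1e-12

    def test_matches_scipy_reference(self, rng):
        x = rng.normal(0, 1, 40)
        y = x + rng.normal(0, 1, 40)
        rho, p = spearman(x, y)
        ref_rho, ref_p = sstats.spearmanr(x, y)
        assert abs(rho - ref_rho) < 1e-12
        assert abs(p - ref_p) < 1e-9

    def test_exact_permutation_small_n(self, rng):
        # n = 6: compare the permutation p-value with an independent
        # brute-force enumeration written here
        from itertools import permutations

        x = rng.normal(0, 1, 6)
        y = rng.normal(0, 1, 6)
        rho, p = spearman(x, y)
        rx = sstats.rankdata(x)
        ry = sstats.rankdata(y)
        rhos = [np.corrcoef(rx, np.asarray(ry)[list(perm)])[0, 1] for perm in permutations(range(6))]
        p_ref = np.mean(np.abs(rhos) >= abs(rho) - 1e-12)
        assert abs(p - p_ref) < 1e-12

    def test_exact_permutation_n9_matches_monte_carlo(self, rng):
        x = rng.normal(0, 1, 9)
        y = x + rng.normal(0, 2, 9)
        rho, p = spearman(x, y)
        rx, ry = sstats.rankdata(x), sstats.rankdata(y)
        draws = 20000
        hits = 0
        for _ in range(draws):
            perm = rng.permutation(9)
            r = np.corrcoef(rx, ry[perm])[0, 1]
            hits += abs(r) >= abs(rho) - 1e-12
        mc = hits / draws
        assert abs(p - mc) < 4 * np.sqrt(mc * (1 - mc) / draws) + 1e-9

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestSubjectTable:
    def test_published_summary_statistics(self):
        table = load_subject_table()
        s = summarize_subjects(table)
        cols = s["columns"]
        assert cols["fma_total"]["median"] == 33.5
        assert abs(cols["fma_total"]["mean"] - 34.7) < 1e-9
        assert cols["age_years"]["median"] == 61.5
        assert cols["months_since_stroke"]["median"] == 31.5

    def test_territory_group_means(self):
        s = summarize_subjects(load_subject_table())
        g = s["territory_groups"]
        assert g["mca_pca"]["n"] == 7
        assert abs(g["mca_pca"]["fma_total_mean"] - 32.6) < 0.05
        assert g["aca"]["n"] == 2
        assert abs(g["aca"]["fma_total_mean"] - 43.0) < 1e-9

    def test_single_row_median_equals_mean(self):
        row = load_subject_table().iloc[:1]
        s = summarize_subjects(row)
        c = s["columns"]["fma_total"]
        assert c["median"] == c["mean"] == 35.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_subjects(load_subject_table().iloc[:0])


def _metric_rows(rng, n_subjects=4, jitter=1.0):
    rows = []
    for s in range(n_subjects):
        for arm in ("AF", "NAF"):
            for block in ("BL", "BW", "BH"):
                for target in ("Tab1", "Tab2", "Top3", "Top4"):
                    for rep in (1, 2, 3):
                        c = TrialCondition(arm, block, target, rep)
                        base = 30.0 + (10.0 if arm == "AF" else 0.0) + (5.0 if c.height == "Top" else 0.0)
                        rows.append({
                            "subject": f"S{s:02d}", "arm": arm, "block": block,
                            "target": target, "height": c.height, "repetition": rep,
                            "trunk_comp": base / 4 + rng.normal(0, jitter / 2) + s,
                            "elbow_rom": base + rng.normal(0, jitter) + 2 * s,
                            "wrist_rom": base / 2 + rng.normal(0, jitter) - s,
                            "finger_rom": 2 * base + rng.normal(0, jitter) + 3 * s,
                        })
    return pd.DataFrame(rows)


class TestAggregation:
    def test_identical_trials_have_zero_spread(self, rng):
        df = _metric_rows(rng, jitter=0.0)
        for col in ("trunk_comp", "elbow_rom", "wrist_rom", "finger_rom"):
            df[col] = 10.0
        out = aggregate_conditions(df)
        for factor, table in out.factor_means.items():
            assert np.allclose(table.xs("std", axis=1, level=1).to_numpy(), 0.0)
            assert np.allclose(table.xs("mean", axis=1, level=1).to_numpy(), 10.0)

    def test_injected_effects_recovered(self, rng):
        df = _metric_rows(rng, jitter=0.5)
        out = aggregate_conditions(df)
        arm = out.factor_means["arm"]["elbow_rom"]["mean"]
        assert abs((arm["AF"] - arm["NAF"]) - 10.0) < 1.0
        height = out.factor_means["height"]["elbow_rom"]["mean"]
        assert abs((height["Top"] - height["Tab"]) - 5.0) < 1.0

    def test_self_correlation_is_unity(self, rng):
        df = _metric_rows(rng)
        cm = correlation_matrix(
            df.groupby("subject")[["elbow_rom", "finger_rom"]].median(),
            ["elbow_rom", "finger_rom"],
        )
        assert np.allclose(np.diag(cm.rho), 1.0)
        assert abs(cm.rho[0, 1]) <= 1.0

    def test_sparse_levels_rejected(self, rng):
        df = _metric_rows(rng).iloc[:3]
        with pytest.raises(ValueError, match="per"):
            aggregate_conditions(df)


class TestMixedModelWrapper:
    def test_arm_effect_estimated(self, rng):
        from reachkin.metrics_stats import fit_condition_lmm

        df = _metric_rows(rng, n_subjects=4, jitter=1.0)
        fit = fit_condition_lmm(df, metric="elbow_rom")
        # the injected AF-NAF shift is 10 deg; C(arm) is coded with AF as base
        coef = fit.params.filter(like="arm").iloc[0]
        assert abs(abs(coef) - 10.0) < 1.5
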
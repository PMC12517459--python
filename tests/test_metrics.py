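"""Tests for the evaluation statistics, each against an independent
oracle where one exists (brute-force chi-square, agreement counting,
closed-form bootstrap width)."""

import math

import numpy as np
import pytest
from scipy.special import expit

from copdgrid.metrics import (
    BootstrapCI,
    ConfusionCounts,
    ContingencyTable,
    DegenerateTableError,
    UndefinedCorrelationError,
    bootstrap_ci,
    cohen_kappa,
    confusion_metrics,
    correlations,
    events_per_variable,
    linear_trend_test,
    pearson_chi_square,
    phenotype_agreement_report,
    simulate_power,
)


class TestConfusionMetrics:
    def test_published_style_lr_from_se_and_sp(self):
        # Se 100%, Sp 94.8%: 1000-patient counts reproducing those rates
        counts = ConfusionCounts(tp=52, fp=52, tn=948, fn=0)
        m = confusion_metrics(counts)
        assert m.sensitivity == 1.0
        assert m.specificity == pytest.approx(0.948, abs=1e-9)
        assert m.lr_pos == pytest.approx(19.23, abs=0.01)

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=10, fp=0, tn=90, fn=0))
        assert m.sensitivity == 1.0 and m.specificity == 1.0
        assert m.lr_neg == 0.0 and math.isinf(m.lr_pos)
        assert m.kappa == 1.0

    def test_infinite_lr_with_partial_sensitivity(self):
        m = confusion_metrics(ConfusionCounts(tp=8, fn=2, tn=90, fp=0))
        assert m.specificity == 1.0
        assert math.isinf(m.lr_pos)
        assert m.sensitivity == pytest.approx(0.8)

    def test_undefined_ppv_is_nan_not_crash(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=90, fn=10))
        assert math.isnan(m.ppv)

    def test_infinity_serializes_as_string(self):
        m = confusion_metrics(ConfusionCounts(tp=10, fp=0, tn=90, fn=0))
        assert m.as_dict()["lr_pos"] == "inf"

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_lr_identity_where_finite(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 50, 4)
            m = confusion_metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            if math.isfinite(m.lr_pos):
                assert m.lr_pos * (1 - m.specificity) == pytest.approx(
                    m.sensitivity, abs=1e-12)


def _kappa_oracle(x, y):
    """Independent textbook kappa: explicit observed/expected agreement."""
    n = len(x)
    cats = sorted(set(x) | set(y))
    po = sum(a == b for a, b in zip(x, y)) / n
    pe = sum((sum(a == c for a in x) / n) * (sum(b == c for b in y) / n)
             for c in cats)
    return (po - pe) / (1 - pe)


class TestCohenKappa:
    def test_identical_sequences(self):
        k, p = cohen_kappa(list("AABBB"), list("AABBB"))
        assert k == 1.0 and p < 0.05

    def test_chance_level_toy(self):
        k, _ = cohen_kappa(list("AABB"), list("ABAB"))
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle_with_one_mislabel(self):
        x = ["A"] * 40 + ["B"] * 35 + ["C"] * 25
        y = list(x)
        y[10] = "B"  # single mislabeled record in n=100
        k, _ = cohen_kappa(x, y)
        assert k == pytest.approx(_kappa_oracle(x, y), abs=1e-12)
        assert k < 1.0

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        x = rng.choice(list("ABC"), 60).tolist()
        y = rng.choice(list("ABC"), 60).tolist()
        assert cohen_kappa(x, y)[0] == pytest.approx(cohen_kappa(y, x)[0], abs=1e-12)

    def test_invariant_under_label_permutation(self):
        rng = np.random.default_rng(2)
        x = rng.choice(list("ABC"), 80).tolist()
        y = rng.choice(list("ABC"), 80).tolist()
        swap = {"A": "C", "B": "A", "C": "B"}
        k1, _ = cohen_kappa(x, y)
        k2, _ = cohen_kappa([swap[v] for v in x], [swap[v] for v in y])
        assert k1 == pytest.approx(k2, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(["A"], ["A", "B"])


def _chi2_oracle(table):
    arr = np.asarray(table, dtype=float)
    n = arr.sum()
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / n
    return float(((arr - expected) ** 2 / expected).sum())


class TestPearsonChiSquare:
    @pytest.mark.parametrize(
        "table,chi2,df",
        [
            ([[15, 6], [34, 51]], 6.691, 1),
            ([[47, 6], [38, 15]], 4.810, 1),
            ([[43, 10], [11, 17], [3, 22]], 35.873, 2),
            ([[31, 22], [7, 21], [10, 15]], 8.662, 2),
        ],
    )
    def test_reference_tables(self, table, chi2, df):
        got_chi2, got_df, p = pearson_chi_square(ContingencyTable(tuple(map(tuple, table))))
        assert got_chi2 == pytest.approx(chi2, abs=0.002)
        assert got_df == df
        assert 0 < p < 1

    def test_uniform_table_has_zero_statistic(self):
        chi2, _, p = pearson_chi_square(ContingencyTable(((10, 10), (10, 10))))
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi_square(ContingencyTable(((0, 0), (5, 5))))

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(12345)
        checked = 0
        while checked < 1000:
            r = int(rng.integers(2, 5))
            c = int(rng.integers(2, 5))
            table = rng.integers(0, 30, (r, c))
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            got, _, _ = pearson_chi_square(ContingencyTable(tuple(map(tuple, table.tolist()))))
            assert got == pytest.approx(_chi2_oracle(table), abs=1e-9)
            checked += 1

    def test_two_by_two_closed_form(self):
        a, b, c, d = 15, 6, 34, 51
        n = a + b + c + d
        want = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        got, _, _ = pearson_chi_square(ContingencyTable(((a, b), (c, d))))
        assert got == pytest.approx(want, abs=1e-12)


class TestLinearTrend:
    def test_strong_monotone_trend(self):
        stat, p = linear_trend_test(
            ContingencyTable(((90, 10), (50, 50), (10, 90))))
        assert p < 0.001

    def test_equal_proportion_rows_have_zero_statistic(self):
        stat, p = linear_trend_test(
            ContingencyTable(((20, 20), (30, 30), (10, 10))))
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_row_reversal_leaves_statistic_unchanged(self):
        t1 = ((90, 10), (50, 50), (30, 70))
        t2 = tuple(reversed(t1))
        s1, _ = linear_trend_test(ContingencyTable(t1))
        s2, _ = linear_trend_test(ContingencyTable(t2))
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_needs_three_rows(self):
        with pytest.raises(ValueError):
            linear_trend_test(ContingencyTable(((1, 2), (3, 4))))

    def test_agrees_with_permutation_oracle(self):
        # small table; compare the chi2_1 p-value with a permutation p-value
        table = ((12, 4), (8, 8), (4, 12))
        stat, p = linear_trend_test(ContingencyTable(table))
        rows = np.repeat([1, 2, 3], [16, 16, 16])
        cols = np.concatenate([np.repeat([1, 2], t) for t in table])
        rng = np.random.default_rng(0)
        n = len(rows)
        obs = abs(np.corrcoef(rows, cols)[0, 1])
        hits = 0
        reps = 20000
        for _ in range(reps):
            perm = rng.permutation(cols)
            if abs(np.corrcoef(rows, perm)[0, 1]) >= obs - 1e-12:
                hits += 1
        p_perm = hits / reps
        assert p == pytest.approx(p_perm, abs=0.02)


class TestCorrelations:
    def test_perfect_linear_relation(self):
        r, _, rho, _ = correlations([1, 2, 3, 4], [3, 5, 7, 9])
        assert r == pytest.approx(1.0) and rho == pytest.approx(1.0)

    def test_monotone_nonlinear_relation(self):
        r, _, rho, _ = correlations([1, 2, 3], [1, 4, 9])
        assert rho == pytest.approx(1.0)
        assert r == pytest.approx(0.9897, abs=1e-4)
        assert r < 1.0

    def test_null_behavior_on_independent_draws(self):
        rng = np.random.default_rng(99)
        r, _, rho, _ = correlations(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(r) < 0.05 and abs(rho) < 0.05

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            correlations([1, 1, 1], [1, 2, 3])


class TestBootstrap:
    def test_constant_statistic_gives_zero_width(self):
        ci = bootstrap_ci(list(range(50)), lambda s: 7.0, iterations=100, seed=0)
        assert ci.point == ci.low == ci.high == 7.0

    def test_deterministic_given_seed(self):
        data = list(np.random.default_rng(5).normal(size=200))
        stat = lambda s: float(np.mean(s))
        c1 = bootstrap_ci(data, stat, iterations=300, seed=42)
        c2 = bootstrap_ci(data, stat, iterations=300, seed=42)
        assert (c1.low, c1.high) == (c2.low, c2.high)

    def test_width_matches_closed_form_for_normal_mean(self):
        rng = np.random.default_rng(8)
        data = list(rng.normal(size=1000))
        ci = bootstrap_ci(data, lambda s: float(np.mean(s)),
                          iterations=1000, seed=3)
        want = 2 * 1.96 / math.sqrt(1000)
        assert abs((ci.high - ci.low) - want) / want < 0.20

    def test_failing_statistic_skipped_and_counted(self):
        calls = {"n": 0}

        def flaky(sample):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("boom")
            return float(np.mean(sample))

        ci = bootstrap_ci(list(range(20)), flaky, iterations=99, seed=1)
        assert ci.failures > 0

    def test_coverage_for_normal_mean(self):
        # meta-test: percentile CI for the mean of a known normal should
        # cover the truth close to nominally
        rng = np.random.default_rng(2024)
        n, covered, outer = 500, 0, 300
        for i in range(outer):
            data = list(rng.normal(size=n))
            ci = bootstrap_ci(data, lambda s: float(np.mean(s)),
                              iterations=500, seed=int(rng.integers(2**31 - 1)))
            covered += ci.low <= 0.0 <= ci.high
        assert abs(covered / outer - 0.95) <= 0.02


class TestPower:
    def test_null_power_matches_alpha(self):
        res = simulate_power((0.0, 0.0, 0.0), n=106, reps=500, alpha=0.05, seed=1)
        assert abs(res.power - 0.05) <= 3 * math.sqrt(0.05 * 0.95 / 500)

    def test_saturating_effect(self):
        res = simulate_power((-8.0, 5.0, 5.0), n=500, reps=200, seed=2)
        assert res.power > 0.99

    def test_deterministic_given_seed(self):
        r1 = simulate_power((-2.0, 0.4, 0.8), n=106, reps=200, seed=7)
        r2 = simulate_power((-2.0, 0.4, 0.8), n=106, reps=200, seed=7)
        assert r1 == r2

    def test_monotone_in_effect_and_sample_size(self):
        powers_effect = [
            simulate_power((-2.0, s, 2 * s), n=150, reps=300, seed=11).power
            for s in (0.05, 0.25, 1.0)
        ]
        assert powers_effect == sorted(powers_effect)
        powers_n = [
            simulate_power((-2.0, 0.15, 0.3), n=n, reps=300, seed=13).power
            for n in (40, 150, 600)
        ]
        assert powers_n == sorted(powers_n)

    def test_degenerate_generator_rejected(self):
        with pytest.raises(ValueError):
            simulate_power((80.0, 0.0, 0.0), n=50, reps=10, seed=0)


class TestAgreementReport:
    def test_identical_labels_are_perfect(self):
        labels = ["A0/B0"] * 50 + ["A1/B1"] * 30 + ["E"] * 20
        table, kappa, _ = phenotype_agreement_report(labels, labels)
        assert kappa == 1.0
        assert (table["accuracy"] == 1.0).all()

    def test_published_style_row_lr(self):
        # one-vs-rest counts giving Se 44%, Sp 96.3% for label E in n=106
        ref = ["E"] * 25 + ["other"] * 81
        pred = (["E"] * 11 + ["other"] * 14) + (["E"] * 3 + ["other"] * 78)
        table, _, _ = phenotype_agreement_report(pred, ref, labels=["E", "other"])
        row = table[table["label"] == "E"].iloc[0]
        assert row["sensitivity"] == pytest.approx(0.44, abs=1e-9)
        assert row["specificity"] == pytest.approx(0.963, abs=5e-4)
        assert row["lr_pos"] == pytest.approx(11.9, abs=0.05)

    def test_absent_label_marked_not_estimable(self):
        table, _, _ = phenotype_agreement_report(
            ["A", "A"], ["A", "B"], labels=["A", "B", "C"])
        assert not table[table["label"] == "C"]["estimable"].iloc[0]

    def test_single_mislabel_drops_kappa_to_oracle_value(self):
        x = ["A"] * 60 + ["B"] * 40
        y = list(x)
        y[0] = "B"
        _, kappa, _ = phenotype_agreement_report(x, y)
        assert kappa == pytest.approx(_kappa_oracle(x, y), abs=1e-12)
        assert kappa < 1.0


class TestEventsPerVariable:
    @pytest.mark.parametrize(
        "args,want",
        [
            ((106, 0.80, 0.557, 2), 23.5),
            ((100, 1.0, 0.5, 2), 25.0),
            ((106, 0.80, 0.557, 4), 11.75),
        ],
    )
    def test_examples(self, args, want):
        assert events_per_variable(*args) == want

    def test_zero_predictors_rejected(self):
        with pytest.raises(ValueError):
            events_per_variable(106, 0.8, 0.5, 0)
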
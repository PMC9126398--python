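import itertools

import numpy as np
import pandas as pd
import pytest

from adcroi.agreement import (
    AgreementStudy,
    bland_altman_multireader,
    friedman_across_methods,
    holm_adjust,
    icc_vs_reference,
    posthoc_pairwise,
    unpaired_group_test,
)


def make_table(values):
    """values: dict (lesion, reader) -> adc for a single session."""
    rows = [
        {"lesion_id": l, "reader_id": r, "session": 1, "adc_value": v}
        for (l, r), v in values.items()
    ]
    return pd.DataFrame(rows)


def anova_icc_oracle(x, y):
    """Shrout-Fleiss single-measure ICCs from two-way ANOVA mean squares,
    computed directly from the defining formulas (independent of pingouin)."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc2 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icc3 = (msr - mse) / (msr + (k - 1) * mse)
    return icc2, icc3


class TestBlandAltman:
    def test_identical_readers_zero_loa(self):
        vals = {(l, r): 1000.0 + 10 * l for l in range(4) for r in range(3)}
        res = bland_altman_multireader(make_table(vals), 1)
        assert res.loa_half_width == pytest.approx(0.0)
        assert res.bias == pytest.approx(0.0)

    def test_hand_calculation_two_by_two(self):
        vals = {(0, "a"): 10.0, (0, "b"): 20.0, (1, "a"): 30.0, (1, "b"): 30.0}
        res = bland_altman_multireader(make_table(vals), 1)
        # differences from lesion means: {-5, +5, 0, 0}; sample SD =
        # sqrt(50/3); LoA = 1.96 x SD
        sd = np.sqrt(50.0 / 3.0)
        assert res.sd_diff == pytest.approx(sd)
        assert res.loa_half_width == pytest.approx(1.96 * sd)
        assert sorted(res.deviations["diff"]) == pytest.approx([-5.0, 0.0, 0.0, 5.0])

    def test_incomplete_block_names_missing_cell(self):
        vals = {(0, "a"): 10.0, (0, "b"): 20.0, (1, "a"): 30.0}
        with pytest.raises(ValueError, match="missing"):
            bland_altman_multireader(make_table(vals), 1)

    def test_invariances(self, rng):
        vals = {
            (l, r): float(rng.uniform(500, 1500))
            for l in range(6)
            for r in ("a", "b", "c")
        }
        base = bland_altman_multireader(make_table(vals), 1).loa_half_width
        shifted = {k: v + 250.0 for k, v in vals.items()}
        scaled = {k: v * 3.0 for k, v in vals.items()}
        relabeled = {(l, {"a": "c", "b": "a", "c": "b"}[r]): v for (l, r), v in vals.items()}
        assert bland_altman_multireader(make_table(shifted), 1).loa_half_width == pytest.approx(base)
        assert bland_altman_multireader(make_table(scaled), 1).loa_half_width == pytest.approx(3.0 * base)
        assert bland_altman_multireader(make_table(relabeled), 1).loa_half_width == pytest.approx(base)

    def test_ddof_conventions_differ_slightly(self, rng):
        vals = {(l, r): float(rng.uniform(500, 1500)) for l in range(20) for r in range(3)}
        r1 = bland_altman_multireader(make_table(vals), 1, ddof=1)
        r0 = bland_altman_multireader(make_table(vals), 1, ddof=0)
        assert r0.sd_diff < r1.sd_diff
        assert r0.sd_diff == pytest.approx(r1.sd_diff, rel=0.02)


class TestICC:
    def test_perfect_agreement(self):
        x = [600.0, 700.0, 800.0, 900.0]
        res = icc_vs_reference(x, x)
        assert res.estimate == pytest.approx(1.0)

    def test_absolute_agreement_penalizes_fixed_bias(self, rng):
        ref = rng.normal(800.0, 100.0, size=40)
        reader = ref + 50.0
        abs_icc = icc_vs_reference(reader, ref, model="ICC2").estimate
        cons_icc = icc_vs_reference(reader, ref, model="ICC3").estimate
        assert abs_icc < cons_icc
        assert cons_icc == pytest.approx(1.0)

    def test_matches_anova_oracle(self, rng):
        ref = rng.normal(800.0, 150.0, size=30)
        reader = ref + rng.normal(40.0, 60.0, size=30)
        o2, o3 = anova_icc_oracle(reader, ref)
        assert icc_vs_reference(reader, ref, model="ICC2").estimate == pytest.approx(o2, rel=1e-6)
        assert icc_vs_reference(reader, ref, model="ICC3").estimate == pytest.approx(o3, rel=1e-6)

    def test_ci_brackets_estimate(self, rng):
        ref = rng.normal(800.0, 150.0, size=25)
        reader = ref + rng.normal(0.0, 80.0, size=25)
        res = icc_vs_reference(reader, ref)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_consistency_affine_invariance(self, rng):
        ref = rng.normal(800.0, 150.0, size=25)
        reader = ref + rng.normal(0.0, 60.0, size=25)
        base = icc_vs_reference(reader, ref, model="ICC3").estimate
        trans = icc_vs_reference(2.0 * reader + 100.0, 2.0 * ref + 100.0, model="ICC3").estimate
        assert trans == pytest.approx(base, rel=1e-9)
        # absolute form: invariant to a joint shift only
        a2 = icc_vs_reference(reader + 300.0, ref + 300.0, model="ICC2").estimate
        assert a2 == pytest.approx(icc_vs_reference(reader, ref, model="ICC2").estimate, rel=1e-9)

    def test_too_few_lesions_rejected(self):
        with pytest.raises(ValueError):
            icc_vs_reference([1.0, 2.0], [1.0, 2.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_vs_reference([5.0] * 10, [5.0] * 10)


def deviation_frame(columns):
    """columns: dict session -> list of per-block deviations."""
    rows = []
    for session, vals in columns.items():
        for block, v in enumerate(vals):
            rows.append({"block_id": block, "session": session, "abs_dev": float(v)})
    return pd.DataFrame(rows)


class TestFriedman:
    def test_identical_columns_zero_statistic(self):
        col = [1.0, 2.0, 3.0, 4.0]
        stat, p = friedman_across_methods(deviation_frame({1: col, 2: col, 3: col}))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_ordering_closed_form(self):
        # k=3 methods, n=4 blocks, strict ordering in every block:
        # chi2 = 12n/(k(k+1)) * sum (R_j - n(k+1)/2)^2 / n ... = 8.0
        df = deviation_frame({1: [1, 1, 1, 1], 2: [2, 2, 2, 2], 3: [3, 3, 3, 3]})
        stat, p = friedman_across_methods(df)
        assert stat == pytest.approx(8.0)

    def test_incomplete_blocks_rejected(self):
        df = deviation_frame({1: [1, 2], 2: [3, 4], 3: [5, 6]}).drop(index=5)
        with pytest.raises(ValueError):
            friedman_across_methods(df)


class TestPosthoc:
    def test_identical_columns_all_one(self):
        col = [1.0, 2.0, 3.0, 4.0, 5.0]
        out = posthoc_pairwise(deviation_frame({1: col, 2: col, 3: col}))
        assert np.allclose(out["p_holm"], 1.0)

    def test_holm_stepdown_hand_oracle(self):
        # raw {0.01, 0.04, 0.03}: sorted (0.01, 0.03, 0.04) multiply by
        # (3, 2, 1) -> (0.03, 0.06, 0.04), enforce monotonicity from the
        # smallest up -> (0.03, 0.06, 0.06)
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_holm_monotone_and_dominates_raw(self, rng):
        raw = rng.uniform(0, 1, size=6)
        adj = holm_adjust(raw)
        assert np.all(adj >= raw - 1e-15)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_signed_rank_flavor_runs(self, rng):
        a = rng.uniform(0, 1, 12)
        df = deviation_frame({1: a, 2: a + 0.3, 3: a + rng.normal(0, 0.05, 12)})
        out = posthoc_pairwise(df, flavor="signed_rank")
        assert len(out) == 3
        assert ((out["p_holm"] >= 0) & (out["p_holm"] <= 1)).all()


class TestGroupTest:
    def test_identical_groups(self):
        t, p, ma, mb = unpaired_group_test([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_welch_closed_form(self):
        t, p, ma, mb = unpaired_group_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        # means 2 and 5, each variance 1: t = -3 / sqrt(2/3)
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-9)
        assert (ma, mb) == (2.0, 5.0)

    def test_student_option(self):
        # unequal n and unequal variance: the two flavors genuinely differ
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 7.0, 9.0, 12.0]
        t_w, *_ = unpaired_group_test(a, b)
        t_s, *_ = unpaired_group_test(a, b, equal_var=True)
        assert t_w != t_s

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            unpaired_group_test([1.0], [2.0, 3.0])


@pytest.fixture(scope="module")
def study_tables():
    from adcroi import run_virtual_study

    return run_virtual_study(n_lesions=10, n_readers=4, seed=11)


class TestAgreementStudy:
    def test_fit_produces_all_sections(self, study_tables):
        meas, ref = study_tables
        res = AgreementStudy(meas, reference=ref).fit()
        assert set(res.loa) == {1, 2, 3}
        assert len(res.posthoc) == 3
        assert res.icc is not None and len(res.icc) == 3 * 4
        lo, hi = res.icc_range(2)
        assert -1.0 <= lo <= hi <= 1.0

    def test_summary_mentions_all_sessions(self, study_tables):
        meas, ref = study_tables
        text = AgreementStudy(meas, reference=ref).fit().summary()
        for s in ("session 1", "session 2", "session 3", "Friedman"):
            assert s in text

    def test_to_dict_schema(self, study_tables):
        meas, ref = study_tables
        d = AgreementStudy(meas, reference=ref).fit().to_dict()
        assert {"loa", "friedman", "posthoc", "icc"} <= set(d)

    def test_lesion_block_option(self, study_tables):
        meas, ref = study_tables
        res = AgreementStudy(meas, friedman_block="lesion").fit()
        assert np.isfinite(res.friedman_stat)
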
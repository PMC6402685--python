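"""Cross-validation curves and the statistical battery vs independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cvep.evaluate import (
    bonferroni_posthoc,
    compare_decoders,
    kfold_accuracy,
    paired_t,
    printed_epoch_duration_s,
    printed_time_grid,
    rm_anova_gg,
    wilcoxon_signed_rank,
)

TABLE_TIMES = [0.344, 0.68, 1.03, 1.37, 1.72, 2.06, 2.40, 2.75, 3.09,
               3.44, 3.78, 4.12, 4.47, 4.81, 5.16, 5.50, 5.84, 6.19]


def signed_rank_p_oracle(d):
    """Exact two-sided signed-rank p by enumerating all sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    mean = n * (n + 1) / 4
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if abs(w - mean) >= abs(w_obs - mean) - 1e-12:
            count += 1
    return count / 2**n


def rm_anova_ss_oracle(scores):
    """One-way repeated-measures ANOVA from explicit sums of squares,
    with the Greenhouse-Geisser epsilon from the condition covariance."""
    y = np.asarray(scores, dtype=float)
    s, c = y.shape
    grand = y.mean()
    ss_cond = s * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = c * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = c - 1, (c - 1) * (s - 1)
    F = (ss_cond / df1) / (ss_err / df2)
    S = np.cov(y, rowvar=False, ddof=1)
    C = np.eye(c) - np.ones((c, c)) / c  # double-centering projector
    T = C @ S @ C
    eps = np.trace(T) ** 2 / ((c - 1) * np.trace(T @ T))
    from scipy.stats import f as fdist

    p = fdist.sf(F, df1 * eps, df2 * eps)
    return F, eps, p


class TestTimingArithmetic:
    def test_printed_epoch_duration(self):
        assert printed_epoch_duration_s() == 0.344

    def test_time_grid_matches_tabulated_values(self):
        np.testing.assert_allclose(printed_time_grid(), TABLE_TIMES, atol=1e-9)

    def test_exact_durations(self):
        assert 31 / 90 == pytest.approx(0.34444, abs=1e-4)
        assert 18 * 31 / 90 == pytest.approx(6.2, abs=1e-12)


class TestKFold:
    def test_noiseless_study_is_perfect_for_both_decoders(self, noiseless_study):
        for decoder in ("cca", "stb"):
            curve = kfold_accuracy(noiseless_study, decoder=decoder, k=10,
                                   epochs_used=[1, 9, 18], seed=0)
            np.testing.assert_allclose(curve.fold_accuracies, 100.0)

    def test_fold_partition_and_determinism(self, sim_study):
        c1 = kfold_accuracy(sim_study, decoder="stb", k=10, epochs_used=[18], seed=3)
        c2 = kfold_accuracy(sim_study, decoder="stb", k=10, epochs_used=[18], seed=3)
        np.testing.assert_array_equal(c1.fold_accuracies, c2.fold_accuracies)
        assert c1.fold_accuracies.shape == (10, 1)

    def test_stimulation_time_axis(self, sim_study):
        curve = kfold_accuracy(sim_study, decoder="stb", k=10, epochs_used=range(1, 19))
        assert curve.stimulation_time_s[-1] == pytest.approx(6.2, abs=0.01)
        assert np.all(np.diff(curve.stimulation_time_s) > 0)

    def test_too_many_folds_rejected(self, sim_study):
        with pytest.raises(ValueError, match="folds"):
            kfold_accuracy(sim_study, k=20)

    def test_high_snr_cca_and_stb_agree(self, noiseless_study):
        from cvep.decode_cca import build_templates, identify_cca
        from cvep.decode_stb import build_beamformers, identify_stb
        from cvep.preproc import EpochArray

        labels = list(noiseless_study)
        train = {
            lab: np.concatenate([t.data for t in noiseless_study[lab][:9]])
            for lab in labels
        }
        fs = 540.0
        ts = build_templates(train, fs_hz=fs)
        bf = build_beamformers(train, shrinkage=0.05, fs_hz=fs)
        for true_i, lab in enumerate(labels, start=1):
            trial = noiseless_study[lab][9]
            p_cca, _ = identify_cca(trial, ts)
            p_stb, _ = identify_stb(trial, bf)
            assert p_cca == p_stb == true_i


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0
        assert "degenerate" in res.extra

    def test_five_one_sided_differences_exact_p(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], [0, 1, 2, 3, 4])
        assert res.p_value == pytest.approx(0.0625, abs=1e-12)

    def test_matches_enumeration_oracle_on_random_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(5, 11)
            a = rng.normal(size=n)
            b = a + rng.normal(scale=0.8, size=n)
            res = wilcoxon_signed_rank(a, b)
            assert res.p_value == pytest.approx(signed_rank_p_oracle(a - b), abs=1e-9)

    def test_z_is_negative_when_b_larger(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=30)
        res = wilcoxon_signed_rank(a, a + 1.0)
        assert res.statistic < 0


class TestPairedT:
    def test_hand_computed_example(self):
        res = paired_t([0.0, 0.0, 1.0], [1.0, 1.0, 0.0])
        assert res.statistic == pytest.approx(-0.5, abs=1e-12)
        assert res.df == (2,)

    def test_identical_samples(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_constant_shift_flagged_infinite(self):
        res = paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        assert math.isinf(res.statistic)
        assert "degenerate" in res.extra

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 25))
        from scipy.stats import ttest_rel

        res = paired_t(a, b)
        ref = ttest_rel(a, b)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)


class TestRMAnova:
    def test_two_conditions_equal_paired_t_squared(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(5, 1, size=(12, 2))
        aov = rm_anova_gg(scores)
        t = paired_t(scores[:, 0], scores[:, 1])
        assert aov.statistic == pytest.approx(t.statistic**2, abs=1e-9)
        assert aov.extra["epsilon"] == pytest.approx(1.0, abs=1e-9)

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(4)
        scores = rng.integers(0, 10, size=(6, 4)).astype(float)
        aov = rm_anova_gg(scores)
        F, eps, p = rm_anova_ss_oracle(scores)
        assert aov.statistic == pytest.approx(F, abs=1e-6)
        assert aov.extra["epsilon"] == pytest.approx(eps, abs=1e-6)
        assert aov.p_value == pytest.approx(p, abs=1e-6)

    def test_missing_cells_rejected(self):
        scores = pd.DataFrame(np.ones((5, 3)))
        scores.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_gg(scores)


class TestBonferroniPosthoc:
    def test_six_pairs_at_corrected_alpha(self):
        rng = np.random.default_rng(5)
        scores = pd.DataFrame(rng.normal(5, 2, size=(20, 4)), columns=list("ABCD"))
        results = bonferroni_posthoc(scores)
        assert len(results) == 6
        assert all(r.alpha == 0.008 for r in results)
        assert {r.extra["pair"] for r in results} == {
            ("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")
        }

    def test_familywise_error_controlled_under_null(self):
        rng = np.random.default_rng(6)
        fw_errors = 0
        n_sims = 500
        for _ in range(n_sims):
            scores = rng.normal(5, 2, size=(44, 4)) + rng.normal(0, 2, size=(44, 1))
            results = bonferroni_posthoc(scores)
            fw_errors += any(r.significant for r in results)
        assert fw_errors / n_sims <= 0.08  # nominal <= 0.047 plus MC slack


class TestCompareDecoders:
    def test_identical_curves_give_p_one(self):
        curves = np.tile(np.linspace(40, 100, 18), (8, 1))
        table = compare_decoders(curves, curves)
        assert len(table) == 18
        assert np.all(table["p_value"] == 1.0)

    def test_row_grid_and_printed_times(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(50, 100, size=(10, 18))
        table = compare_decoders(a, a + rng.uniform(0, 5, size=a.shape))
        assert table["epochs_used"].tolist() == list(range(1, 19))
        assert table.loc[table.epochs_used == 10, "stimulation_time_s"].item() == 3.44
        assert table.loc[table.epochs_used == 18, "stimulation_time_s"].item() == 6.19

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="share shape"):
            compare_decoders(np.zeros((5, 18)), np.zeros((5, 17)))
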
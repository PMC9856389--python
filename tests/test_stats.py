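import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fcmst import (
    InvalidParameterError,
    UndefinedEffectError,
    chi_square_counts,
    cohens_d,
    cohens_d_from_summary,
    fdr_adjust,
    ttest_from_summary,
    ttest_two_sample,
    within_subjects_anova,
)


def long_table(y, measures=("PLI", "PLV"), metrics=None):
    """Build the long-format ANOVA table from a (subjects, measures, metrics) cube."""
    n, a, b = y.shape
    metrics = metrics or [f"m{k}" for k in range(b)]
    rows = [
        {
            "subject_id": f"s{s}",
            "measure": measures[i],
            "metric": metrics[k],
            "value": y[s, i, k],
        }
        for s in range(n)
        for i in range(a)
        for k in range(b)
    ]
    return pd.DataFrame(rows)


class TestTTest:
    def test_published_demographics_row(self):
        # age 21.10 (1.80) vs 21.20 (1.96), n = 20 per group
        _, p = ttest_from_summary(21.10, 1.80, 20, 21.20, 1.96, 20)
        assert round(p, 3) == 0.867

    def test_identical_groups(self):
        t, p = ttest_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_unit_effect_closed_form(self):
        # means 0/1, SDs 1/1, n=20 each: t = -1 / sqrt(2/20)
        t, p = ttest_from_summary(0, 1, 20, 1, 1, 20)
        assert t == pytest.approx(-np.sqrt(10), abs=1e-4)
        assert p == pytest.approx(2 * sps.t.sf(np.sqrt(10), 38), abs=1e-12)
        assert p == pytest.approx(0.0031, abs=2e-4)

    def test_raw_and_summary_paths_agree(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 30))
            b = rng.normal(loc=0.3, size=rng.integers(2, 30))
            t1, p1 = ttest_two_sample(a, b)
            t2, p2 = ttest_from_summary(
                a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
            )
            assert t1 == pytest.approx(t2, abs=1e-12)
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_degenerate_variance(self):
        t, p = ttest_two_sample([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        with pytest.raises(InvalidParameterError):
            ttest_two_sample([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(InvalidParameterError):
            ttest_two_sample([1.0], [1.0, 2.0])


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d([1, 2, 3], [3, 2, 1]) == pytest.approx(0.0)

    def test_unit_effect(self):
        assert abs(cohens_d_from_summary(0, 1, 20, 1, 1, 20)) == pytest.approx(1.0)

    def test_scale_property(self):
        d1 = cohens_d_from_summary(0, 1, 20, 1, 1, 20)
        d2 = cohens_d_from_summary(0, 2, 20, 1, 2, 20)
        assert d2 == pytest.approx(d1 / 2)

    def test_sign_matches_mean_difference(self, rng):
        a = rng.normal(loc=1.0, size=20)
        b = rng.normal(loc=0.0, size=20)
        assert np.sign(cohens_d(a, b)) == np.sign(a.mean() - b.mean())

    def test_zero_pooled_sd_undefined(self):
        with pytest.raises(UndefinedEffectError):
            cohens_d_from_summary(0, 0, 20, 1, 0, 20)


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03]) == pytest.approx([0.03])

    def test_two_p_hand_stepup(self):
        assert fdr_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_order_invariance(self, rng):
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        assert np.allclose(fdr_adjust(p)[perm], fdr_adjust(p[perm]))

    def test_never_decreases(self, rng):
        p = rng.uniform(size=50)
        assert (fdr_adjust(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            fdr_adjust([0.1, 1.2])


def test_chi_square_balanced_table_is_flat():
    chi2, p = chi_square_counts([[10, 10], [10, 10]])
    assert chi2 == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


class TestWithinSubjectsAnova:
    def test_identical_measures_give_zero_f(self, rng):
        vals = rng.normal(size=(10, 1, 4))
        y = np.concatenate([vals, vals], axis=1)  # PLI column == PLV column
        res = within_subjects_anova(long_table(y))
        eff = res.effects["measure"]
        assert eff.F == pytest.approx(0.0)
        assert eff.partial_eta_sq == pytest.approx(0.0)
        assert (res.posthoc["p"] == 1.0).all()

    def test_two_level_factor_equals_paired_t(self, rng):
        """Classical equivalence: F(1, n-1) for a two-level within factor
        is the square of the paired t statistic, with identical p."""
        y = rng.normal(size=(12, 2, 1))
        res = within_subjects_anova(long_table(y), zscore_metrics=False)
        t, p = sps.ttest_rel(y[:, 0, 0], y[:, 1, 0])
        eff = res.effects["measure"]
        assert eff.F == pytest.approx(t**2, rel=1e-10)
        assert eff.p == pytest.approx(p, rel=1e-10)
        assert "metric" not in res.effects  # single metric: no such term

    def test_affine_invariance_with_zscoring(self, rng):
        y = rng.normal(size=(9, 2, 5))
        base = within_subjects_anova(long_table(y))
        y2 = y.copy()
        y2[:, :, 2] = 100.0 + 7.5 * y2[:, :, 2]  # rescale one metric
        moved = within_subjects_anova(long_table(y2))
        for name in ("measure", "metric", "measure:metric"):
            assert moved.effects[name].F == pytest.approx(
                base.effects[name].F, rel=1e-8
            )

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(size=(8, 2, 3)) + rng.normal(size=(8, 1, 1))
        table = long_table(y)
        ours = within_subjects_anova(table, zscore_metrics=False)
        theirs = pg.rm_anova(
            data=table, dv="value", within=["measure", "metric"],
            subject="subject_id", detailed=True,
        ).set_index("Source")
        pairs = {
            "measure": "measure",
            "metric": "metric",
            "measure:metric": "measure * metric",
        }
        for ours_name, pg_name in pairs.items():
            assert ours.effects[ours_name].F == pytest.approx(
                float(theirs.loc[pg_name, "F"]), rel=1e-8
            )
            assert ours.effects[ours_name].p == pytest.approx(
                float(theirs.loc[pg_name, "p_unc"]), rel=1e-6
            )

    def test_partial_eta_sq_recovery(self, rng):
        """Estimated eta_p^2 recovers its generating value at n = 20.

        Paired design y_i1 = s_i + e_i1, y_i2 = s_i + tau + e_i2; the
        generating value is E[SS_eff] / (E[SS_eff] + E[SS_err]) with
        E[SS_eff] = n tau^2 / 2 + sigma^2 and E[SS_err] = (n-1) sigma^2.
        """
        n, tau, sigma = 20, 0.8, 1.0
        expected_ss_eff = n * tau**2 / 2 + sigma**2
        expected_ss_err = (n - 1) * sigma**2
        target = expected_ss_eff / (expected_ss_eff + expected_ss_err)
        estimates = []
        for _ in range(100):
            subj = rng.normal(size=(n, 1, 1))
            y = subj + rng.normal(scale=sigma, size=(n, 2, 1))
            y[:, 1, :] += tau
            res = within_subjects_anova(long_table(y), zscore_metrics=False)
            estimates.append(res.effects["measure"].partial_eta_sq)
        assert np.mean(estimates) == pytest.approx(target, abs=0.05)

    def test_posthoc_bonferroni_capped(self, rng):
        y = rng.normal(size=(6, 2, 4))
        res = within_subjects_anova(long_table(y))
        assert len(res.posthoc) == 4
        assert (res.posthoc["p_bonferroni"] <= 1.0).all()
        assert np.allclose(
            np.minimum(1.0, res.posthoc["p"] * 4), res.posthoc["p_bonferroni"]
        )

    def test_missing_cell_rejected(self, rng):
        table = long_table(rng.normal(size=(5, 2, 3)))
        broken = table.drop(table.index[3])
        with pytest.raises(InvalidParameterError, match="missing"):
            within_subjects_anova(broken)
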
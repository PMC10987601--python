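"""Differential statistics: normalization, moderated t, NB Wald, BH."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cosmotherm.config import Config
from cosmotherm.diffstats import (bh_adjust, call_significant,
                                  correct_phospho_for_protein, fit_f_dist,
                                  moderated_ttest, nb_wald_test,
                                  quantile_normalize, size_factors)
from conftest import make_matrix


class TestQuantileNormalize:
    def test_two_column_reference(self):
        # columns [1,2,3] and [4,5,6]: row means of sorted columns
        m = make_matrix(np.array([[1, 4], [2, 5], [3, 6]]).astype(float),
                        n_t=1)
        out = quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out[:, 1], [2.5, 3.5, 4.5])

    def test_identical_columns_fixed_point(self):
        vals = np.tile(np.array([[3.0], [1.0], [7.0]]), (1, 4))
        m = make_matrix(vals)
        np.testing.assert_allclose(quantile_normalize(m).values, vals)

    def test_column_multisets_identical(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(40, 6)))
        out = quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_missing_values_stay_missing(self):
        vals = np.arange(24, dtype=float).reshape(6, 4)
        vals[2, 1] = np.nan
        out = quantile_normalize(make_matrix(vals)).values.to_numpy()
        assert np.isnan(out[2, 1]) and np.isfinite(out).sum() == 23

    def test_single_row_warns_and_passes(self):
        m = make_matrix([[1.0, 2.0]], n_t=1)
        np.testing.assert_array_equal(quantile_normalize(m).values, m.values)


class TestModeratedTTest:
    def test_reduces_to_student_t_at_zero_prior_df(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(size=(50, 6)))
        de = moderated_ttest(m, prior_df=0)
        x = m.values.iloc[:, :3].to_numpy()
        y = m.values.iloc[:, 3:].to_numpy()
        ref = stats.ttest_ind(x, y, axis=1)
        np.testing.assert_allclose(de["stat"], ref.statistic, rtol=1e-12)
        np.testing.assert_allclose(de["pvalue"], ref.pvalue, rtol=1e-12)

    def test_infinite_prior_df_uses_common_variance(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(size=(30, 6)))
        de = moderated_ttest(m, prior_df=math.inf)
        # all features tested against the same prior variance: stat must be
        # proportional to log2fc
        ratio = de["stat"] / de["log2fc"]
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-9)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(size=(1000, 6)))
        de = moderated_ttest(m)
        ks = stats.kstest(de["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_posterior_variance_between_prior_and_sample(self):
        rng = np.random.default_rng(4)
        s2 = rng.chisquare(4, size=200) / 4 * 0.3
        d = np.full(200, 4.0)
        d0, s0 = fit_f_dist(s2, d)
        assert d0 > 0 and s0 > 0
        post = (d0 * s0 + d * s2) / (d0 + d)
        lo = np.minimum(s2, s0)
        hi = np.maximum(s2, s0)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_requires_two_replicates(self):
        m = make_matrix(np.ones((5, 3)), n_t=1)
        with pytest.raises(ValueError, match="2 replicates"):
            moderated_ttest(m)


class TestNbWaldTest:
    def _counts(self, rng, n_genes=300, mu=100.0, disp=0.05, shift=None):
        r = 1.0 / disp
        base = rng.gamma(2.0, mu / 2.0, size=n_genes) + 5
        out = np.zeros((n_genes, 6))
        for i in range(n_genes):
            m_t = base[i] * (2.0 ** shift[i] if shift is not None else 1.0)
            mu_vec = np.array([m_t] * 3 + [base[i]] * 3)
            out[i] = rng.negative_binomial(r, r / (r + mu_vec))
        return out

    def test_prefilter_strictly_greater_than_ten(self):
        vals = np.zeros((3, 4))
        vals[0] = [3, 3, 2, 2]    # total 10: excluded
        vals[1] = [3, 3, 3, 2]    # total 11: tested
        vals[2] = [50, 40, 60, 55]
        m = make_matrix(vals, kind="transcript_counts")
        de = nb_wald_test(m)
        assert set(de["feature"]) == {"F2", "F3"}

    def test_identical_groups_centered(self):
        rng = np.random.default_rng(5)
        counts = self._counts(rng)
        m = make_matrix(counts, kind="transcript_counts")
        de = nb_wald_test(m)
        assert abs(de["log2fc"].median()) < 0.1
        assert 0.3 < de["pvalue"].median() < 0.7

    def test_size_factor_recovers_scaling(self):
        rng = np.random.default_rng(6)
        base = rng.poisson(100, size=(200, 1)).astype(float) + 1
        counts = np.hstack([base, base * 2.0])
        sf = size_factors(counts)
        assert sf[1] / sf[0] == pytest.approx(2.0, rel=1e-9)

    def test_detects_planted_shift(self):
        rng = np.random.default_rng(7)
        shift = np.zeros(300)
        shift[:30] = 2.0
        counts = self._counts(rng, shift=shift)
        m = make_matrix(counts, kind="transcript_counts")
        de = nb_wald_test(m).set_index("feature")
        planted = [f"F{i+1}" for i in range(30) if f"F{i+1}" in de.index]
        assert de.loc[planted, "significant"].mean() > 0.8

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(8)
        counts = self._counts(rng, n_genes=2000)
        m = make_matrix(counts, kind="transcript_counts")
        de = nb_wald_test(m)
        rate = (de["pvalue"] < 0.05).mean()
        assert 0.03 <= rate <= 0.08


class TestPhosphoCorrection:
    def _pair(self, site_vals, prot_vals, site="AKT1_S473", prot="AKT1"):
        ph = make_matrix(site_vals, features=[site])
        pr = make_matrix(prot_vals, kind="protein_log2", features=[prot])
        return ph, pr

    def test_constant_protein_passes_through(self):
        ph, pr = self._pair([[1.0, 2, 3, 4, 5, 6]], [[5.0] * 6])
        out = correct_phospho_for_protein(ph, pr)
        np.testing.assert_allclose(out.values, ph.values)
        assert "AKT1_S473" in out.notes["uncorrected_sites"]

    def test_site_equal_to_protein_becomes_flat(self):
        trace = [[3.0, 4, 5, 6, 7, 8]]
        ph, pr = self._pair(trace, trace)
        out = correct_phospho_for_protein(ph, pr).values.to_numpy()
        np.testing.assert_allclose(out, out[0, 0], atol=1e-9)

    def test_treatment_shift_survives_correction(self):
        # protein trace balanced across groups, so the in-sample covariance
        # with the treatment indicator is exactly zero and the OLS slope is
        # exactly 1: the corrected fold change equals the planted shift
        prot = np.array([[9.0, 10.0, 11.0, 9.0, 10.0, 11.0]])
        shift = np.array([[1.5, 1.5, 1.5, 0, 0, 0]])
        ph, pr = self._pair(prot + shift, prot)
        out = correct_phospho_for_protein(ph, pr)
        vals = out.values.to_numpy()[0]
        lfc = vals[:3].mean() - vals[3:].mean()
        assert lfc == pytest.approx(1.5, abs=1e-9)

    def test_unmatched_site_flagged(self):
        ph = make_matrix([[1.0, 2, 3, 4, 5, 6]], features=["NOPE_S1"])
        pr = make_matrix([[1.0] * 6], kind="protein_log2", features=["AKT1"])
        out = correct_phospho_for_protein(ph, pr)
        assert out.notes["uncorrected_sites"] == ("NOPE_S1",)


class TestBhAdjust:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=40))
    def test_stepup_definition(self, pvals):
        """q_i = min_{j: p_j >= p_i} (m * p_j / rank_j), capped at 1."""
        q = bh_adjust(pvals)
        m = len(pvals)
        order = np.argsort(pvals, kind="mergesort")
        ranked = np.asarray(pvals)[order]
        expected = np.minimum.accumulate(
            (m * ranked / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.minimum(expected, 1.0)
        np.testing.assert_allclose(q[order], expected, rtol=1e-12)

    def test_fdr_control_on_mixtures(self):
        """Empirical FDR <= alpha + 0.03 over 200 null/alt mixtures."""
        rng = np.random.default_rng(10)
        m, pi0, alpha = 1000, 0.9, 0.05
        n_null = int(m * pi0)
        fdps = []
        for _ in range(200):
            p_null = rng.uniform(size=n_null)
            z_alt = rng.normal(3.0, 1.0, size=m - n_null)
            p_alt = 2 * stats.norm.sf(np.abs(z_alt))
            p = np.concatenate([p_null, p_alt])
            q = bh_adjust(p)
            rejected = q < alpha
            n_rej = rejected.sum()
            fdps.append(rejected[:n_null].sum() / max(1, n_rej))
        assert np.mean(fdps) <= alpha + 0.03


class TestCallSignificant:
    @pytest.mark.parametrize("lfc,q,expected", [
        (0.30, 0.04, True),     # above both default thresholds
        (0.20, 0.01, False),    # below log2(1.2)
        (0.30, 0.05, False),    # q not strictly below alpha
        (-0.30, 0.04, True),    # absolute fold change
    ])
    def test_threshold_rules(self, lfc, q, expected):
        from cosmotherm.core_io import make_de_frame
        de = make_de_frame(["x"], [lfc], [0.0], [q], [q])
        assert bool(call_significant(de)["significant"][0]) is expected

    def test_configurable_transcript_threshold(self):
        from cosmotherm.core_io import make_de_frame
        de = make_de_frame(["x"], [1.0], [0.0], [0.001], [0.001])
        assert not call_significant(de, lfc_min=1.5)["significant"][0]
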
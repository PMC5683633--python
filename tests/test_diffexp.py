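import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import nbinom
from statsmodels.stats.multitest import multipletests

from plasmir import diffexp, normalize
from plasmir.counts_io import CountMatrix
from plasmir.diffexp import (
    DispersionFit,
    bh_adjust,
    consensus_calls,
    de_test_modt,
    de_test_nbexact,
    de_test_nbwald,
    estimate_dispersions,
)
from plasmir.simdata import nb_draw
from tests.conftest import null_nb_cohort


def _cm(counts):
    counts = np.asarray(counts)
    return CountMatrix(
        counts,
        [f"f{i:03d}" for i in range(counts.shape[0])],
        [f"s{j}" for j in range(counts.shape[1])],
    )


def _fixed_disp(nf, phi):
    arr = np.full(nf, phi)
    return DispersionFit(arr, (phi, 0.0), arr, 0.5, np.full(nf, 100.0))


def _groups(n1, n2):
    return ["control"] * n1 + ["DLBCL"] * n2


class TestEstimateDispersions:
    def test_poisson_counts_near_zero(self, rng):
        mu = np.exp(rng.normal(5, 1, 200))
        counts = nb_draw(rng, np.tile(mu[:, None], (1, 40)), np.zeros((200, 40)))
        cm = _cm(counts)
        fit = estimate_dispersions(cm, np.ones(40), _groups(20, 20))
        assert np.median(fit.phi_shrunk) < 0.05

    def test_nb_consistency_at_phi_04(self, rng):
        mu = np.exp(rng.normal(5.5, 1, 2000))
        counts = nb_draw(rng, np.tile(mu[:, None], (1, 40)), np.full((2000, 40), 0.4))
        cm = _cm(counts)
        fit = estimate_dispersions(cm, np.ones(40), _groups(20, 20))
        assert 0.3 <= np.median(fit.phi_shrunk) <= 0.5

    def test_constant_feature_phi_zero(self, rng):
        counts = rng.integers(50, 500, size=(30, 8))
        counts[0] = 100
        cm = _cm(counts)
        fit = estimate_dispersions(cm, np.ones(8), _groups(4, 4))
        assert fit.phi_raw[0] == 0.0

    def test_shrunken_between_raw_and_trend(self, default_cohort):
        cm, st, _ = default_cohort
        groups = [st.groups[s] for s in cm.sample_ids]
        f = normalize.size_factors_median_ratio(cm)
        fit = estimate_dispersions(cm, f, ["control" if g == "control" else "patient"
                                           for g in groups])
        trend = fit.trend_at(fit.mean_norm_counts)
        lo = np.minimum(fit.phi_raw, trend) - 1e-12
        hi = np.maximum(fit.phi_raw, trend) + 1e-12
        assert ((fit.phi_shrunk >= lo) & (fit.phi_shrunk <= hi)).all()

    def test_small_group_rejected(self, small_cm):
        with pytest.raises(ValueError):
            estimate_dispersions(small_cm, np.ones(6), ["control"] * 5 + ["HL"])


class TestNBWald:
    def test_identical_groups_zero_lfc(self, rng):
        half = nb_draw(rng, np.full((30, 5), 200.0), np.full((30, 5), 0.2))
        counts = np.hstack([half, half])  # same draws reused in both groups
        cm = _cm(counts)
        t = de_test_nbwald(cm, _groups(5, 5), np.ones(10), _fixed_disp(30, 0.2))
        np.testing.assert_array_equal(t["log2fc"].to_numpy(), 0.0)
        np.testing.assert_array_equal(t["pvalue"].to_numpy(), 1.0)

    def test_estimator_consistency_lfc2(self, rng):
        # one feature with a true 4x mean ratio; median estimate near log2FC=2
        lfcs = []
        for _ in range(100):
            mu = np.tile(np.full(34, 500.0), (40, 1))  # stable background
            mu[0] = 300.0
            mu[0, 20:] *= 4
            counts = nb_draw(rng, mu, np.full((40, 34), 0.1))
            cm = _cm(counts)
            t = de_test_nbwald(cm, _groups(20, 14), np.ones(34), _fixed_disp(40, 0.1))
            lfcs.append(t["log2fc"].iloc[0])
        assert abs(np.median(lfcs) - 2.0) < 0.3

    def test_all_zero_feature(self, rng):
        counts = nb_draw(rng, np.full((5, 10), 100.0), np.full((5, 10), 0.1))
        counts[2] = 0
        cm = _cm(counts)
        t = de_test_nbwald(cm, _groups(5, 5), np.ones(10), _fixed_disp(5, 0.1))
        assert t["pvalue"].iloc[2] == 1.0 and t["log2fc"].iloc[2] == 0.0

    def test_label_swap_antisymmetry(self, rng):
        cm, _ = null_nb_cohort(rng, nf=40, n1=6, n2=8)
        disp = _fixed_disp(40, 0.2)
        g1 = ["control"] * 6 + ["DLBCL"] * 8
        g2 = ["DLBCL"] * 6 + ["control"] * 8
        t1 = de_test_nbwald(cm, g1, np.ones(14), disp)
        t2 = de_test_nbwald(cm, g2, np.ones(14), disp)
        np.testing.assert_allclose(t1["log2fc"], -t2["log2fc"], atol=1e-8)
        np.testing.assert_allclose(t1["pvalue"], t2["pvalue"], atol=1e-10)


def _binomial_double_tail(s1, s, p):
    lower = stats.binom.cdf(s1, s, p)
    upper = stats.binom.sf(s1 - 1, s, p)
    return min(1.0, 2 * min(lower, upper))


class TestNBExact:
    def test_poisson_limit_matches_binomial(self, rng):
        # at phi -> 0 the conditional law is Binomial(s, n1/(n1+n2))
        n1, n2 = 6, 4
        for _ in range(20):
            s1 = int(rng.integers(0, 100))
            s2 = int(rng.integers(0, 100))
            if s1 + s2 == 0 or s1 + s2 > 200:
                continue
            p = diffexp._exact_nb_split_pvalue(s1, s2, n1, n2, 1e-8)
            expected = _binomial_double_tail(s1, s1 + s2, n1 / (n1 + n2))
            assert p == pytest.approx(expected, abs=1e-3)

    def test_balanced_split_p_one(self):
        assert diffexp._exact_nb_split_pvalue(25, 25, 5, 5, 0.3) == 1.0

    def test_exhaustive_enumeration_oracle(self, rng):
        # independent oracle straight from scipy's NB pmf
        for _ in range(15):
            n1, n2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            s = int(rng.integers(1, 51))
            s1 = int(rng.integers(0, s + 1))
            phi = float(rng.uniform(0.05, 0.8))
            m = s / (n1 + n2)
            r1, r2 = n1 / phi, n2 / phi
            pp = r1 / (r1 + n1 * m)
            k = np.arange(s + 1)
            f = nbinom.pmf(k, r1, pp) * nbinom.pmf(s - k, r2, pp)
            f /= f.sum()
            lower, upper = f[: s1 + 1].sum(), f[s1:].sum()
            expected = min(1.0, 2 * min(lower, upper))
            got = diffexp._exact_nb_split_pvalue(s1, s - s1, n1, n2, phi)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_all_zero_feature_p_one(self, rng):
        counts = nb_draw(rng, np.full((3, 8), 50.0), np.full((3, 8), 0.1))
        counts[1] = 0
        cm = _cm(counts)
        t = de_test_nbexact(cm, _groups(4, 4), np.ones(8), _fixed_disp(3, 0.1))
        assert t["pvalue"].iloc[1] == 1.0

    def test_label_swap_symmetry(self, rng):
        cm, _ = null_nb_cohort(rng, nf=30, n1=5, n2=5)
        disp = _fixed_disp(30, 0.2)
        t1 = de_test_nbexact(cm, ["control"] * 5 + ["DLBCL"] * 5, np.ones(10), disp)
        t2 = de_test_nbexact(cm, ["DLBCL"] * 5 + ["control"] * 5, np.ones(10), disp)
        np.testing.assert_allclose(t1["log2fc"], -t2["log2fc"], atol=1e-10)
        np.testing.assert_allclose(t1["pvalue"], t2["pvalue"], atol=1e-10)


def _weighted_tm(values, weights=None):
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.ones_like(values)
    return normalize.TransformedMatrix(
        values,
        [f"f{i:03d}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        "weighted_logcpm",
        weights=np.asarray(weights, dtype=float),
    )


class TestModT:
    def test_equal_variances_moderation_noop(self, rng):
        # identical residual variance across features -> s2_tilde == s2
        base = rng.normal(size=8)
        values = np.vstack([base + off for off in (0, 1, 5, -2)])
        tm = _weighted_tm(values)
        t = de_test_modt(tm, _groups(4, 4))
        # all features share the same residual variance, so the moderated
        # statistic must equal the classical pooled t value exactly (the
        # reference distribution gains the infinite prior df)
        for i in range(4):
            tt, _ = stats.ttest_ind(values[i, 4:], values[i, :4], equal_var=True)
            expected_p = 2 * stats.norm.sf(abs(tt))
            assert t["pvalue"].iloc[i] == pytest.approx(expected_p, abs=1e-10)

    def test_null_gaussian_p_uniform(self, rng):
        ks_stats = []
        for _ in range(50):
            values = rng.normal(size=(159, 34))
            tm = _weighted_tm(values)
            t = de_test_modt(tm, _groups(20, 14))
            ks_stats.append(stats.kstest(t["pvalue"], "uniform").statistic)
        assert np.median(ks_stats) < 0.1

    def test_single_feature_equals_classical_t(self, rng):
        values = rng.normal(size=(1, 12))
        tm = _weighted_tm(values)
        t = de_test_modt(tm, _groups(6, 6))
        tt, pp = stats.ttest_ind(values[0, 6:], values[0, :6], equal_var=True)
        assert t["pvalue"].iloc[0] == pytest.approx(pp, rel=1e-9)
        assert t["log2fc"].iloc[0] == pytest.approx(
            values[0, 6:].mean() - values[0, :6].mean()
        )

    def test_label_swap_antisymmetry(self, rng):
        values = rng.normal(size=(50, 14))
        weights = rng.uniform(0.5, 2.0, size=(50, 14))
        tm = _weighted_tm(values, weights)
        t1 = de_test_modt(tm, ["control"] * 6 + ["DLBCL"] * 8)
        t2 = de_test_modt(tm, ["DLBCL"] * 6 + ["control"] * 8)
        np.testing.assert_allclose(t1["log2fc"], -t2["log2fc"], atol=1e-10)
        np.testing.assert_allclose(t1["pvalue"], t2["pvalue"], atol=1e-10)

    def test_requires_weights(self, rng):
        tm = normalize.TransformedMatrix(
            rng.normal(size=(5, 6)), [f"f{i}" for i in range(5)],
            [f"s{j}" for j in range(6)], "logcpm",
        )
        with pytest.raises(ValueError):
            de_test_modt(tm, _groups(3, 3))


class TestBHAdjust:
    def test_hand_step_up_triple(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust(np.full(7, 0.2)), 0.2)

    def test_against_statsmodels(self, rng):
        for _ in range(10):
            p = rng.uniform(size=50)
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_properties(self, rng):
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))


def _table(feats, lfc, q):
    return pd.DataFrame({
        "feature_id": feats, "log2fc": lfc, "pvalue": q, "qvalue": q,
        "method": "x", "comparison": "c",
    })


class TestConsensus:
    def test_two_votes_up(self):
        t = [_table(["a"], [x], [y]) for x, y in
             [(1.2, 0.01), (0.9, 0.04), (0.1, 0.8)]]
        out = consensus_calls(t)
        assert out["consensus"].iloc[0] and out["direction"].iloc[0] == "up"
        assert out["n_significant"].iloc[0] == 2

    def test_discordant_votes_flagged(self):
        t = [_table(["a"], [x], [y]) for x, y in
             [(1.0, 0.01), (-1.0, 0.01), (0.0, 0.9)]]
        out = consensus_calls(t)
        assert not out["consensus"].iloc[0]
        assert out["direction"].iloc[0] == "discordant"

    def test_single_vote_no_consensus(self):
        t = [_table(["a"], [x], [y]) for x, y in
             [(2.0, 0.001), (1.5, 0.2), (1.0, 0.9)]]
        out = consensus_calls(t)
        assert not out["consensus"].iloc[0] and out["direction"].iloc[0] == "none"

    def test_order_invariance(self, rng):
        feats = [f"f{i}" for i in range(30)]
        tables = [
            _table(feats, rng.normal(size=30), rng.uniform(size=30))
            for _ in range(3)
        ]
        out1 = consensus_calls(tables)
        out2 = consensus_calls(tables[::-1])
        pd.testing.assert_frame_equal(out1, out2)

    def test_mismatched_features_rejected(self):
        t1 = _table(["a"], [1.0], [0.01])
        t2 = _table(["b"], [1.0], [0.01])
        with pytest.raises(ValueError):
            consensus_calls([t1, t2, t1])

    def test_qvalue_column_monotone_in_p(self, rng):
        cm, groups = null_nb_cohort(rng, nf=50, n1=6, n2=6)
        t = de_test_nbwald(cm, groups, np.ones(12), _fixed_disp(50, 0.2))
        order = np.argsort(t["pvalue"].to_numpy())
        assert (np.diff(t["qvalue"].to_numpy()[order]) >= -1e-15).all()
        assert (t["qvalue"] >= t["pvalue"] - 1e-15).all()
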
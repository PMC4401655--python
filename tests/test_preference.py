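"""Dirichlet-multinomial model: prior, samplers, D statistics, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import dirichlet as sp_dirichlet

import hostpref as hp
from hostpref.errors import ConvergenceError, ValidationError
from hostpref.preference import compute_D, gelman_rubin

from conftest import make_assoc


class TestAlpha:
    def test_direct_formula(self):
        a = make_assoc([[1, 2, 2]], T=(10, 30, 60))
        alpha = hp.compute_alpha(a)
        assert np.allclose(alpha.to_numpy(), [[0.5, 1.5, 3.0]])

    def test_row_sums_equal_N(self, small_pipeline):
        occ, hosts = small_pipeline["occ"], small_pipeline["hosts"]
        assoc = hp.build_association(occ, hosts, "97")
        alpha = hp.compute_alpha(assoc)
        assert np.allclose(alpha.sum(axis=1).to_numpy(), assoc.N.to_numpy(), rtol=1e-9)
        assert (alpha.to_numpy() > 0).all()

    def test_prior_mean_is_sampling_share(self):
        a = make_assoc([[1, 2, 2], [0, 0, 7], [3, 3, 4]], T=(10, 30, 60))
        alpha = hp.compute_alpha(a)
        means = alpha.div(alpha.sum(axis=1), axis=0)
        assert np.allclose(means.to_numpy(), np.tile([0.1, 0.3, 0.6], (3, 1)))

    def test_single_host_rejected(self):
        with pytest.raises(ValidationError, match="single host"):
            hp.compute_alpha(make_assoc([[3]], T=(10,)))


class TestSamplers:
    def test_conjugate_mean_matches_closed_form(self):
        a = make_assoc([[10, 2, 8]], T=(20, 30, 50))
        model = hp.HostPreferenceModel(a, min_occurrence=1)
        draws = 50_000
        rng = np.random.default_rng([3, 17])
        from hostpref.preference import _draw_conjugate

        post_alpha = model.alpha.to_numpy() + a.y.to_numpy()
        pi = _draw_conjugate(post_alpha, draws, rng)
        target = post_alpha[0] / post_alpha[0].sum()  # (alpha+y)/(2N)
        a0 = post_alpha[0].sum()
        mc_se = np.sqrt(target * (1 - target) / (a0 + 1) / draws)
        assert (np.abs(pi.mean(axis=0)[0] - target) < 4 * mc_se).all()
        assert post_alpha[0].sum() == pytest.approx(2 * a.N.iloc[0])

    def test_gibbs_agrees_with_conjugate(self):
        rng = np.random.default_rng(5)
        y = rng.multinomial(15, [0.2, 0.3, 0.5], size=6)
        a = make_assoc(y, T=(20, 30, 50))
        model = hp.HostPreferenceModel(a, min_occurrence=1)
        rc = model.fit(mode="conjugate", draws=100_000, seed=1)
        rg = model.fit(mode="gibbs", iterations=150_000, burn_in=30_000, thin=5,
                       chains=3, seed=2)
        assert np.abs(rc.d_hat.to_numpy() - rg.d_hat.to_numpy()).max() < 0.01
        assert rg.max_rhat() < 1.05
        assert rc.rhat is None

    def test_shrinkage_to_prior_mean_for_proportional_counts(self):
        T = np.array([20, 30, 50])
        y = (T // 10).reshape(1, 3)  # counts exactly proportional to effort
        a = make_assoc(y, T=T)
        res = hp.HostPreferenceModel(a, min_occurrence=1).fit(draws=20_000, seed=3)
        # posterior mean of pi equals the prior mean exactly; D-hat ~ 0
        assert np.abs(res.d_hat.to_numpy()).max() < 0.05

    def test_invalid_sampler_settings(self):
        a = make_assoc([[3, 4]], T=(5, 5))
        model = hp.HostPreferenceModel(a, min_occurrence=1)
        with pytest.raises(ValidationError):
            model.fit(mode="conjugate", draws=0)
        with pytest.raises(ValidationError):
            model.fit(mode="gibbs", iterations=100, burn_in=100)
        with pytest.raises(ValidationError):
            model.fit(mode="nope")

    def test_fit_reproducible(self):
        a = make_assoc([[10, 2, 8], [1, 1, 18]], T=(20, 30, 50))
        model = hp.HostPreferenceModel(a, min_occurrence=1)
        r1 = model.fit(draws=500, seed=9)
        r2 = model.fit(draws=500, seed=9)
        pd.testing.assert_frame_equal(r1.d_hat, r2.d_hat)


class TestDStatistic:
    def test_draw_invariants(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet([2.0, 1.0, 3.0, 4.0], size=(2000, 3))
        expected = np.array([0.1, 0.2, 0.3, 0.4])
        out = compute_D(pi, expected)
        dbar = out["dbar"]
        ok = ~np.isnan(dbar).any(axis=2)
        sums = np.nansum(dbar, axis=2)[ok]
        norms = np.linalg.norm(dbar, axis=2)[ok]
        assert np.abs(sums).max() < 1e-8
        assert np.abs(norms - 1).max() < 1e-8
        assert dbar[~np.isnan(dbar)].max() <= 1 + 1e-12
        assert dbar[~np.isnan(dbar)].min() >= -1 - 1e-12

    def test_degenerate_draw_rejected(self):
        expected = np.array([0.25, 0.25, 0.25, 0.25])
        pi = np.tile(expected, (100, 1, 1))  # every draw exactly at the prior mean
        with pytest.raises(ConvergenceError):
            compute_D(pi, expected)
        # a single degenerate draw among many is rejected, not fatal
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.ones(4), size=(1000, 1))
        pi[0, 0] = expected
        out = compute_D(pi, expected)
        assert out["n_rejected"][0] == 1
        assert np.isnan(out["dbar"][0, 0]).all()

    def test_exclusive_host_positive_significant(self):
        # fungus found only in host j*: strong positive deviation there
        a = make_assoc([[30, 0, 0]], T=(30, 30, 30))
        res = hp.HostPreferenceModel(a, min_occurrence=1).fit(draws=4000, seed=7)
        assert res.d_hat.iloc[0, 0] > 0
        assert res.ci99_lo.iloc[0, 0] > 0
        # independent high-precision oracle: scipy Dirichlet sampler
        alpha_post = hp.compute_alpha(a).to_numpy()[0] + np.array([30, 0, 0])
        draws = sp_dirichlet.rvs(alpha_post, size=200_000,
                                 random_state=np.random.default_rng(11))
        dev = draws - 1 / 3
        dbar = dev / np.linalg.norm(dev, axis=1, keepdims=True)
        assert res.d_hat.iloc[0, 0] == pytest.approx(dbar[:, 0].mean(), abs=0.01)

    def test_monotone_in_target_count(self):
        # raising y at host j* (others fixed) never lowers D-hat there
        d_hats = []
        for y_star in (0, 3, 6, 12, 24):
            a = make_assoc([[y_star, 5, 5]], T=(40, 40, 40))
            res = hp.HostPreferenceModel(a, min_occurrence=1).fit(draws=20_000, seed=13)
            d_hats.append(res.d_hat.iloc[0, 0])
        assert all(b > a - 0.01 for a, b in zip(d_hats, d_hats[1:]))
        assert d_hats[-1] > d_hats[0]


class TestDmax:
    def test_signed_max(self):
        d_hat = pd.DataFrame([[0.1, -0.5, 0.3]], index=["f1"], columns=list("abc"))
        out = hp.compute_Dmax(d_hat)
        assert out.loc["f1", "d_max"] == pytest.approx(0.3)
        assert bool(out.loc["f1", "abs_max_differs"]) is True  # |−0.5| > 0.3

    def test_dominant_host_near_one(self):
        a = make_assoc([[50, 0, 0, 0, 0]], T=(50, 50, 50, 50, 50))
        res = hp.HostPreferenceModel(a, min_occurrence=1).fit(draws=4000, seed=2)
        dmax = res.dmax()
        assert dmax["d_max"].iloc[0] > 0.8
        assert not dmax["abs_max_differs"].iloc[0]


class TestGelmanRubin:
    def test_identical_chains(self):
        chain = np.random.default_rng(0).normal(size=(1, 1000, 3))
        chains = np.repeat(chain, 3, axis=0)
        rhat = gelman_rubin(chains)
        # B = 0: the statistic equals sqrt((n-1)/n), i.e. ~1
        assert np.allclose(rhat, np.sqrt(999 / 1000))

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert gelman_rubin(chains[:, :, None])[0] > 1.1

    def test_hand_computation(self):
        c1 = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        c2 = c1 + 0.5
        n = 10
        w = (c1.var(ddof=1) + c2.var(ddof=1)) / 2
        b = n * np.var([c1.mean(), c2.mean()], ddof=1)
        expected = np.sqrt(((n - 1) / n * w + b / n) / w)
        assert gelman_rubin(np.stack([c1, c2])) == pytest.approx(expected)

    def test_requirements(self):
        with pytest.raises(ValidationError):
            gelman_rubin(np.zeros((1, 100)))
        with pytest.raises(ValidationError):
            gelman_rubin(np.zeros((2, 5)))
        with pytest.raises(ConvergenceError):
            gelman_rubin(np.ones((2, 100)))


class TestCompareLevels:
    def test_identical_columns_p_one(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(size=10)
        table = pd.DataFrame({lv: col for lv in hp.LEVELS})
        with pytest.warns(UserWarning):
            pairs, letters = hp.compare_Dmax_levels(table)
        assert (pairs["p"] == 1.0).all()
        assert len(set(letters.values())) == 1

    def test_shifted_column_detected(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.1, 0.4, size=12)
        table = pd.DataFrame(
            {"99.8": base, "99": base + rng.normal(0, 0.01, 12),
             "98": base + 0.3, "97": base + 0.31 + rng.normal(0, 0.005, 12)}
        )
        pairs, letters = hp.compare_Dmax_levels(table)
        key = pairs.set_index(["level_a", "level_b"])
        assert bool(key.loc[("99.8", "98"), "significant"])
        assert not bool(key.loc[("99.8", "99"), "significant"])
        assert letters["99.8"] == letters["99"]
        assert set(letters["99.8"]) != set(letters["98"])

    def test_too_few_otus(self):
        table = pd.DataFrame(np.ones((4, 4)), columns=hp.LEVELS)
        with pytest.raises(ValidationError):
            hp.compare_Dmax_levels(table)


def test_min_occurrence_filter(small_pipeline):
    occ, hosts = small_pipeline["occ"], small_pipeline["hosts"]
    assoc = hp.build_association(occ, hosts, "97")
    model = hp.HostPreferenceModel(assoc, min_occurrence=5)
    assert (model.assoc.N >= 5).all()
    assert len(model.assoc.y) <= len(assoc.y)


def test_summary_table_shape(small_pipeline):
    occ, hosts = small_pipeline["occ"], small_pipeline["hosts"]
    res = hp.HostPreferenceModel.from_occurrence(occ, hosts, "97", min_occurrence=5).fit(
        draws=500, seed=1
    )
    summ = res.summary()
    assert {"otu", "host", "d_hat", "ci95_lo", "ci99_hi", "flag"} <= set(summ.columns)
    assert len(summ) == res.d_hat.size
    assert summ["ci95_lo"].le(summ["ci95_hi"]).all()
    assert summ["d_hat"].between(-1, 1).all()
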
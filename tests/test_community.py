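"""Raup-Crick null model, Mantel machinery, Moran's I, host-group split."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, spearmanr

import hostpref as hp
from hostpref.errors import ValidationError

from conftest import make_distance, random_distance


def exact_raup_crick(pool, r_a, r_b, obs_shared):
    """Exact dissimilarity for an equal-frequency pool: shared OTUs between two
    independent uniform subsets follow a hypergeometric law."""
    ks = np.arange(0, min(r_a, r_b) + 1)
    pmf = hypergeom.pmf(ks, pool, r_a, r_b)
    return float(pmf[ks > obs_shared].sum() + 0.5 * pmf[ks == obs_shared].sum())


class TestRaupCrick:
    def test_identical_units_score_low(self):
        row = np.r_[np.ones(10), np.zeros(90)].astype(int)
        units = pd.DataFrame([row, row], index=["A", "B"])
        d = hp.raup_crick(units, n_null=999, seed=1, frequencies=np.ones(100))
        oracle = exact_raup_crick(100, 10, 10, 10)
        assert d.data.loc["A", "B"] < 0.5
        assert d.data.loc["A", "B"] == pytest.approx(oracle, abs=0.05)

    def test_disjoint_units_score_high(self):
        a = np.zeros(200, int); a[:5] = 1
        b = np.zeros(200, int); b[5:10] = 1
        units = pd.DataFrame([a, b], index=["A", "B"])
        d = hp.raup_crick(units, n_null=999, seed=2, frequencies=np.ones(200))
        oracle = exact_raup_crick(200, 5, 5, 0)
        assert d.data.loc["A", "B"] > 0.5
        assert d.data.loc["A", "B"] == pytest.approx(oracle, abs=0.05)

    def test_bounds_symmetry_and_reproducibility(self, small_pipeline):
        units = hp.group_by_plant_otu(small_pipeline["occ"], small_pipeline["hosts"], "99.8")
        d1 = hp.raup_crick(units, n_null=99, seed=5)
        d2 = hp.raup_crick(units, n_null=99, seed=5)
        v = d1.data.to_numpy()
        assert ((v >= 0) & (v <= 1)).all()
        assert np.allclose(v, v.T) and np.allclose(np.diag(v), 0)
        pd.testing.assert_frame_equal(d1.data, d2.data)

    def test_richness_exceeding_pool_rejected(self):
        units = pd.DataFrame([[1, 1], [1, 0]], index=["A", "B"], columns=["x", "y"])
        with pytest.raises(ValidationError, match="exceeds"):
            hp.raup_crick(units, n_null=9, seed=0, frequencies=np.array([1.0, 0.0]))

    def test_null_pairs_centred_at_half(self):
        # pairs drawn from the null itself: mean dissimilarity ~ 0.5
        rng = np.random.default_rng(3)
        K, r = 100, 12
        vals = []
        for rep in range(120):
            a = np.zeros(K, int); a[rng.choice(K, r, replace=False)] = 1
            b = np.zeros(K, int); b[rng.choice(K, r, replace=False)] = 1
            units = pd.DataFrame([a, b], index=["A", "B"])
            d = hp.raup_crick(units, n_null=99, seed=rep, frequencies=np.ones(K))
            vals.append(d.data.iloc[0, 1])
        assert abs(np.mean(vals) - 0.5) < 0.05


class TestMantel:
    def test_perfect_concordance(self):
        rng = np.random.default_rng(0)
        d1 = random_distance(8, rng)
        res = hp.mantel(d1, d1, n_perm=999, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 1000)

    def test_exact_enumeration_n4(self):
        rng = np.random.default_rng(4)
        d1, d2 = random_distance(4, rng), random_distance(4, rng)
        res = hp.mantel(d1, d2, exact=True)
        # independent brute force over all 4! relabelings of d2
        v1, v2 = d1.data.to_numpy(), d2.data.to_numpy()
        il = np.tril_indices(4, k=-1)
        r_obs = spearmanr(v1[il], v2[il]).statistic
        r_perms = []
        for perm in itertools.permutations(range(4)):
            vp = v2[np.ix_(perm, perm)]
            r_perms.append(spearmanr(v1[il], vp[il]).statistic)
        expected_p = np.mean(np.array(r_perms) >= r_obs - 1e-12)
        assert res.r == pytest.approx(r_obs)
        assert res.p == pytest.approx(expected_p)

    def test_constant_matrix_rejected(self):
        ones = make_distance(1 - np.eye(5))
        rng = np.random.default_rng(1)
        with pytest.raises(ValidationError, match="constant"):
            hp.mantel(ones, random_distance(5, rng), n_perm=99)

    def test_label_order_invariance(self):
        rng = np.random.default_rng(7)
        labels = [f"l{i}" for i in range(7)]
        d1 = random_distance(7, rng, labels=labels)
        d2 = random_distance(7, rng, labels=labels)
        r_a = hp.mantel(d1, d2, n_perm=99, seed=0).r
        shuffled = labels[::-1]
        r_b = hp.mantel(d1.reindex(shuffled), d2.reindex(shuffled), n_perm=99, seed=0).r
        assert r_a == pytest.approx(r_b)

    def test_null_pvalues_near_uniform(self):
        # empirical CDF of p under the null stays inside a Kolmogorov band
        rng = np.random.default_rng(11)
        pvals = [
            hp.mantel(random_distance(9, rng), random_distance(9, rng),
                      n_perm=99, seed=i).p
            for i in range(300)
        ]
        grid = np.linspace(0.05, 0.95, 19)
        ecdf = np.array([(np.array(pvals) <= g).mean() for g in grid])
        band = 1.36 / np.sqrt(300)  # ~alpha=0.05 Kolmogorov band
        assert np.abs(ecdf - grid).max() < band + 0.01


class TestPartialMantel:
    def test_reduces_to_mantel_with_independent_control(self):
        rng = np.random.default_rng(2)
        n = 30
        base = rng.uniform(size=(n, n)); base = (base + base.T) / 2; np.fill_diagonal(base, 0)
        noise = rng.uniform(size=(n, n)); noise = (noise + noise.T) / 2
        d1 = make_distance(base)
        d2 = make_distance(np.clip(base + 0.2 * noise, 0, None) * (1 - np.eye(n)))
        control = random_distance(n, rng)
        plain = hp.mantel(d1, d2, n_perm=99, seed=3).r
        partial = hp.partial_mantel(d1, d2, control, n_perm=99, seed=3).r
        assert abs(plain - partial) < 0.02

    def test_degenerate_control_rejected(self):
        rng = np.random.default_rng(5)
        d1 = random_distance(6, rng)
        with pytest.raises(ValidationError, match="degenerate"):
            hp.partial_mantel(d1, d1, d1, n_perm=9)

    def test_hand_sized_formula(self):
        rng = np.random.default_rng(9)
        d1, d2, d3 = (random_distance(5, rng) for _ in range(3))
        il = np.tril_indices(5, k=-1)
        r12 = spearmanr(d1.data.to_numpy()[il], d2.data.to_numpy()[il]).statistic
        r13 = spearmanr(d1.data.to_numpy()[il], d3.data.to_numpy()[il]).statistic
        r23 = spearmanr(d2.data.to_numpy()[il], d3.data.to_numpy()[il]).statistic
        expected = (r12 - r13 * r23) / np.sqrt((1 - r13**2) * (1 - r23**2))
        res = hp.partial_mantel(d1, d2, d3, n_perm=9, seed=0)
        assert res.r == pytest.approx(expected)


class TestMoransI:
    def test_alternating_values_negative(self):
        values = np.tile([1.0, -1.0], 10)
        out = hp.morans_i(values, np.arange(20.0))
        assert out["I"] < out["expected"]

    def test_hand_worked_case(self):
        values = np.array([2.0, 4.0, 3.0, 7.0, 1.0])
        coords = np.array([0.0, 1.0, 3.0, 6.0, 10.0])
        z = values - values.mean()
        diff = np.abs(coords[:, None] - coords[None, :])
        w = np.where(np.eye(5, dtype=bool), 0.0, 1.0 / np.where(diff == 0, 1, diff))
        expected_i = (5 / w.sum()) * (z @ w @ z) / (z @ z)
        out = hp.morans_i(values, coords)
        assert out["I"] == pytest.approx(expected_i)
        assert out["expected"] == pytest.approx(-0.25)

    def test_null_expectation_calibrated(self):
        rng = np.random.default_rng(13)
        n = 25
        stats = [
            hp.morans_i(rng.normal(size=n), np.arange(float(n)))["I"] for _ in range(400)
        ]
        se = np.std(stats, ddof=1) / np.sqrt(len(stats))
        assert abs(np.mean(stats) - (-1 / (n - 1))) < 3 * se

    def test_errors(self):
        with pytest.raises(ValidationError, match="constant"):
            hp.morans_i(np.ones(6), np.arange(6.0))
        with pytest.raises(ValidationError, match="duplicate"):
            hp.morans_i(np.arange(6.0), np.array([0.0, 1, 1, 3, 4, 5]))
        with pytest.raises(ValidationError):
            hp.morans_i(np.arange(3.0), np.arange(3.0))


class TestSplit:
    def test_sizes_partition_samples(self, small_pipeline):
        occ, hosts = small_pipeline["occ"], small_pipeline["hosts"]
        dip, nondip = hp.split_by_host(occ, hosts)
        assert dip.data.shape[0] + nondip.data.shape[0] == occ.data.shape[0]
        assert set(dip.sample_ids).isdisjoint(nondip.sample_ids)

    def test_empty_subset_errors(self, small_pipeline):
        occ = small_pipeline["occ"]
        table = small_pipeline["hosts"].table.copy()
        table["is_dipterocarp"] = True
        with pytest.raises(ValidationError):
            hp.split_by_host(occ, hp.HostAssignment(table))


def test_unit_geographic_distances(small_pipeline):
    hosts, coords, occ = (
        small_pipeline["hosts"], small_pipeline["coords"], small_pipeline["occ"]
    )
    geo = hp.unit_geographic_distances(hosts, coords, "99.8", sample_ids=occ.sample_ids)
    v = geo.data.to_numpy()
    assert np.allclose(v, v.T) and (v >= 0).all()
    # spot-check one entry against a direct mean-position computation
    labels = list(geo.labels)[:2]
    sub = hosts.table.loc[list(occ.sample_ids)]
    centres = [
        coords.loc[sub.index[sub["otu_99.8"] == lab]].mean() for lab in labels
    ]
    assert geo.data.loc[labels[0], labels[1]] == pytest.approx(abs(centres[0] - centres[1]))
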
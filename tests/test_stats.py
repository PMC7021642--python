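"""Statistical machinery against independent oracles.

Cluster permutation vs exhaustive enumeration; partial correlation vs the
residual-regression oracle and pingouin; BH-FDR vs the step-up definition
and statsmodels; the mixed ANOVA vs hand-computed sums of squares and
pingouin; Fisher's exact test vs hand enumeration of the hypergeometric.
"""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from rtmseeg import stats


# --------------------------------------------------------------------------
# cluster permutation
# --------------------------------------------------------------------------

def _line_graph(channels):
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(channels)
    g.add_edges_from(zip(channels[:-1], channels[1:]))
    return g


def _exhaustive_two_group_p(data: np.ndarray, n1: int, adjacency, threshold):
    """Brute-force permutation p of the max |cluster mass| statistic,
    enumerating all group relabelings (the oracle for the Monte-Carlo test)."""
    channels = list(adjacency.nodes)
    n = data.shape[0]

    def max_mass(idx1):
        idx1 = list(idx1)
        idx2 = [i for i in range(n) if i not in idx1]
        a, b = data[idx1], data[idx2]
        sp = np.sqrt(((len(a) - 1) * a.var(0, ddof=1)
                      + (len(b) - 1) * b.var(0, ddof=1)) / (n - 2))
        t = (a.mean(0) - b.mean(0)) / (sp * np.sqrt(1 / len(a) + 1 / len(b)))
        best = 0.0
        for sign in (1, -1):
            supra = [c for c, s in zip(channels, t) if sign * s > threshold]
            sub = adjacency.subgraph(supra)
            import networkx as nx
            for comp in nx.connected_components(sub):
                mass = abs(sum(t[channels.index(c)] for c in comp))
                best = max(best, mass)
        return best

    observed = max_mass(range(n1))
    null = [max_mass(c) for c in itertools.combinations(range(n), n1)]
    return np.mean([m >= observed - 1e-12 for m in null]), observed


def test_cluster_permutation_matches_exhaustive_enumeration():
    """Monte-Carlo p agrees with the exact p over all 20 relabelings (n=6)."""
    rng = np.random.default_rng(3)
    channels = ["a", "b", "c"]
    g = _line_graph(channels)
    data = rng.standard_normal((6, 3))
    data[:3] += 1.5  # group difference on every channel
    df = pd.DataFrame(data, columns=channels)
    groups = np.array(["x"] * 3 + ["y"] * 3)
    res = stats.cluster_permutation(df, "two_group", g, groups=groups,
                                    n_perm=4000, seed=0)
    p_exact, _ = _exhaustive_two_group_p(data, 3, g, res.threshold)
    assert res.clusters, "expected at least one cluster"
    p_mc = res.clusters[0].p_mc
    # MC error at 4000 draws, plus the +1 smoothing of the estimator
    assert abs(p_mc - p_exact) < 0.03


def test_cluster_permutation_all_zero_data_gives_no_clusters():
    g = _line_graph(["a", "b", "c"])
    data = pd.DataFrame(np.zeros((6, 3)), columns=["a", "b", "c"])
    with pytest.warns(UserWarning, match="zero-variance"):
        res = stats.cluster_permutation(data, "correlate", g,
                                        covariate=np.arange(6.0),
                                        n_perm=50, seed=0)
    assert res.clusters == []
    assert set(res.excluded) == {"a", "b", "c"}


def test_cluster_permutation_excludes_zero_variance_channels():
    g = _line_graph(["a", "b", "c"])
    rng = np.random.default_rng(1)
    data = pd.DataFrame(rng.standard_normal((8, 3)), columns=["a", "b", "c"])
    data["b"] = 1.0
    with pytest.warns(UserWarning, match="zero-variance"):
        res = stats.cluster_permutation(data, "correlate", g,
                                        covariate=rng.standard_normal(8),
                                        n_perm=20, seed=0)
    assert res.excluded == ("b",)
    assert np.isnan(res.statistic["b"])


def test_cluster_permutation_rejects_bad_inputs(montage):
    rng = np.random.default_rng(0)
    data = pd.DataFrame(rng.standard_normal((8, 64)),
                        columns=montage.channel_names)
    with pytest.raises(ValueError, match="design"):
        stats.cluster_permutation(data, "anova3", montage.adjacency)
    with pytest.raises(ValueError, match="zero variance"):
        stats.cluster_permutation(data, "correlate", montage.adjacency,
                                  covariate=np.ones(8))
    with pytest.raises(ValueError, match="5 subjects"):
        stats.cluster_permutation(data.iloc[:3], "correlate",
                                  montage.adjacency,
                                  covariate=rng.standard_normal(3))


def test_cluster_permutation_p_floor_is_one_over_nperm_plus_one():
    g = _line_graph(["a", "b"])
    rng = np.random.default_rng(2)
    base = rng.standard_normal((10, 2)) * 0.1
    base[5:] += 8.0
    df = pd.DataFrame(base, columns=["a", "b"])
    res = stats.cluster_permutation(df, "two_group", g,
                                    groups=np.repeat(["p", "q"], 5),
                                    n_perm=199, seed=1)
    assert res.clusters[0].p_mc >= 1 / 200


# --------------------------------------------------------------------------
# partial correlation
# --------------------------------------------------------------------------

class TestPartialCorrelation:
    def test_orthogonal_control_reduces_to_simple_r(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        z = rng.standard_normal(40)
        z -= np.polyval(np.polyfit(x, z, 1), x)  # orthogonalise vs x
        z -= np.polyval(np.polyfit(y, z, 1), y)  # ... and vs y (approx)
        r, _, _ = stats.partial_correlation(x, y, z)
        r_xy = np.corrcoef(x, y)[0, 1]
        assert abs(r - r_xy) < 0.02  # residual z-correlation is tiny, not 0

    def test_x_equals_y_gives_unity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20)
        z = rng.standard_normal(20)
        r, _, p = stats.partial_correlation(x, x, z)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x, y, z = rng.standard_normal((3, 30))
            r, _, _ = stats.partial_correlation(x, y, z)
            rx = x - np.polyval(np.polyfit(z, x, 1), z)
            ry = y - np.polyval(np.polyfit(z, y, 1), z)
            assert abs(r - np.corrcoef(rx, ry)[0, 1]) < 1e-10

    def test_matches_pingouin(self):
        import pingouin as pg
        rng = np.random.default_rng(3)
        x, y, z = rng.standard_normal((3, 25))
        r, _, p = stats.partial_correlation(x, y, z)
        ref = pg.partial_corr(pd.DataFrame({"x": x, "y": y, "z": z}),
                              x="x", y="y", covar="z")
        assert r == pytest.approx(ref["r"].iloc[0], abs=1e-12)
        assert p == pytest.approx(ref["p_val"].iloc[0], abs=1e-12)

    def test_collinear_control_raises(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            stats.partial_correlation(x, np.random.default_rng(0).random(10),
                                      2 * x + 1)

    @given(st.floats(0.1, 5), st.floats(-10, 10), st.floats(0.1, 5),
           st.floats(-10, 10))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance_and_symmetry(self, a, b, c, d):
        rng = np.random.default_rng(4)
        x, y, z = rng.standard_normal((3, 20))
        r0, _, _ = stats.partial_correlation(x, y, z)
        r1, _, _ = stats.partial_correlation(a * x + b, y, c * z + d)
        r2, _, _ = stats.partial_correlation(y, x, z)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert r2 == pytest.approx(r0, abs=1e-12)


# --------------------------------------------------------------------------
# FDR
# --------------------------------------------------------------------------

def _bh_bruteforce(p, q):
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    rejected = np.zeros(m, bool)
    if k_star:
        rejected[order[:k_star]] = True
    return rejected


class TestBHFDR:
    def test_single_p_reduces_to_threshold(self):
        rej, _ = stats.bh_fdr([0.04], 0.05)
        assert rej[0]
        rej, _ = stats.bh_fdr([0.06], 0.05)
        assert not rej[0]

    def test_all_small_ps_all_rejected(self):
        rej, _ = stats.bh_fdr([0.001] * 54, 0.05)
        assert rej.all()

    def test_matches_stepup_definition_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=54) ** rng.uniform(1, 3)
            rej, _ = stats.bh_fdr(p, 0.05)
            assert (rej == _bh_bruteforce(p, 0.05)).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(1)
        p = rng.uniform(size=54) ** 2
        rej, qv = stats.bh_fdr(p, 0.05)
        ref_rej, ref_q, *_ = multipletests(p, 0.05, method="fdr_bh")
        assert (rej == ref_rej).all()
        np.testing.assert_allclose(qv, ref_q)

    def test_rejections_monotone_in_family_size(self):
        """FDR over a subset of 8 rejects a superset of FDR over all 54."""
        rng = np.random.default_rng(2)
        p = rng.uniform(size=54) ** 3
        rej54, _ = stats.bh_fdr(p, 0.05)
        rej8, _ = stats.bh_fdr(p[:8], 0.05)
        assert (rej8 | ~rej54[:8]).all()

    def test_empty_input(self):
        rej, qv = stats.bh_fdr([], 0.05)
        assert rej.size == 0 and qv.size == 0

    def test_controls_empirical_fdr(self):
        """Average false-discovery proportion stays below q with planted
        signals (m = 54, 10 true effects)."""
        rng = np.random.default_rng(3)
        fdp = []
        for _ in range(500):
            p = np.concatenate([
                rng.uniform(size=44),
                np.clip(sps.norm.sf(rng.standard_normal(10) + 3.0) * 2,
                        0, 1),
            ])
            rej, _ = stats.bh_fdr(p, 0.05)
            n_rej = rej.sum()
            fdp.append(rej[:44].sum() / n_rej if n_rej else 0.0)
        mc_se = np.std(fdp) / np.sqrt(len(fdp))
        assert np.mean(fdp) <= 0.05 + 2 * mc_se


# --------------------------------------------------------------------------
# effect sizes, responders, Fisher
# --------------------------------------------------------------------------

@pytest.mark.parametrize("F,df1,df2,expected", [
    (15.60, 1, 39, 0.29),
    (3.45, 2, 39, 0.15),
    (20.45, 1, 39, 0.34),
    (18.39, 1, 26, 0.41),
    (3.95, 1, 26, 0.13),
    (0.0, 1, 10, 0.0),
])
def test_partial_eta_squared(F, df1, df2, expected):
    assert stats.partial_eta_squared(F, df1, df2) == pytest.approx(expected,
                                                                   abs=0.005)


class TestCohensD:
    def test_equal_means_zero(self):
        assert stats.cohens_d(5, 1, 10, 5, 1, 10) == 0.0

    def test_unit_case(self):
        assert stats.cohens_d(1, 1, 10, 0, 1, 10) == pytest.approx(1.0)

    def test_matches_recomputation_from_raw_samples(self):
        rng = np.random.default_rng(0)
        a = rng.normal(2, 1.5, 20)
        b = rng.normal(0, 2.0, 15)
        d = stats.cohens_d(a.mean(), a.std(ddof=1), len(a),
                           b.mean(), b.std(ddof=1), len(b))
        sp = np.sqrt(((19) * a.var(ddof=1) + (14) * b.var(ddof=1)) / 33)
        assert d == pytest.approx((a.mean() - b.mean()) / sp, abs=1e-12)


class TestResponders:
    def test_boundary_is_inclusive(self):
        flags, rate = stats.classify_responders([80, 80], [60, 61])
        assert flags.tolist() == [True, False]
        assert rate == 50.0

    def test_rate_six_of_fifteen(self):
        pre = np.full(15, 100.0)
        post = np.where(np.arange(15) < 6, 70.0, 90.0)
        _, rate = stats.classify_responders(pre, post)
        assert rate == pytest.approx(40.0)

    def test_nonpositive_pre_rejected(self):
        with pytest.raises(ValueError):
            stats.classify_responders([0.0], [1.0])


class TestFisherExact:
    def test_symmetric_table_p_one(self):
        p, _ = stats.fisher_exact(1, 0, 0, 1)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_hand_enumeration(self):
        """[[5,0],[0,5]]: only the two extreme tables are as unlikely,
        each with probability 1/C(10,5) = 1/252."""
        p, odds = stats.fisher_exact(5, 0, 0, 5)
        assert p == pytest.approx(2 / 252)
        assert odds == np.inf

    def test_responder_contrast(self):
        p, _ = stats.fisher_exact(6, 9, 1, 13)
        assert p == pytest.approx(0.08, abs=0.005)

    def test_hypergeometric_enumeration_oracle(self):
        a, b, c, d = 4, 6, 2, 9
        p, _ = stats.fisher_exact(a, b, c, d)
        n1, n2, k = a + b, c + d, a + c
        probs = [sps.hypergeom.pmf(x, n1 + n2, n1, k)
                 for x in range(max(0, k - n2), min(k, n1) + 1)]
        obs = sps.hypergeom.pmf(a, n1 + n2, n1, k)
        p_oracle = sum(pr for pr in probs if pr <= obs * (1 + 1e-9))
        assert p == pytest.approx(p_oracle, abs=1e-12)


# --------------------------------------------------------------------------
# mixed ANOVA
# --------------------------------------------------------------------------

class TestMixedAnova:
    def test_all_identical_values_give_zero_f(self):
        df = pd.DataFrame({"pre": [3.0] * 6, "post": [3.0] * 6})
        res = stats.mixed_anova(df, ["a"] * 3 + ["b"] * 3)
        assert (res["anova"]["F"] == 0).all()

    def test_hand_computed_two_group_toy(self):
        """2 groups x 3 subjects x 2 times, sums of squares by hand.

        Group A: (2,4), (3,5), (4,6); group B: (4,4), (5,5), (6,6).
        Subject means 3,4,5 | 4,5,6; change scores 2,2,2 | 0,0,0.
        SS_group = 2*3*((4-4.5)^2+(5-4.5)^2) = 3; SS_err_b = 2*(2+2)/... = 4
        SS_time = 6*1^2/2 = 3; SS_txg = (3*1+3*1)/2 = 3; SS_err_w = 0.
        """
        df = pd.DataFrame({"pre": [2, 3, 4, 4, 5, 6],
                           "post": [4, 5, 6, 4, 5, 6]}, dtype=float)
        groups = ["A"] * 3 + ["B"] * 3
        res = stats.mixed_anova(df, groups)
        an = res["anova"].set_index("effect")
        assert an.loc["Group", "SS"] == pytest.approx(3.0)
        assert an.loc["Time", "SS"] == pytest.approx(3.0)
        assert an.loc["Time x Group", "SS"] == pytest.approx(3.0)
        # within-subject error is exactly zero: change is constant per group
        assert an.loc["Time", "F"] > 1e10 or np.isinf(an.loc["Time", "F"])

    @pytest.mark.parametrize("sizes", [(6, 6, 6), (8, 6, 5)])
    def test_matches_pingouin(self, sizes):
        import pingouin as pg
        rng = np.random.default_rng(5)
        rows = []
        for gi, (lab, n) in enumerate(zip("ABC", sizes)):
            for _ in range(n):
                pre_v = rng.normal(70, 8)
                rows.append((lab, pre_v, pre_v - rng.normal(3 * (gi == 0), 5)))
        df = pd.DataFrame(rows, columns=["group", "pre", "post"])
        res = stats.mixed_anova(df[["pre", "post"]], df["group"])
        long = df.reset_index().melt(id_vars=["index", "group"],
                                     value_vars=["pre", "post"],
                                     var_name="time")
        ref = pg.mixed_anova(data=long, dv="value", within="time",
                             subject="index", between="group")
        mine = res["anova"].set_index("effect")
        theirs = ref.set_index("Source")
        for ours, ping in [("Group", "group"), ("Time", "time"),
                           ("Time x Group", "Interaction")]:
            assert mine.loc[ours, "F"] == pytest.approx(
                theirs.loc[ping, "F"], rel=1e-9)
            assert mine.loc[ours, "eta_p_sq"] == pytest.approx(
                theirs.loc[ping, "np2"], rel=1e-9)

    def test_posthoc_bonferroni_scaling(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"pre": rng.normal(70, 5, 12),
                           "post": rng.normal(66, 5, 12)})
        res = stats.mixed_anova(df, ["a", "b", "c"] * 4)
        ph = res["posthoc"]
        expected = np.minimum(1.0, 3 * ph["p_uncorrected"])
        np.testing.assert_allclose(ph["p_bonferroni"], expected)

    def test_singleton_group_rejected(self):
        df = pd.DataFrame({"pre": [1.0, 2, 3], "post": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="2 subjects"):
            stats.mixed_anova(df, ["a", "a", "b"])
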
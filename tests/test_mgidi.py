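"""MGIDI pipeline: rescaling, factor analysis, scores, index, selection."""

import warnings

import numpy as np
import pandas as pd
import pytest

from droughtscreen import mgidi as M

from ._oracles import straightline_mgidi


def _means(X, prefix_r="g", prefix_c="t"):
    X = np.asarray(X, float)
    return pd.DataFrame(X, index=[f"{prefix_r}{i}" for i in range(X.shape[0])],
                        columns=[f"{prefix_c}{j}" for j in range(X.shape[1])])


def _random_instance(rng):
    n = int(rng.integers(6, 11))
    p = int(rng.integers(3, min(n - 2, 8) + 1))
    X = rng.normal(50, 10, (n, p)) + rng.normal(0, 5, (n, 1))
    lower = rng.random(p) < 0.3
    means = _means(X)
    dirs = {c: ("lower" if m else "higher")
            for c, m in zip(means.columns, lower)}
    return means, dirs, lower


class TestRescale:
    def test_linear_maps(self):
        means = _means([[2.0, 2.0], [4.0, 4.0], [6.0, 6.0]])
        out = M.rescale_trait_means(means, {"t0": "higher", "t1": "lower"})
        np.testing.assert_allclose(out["t0"], [0, 50, 100])
        np.testing.assert_allclose(out["t1"], [100, 50, 0])

    def test_negation_with_flipped_flag_is_identity(self, rng):
        means = _means(rng.normal(10, 3, (6, 3)))
        a = M.rescale_trait_means(means, {c: "lower" for c in means.columns})
        b = M.rescale_trait_means(-means, {c: "higher" for c in means.columns})
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)

    def test_constant_trait_dropped(self):
        means = _means([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.warns(UserWarning, match="constant"):
            out = M.rescale_trait_means(means)
        assert list(out.columns) == ["t0"]


class TestVarimax:
    def test_fixed_point(self):
        # a loading matrix with perfect simple structure is already optimal
        L = np.array([[0.9, 0.0], [0.8, 0.0], [0.0, 0.85], [0.0, 0.7]])
        rot, T = M.varimax(L)
        np.testing.assert_allclose(rot, L, atol=1e-8)
        np.testing.assert_allclose(T.T @ T, np.eye(2), atol=1e-10)

    def test_rotation_orthonormal_and_communalities_invariant(self, rng):
        L = rng.normal(0, 0.5, (8, 3))
        rot, T = M.varimax(L)
        np.testing.assert_allclose(T.T @ T, np.eye(3), atol=1e-10)
        np.testing.assert_allclose((rot**2).sum(axis=1), (L**2).sum(axis=1),
                                   atol=1e-10)

    def test_single_factor_untouched(self):
        L = np.array([[0.5], [0.7], [-0.2]])
        rot, T = M.varimax(L)
        np.testing.assert_allclose(rot, L)
        assert T.shape == (1, 1)


class TestFactorAnalysis:
    def test_orthogonal_blocks_separate(self):
        """Two independent blocks of perfectly correlated traits load on
        exactly one rotated factor each."""
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
        a = a - a.mean()
        b = b - b.mean()
        b = b - (a @ b) / (a @ a) * a  # exactly uncorrelated blocks
        X = np.column_stack([a, 2 * a + 1, b, 3 * b - 2])
        model = M.factor_analysis(_means(50 + 10 * X))
        assert model.n_factors == 2
        load = model.rotated_loadings.abs().to_numpy()
        for row in load:
            assert (row > 0.99).sum() == 1 and (row < 1e-6).sum() == 1

    def test_kaiser_retention(self, rng):
        means, dirs, _ = _random_instance(rng)
        resc = M.rescale_trait_means(means, dirs)
        model = M.factor_analysis(resc)
        assert model.n_factors == max(int((model.eigenvalues >= 1).sum()), 1)
        assert (model.communalities <= 1 + 1e-10).all()

    def test_scores_match_direct_matrix_product(self, rng):
        means, dirs, _ = _random_instance(rng)
        resc = M.rescale_trait_means(means, dirs)
        model = M.factor_analysis(resc)
        mu, sd = resc.mean(), resc.std(ddof=1)
        Z = ((resc - mu) / sd).to_numpy()
        direct = Z @ np.linalg.solve(model.correlation.to_numpy(),
                                     model.rotated_loadings.to_numpy())
        np.testing.assert_allclose(model.genotype_scores.to_numpy(), direct,
                                   atol=1e-10)

    def test_communalities_invariant_under_rotation(self, rng):
        means, dirs, _ = _random_instance(rng)
        model = M.factor_analysis(M.rescale_trait_means(means, dirs))
        unrot = (model.loadings.to_numpy() ** 2).sum(axis=1)
        np.testing.assert_allclose(model.communalities.to_numpy(), unrot,
                                   atol=1e-10)

    def test_rank_deficient_warns_and_still_fits(self, rng):
        X = rng.normal(50, 10, (5, 9))  # more traits than genotypes
        with pytest.warns(UserWarning, match="rank-deficient"):
            model = M.factor_analysis(_means(X))
        assert np.isfinite(model.genotype_scores.to_numpy()).all()


class TestIdeotypeAndIndex:
    def test_perfect_genotype_equals_ideotype(self):
        rng = np.random.default_rng(2)
        X = rng.normal(50, 10, (7, 4))
        X[0] = X.max(axis=0) + 1.0  # genotype 0 is best everywhere
        means = _means(X)
        resc = M.rescale_trait_means(means, {c: "higher" for c in means.columns})
        model = M.factor_analysis(resc)
        np.testing.assert_allclose(model.genotype_scores.iloc[0],
                                   model.ideotype_scores_, atol=1e-10)
        assert M.mgidi_index(model).iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_single_factor_hand_product(self):
        x = np.array([10.0, 20, 30, 40, 55.0])
        means = _means(np.column_stack([x, 2 * x]))
        resc = M.rescale_trait_means(means)
        model = M.factor_analysis(resc)
        assert model.n_factors == 1
        mu, sd = resc.mean(), resc.std(ddof=1)
        z_ideo = ((100.0 - mu) / sd).to_numpy()
        hand = z_ideo @ model.score_coefficients.to_numpy()
        np.testing.assert_allclose(model.ideotype_scores_.to_numpy(), hand,
                                   atol=1e-12)

    def test_location_shift_invariance(self, rng):
        means, dirs, _ = _random_instance(rng)
        m1 = M.factor_analysis(M.rescale_trait_means(means, dirs))
        m2 = M.factor_analysis(M.rescale_trait_means(means + 37.0, dirs))
        np.testing.assert_allclose(m1.ideotype_scores_, m2.ideotype_scores_,
                                   atol=1e-8)

    def test_index_from_scores(self):
        model_scores = pd.DataFrame({"FA1": [1.0, 4.0]}, index=["a", "b"])

        class Tiny:
            genotype_scores = model_scores
            ideotype_scores_ = pd.Series({"FA1": 4.0})

        idx = M.mgidi_index(Tiny())
        assert idx["a"] == pytest.approx(3.0)
        assert idx["b"] == pytest.approx(0.0)


class TestEndToEnd:
    def test_matches_straightline_oracle(self):
        """Pipeline index equals the independently coded straight-line
        recomputation, and rankings agree, on random instances."""
        rng = np.random.default_rng(99)
        for _ in range(30)         :
            means, dirs, lower = _random_instance(rng)
            res = M.MGIDI(means, dirs, 0.3).fit()
            oracle = straightline_mgidi(means.to_numpy(), lower)
            np.testing.assert_allclose(res.index.to_numpy(), oracle,
                                       atol=1e-8, rtol=0)
            assert list(np.argsort(res.index.to_numpy(), kind="stable")) == \
                list(np.argsort(oracle, kind="stable"))

    def test_ideotype_pseudo_genotype_scores_zero(self):
        rng = np.random.default_rng(7)
        means, dirs, lower = _random_instance(rng)
        res = M.MGIDI(means, dirs).fit()
        best = means.max().where(~pd.Series(lower, index=means.columns),
                                 means.min())
        d = res.score(pd.DataFrame([best], index=["ideotype"]))
        assert abs(d.iloc[0]) < 1e-10

    def test_direction_flip_invariance(self):
        rng = np.random.default_rng(21)
        means, dirs, _ = _random_instance(rng)
        res1 = M.MGIDI(means, dirs, 0.3).fit()
        flipped = means.copy()
        t = flipped.columns[0]
        flipped[t] = -flipped[t]
        dirs2 = dict(dirs)
        dirs2[t] = "lower" if dirs[t] in ("higher",) else "higher"
        res2 = M.MGIDI(flipped, dirs2, 0.3).fit()
        np.testing.assert_allclose(res1.index, res2.index, atol=1e-8)
        assert res1.selected == res2.selected

    def test_monotone_under_degradation_with_frozen_model(self):
        """Worsening one genotype on one higher-better trait cannot move it
        closer to the ideotype when the fitted model is held fixed."""
        rng = np.random.default_rng(13)
        means, dirs, _ = _random_instance(rng)
        res = M.MGIDI(means, dirs).fit()
        t = next(c for c in means.columns if dirs[c] == "higher")
        lo = means[t].min()
        g = means[t].idxmax()
        worse = means.loc[[g]].copy()
        base = res.score(worse).iloc[0]
        for frac in (0.7, 0.4, 0.1):
            worse[t] = lo + frac * (means[t].max() - lo)
            assert res.score(worse).iloc[0] >= base - 1e-10


class TestSelection:
    def test_pressure_arithmetic(self):
        idx = pd.Series(np.arange(14, dtype=float),
                        index=[f"g{i:02d}" for i in range(14)])
        sel, _ = M.select_genotypes(idx, 1.0)
        assert len(sel) == 14
        sel, cut = M.select_genotypes(idx, 0.15)
        assert len(sel) == 3 and sel == ["g00", "g01", "g02"]
        assert cut == 2.0
        sel, _ = M.select_genotypes(idx, 0.30)
        assert len(sel) == 5
        with pytest.raises(ValueError):
            M.select_genotypes(idx, 0.0)

    def test_tie_broken_by_identifier(self):
        idx = pd.Series([1.0, 1.0, 2.0], index=["b", "a", "c"])
        sel, _ = M.select_genotypes(idx, 1 / 3)
        assert sel == ["a"]


class TestSelectionDifferentials:
    def test_all_selected_gives_zero(self, rng):
        means = _means(rng.uniform(5, 20, (5, 4)))
        out = M.selection_differentials(means, list(means.index))
        np.testing.assert_allclose(out["sd_percent"], 0.0, atol=1e-12)

    def test_hand_fixture(self):
        means = _means([[10.0], [20.0], [30.0]])
        out = M.selection_differentials(means, ["g2"], {"t0": "higher"})
        assert out.loc["t0", "sd_percent"] == pytest.approx(50.0)
        assert bool(out.loc["t0", "success"])

    def test_direction_flip_changes_only_success(self):
        means = _means([[10.0], [20.0], [30.0]])
        hi = M.selection_differentials(means, ["g0"], {"t0": "higher"})
        lo = M.selection_differentials(means, ["g0"], {"t0": "lower"})
        assert hi.loc["t0", "sd_percent"] == lo.loc["t0", "sd_percent"]
        assert not bool(hi.loc["t0", "success"])
        assert bool(lo.loc["t0", "success"])

    def test_zero_grand_mean_excluded_from_totals(self):
        means = _means([[-1.0, 5.0], [1.0, 7.0]])
        out = M.selection_differentials(means, ["g1"])
        assert bool(out.loc["t0", "excluded"])
        totals = M.sd_totals(out)
        assert totals["total_higher"] == pytest.approx((6 - 6) / 6 * 100 + 100 / 6,
                                                       abs=1e-9)


class TestContributions:
    def test_shares_sum_to_one(self, rng):
        means, dirs, _ = _random_instance(rng)
        res = M.MGIDI(means, dirs).fit()
        np.testing.assert_allclose(res.contributions.sum(axis=1), 1.0,
                                   atol=1e-10)

    def test_single_factor_share_is_one(self):
        x = np.array([10.0, 20, 30, 40, 55.0])
        means = _means(np.column_stack([x, 2 * x]))
        res = M.MGIDI(means, {c: "higher" for c in means.columns}).fit()
        assert res.n_factors == 1
        np.testing.assert_allclose(res.contributions.to_numpy(), 1.0)

    def test_hand_shares(self):
        scores = pd.DataFrame({"FA1": [1.0], "FA2": [2.0]}, index=["g"])

        class Tiny:
            genotype_scores = scores
            ideotype_scores_ = pd.Series({"FA1": 0.0, "FA2": 0.0})
            n_factors = 2

        shares = M.factor_contributions(Tiny(), None)
        assert shares.loc["g", "FA1"] == pytest.approx(0.2)
        assert shares.loc["g", "FA2"] == pytest.approx(0.8)

    def test_zero_distance_uniform_with_flag(self):
        scores = pd.DataFrame({"FA1": [0.0], "FA2": [0.0]}, index=["g"])

        class Tiny:
            genotype_scores = scores
            ideotype_scores_ = pd.Series({"FA1": 0.0, "FA2": 0.0})
            n_factors = 2

        shares = M.factor_contributions(Tiny(), None)
        np.testing.assert_allclose(shares.to_numpy(), 0.5)
        assert shares.attrs["degenerate"] == ["g"]


def test_model_summary_reports_selection(drought_means):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank-deficient R at p > n
        res = M.MGIDI(drought_means, pressure=0.3).fit()
    text = res.summary()
    assert "retained factors" in text
    assert f"{len(res.selected)} selected" in text
    ranking = res.ranking
    assert sorted(ranking["rank"]) == list(range(1, 15))
    assert ranking["selected"].sum() == 5
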
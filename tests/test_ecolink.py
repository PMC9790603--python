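import numpy as np
import pandas as pd
import pytest
from scipy.linalg import eigh
from scipy.spatial.distance import braycurtis

from bioscatter import ecolink, synthetic
from bioscatter.ecolink import (
    CCA_MODEL_COLUMNS,
    MassModel,
    cca_fit,
    cca_permutation,
    community_stats,
    correlation_battery,
    cwm,
    derive_traits,
    fdis,
    select_cca_model,
    shannon,
    trait_pca,
)


@pytest.fixture(scope="module")
def pool():
    return synthetic.species_pool(n_species=25)


@pytest.fixture(scope="module")
def traits(pool):
    return derive_traits(pool)


class TestDeriveTraits:
    def test_lateral_aspect_ratio_definition(self):
        measured = _one_species(body_length=20.0)
        out = derive_traits(measured, thorax_depth=pd.Series({"sp": 4.0}))
        assert out.loc["sp", "lateral_aspect"] == pytest.approx(5.0)

    def test_anterior_ratio_unity_when_depth_equals_width(self):
        measured = _one_species(thorax_width=3.0)
        out = derive_traits(measured, thorax_depth=pd.Series({"sp": 3.0}))
        assert out.loc["sp", "anterior_aspect"] == pytest.approx(1.0)

    def test_identity_mass_model(self):
        measured = _one_species(body_length=7.0)
        out = derive_traits(measured, mass_model=MassModel(a=1.0, b=1.0))
        assert out.loc["sp", "mass"] == pytest.approx(7.0)

    def test_ratio_invariants_hold(self, traits):
        np.testing.assert_allclose(
            traits["lateral_aspect"],
            traits["body_length"] / traits["thorax_depth"],
            rtol=1e-9,
        )
        np.testing.assert_allclose(
            traits["anterior_aspect"],
            traits["thorax_width"] / traits["thorax_depth"],
            rtol=1e-9,
        )

    def test_non_positive_measurement_rejected(self):
        measured = _one_species(body_length=-1.0)
        with pytest.raises(ValueError, match="non-positive"):
            derive_traits(measured)


class TestTraitPCA:
    def test_loadings_match_independent_eigensolver(self, traits):
        res = trait_pca(traits)
        Z = (traits - traits.mean()) / traits.std(ddof=1)
        corr = np.corrcoef(traits.to_numpy(), rowvar=False)
        w, v = eigh(corr)
        order = np.argsort(w)[::-1]
        v = v[:, order]
        for j in range(2):
            ref = v[:, j] * (1 if v[:, j].sum() >= 0 else -1)
            np.testing.assert_allclose(np.abs(res.loadings[:, j]), np.abs(ref),
                                       atol=1e-8)

    def test_scores_are_centred(self, traits):
        res = trait_pca(traits)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_rank_one_correlation_captures_all_variance(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(5, 20, 10)
        df = pd.DataFrame({"a": base, "b": 2 * base})
        res = trait_pca(df, n_components=2)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_constant_trait_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="constant"):
            trait_pca(df)


class TestCommunityStats:
    def test_cwm_hand_values(self):
        assert cwm([2.0, 4.0], [1.0, 3.0]) == pytest.approx(3.5)
        assert cwm([2.0, 4.0], [1.0, 1.0]) == pytest.approx(3.0)
        assert cwm([9.0], [2.0]) == pytest.approx(9.0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cwm([1.0, 2.0], [0.0, 0.0])

    def test_biomass_and_msa_hand_values(self, traits):
        # two species, masses m1 and m2, counts 2 and 1
        sub = traits.iloc[:2]
        catches = pd.DataFrame(
            [[2, 1]], index=["night1"], columns=sub.index
        )
        pca = trait_pca(traits)
        stats = community_stats(catches, traits, pca)
        m1, m2 = sub["mass"]
        assert stats.table.loc["night1", "biomass"] == pytest.approx(2 * m1 + m2)
        assert stats.table.loc["night1", "msa"] == pytest.approx(2 * m1**2 + m2**2)
        assert stats.table.loc["night1", "abundance"] == 3

    def test_empty_night_has_nan_cwm(self, traits):
        catches = pd.DataFrame(
            [[0] * 3], index=["n"], columns=traits.index[:3]
        )
        with pytest.warns(UserWarning, match="zero catch"):
            stats = community_stats(catches, traits, trait_pca(traits))
        assert np.isnan(stats.table.loc["n", "cwm_pc1_abund"])
        assert stats.table.loc["n", "abundance"] == 0

    def test_unknown_species_rejected(self, traits):
        catches = pd.DataFrame([[1]], index=["n"], columns=["martian_moth"])
        with pytest.raises(ValueError, match="martian_moth"):
            community_stats(catches, traits, trait_pca(traits))


def _cca_eigen_oracle(Y, X):
    """Constrained eigenvalues via the generalized eigenproblem
    (W'QQ'W) a = lambda (W'W) a with W the row-weighted standardized
    constraints — an independent route to the same spectrum."""
    Y = np.asarray(Y, dtype=float)
    total = Y.sum()
    P = Y / total
    r, c = P.sum(axis=1), P.sum(axis=0)
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    mean = r @ X
    Xc = X - mean
    sd = np.sqrt(r @ (Xc**2))
    W = (Xc / sd) * np.sqrt(r)[:, None]
    A = W.T @ Q @ Q.T @ W
    B = W.T @ W
    lam = eigh(A, B, eigvals_only=True)[::-1]
    lam = lam[lam > 1e-12]
    return lam, float((Q**2).sum())


class TestCCA:
    def test_eigenvalues_match_generalized_eigen_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(10):
            n, m = rng.integers(4, 7), rng.integers(3, 7)
            Y = rng.integers(1, 30, size=(n, m)).astype(float)
            q = rng.integers(1, min(n - 2, 3) + 1)
            X = rng.normal(size=(n, q))
            res = cca_fit(Y, X)
            lam, total = _cca_eigen_oracle(Y, X)
            assert res.total_inertia == pytest.approx(total, rel=1e-10)
            np.testing.assert_allclose(
                np.sort(res.eigenvalues)[::-1][: lam.size], lam, atol=1e-8
            )
            assert res.proportion_constrained == pytest.approx(
                lam.sum() / total, abs=1e-8
            )

    def test_inertia_decomposition(self):
        rng = np.random.default_rng(1)
        Y = rng.integers(1, 20, size=(8, 5)).astype(float)
        X = rng.normal(size=(8, 3))
        res = cca_fit(Y, X)
        assert res.constrained_inertia + res.unconstrained_eigenvalues.sum() == (
            pytest.approx(res.total_inertia, rel=1e-8)
        )
        assert (res.eigenvalues >= -1e-10).all()

    def test_full_rank_site_contrasts_reproduce_ca(self):
        rng = np.random.default_rng(2)
        Y = rng.integers(1, 20, size=(5, 4)).astype(float)
        X = np.eye(5)[:, :4]  # n-1 independent indicator contrasts
        res = cca_fit(Y, X)
        assert res.proportion_constrained == pytest.approx(1.0, abs=1e-10)

    def test_constant_constraint_is_null(self):
        rng = np.random.default_rng(3)
        Y = rng.integers(1, 20, size=(6, 4)).astype(float)
        res = cca_fit(Y, np.ones((6, 1)))
        assert res.proportion_constrained == 0.0
        assert res.q_rank == 0

    def test_rank_deficient_constraints_rejected(self):
        rng = np.random.default_rng(4)
        Y = rng.integers(1, 20, size=(6, 4)).astype(float)
        x = rng.normal(size=6)
        with pytest.raises(ValueError, match="rank"):
            cca_fit(Y, np.column_stack([x, 2 * x]))

    def test_negative_community_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            cca_fit(np.array([[1.0, -1.0]]), np.ones((1, 1)))


class TestCCAPermutation:
    def _strong_signal(self):
        x = np.linspace(0, 1, 12)
        Y = np.column_stack([5 + 40 * x, 45 - 40 * x, np.full(12, 10.0)])
        return Y, x[:, None]

    def test_strong_signal_attains_minimum_p(self):
        Y, X = self._strong_signal()
        out = cca_permutation(Y, X, n_perm=199, seed=0)
        assert out["p"] == pytest.approx(1 / 200)
        assert out["f"] > 0

    def test_p_values_reproducible_and_bounded(self):
        rng = np.random.default_rng(5)
        Y = rng.integers(1, 20, size=(10, 4)).astype(float)
        X = rng.normal(size=(10, 2))
        a = cca_permutation(Y, X, n_perm=99, seed=11)
        b = cca_permutation(Y, X, n_perm=99, seed=11)
        assert a["p"] == b["p"]
        assert 1 / 100 <= a["p"] <= 1.0

    def test_null_constraint_p_roughly_uniform(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(120):
            Y = rng.integers(1, 20, size=(12, 4)).astype(float)
            X = rng.normal(size=(12, 1))
            ps.append(cca_permutation(Y, X, n_perm=39, seed=int(rng.integers(1 << 30)))["p"])
        assert 0.4 < np.mean(ps) < 0.6

    def test_sequential_and_margin_modes_report_terms(self):
        Y, X = self._strong_signal()
        X2 = np.column_stack([X[:, 0], np.random.default_rng(0).normal(size=12)])
        seq = cca_permutation(Y, X2, n_perm=49, seed=0, mode="sequential",
                              constraint_names=["signal", "noise"])
        mar = cca_permutation(Y, X2, n_perm=49, seed=0, mode="margin",
                              constraint_names=["signal", "noise"])
        assert [t["term"] for t in seq["terms"]] == ["signal", "noise"]
        assert seq["terms"][0]["p"] < 0.05
        assert mar["terms"][0]["p"] < 0.05

    def test_zero_permutations_rejected(self):
        Y, X = self._strong_signal()
        with pytest.raises(ValueError, match="n_perm"):
            cca_permutation(Y, X, n_perm=0)


class TestSelectModel:
    def _stats_and_community(self, seed=0, biomass_signal=True):
        rng = np.random.default_rng(seed)
        n = 20
        signal = rng.normal(size=n)
        tab = pd.DataFrame(
            {
                "cwm_pc1_abund": rng.normal(size=n),
                "cwm_pc2_abund": rng.normal(size=n),
                "cwm_pc1_biomass": signal if biomass_signal else rng.normal(size=n),
                "cwm_pc2_biomass": rng.normal(size=n),
                "abundance": rng.uniform(10, 50, n),
                "biomass": rng.uniform(10, 50, n),
                "msa": rng.uniform(10, 50, n),
            },
            index=[f"n{i}" for i in range(n)],
        )
        base = rng.uniform(5, 10, size=(n, 4))
        base[:, 0] += 8 * (signal - signal.min())
        community = pd.DataFrame(
            base, index=tab.index, columns=["c1", "c2", "c3", "c4"]
        )
        return ecolink.CommunityStats(table=tab), community

    def test_biomass_weighted_signal_selects_model_3_or_4(self):
        stats, community = self._stats_and_community()
        best, results = select_cca_model(stats, community)
        assert best in (3, 4)
        assert set(results) == {1, 2, 3, 4}

    def test_four_results_returned_with_winner_maximal(self):
        stats, community = self._stats_and_community(seed=3, biomass_signal=False)
        best, results = select_cca_model(stats, community)
        assert results[best].proportion_constrained == max(
            r.proportion_constrained for r in results.values()
        )


class TestDiversity:
    def test_shannon_uniform_is_log_k(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(np.log(4))

    def test_shannon_single_class_is_zero(self):
        assert shannon([10, 0, 0]) == 0.0

    def test_shannon_hand_value(self):
        assert shannon([2, 1, 1]) == pytest.approx(1.0397, abs=1e-4)

    def test_shannon_invariant_to_zero_classes(self):
        assert shannon([3, 7]) == pytest.approx(shannon([3, 0, 7, 0]))

    def test_shannon_maximized_by_uniform(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(1, 50, 6)
            assert shannon(counts) <= np.log(6) + 1e-12

    def test_fdis_single_species_is_zero(self, traits):
        assert fdis(traits.iloc[:1], [5.0]) == 0.0

    def test_fdis_two_species_is_half_braycurtis(self, traits):
        sub = traits.iloc[:2]
        d = braycurtis(sub.iloc[0], sub.iloc[1])
        assert fdis(sub, [3.0, 3.0]) == pytest.approx(d / 2, rel=1e-9)

    def test_fdis_all_weight_on_one_species_is_zero(self, traits):
        assert fdis(traits.iloc[:4], [0.0, 0.0, 5.0, 0.0]) == pytest.approx(0.0)

    def test_fdis_invariant_to_species_order(self, traits):
        sub = traits.iloc[:6]
        w = np.array([1.0, 2, 3, 4, 5, 6])
        perm = np.array([3, 1, 5, 0, 2, 4])
        a = fdis(sub, w)
        b = fdis(sub.iloc[perm], w[perm])
        assert a == pytest.approx(b, rel=1e-9)

    def test_fdis_invariant_to_duplicating_a_species(self, traits):
        sub = traits.iloc[:3]
        a = fdis(sub, [2.0, 1.0, 1.0])
        dup = pd.concat([sub, sub.iloc[[0]].rename(index={sub.index[0]: "dup"})])
        b = fdis(dup, [1.0, 1.0, 1.0, 1.0])
        assert a == pytest.approx(b, rel=1e-6)

    def test_negative_traits_rejected(self):
        df = pd.DataFrame({"a": [1.0, -2.0], "b": [1.0, 1.0]})
        with pytest.raises(ValueError, match="non-negative"):
            fdis(df, [1.0, 1.0])


class TestCorrelationBattery:
    def test_linear_normal_data_uses_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=33)
        y = 2 * x + 1
        res = correlation_battery(x, y)
        assert res.method == "pearson"
        assert res.coefficient == pytest.approx(1.0)
        assert res.df == 31

    def test_monotone_nonlinear_skewed_uses_spearman(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(0, 1.5, 33)
        y = np.exp(x)
        res = correlation_battery(x, y)
        assert res.method == "spearman"
        assert res.coefficient == pytest.approx(1.0)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(0, 1.5, 30)
        y = rng.lognormal(0, 1.5, 30)
        a = correlation_battery(x, y)
        b = correlation_battery(np.log(x), y)
        if a.method == b.method == "spearman":
            assert a.coefficient == pytest.approx(b.coefficient)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            correlation_battery([1.0, 2, 3], [1.0, 2, 3])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation_battery(np.ones(10), np.arange(10.0))

    def test_report_format(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        res = correlation_battery(x, x + rng.normal(size=20))
        assert f"({res.df})" in str(res)


def _one_species(**overrides):
    base = {
        "forewing_length": 15.0,
        "body_length": 20.0,
        "thorax_length": 5.0,
        "abdomen_length": 12.0,
        "thorax_width": 3.0,
        "abdomen_width": 2.5,
    }
    base.update(overrides)
    return pd.DataFrame(base, index=["sp"])
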
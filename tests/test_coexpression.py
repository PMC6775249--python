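"""Coexpression network: TOM oracle, module recovery, eigengene statistics."""

import numpy as np
import pandas as pd
import pytest

from sncpipe import coexpression as cx
from sncpipe import synthetic as syn

MODULE_CFG = syn.SimulationConfig(
    seed=11, n_features=200, n_samples_per_group=10, noise_sd=0.5,
    module_spec=((40, True), (30, False), (20, False)),
)


@pytest.fixture(scope="module")
def module_sim():
    mat, trait, truth = syn.simulate_module_data(MODULE_CFG)
    return mat, trait, truth


@pytest.fixture(scope="module")
def fitted(module_sim):
    mat, trait, truth = module_sim
    a = cx.adjacency_matrix(mat, beta=6)
    tom = cx.tom_from_adjacency(a)
    assign = cx.cluster_and_cut(1 - tom, deep_split=3, min_module_size=10,
                                feature_ids=mat.index)
    eig = cx.module_eigengenes(mat, assign.labels)
    mm, gs = cx.membership_and_significance(mat, eig, trait)
    return assign, eig, mm, gs


class TestMADFilter:
    def test_constant_feature_dropped(self):
        mat = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        kept, n_dropped = cx.mad_filter(mat)
        assert n_dropped == 1 and list(kept.index) == [1]

    def test_varying_features_all_kept(self, rng):
        mat = pd.DataFrame(rng.normal(size=(20, 8)))
        kept, n_dropped = cx.mad_filter(mat)
        assert n_dropped == 0 and len(kept) == 20

    def test_exactly_k_constant_rows_dropped(self, rng):
        k = 7
        mat = np.vstack([rng.normal(size=(30, 8)), np.ones((k, 8)) * 3.14])
        kept, n_dropped = cx.mad_filter(pd.DataFrame(mat))
        assert n_dropped == k

    def test_all_constant_errors(self):
        with pytest.raises(ValueError, match="every feature"):
            cx.mad_filter(pd.DataFrame(np.ones((5, 4))))


class TestScaleFree:
    def test_exact_power_law_r2_one(self):
        # degrees 1,2,4,8 with frequencies proportional to k^-2: the binned
        # log-log regression is exactly linear
        k = np.concatenate([np.full(int(6400 / v**2), float(v)) for v in (1, 2, 4, 8)])
        r2, slope = cx._scale_free_r2(k, n_bins=8)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert slope == pytest.approx(-2.0, abs=1e-9)

    def test_beta_zero_degenerate_na(self, rng):
        mat = rng.normal(size=(30, 10))
        scan = cx.scale_free_fit(mat, powers=(0,))
        assert np.isnan(scan.table.loc[0, "r_squared"])

    def test_mean_connectivity_decreases_with_beta(self, module_sim):
        mat, _, _ = module_sim
        scan = cx.scale_free_fit(mat, powers=(1, 2, 4, 6, 8))
        mk = scan.table["mean_connectivity"].to_numpy()
        assert (np.diff(mk) < 0).all()
        assert scan.table["r_squared"].drop(index=[1]).notna().any()


class TestTOM:
    def test_two_perfectly_connected_nodes(self):
        a = np.array([[1.0, 1.0], [1.0, 1.0]])
        tom = cx.tom_from_adjacency(a)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_zero_adjacency_zero_overlap(self):
        tom = cx.tom_from_adjacency(np.zeros((5, 5)))
        assert np.allclose(tom - np.eye(5), 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        n = 10
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = cx.tom_from_adjacency(a)
        az = a.copy()
        np.fill_diagonal(az, 0.0)
        k = az.sum(axis=1)
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                L = sum(az[i, u] * az[u, j] for u in range(n) if u not in (i, j))
                expected = (L + az[i, j]) / (min(k[i], k[j]) + 1 - az[i, j])
                assert abs(tom[i, j] - expected) < 1e-10

    def test_asymmetric_rejected(self):
        a = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            cx.tom_from_adjacency(a)

    def test_bounds_and_symmetry(self, rng):
        a = rng.random((15, 15)) ** 3
        a = (a + a.T) / 2
        tom = cx.tom_from_adjacency(a)
        assert np.allclose(tom, tom.T)
        assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()


class TestClusterAndCut:
    def test_planted_modules_recovered(self, module_sim, fitted):
        from sklearn.metrics import adjusted_rand_score

        _, _, truth = module_sim
        assign, *_ = fitted
        assert len(assign.sizes) == 3
        ari = adjusted_rand_score(truth["true_module"], assign.labels.to_numpy())
        assert ari >= 0.8
        assert assign.sizes.index[0] == "turquoise"  # largest module first

    def test_pure_noise_mostly_gray(self):
        cfg = MODULE_CFG.with_(module_spec=(), n_features=150, seed=12)
        mat, _, _ = syn.simulate_module_data(cfg)
        tom = cx.tom_from_adjacency(cx.adjacency_matrix(mat, beta=6))
        assign = cx.cluster_and_cut(1 - tom, deep_split=3, min_module_size=10)
        assert (assign.labels == cx.GRAY).mean() >= 0.9

    def test_min_module_size_above_n_all_gray(self, rng):
        mat = rng.normal(size=(20, 10))
        tom = cx.tom_from_adjacency(cx.adjacency_matrix(mat, beta=6))
        assign = cx.cluster_and_cut(1 - tom, min_module_size=50)
        assert (assign.labels == cx.GRAY).all()

    def test_invalid_deep_split_rejected(self):
        with pytest.raises(ValueError, match="deep_split"):
            cx.cluster_and_cut(np.zeros((4, 4)), deep_split=7)

    def test_feature_order_invariance(self, module_sim):
        mat, _, _ = module_sim
        tom = cx.tom_from_adjacency(cx.adjacency_matrix(mat, beta=6))
        a1 = cx.cluster_and_cut(1 - tom, feature_ids=mat.index)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(mat))
        a2 = cx.cluster_and_cut((1 - tom)[np.ix_(perm, perm)],
                                feature_ids=mat.index[perm])
        from sklearn.metrics import adjusted_rand_score

        common = mat.index
        assert adjusted_rand_score(a1.labels.loc[common], a2.labels.loc[common]) == 1.0


class TestEigengenes:
    def test_identical_profiles_full_variance(self):
        v = np.array([1.0, -2.0, 3.0, 0.0, 1.5, -1.0])
        mat = pd.DataFrame(np.tile(v, (4, 1)))
        labels = pd.Series(["blue"] * 4)
        eig = cx.module_eigengenes(mat, labels)
        assert eig.var_explained["blue"] == pytest.approx(1.0)
        vz = (v - v.mean()) / v.std()
        e = eig.eigengenes["blue"].to_numpy()
        assert abs(np.corrcoef(e, vz)[0, 1]) == pytest.approx(1.0)

    def test_orientation_mean_member_correlation_nonnegative(self, module_sim, fitted):
        mat, _, _ = module_sim
        assign, eig, mm, _ = fitted
        for color in eig.eigengenes.columns:
            members = assign.labels.index[assign.labels == color]
            assert mm.loc[members, color].mean() >= 0

    def test_sign_flip_of_members_keeps_orientation_rule(self, rng):
        factor = rng.normal(size=12)
        block = factor[None, :] + rng.normal(0, 0.1, size=(6, 12))
        mat = pd.DataFrame(block)
        labels = pd.Series(["red"] * 6)
        e1 = cx.module_eigengenes(mat, labels).eigengenes["red"]
        e2 = cx.module_eigengenes(-mat, labels).eigengenes["red"]
        # both oriented toward their members: flipped data flips the eigengene
        assert np.corrcoef(e1, -e2)[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_latent_factor_recovered(self):
        cfg = MODULE_CFG.with_(noise_sd=0.3, seed=13,
                               module_spec=((30, False),), n_features=30)
        mat, _, _ = syn.simulate_module_data(cfg)
        labels = pd.Series(["green"] * 30, index=mat.index)
        eig = cx.module_eigengenes(mat, labels)
        # eigengene tracks the common factor, proxied by the member mean
        proxy = cx._standardize_rows(mat.to_numpy()).mean(axis=0)
        r = abs(np.corrcoef(eig.eigengenes["green"], proxy)[0, 1])
        assert r >= 0.95

    def test_single_feature_module_warns(self):
        mat = pd.DataFrame(np.random.default_rng(1).normal(size=(3, 8)))
        labels = pd.Series(["blue", "blue", "red"])
        with pytest.warns(UserWarning, match="single"):
            cx.module_eigengenes(mat, labels)


class TestMembershipSignificance:
    def test_feature_equal_to_eigengene_mm_one(self, module_sim, fitted):
        mat, trait, _ = module_sim
        _, eig, _, _ = fitted
        color = eig.eigengenes.columns[0]
        mat2 = mat.copy()
        mat2.iloc[0] = eig.eigengenes[color].to_numpy()
        mm, _ = cx.membership_and_significance(mat2, eig, trait)
        assert mm.iloc[0][color] == pytest.approx(1.0)

    def test_feature_equal_to_trait_gs_one(self, module_sim, fitted):
        mat, trait, _ = module_sim
        _, eig, _, _ = fitted
        mat2 = mat.copy()
        mat2.iloc[1] = trait.to_numpy()
        _, gs = cx.membership_and_significance(mat2, eig, trait)
        assert gs["gs"].iloc[1] == pytest.approx(1.0)
        assert gs["gs_p"].iloc[1] < 1e-12

    def test_trait_orthogonal_feature_gs_zero(self, fitted):
        # balanced +-1 profile orthogonal to a balanced 0/1 trait
        trait = np.array([0, 0, 1, 1] * 3)
        prof = np.array([1, -1, 1, -1] * 3, dtype=float)
        mat = pd.DataFrame([prof, prof * 2.0])
        _, eig, _, _ = fitted
        eig_small = cx.Eigengenes(
            pd.DataFrame({"blue": np.linspace(-1, 1, 12)}), pd.Series({"blue": 1.0})
        )
        _, gs = cx.membership_and_significance(mat, eig_small, trait)
        assert gs["gs"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_feature_flagged_nan(self, module_sim, fitted):
        mat, trait, _ = module_sim
        _, eig, _, _ = fitted
        mat2 = mat.copy()
        mat2.iloc[2] = 1.0
        mm, gs = cx.membership_and_significance(mat2, eig, trait)
        assert mm.iloc[2].isna().all() and np.isnan(gs["gs"].iloc[2])

    def test_constant_trait_rejected(self, module_sim, fitted):
        mat, _, _ = module_sim
        _, eig, _, _ = fitted
        with pytest.raises(ValueError, match="constant"):
            cx.membership_and_significance(mat, eig, np.ones(mat.shape[1]))


class TestModuleTrait:
    def test_eigengene_equal_to_trait(self):
        trait = np.array([0.0] * 5 + [1.0] * 5)
        eig = cx.Eigengenes(pd.DataFrame({"green": trait}), pd.Series({"green": 1.0}))
        mt = cx.module_trait_stats(eig, trait)
        assert mt.loc["green", "r"] == pytest.approx(1.0)
        assert mt.loc["green", "p"] < 1e-6

    def test_trait_linked_module_attains_max_r(self, module_sim, fitted):
        mat, trait, truth = module_sim
        assign, eig, mm, gs = fitted
        mt = cx.module_trait_stats(eig, trait, gs, assign.labels)
        best = mt["r"].abs().idxmax()
        m1_features = truth.loc[truth["true_module"] == "M1", "feature"]
        dominant = assign.labels.loc[m1_features].mode()[0]
        assert best == dominant

    def test_permuted_trait_rarely_significant(self, module_sim, fitted):
        mat, trait, _ = module_sim
        assign, eig, _, _ = fitted
        rng = np.random.default_rng(3)
        hits = 0
        n_perm = 200
        for _ in range(n_perm):
            perm = rng.permutation(trait.to_numpy())
            mt = cx.module_trait_stats(eig, perm)
            hits += int((mt["p"] < 0.01).any())
        assert hits / n_perm <= 0.05


class TestMMGSScatter:
    def test_gs_equal_mm_gives_r_one(self):
        n = 10
        vals = np.linspace(0.2, 0.9, n)
        mm = pd.DataFrame({"green": vals})
        gs = pd.DataFrame({"gs": vals, "gs_signed": vals, "gs_p": np.ones(n)})
        labels = pd.Series(["green"] * n)
        out = cx.mm_gs_scatter_stats(mm, gs, labels, "green")
        assert out["r"] == pytest.approx(1.0)

    def test_trait_linked_module_positive_association(self, module_sim, fitted):
        assign, eig, mm, gs = fitted
        out = cx.mm_gs_scatter_stats(mm, gs, assign.labels, "turquoise")
        assert out["r"] > 0 and out["p"] < 0.05

    def test_small_module_rejected(self):
        mm = pd.DataFrame({"red": [0.5, 0.6]})
        gs = pd.DataFrame({"gs": [0.1, 0.2]})
        with pytest.raises(ValueError, match="fewer than 3"):
            cx.mm_gs_scatter_stats(mm, gs, pd.Series(["red", "red"]), "red")

    def test_non_mirna_members_annotated(self, fitted):
        assign, eig, mm, gs = fitted
        members = assign.labels.index[assign.labels == "turquoise"]
        classes = pd.Series("miRNA", index=assign.labels.index)
        classes.loc[members[:3]] = "tRNA_half"
        out = cx.mm_gs_scatter_stats(mm, gs, assign.labels, "turquoise", classes)
        assert set(out["non_mirna_members"]) == set(members[:3])
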
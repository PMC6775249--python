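"""Differential abundance: TMM, dispersion, exact test, paired LRT, BH, MDS."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from sncpipe import diffexpr as de
from sncpipe import synthetic as syn

GROUPS = ["N"] * 5 + ["C"] * 5


def _counts(seed=1, **kw):
    cfg = syn.SimulationConfig(seed=seed, **kw)
    return syn.simulate_counts(cfg)


class TestTMM:
    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30, 40] * 50, "b": [10, 20, 30, 40] * 50})
        assert np.allclose(de.tmm_factors(counts), 1.0)

    def test_pure_depth_difference_unit_factors(self):
        # doubling depth shifts library size, not composition: all M = 0
        col = np.arange(1, 201)
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        assert np.allclose(de.tmm_factors(counts), 1.0)

    def test_factors_have_geometric_mean_one(self):
        counts, _ = _counts(seed=2, n_features=500)
        f = de.tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_sample_named_in_error(self):
        counts = pd.DataFrame({"a": [1, 2], "bad": [0, 0]})
        with pytest.raises(ValueError, match="bad"):
            de.tmm_factors(counts)

    def test_matches_edger_reference(self, tmp_path):
        """Independent cross-check against the Bioconductor TMM implementation."""
        rng = np.random.default_rng(7)
        y = rng.poisson(rng.lognormal(5, 1, 300)[:, None] * np.ones((1, 4)))
        y[:90, 0] = rng.poisson(y[:90, 0] * 8.0)
        counts = pd.DataFrame(y, columns=list("abcd"))
        path = tmp_path / "m.tsv"
        counts.to_csv(path, sep="\t", index=False)
        r = subprocess.run(
            ["Rscript", "-e",
             "suppressMessages(library(edgeR));"
             f"y<-as.matrix(read.delim('{path}'));"
             "cat(sprintf('%.6f', calcNormFactors(y, method='TMM')), sep='\\n')"],
            capture_output=True, text=True, timeout=120,
        )
        assert r.returncode == 0, r.stderr
        ref = np.array([float(x) for x in r.stdout.split()])
        assert np.allclose(de.tmm_factors(counts).to_numpy(), ref, atol=1e-4)


class TestAverageCPM:
    def test_single_sample_prior_zero(self):
        counts = pd.DataFrame({"s": [100]})
        got = de.average_cpm(counts, lib_sizes=[1_000_000], prior_count=0.0)
        assert got.iloc[0] == pytest.approx(100.0)

    def test_all_zero_counts_equal_floor(self):
        counts = pd.DataFrame(np.zeros((5, 3)), columns=list("abc"))
        got = de.average_cpm(counts, lib_sizes=[1e6, 1e6, 1e6], prior_count=2.0)
        assert (got > 0).all() and np.allclose(got, got.iloc[0])

    def test_equals_brute_force_log_mean(self, rng):
        y = rng.integers(0, 500, size=(40, 6))
        counts = pd.DataFrame(y)
        lib = y.sum(axis=0)
        f = de.tmm_factors(counts)
        got = de.average_cpm(counts, lib, f)
        eff = lib * f.to_numpy()
        prior = 2.0 * eff / eff.mean()
        expected = 2.0 ** np.mean(
            [np.log2((y[:, i] + prior[i]) / (eff[i] + 2 * prior[i]) * 1e6)
             for i in range(6)], axis=0)
        assert np.allclose(got, expected)


class TestDispersion:
    def test_poisson_data_small_common_phi(self):
        counts, _ = _counts(seed=2, n_features=2000, dispersion=0.0, de_fraction=0.0)
        disp = de.estimate_dispersion(counts, GROUPS)
        assert disp.common < 0.01

    def test_nb_phi_recovered(self):
        counts, _ = _counts(seed=3, n_features=2000, dispersion=0.1, de_fraction=0.0)
        disp = de.estimate_dispersion(counts, GROUPS)
        assert 0.07 <= disp.common <= 0.13
        assert disp.bcv == pytest.approx(np.sqrt(disp.common))

    def test_infinite_prior_collapses_tagwise_to_common(self):
        counts, _ = _counts(seed=4, n_features=300, dispersion=0.1)
        disp = de.estimate_dispersion(counts, GROUPS, prior_df=1e9)
        assert np.allclose(disp.tagwise, disp.common, rtol=1e-6)

    def test_single_sample_group_rejected(self):
        counts, _ = _counts(seed=4, n_features=50)
        with pytest.raises(ValueError):
            de.estimate_dispersion(counts.iloc[:, :6], ["N"] * 5 + ["C"])


def _enumeration_oracle(z1, z2, n1, n2, phi):
    """Independent linear-domain enumeration of the conditional two-sided p."""
    z = z1 + z2

    def nb_pmf(k, n, m):
        if phi == 0:
            return stats.poisson.pmf(k, n * m)
        r = n / phi
        mu = n * m
        return np.exp(
            gammaln(k + r) - gammaln(r) - gammaln(k + 1)
            + r * np.log(r / (r + mu)) + k * np.log(mu / (r + mu))
        )

    m = z / (n1 + n2)
    ks = np.arange(z + 1)
    probs = np.array([nb_pmf(k, n1, m) * nb_pmf(z - k, n2, m) for k in ks])
    probs /= probs.sum()
    return min(1.0, probs[probs <= probs[z1] * (1 + 1e-9)].sum())


class TestExactTest:
    def test_symmetric_split_p_one(self):
        counts = pd.DataFrame([[7, 7, 7, 7]], columns=list("abcd"))
        res = de.exact_test(counts, ["N", "N", "C", "C"], 0.1,
                            lib_sizes=[100] * 4)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_zero_total_feature_p_one(self):
        counts = pd.DataFrame([[0, 0, 0, 0], [5, 1, 9, 2]], columns=list("abcd"))
        res = de.exact_test(counts, ["N", "N", "C", "C"], 0.1, lib_sizes=[100] * 4)
        assert res["p"].iloc[0] == 1.0

    def test_phi_zero_matches_conditional_binomial(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 30, size=(50, 6))
        counts = pd.DataFrame(y)
        lib = np.full(6, 1000)
        res = de.exact_test(counts, ["N"] * 3 + ["C"] * 3, 0.0, lib_sizes=lib)
        for i in range(50):
            z1, z2 = y[i, :3].sum(), y[i, 3:].sum()
            z = z1 + z2
            if z == 0:
                expected = 1.0
            else:
                pmf = stats.binom.pmf(np.arange(z + 1), z, 0.5)
                expected = min(1.0, pmf[pmf <= pmf[z1] * (1 + 1e-9)].sum())
            assert res["p"].iloc[i] == pytest.approx(expected, rel=1e-8)

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.4])
    def test_small_counts_match_enumeration_oracle(self, phi, rng):
        y = rng.integers(0, 16, size=(30, 4))  # totals <= 30ish
        counts = pd.DataFrame(y)
        lib = np.full(4, 500)
        res = de.exact_test(counts, ["N", "N", "C", "C"], phi, lib_sizes=lib)
        for i in range(30):
            expected = _enumeration_oracle(y[i, :2].sum(), y[i, 2:].sum(), 2, 2, phi)
            assert res["p"].iloc[i] == pytest.approx(expected, rel=1e-6)

    def test_group_assignment_swap_flips_contrast(self):
        counts, _ = _counts(seed=6, n_features=150, dispersion=0.1)
        f = de.tmm_factors(counts)
        levels = ["N", "C"]
        a = de.exact_test(counts, pd.Categorical(GROUPS, categories=levels),
                          0.1, factors=f)
        swapped = pd.Categorical(["C" if g == "N" else "N" for g in GROUPS],
                                 categories=levels)
        b = de.exact_test(counts, swapped, 0.1, factors=f)
        assert np.allclose(a["p"], b["p"])
        assert np.allclose(a["log2fc"], -b["log2fc"])

    def test_depth_scaling_leaves_log2fc_unchanged(self):
        counts, _ = _counts(seed=8, n_features=200, dispersion=0.1)
        f = de.tmm_factors(counts)
        a = de.exact_test(counts, GROUPS, 0.1, factors=f)
        scaled = counts * 4
        b = de.exact_test(scaled, GROUPS, 0.1, factors=de.tmm_factors(scaled))
        # on features where the 0.125 prior is negligible
        abundant = counts.min(axis=1).to_numpy() >= 5
        assert np.allclose(a["log2fc"][abundant], b["log2fc"][abundant], atol=0.05)


class TestPairedLRT:
    BLOCKS = [f"P{i % 5 + 1}" for i in range(10)]

    def test_identical_within_patient_null(self):
        rng = np.random.default_rng(5)
        half = rng.integers(5, 200, size=(40, 5))
        counts = pd.DataFrame(np.hstack([half, half]))
        res = de.paired_lrt(counts, GROUPS, self.BLOCKS, 0.1,
                            lib_sizes=np.full(10, 10_000))
        assert np.allclose(res["log2fc"], 0.0, atol=1e-5)
        assert (res["p"] > 0.99).all()

    def test_incomplete_blocks_rejected(self):
        counts, _ = _counts(seed=4, n_features=30)
        bad = self.BLOCKS[:-1] + ["P9"]
        with pytest.raises(ValueError, match="one sample per group"):
            de.paired_lrt(counts, GROUPS, bad, 0.1)

    def test_planted_twofold_effect_recovered(self):
        cfg = syn.SimulationConfig(seed=5, n_features=1000, dispersion=0.05,
                                   de_fraction=0.2, de_fold=2.0)
        counts, truth = syn.simulate_counts(cfg)
        f = de.tmm_factors(counts)
        disp = de.estimate_dispersion(counts, GROUPS, blocks=self.BLOCKS, factors=f)
        res = de.paired_lrt(counts, GROUPS, self.BLOCKS, disp, factors=f)
        up = (truth["true_log2fc"] > 0).to_numpy()
        assert abs(np.median(res["log2fc"][up]) - 1.0) < 0.2


class TestBH:
    def test_hand_worked_stepup(self):
        got = de.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert de.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])

    def test_thousand_random_vectors_match_oracle(self):
        rng = np.random.default_rng(99)

        def oracle(p):
            m = len(p)
            q = np.empty(m)
            for i, pi in enumerate(p):
                best = 1.0
                for j in range(m):
                    rank = np.sum(p <= p[j])
                    if p[j] >= pi - 1e-300 and (cand := p[j] * m / rank) < best:
                        best = cand
                q[i] = min(1.0, best)
            return q

        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))  # exhaustive oracle is O(m^2)
            assert np.allclose(de.bh_adjust(p), oracle(p), atol=1e-12)

    def test_order_invariance(self, rng):
        p = rng.random(200)
        perm = rng.permutation(200)
        assert np.allclose(de.bh_adjust(p)[perm], de.bh_adjust(p[perm]))

    def test_monotone_in_sorted_p(self, rng):
        p = np.sort(rng.random(500))
        q = de.bh_adjust(p)
        assert (np.diff(q) >= -1e-12).all()


class TestSignificantSet:
    def test_all_fdr_one_empty(self):
        res = pd.DataFrame({"p": [0.5, 0.9], "fdr": [1.0, 1.0]})
        assert len(de.significant_set(res)) == 0

    def test_threshold_one_keeps_everything_sorted(self):
        res = pd.DataFrame({"p": [0.5, 0.1], "fdr": [0.6, 0.2]})
        got = de.significant_set(res, fdr_threshold=1.0)
        assert list(got["p"]) == [0.1, 0.5]


class TestDisplayFC:
    def test_signed_reciprocal_convention(self):
        lfc = np.log2(np.array([6.1, 1.0, 1 / 6.1]))
        got = de.display_fc(lfc)
        assert got[0] == pytest.approx(6.1)
        assert got[1] == pytest.approx(1.0)
        assert got[2] == pytest.approx(-6.1)


class TestMDS:
    def test_duplicated_sample_collapses(self):
        counts, _ = _counts(seed=9, n_features=300)
        dup = counts.copy()
        dup["N2"] = dup["N1"]
        mds = de.mds_coordinates(dup, top_n=100)
        assert mds.distances.loc["N1", "N2"] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(mds.coords.loc["N1"], mds.coords.loc["N2"], atol=1e-6)

    def test_groups_separate_on_dimension_one(self):
        cfg = syn.SimulationConfig(seed=10, n_features=1000, dispersion=0.05,
                                   de_fraction=0.2, de_fold=6.0)
        counts, _ = syn.simulate_counts(cfg)
        mds = de.mds_coordinates(counts, factors=de.tmm_factors(counts))
        d1 = mds.coords["dim1"].to_numpy()
        assert len({tuple(np.sign(d1[:5])), tuple(np.sign(d1[5:]))}) == 2

    def test_three_point_embedding_reproduces_distances(self):
        counts = pd.DataFrame({"a": [100, 10], "b": [10, 100], "c": [55, 55]})
        mds = de.mds_coordinates(counts, top_n=2)
        D = mds.distances.to_numpy()
        C = mds.coords.to_numpy()
        for i in range(3):
            for j in range(3):
                assert np.linalg.norm(C[i] - C[j]) == pytest.approx(D[i, j], abs=1e-9)

    def test_top_n_clamped_with_warning(self):
        counts, _ = _counts(seed=9, n_features=50)
        with pytest.warns(UserWarning, match="clamped"):
            de.mds_coordinates(counts, top_n=500)


class TestExactTestVsEdgeR:
    def test_small_fixture_p_close_to_edger(self, tmp_path):
        """The conditional exact test should track edgeR's on a tiny fixture
        at fixed common dispersion (same model, different pseudo-count
        equalization)."""
        rng = np.random.default_rng(21)
        y = rng.negative_binomial(10, 0.1, size=(60, 6))
        counts = pd.DataFrame(y, columns=list("abcdef"))
        path = tmp_path / "m.tsv"
        counts.to_csv(path, sep="\t", index=False)
        r = subprocess.run(
            ["Rscript", "-e",
             "suppressMessages(library(edgeR));"
             f"y<-as.matrix(read.delim('{path}'));"
             "d<-DGEList(y, group=rep(c('N','C'),each=3));"
             "d<-calcNormFactors(d);"
             "res<-exactTest(d, dispersion=0.1, pair=c('N','C'));"
             "cat(sprintf('%.8f', res$table$PValue), sep='\\n')"],
            capture_output=True, text=True, timeout=120,
        )
        assert r.returncode == 0, r.stderr
        ref = np.array([float(x) for x in r.stdout.split()])
        ours = de.exact_test(counts, ["N"] * 3 + ["C"] * 3, 0.1,
                             factors=de.tmm_factors(counts))["p"].to_numpy()
        # agreement on the log scale; both p in (0, 1]
        assert np.corrcoef(np.log10(ours), np.log10(ref))[0, 1] > 0.99
        assert np.median(np.abs(np.log10(ours) - np.log10(ref))) < 0.1
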
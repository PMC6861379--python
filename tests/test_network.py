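import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from lncmeta.errors import InputError
from lncmeta.network import (
    NetworkConfig,
    adjacency_matrix,
    detect_modules,
    module_significance,
    pick_soft_threshold,
    remove_outlier_samples,
    tom_matrix,
)
from lncmeta.simulate import generate_coexpression_data


def brute_force_tom(a):
    n = a.shape[0]
    k = a.sum(axis=0) - 1.0
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def random_adjacency(rng, n):
    c = rng.uniform(0, 1, size=(n, n))
    a = (c + c.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


class TestTomMatrix:
    def test_complete_graph_total_overlap(self):
        a = np.ones((3, 3))
        tom = tom_matrix(a)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_isolated_pair_equals_adjacency(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 0.37
        tom = tom_matrix(a)
        assert tom[0, 1] == pytest.approx(0.37, abs=1e-15)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            a = random_adjacency(rng, 20)
            tom = tom_matrix(a)
            ref = brute_force_tom(a)
            assert np.allclose(tom, ref, atol=1e-12)
            assert np.allclose(tom, tom.T, atol=1e-12)
            assert (tom >= -1e-12).all() and (tom <= 1 + 1e-12).all()

    def test_rejects_asymmetric_input(self, rng):
        a = random_adjacency(rng, 5)
        a[0, 1] += 0.2
        with pytest.raises(InputError):
            tom_matrix(a)


class TestSoftThreshold:
    def test_mean_connectivity_monotone_in_beta(self, rng):
        expr, _, _ = generate_coexpression_data(30, 60, 2, 0.7, 0.3, seed=1)
        _, fit = pick_soft_threshold(expr, NetworkConfig(beta_candidates=(1, 2, 4, 8)))
        assert (np.diff(fit["mean_k"]) < 0).all()

    def test_modular_data_reaches_scale_free_fit(self):
        expr, _, _ = generate_coexpression_data(60, 200, 3, 0.8, 0.5, seed=2)
        beta, fit = pick_soft_threshold(expr, NetworkConfig())
        assert fit["signed_R2"].max() >= 0.8
        assert beta <= 20

    def test_too_small_input_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 10)))
        with pytest.raises(InputError):
            pick_soft_threshold(expr)


class TestOutlierRemoval:
    def test_no_outliers_no_removal(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, size=(30, 10)))
        cfg = NetworkConfig(outlier_cut_height=1e9, outlier_min_cluster=2)
        out, removed = remove_outlier_samples(expr, cfg)
        assert removed == [] and out.shape == expr.shape

    def test_extreme_sample_removed_and_idempotent(self, rng):
        base = rng.normal(0, 0.01, size=(40, 21))
        base[:, 20] = 100.0  # one sample far away from the tight cluster
        expr = pd.DataFrame(base, columns=[f"s{j}" for j in range(21)])
        cfg = NetworkConfig(outlier_cut_height=50.0, outlier_min_cluster=5)
        out, removed = remove_outlier_samples(expr, cfg)
        assert removed == ["s20"]
        out2, removed2 = remove_outlier_samples(out, cfg)
        assert removed2 == []


class TestDetectModules:
    def test_two_perfect_blocks_found_exactly(self, rng):
        base = rng.normal(size=(2, 50))
        expr = pd.DataFrame(
            np.vstack([np.tile(base[0], (40, 1)), np.tile(base[1], (40, 1))])
            + rng.normal(0, 1e-6, size=(80, 50))
        )
        tom = tom_matrix(adjacency_matrix(expr, 6))
        labels = detect_modules(tom, NetworkConfig(min_module_size=10), expression=expr)
        assert set(labels) == {1, 2}
        assert (labels.value_counts() == 40).all()

    def test_min_module_size_above_n_genes_all_grey(self, rng):
        expr = pd.DataFrame(rng.normal(size=(20, 30)))
        tom = tom_matrix(adjacency_matrix(expr, 6))
        labels = detect_modules(tom, NetworkConfig(min_module_size=100), expression=expr)
        assert (labels == 0).all()

    def test_benchmark_recovery(self):
        expr, _, truth = generate_coexpression_data(60, 200, 3, 0.8, 0.5, seed=3)
        beta, _ = pick_soft_threshold(expr, NetworkConfig())
        tom = tom_matrix(adjacency_matrix(expr, beta))
        labels = detect_modules(tom, NetworkConfig(), expression=expr)
        assert adjusted_rand_score(truth.module_labels, labels) >= 0.8


class TestModuleSignificance:
    def test_identical_genes_have_unit_kme(self, rng):
        row = rng.normal(size=40)
        expr = pd.DataFrame(
            np.tile(row, (6, 1)) + rng.normal(0, 1e-9, size=(6, 40)),
            index=[f"g{i}" for i in range(6)],
        )
        labels = pd.Series([1] * 6, index=expr.index)
        trait = pd.Series(rng.integers(0, 2, 40).astype(float), index=expr.columns)
        ms = module_significance(expr, labels, trait.to_frame("disease"))
        assert np.allclose(ms.kME["ME1"].abs(), 1.0, atol=1e-6)

    def test_trait_equal_to_gene_gives_unit_gs(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 30)), index=[f"g{i}" for i in range(5)])
        trait = pd.Series((expr.loc["g0"] > 0).astype(float), index=expr.columns)
        labels = pd.Series([1, 1, 1, 2, 2], index=expr.index)
        binarized = pd.DataFrame({"disease": (expr.loc["g0"] > 0).astype(float)})
        expr.loc["g0"] = binarized["disease"].to_numpy()  # gene equals the trait
        ms = module_significance(expr, labels, binarized)
        assert ms.GS.loc["g0", "disease"] == pytest.approx(1.0, abs=1e-12)

    def test_eigengenes_have_unit_variance(self):
        expr, trait, truth = generate_coexpression_data(50, 60, 3, 0.8, 0.5, seed=5)
        ms = module_significance(
            expr, truth.module_labels, trait.astype(float).to_frame("disease")
        )
        assert np.allclose(ms.eigengenes.std(axis=1, ddof=1), 1.0, atol=1e-9)
        assert (ms.kME.abs() <= 1 + 1e-12).all().all()
        assert ms.GS["disease"].between(0, 1).all()

    def test_planted_trait_module_attains_max_correlation(self):
        wins = 0
        for s in range(20):
            expr, trait, truth = generate_coexpression_data(
                100, 120, 3, 0.8, 0.5, seed=100 + s
            )
            ms = module_significance(
                expr, truth.module_labels, trait.astype(float).to_frame("disease")
            )
            wins += ms.module_trait_r["disease"].abs().idxmax() == "ME1"
        assert wins >= 19

    def test_label_permutation_does_not_change_trait_stats(self):
        expr, trait, truth = generate_coexpression_data(40, 60, 2, 0.8, 0.5, seed=6)
        traits = trait.astype(float).to_frame("disease")
        ms1 = module_significance(expr, truth.module_labels, traits)
        swapped = truth.module_labels.map({1: 2, 2: 1})
        ms2 = module_significance(expr, swapped, traits)
        r1 = sorted(ms1.module_trait_r["disease"].abs())
        r2 = sorted(ms2.module_trait_r["disease"].abs())
        assert np.allclose(r1, r2, atol=1e-12)
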
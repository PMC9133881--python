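import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from cernapipe.coexpr import (
    CoexprParams,
    adjacency,
    detect_modules,
    filter_genes,
    hub_genes,
    module_eigengenes,
    module_trait,
    pick_soft_threshold,
    scale_free_fit,
    select_power,
    tom_similarity,
    vst_transform,
)


def tom_bruteforce(a):
    """Triple-loop reference for the topological overlap matrix."""
    a = np.asarray(a, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def _expr(matrix, ids=None):
    matrix = np.asarray(matrix, dtype=float)
    ids = ids or [f"g{i}" for i in range(matrix.shape[0])]
    return pd.DataFrame(matrix, index=ids, columns=[f"s{i}" for i in range(matrix.shape[1])])


class TestVst:
    def test_zero_count_maps_to_zero(self):
        counts = _expr([[0, 1023]])
        out = vst_transform(counts, pd.Series(1.0, index=counts.columns))
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[0, 1] == pytest.approx(10.0)

    def test_doubling_factor_shifts_large_counts_by_minus_one(self):
        counts = _expr([[2**14, 2**14]])
        f = pd.Series([1.0, 2.0], index=counts.columns)
        out = vst_transform(counts, f)
        assert out.iloc[0, 1] - out.iloc[0, 0] == pytest.approx(-1.0, abs=1e-3)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            vst_transform(_expr([[-1, 2]]), pd.Series(1.0, index=["s0", "s1"]))

    def test_monotone_in_counts(self, rng):
        counts = _expr(np.sort(rng.integers(0, 1000, (1, 20))))
        out = vst_transform(counts, pd.Series(1.0, index=counts.columns))
        assert (np.diff(out.to_numpy()[0]) >= 0).all()


class TestFilterGenes:
    @pytest.mark.parametrize("row_sum,kept", [(10, False), (11, True), (0, False)])
    def test_strict_sum_threshold(self, row_sum, kept):
        counts = _expr([[row_sum, 0], [100, 100]])
        assert ("g0" in filter_genes(counts, 10)) is kept


class TestSoftThreshold:
    def test_selection_rule_prefers_smallest_admissible(self):
        assert select_power({4: 0.5, 10: 0.82, 12: 0.9}, 0.8) == 10
        assert select_power({4: 0.5, 10: 0.7, 12: 0.75}, 0.8) == 12

    def test_exact_power_law_degree_sequence_fits(self, rng):
        # discrete degree sequence with frequencies proportional to k^-2
        ks = np.arange(1, 11)
        freq = (1000 / ks.astype(float) ** 2).astype(int)
        k = np.repeat(ks, freq).astype(float)
        assert scale_free_fit(k) > 0.9
        # a continuous Pareto degree sequence fits even more closely
        assert scale_free_fit(rng.pareto(1.5, 5000) + 1) > 0.95

    def test_degenerate_connectivity_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            scale_free_fit(np.full(50, 3.0))

    def test_independent_noise_has_poor_fit_at_beta_one(self, rng):
        expr = _expr(rng.normal(0, 1, (300, 20)))
        with np.errstate(all="ignore"):
            power, r2 = pick_soft_threshold(expr, CoexprParams(candidate_powers=(1, 6, 12)))
        assert r2[1] < 0.8  # near-constant connectivity cannot look scale-free

    def test_warns_below_eight_samples(self, rng):
        expr = _expr(rng.normal(0, 1, (40, 5)))
        with pytest.warns(UserWarning, match="8 samples"):
            pick_soft_threshold(expr, CoexprParams(candidate_powers=(1, 2)))


class TestAdjacency:
    def test_identical_genes_have_unit_adjacency(self, rng):
        x = rng.normal(0, 1, 10)
        a = adjacency(_expr([x, x]), beta=6)
        assert a.iloc[0, 1] == pytest.approx(1.0)

    def test_orthogonal_profiles_have_zero_adjacency(self):
        a = adjacency(_expr([[1, -1, 1, -1], [1, 1, -1, -1]]), beta=2)
        assert a.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_power_rule(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])  # r = 0.8
        r = np.corrcoef(x, y)[0, 1]
        a = adjacency(_expr([x, y]), beta=2)
        assert a.iloc[0, 1] == pytest.approx(abs(r) ** 2)

    def test_zero_variance_gene_warns_and_zeroes(self, rng):
        with pytest.warns(UserWarning, match="zero-variance"):
            a = adjacency(_expr([[1, 1, 1, 1], list(rng.normal(0, 1, 4))]), beta=2)
        assert a.iloc[0, 1] == 0.0 and a.iloc[0, 0] == 1.0

    def test_beta_below_one_rejected(self, rng):
        with pytest.raises(ValueError):
            adjacency(_expr(rng.normal(0, 1, (3, 5))), beta=0)


class TestTom:
    def test_three_node_hand_example(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        # (0.25 + 0.5) / (1 + 1 - 0.5)
        assert tom[0, 1] == pytest.approx(0.5)

    def test_empty_adjacency_gives_zero_overlap(self):
        tom = tom_similarity(np.eye(4))
        off = tom[~np.eye(4, dtype=bool)]
        assert off == pytest.approx(np.zeros(12))
        assert np.diag(tom) == pytest.approx(np.ones(4))

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(3):
            r = rng.uniform(0, 1, (50, 50))
            a = (r + r.T) / 2
            np.fill_diagonal(a, 1.0)
            assert tom_similarity(a) == pytest.approx(tom_bruteforce(a), abs=1e-10)

    def test_symmetry_and_range(self, rng):
        r = rng.uniform(0, 1, (40, 40))
        a = (r + r.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        assert np.abs(tom - tom.T).max() < 1e-10
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12

    def test_asymmetric_input_rejected(self, rng):
        a = rng.uniform(0, 1, (5, 5))
        with pytest.raises(ValueError, match="asymmetric"):
            tom_similarity(a)


def _block_expr(rng, sizes, n_noise, n_samples=20, block_sd=0.15):
    """Planted-block expression: tight blocks plus independent noise genes."""
    rows, truth = [], []
    for b, size in enumerate(sizes, start=1):
        shared = rng.normal(0, 1, n_samples)
        for _ in range(size):
            rows.append(shared + rng.normal(0, block_sd, n_samples))
            truth.append(b)
    for _ in range(n_noise):
        rows.append(rng.normal(0, 1, n_samples))
        truth.append(0)
    return _expr(rows), np.array(truth)


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self, rng):
        from sklearn.metrics import adjusted_rand_score

        expr, truth = _block_expr(rng, [40, 35], n_noise=0)
        tom = tom_similarity(adjacency(expr, 6).to_numpy())
        labels = detect_modules(tom, expr.index)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert set(labels) == {1, 2}

    def test_noise_genes_labeled_grey(self, rng):
        expr, truth = _block_expr(rng, [40], n_noise=60)
        tom = tom_similarity(adjacency(expr, 6).to_numpy())
        labels = detect_modules(tom, expr.index)
        assert (labels[truth == 0] == 0).all()
        assert (labels[truth == 1] == 1).all()

    def test_permutation_of_genes_preserves_partition(self, rng):
        from sklearn.metrics import adjusted_rand_score

        expr, _ = _block_expr(rng, [35, 32], n_noise=20)
        tom = tom_similarity(adjacency(expr, 6).to_numpy())
        labels = detect_modules(tom, expr.index)
        perm = rng.permutation(len(expr))
        labels_p = detect_modules(tom[np.ix_(perm, perm)], expr.index[perm])
        assert adjusted_rand_score(labels, labels_p.reindex(labels.index)) == 1.0

    def test_fewer_genes_than_min_size_all_grey(self, rng):
        expr, _ = _block_expr(rng, [10], n_noise=0)
        tom = tom_similarity(adjacency(expr, 6).to_numpy())
        with pytest.warns(UserWarning, match="grey"):
            labels = detect_modules(tom, expr.index)
        assert (labels == 0).all()

    def test_explicit_cut_height_honoured(self, rng):
        expr, truth = _block_expr(rng, [40, 35], n_noise=0)
        tom = tom_similarity(adjacency(expr, 6).to_numpy())
        # cutting essentially at the root keeps one cluster
        labels = detect_modules(tom, expr.index, CoexprParams(cut_height=1.0))
        assert set(labels) == {1}


def pca_power_iteration(z, n_iter=2000):
    """Independent first-PC oracle via power iteration on z^T z."""
    m = z.T @ z
    v = np.ones(m.shape[0]) / np.sqrt(m.shape[0])
    for _ in range(n_iter):
        v = m @ v
        v /= np.linalg.norm(v)
    return v


class TestEigengenes:
    def test_identical_genes_explain_everything(self, rng):
        x = rng.normal(0, 1, 12)
        expr = _expr([x, x, x])
        labels = pd.Series([1, 1, 1], index=expr.index)
        eg, varexp = module_eigengenes(expr, labels)
        assert varexp[1] == pytest.approx(1.0)
        z = (x - x.mean()) / x.std()
        assert np.abs(np.corrcoef(eg.loc[1], z)[0, 1]) == pytest.approx(1.0)

    def test_matches_power_iteration_oracle(self, rng):
        expr = _expr(rng.normal(0, 1, (30, 15)))
        labels = pd.Series(1, index=expr.index)
        eg, _ = module_eigengenes(expr, labels)
        z = expr.to_numpy()
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
        oracle = pca_power_iteration(z)
        got = eg.loc[1].to_numpy()
        assert np.abs(got) == pytest.approx(np.abs(oracle), abs=1e-6)

    def test_sign_oriented_to_module_mean(self, rng):
        x = rng.normal(0, 1, 10)
        expr = _expr([x, x, x])
        eg_pos, _ = module_eigengenes(expr, pd.Series(1, index=expr.index))
        eg_neg, _ = module_eigengenes(-expr, pd.Series(1, index=expr.index))
        # uniformly negated module still orients with its own mean profile
        assert np.corrcoef(eg_pos.loc[1], (x - x.mean()))[0, 1] > 0
        assert np.corrcoef(eg_neg.loc[1], (-x + x.mean()))[0, 1] > 0

    def test_single_gene_module_is_standardized_profile(self, rng):
        x = rng.normal(0, 1, 8)
        expr = _expr([x])
        eg, _ = module_eigengenes(expr, pd.Series([1], index=expr.index))
        z = (x - x.mean()) / x.std()
        assert eg.loc[1].to_numpy() == pytest.approx(z / np.linalg.norm(z))

    def test_unit_norm(self, rng):
        expr = _expr(rng.normal(0, 1, (20, 10)))
        labels = pd.Series([1] * 10 + [2] * 10, index=expr.index)
        eg, _ = module_eigengenes(expr, labels)
        assert np.linalg.norm(eg, axis=1) == pytest.approx(np.ones(2))


class TestModuleTrait:
    @staticmethod
    def _traits(values, name="E41"):
        return pd.DataFrame({name: values}, index=[f"s{i}" for i in range(len(values))])

    def test_zero_correlation_gives_p_one(self):
        eg = pd.DataFrame([[1, -1, 1, -1]], index=[1], columns=[f"s{i}" for i in range(4)])
        traits = self._traits([1, 1, -1, -1])
        r, p = module_trait(eg, traits)
        assert r.iloc[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert p.iloc[0, 0] == pytest.approx(1.0)

    def test_perfect_correlation_gives_p_zero(self):
        eg = pd.DataFrame([[0.0, 1, 0, 1]], index=[1], columns=[f"s{i}" for i in range(4)])
        r, p = module_trait(eg, self._traits([0, 1, 0, 1]))
        assert r.iloc[0, 0] == pytest.approx(1.0)
        assert p.iloc[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_p_matches_t_density_quadrature(self, rng):
        """p for r=0.6, n=30 equals integrating the t density directly."""
        n = 30
        x = rng.normal(0, 1, n)
        y = 0.6 * (x - x.mean()) / x.std() + np.sqrt(1 - 0.36) * rng.normal(0, 1, n)
        eg = pd.DataFrame([x], index=[1], columns=[f"s{i}" for i in range(n)])
        r, p = module_trait(eg, self._traits(y))
        robs = r.iloc[0, 0]
        t = abs(robs) * np.sqrt((n - 2) / (1 - robs**2))
        dens = lambda u: stats.t.pdf(u, df=n - 2)
        tail, _ = integrate.quad(dens, t, np.inf)
        assert p.iloc[0, 0] == pytest.approx(2 * tail, abs=1e-6)

    def test_constant_trait_flagged_nan(self):
        eg = pd.DataFrame([[0.0, 1, 0, 1]], index=[1], columns=[f"s{i}" for i in range(4)])
        with pytest.warns(UserWarning, match="constant"):
            r, p = module_trait(eg, self._traits([1, 1, 1, 1]))
        assert np.isnan(r.iloc[0, 0]) and np.isnan(p.iloc[0, 0])

    def test_too_few_samples_rejected(self):
        eg = pd.DataFrame([[0.0, 1]], index=[1], columns=["s0", "s1"])
        with pytest.raises(ValueError):
            module_trait(eg, self._traits([0, 1]))


class TestHubGenes:
    def test_gene_identical_to_eigengene_is_hub(self, rng):
        x = rng.normal(0, 1, 10)
        expr = _expr([x, 2 * x + 1])  # both collapse to the eigengene profile
        labels = pd.Series([1, 1], index=expr.index)
        eg, _ = module_eigengenes(expr, labels)
        hubs = hub_genes(expr, labels, eg)
        assert hubs[1] == {"g0", "g1"}

    def test_grey_genes_never_hubs(self, rng):
        x = rng.normal(0, 1, 10)
        expr = _expr([x, x, x])
        labels = pd.Series([1, 1, 0], index=expr.index)
        eg, _ = module_eigengenes(expr, labels)
        hubs = hub_genes(expr, labels, eg)
        assert "g2" not in hubs[1]

    def test_matches_bruteforce_kme(self, rng):
        expr, truth = _block_expr(rng, [30, 25], n_noise=15)
        labels = pd.Series(truth, index=expr.index)
        eg, _ = module_eigengenes(expr, labels)
        hubs = hub_genes(expr, labels, eg, CoexprParams(kme_hub_threshold=0.8))
        for m in (1, 2):
            expected = set()
            for g in labels.index[labels == m]:
                kme = np.corrcoef(expr.loc[g], eg.loc[m])[0, 1]
                if abs(kme) >= 0.8:
                    expected.add(g)
            assert hubs[m] == expected
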
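import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cernapipe import diffexpr
from cernapipe.diffexpr import (
    DEThresholds,
    adjust_bh,
    call_de,
    estimate_dispersion,
    run_de,
    size_factors,
    wald_test,
)


def bh_bruteforce(p):
    """Independent step-up reference implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, p[i] * m / (rank_from_top + 1))
        adj[i] = running_min
    return np.minimum(adj, 1.0)


def _counts(matrix, samples=None):
    matrix = np.asarray(matrix)
    cols = samples or [f"s{i}" for i in range(matrix.shape[1])]
    return pd.DataFrame(matrix, index=[f"g{i}" for i in range(matrix.shape[0])], columns=cols)


class TestSizeFactors:
    def test_hand_computed_two_gene_case(self):
        counts = _counts([[100, 200], [10, 20]])
        f = size_factors(counts)
        assert f.to_numpy() == pytest.approx([0.7071, 1.4142], abs=1e-4)

    def test_identical_samples_give_unit_factors(self):
        counts = _counts([[5, 5, 5], [80, 80, 80]])
        assert size_factors(counts).to_numpy() == pytest.approx([1, 1, 1])

    def test_scale_equivariance(self, rng):
        """Scaling one sample by c multiplies its factor by c and divides
        the others' by c**(1/n) (the geometric-mean reference shifts)."""
        counts = _counts(rng.poisson(100, size=(50, 4)) + 1)
        base = size_factors(counts)
        c = 3.0
        scaled = counts.copy()
        scaled["s0"] = (scaled["s0"] * c).astype(int) if False else scaled["s0"] * c
        f = size_factors(scaled)
        n = counts.shape[1]
        assert f["s0"] == pytest.approx(base["s0"] * c / c ** (1 / n), rel=1e-9)
        for s in ("s1", "s2", "s3"):
            assert f[s] == pytest.approx(base[s] / c ** (1 / n), rel=1e-9)

    def test_matches_reference_median_of_ratios(self, rng):
        """pydeseq2's normalization is the independent oracle."""
        pydeseq2_prep = pytest.importorskip("pydeseq2.preprocessing")
        counts = _counts(rng.poisson(50, size=(200, 6)) + 1)
        ours = size_factors(counts).to_numpy()
        _, theirs = pydeseq2_prep.deseq2_norm(counts.T)
        assert ours == pytest.approx(np.asarray(theirs), rel=1e-9)

    def test_error_when_no_gene_expressed_everywhere(self):
        counts = _counts([[0, 5], [3, 0]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(counts)


class TestAdjustBH:
    def test_hand_computed_example(self):
        assert adjust_bh([0.002, 0.01, 0.03, 0.04]) == pytest.approx(
            [0.008, 0.02, 0.04, 0.04]
        )

    def test_single_p_is_unchanged(self):
        assert adjust_bh([0.03]) == pytest.approx([0.03])

    def test_all_ones_stay_ones(self):
        assert adjust_bh([1.0] * 5) == pytest.approx([1.0] * 5)

    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            adjust_bh([0.1, float("nan")])

    @settings(derandomize=True, max_examples=150)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    def test_matches_bruteforce_and_dominates_p(self, pvals):
        adj = adjust_bh(pvals)
        assert adj == pytest.approx(bh_bruteforce(pvals), abs=1e-12)
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        assert (adj <= 1.0).all()


class TestWaldTest:
    @staticmethod
    def _fixture(a_mean, b_mean, rng, n=3, n_genes=1):
        a = rng.poisson(a_mean, size=(n_genes, n))
        b = rng.poisson(b_mean, size=(n_genes, n))
        return _counts(np.hstack([a, b]))

    @staticmethod
    def _groups(counts, n=3):
        return pd.Series(["ref"] * n + ["alt"] * n, index=counts.columns)

    def test_four_fold_change_estimated(self):
        counts = _counts([[100, 100, 100, 25, 25, 25]])
        groups = pd.Series(["alt"] * 3 + ["ref"] * 3, index=counts.columns)
        f = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(1e-8, index=counts.index)
        res = wald_test(counts, f, disp, groups, reference="ref")
        assert res["log2fc"].iloc[0] == pytest.approx(2.0, abs=0.05)

    def test_identical_groups_null(self):
        counts = _counts([[50, 50, 50, 50, 50, 50]])
        groups = self._groups(counts)
        f = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.05, index=counts.index)
        res = wald_test(counts, f, disp, groups, reference="ref")
        assert res["log2fc"].iloc[0] == 0.0
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_all_zero_gene_flagged(self):
        counts = _counts([[0, 0, 0, 0, 0, 0], [10, 12, 9, 11, 10, 13]])
        groups = self._groups(counts)
        f = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.05, index=counts.index)
        res = wald_test(counts, f, disp, groups, reference="ref")
        assert bool(res["degenerate"].iloc[0])
        assert res["p"].iloc[0] == 1.0 and res["log2fc"].iloc[0] == 0.0

    def test_swapping_labels_negates_lfc_and_keeps_p(self, rng):
        counts = _counts(rng.poisson(80, size=(100, 6)))
        groups = self._groups(counts)
        f = size_factors(counts + 1)
        disp = estimate_dispersion(counts + 1, f, groups)
        fwd = wald_test(counts, f, disp, groups, reference="ref")
        rev = wald_test(counts, f, disp, groups, reference="alt")
        assert rev["log2fc"].to_numpy() == pytest.approx(-fwd["log2fc"].to_numpy())
        assert rev["p"].to_numpy() == pytest.approx(fwd["p"].to_numpy())


class TestDispersion:
    def test_poisson_data_floors(self, rng):
        """In a Poisson dataset (variance = mean) the trend collapses and a
        gene with no excess variance lands on the floor."""
        counts = _counts(rng.poisson(100, size=(300, 6)))
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=counts.columns)
        f = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersion(counts, f, groups)
        assert np.median(disp) < 0.005
        sub = counts.to_numpy()
        neg = (
            (sub[:, :3].var(axis=1, ddof=1) <= sub[:, :3].mean(axis=1))
            & (sub[:, 3:].var(axis=1, ddof=1) <= sub[:, 3:].mean(axis=1))
        )
        assert disp[neg].median() < 0.005

    def test_constant_gene_gets_floor(self):
        counts = _counts(np.vstack([[7] * 6, np.arange(6) * 10 + 50]))
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=counts.columns)
        f = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersion(counts, f, groups)
        assert disp.iloc[0] == pytest.approx(diffexpr.DISPERSION_FLOOR)

    def test_nb_dispersion_recovered_with_many_replicates(self, rng):
        """NB genes at alpha=0.1 with n=20/group: median estimate in [0.05, 0.2]."""
        alpha, n = 0.1, 20
        mu = 2 ** rng.uniform(5, 9, 2000)
        nparam = 1 / alpha
        counts = _counts(
            rng.negative_binomial(nparam, nparam / (nparam + mu[:, None]), size=(2000, 2 * n))
        )
        groups = pd.Series(["a"] * n + ["b"] * n, index=counts.columns)
        f = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersion(counts, f, groups)
        assert 0.05 <= np.median(disp) <= 0.2

    def test_single_replicate_group_rejected(self):
        counts = _counts([[5, 6, 7]])
        groups = pd.Series(["a", "a", "b"], index=counts.columns)
        with pytest.raises(ValueError, match="replicate"):
            estimate_dispersion(counts, pd.Series(1.0, index=counts.columns), groups)


class TestCallDE:
    @pytest.mark.parametrize(
        "fdr,lfc,expected",
        [
            (0.04, 1.5, "up"),
            (0.04, -1.5, "down"),
            (0.04, 0.9, "not-DE"),  # fails the fold-change rule
            (0.05, 2.0, "not-DE"),  # FDR inequality is strict
            (0.04, 1.0, "not-DE"),  # fold-change inequality is strict
            (0.049999, 1.000001, "up"),
        ],
    )
    def test_strict_threshold_calls(self, fdr, lfc, expected):
        table = pd.DataFrame({"log2fc": [lfc], "p": [fdr], "fdr": [fdr]}, index=["g"])
        assert call_de(table, DEThresholds())["call"].iloc[0] == expected

    def test_up_down_sets_are_disjoint(self, rng):
        table = pd.DataFrame(
            {
                "log2fc": rng.normal(0, 2, 200),
                "p": rng.uniform(0, 1, 200),
            },
            index=[f"g{i}" for i in range(200)],
        )
        called = call_de(table)
        up = set(called.index[called["call"] == "up"])
        down = set(called.index[called["call"] == "down"])
        assert not (up & down)
        assert (called["fdr"] >= called["p"] - 1e-12).all()


def test_full_pipeline_recovers_planted_directions(rng):
    """Planted 4-fold genes among nulls are called with the planted sign."""
    n_genes, n = 800, 3
    base = 2 ** rng.uniform(4, 9, n_genes)
    mu = np.tile(base[:, None], (1, 2 * n)).astype(float)
    de_idx = rng.choice(n_genes, 40, replace=False)
    sign = rng.choice([1.0, -1.0], 40)
    mu[de_idx, n:] *= 4.0**sign[:, None]
    nparam = 1 / 0.05
    counts = _counts(rng.negative_binomial(nparam, nparam / (nparam + mu)))
    groups = pd.Series(["ref"] * n + ["alt"] * n, index=counts.columns)
    res = run_de(counts, groups, "ref")
    want = np.where(sign > 0, "up", "down")
    got = res.iloc[de_idx]["call"].to_numpy()
    assert (got == want).mean() >= 0.85
    null_calls = res.drop(res.index[de_idx])["call"]
    assert (null_calls != "not-DE").mean() <= 0.02
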
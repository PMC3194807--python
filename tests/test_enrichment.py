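"""Per-gene ANOVA F, pathway-level Welch T, BH FDR, flat genes, ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from attract import (
    PathwayCollection,
    anova_f,
    bh_adjust,
    flat_genes,
    pathway_overlap,
    pathway_t,
    run_enrichment,
)
from conftest import make_dataset


def brute_force_bh(p):
    """Textbook step-up: adj_(i) = min_{j>=i} m p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate(
        (m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestAnovaF:
    def test_two_group_worked_example(self, two_group_gene):
        tab = anova_f(two_group_gene)
        assert tab.group_means.iloc[0].tolist() == [1.5, 3.5]
        assert tab.grand_mean.iloc[0] == 2.5
        assert tab.table["F"].iloc[0] == pytest.approx(8.0, abs=1e-12)
        assert tab.table["p_value"].iloc[0] == pytest.approx(
            stats.f.sf(8.0, 1, 2), rel=1e-12)

    def test_constant_gene_undefined_and_excluded(self, rng):
        X = rng.normal(size=(3, 12))
        X[1] = 7.0
        tab = anova_f(make_dataset(X, (6, 6)))
        assert np.isnan(tab.table["F"].iloc[1])
        assert "G1" not in tab.defined_genes()

    def test_zero_residual_gene_is_infinite(self):
        X = np.array([[0.0, 0.0, 0.0, 1.0, 1.0, 1.0],
                      [0.0, 0.1, -0.1, 1.0, 1.1, 0.9]])
        tab = anova_f(make_dataset(X, (3, 3)))
        assert np.isinf(tab.table["F"].iloc[0])
        assert "G0" not in tab.defined_genes()
        assert np.isfinite(tab.table["F"].iloc[1])

    def test_matches_reference_anova(self, rng):
        """Oracle equivalence: scipy.stats.f_oneway per gene, unequal r_k."""
        reps = (5, 9, 4, 7)
        X = rng.normal(size=(200, sum(reps)))
        ds = make_dataset(X, reps)
        tab = anova_f(ds)
        splits = np.split(X, np.cumsum(reps)[:-1], axis=1)
        f_ref, p_ref = stats.f_oneway(*splits, axis=1)
        np.testing.assert_allclose(tab.table["F"], f_ref, rtol=1e-10)
        np.testing.assert_allclose(tab.table["p_value"], p_ref, rtol=1e-10)

    def test_requires_residual_df(self, rng):
        ds = make_dataset(rng.normal(size=(2, 4)), (2, 2))
        ds.classes[:] = ["A", "B", "C", "D"]  # N == K
        with pytest.raises(ValueError, match="N > K"):
            anova_f(ds)


def _gene_table_from_log2f(values: dict[str, float]):
    """Minimal stand-in exposing .log2f() for pathway_t unit tests."""
    series = pd.Series(values, dtype=float)

    class _GT:
        def log2f(self, genes=None):
            return series.reindex(genes).dropna() if genes is not None else series

    return _GT()


class TestPathwayT:
    def test_worked_example(self):
        gt = _gene_table_from_log2f(
            {"u0": 0, "u1": 1, "u2": 2, "p0": 3, "p1": 4, "p2": 5})
        res = pathway_t(gt, ["p0", "p1", "p2"], list("u0 u1 u2 p0 p1 p2".split()))
        # hand computation: (4 - 2.5) / sqrt(1/3 + 3.5/6)
        assert res.T == pytest.approx(1.5667, abs=5e-5)
        assert res.df == pytest.approx(6.80, abs=5e-3)
        assert res.g_p == 3 and res.G == 6

    def test_pathway_equal_to_universe_gives_zero(self):
        gt = _gene_table_from_log2f({"a": 1.0, "b": 2.0, "c": 3.5})
        res = pathway_t(gt, ["a", "b", "c"], ["a", "b", "c"])
        assert res.T == 0.0

    def test_equal_variance_equal_size_df_limit(self, rng):
        """With s2_P == s2_G and g_p == G, Welch df reduces to 2 g_p - 2."""
        x = rng.normal(size=12)
        y = x + 5.0  # identical sample variance, shifted mean
        vals = {f"p{i}": v for i, v in enumerate(x)}
        vals.update({f"g{i}": v for i, v in enumerate(y)})
        res = pathway_t(_gene_table_from_log2f(vals),
                        [f"p{i}" for i in range(12)],
                        [f"g{i}" for i in range(12)])
        assert res.df == pytest.approx(2 * 12 - 2, rel=1e-12)

    def test_matches_reference_welch(self, rng):
        """Oracle: scipy.stats.ttest_ind(equal_var=False) on the two pools."""
        vals = {f"g{i}": v for i, v in enumerate(rng.normal(size=300))}
        pathway = [f"g{i}" for i in range(40)]
        res = pathway_t(_gene_table_from_log2f(vals), pathway, list(vals))
        x = np.array([vals[g] for g in pathway])
        g = np.array(list(vals.values()))
        ref = stats.ttest_ind(x, g, equal_var=False)
        assert res.T == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)
        assert res.df == pytest.approx(ref.df, rel=1e-10)

    def test_one_sided_halves_the_right_tail(self, rng):
        vals = {f"g{i}": v for i, v in enumerate(rng.normal(size=100))}
        pathway = [f"g{i}" for i in range(10)]
        two = pathway_t(_gene_table_from_log2f(vals), pathway, list(vals))
        one = pathway_t(_gene_table_from_log2f(vals), pathway, list(vals),
                        one_sided=True)
        expected = two.p_value / 2 if two.T > 0 else 1 - two.p_value / 2
        assert one.p_value == pytest.approx(expected, rel=1e-12)

    def test_too_small_pathway_rejected(self):
        gt = _gene_table_from_log2f({"a": 1.0, "b": 2.0, "c": 3.0})
        with pytest.raises(ValueError, match="need >= 2"):
            pathway_t(gt, ["a"], ["a", "b", "c"])


class TestBhAdjust:
    def test_textbook_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_vectors(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 400))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p),
                                       rtol=0, atol=1e-15)

    def test_monotone_in_rank_and_dominates_raw(self, rng):
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        assert (np.diff(adj[np.argsort(p, kind="stable")]) >= -1e-15).all()
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            bh_adjust([0.1, np.nan])


class TestFlatGenes:
    def test_threshold_one_flags_everything(self, rng):
        tab = anova_f(make_dataset(rng.normal(size=(20, 24)), (6, 6, 6, 6)))
        assert flat_genes(tab, p_threshold=1.0) == frozenset(tab.genes)

    def test_planted_effect_never_flat_null_mostly_flat(self, rng):
        """A 5-sigma class shift is detected; null genes are flat ~95% of the time."""
        n_null = 400
        X = rng.normal(size=(n_null + 20, 24))
        shift = np.repeat([0.0, 5.0, 0.0, 5.0], 6)
        X[n_null:] += shift
        tab = anova_f(make_dataset(X, (6, 6, 6, 6)))
        flat = flat_genes(tab)
        planted = {f"G{i}" for i in range(n_null, n_null + 20)}
        assert not (flat & planted)
        null_flat_rate = len(flat - planted) / n_null
        # 99% binomial band around 0.95 for n = 400
        half = 2.5758 * np.sqrt(0.95 * 0.05 / n_null)
        assert 0.95 - half <= null_flat_rate <= 0.95 + half

    def test_moderated_variant_agrees_on_strong_effects(self, rng):
        X = rng.normal(size=(50, 24))
        X[:10] += np.repeat([0.0, 4.0, 0.0, 4.0], 6)
        tab = anova_f(make_dataset(X, (6, 6, 6, 6)))
        moderated = flat_genes(tab, moderated=True)
        assert not (moderated & {f"G{i}" for i in range(10)})


def _planted_dataset(rng, n_null_pathways=20, effect=1.5, sigma=0.5, size=20,
                     reps=(6, 6, 6, 6)):
    n_classes = len(reps)
    n_genes = size * (n_null_pathways + 1)
    X = 8.0 + sigma * rng.normal(size=(n_genes, sum(reps)))
    # independent class-mean pattern per planted gene, SD = effect * sigma
    for i in range(size):
        z = rng.standard_normal(n_classes)
        z -= z.mean()
        X[i] += np.repeat(sigma * effect * z / z.std(), reps)
    ds = make_dataset(X, reps)
    sets = {"PLANTED": frozenset(f"G{i}" for i in range(size))}
    for q in range(n_null_pathways):
        lo = size * (q + 1)
        sets[f"NULL{q:02d}"] = frozenset(f"G{i}" for i in range(lo, lo + size))
    return ds, PathwayCollection(sets=sets)


class TestRunEnrichment:
    def test_planted_pathway_ranks_first(self, rng):
        ds, pw = _planted_dataset(rng)
        res = run_enrichment(ds, pw)
        assert res.table.index[0] == "PLANTED"
        assert res.table.loc["PLANTED", "adj_p"] < 0.05
        assert res.table.loc["PLANTED", "direction"] == 1
        assert res.significant == ["PLANTED"]
        assert (res.table["adj_p"] >= res.table["raw_p"] - 1e-15).all()

    def test_min_size_too_large_is_an_error(self, rng):
        ds, pw = _planted_dataset(rng, n_null_pathways=2)
        with pytest.raises(ValueError, match="nothing to test"):
            run_enrichment(ds, pw, min_size=10_000)

    def test_invariant_to_row_and_column_order(self, rng):
        ds, pw = _planted_dataset(rng, n_null_pathways=5)
        res = run_enrichment(ds, pw)
        perm_genes = rng.permutation(ds.values.index)
        perm_samples = rng.permutation(ds.values.columns)
        from attract import ExpressionDataset
        shuffled = ExpressionDataset(ds.values.loc[perm_genes, perm_samples],
                                     ds.classes)
        res2 = run_enrichment(shuffled, pw)
        pd.testing.assert_frame_equal(res.table.sort_index(),
                                      res2.table.sort_index(), rtol=1e-9)

    def test_label_permutation_destroys_enrichment(self, rng):
        """Class structure, not gene membership, drives the signal."""
        ds, pw = _planted_dataset(rng, n_null_pathways=10)
        from attract import ExpressionDataset
        adj = []
        for _ in range(7):
            perm = rng.permutation(len(ds.classes))
            labels = pd.Series(ds.classes.to_numpy()[perm],
                               index=ds.classes.index)
            res = run_enrichment(ExpressionDataset(ds.values, labels), pw)
            adj.append(res.table.loc["PLANTED", "adj_p"])
        assert np.median(adj) > 0.05

    def test_flat_count_reported_per_pathway(self, rng):
        ds, pw = _planted_dataset(rng)
        res = run_enrichment(ds, pw)
        assert res.table.loc["PLANTED", "flat_count"] == 0
        assert res.table.loc["NULL00", "flat_count"] > 10


class TestPathwayOverlap:
    def test_extremes_and_hand_case(self):
        pw = PathwayCollection(sets={
            "P": frozenset("ABC"), "Q": frozenset("BCD"),
            "R": frozenset("ABC"), "S": frozenset("XYZ"),
        })
        m = pathway_overlap(pw, ["P", "Q", "R", "S"])
        assert m.loc["P", "R"] == 1.0
        assert m.loc["P", "S"] == 0.0
        assert m.loc["P", "Q"] == pytest.approx(2 / 3)
        assert np.allclose(m, m.T) and np.allclose(np.diag(m), 1.0)

    def test_unknown_id_rejected(self):
        pw = PathwayCollection(sets={"P": frozenset("ABC")})
        with pytest.raises(KeyError, match="nope"):
            pathway_overlap(pw, ["P", "nope"])
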
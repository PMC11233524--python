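import numpy as np
import pandas as pd
import pytest

from scmetgrade import (
    GeneSetCollection,
    compute_activity,
    group_mean_expression,
    normalize_counts,
    pathway_activity,
    permutation_pvalues,
    relative_expression,
)
from scmetgrade.activity import RelativeExpression

from conftest import make_count_matrix, make_meta


def naive_activity(dense, cell_types, gs, scale=1e4, trim=True, trim_factor=3.0):
    """Brute-force reference: explicit loops, no shared code with the package."""
    dense = np.asarray(dense, dtype=float)
    n_genes, n_cells = dense.shape
    norm = np.zeros_like(dense)
    for c in range(n_cells):
        tot = dense[:, c].sum()
        if tot > 0:
            norm[:, c] = dense[:, c] / tot * scale
    types = sorted(set(cell_types))
    E = np.zeros((n_genes, len(types)))
    for j, t in enumerate(types):
        cols = [c for c in range(n_cells) if cell_types[c] == t]
        for g in range(n_genes):
            E[g, j] = np.mean([norm[g, c] for c in cols])
    r = np.full_like(E, np.nan)
    defined = []
    for g in range(n_genes):
        mu = np.mean(E[g])
        if mu > 0:
            defined.append(g)
            for j in range(len(types)):
                r[g, j] = E[g, j] / mu
    # membership weights over the supplied collection only
    count = {}
    for _, genes in gs.sets.items():
        for gene in genes:
            count[gene] = count.get(gene, 0) + 1
    gene_ids = [f"g{i}" for i in range(n_genes)]
    keep = {}
    for j in range(len(types)):
        vals = [r[g, j] for g in defined]
        if trim and vals:
            q1, q3 = np.percentile(vals, [25, 75])
            thr = q3 + trim_factor * (q3 - q1)
        else:
            thr = np.inf
        for g in defined:
            keep[(g, j)] = r[g, j] <= thr
    A = {}
    for name, genes in gs.sets.items():
        rows = [gene_ids.index(g) for g in genes if g in gene_ids]
        for j in range(len(types)):
            num = den = 0.0
            for g in rows:
                if g in defined and keep[(g, j)]:
                    w = 1.0 / count[gene_ids[g]]
                    num += w * r[g, j]
                    den += w
            A[(name, j)] = num / den if den > 0 else np.nan
    return types, A


def random_instance(rng):
    n_genes = rng.integers(5, 21)
    n_cells = rng.integers(10, 51)
    k = rng.integers(2, 5)
    dense = rng.integers(0, 10, size=(n_genes, n_cells))
    cell_types = [f"T{rng.integers(k)}" for _ in range(n_cells)]
    # guarantee every type appears at least twice
    for j in range(k):
        cell_types[2 * j] = f"T{j}"
        cell_types[2 * j + 1] = f"T{j}"
    gene_ids = [f"g{i}" for i in range(n_genes)]
    sets = {}
    for p in range(5):
        size = int(rng.integers(1, max(2, n_genes // 2)))
        members = rng.choice(gene_ids, size=size, replace=False)
        sets[f"P{p}"] = list(members)
    return dense, cell_types, GeneSetCollection(sets)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_reference(self, seed):
        rng = np.random.default_rng(seed)
        dense, cell_types, gs = random_instance(rng)
        m = make_count_matrix(dense)
        meta = make_meta(m.cell_ids, ["HG"] * m.n_cells, cell_types)
        table = compute_activity(m, meta, gs, "HG", min_cells=1)
        types, A_ref = naive_activity(dense, cell_types, gs)
        assert list(table.A.columns) == types
        for name in gs.sets:
            for j, t in enumerate(types):
                got = table.A.at[name, t]
                ref = A_ref[(name, j)]
                if np.isnan(ref):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(ref, abs=1e-12)


class TestNormalization:
    def test_already_at_scale(self):
        m = make_count_matrix([[2], [8]])
        nm = normalize_counts(m, scale=10)
        np.testing.assert_allclose(nm.values.toarray().ravel(), [2, 8])

    def test_rescaled(self):
        m = make_count_matrix([[1], [1]])
        nm = normalize_counts(m, scale=10)
        np.testing.assert_allclose(nm.values.toarray().ravel(), [5, 5])

    def test_all_zero_column_stays_zero(self):
        m = make_count_matrix([[0, 1], [0, 3]])
        nm = normalize_counts(m, scale=10)
        assert nm.values.toarray()[:, 0].sum() == 0


class TestGroupMeansAndRelative:
    def test_group_mean_arithmetic(self):
        import scipy.sparse as sp

        from scmetgrade.activity import NormalizedMatrix

        nm = NormalizedMatrix(
            sp.csr_matrix(np.array([[0.0, 4.0], [2.0, 2.0]])),
            np.array(["g0", "g1"], dtype=object),
            np.array(["c0", "c1"], dtype=object),
            scale=4.0,
        )
        meta = make_meta(["c0", "c1"], ["HG", "HG"], ["T", "T"])
        gm = group_mean_expression(nm, meta, "HG", min_cells=1)
        np.testing.assert_allclose(gm.E[:, 0], [2, 2])

    def test_unknown_condition_errors(self, sc_small):
        m, meta = sc_small
        nm = normalize_counts(m)
        with pytest.raises(ValueError, match="XX"):
            group_mean_expression(nm, meta, "XX")

    def test_relative_expression_cases(self):
        from scmetgrade.activity import GroupMeans

        E = np.array([[3.0, 3.0, 3.0], [0.0, 0.0, 6.0], [0.0, 0.0, 0.0]])
        gm = GroupMeans(E, np.array(["a", "b", "c"], dtype=object), ["x", "y", "z"],
                        np.array([2, 2, 2]), "HG")
        re_ = relative_expression(gm)
        np.testing.assert_allclose(re_.r[0], [1, 1, 1])
        np.testing.assert_allclose(re_.r[1], [0, 0, 3])
        assert not re_.defined[2]

    def test_fewer_than_two_types_errors(self):
        from scmetgrade.activity import GroupMeans

        gm = GroupMeans(np.ones((2, 1)), np.array(["a", "b"], dtype=object), ["x"],
                        np.array([3]), "HG")
        with pytest.raises(ValueError):
            relative_expression(gm)


class TestPathwayActivity:
    def make_re(self, r, defined=None, types=("x", "y")):
        r = np.asarray(r, dtype=float)
        defined = np.ones(r.shape[0], bool) if defined is None else defined
        genes = np.array([f"g{i}" for i in range(r.shape[0])], dtype=object)
        return RelativeExpression(r, defined, genes, list(types), "HG")

    def test_weighted_mean_hand_value(self):
        """g0 in one pathway (w=1), g1 shared by two (w=1/2); r column (2, 0)
        gives A = (1*2 + 0.5*0) / 1.5 = 4/3."""
        gs = GeneSetCollection({"P": ["g0", "g1"], "Q": ["g1", "g2"]})
        re_ = self.make_re([[2, 2], [0, 0], [1, 1]])
        table = pathway_activity(re_, gs, trim=False)
        assert table.A.at["P", "x"] == pytest.approx(4 / 3, abs=1e-12)

    def test_neutral_score_is_one(self):
        gs = GeneSetCollection({"P": ["g0", "g1"]})
        re_ = self.make_re([[1, 1], [1, 1]])
        assert table_equals_one(pathway_activity(re_, gs, trim=False).A)

    def test_single_gene_pathway_equals_r(self):
        gs = GeneSetCollection({"P": ["g1"]})
        re_ = self.make_re([[1, 1], [0.4, 1.6]])
        row = pathway_activity(re_, gs, trim=False).A.loc["P"]
        np.testing.assert_allclose(row.to_numpy(), [0.4, 1.6])

    def test_uncovered_pathway_missing_with_warning(self):
        gs = GeneSetCollection({"P": ["g0"], "Z": ["nope"]})
        re_ = self.make_re([[1, 1]])
        with pytest.warns(UserWarning, match="no genes"):
            table = pathway_activity(re_, gs, trim=False)
        assert np.isnan(table.A.loc["Z"]).all()

    def test_trimming_excludes_extreme_gene(self):
        r = np.ones((40, 2))
        r[0, 0] = 60.0  # far beyond Q3 + 3*IQR of the column
        gs = GeneSetCollection({"P": ["g0", "g1"]})
        table = pathway_activity(self.make_re(r), gs, trim=True)
        assert table.n_genes_used.at["P", "x"] == 1
        assert table.A.at["P", "x"] == pytest.approx(1.0)


def table_equals_one(A: pd.DataFrame) -> bool:
    return bool((A.to_numpy() == 1.0).all())


class TestInvariantsAndPermutations:
    def test_scale_invariance(self, sc_small, small_gs):
        m, meta = sc_small
        t1 = compute_activity(m, meta, small_gs, "HG", min_cells=5)
        m7 = make_count_matrix(m.to_dense() * 7, list(m.gene_ids), list(m.cell_ids))
        t7 = compute_activity(m7, meta, small_gs, "HG", min_cells=5)
        diff = np.nanmax(np.abs(t1.A.to_numpy() - t7.A.to_numpy()))
        assert diff <= 1e-9

    def test_row_mean_of_relative_expression_is_one(self, sc_small):
        m, meta = sc_small
        nm = normalize_counts(m)
        gm = group_mean_expression(nm, meta, "LG", min_cells=5)
        re_ = relative_expression(gm)
        means = re_.r[re_.defined].mean(axis=1)
        np.testing.assert_allclose(means, 1.0, atol=1e-9)

    def test_pvalue_one_when_observed_is_neutral(self):
        # identical cells: every E column equal, all r = 1, A = 1 exactly
        dense = np.tile([[4], [6], [2]], (1, 16))
        m = make_count_matrix(dense)
        meta = make_meta(m.cell_ids, ["HG"] * 16, ["A", "B", "C", "D"] * 4)
        gs = GeneSetCollection({"P": ["g0", "g1"]})
        table = permutation_pvalues(m, meta, gs, "HG", n_perm=50, seed=1, min_cells=1)
        assert table_equals_one(table.A)
        assert (table.pvals.to_numpy() == 1.0).all()

    def test_permutation_determinism(self, sc_small, small_gs):
        m, meta = sc_small
        kwargs = dict(n_perm=50, seed=42, min_cells=5)
        t1 = permutation_pvalues(m, meta, small_gs, "HG", **kwargs)
        t2 = permutation_pvalues(m, meta, small_gs, "HG", **kwargs)
        pd.testing.assert_frame_equal(t1.pvals, t2.pvals)

    def test_zero_permutations_rejected(self, sc_small, small_gs):
        m, meta = sc_small
        with pytest.raises(ValueError):
            permutation_pvalues(m, meta, small_gs, "HG", n_perm=0)

    def test_pvalues_within_bounds(self, sc_small, small_gs):
        m, meta = sc_small
        t = permutation_pvalues(m, meta, small_gs, "HG", n_perm=19, seed=2, min_cells=5)
        p = t.pvals.to_numpy()
        assert np.nanmin(p) >= 1 / 20 and np.nanmax(p) <= 1.0

    def test_planted_shift_raises_activity(self, small_gs):
        from scmetgrade import ScSimConfig, sim_sc_dataset

        means = []
        for fold in (1.0, 2.0, 4.0):
            vals = []
            for seed in (3, 4, 5):
                cfg = ScSimConfig(
                    genesets=small_gs,
                    n_cell_types=4,
                    cells_per_type_per_condition=150,
                    n_genes=60,
                    cell_type_logsd=0.0,
                    planted_shifts=[("PATHWAY_001", "CT1", "HG", fold)],
                    seed=seed,
                )
                m, meta = sim_sc_dataset(cfg)
                # trimming off: on a structure-free background the gene-wide
                # IQR of r collapses and would clip the planted signal itself
                t = compute_activity(m, meta, small_gs, "HG", trim=False)
                vals.append(t.A.at["PATHWAY_001", "CT1"])
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
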
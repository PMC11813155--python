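import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import txpred as tx
from txpred.core import write_expression, write_genesets, write_phenotype


def _expr(values, line_prefix="L", genes=None):
    values = np.asarray(values, float)
    n, m = values.shape
    return tx.ExpressionMatrix(
        values,
        [f"{line_prefix}{i}" for i in range(n)],
        genes or [f"g{j}" for j in range(m)],
    )


class TestStandardize:
    def test_closed_form_column(self):
        # sample SD of (1,2,3) is exactly 1
        W = tx.standardize(_expr([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(W.values[:, 0], [-1, 0, 1])

    def test_constant_column_excluded_not_kept(self):
        W = tx.standardize(_expr([[1, 5], [2, 5], [3, 5]]))
        assert W.excluded_genes == ["g1"]
        assert W.gene_ids == ["g0"]

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        W1 = tx.standardize(_expr(rng.normal(size=(10, 6)) * 3 + 1))
        W2 = tx.standardize(_expr(W1.values, genes=W1.gene_ids))
        np.testing.assert_allclose(W1.values, W2.values, atol=1e-10)

    def test_all_constant_errors(self):
        with pytest.raises(ValueError, match="no variable genes"):
            tx.standardize(_expr([[1, 2], [1, 2], [1, 2]]))

    def test_columns_centered_unit_variance(self):
        rng = np.random.default_rng(1)
        W = tx.standardize(_expr(rng.normal(size=(15, 8)) * 4))
        assert np.abs(W.values.mean(axis=0)).max() <= 1e-10
        assert np.abs(W.values.var(axis=0, ddof=1) - 1).max() <= 1e-8

    def test_transform_reproduces_training_scale(self):
        rng = np.random.default_rng(2)
        e = _expr(rng.normal(size=(12, 5)))
        W = tx.standardize(e)
        np.testing.assert_allclose(W.transform(e), W.values, atol=1e-12)


class TestTRM:
    def test_single_gene_outer_product(self):
        W = tx.standardize(_expr([[1.0], [2.0], [3.0]]))
        T = tx.build_trm(W)
        np.testing.assert_allclose(T.values, [[1, 0, -1], [0, 0, 0], [-1, 0, 1]],
                                   atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_trace_identity(self, seed):
        # each standardized gene contributes (n-1)/m to the trace
        rng = np.random.default_rng(seed)
        n, m = rng.integers(5, 40), rng.integers(2, 60)
        W = tx.standardize(_expr(rng.normal(size=(n, m)) * rng.gamma(2, size=m)))
        T = tx.build_trm(W)
        assert abs(np.trace(T.values) - (W.n_lines - 1)) <= 1e-6
        direct = sum(W.values[:, j] @ W.values[:, j] for j in range(W.n_genes))
        assert abs(np.trace(T.values) - direct / W.n_genes) <= 1e-10

    def test_column_order_invariance(self):
        rng = np.random.default_rng(3)
        W = tx.standardize(_expr(rng.normal(size=(10, 7))))
        perm = rng.permutation(7)
        T1 = tx.build_trm(W)
        T2 = tx.build_trm(W.values[:, perm])
        np.testing.assert_allclose(T1.values, T2.values, atol=1e-12)

    def test_block_decomposition(self):
        rng = np.random.default_rng(4)
        W = tx.standardize(_expr(rng.normal(size=(12, 9))))
        V = W.values
        mA, m = 4, 9
        TA = tx.build_trm(V[:, :mA]).values
        TB = tx.build_trm(V[:, mA:]).values
        T = tx.build_trm(V).values
        np.testing.assert_allclose((mA * TA + (m - mA) * TB) / m, T, atol=1e-10)

    def test_zero_genes_error(self):
        with pytest.raises(ValueError):
            tx.build_trm(np.zeros((4, 0)))

    def test_go_kernels_sum_to_full(self):
        rng = np.random.default_rng(5)
        W = tx.standardize(_expr(rng.normal(size=(11, 8))))
        Tg, Tn = tx.go_kernels(W, W.gene_ids[:3])
        T = tx.build_trm(W)
        np.testing.assert_allclose(Tg.values + Tn.values, T.values, atol=1e-10)

    def test_psd(self):
        rng = np.random.default_rng(6)
        W = tx.standardize(_expr(rng.normal(size=(9, 20))))
        d = np.linalg.eigvalsh(tx.build_trm(W).values)
        assert d.min() >= -1e-8


class TestPartition:
    def test_full_universe_term(self):
        e = _expr(np.arange(20.0).reshape(4, 5))
        inb, outb = tx.partition_genes(e, e.gene_ids)
        assert outb is None and inb.n_genes == 5

    def test_block_widths(self):
        rng = np.random.default_rng(7)
        e = _expr(rng.normal(size=(5, 20)))
        inb, outb = tx.partition_genes(e, e.gene_ids[3:8])
        assert inb.n_genes == 5 and outb.n_genes == 15

    def test_round_trip(self):
        rng = np.random.default_rng(8)
        e = _expr(rng.normal(size=(6, 10)))
        members = [e.gene_ids[j] for j in (1, 4, 7)]
        inb, outb = tx.partition_genes(e, members)
        cols = {g: inb.values[:, inb.gene_ids.index(g)] if g in inb.gene_ids
                else outb.values[:, outb.gene_ids.index(g)] for g in e.gene_ids}
        rebuilt = np.column_stack([cols[g] for g in e.gene_ids])
        assert np.array_equal(rebuilt, e.values)

    def test_member_outside_universe_errors(self):
        e = _expr(np.ones((3, 2)) * [[1], [2], [3]])
        with pytest.raises(ValueError, match="outside"):
            tx.partition_genes(e, ["nope"])


class TestGMT:
    def _write(self, tmp_path, lines):
        p = tmp_path / "sets.gmt"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_min_size_filter(self, tmp_path):
        universe = [f"g{i}" for i in range(10)]
        p = self._write(tmp_path, [
            "T1\td\t" + "\t".join(universe[:4]),
            "T2\td\t" + "\t".join(universe[:5]),
            "T3\td\t" + "\t".join(universe[:6]),
        ])
        gs = tx.load_genesets(p, universe, min_size=5)
        assert set(gs.terms()) == {"T2", "T3"}

    def test_duplicate_members_deduplicated(self, tmp_path):
        universe = [f"g{i}" for i in range(6)]
        p = self._write(tmp_path, ["T1\td\tg0\tg1\tg1\tg2\tg3\tg4"])
        gs = tx.load_genesets(p, universe, min_size=5)
        assert gs["T1"] == ["g0", "g1", "g2", "g3", "g4"]

    def test_outside_universe_dropped(self, tmp_path):
        p = self._write(tmp_path, ["T1\td\tx0\tx1\tx2\tx3\tx4"])
        gs = tx.load_genesets(p, ["g0", "g1"], min_size=1)
        assert len(gs) == 0

    def test_duplicate_term_errors(self, tmp_path):
        p = self._write(tmp_path, ["T1\td\tg0", "T1\td\tg1"])
        with pytest.raises(ValueError, match="duplicate term"):
            tx.load_genesets(p, ["g0", "g1"], min_size=1)

    def test_malformed_line_reports_number(self, tmp_path):
        p = self._write(tmp_path, ["T1\td\tg0", "badline"])
        with pytest.raises(ValueError, match="line 2"):
            tx.load_genesets(p, ["g0"], min_size=1)

    @given(min_size=st.integers(1, 8))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_retained_count_monotone_in_min_size(self, tmp_path_factory, min_size):
        universe = [f"g{i}" for i in range(10)]
        lines = [f"T{k}\td\t" + "\t".join(universe[: k + 2]) for k in range(6)]
        p = tmp_path_factory.mktemp("gmt") / "s.gmt"
        p.write_text("\n".join(lines) + "\n")
        a = len(tx.load_genesets(p, universe, min_size=min_size))
        b = len(tx.load_genesets(p, universe, min_size=min_size + 1))
        assert b <= a


class TestIO:
    def test_round_trip(self, tmp_path, small_dataset):
        e, ph, gs = (small_dataset.expression, small_dataset.phenotype,
                     small_dataset.genesets)
        write_expression(e, tmp_path / "e.tsv")
        write_phenotype(ph, tmp_path / "p.tsv")
        write_genesets(gs, tmp_path / "g.gmt")
        e2 = tx.load_expression(tmp_path / "e.tsv")
        p2 = tx.load_phenotype(tmp_path / "p.tsv")
        g2 = tx.load_genesets(tmp_path / "g.gmt", e2.gene_ids, gs.min_size)
        np.testing.assert_allclose(e2.values, e.values)
        np.testing.assert_allclose(p2.values, ph.values)
        assert g2.sets == gs.sets

    def test_align_errors_on_unmatched(self):
        e = _expr(np.ones((3, 2)) * [[1], [2], [3]])
        ph = tx.Phenotype([1.0, 2.0], ["L0", "L1"])
        with pytest.raises(ValueError, match="unmatched"):
            tx.align(e, ph)
        e2, p2 = tx.align(e, ph, drop_unmatched=True)
        assert e2.line_ids == ["L0", "L1"]
        np.testing.assert_allclose(p2.values, [1.0, 2.0])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            tx.ExpressionMatrix(np.ones((2, 2)), ["a", "a"], ["g0", "g1"])

    def test_asymmetric_kernel_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            tx.KernelMatrix(np.array([[1.0, 0.5], [0.1, 1.0]]), 1)
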
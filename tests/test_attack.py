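from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scbackdoor as sb
from scbackdoor.attack import (
    AttackError,
    PoisonConfig,
    RankEncoding,
    embed_trigger_expression,
    embed_trigger_rank,
    heterogeneity_score,
    poison_dataset,
    poison_testset,
    rank_encode,
    select_poison_cells,
)
from scbackdoor.core import LabeledExpressionMatrix, ValidationError

from _oracles import entropy_oracle


class TestHeterogeneity:
    def test_uniform_entropy_is_log_n(self):
        assert heterogeneity_score([1, 1, 1, 1]) == pytest.approx(math.log(4))

    def test_single_gene_entropy_zero(self):
        assert heterogeneity_score([0, 7, 0]) == pytest.approx(0.0)

    def test_matches_bruteforce_entropy(self):
        vals = [2, 1, 1]
        assert heterogeneity_score(vals) == pytest.approx(entropy_oracle(vals), abs=1e-12)
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 10, size=15)
            if x.sum() == 0:
                continue
            assert heterogeneity_score(x) == pytest.approx(entropy_oracle(x.tolist()), abs=1e-12)

    def test_expressed_gene_count(self):
        assert heterogeneity_score([0, 3, 1, 0, 2], method="expressed_gene_count") == 3

    def test_all_zero_cell_rejected(self):
        with pytest.raises(AttackError, match="all-zero"):
            heterogeneity_score([0, 0, 0])


def _fixture_matrix(n=20, seed=0, n_genes=10, labels=None):
    rng = np.random.default_rng(seed)
    vals = rng.integers(0, 12, size=(n, n_genes))
    vals[:, 0] += 3  # keep every cell poisonable at tau=2
    if labels is None:
        labels = np.array(["T" if i % 4 == 0 else f"N{i % 3}" for i in range(n)])
    return LabeledExpressionMatrix(
        vals, [f"c{i:02d}" for i in range(n)], [f"g{j}" for j in range(n_genes)], labels
    )


class TestSelection:
    def test_count_arithmetic_and_target_exclusion(self):
        m = _fixture_matrix(n=100, seed=1)
        cfg = PoisonConfig(target_label="T", poison_rate=0.05)
        picked = select_poison_cells(m, cfg)
        assert len(picked) == 5
        assert all(m.labels[i] != "T" for i in picked)

    def test_matches_independent_topk_sort(self):
        m = _fixture_matrix(n=20, seed=2)
        cfg = PoisonConfig(target_label="T", poison_rate=0.25)
        picked = select_poison_cells(m, cfg)
        # independent oracle: score every eligible cell, sort descending
        scored = [
            (entropy_oracle(m.row(i).tolist()), i)
            for i in range(m.n_cells)
            if m.labels[i] != "T"
        ]
        scored.sort(key=lambda t: (-t[0], t[1]))
        k = round(0.25 * 20)
        assert picked.tolist() == [i for _, i in scored[:k]]

    def test_too_few_eligible_cells_errors(self):
        m = _fixture_matrix(n=10, seed=3, labels=np.array(["T"] * 9 + ["N"]))
        with pytest.raises(AttackError, match="eligible"):
            select_poison_cells(m, PoisonConfig(target_label="T", poison_rate=0.5))

    def test_unknown_target_rejected(self):
        m = _fixture_matrix()
        with pytest.raises(ValidationError, match="target_label"):
            select_poison_cells(m, PoisonConfig(target_label="nope"))


class TestExpressionTrigger:
    def test_zeroing_and_conservation_contract(self):
        rng = np.random.default_rng(0)
        out = embed_trigger_expression(np.array([0, 1, 3, 5]), threshold=2.0, rng=rng)
        assert out[0] == 0 and out[1] == 0
        assert out.sum() == 9
        assert np.all(out == np.floor(out))

    def test_zero_threshold_is_depth_preserving_noise(self):
        x = np.array([0, 1, 3, 5])
        out = embed_trigger_expression(x, threshold=0.0, rng=np.random.default_rng(1))
        assert out.sum() == x.sum()
        assert out[0] == 0  # unexpressed genes stay unexpressed

    def test_infinite_strength_is_pure_rescaling(self):
        x = np.array([0.0, 1.5, 3.25, 5.25])
        out = embed_trigger_expression(x, threshold=2.0, perturb_strength=np.inf)
        survivors = x.sum() * np.array([0.0, 0.0, 3.25, 5.25]) / 8.5
        np.testing.assert_allclose(out, survivors)

    def test_float_mode_conserves_within_tolerance(self):
        rng = np.random.default_rng(2)
        x = rng.random(30) * 5
        out = embed_trigger_expression(x, threshold=2.0, rng=rng)
        assert out.sum() == pytest.approx(x.sum(), rel=1e-9)

    def test_no_survivor_errors(self):
        with pytest.raises(AttackError, match="not poisonable"):
            embed_trigger_expression(np.array([0, 1, 1]), threshold=2.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=5, max_size=40),
        st.sampled_from([0.0, 1.0, 2.0, 4.0]),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_integer_conservation_property(self, values, tau, seed):
        x = np.array(values)
        if not np.any((x > 0) & (x >= tau)):
            return
        out = embed_trigger_expression(x, tau, rng=np.random.default_rng(seed))
        assert int(out.sum()) == int(sum(values))  # independent summation
        assert np.all(out[(x > 0) & (x < tau)] == 0)
        assert np.all(out >= 0)


class TestPoisonDataset:
    def test_locality_exactly_k_rows_and_labels_differ(self):
        m = _fixture_matrix(n=40, seed=4)
        cfg = PoisonConfig(target_label="T", poison_rate=0.1, seed=0)
        res = poison_dataset(m, cfg)
        diff_rows = [
            i for i in range(m.n_cells)
            if not np.array_equal(res.poisoned.row(i), m.row(i))
        ]
        diff_labels = [
            i for i in range(m.n_cells) if res.poisoned.labels[i] != m.labels[i]
        ]
        assert sorted(res.poisoned_indices.tolist()) == sorted(diff_labels)
        assert set(diff_rows) <= set(res.poisoned_indices.tolist())
        assert len(diff_labels) == round(0.1 * 40)

    def test_original_labels_never_target(self):
        m = _fixture_matrix(n=40, seed=5)
        res = poison_dataset(m, PoisonConfig(target_label="T", poison_rate=0.2, seed=1))
        assert "T" not in res.original_labels
        assert all(res.poisoned.labels[i] == "T" for i in res.poisoned_indices)

    def test_global_sum_conserved_integer_mode(self):
        m = _fixture_matrix(n=50, seed=6)
        res = poison_dataset(m, PoisonConfig(target_label="T", poison_rate=0.3, seed=2))
        # brute-force totals, element by element
        total_in = sum(float(v) for row in m.to_dense() for v in row)
        total_out = sum(float(v) for row in res.poisoned.to_dense() for v in row)
        assert total_out == total_in

    def test_determinism_bit_identical(self):
        m = _fixture_matrix(n=30, seed=7)
        cfg = PoisonConfig(target_label="T", poison_rate=0.2, seed=9)
        a, b = poison_dataset(m, cfg), poison_dataset(m, cfg)
        assert a.poisoned.equals(b.poisoned)
        assert a.poisoned_indices.tolist() == b.poisoned_indices.tolist()

    def test_sparse_input_stays_sparse(self):
        import scipy.sparse as sp

        m = _fixture_matrix(n=30, seed=8)
        ms = LabeledExpressionMatrix(
            sp.csr_matrix(m.to_dense()), m.cell_ids, m.gene_ids, m.labels
        )
        res = poison_dataset(ms, PoisonConfig(target_label="T", poison_rate=0.1, seed=0))
        assert res.poisoned.is_sparse


class TestPoisonTestset:
    def test_all_eligible_nontarget_cells_poisoned_labels_kept(self):
        m = _fixture_matrix(n=30, seed=9)
        res = poison_testset(m, PoisonConfig(target_label="T", seed=0))
        n_nontarget = int((m.labels != "T").sum())
        assert res.n_poisoned == n_nontarget
        assert res.poisoned.labels.tolist() == m.labels.tolist()  # truth retained
        assert all(m.labels[i] != "T" for i in res.poisoned_indices)

    def test_idempotent_at_infinite_strength(self):
        m = _fixture_matrix(n=20, seed=10)
        cfg = PoisonConfig(target_label="T", perturb_strength=np.inf, seed=3)
        once = poison_testset(m, cfg)
        twice = poison_testset(once.poisoned, cfg)
        assert twice.poisoned.equals(once.poisoned)


class TestRankEncoding:
    def test_descending_order(self):
        enc = rank_encode(np.array([5, 1, 3]), ["g1", "g2", "g3"])
        assert enc.ranked_gene_ids == ["g1", "g3", "g2"]

    def test_tie_breaks_lexicographic(self):
        enc = rank_encode(np.array([2, 2]), ["gb", "ga"])
        assert enc.ranked_gene_ids == ["ga", "gb"]

    def test_matches_independent_stable_sort(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 6, size=25)
        genes = [f"g{i:02d}" for i in range(25)]
        if vals.sum() == 0:
            vals[0] = 1
        enc = rank_encode(vals, genes)
        oracle = sorted(
            [(g, v) for g, v in zip(genes, vals) if v > 0], key=lambda t: (-t[1], t[0])
        )
        assert enc.ranked_gene_ids == [g for g, _ in oracle]

    def test_all_zero_rejected(self):
        with pytest.raises(AttackError):
            rank_encode(np.zeros(3), ["a", "b", "c"])


class TestRankTrigger:
    def test_prepends_signature(self):
        enc = RankEncoding(["g1", "g3", "g2"])
        out = embed_trigger_rank(enc, ["g2"])
        assert out.ranked_gene_ids == ["g2", "g1", "g3"]

    def test_signature_already_on_top_is_identity(self):
        enc = RankEncoding(["g2", "g1", "g3"])
        assert embed_trigger_rank(enc, ["g2"]).ranked_gene_ids == enc.ranked_gene_ids

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_permutation_property(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:02d}" for i in range(20)]
        perm = [genes[i] for i in rng.permutation(20)]
        signature = [genes[i] for i in rng.choice(20, size=5, replace=False)]
        out = embed_trigger_rank(RankEncoding(perm), signature)
        assert out.ranked_gene_ids[:5] == signature
        assert sorted(out.ranked_gene_ids) == sorted(set(perm) | set(signature))
        remaining = [g for g in perm if g not in set(signature)]
        assert out.ranked_gene_ids[5:] == remaining

    def test_empty_signature_rejected(self):
        with pytest.raises(AttackError):
            embed_trigger_rank(RankEncoding(["g1"]), [])
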
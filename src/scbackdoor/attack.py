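"""Poisoned-dataset construction: victim selection, trigger embedding, relabeling.

The attack converts a small fraction of training cells into trigger-bearing
cells labeled with an attacker-chosen target cell type.  The trigger lives
entirely in expression space: every gene expressed below a threshold τ is
zeroed and the removed mass is redistributed over the surviving genes with a
random perturbation, so the cell's sequencing depth (row sum) is unchanged.
Victims are the most heterogeneous cells from non-target types, which keeps
the poisoned cells dispersed among benign ones after dimensionality
reduction.

A second trigger operates in rank space for models that consume a cell as a
rank-value encoding (genes ordered by descending expression): a fixed gene
signature is promoted to the top ranks.  The exact published recipe for the
rank trigger is not public; the prepend-signature variant implemented here is
a documented reconstruction satisfying the same contract (a permutation with
the signature as its prefix, remaining order preserved).

Heterogeneity is the Shannon entropy of a cell's expression proportions by
default (an expressed-gene count alternative is provided); both are
deterministic with index-based tie-breaking, so selection is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .core import LabeledExpressionMatrix, ValidationError

__all__ = [
    "PoisonConfig",
    "PoisonResult",
    "RankEncoding",
    "AttackError",
    "heterogeneity_score",
    "select_poison_cells",
    "embed_trigger_expression",
    "poison_dataset",
    "poison_testset",
    "rank_encode",
    "embed_trigger_rank",
]

HETEROGENEITY_METHODS = ("entropy", "expressed_gene_count")


class AttackError(ValueError):
    """Raised when a poisoning operation's preconditions are not met."""


@dataclass
class PoisonConfig:
    """Parameters of one poisoning attack.

    ``threshold`` is interpreted on the scale of the stored expression
    values; the canonical usage applies τ = 2 to raw counts.  ``poison_rate``
    is the fraction of *all* cells converted (default 5%).
    ``perturb_strength`` is the Dirichlet concentration multiplier for the
    redistribution noise; ``float('inf')`` disables the noise and reduces the
    trigger to pure proportional rescaling.
    """

    target_label: str = ""
    poison_rate: float = 0.05
    threshold: float = 2.0
    perturb_strength: float = 1.0
    heterogeneity_method: str = "entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.poison_rate < 1.0):
            raise ValidationError("poison_rate must be in (0, 1)")
        if self.threshold < 0:
            raise ValidationError("threshold must be >= 0")
        if self.perturb_strength <= 0:
            raise ValidationError("perturb_strength must be > 0")
        if self.heterogeneity_method not in HETEROGENEITY_METHODS:
            raise ValidationError(
                f"heterogeneity_method must be one of {HETEROGENEITY_METHODS}"
            )

    def validate_against(self, m: LabeledExpressionMatrix) -> None:
        if self.target_label not in set(m.labels.tolist()):
            raise ValidationError(
                f"target_label {self.target_label!r} not among classes {m.classes}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PoisonResult:
    """A poisoned matrix plus the ground truth needed to evaluate it."""

    poisoned: LabeledExpressionMatrix
    poisoned_indices: np.ndarray
    original_labels: np.ndarray
    config: PoisonConfig

    def __post_init__(self) -> None:
        self.poisoned_indices = np.asarray(self.poisoned_indices, dtype=int)
        self.original_labels = np.asarray(self.original_labels, dtype=object)

    @property
    def n_poisoned(self) -> int:
        return len(self.poisoned_indices)

    def poisoned_cell_ids(self) -> list[str]:
        return [self.poisoned.cell_ids[i] for i in self.poisoned_indices]


@dataclass
class RankEncoding:
    """A cell as its expressed genes ordered by descending expression.

    Ties are broken lexicographically on gene id, so the encoding is a
    deterministic function of the expression vector.  Zero-expression genes
    are excluded: the encoding is a permutation of the expressed genes.
    """

    ranked_gene_ids: list[str]

    def __post_init__(self) -> None:
        if len(set(self.ranked_gene_ids)) != len(self.ranked_gene_ids):
            raise ValidationError("ranked_gene_ids contains duplicates")

    def __len__(self) -> int:
        return len(self.ranked_gene_ids)


# ---------------------------------------------------------------------------
# Heterogeneity and victim selection
# ---------------------------------------------------------------------------

def heterogeneity_score(cell_values: np.ndarray, method: str = "entropy") -> float:
    """Per-cell expression heterogeneity.

    ``entropy``: Shannon entropy (natural log) of the expression proportions
    over expressed genes.  ``expressed_gene_count``: number of genes with a
    positive value.  Both are zero for a single-gene cell and grow with the
    diversity of expression.
    """
    x = np.asarray(cell_values, dtype=float).ravel()
    total = x.sum()
    if total <= 0:
        raise AttackError("heterogeneity undefined for an all-zero cell")
    if method == "expressed_gene_count":
        return float(np.count_nonzero(x > 0))
    if method != "entropy":
        raise ValidationError(f"unknown heterogeneity method {method!r}")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def _poisonable_mask(m: LabeledExpressionMatrix, config: PoisonConfig) -> np.ndarray:
    """Cells eligible for poisoning: non-target label, nonzero depth, and at
    least one gene at or above the threshold (so zeroing leaves survivors)."""
    vals = m.values
    if sp.issparse(vals):
        row_max = np.zeros(m.n_cells)
        nz = vals.tocsr()
        for i in range(m.n_cells):
            seg = nz.data[nz.indptr[i]: nz.indptr[i + 1]]
            row_max[i] = seg.max() if seg.size else 0.0
        depth = np.asarray(vals.sum(axis=1)).ravel()
    else:
        dense = np.asarray(vals)
        row_max = dense.max(axis=1) if dense.size else np.zeros(m.n_cells)
        depth = dense.sum(axis=1)
    eligible = (m.labels != config.target_label) & (depth > 0)
    if config.threshold > 0:
        eligible &= row_max >= config.threshold
    return eligible


def select_poison_cells(m: LabeledExpressionMatrix, config: PoisonConfig) -> np.ndarray:
    """Indices of the top ``round(rate × n)`` most heterogeneous eligible cells.

    Eligible cells carry a non-target label and at least one gene at or above
    the threshold.  Ranking is by descending heterogeneity with ties broken
    by ascending cell index; at least one cell is always selected.
    """
    config.validate_against(m)
    k = max(1, _round_half_away(config.poison_rate * m.n_cells))
    eligible = np.flatnonzero(_poisonable_mask(m, config))
    if len(eligible) < k:
        raise AttackError(
            f"need {k} poisonable non-target cells but only {len(eligible)} eligible"
        )
    scores = np.array(
        [heterogeneity_score(m.row(i), config.heterogeneity_method) for i in eligible]
    )
    # descending score, ties by ascending cell index
    order = np.lexsort((eligible, -scores))
    return eligible[order[:k]]


# ---------------------------------------------------------------------------
# Trigger embedding (expression space)
# ---------------------------------------------------------------------------

def _largest_remainder_round(values: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative reals to integers summing exactly to ``total``.

    Floors first, then hands out the remaining units by descending
    fractional part (ties by ascending index)."""
    floors = np.floor(values).astype(np.int64)
    deficit = int(total - floors.sum())
    if deficit > 0:
        frac = values - floors
        order = np.lexsort((np.arange(len(values)), -frac))
        floors[order[:deficit]] += 1
    return floors


def embed_trigger_expression(
    cell_values: np.ndarray,
    threshold: float,
    perturb_strength: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Embed the depth-conserving zeroing trigger into one expression vector.

    Every gene expressed below ``threshold`` is set to zero; the surviving
    genes absorb the removed mass via a Dirichlet resampling of their
    original proportions (concentration = ``perturb_strength`` × proportion ×
    number of survivors), rescaled so the output row sum equals the input row
    sum.  An all-integer input yields an all-integer output with the sum
    conserved exactly (largest-remainder rounding); float inputs conserve the
    sum to floating-point precision.  ``perturb_strength = inf`` skips the
    Dirichlet draw: survivors are rescaled proportionally.
    """
    x = np.asarray(cell_values, dtype=float).ravel()
    if rng is None:
        rng = np.random.default_rng(0)
    survivors = np.flatnonzero((x > 0) & (x >= threshold))
    if survivors.size == 0:
        raise AttackError(f"no gene at or above threshold {threshold}; cell not poisonable")
    total = x.sum()
    surv_vals = x[survivors]
    p = surv_vals / surv_vals.sum()
    if np.isinf(perturb_strength):
        q = p
    else:
        alpha = perturb_strength * p * survivors.size
        q = rng.dirichlet(alpha)
        if q.sum() <= 0 or not np.all(np.isfinite(q)):  # pathological tiny alphas
            q = p
    new_vals = q * total

    integer_mode = bool(np.all(x == np.floor(x)))
    out = np.zeros_like(x)
    if integer_mode:
        out_int = np.zeros(len(x), dtype=np.int64)
        out_int[survivors] = _largest_remainder_round(new_vals, int(round(total)))
        return out_int.astype(np.asarray(cell_values).dtype, copy=False) \
            if np.issubdtype(np.asarray(cell_values).dtype, np.integer) else out_int.astype(float)
    # float mode: rescale exactly so the sum matches to fp precision
    s = new_vals.sum()
    if s > 0:
        new_vals = new_vals * (total / s)
    out[survivors] = new_vals
    return out


def _cell_rng(seed: int, cell_index: int) -> np.random.Generator:
    """Per-cell RNG stream, independent of processing order."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(cell_index)]))


def _apply_triggers(
    m: LabeledExpressionMatrix,
    indices: np.ndarray,
    config: PoisonConfig,
    relabel: bool,
) -> PoisonResult:
    dense = m.to_dense().copy()
    labels = m.labels.copy()
    original = labels[indices].copy()
    for i in np.sort(indices):
        dense[i] = embed_trigger_expression(
            dense[i], config.threshold, config.perturb_strength, _cell_rng(config.seed, i)
        )
        if relabel:
            labels[i] = config.target_label
    values: np.ndarray | sp.spmatrix = dense
    if m.is_sparse:
        values = sp.csr_matrix(dense)
    poisoned = LabeledExpressionMatrix(
        values=values,
        cell_ids=list(m.cell_ids),
        gene_ids=list(m.gene_ids),
        labels=labels,
    )
    # report indices in selection order (descending heterogeneity)
    order = {int(i): orig for i, orig in zip(indices, original)}
    return PoisonResult(
        poisoned=poisoned,
        poisoned_indices=np.asarray(indices, dtype=int),
        original_labels=np.asarray([order[int(i)] for i in indices], dtype=object),
        config=config,
    )


def poison_dataset(m: LabeledExpressionMatrix, config: PoisonConfig) -> PoisonResult:
    """Construct a poisoned training set.

    Selects the top ``poison_rate × n`` heterogeneous non-target cells,
    embeds the depth-conserving trigger into each, and relabels them with the
    target label.  All other cells are bit-identical to the input.
    Deterministic given ``config.seed``.
    """
    indices = select_poison_cells(m, config)
    return _apply_triggers(m, indices, config, relabel=True)


def poison_testset(m: LabeledExpressionMatrix, config: PoisonConfig) -> PoisonResult:
    """Embed the trigger into *every* eligible non-target test cell.

    Unlike :func:`poison_dataset`, no rate cap applies and the returned
    labels keep the cells' true types: at inference the trigger alone should
    flip predictions, and the retained truth enables attack-success-rate and
    defense evaluation in one pass.
    """
    config.validate_against(m)
    indices = np.flatnonzero(_poisonable_mask(m, config))
    if indices.size == 0:
        raise AttackError("no eligible non-target poisonable cells in the test set")
    return _apply_triggers(m, indices, config, relabel=False)


# ---------------------------------------------------------------------------
# Rank-space trigger
# ---------------------------------------------------------------------------

def rank_encode(cell_values: np.ndarray, gene_ids: Sequence[str]) -> RankEncoding:
    """Rank-value encoding: expressed genes by descending expression.

    Ties are broken lexicographically on gene id; zero-expression genes are
    excluded."""
    x = np.asarray(cell_values, dtype=float).ravel()
    if len(x) != len(gene_ids):
        raise ValidationError("cell_values and gene_ids length mismatch")
    if x.sum() <= 0:
        raise AttackError("rank encoding undefined for an all-zero cell")
    expressed = [(g, v) for g, v in zip(gene_ids, x) if v > 0]
    expressed.sort(key=lambda t: (-t[1], t[0]))
    return RankEncoding(ranked_gene_ids=[g for g, _ in expressed])


def embed_trigger_rank(enc: RankEncoding, signature_genes: Sequence[str]) -> RankEncoding:
    """Promote a gene signature to the top ranks of a rank encoding.

    The signature occupies the first ``len(signature_genes)`` ranks in the
    given order; the relative order of all remaining genes is preserved.  The
    output is a permutation of the union of the input genes and the
    signature."""
    signature = [str(g) for g in signature_genes]
    if not signature:
        raise AttackError("signature_genes must be non-empty")
    if len(set(signature)) != len(signature):
        raise ValidationError("signature_genes contains duplicates")
    sig_set = set(signature)
    rest = [g for g in enc.ranked_gene_ids if g not in sig_set]
    return RankEncoding(ranked_gene_ids=signature + rest)
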
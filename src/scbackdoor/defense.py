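"""Defenses against training-set poisoning: integrity checks, sanitization, purification.

Three countermeasure families are implemented, each one concrete, auditable
instantiation of a broader category:

* **Download integrity** — :func:`verify_download` compares a file's SHA1
  digest against a publisher-provided value, the routine software-supply
  safeguard that is often skipped for datasets and model weights.
* **Data sanitization** — :func:`anomaly_scores` flags cells that sit far
  from their own label's centroid in PC space (the footprint of relabeling)
  and cells whose sub-threshold expression mass is anomalously low versus
  label peers (the footprint of a zeroing trigger); :func:`sanitize` removes
  the top-scoring fraction before training.
* **Model purification** — :func:`purify_retrain` re-fits a suspect model on
  a verified-benign subset, erasing data-borne backdoors at the cost of a
  second training pass.
"""

from __future__ import annotations

import hashlib
import logging
import os
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.decomposition import PCA

from .core import LabeledExpressionMatrix, ValidationError
from .evaluation import TrainablePredictor, log_normalize

__all__ = [
    "SanitizationReport",
    "verify_download",
    "anomaly_scores",
    "sanitize",
    "purify_retrain",
]

logger = logging.getLogger(__name__)

_SHA1_RE = re.compile(r"^[0-9a-fA-F]{40}$")


def sha1_of_file(path: Union[str, os.PathLike]) -> str:
    """Hex SHA1 digest of a file's bytes."""
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def verify_download(path: Union[str, os.PathLike], expected_sha1: str) -> bool:
    """True iff the file's SHA1 equals ``expected_sha1`` (case-insensitive)."""
    if not _SHA1_RE.match(expected_sha1 or ""):
        raise ValidationError(
            f"expected_sha1 must be a 40-character hex string, got {expected_sha1!r}"
        )
    return sha1_of_file(path) == expected_sha1.lower()


@dataclass
class SanitizationReport:
    """Outcome of one sanitization pass, with ground-truth rates if known."""

    anomaly_scores: np.ndarray
    removed_indices: np.ndarray
    removal_fraction: float
    recall_on_poisoned: Optional[float] = None
    fpr_on_benign: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "removal_fraction": self.removal_fraction,
            "n_removed": int(len(self.removed_indices)),
            "removed_indices": [int(i) for i in self.removed_indices],
            "recall_on_poisoned": self.recall_on_poisoned,
            "fpr_on_benign": self.fpr_on_benign,
        }


def anomaly_scores(
    m: LabeledExpressionMatrix,
    n_components: int = 30,
    threshold_grid: Sequence[float] = (0.5, 1.0, 2.0, 4.0),
) -> np.ndarray:
    """Per-cell suspicion score; higher means more likely poisoned.

    Two label-conditioned signals are summed:

    (a) standardized distance of each cell to its own label's centroid in PC
        space (per-component spread of that label) — both a relabeled cell,
        which sits in the wrong class's neighborhood, and a trigger-modified
        cell, which sits off the data manifold, score high;
    (b) a zero-inflation scan: for each threshold τ in ``threshold_grid``,
        the fraction of genes expressed in (0, τ); a cell whose sub-threshold
        mass is anomalously *low* versus its label peers (the signature of a
        zeroing trigger) scores high.  The scan maximum is used.

    Label statistics are robust (median centroid, MAD spread) so that a
    contaminating minority cannot mask itself by inflating its own label's
    spread.  Labels with fewer than 3 cells fall back to the global
    centroid/spread with a logged warning.  Deterministic: no randomness
    anywhere.
    """
    X = log_normalize(m)
    n_comp = min(n_components, m.n_genes, m.n_cells - 1)
    pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)

    dense = m.to_dense()
    grid = np.asarray(threshold_grid, dtype=float)
    # sub-threshold mass fraction per (cell, tau)
    frac = np.stack(
        [((dense > 0) & (dense < tau)).mean(axis=1) for tau in grid], axis=1
    )

    labels = m.labels
    classes = sorted(set(labels.tolist()))
    # scale-aware floor keeps z finite for degenerate (zero-spread) labels
    floor = 1e-8 * (np.abs(pcs).max() + 1.0)

    def _robust(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        center = np.median(points, axis=0)
        mad = np.median(np.abs(points - center), axis=0) * 1.4826
        return center, np.maximum(mad, floor)

    global_centroid, global_spread = _robust(pcs)
    score_a = np.zeros(m.n_cells)
    score_b = np.zeros(m.n_cells)
    for cls in classes:
        members = np.flatnonzero(labels == cls)
        if len(members) < 3:
            logger.warning(
                "label %r has %d cells; scored against global centroid", cls, len(members)
            )
            centroid, spread = global_centroid, global_spread
        else:
            centroid, spread = _robust(pcs[members])
        z = (pcs[members] - centroid) / spread
        score_a[members] = np.sqrt((z ** 2).mean(axis=1))

        mu = np.median(frac[members], axis=0)
        sd = np.maximum(np.median(np.abs(frac[members] - mu), axis=0) * 1.4826, 1e-6)
        # low sub-threshold mass relative to peers -> positive z
        zb = (mu[None, :] - frac[members]) / sd[None, :]
        score_b[members] = np.clip(zb, 0.0, None).max(axis=1)

    return score_a + score_b


def sanitize(
    m: LabeledExpressionMatrix,
    scores: np.ndarray,
    removal_fraction: float,
    poisoned_indices: Optional[Sequence[int]] = None,
) -> tuple[LabeledExpressionMatrix, SanitizationReport]:
    """Drop the top ``removal_fraction`` of cells by anomaly score.

    Ties break by ascending cell index.  When the true poisoned indices are
    supplied (synthetic ground truth), the report carries the recall on
    poisoned cells and the false-positive rate on benign cells.
    """
    if not (0.0 <= removal_fraction < 1.0):
        raise ValidationError("removal_fraction must be in [0, 1)")
    scores = np.asarray(scores, dtype=float)
    if len(scores) != m.n_cells:
        raise ValidationError("scores length must equal the number of cells")
    n_remove = int(round(removal_fraction * m.n_cells))
    if n_remove == 0:
        removed = np.empty(0, dtype=int)
    else:
        order = np.lexsort((np.arange(m.n_cells), -scores))
        removed = np.sort(order[:n_remove])
    keep = np.setdiff1d(np.arange(m.n_cells), removed)
    cleaned = m.subset_cells(keep)

    recall = fpr = None
    if poisoned_indices is not None:
        truth = set(int(i) for i in poisoned_indices)
        removed_set = set(removed.tolist())
        n_benign = m.n_cells - len(truth)
        recall = len(truth & removed_set) / len(truth) if truth else 0.0
        fpr = len(removed_set - truth) / n_benign if n_benign else 0.0

    report = SanitizationReport(
        anomaly_scores=scores,
        removed_indices=removed,
        removal_fraction=removal_fraction,
        recall_on_poisoned=recall,
        fpr_on_benign=fpr,
    )
    return cleaned, report


def purify_retrain(
    model: TrainablePredictor, clean_subset: LabeledExpressionMatrix
) -> TrainablePredictor:
    """Re-fit a (possibly backdoored) model on a verified-benign subset.

    The clean subset must cover every class the model was fitted on, so the
    purified model keeps the full label space.  Returns the same predictor
    object, re-fit; its own seed governs any training randomness.
    """
    fitted_classes = getattr(model, "classes_", None)
    if fitted_classes is not None:
        missing = set(str(c) for c in fitted_classes) - set(clean_subset.labels.tolist())
        if missing:
            raise ValidationError(
                f"clean subset is missing classes required for purification: {sorted(missing)}"
            )
    return model.fit(clean_subset)
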
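"""Attack evaluation: annotation metrics, surrogate classifiers, sweeps.

A backdoor attack is judged on two axes at once: the backdoored model must
keep near-baseline annotation quality on a clean test set (Accuracy, Cohen's
Kappa, Macro-F1), while the attack success rate (ASR) — the fraction of
trigger-bearing, originally non-target cells annotated as the target label —
should be high.  :func:`run_attack_experiment` performs one full
poison → train → evaluate loop and returns both; :func:`sweep` varies one
attack parameter at a time over a seed grid, mirroring the standard
one-factor-at-a-time experimental design.

The attack operates purely on data, so any classifier honouring the
:class:`TrainablePredictor` contract can play the victim.  Two surrogates are
shipped — a multinomial logistic (soft-max) model and a k-nearest-neighbor
voter, both over depth-normalized log1p features — to exercise the attack's
model-agnosticism at desk scale without GPU-scale foundation models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, cohen_kappa_score, f1_score
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .core import LabeledExpressionMatrix, LabelVector, ValidationError, sequencing_depth
from .attack import PoisonConfig, poison_dataset, poison_testset

__all__ = [
    "TrainablePredictor",
    "AttackReport",
    "accuracy",
    "cohens_kappa",
    "macro_f1",
    "attack_success_rate",
    "run_attack_experiment",
    "sweep",
    "concealment_score",
    "baseline_predictor",
    "knn_predictor",
    "SoftmaxPredictor",
    "KNNPredictor",
    "log_normalize",
]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _entries(v) -> np.ndarray:
    if isinstance(v, LabelVector):
        return v.entries
    return np.asarray([str(x) for x in np.asarray(v).ravel()], dtype=object)


def _paired(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    t, p = _entries(y_true), _entries(y_pred)
    if len(t) != len(p):
        raise ValidationError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    if len(t) == 0:
        raise ValidationError("empty label vectors")
    return t, p


def accuracy(y_true, y_pred) -> float:
    """Fraction of exact label matches."""
    t, p = _paired(y_true, y_pred)
    return float(accuracy_score(t, p))


def cohens_kappa(y_true, y_pred) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e) with marginal-product chance.

    The degenerate case of perfect agreement on a single class (p_e = 1,
    p_o = 1) returns 1.0.
    """
    t, p = _paired(y_true, y_pred)
    classes = sorted(set(t.tolist()) | set(p.tolist()))
    if len(classes) == 1:
        return 1.0
    return float(cohen_kappa_score(t, p))


def macro_f1(y_true, y_pred) -> float:
    """Unweighted mean F1 over the classes present in ``y_true``.

    A class with zero precision + recall contributes an F1 of 0.
    """
    t, p = _paired(y_true, y_pred)
    labels = sorted(set(t.tolist()))
    return float(f1_score(t, p, labels=labels, average="macro", zero_division=0))


def attack_success_rate(y_pred_on_poisoned, original_labels, target_label: str) -> float:
    """Fraction of poisoned (originally non-target) cells predicted as target."""
    p, orig = _paired(y_pred_on_poisoned, original_labels)
    if np.any(orig == str(target_label)):
        raise ValidationError(
            "original_labels must not contain the target label (those cells are not "
            "valid backdoor probes)"
        )
    return float(np.mean(p == str(target_label)))


# ---------------------------------------------------------------------------
# Surrogate classifiers
# ---------------------------------------------------------------------------

def log_normalize(m: LabeledExpressionMatrix, scale: float = 1e4) -> np.ndarray:
    """Depth-normalized log1p features: log1p(scale * x / depth) per cell."""
    x = m.to_dense().astype(float)
    depth = sequencing_depth(m).astype(float)
    depth[depth == 0] = 1.0
    return np.log1p(scale * x / depth[:, None])


@runtime_checkable
class TrainablePredictor(Protocol):
    """Contract for any classifier used as the attacked model."""

    def fit(self, m: LabeledExpressionMatrix) -> "TrainablePredictor": ...

    def predict(self, m: LabeledExpressionMatrix) -> np.ndarray: ...


class SoftmaxPredictor:
    """Multinomial logistic regression over standardized log1p features.

    A deliberately simple, fast, deterministic stand-in for a fine-tuned
    annotation model: depth-normalize, log1p, z-score per gene, then a
    soft-max linear model fit by L-BFGS with a fixed iteration budget.
    """

    def __init__(self, seed: int = 0, C: float = 10.0, max_iter: int = 500):
        self.seed = int(seed)
        self._scaler = StandardScaler()
        self._clf = LogisticRegression(C=C, max_iter=max_iter, random_state=self.seed)
        self.classes_: np.ndarray | None = None

    def fit(self, m: LabeledExpressionMatrix) -> "SoftmaxPredictor":
        X = self._scaler.fit_transform(log_normalize(m))
        self._clf.fit(X, m.labels.astype(str))
        self.classes_ = self._clf.classes_
        return self

    def predict(self, m: LabeledExpressionMatrix) -> np.ndarray:
        if self.classes_ is None:
            raise ValidationError("predictor is not fitted")
        X = self._scaler.transform(log_normalize(m))
        return np.asarray(self._clf.predict(X), dtype=object)


class KNNPredictor:
    """k-nearest-neighbor voter over log1p features (reference surrogate)."""

    def __init__(self, seed: int = 0, k: int = 15):
        self.seed = int(seed)
        self._clf = KNeighborsClassifier(n_neighbors=k)
        self.classes_: np.ndarray | None = None

    def fit(self, m: LabeledExpressionMatrix) -> "KNNPredictor":
        self._clf.fit(log_normalize(m), m.labels.astype(str))
        self.classes_ = self._clf.classes_
        return self

    def predict(self, m: LabeledExpressionMatrix) -> np.ndarray:
        if self.classes_ is None:
            raise ValidationError("predictor is not fitted")
        return np.asarray(self._clf.predict(log_normalize(m)), dtype=object)


def baseline_predictor(seed: int = 0) -> SoftmaxPredictor:
    """The default surrogate victim model: a linear soft-max classifier."""
    return SoftmaxPredictor(seed=seed)


def knn_predictor(seed: int = 0, k: int = 15) -> KNNPredictor:
    """Second reference surrogate: k-nearest-neighbor voting."""
    return KNNPredictor(seed=seed, k=k)


# ---------------------------------------------------------------------------
# Experiment runner
# ---------------------------------------------------------------------------

@dataclass
class AttackReport:
    """Clean-set metrics plus ASR for one attack configuration."""

    clean_accuracy: float
    clean_kappa: float
    clean_macro_f1: float
    asr: float
    n_poisoned_eval: int
    config: PoisonConfig

    def to_dict(self) -> dict:
        d = {
            "clean_accuracy": self.clean_accuracy,
            "clean_kappa": self.clean_kappa,
            "clean_macro_f1": self.clean_macro_f1,
            "asr": self.asr,
            "n_poisoned_eval": self.n_poisoned_eval,
        }
        d.update({f"config_{k}": v for k, v in self.config.to_dict().items()})
        return d


def run_attack_experiment(
    train: LabeledExpressionMatrix,
    test: LabeledExpressionMatrix,
    config: PoisonConfig,
    model: TrainablePredictor,
) -> AttackReport:
    """One full backdoor experiment: poison train, fit, score clean and triggered.

    The training set is poisoned at ``config.poison_rate`` and the model fit
    on it.  Clean metrics come from the untouched test set; the ASR from a
    fully triggered copy of the test set (every eligible non-target cell),
    counting predictions equal to the target label.  Deterministic given the
    config seed and the model's own seed.
    """
    if train.gene_ids != test.gene_ids:
        raise ValidationError("train and test must share the same gene universe")
    poisoned_train = poison_dataset(train, config)
    model.fit(poisoned_train.poisoned)

    clean_pred = model.predict(test)
    poisoned_test = poison_testset(test, config)
    probe = poisoned_test.poisoned.subset_cells(poisoned_test.poisoned_indices)
    asr = attack_success_rate(
        model.predict(probe), poisoned_test.original_labels, config.target_label
    )
    return AttackReport(
        clean_accuracy=accuracy(test.labels, clean_pred),
        clean_kappa=cohens_kappa(test.labels, clean_pred),
        clean_macro_f1=macro_f1(test.labels, clean_pred),
        asr=asr,
        n_poisoned_eval=poisoned_test.n_poisoned,
        config=config,
    )


SWEEPABLE = ("threshold", "target_label", "poison_rate")


def sweep(
    train: LabeledExpressionMatrix,
    test: LabeledExpressionMatrix,
    base_config: PoisonConfig,
    vary: str,
    values: Sequence,
    model_factory=baseline_predictor,
    seeds: Sequence[int] = (0,),
) -> pd.DataFrame:
    """One-factor-at-a-time parameter sweep over a seed grid.

    Returns a long-format table with one row per (value, seed): columns
    ``varied_param, value, seed, clean_accuracy, clean_kappa, clean_macro_f1,
    asr, n_poisoned_eval``.
    """
    if vary not in SWEEPABLE:
        raise ValidationError(f"vary must be one of {SWEEPABLE}")
    if len(values) == 0:
        raise ValidationError("values must be non-empty")
    rows = []
    for value in values:
        for seed in seeds:
            cfg_kwargs = base_config.to_dict()
            cfg_kwargs[vary if vary != "poison_rate" else "poison_rate"] = value
            cfg_kwargs["seed"] = int(seed)
            cfg = PoisonConfig(**cfg_kwargs)
            report = run_attack_experiment(train, test, cfg, model_factory(int(seed)))
            rows.append(
                {
                    "varied_param": vary,
                    "value": value,
                    "seed": int(seed),
                    "clean_accuracy": report.clean_accuracy,
                    "clean_kappa": report.clean_kappa,
                    "clean_macro_f1": report.clean_macro_f1,
                    "asr": report.asr,
                    "n_poisoned_eval": report.n_poisoned_eval,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Concealment diagnostic
# ---------------------------------------------------------------------------

def concealment_score(
    m_poisoned: LabeledExpressionMatrix,
    poisoned_indices: Sequence[int],
    k_neighbors: int = 15,
    n_components: int = 50,
) -> float:
    """Mean benign fraction among each poisoned cell's k nearest PC neighbors.

    Values are depth-normalized, log1p-transformed and reduced to
    ``n_components`` principal components (capped at the number of genes);
    neighbors are Euclidean in PC space, excluding the cell itself.  1.0
    means poisoned cells are perfectly mixed among benign ones; 0.0 means
    they segregate completely.  Deterministic — no randomness in scoring.
    """
    n = m_poisoned.n_cells
    if not (1 <= k_neighbors < n):
        raise ValidationError(f"k_neighbors must be in [1, {n - 1}]")
    idx = np.asarray(poisoned_indices, dtype=int)
    X = log_normalize(m_poisoned)
    n_comp = min(n_components, m_poisoned.n_genes, n - 1)
    pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(pcs)
    _, neigh = nn.kneighbors(pcs[idx])
    poisoned_set = set(idx.tolist())
    fractions = []
    for row_i, cell in enumerate(idx):
        others = [j for j in neigh[row_i] if j != cell][:k_neighbors]
        benign = sum(1 for j in others if j not in poisoned_set)
        fractions.append(benign / len(others))
    return float(np.mean(fractions))
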
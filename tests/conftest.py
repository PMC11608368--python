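from __future__ import annotations

import numpy as np
import pytest

import scbackdoor as sb
from scbackdoor.defense import anomaly_scores, purify_retrain, sanitize

STUDY_SEEDS = (0, 1, 2, 3, 4)
TARGET = "type_0"


@pytest.fixture
def tiny_matrix():
    """3 cells x 4 genes, labels {A, A, B} — hand-checkable."""
    return sb.LabeledExpressionMatrix(
        values=np.array([[0, 1, 3, 5], [2, 2, 0, 0], [4, 0, 0, 1]], dtype=np.int64),
        cell_ids=["c1", "c2", "c3"],
        gene_ids=["g1", "g2", "g3", "g4"],
        labels=np.array(["A", "A", "B"]),
    )


@pytest.fixture(scope="session")
def small_synth():
    """A quick 300-cell, 3-type dataset shared by cheaper end-to-end tests."""
    m = sb.generate(sb.SyntheticSpec(n_cells=300, n_genes=120, n_types=3, seed=7))
    train, test = sb.train_test_split(m, 0.25, seed=7)
    return m, train, test


def _one_study_run(seed: int) -> dict:
    """One full replicate of the study conditions: default generator,
    default attack config, linear surrogate; plus defense outcomes."""
    m = sb.generate(sb.SyntheticSpec(seed=seed))
    train, test = sb.train_test_split(m, 0.25, seed=seed)
    config = sb.PoisonConfig(target_label=TARGET, seed=seed)

    result = sb.poison_dataset(train, config)
    backdoored = sb.baseline_predictor(seed).fit(result.poisoned)
    clean_pred = backdoored.predict(test)
    probe_res = sb.poison_testset(test, config)
    probe = probe_res.poisoned.subset_cells(probe_res.poisoned_indices)
    asr = sb.attack_success_rate(
        backdoored.predict(probe), probe_res.original_labels, TARGET
    )

    baseline = sb.baseline_predictor(seed).fit(train)
    baseline_acc = sb.accuracy(test.labels, baseline.predict(test))

    scores = anomaly_scores(result.poisoned)
    removal = 2 * config.poison_rate
    cleaned, san_report = sanitize(
        result.poisoned, scores, removal, poisoned_indices=result.poisoned_indices
    )
    sanitized_model = sb.baseline_predictor(seed).fit(cleaned)
    asr_sanitized = sb.attack_success_rate(
        sanitized_model.predict(probe), probe_res.original_labels, TARGET
    )

    benign_idx = np.setdiff1d(np.arange(train.n_cells), result.poisoned_indices)
    purify_retrain(backdoored, train.subset_cells(benign_idx))
    asr_purified = sb.attack_success_rate(
        backdoored.predict(probe), probe_res.original_labels, TARGET
    )
    purified_acc = sb.accuracy(test.labels, backdoored.predict(test))

    return {
        "seed": seed,
        "train": train,
        "test": test,
        "config": config,
        "result": result,
        "probe": probe,
        "probe_res": probe_res,
        "asr": asr,
        "clean_accuracy": sb.accuracy(test.labels, clean_pred),
        "baseline_accuracy": baseline_acc,
        "san_report": san_report,
        "removal_fraction": removal,
        "asr_sanitized": asr_sanitized,
        "asr_purified": asr_purified,
        "purified_accuracy": purified_acc,
    }


@pytest.fixture(scope="session")
def study_runs():
    """Five seeded replicates of the default attack + defenses, shared by the
    end-to-end acceptance checks."""
    return [_one_study_run(s) for s in STUDY_SEEDS]
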
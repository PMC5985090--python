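"""End-to-end experiment glue: trials -> chunks -> features -> decoder -> report.

Mirrors the original study protocol: every trial is replayed as 250 ms
chunks, each chunk becomes one 14-value band-power feature vector, the
chunk pool is split 75/25 stratified by class, the two-stage network is
trained on the 75 %, and a fixed number of randomly chosen test chunks
per class (31 by default, as in the embedded evaluation) feeds the
confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import TwoStageModel, classify, stratified_split, train_two_stage
from .control_eval import ConfusionMatrix, confusion, evaluation_report
from .features import DEFAULT_PSD, FEATURE_NAMES, PSDConfig, extract_features
from .io_streaming import EEGTrial, stream_chunks
from .synthetic_eeg import SynthConfig, SynthDataset, generate_dataset


def featurize_trials(trials: list[EEGTrial], cfg: PSDConfig = DEFAULT_PSD) -> pd.DataFrame:
    """One row per chunk: trial_id, chunk_index, label, 14 channel features."""
    rows = []
    for trial in trials:
        for chunk in stream_chunks(trial):
            feats = extract_features(chunk, cfg)
            row = {"trial_id": chunk.trial_id, "chunk_index": chunk.index,
                   "label": chunk.label}
            row.update(dict(zip(FEATURE_NAMES, feats)))
            rows.append(row)
    return pd.DataFrame(rows)


def predict_frame(model: TwoStageModel, table: pd.DataFrame) -> list[str]:
    X = table[list(FEATURE_NAMES)].to_numpy()
    return [classify(model, f).label for f in X]


@dataclass
class ExperimentResult:
    model: TwoStageModel
    cm: ConfusionMatrix
    report: dict
    features: pd.DataFrame
    test_index: np.ndarray

    @property
    def mean_accuracy_pct(self) -> int:
        return self.report["mean_accuracy_pct"]


def run_experiment(
    cfg: SynthConfig,
    split_seed: int = 0,
    test_fraction: float = 0.25,
    n_test_per_class: int = 31,
    ridge: float = 1e-8,
) -> ExperimentResult:
    """Generate, decode and score one synthetic session.

    ``n_test_per_class`` chunks per class are sampled from the held-out
    25 % for the confusion matrix (capped at what is available), matching
    the original embedded evaluation's 31 randomly chosen samples per
    movement.
    """
    dataset = generate_dataset(cfg)
    table = featurize_trials(dataset.trials)
    labels = table["label"].to_numpy()
    train_idx, test_idx = stratified_split(labels, test_fraction=test_fraction,
                                           seed=split_seed)
    X = table[list(FEATURE_NAMES)].to_numpy()
    model = train_two_stage(X[train_idx], labels[train_idx].tolist(), ridge=ridge)

    rng = np.random.default_rng(split_seed + 1)
    chosen = []
    for cls in sorted(set(labels.tolist())):
        cls_test = test_idx[labels[test_idx] == cls]
        k = min(n_test_per_class, len(cls_test))
        chosen.append(rng.choice(cls_test, size=k, replace=False))
    chosen = np.sort(np.concatenate(chosen))

    predictions = [classify(model, f).label for f in X[chosen]]
    cm = confusion(labels[chosen].tolist(), predictions)
    return ExperimentResult(model=model, cm=cm, report=evaluation_report(cm),
                            features=table, test_index=chosen)
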
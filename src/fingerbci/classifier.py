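"""Two-stage binary logistic-regression decoder.

The three movement classes are separated hierarchically (a decision
cascade rather than one multinomial fit):

* **network I** — fist vs. {thumb, index};
* **network II** — thumb vs. index, consulted only when network I rules
  out fist.

Each network models the class-1 probability as the sigmoid of a linear
score, P(G=1) = exp(B'F) / (exp(B'F) + 1), where F is the 14-value
band-power feature vector augmented with a leading 1 for the intercept
and B holds 15 coefficients. The decision rule is class 1 iff P > 0.5;
an exact tie goes to class 2 (measure-zero, documented).

Training maximizes the ridge-penalized binomial log-likelihood by
iteratively reweighted least squares (IRLS): deterministic, no data
ordering or random initialization effects. The default ridge of 1e-8 is
a numerical stabilizer, not a tuned hyperparameter.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_streaming import CLASSES, N_CHANNELS

N_COEF = N_CHANNELS + 1  # intercept + one weight per channel


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class LogisticModel:
    """One binary logistic network: 15 coefficients plus its two labels."""

    B: np.ndarray
    class1_label: str
    class2_label: str
    converged: bool = True
    n_obs: int = 0

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        if self.B.shape != (N_COEF,):
            raise ValueError(f"B must hold {N_COEF} coefficients; got {self.B.shape}")
        if not np.isfinite(self.B).all():
            raise ValueError("non-finite coefficients")
        if self.class1_label == self.class2_label:
            raise ValueError("class labels must be distinct")


@dataclass
class TwoStageModel:
    """The decision cascade: network I (fist vs. rest), network II (thumb vs. index)."""

    network1: LogisticModel
    network2: LogisticModel

    def __post_init__(self):
        if self.network1.class2_label != "fist":
            raise ValueError("network I must have fist as class 2")
        if {self.network2.class1_label, self.network2.class2_label} != {"thumb", "index"}:
            raise ValueError("network II must separate thumb from index")

    def to_json(self) -> str:
        def enc(m: LogisticModel) -> dict:
            return {"class1": m.class1_label, "class2": m.class2_label, "B": m.B.tolist()}
        return json.dumps({"network1": enc(self.network1), "network2": enc(self.network2)},
                          indent=2)

    @classmethod
    def from_json(cls, doc: str) -> "TwoStageModel":
        d = json.loads(doc)
        def dec(m: dict) -> LogisticModel:
            return LogisticModel(B=np.array(m["B"]), class1_label=m["class1"],
                                 class2_label=m["class2"])
        return cls(network1=dec(d["network1"]), network2=dec(d["network2"]))


@dataclass(frozen=True)
class Prediction:
    """Decoder output for one chunk: label plus the stage probabilities.

    ``p2`` is present only when network I chose class 1 (not fist), since
    network II is never consulted otherwise.
    """

    label: str
    p1: float
    p2: float | None = None


def _sigmoid(z: float) -> float:
    # branch keeps exp() off large positive arguments
    if z >= 0.0:
        return 1.0 / (1.0 + np.exp(-z))
    ez = np.exp(z)
    return ez / (1.0 + ez)


def logistic_probability(model: LogisticModel, f: np.ndarray) -> float:
    """P(class 1 | features) = exp(B'F) / (exp(B'F) + 1), with leading-1 augmentation."""
    f = np.asarray(f, dtype=float)
    if f.shape != (N_CHANNELS,):
        raise ValueError(f"feature vector must have {N_CHANNELS} values; got {f.shape}")
    if not np.isfinite(f).all():
        raise ValueError("non-finite features")
    z = model.B[0] + float(model.B[1:] @ f)
    return _sigmoid(z)


def decide(p: float) -> int:
    """Class 1 iff p > 0.5; ties (exactly 0.5) go to class 2."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability out of [0, 1]: {p}")
    return 1 if p > 0.5 else 2


def classify(model: TwoStageModel, f: np.ndarray) -> Prediction:
    """Run the cascade: network I gates on fist, network II resolves thumb/index."""
    p1 = logistic_probability(model.network1, f)
    if decide(p1) == 2:
        return Prediction(label=model.network1.class2_label, p1=p1)
    p2 = logistic_probability(model.network2, f)
    label = model.network2.class1_label if decide(p2) == 1 else model.network2.class2_label
    return Prediction(label=label, p1=p1, p2=p2)


def _penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray, ridge: float) -> float:
    z = X @ beta
    # log-likelihood sum y*z - log(1+e^z), computed stably
    ll = float(np.sum(y * z - np.logaddexp(0.0, z)))
    return ll - 0.5 * ridge * float(beta[1:] @ beta[1:])


def train_logistic(
    features: np.ndarray,
    labels: Sequence[str],
    class1_label: str,
    class2_label: str,
    ridge: float = 1e-8,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticModel:
    """Fit one binary network by IRLS.

    ``labels`` holds the two class names; rows labeled ``class1_label``
    are the positive class. The intercept is unpenalized. Stops when the
    penalized-gradient norm falls below ``tol`` (default 1e-8) or after
    ``max_iter`` sweeps; non-convergence is flagged on the model and
    warned, never silent.
    """
    X0 = np.asarray(features, dtype=float)
    if X0.ndim != 2 or X0.shape[1] != N_CHANNELS:
        raise ValueError(f"features must be (n, {N_CHANNELS}); got {X0.shape}")
    if not np.isfinite(X0).all():
        raise ValueError("non-finite features")
    labels = list(labels)
    if len(labels) != X0.shape[0]:
        raise ValueError("labels length must match feature rows")
    unknown = set(labels) - {class1_label, class2_label}
    if unknown:
        raise ValueError(f"unexpected labels {sorted(unknown)}")
    y = np.array([1.0 if lab == class1_label else 0.0 for lab in labels])
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 examples of each class")

    n = X0.shape[0]
    X = np.column_stack([np.ones(n), X0])
    pen = np.full(N_COEF, ridge)
    pen[0] = 0.0  # intercept unpenalized
    beta = np.zeros(N_COEF)
    converged = False
    for _ in range(max_iter):
        z = X @ beta
        p = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700))),
                     np.exp(np.clip(z, -700, 700)) / (1.0 + np.exp(np.clip(z, -700, 700))))
        grad = X.T @ (y - p) - pen * beta
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        w = np.maximum(p * (1.0 - p), 1e-10)
        H = (X.T * w) @ X + np.diag(pen)
        beta = beta + np.linalg.solve(H, grad)
    else:
        z = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
        converged = bool(np.linalg.norm(X.T @ (y - p) - pen * beta) < tol)
    if not converged:
        warnings.warn(
            f"IRLS did not reach gradient norm {tol} in {max_iter} iterations "
            f"({class1_label} vs {class2_label}); returning last iterate",
            ConvergenceWarning,
        )
    return LogisticModel(B=beta, class1_label=class1_label, class2_label=class2_label,
                         converged=converged, n_obs=n)


def train_two_stage(
    features: np.ndarray,
    labels: Sequence[str],
    ridge: float = 1e-8,
) -> TwoStageModel:
    """Fit the cascade on 3-class data.

    Network I is trained on all rows with {thumb, index} relabeled as its
    class 1 and fist as class 2; network II only ever sees the thumb and
    index rows.
    """
    labels = list(labels)
    present = set(labels)
    missing = set(CLASSES) - present
    if missing:
        raise ValueError(f"all three classes required; missing {sorted(missing)}")
    X = np.asarray(features, dtype=float)
    stage1_labels = ["not_fist" if lab != "fist" else "fist" for lab in labels]
    net1 = train_logistic(X, stage1_labels, class1_label="not_fist",
                          class2_label="fist", ridge=ridge)
    mask = np.array([lab != "fist" for lab in labels])
    net2 = train_logistic(X[mask], [lab for lab in labels if lab != "fist"],
                          class1_label="thumb", class2_label="index", ridge=ridge)
    return TwoStageModel(network1=net1, network2=net2)


def stratified_split(
    labels: Sequence[str],
    test_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random 75/25 split; returns (train_idx, test_idx).

    Each class contributes ``round(n_class * test_fraction)`` test rows
    (at least 1), so the split stays stratified under imbalance.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_test = max(1, round(len(idx) * test_fraction))
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def save_model(model: TwoStageModel, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(model.to_json() + "\n")


def load_model(path: str | os.PathLike) -> TwoStageModel:
    with open(path, "r", encoding="utf-8") as fh:
        return TwoStageModel.from_json(fh.read())
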
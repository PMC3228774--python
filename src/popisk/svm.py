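"""Soft-margin SVM on the precomputed string kernel.

The classifier solves the usual dual problem on the WD-kernel Gram matrix
(box constraints ``0 <= alpha_i <= C``, equality ``sum alpha_i y_i = 0``)
and scores a query peptide ``q`` as

    f(q) = sum_i alpha_i y_i k(x_i, q) + b.

A peptide is called immunogenic exactly when its decision score is strictly
greater than zero; a score of exactly zero maps to non-immunogenic.  The
published web tool's final model uses C = 1.0 and degree d = 9 trained on
the whole dataset, which :func:`train_final_model` reproduces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .dataset import LabeledDataset
from .kernel import KernelSpec, cross_gram, gram_matrix

MODEL_FORMAT_VERSION = 1

#: Solver tolerance; tight enough that permutation/label-flip contracts hold
#: to 1e-6 on the score scale.
SOLVER_TOL = 1e-8


@dataclass
class TrainedModel:
    """A fitted kernel SVM: support expansion over the training peptides."""

    train_peptides: list[str]
    alpha_y: np.ndarray  # alpha_i * y_i per training peptide (0 off-support)
    bias: float
    C: float
    spec: KernelSpec
    labels: np.ndarray | None = None

    @property
    def d(self) -> int:
        return self.spec.d

    @property
    def length(self) -> int:
        return len(self.train_peptides[0])

    def check_dual_feasibility(self, tol: float = 1e-6) -> None:
        """Raise if the box or equality constraints are violated beyond tol."""
        if self.labels is None:
            raise ValueError("model carries no training labels")
        alpha = self.alpha_y * self.labels  # alpha_i >= 0
        if np.any(alpha < -tol) or np.any(alpha > self.C + tol):
            raise AssertionError("box constraint 0 <= alpha_i <= C violated")
        if abs(self.alpha_y.sum()) > tol * max(1.0, len(self.alpha_y)):
            raise AssertionError("equality constraint sum alpha_i y_i = 0 violated")


@dataclass
class PredictionResult:
    """Decision scores and the binary immunogenicity calls derived from them."""

    peptides: list[str]
    scores: np.ndarray
    labels: np.ndarray  # +1 iff score > 0

    def __len__(self) -> int:
        return len(self.peptides)


def train(data: LabeledDataset, spec: KernelSpec, C: float = 1.0) -> TrainedModel:
    """Fit the kernel SVM on a labeled dataset.

    Deterministic for a fixed input ordering.  Raises on single-class data,
    non-positive C, or non-finite kernel values.
    """
    if C <= 0:
        raise ValueError(f"cost parameter C must be > 0, got {C}")
    data.require_both_classes()
    gram = gram_matrix(data.peptides, spec)
    if not np.all(np.isfinite(gram)):
        raise ValueError("non-finite kernel values in the Gram matrix")
    return _fit_precomputed(gram, data.labels, data.peptides, spec, C)


def _fit_precomputed(
    gram: np.ndarray,
    y: np.ndarray,
    peptides: list[str],
    spec: KernelSpec,
    C: float,
) -> TrainedModel:
    clf = SVC(C=C, kernel="precomputed", tol=SOLVER_TOL, shrinking=False)
    clf.fit(gram, y)
    alpha_y = np.zeros(len(y))
    alpha_y[clf.support_] = clf.dual_coef_[0]
    return TrainedModel(
        train_peptides=list(peptides),
        alpha_y=alpha_y,
        bias=float(clf.intercept_[0]),
        C=float(C),
        spec=spec,
        labels=np.asarray(y, dtype=int),
    )


def decision_scores(model: TrainedModel, kernel_columns: np.ndarray) -> np.ndarray:
    """Scores from a precomputed (n_query, n_train) kernel block."""
    return kernel_columns @ model.alpha_y + model.bias


def predict(model: TrainedModel, query: list[str]) -> PredictionResult:
    """Score query peptides and call each immunogenic iff score > 0."""
    kernels = cross_gram(query, model.train_peptides, model.spec)
    scores = decision_scores(model, kernels)
    return PredictionResult(
        peptides=list(query),
        scores=scores,
        labels=np.where(scores > 0, 1, -1),
    )


def train_final_model(data: LabeledDataset) -> TrainedModel:
    """Train on the whole dataset with the production parameters C=1, d=9."""
    return train(data, KernelSpec(d=9), C=1.0)


# -- serialization ---------------------------------------------------------

def save_model(model: TrainedModel, path) -> None:
    """Write a self-describing JSON archive; round-trips scores bit-identically.

    Floats are stored as IEEE-754 hex strings so no decimal rounding occurs.
    """
    payload = {
        "format": "popisk-model",
        "version": MODEL_FORMAT_VERSION,
        "C": model.C,
        "d": model.spec.d,
        "normalize": model.spec.normalize,
        "betas_hex": [float(b).hex() for b in model.spec.betas],
        "bias_hex": float(model.bias).hex(),
        "train_peptides": model.train_peptides,
        "alpha_y_hex": [float(a).hex() for a in model.alpha_y],
        "labels": None if model.labels is None else model.labels.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> TrainedModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "popisk-model":
        raise ValueError(f"{path}: not a popisk model archive")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {payload.get('version')!r}")
    spec = KernelSpec(
        d=int(payload["d"]),
        betas=np.array([float.fromhex(h) for h in payload["betas_hex"]]),
        normalize=bool(payload["normalize"]),
    )
    labels = payload.get("labels")
    return TrainedModel(
        train_peptides=list(payload["train_peptides"]),
        alpha_y=np.array([float.fromhex(h) for h in payload["alpha_y_hex"]]),
        bias=float.fromhex(payload["bias_hex"]),
        C=float(payload["C"]),
        spec=spec,
        labels=None if labels is None else np.asarray(labels, dtype=int),
    )
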
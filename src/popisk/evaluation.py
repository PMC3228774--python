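"""Performance metrics and the evaluation protocol.

Metrics are overall accuracy (ACC), Matthews correlation coefficient (MCC)
and the area under the ROC curve (AUC, the Mann-Whitney statistic with
half-credit for ties):

    ACC = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

The model-selection protocol is a nested 10-fold cross-validation: the
outer loop estimates test performance, the inner loop grid-searches the
SVM cost C in {2^-4..2^4} and the kernel degree d in {1..9} by highest
inner AUC.  The whole procedure is repeated over independent runs and
summarised as mean +/- sd per metric.  Folds are stratified so that small
synthetic datasets never produce single-class folds; when several grid
points tie on inner AUC the smallest d, then the smallest C, wins.

Also provided: a learning curve over training-set sizes on a fixed
50/25/25 train/validation/test split, and the mean-physicochemical-property
RBF-kernel SVM baseline (the "POPI-modified" reference method) evaluated
under the identical nested protocol.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataset import LabeledDataset
from .kernel import KernelSpec, encode_peptides, gram_matrix
from .svm import SOLVER_TOL

logger = logging.getLogger("popisk")


# -- metrics ---------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricSet:
    ACC: float
    MCC: float
    AUC: float

    def as_dict(self) -> dict:
        return {"ACC": self.ACC, "MCC": self.MCC, "AUC": self.AUC}


def confusion(scores, truth, threshold: float = 0.0) -> ConfusionCounts:
    """Confusion counts with the strict rule ``score > threshold => positive``."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if scores.size == 0:
        raise ValueError("empty score vector")
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    pred = np.where(scores > threshold, 1, -1)
    return ConfusionCounts(
        TP=int(np.sum((pred == 1) & (truth == 1))),
        TN=int(np.sum((pred == -1) & (truth == -1))),
        FP=int(np.sum((pred == 1) & (truth == -1))),
        FN=int(np.sum((pred == -1) & (truth == 1))),
    )


def compute_metrics(counts: ConfusionCounts, scores=None, truth=None) -> MetricSet:
    """ACC and MCC from the confusion counts; AUC from the raw scores.

    MCC with a zero denominator (a degenerate row or column of the confusion
    matrix) is defined as 0, with a logged warning.  AUC requires scores and
    truth containing both classes; if omitted it is reported as NaN.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    acc = (tp + tn) / counts.total
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    if denom == 0:
        logger.warning("MCC denominator is zero; reporting MCC = 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    if scores is None or truth is None:
        auc = float("nan")
    else:
        truth = np.asarray(truth, dtype=int)
        if len(np.unique(truth)) < 2:
            raise ValueError("AUC requires both classes in truth")
        auc = float(roc_auc_score(truth, np.asarray(scores, dtype=float)))
    return MetricSet(ACC=float(acc), MCC=float(mcc), AUC=auc)


def metrics_from_scores(scores, truth, threshold: float = 0.0) -> MetricSet:
    """Convenience: confusion + metrics in one call."""
    return compute_metrics(confusion(scores, truth, threshold), scores, truth)


# -- grids and reports -----------------------------------------------------

def _log2_grid() -> tuple[float, ...]:
    return tuple(float(2.0 ** e) for e in range(-4, 5))


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid: SVM cost and kernel parameter values.

    ``Cs`` defaults to {2^-4 .. 2^4}.  ``ds`` (string-kernel degree) defaults
    to {1 .. 9}; ``gammas`` (RBF width) defaults to {2^-4 .. 2^4} and is only
    consulted by the property baseline.
    """

    Cs: tuple = field(default_factory=_log2_grid)
    ds: tuple = tuple(range(1, 10))
    gammas: tuple = field(default_factory=_log2_grid)

    def __post_init__(self):
        if len(self.Cs) == 0 or (len(self.ds) == 0 and len(self.gammas) == 0):
            raise ValueError("empty hyperparameter grid")

    def capped(self, d_max: int) -> "GridSpec":
        """Same grid with degrees capped at ``d_max`` (position-deletion runs)."""
        ds = tuple(d for d in self.ds if d <= d_max)
        if not ds:
            raise ValueError(f"no degree in grid is <= {d_max}")
        return GridSpec(Cs=self.Cs, ds=ds, gammas=self.gammas)


#: Small grid for routine synthetic-data work; the full published grid
#: (9 C values x 9 degrees) is GridSpec().
FAST_GRID = GridSpec(Cs=(0.25, 1.0, 4.0), ds=(1, 3, 5, 7, 9))


@dataclass
class CVReport:
    """Nested-CV results: one row per (run, outer fold) plus run aggregates."""

    folds: pd.DataFrame        # run, fold, param columns, ACC, MCC, AUC
    runs: pd.DataFrame         # run, ACC, MCC, AUC (outer-fold predictions pooled)
    summary: dict              # means, sds, seed, grid, n_runs

    @property
    def mean(self) -> MetricSet:
        return MetricSet(**{m: self.summary["mean"][m] for m in ("ACC", "MCC", "AUC")})

    @property
    def sd(self) -> MetricSet:
        return MetricSet(**{m: self.summary["sd"][m] for m in ("ACC", "MCC", "AUC")})

    def write(self, folds_tsv, summary_json) -> None:
        self.folds.to_csv(folds_tsv, sep="\t", index=False)
        with open(summary_json, "w") as fh:
            json.dump(self.summary, fh, indent=1)


# -- nested cross-validation core -----------------------------------------

def _fit_scores(gram: np.ndarray, y: np.ndarray, tr, te, C: float) -> np.ndarray:
    """Fit an SVC on the training block of a precomputed Gram, score test rows."""
    clf = SVC(C=C, kernel="precomputed", tol=SOLVER_TOL, shrinking=False)
    clf.fit(gram[np.ix_(tr, tr)], y[tr])
    return clf.decision_function(gram[np.ix_(te, tr)])


def _nested_cv_precomputed(
    grams: dict,
    param_grid: list[tuple[float, object]],
    y: np.ndarray,
    param_name: str,
    n_runs: int,
    seed: int,
    n_outer: int,
    n_inner: int,
) -> CVReport:
    """Generic nested CV over (C, kernel-parameter) pairs with cached Grams.

    ``grams`` maps each kernel parameter value to its full N x N Gram matrix.
    Ties on inner AUC resolve to the smallest kernel parameter, then the
    smallest C (grid order is sorted ascending on both axes).
    """
    n = len(y)
    if n < 2 * n_outer:
        raise ValueError(f"dataset of size {n} too small for {n_outer} outer folds")
    rng = np.random.default_rng(seed)
    fold_rows, run_rows = [], []
    for run in range(n_runs):
        run_seed = int(rng.integers(0, 2**31 - 1))
        outer = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=run_seed)
        pooled_scores = np.empty(n)
        pooled_mask = np.zeros(n, dtype=bool)
        for fold, (tr, te) in enumerate(outer.split(np.zeros(n), y)):
            inner = StratifiedKFold(
                n_splits=n_inner, shuffle=True, random_state=run_seed + 1 + fold
            )
            inner_splits = list(inner.split(np.zeros(len(tr)), y[tr]))
            best = None  # (auc, param_key_index) with tie-break by grid order
            for pi, (C, gkey) in enumerate(param_grid):
                gram = grams[gkey]
                aucs = []
                for itr, ite in inner_splits:
                    s = _fit_scores(gram, y, tr[itr], tr[ite], C)
                    aucs.append(roc_auc_score(y[tr[ite]], s))
                mean_auc = float(np.mean(aucs))
                if best is None or mean_auc > best[0] + 1e-12:
                    best = (mean_auc, pi)
            C_best, gkey_best = param_grid[best[1]]
            scores = _fit_scores(grams[gkey_best], y, tr, te, C_best)
            pooled_scores[te] = scores
            pooled_mask[te] = True
            m = metrics_from_scores(scores, y[te])
            fold_rows.append(
                {"run": run, "fold": fold, "C": C_best, param_name: gkey_best,
                 "inner_AUC": best[0], **m.as_dict()}
            )
        assert pooled_mask.all(), "outer folds must cover the dataset"
        rm = metrics_from_scores(pooled_scores, y)
        run_rows.append({"run": run, **rm.as_dict()})

    folds = pd.DataFrame(fold_rows)
    runs = pd.DataFrame(run_rows)
    summary = {
        "n_runs": n_runs,
        "seed": seed,
        "n_outer": n_outer,
        "n_inner": n_inner,
        "param_name": param_name,
        "grid": {"C": [float(c) for c in sorted({c for c, _ in param_grid})],
                 param_name: [float(g) if isinstance(g, float) else int(g)
                              for g in sorted({g for _, g in param_grid})]},
        "mean": {m: float(runs[m].mean()) for m in ("ACC", "MCC", "AUC")},
        "sd": {m: float(runs[m].std(ddof=1)) if n_runs > 1 else 0.0
               for m in ("ACC", "MCC", "AUC")},
        "selected": folds.groupby(["C", param_name]).size()
                         .sort_values(ascending=False).index[0],
    }
    sel_c, sel_g = summary["selected"]
    summary["selected"] = {
        "C": float(sel_c),
        param_name: float(sel_g) if isinstance(sel_g, (float, np.floating))
        else int(sel_g),
    }
    return CVReport(folds=folds, runs=runs, summary=summary)


def nested_cv(
    data: LabeledDataset,
    grid: GridSpec | None = None,
    n_runs: int = 20,
    seed: int = 0,
    n_outer: int = 10,
    n_inner: int = 10,
) -> CVReport:
    """Nested CV of the string-kernel SVM; see the module docstring."""
    data.require_both_classes()
    grid = grid or GridSpec()
    ds = tuple(sorted(set(grid.ds)))
    if max(ds) > data.length:
        raise ValueError(f"grid degree {max(ds)} exceeds peptide length {data.length}")
    grams = {d: gram_matrix(data.peptides, KernelSpec(d=d)) for d in ds}
    # sorted (d outer, C inner) so earlier grid entries win AUC ties:
    # smallest d first, then smallest C
    param_grid = [(C, d) for d in ds for C in sorted(set(grid.Cs))]
    report = _nested_cv_precomputed(
        grams, param_grid, data.labels, "d", n_runs, seed, n_outer, n_inner
    )
    report.summary["kernel"] = "weighted_degree"
    return report


# -- learning curve --------------------------------------------------------

def learning_curve(
    data: LabeledDataset,
    sizes: list[int] | None = None,
    seed: int = 0,
    C: float = 1.0,
    d: int = 9,
    grid: GridSpec | None = None,
    n_inner: int = 10,
) -> pd.DataFrame:
    """Performance versus training-set size on one 50/25/25 random split.

    The dataset is split once (stratified) into a training pool (50%),
    a validation set (25%) and a test set (25%).  For each requested size
    ``s`` a model is trained on the first ``s`` peptides of the shuffled
    pool with the production parameters C=1, d=9 — or, if ``grid`` is
    given, with parameters re-tuned by inner CV at every size — and
    evaluated on both held-out sets.
    """
    data.require_both_classes()
    n = len(data)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = n // 2
    n_valid = (n - n_train) // 2
    pool, valid, test = np.split(perm, [n_train, n_train + n_valid])
    if sizes is None:
        sizes = [s for s in range(50, n_train + 1, 50)]
        if not sizes or sizes[-1] != n_train:
            sizes.append(n_train)
    sizes = sorted(set(int(s) for s in sizes))
    if sizes[0] < 2 or sizes[-1] > n_train:
        raise ValueError(
            f"sizes must lie in [2, {n_train}] (50% training pool), got {sizes}"
        )
    spec = KernelSpec(d=min(d, data.length))
    gram = gram_matrix(data.peptides, spec)
    y = data.labels
    rows = []
    for s in sizes:
        tr = pool[:s]
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"training subset of size {s} is single-class")
        C_s, d_s = C, spec.d
        if grid is not None:
            C_s, d_s = _tune_on_subset(
                data.subset(tr), grid, seed=seed, n_inner=n_inner
            )
        g = gram if d_s == spec.d else gram_matrix(data.peptides, KernelSpec(d=d_s))
        val_scores = _fit_scores(g, y, tr, valid, C_s)
        test_scores = _fit_scores(g, y, tr, test, C_s)
        mv = metrics_from_scores(val_scores, y[valid])
        mt = metrics_from_scores(test_scores, y[test])
        rows.append({
            "size": s, "C": C_s, "d": d_s,
            "val_ACC": mv.ACC, "val_MCC": mv.MCC, "val_AUC": mv.AUC,
            "test_ACC": mt.ACC, "test_MCC": mt.MCC, "test_AUC": mt.AUC,
        })
    return pd.DataFrame(rows)


def _tune_on_subset(
    sub: LabeledDataset, grid: GridSpec, seed: int, n_inner: int
) -> tuple[float, int]:
    """Pick (C, d) maximising inner-CV AUC on a training subset."""
    ds = tuple(sorted(set(d for d in grid.ds if d <= sub.length)))
    grams = {d: gram_matrix(sub.peptides, KernelSpec(d=d)) for d in ds}
    y = sub.labels
    inner = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=seed)
    splits = list(inner.split(np.zeros(len(y)), y))
    best = None
    for d in ds:
        for C in sorted(set(grid.Cs)):
            aucs = [roc_auc_score(y[ite], _fit_scores(grams[d], y, itr, ite, C))
                    for itr, ite in splits]
            mean_auc = float(np.mean(aucs))
            if best is None or mean_auc > best[0] + 1e-12:
                best = (mean_auc, C, d)
    return best[1], best[2]


# -- mean-property RBF baseline -------------------------------------------

def baseline_property_svm(
    data: LabeledDataset,
    properties,
    grid: GridSpec | None = None,
    n_runs: int = 20,
    seed: int = 0,
    n_outer: int = 10,
    n_inner: int = 10,
) -> CVReport:
    """Position-blind reference method: mean-property encoding + RBF SVM.

    Each peptide becomes a vector of per-property means over its residues
    (see :func:`popisk.physchem.encode_mean_properties`); the SVM uses the
    Gaussian kernel k(x, y) = exp(-gamma ||x - y||^2) with (C, gamma)
    tuned by the identical nested-CV protocol.  Because averaging discards
    residue position, this baseline is blind to positional information the
    string kernel exploits.
    """
    from .physchem import PropertyTable, encode_mean_properties

    data.require_both_classes()
    grid = grid or GridSpec()
    if not isinstance(properties, PropertyTable):
        raise TypeError("properties must be a PropertyTable")
    X = encode_mean_properties(data.peptides, properties).to_numpy()
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=-1)
    gammas = tuple(sorted(set(grid.gammas)))
    grams = {g: np.exp(-g * sq) for g in gammas}
    param_grid = [(C, g) for g in gammas for C in sorted(set(grid.Cs))]
    report = _nested_cv_precomputed(
        grams, param_grid, data.labels, "gamma", n_runs, seed, n_outer, n_inner
    )
    report.summary["kernel"] = "rbf_mean_property"
    return report
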
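"""Couple the binary firefly search to an RBF-SVM classifier.

A firefly bit string is partitioned into three fields: ``t`` bits for the
SVM cost C, ``t`` bits for the kernel width gamma, and ``w`` bits of
feature mask (one per feature, 1 = selected).  Each parameter field is
read as an unsigned integer and mapped log2-uniformly onto the standard
libsvm grid ranges (C in [2^-5, 2^15], gamma in [2^-15, 2^3]).

Fitness (light intensity) trades cross-validated classification quality
against mask sparsity:

    I = omega * MCC + (1 - omega) * (1 - n/N)

with MCC pooled over an internal seeded stratified 5-fold CV, n the number
of selected features, N the feature-space dimension, and omega = 0.55 by
default.  Final models are evaluated with leave-one-out CV or repeated
stratified train/test splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, train_test_split
from sklearn.svm import SVC

from . import bfa
from .bfa import BFAConfig, BFAResult, BitArray, ContractError

#: log2 decode ranges for the two SVM parameter fields (libsvm grid)
C_EXP_RANGE = (-5.0, 15.0)
GAMMA_EXP_RANGE = (-15.0, 3.0)

#: default sparsity/accuracy trade-off weight in the light intensity
DEFAULT_OMEGA = 0.55

#: penalty intensity assigned to a firefly selecting zero features
ZERO_MASK_PENALTY = -1.0


class ProtocolError(ValueError):
    """An evaluation protocol's preconditions are not met."""


@dataclass(frozen=True)
class FireflyLayout:
    """Bit-string partition: C field | gamma field | feature mask."""

    t: int = 10
    w: int = 46

    def __post_init__(self) -> None:
        if self.t < 1 or self.w < 1:
            raise ContractError("t and w must be >= 1")

    @property
    def n(self) -> int:
        return 2 * self.t + self.w

    @property
    def c_slice(self) -> slice:
        return slice(0, self.t)

    @property
    def gamma_slice(self) -> slice:
        return slice(self.t, 2 * self.t)

    @property
    def mask_slice(self) -> slice:
        return slice(2 * self.t, self.n)


@dataclass(frozen=True)
class SVMParams:
    """RBF-SVM hyperparameters decoded from a firefly."""

    c: float
    gamma_svm: float
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.c <= 0 or self.gamma_svm <= 0:
            raise ContractError("c and gamma_svm must be positive")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ContractError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class Metrics:
    """Sensitivity, specificity, accuracy and Matthews correlation.

    SN = TP/(TP+FN) and SP = TN/(TN+FP) are ``None`` when their class is
    absent; MCC falls back to 0 when its denominator vanishes (the usual
    convention for degenerate confusion tables).
    """

    sn: float | None
    sp: float | None
    acc: float
    mcc: float


def metrics(cc: ConfusionCounts) -> Metrics:
    """Evaluate SN/SP/ACC/MCC from pooled confusion counts."""
    if cc.total == 0:
        raise ProtocolError("no evaluated samples")
    sn = cc.TP / (cc.TP + cc.FN) if (cc.TP + cc.FN) > 0 else None
    sp = cc.TN / (cc.TN + cc.FP) if (cc.TN + cc.FP) > 0 else None
    acc = (cc.TP + cc.TN) / cc.total
    denom2 = (
        (cc.TP + cc.FN) * (cc.TP + cc.FP) * (cc.TN + cc.FP) * (cc.TN + cc.FN)
    )
    if denom2 == 0:
        mcc = 0.0
    else:
        mcc = (cc.TP * cc.TN - cc.FN * cc.FP) / float(np.sqrt(denom2))
    return Metrics(sn=sn, sp=sp, acc=acc, mcc=mcc)


@dataclass(frozen=True)
class FitnessReport:
    """Light intensity plus the confusion-matrix metrics behind it."""

    intensity: float
    mcc: float
    sn: float | None
    sp: float | None
    acc: float
    n_selected: int
    n_total: int
    omega: float


def _field_value(bits: BitArray) -> int:
    """Read a bit field as an unsigned integer, most significant bit first."""
    return int("".join(str(int(b)) for b in bits), 2)


def decode(f: BitArray, layout: FireflyLayout) -> tuple[SVMParams, np.ndarray]:
    """Split a firefly into (SVMParams, boolean feature mask).

    Each t-bit field gives v in [0, 2^t - 1], mapped onto its exponent
    range as lo + v*(hi - lo)/(2^t - 1); the parameter is 2^exponent, so
    the all-zero field hits the range minimum and the all-one field the
    maximum exactly.
    """
    f = np.asarray(f, dtype=np.uint8)
    if f.shape != (layout.n,):
        raise ContractError(
            f"firefly length {f.size} does not match layout n={layout.n}"
        )
    levels = (1 << layout.t) - 1

    def _decode_field(bits: BitArray, lo: float, hi: float) -> float:
        v = _field_value(bits)
        return 2.0 ** (lo + v * (hi - lo) / levels)

    c = _decode_field(f[layout.c_slice], *C_EXP_RANGE)
    gamma = _decode_field(f[layout.gamma_slice], *GAMMA_EXP_RANGE)
    mask = f[layout.mask_slice].astype(bool)
    return SVMParams(c=c, gamma_svm=gamma), mask


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ContractError("X must be (n_samples, n_features) with matching y")
    if set(np.unique(y)) - {0, 1}:
        raise ContractError("labels must be binary 0/1")
    return X, y


def _svc(params: SVMParams) -> SVC:
    return SVC(C=params.c, gamma=params.gamma_svm, kernel=params.kernel)


def _pooled_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def cross_val_counts(
    X: np.ndarray,
    y: np.ndarray,
    params: SVMParams,
    mask: np.ndarray,
    n_folds: int = 5,
    eval_seed: int = 0,
) -> ConfusionCounts:
    """Pooled confusion counts from seeded stratified k-fold CV."""
    X, y = _check_xy(X, y)
    Xm = X[:, mask]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=eval_seed)
    preds = np.empty_like(y)
    for train_idx, test_idx in skf.split(Xm, y):
        clf = _svc(params)
        clf.fit(Xm[train_idx], y[train_idx])
        preds[test_idx] = clf.predict(Xm[test_idx])
    return _pooled_counts(y, preds)


def fitness(
    f: BitArray,
    layout: FireflyLayout,
    X: np.ndarray,
    y: np.ndarray,
    omega: float = DEFAULT_OMEGA,
    eval_seed: int = 0,
    n_folds: int = 5,
) -> FitnessReport:
    """Light intensity of a firefly on a labelled feature matrix.

    Decodes the firefly, scores the masked feature set with internal
    stratified ``n_folds``-fold CV (seeded, deterministic), and combines
    the pooled-fold MCC with the sparsity bonus.  An all-zero mask is a
    degenerate solution and receives the hard penalty I = -1 so it can
    never compete.
    """
    if not 0.0 <= omega <= 1.0:
        raise ContractError("omega must lie in [0, 1]")
    X, y = _check_xy(X, y)
    if X.shape[1] != layout.w:
        raise ContractError(
            f"data has {X.shape[1]} features but layout.w = {layout.w}"
        )
    params, mask = decode(f, layout)
    n_selected = int(mask.sum())
    if n_selected == 0:
        return FitnessReport(
            intensity=ZERO_MASK_PENALTY,
            mcc=0.0,
            sn=None,
            sp=None,
            acc=0.0,
            n_selected=0,
            n_total=layout.w,
            omega=omega,
        )
    cc = cross_val_counts(X, y, params, mask, n_folds=n_folds, eval_seed=eval_seed)
    m = metrics(cc)
    intensity = omega * m.mcc + (1.0 - omega) * (1.0 - n_selected / layout.w)
    return FitnessReport(
        intensity=intensity,
        mcc=m.mcc,
        sn=m.sn,
        sp=m.sp,
        acc=m.acc,
        n_selected=n_selected,
        n_total=layout.w,
        omega=omega,
    )


def make_objective(
    X: np.ndarray,
    y: np.ndarray,
    layout: FireflyLayout,
    omega: float = DEFAULT_OMEGA,
    eval_seed: int = 0,
    n_folds: int = 5,
) -> Callable[[BitArray], float]:
    """Objective for :func:`bfa.optimize`: bits -> light intensity."""

    def objective(bits: BitArray) -> float:
        return fitness(
            bits, layout, X, y, omega=omega, eval_seed=eval_seed, n_folds=n_folds
        ).intensity

    return objective


def loocv(
    X: np.ndarray,
    y: np.ndarray,
    params: SVMParams,
    mask: np.ndarray | None = None,
) -> tuple[ConfusionCounts, Metrics]:
    """Leave-one-out cross-validation: one held-out prediction per sample."""
    X, y = _check_xy(X, y)
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ProtocolError("LOOCV needs at least 2 samples per class")
    mask = np.ones(X.shape[1], dtype=bool) if mask is None else np.asarray(mask, bool)
    Xm = X[:, mask]
    preds = np.empty_like(y)
    for train_idx, test_idx in LeaveOneOut().split(Xm):
        clf = _svc(params)
        clf.fit(Xm[train_idx], y[train_idx])
        preds[test_idx] = clf.predict(Xm[test_idx])
    cc = _pooled_counts(y, preds)
    return cc, metrics(cc)


@dataclass
class TrainedModel:
    """A trained predictor: mask + hyperparameters + fitted classifier.

    The artifact (see :meth:`save`) is a self-describing JSON bundling the
    mask, decoded SVM parameters, layout, property-table version and the
    training set itself, so :meth:`load` can refit deterministically.
    """

    params: SVMParams
    mask: np.ndarray
    layout: FireflyLayout
    clf: SVC
    table_version: str = "unknown"
    metadata: dict = field(default_factory=dict)
    _train_X: np.ndarray | None = None
    _train_y: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels and decision-function margins for new feature rows."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.layout.w:
            raise ContractError(
                f"input must have {self.layout.w} columns, got "
                f"{X.shape[1] if X.ndim == 2 else 'non-2D'}"
            )
        if X.shape[0] == 0:
            return np.empty(0, dtype=int), np.empty(0)
        Xm = X[:, self.mask]
        return self.clf.predict(Xm).astype(int), self.clf.decision_function(Xm)

    def save(self, path: str | Path) -> None:
        payload = {
            "params": {"c": self.params.c, "gamma_svm": self.params.gamma_svm},
            "mask": self.mask.astype(int).tolist(),
            "layout": {"t": self.layout.t, "w": self.layout.w},
            "table_version": self.table_version,
            "metadata": self.metadata,
            "train_X": np.asarray(self._train_X).tolist(),
            "train_y": np.asarray(self._train_y).tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text())
        params = SVMParams(**payload["params"])
        layout = FireflyLayout(**payload["layout"])
        mask = np.array(payload["mask"], dtype=bool)
        X = np.array(payload["train_X"], dtype=float)
        y = np.array(payload["train_y"], dtype=int)
        return train_model(
            X,
            y,
            params,
            mask,
            layout=layout,
            table_version=payload["table_version"],
            metadata=payload["metadata"],
        )


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    params: SVMParams,
    mask: np.ndarray | None = None,
    layout: FireflyLayout | None = None,
    table_version: str = "unknown",
    metadata: dict | None = None,
) -> TrainedModel:
    """Fit the final RBF-SVM on masked features."""
    X, y = _check_xy(X, y)
    layout = layout if layout is not None else FireflyLayout(w=X.shape[1])
    mask = np.ones(X.shape[1], dtype=bool) if mask is None else np.asarray(mask, bool)
    clf = _svc(params)
    clf.fit(X[:, mask], y)
    return TrainedModel(
        params=params,
        mask=mask,
        layout=layout,
        clf=clf,
        table_version=table_version,
        metadata=metadata or {},
        _train_X=X,
        _train_y=y,
    )


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC area from decision scores (rank-based, monotone-invariant)."""
    return float(roc_auc_score(np.asarray(y_true, int), np.asarray(scores, float)))


@dataclass
class SplitResult:
    """One train/test repetition of the under-sampling protocol."""

    seed: int
    report: FitnessReport  # best firefly's in-search fitness
    params: SVMParams
    mask: np.ndarray
    test_metrics: Metrics
    test_auc: float
    baseline_metrics: Metrics | None = None


@dataclass
class ProtocolSummary:
    """All repetitions plus their aggregate.

    ``median_index`` flags the run whose test MCC is the median across
    repetitions — the run whose mask/parameters would seed a final model.
    """

    splits: list[SplitResult]
    mean_mcc: float
    mean_acc: float
    mean_sn: float
    mean_sp: float
    median_index: int


def repeated_split_protocol(
    X: np.ndarray,
    y: np.ndarray,
    layout: FireflyLayout | None = None,
    cfg: BFAConfig | None = None,
    omega: float = DEFAULT_OMEGA,
    k_repeats: int = 20,
    train_fraction: float = 355.0 / 455.0,
    seed: int = 0,
    with_baseline: bool = False,
) -> ProtocolSummary:
    """Repeated stratified under-sampling evaluation.

    For each of ``k_repeats`` seeded repetitions: draw a stratified random
    train/test split (``train_fraction`` of each class trains, mirroring
    the 355-of-455 draw of the reference protocol), run a full BFA
    optimization on the training part, refit the decoded model and score
    it on the held-out part.  The summary carries per-split rows, their
    mean, and the index of the median-MCC run.  ``with_baseline`` also
    scores an all-features RBF-SVM at libsvm defaults (C=1,
    gamma='scale') on the same splits.
    """
    if k_repeats < 1:
        raise ContractError("k_repeats must be >= 1")
    X, y = _check_xy(X, y)
    layout = layout if layout is not None else FireflyLayout(w=X.shape[1])
    cfg = cfg if cfg is not None else BFAConfig()

    splits: list[SplitResult] = []
    for rep in range(k_repeats):
        rep_seed = seed + rep
        X_tr, X_te, y_tr, y_te = train_test_split(
            X,
            y,
            train_size=train_fraction,
            stratify=y,
            random_state=rep_seed,
        )
        run_cfg = BFAConfig(
            population_size=cfg.population_size,
            max_iterations=cfg.max_iterations,
            gamma_fa=cfg.gamma_fa,
            beta0=cfg.beta0,
            rng_seed=rep_seed,
            elitism=cfg.elitism,
        )
        objective = make_objective(
            X_tr, y_tr, layout, omega=omega, eval_seed=rep_seed
        )
        result = bfa.optimize(objective, layout.n, run_cfg)
        report = fitness(
            result.best_bits, layout, X_tr, y_tr, omega=omega, eval_seed=rep_seed
        )
        params, mask = decode(result.best_bits, layout)
        model = train_model(X_tr, y_tr, params, mask, layout=layout)
        pred, scores = model.predict(X_te)
        test_m = metrics(_pooled_counts(y_te, pred))
        auc = roc_auc(y_te, scores)

        baseline_m = None
        if with_baseline:
            base = SVC(C=1.0, gamma="scale", kernel="rbf")
            base.fit(X_tr, y_tr)
            baseline_m = metrics(_pooled_counts(y_te, base.predict(X_te)))

        splits.append(
            SplitResult(
                seed=rep_seed,
                report=report,
                params=params,
                mask=mask,
                test_metrics=test_m,
                test_auc=auc,
                baseline_metrics=baseline_m,
            )
        )

    mccs = np.array([s.test_metrics.mcc for s in splits])
    median_index = int(np.argsort(mccs)[len(mccs) // 2])
    return ProtocolSummary(
        splits=splits,
        mean_mcc=float(mccs.mean()),
        mean_acc=float(np.mean([s.test_metrics.acc for s in splits])),
        mean_sn=float(np.mean([s.test_metrics.sn for s in splits])),
        mean_sp=float(np.mean([s.test_metrics.sp for s in splits])),
        median_index=median_index,
    )
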
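"""Semantic scales: regression from text embeddings to ratings.

A semantic scale maps a text embedding x to a numeric construct y (here
severity of violence on a 0-10 scale) through ordinary multiple linear
regression on the first k embedding dimensions, or through multiple
logistic regression for binary constructs. No regularization is applied.

Evaluation uses grouped leave-out cross-validation: all ratings of one
source text share a fold, so a model is never tested on a text it was
trained on. The partition is created once and reused ("1 unique
partition"); every record receives exactly one out-of-fold prediction.
Within each training fold, the number of leading dimensions k is selected
from a candidate grid — by default scored with an inner grouped 5-fold
cross-validated Pearson r; a plain training-fit criterion is available as
``selection="train-fit"``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Sequence

import numpy as np
import scipy.special
import scipy.stats
from sklearn.linear_model import LogisticRegression

from semscale.embed import TextEmbedding

__all__ = [
    "RatedRecord",
    "SemanticScaleModel",
    "CrossValidationPlan",
    "CvPrediction",
    "CvResult",
    "DEFAULT_DIMENSION_GRID",
    "make_folds",
    "select_dimensions",
    "train_scale",
    "predict_scale",
    "cross_validated_fit",
    "save_model",
    "load_model",
]

log = logging.getLogger(__name__)

#: Candidate numbers of leading dimensions, clipped to the space width d.
DEFAULT_DIMENSION_GRID: tuple[int, ...] = (2, 4, 8, 16, 32, 64, 96, 128, 192, 256, 384, 512)


@dataclass(frozen=True)
class RatedRecord:
    """One rated response: embedding vector, outcome, and its CV group.

    ``group`` identifies the source text (the P1 event) so that grouped
    cross-validation can keep all ratings of one text in one fold.
    """

    record_id: str
    group: Hashable
    embedding: np.ndarray
    outcome: float


@dataclass
class SemanticScaleModel:
    family: str  # "linear" | "logistic"
    coefficients: np.ndarray
    intercept: float
    k_dims: int
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.family not in ("linear", "logistic"):
            raise ValueError(f"unknown model family: {self.family!r}")
        if self.coefficients.shape != (self.k_dims,):
            raise ValueError("coefficients length must equal k_dims")


@dataclass(frozen=True)
class CrossValidationPlan:
    n_folds: int
    group_key: str
    assignment: dict  # group -> fold id

    def fold_of(self, group: Hashable) -> int:
        return self.assignment[group]

    def groups_in_fold(self, fold: int) -> list:
        return [g for g, f in self.assignment.items() if f == fold]


@dataclass(frozen=True)
class CvPrediction:
    record_id: str
    predicted: float
    fold: int
    k_dims: int


@dataclass
class CvResult:
    predictions: list[CvPrediction]
    pearson_r: float
    fold_dims: list[int]
    selection_traces: list[list[tuple[int, float]]]

    @property
    def mean_k(self) -> float:
        return float(np.mean(self.fold_dims))

    @property
    def sd_k(self) -> float:
        return float(np.std(self.fold_dims, ddof=1)) if len(self.fold_dims) > 1 else 0.0


def _groups_of(records: Sequence) -> list:
    if len(records) and hasattr(records[0], "group"):
        return [r.group for r in records]
    return list(records)


def make_folds(
    records: Sequence,
    n_folds: int = 10,
    group_key: str = "event_id",
    seed: int = 0,
) -> CrossValidationPlan:
    """Assign source-text groups to folds, sizes differing by at most one.

    ``records`` may be RatedRecords (their ``group`` attribute is used) or a
    plain sequence of group labels. Deterministic given the seed; groups are
    sorted before shuffling so the plan is independent of record order.
    """
    groups = sorted(set(_groups_of(records)), key=str)
    if len(groups) < n_folds:
        raise ValueError(
            f"need at least {n_folds} distinct groups for {n_folds} folds, got {len(groups)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    assignment = {groups[g]: int(i % n_folds) for i, g in enumerate(order)}
    return CrossValidationPlan(n_folds=n_folds, group_key=group_key, assignment=assignment)


def _design(records: Sequence[RatedRecord], k: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([np.asarray(r.embedding)[:k] for r in records], dtype=float)
    y = np.array([r.outcome for r in records], dtype=float)
    return x, y


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("Pearson r undefined: zero variance")
    return float(scipy.stats.pearsonr(a, b).statistic)


def train_scale(
    records: Sequence[RatedRecord], k: int, family: str = "linear"
) -> SemanticScaleModel:
    """Fit an unregularized scale on the first k embedding dimensions.

    Linear: ordinary least squares with intercept. Logistic:
    maximum-likelihood logit (lbfgs, no penalty); complete separation is
    flagged with a warning since the MLE then diverges.
    """
    x, y = _design(records, k)
    n = x.shape[0]
    if family == "linear":
        if n <= k:
            raise ValueError(f"need more than k={k} training records, got {n}")
        design = np.column_stack([np.ones(n), x])
        beta, _res, rank, _sv = np.linalg.lstsq(design, y, rcond=None)
        if rank < k + 1:
            raise ValueError(
                f"rank-deficient design: rank {rank} < {k + 1} "
                f"(intercept + first {k} embedding dimensions)"
            )
        return SemanticScaleModel(
            family="linear",
            coefficients=beta[1:],
            intercept=float(beta[0]),
            k_dims=k,
            training_meta={"n_train": n},
        )
    elif family == "logistic":
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"logistic scale needs exactly two classes, got {classes.size}")
        # C=inf: unregularized maximum-likelihood logit
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000, tol=1e-10)
        clf.fit(x, y)
        n_iter = int(np.max(clf.n_iter_))
        if n_iter >= 2000:
            raise RuntimeError(f"logistic fit did not converge after {n_iter} iterations")
        margin = clf.decision_function(x)
        if np.all((margin > 0) == (y == classes[1])) and np.max(np.abs(margin)) > 30:
            log.warning(
                "logistic scale: classes appear perfectly separated; "
                "unregularized coefficients are unstable"
            )
        return SemanticScaleModel(
            family="logistic",
            coefficients=clf.coef_.ravel(),
            intercept=float(clf.intercept_[0]),
            k_dims=k,
            training_meta={"n_train": n, "n_iter": n_iter, "classes": classes.tolist()},
        )
    raise ValueError(f"unknown model family: {family!r}")


def predict_scale(
    model: SemanticScaleModel, embedding: TextEmbedding | np.ndarray
) -> float:
    """Score one embedding: linear value, or probability for logistic."""
    vec = embedding.vector if isinstance(embedding, TextEmbedding) else np.asarray(embedding)
    if vec.shape[0] < model.k_dims:
        raise ValueError(
            f"embedding has {vec.shape[0]} dimensions, model needs {model.k_dims}"
        )
    eta = model.intercept + float(np.dot(model.coefficients, vec[: model.k_dims]))
    if model.family == "logistic":
        return float(scipy.special.expit(eta))
    return eta


def _predict_batch(model: SemanticScaleModel, x: np.ndarray) -> np.ndarray:
    eta = model.intercept + x[:, : model.k_dims] @ model.coefficients
    if model.family == "logistic":
        return scipy.special.expit(eta)
    return eta


def select_dimensions(
    train_records: Sequence[RatedRecord],
    grid: Sequence[int] | None = None,
    inner_folds: int = 5,
    family: str = "linear",
    selection: str = "inner-cv",
    seed: int = 0,
    return_trace: bool = False,
):
    """Choose the number of leading dimensions k from a candidate grid.

    ``selection="inner-cv"`` scores each k by the Pearson r between pooled
    inner-out-of-fold predictions and outcomes, using a grouped inner
    k-fold on the training partition. ``selection="train-fit"`` scores by
    the training-set Pearson r instead. Ties go to the smallest k.
    """
    d = int(np.asarray(train_records[0].embedding).shape[0])
    if grid is None:
        grid = DEFAULT_DIMENSION_GRID
    grid = sorted({min(int(k), d) for k in grid if k >= 1})
    if not grid:
        raise ValueError("empty dimension grid")
    y_all = np.array([r.outcome for r in train_records], dtype=float)
    if np.std(y_all) == 0:
        raise ValueError("constant outcomes: dimension selection is undefined")

    trace: list[tuple[int, float]] = []
    if selection == "train-fit":
        for k in grid:
            model = train_scale(train_records, k, family=family)
            x, y = _design(train_records, k)
            trace.append((k, _pearson(_predict_batch(model, x), y)))
    elif selection == "inner-cv":
        inner_plan = make_folds(
            train_records, n_folds=min(inner_folds, len(set(_groups_of(train_records)))),
            seed=seed,
        )
        fold_ids = np.array([inner_plan.fold_of(r.group) for r in train_records])
        for k in grid:
            preds = np.empty(len(train_records))
            ok = True
            for f in range(inner_plan.n_folds):
                tr = [r for r, fi in zip(train_records, fold_ids) if fi != f]
                te_idx = np.where(fold_ids == f)[0]
                try:
                    model = train_scale(tr, k, family=family)
                except (ValueError, RuntimeError):
                    ok = False
                    break
                x_te = np.array(
                    [np.asarray(train_records[i].embedding)[:k] for i in te_idx]
                )
                preds[te_idx] = _predict_batch(model, x_te)
            if not ok:
                continue
            trace.append((k, _pearson(preds, y_all)))
    else:
        raise ValueError(f"unknown selection mode: {selection!r}")

    if not trace:
        raise ValueError("no candidate dimension count produced a valid fit")
    best_r = max(r for _, r in trace)
    best_k = min(k for k, r in trace if r >= best_r - 1e-12)
    if return_trace:
        return best_k, trace
    return best_k


def cross_validated_fit(
    records: Sequence[RatedRecord],
    plan: CrossValidationPlan,
    grid: Sequence[int] | None = None,
    family: str = "linear",
    selection: str = "inner-cv",
    seed: int = 0,
) -> CvResult:
    """Grouped leave-out cross-validation with per-fold dimension selection.

    Per fold: select k on the training partition, fit, predict the held-out
    records. Every record is predicted exactly once; the overall Pearson r
    pools all out-of-fold (prediction, outcome) pairs.
    """
    missing = [r.record_id for r in records if r.group not in plan.assignment]
    if missing:
        raise ValueError(f"records with groups outside the plan: {missing[:5]}")
    order = np.argsort([r.record_id for r in records], kind="stable")
    records = [records[i] for i in order]  # record-order invariance
    fold_ids = np.array([plan.fold_of(r.group) for r in records])

    predictions: list[CvPrediction] = []
    fold_dims: list[int] = []
    traces: list[list[tuple[int, float]]] = []
    pred_values = np.empty(len(records))
    for f in range(plan.n_folds):
        train = [r for r, fi in zip(records, fold_ids) if fi != f]
        test_idx = np.where(fold_ids == f)[0]
        if len(test_idx) == 0:
            continue
        try:
            k, trace = select_dimensions(
                train, grid=grid, family=family, selection=selection,
                seed=seed + f, return_trace=True,
            )
            model = train_scale(train, k, family=family)
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(f"cross-validation failed in fold {f}: {exc}") from exc
        x_te = np.array([np.asarray(records[i].embedding) for i in test_idx])
        preds = _predict_batch(model, x_te)
        pred_values[test_idx] = preds
        fold_dims.append(k)
        traces.append(trace)
        for i, p in zip(test_idx, preds):
            predictions.append(
                CvPrediction(record_id=records[i].record_id, predicted=float(p), fold=f, k_dims=k)
            )
    outcomes = np.array([r.outcome for r in records])
    r = _pearson(pred_values, outcomes)
    return CvResult(
        predictions=predictions, pearson_r=r, fold_dims=fold_dims, selection_traces=traces
    )


# ---------------------------------------------------------------------------
# persistence


def save_model(model: SemanticScaleModel, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "family": model.family,
        "k_dims": model.k_dims,
        "intercept": model.intercept,
        "coefficients": model.coefficients.tolist(),
        "training_meta": model.training_meta,
    }
    path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    return path


def load_model(path: str | Path) -> SemanticScaleModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return SemanticScaleModel(
        family=payload["family"],
        coefficients=np.array(payload["coefficients"], dtype=float),
        intercept=float(payload["intercept"]),
        k_dims=int(payload["k_dims"]),
        training_meta=payload.get("training_meta", {}),
    )
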
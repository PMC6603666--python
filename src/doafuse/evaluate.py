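"""Evaluation of a depth-of-anesthesia index against a reference.

The continuous 0–100 index is discretized into the four conventional
anesthesia states — awake [80, 100], light [60, 80), general [40, 60),
deep [0, 40) — and compared with the discretized reference via per-state
sensitivity ``S_i = N_i,detected / N_i,total`` and overall classification
accuracy ``ACC = N_detected / N_total``.  Agreement of the continuous
values is measured by Pearson correlation and Bland–Altman bias/limits.

Generalization is estimated by leave-one-subject-out cross-validation
(LOOCV): every subject serves as the test set once, with the model
retrained on the rest; all metrics are computed on the minutes pooled
across folds (micro-averaged), matching how single cohort-level numbers
are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .io import IndexSeries
from .model import AnnHyper, predict_index, train_ann, train_svr
from .spectral import FeatureVector
from .synthetic import SyntheticPatient

__all__ = [
    "STATES",
    "STATE_BANDS",
    "classify_state",
    "ConfusionTable",
    "EvaluationReport",
    "sensitivity",
    "accuracy",
    "pearson_r",
    "bland_altman",
    "SubjectData",
    "loocv",
    "ablation_study",
]

STATES = ("awake", "light", "general", "deep")

#: Half-open downward bands; awake is closed at both ends.
STATE_BANDS = {
    "awake": (80.0, 100.0),
    "light": (60.0, 80.0),
    "general": (40.0, 60.0),
    "deep": (0.0, 40.0),
}


def classify_state(index: float) -> str:
    """Map a 0–100 index value to its anesthesia state.

    Boundary convention: bands are half-open downward, so 80 → awake,
    60 → light, 40 → general.
    """
    if not 0 <= index <= 100:
        raise ValueError(f"index {index} outside [0, 100]")
    if index >= 80:
        return "awake"
    if index >= 60:
        return "light"
    if index >= 40:
        return "general"
    return "deep"


@dataclass
class ConfusionTable:
    """4×4 reference-state × predicted-state counts."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros((4, 4), int))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, int)
        if self.counts.shape != (4, 4) or np.any(self.counts < 0):
            raise ValueError("counts must be a nonnegative 4×4 table")

    def add(self, reference_state: str, predicted_state: str, n: int = 1) -> None:
        self.counts[STATES.index(reference_state), STATES.index(predicted_state)] += n

    @classmethod
    def from_indices(cls, reference: np.ndarray, predicted: np.ndarray) -> "ConfusionTable":
        t = cls()
        for r, p in zip(reference, predicted):
            t.add(classify_state(r), classify_state(p))
        return t

    def total(self, state: str) -> int:
        return int(self.counts[STATES.index(state)].sum())

    def detected(self, state: str) -> int:
        i = STATES.index(state)
        return int(self.counts[i, i])


def sensitivity(table: ConfusionTable, state: str) -> float | None:
    """Per-state sensitivity ``N_detected / N_total``; None when the state
    never occurs in the reference (undefined, not zero)."""
    total = table.total(state)
    if total == 0:
        return None
    return table.detected(state) / total


def accuracy(table: ConfusionTable) -> float:
    """Overall classification accuracy: trace over grand total."""
    total = int(table.counts.sum())
    if total == 0:
        raise ValueError("empty confusion table")
    return float(np.trace(table.counts) / total)


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length series with n ≥ 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bland_altman(reference: np.ndarray, predicted: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Bland–Altman bias and 95% limits of agreement.

    ``bias = mean(predicted - reference)``; limits are
    ``bias ± 1.96 · SD`` of the differences (sample SD, n−1).
    """
    reference = np.asarray(reference, float)
    predicted = np.asarray(predicted, float)
    if reference.size != predicted.size or reference.size < 2:
        raise ValueError("need equal-length series with n ≥ 2")
    diff = predicted - reference
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


@dataclass
class SubjectData:
    """Per-subject aligned features and reference-index minutes."""

    features: np.ndarray  # (n_minutes, 4)
    targets: np.ndarray  # (n_minutes,) in [0, 100]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, float)
        self.targets = np.asarray(self.targets, float)
        if self.features.shape[0] != self.targets.size:
            raise ValueError("features and targets must align per minute")


@dataclass
class EvaluationReport:
    sensitivities: dict[str, float | None]
    accuracy: float
    pearson_r: float
    pearson_p: float
    ba_bias: float
    ba_limits: tuple[float, float]
    rmse: float
    confusion: ConfusionTable
    per_fold: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sensitivities": self.sensitivities,
            "accuracy": self.accuracy,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "ba_bias": self.ba_bias,
            "ba_limits": list(self.ba_limits),
            "rmse": self.rmse,
            "confusion": self.counts_list(),
            "per_fold": self.per_fold,
        }

    def counts_list(self) -> list[list[int]]:
        return self.confusion.counts.tolist()


def _coerce_subject(subject, i: int) -> SubjectData:
    if isinstance(subject, SubjectData):
        return subject
    if isinstance(subject, SyntheticPatient):
        raise TypeError(
            "SyntheticPatient must be run through preprocessing/feature "
            "extraction first; pass SubjectData(features, targets)"
        )
    if isinstance(subject, tuple) and len(subject) == 2:
        feats, targs = subject
        if feats and isinstance(feats[0], FeatureVector):
            feats = np.array([fv.as_array() for fv in feats])
        targs = targs.values if isinstance(targs, IndexSeries) else np.asarray(targs, float)
        return SubjectData(np.asarray(feats, float), targs, subject_id=f"S{i}")
    raise TypeError(f"cannot interpret subject {type(subject)}")


def loocv(
    cohort: list,
    model_kind: str = "ann",
    seed: int = 0,
    hyper: AnnHyper | None = None,
    feature_subset: tuple[int, ...] | None = None,
) -> EvaluationReport:
    """Leave-one-subject-out cross-validation of the fusion model.

    Each subject is held out in turn; the model is retrained on the rest
    and predicts the held-out minutes.  Predictions are pooled across
    folds, then discretized and scored.  Subjects with no valid minutes
    are skipped (logged in ``per_fold``).
    """
    subjects = [_coerce_subject(s, i) for i, s in enumerate(cohort)]
    if len(subjects) < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    pooled_ref: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    per_fold: list[dict] = []
    rng = np.random.default_rng(seed)
    for k, test in enumerate(subjects):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        if test.targets.size == 0:
            per_fold.append({"subject": test.subject_id or str(k), "skipped": True})
            continue
        train = [s for j, s in enumerate(subjects) if j != k]
        X = np.vstack([s.features for s in train])
        y = np.concatenate([s.targets for s in train])
        if model_kind == "ann":
            model = train_ann(X, y, hyper=hyper, seed=fold_seed, feature_subset=feature_subset)
        elif model_kind == "svr":
            model = train_svr(X, y, feature_subset=feature_subset)
        else:
            raise ValueError(f"unknown model kind {model_kind!r}")
        pred = predict_index(model, test.features).values
        pooled_ref.append(test.targets)
        pooled_pred.append(pred)
        fold_table = ConfusionTable.from_indices(test.targets, pred)
        per_fold.append(
            {
                "subject": test.subject_id or str(k),
                "n_minutes": int(test.targets.size),
                "accuracy": accuracy(fold_table),
            }
        )
    ref = np.concatenate(pooled_ref)
    pred = np.concatenate(pooled_pred)
    table = ConfusionTable.from_indices(ref, pred)
    r, p = pearson_r(ref, pred)
    bias, limits = bland_altman(ref, pred)
    return EvaluationReport(
        sensitivities={s: sensitivity(table, s) for s in STATES},
        accuracy=accuracy(table),
        pearson_r=r,
        pearson_p=p,
        ba_bias=bias,
        ba_limits=limits,
        rmse=float(np.sqrt(np.mean((pred - ref) ** 2))),
        confusion=table,
        per_fold=per_fold,
    )


def ablation_study(
    cohort: list,
    model_kind: str = "ann",
    seed: int = 0,
    hyper: AnnHyper | None = None,
) -> dict[tuple[str, ...], float]:
    """LOOCV accuracy for every nonempty subset of the four features.

    Returns ``{("pe",): acc, ..., ("pe","br","sef95","sfs"): acc}`` over
    all 15 subsets, the shape of a feature-combination comparison table.
    """
    names = FeatureVector.FEATURE_NAMES
    results: dict[tuple[str, ...], float] = {}
    for size in range(1, 5):
        for subset in combinations(range(4), size):
            report = loocv(
                cohort, model_kind=model_kind, seed=seed, hyper=hyper, feature_subset=subset
            )
            results[tuple(names[i] for i in subset)] = report.accuracy
    return results
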
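"""Evaluation of mutation-load estimators as immunotherapy-response predictors.

An estimator is judged on four axes: agreement with the actual (exome-wide)
mutation load (R^2); discrimination of durable clinical benefit (DCB) from
no durable benefit (NDB) by ROC/AUC with an optimal threshold chosen by
Youden's J; survival separation of high- vs low-estimate patients by the
log-rank test; and calibration against an empirical null of models built
from randomly chosen gene panels of the same size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.metrics import roc_auc_score

from .estimation import EstimationModel, fit_least_squares
from .maf_io import MutationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseLabel",
    "SurvivalRecord",
    "RocCurve",
    "ClassificationReport",
    "NullDistribution",
    "UndefinedMetricError",
    "r_squared",
    "roc_auc",
    "optimal_threshold",
    "classify_response",
    "median_split",
    "km_logrank",
    "random_model_null",
    "read_clinical",
]

DCB = "DCB"
NDB = "NDB"


class UndefinedMetricError(ValueError):
    """The requested metric is undefined for the given inputs."""


@dataclass(frozen=True)
class ResponseLabel:
    """Immunotherapy response: durable clinical benefit or not."""

    patient_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in (DCB, NDB):
            raise ValueError(f"label must be {DCB!r} or {NDB!r}, got {self.label!r}")


@dataclass(frozen=True)
class SurvivalRecord:
    """Survival observation with a high/low estimated-load group tag."""

    patient_id: str
    time: float
    event: bool
    group: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be non-negative")
        if self.group not in ("high", "low"):
            raise ValueError("group must be 'high' or 'low'")


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC over the observed score thresholds.

    At threshold t a patient is called DCB iff score >= t. ``thresholds``
    ascend; sensitivity is non-increasing along them. ``optimal_threshold``
    maximizes Youden's J = sensitivity + specificity - 1, ties broken toward
    the higher (more conservative) threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


@dataclass(frozen=True)
class ClassificationReport:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else float("nan")


@dataclass(frozen=True)
class NullDistribution:
    """Empirical null for one metric from random same-size gene panels.

    ``empirical_p`` is (#null >= observed) / n_iter, at resolution 1/n_iter;
    a zero count is reported as below resolution ("< 1/n_iter").
    """

    metric: str
    null_values: np.ndarray
    observed: float
    seed: int

    @property
    def n_iter(self) -> int:
        return len(self.null_values)

    @property
    def tail_count(self) -> int:
        finite = self.null_values[np.isfinite(self.null_values)]
        return int(np.sum(finite >= self.observed))

    @property
    def empirical_p(self) -> float:
        return self.tail_count / self.n_iter

    @property
    def below_resolution(self) -> bool:
        return self.tail_count == 0

    def formatted_p(self) -> str:
        if self.below_resolution:
            return f"< {1 / self.n_iter:g}"
        return f"{self.empirical_p:g}"


def _labels_to_binary(labels: Sequence) -> np.ndarray:
    values = [lab.label if isinstance(lab, ResponseLabel) else str(lab) for lab in labels]
    bad = sorted(set(values) - {DCB, NDB})
    if bad:
        raise ValueError(f"unknown response label(s): {', '.join(bad)}")
    return np.array([v == DCB for v in values])


def r_squared(
    estimated: Sequence[float],
    actual: Sequence[float],
    method: str = "pearson_squared",
) -> float:
    """R^2 between estimated and actual loads.

    Default is the squared Pearson correlation, appropriate for validation
    cohorts the model was not fitted on; ``coefficient_of_determination``
    gives 1 - RSS/TSS instead. A constant actual vector is undefined.
    """
    est = np.asarray(estimated, dtype=float)
    act = np.asarray(actual, dtype=float)
    if est.shape != act.shape or est.size < 3:
        raise ValueError("estimated and actual must be same-length vectors, n >= 3")
    if np.ptp(act) == 0:
        raise UndefinedMetricError("actual loads are constant; R^2 is undefined")
    if method == "pearson_squared":
        r, _ = stats.pearsonr(est, act)
        return float(r * r)
    if method == "coefficient_of_determination":
        rss = float(((act - est) ** 2).sum())
        tss = float(((act - act.mean()) ** 2).sum())
        return 1.0 - rss / tss
    raise ValueError(f"unknown R^2 method {method!r}")


def roc_auc(scores: Sequence[float], labels: Sequence) -> RocCurve:
    """ROC curve for DCB/NDB discrimination by estimated load.

    Higher score means more likely DCB. Candidate thresholds are the unique
    observed scores (prediction rule: DCB iff score >= threshold); AUC is the
    tie-aware empirical AUC, identical to the Mann-Whitney U statistic
    divided by n_DCB * n_NDB.
    """
    scores = np.asarray(scores, dtype=float)
    y = _labels_to_binary(labels)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must align")
    if y.all() or not y.any():
        raise UndefinedMetricError("ROC undefined with a single response class")
    thresholds = np.unique(scores)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        called = scores >= t
        sens[i] = (called & y).sum() / n_pos
        spec[i] = (~called & ~y).sum() / n_neg
    auc = float(roc_auc_score(y, scores))
    j = sens + spec
    best_j = j.max()
    # ties toward the higher threshold: last index achieving max J
    opt = float(thresholds[np.nonzero(j >= best_j - 1e-12)[0][-1]])
    if np.ptp(scores) == 0:
        logger.warning("all scores identical; ROC threshold is degenerate (J = 0)")
    return RocCurve(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        auc=auc, optimal_threshold=opt,
    )


def optimal_threshold(roc: RocCurve) -> float:
    """Threshold maximizing sensitivity + specificity (Youden's J)."""
    return roc.optimal_threshold


def classify_response(
    estimated: Sequence[float], threshold: float, labels: Sequence
) -> ClassificationReport:
    """Call DCB iff estimated load >= threshold (inclusive) and tabulate."""
    est = np.asarray(estimated, dtype=float)
    y = _labels_to_binary(labels)
    called = est >= threshold
    return ClassificationReport(
        tp=int((called & y).sum()),
        fp=int((called & ~y).sum()),
        tn=int((~called & ~y).sum()),
        fn=int((~called & y).sum()),
    )


def median_split(estimated: Sequence[float]) -> np.ndarray:
    """Assign 'high' to estimates above the median, 'low' at or below.

    For even n with distinct values this yields two equal halves. If all
    values tie, everyone is 'low' (warned).
    """
    est = np.asarray(estimated, dtype=float)
    if est.size < 2:
        raise ValueError("median split needs at least two patients")
    med = np.median(est)
    groups = np.where(est > med, "high", "low")
    if np.ptp(est) == 0:
        logger.warning("all estimates equal; median split assigns everyone 'low'")
    return groups


def km_logrank(records: Sequence[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank test comparing high vs low estimated-load survival.

    Returns the chi-square statistic (1 df) and its p-value. Requires both
    groups non-empty and at least one observed event.
    """
    high = [r for r in records if r.group == "high"]
    low = [r for r in records if r.group == "low"]
    if not high or not low:
        raise UndefinedMetricError("log-rank needs both groups non-empty")
    if not any(r.event for r in records):
        raise UndefinedMetricError("log-rank needs at least one observed event")
    result = logrank_test(
        [r.time for r in high], [r.time for r in low],
        event_observed_A=[r.event for r in high],
        event_observed_B=[r.event for r in low],
    )
    return float(result.test_statistic), float(result.p_value)


def random_model_null(
    model: EstimationModel,
    train_matrix: MutationMatrix,
    valid_matrix: MutationMatrix,
    labels: Mapping[str, str] | None = None,
    p_genes: int | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
) -> dict[str, NullDistribution]:
    """Empirical null from random p-gene panels, mirroring the evaluation of
    the model of interest.

    Each iteration draws ``p_genes`` genes uniformly without replacement
    from the training matrix, fits them by least squares to the training
    loads, and evaluates on the validation matrix: R^2 (squared Pearson)
    between estimated and actual validation loads and, when ``labels`` maps
    validation patients to DCB/NDB, the AUC and the accuracy at that random
    model's own ROC-optimal threshold. Returns one null distribution per
    metric with the observed model's value and empirical p.
    """
    if p_genes is None:
        p_genes = model.n_genes
    if p_genes > train_matrix.n_genes:
        raise ValueError(
            f"p_genes={p_genes} exceeds the {train_matrix.n_genes} genes "
            "available in the training matrix"
        )
    rng = np.random.default_rng(seed)
    train_loads = train_matrix.loads().astype(float)
    valid_loads = valid_matrix.loads().astype(float)

    label_vec = None
    if labels is not None:
        label_vec = [labels[p] for p in valid_matrix.patients]

    def evaluate(candidate: EstimationModel) -> tuple[float, float, float]:
        from .estimation import predict_load

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = predict_load(candidate, valid_matrix)
            try:
                r2 = r_squared(est, valid_loads)
            except UndefinedMetricError:
                r2 = float("nan")
            auc = acc = float("nan")
            if label_vec is not None:
                try:
                    roc = roc_auc(est, label_vec)
                    auc = roc.auc
                    acc = classify_response(
                        est, roc.optimal_threshold, label_vec
                    ).accuracy
                except UndefinedMetricError:
                    pass
        return r2, auc, acc

    obs_r2, obs_auc, obs_acc = evaluate(model)

    null_r2 = np.empty(n_iter)
    null_auc = np.empty(n_iter)
    null_acc = np.empty(n_iter)
    gene_array = np.asarray(train_matrix.genes)
    # genes unmutated in the validation cohort are legitimately absent there;
    # per-iteration absent-gene warnings would swamp the log
    maf_logger = logging.getLogger("mutload.maf_io")
    old_level = maf_logger.level
    maf_logger.setLevel(logging.ERROR)
    for i in range(n_iter):
        genes = sorted(rng.choice(gene_array, size=p_genes, replace=False))
        counts = train_matrix.gene_counts(genes)
        design = np.column_stack([np.ones(train_matrix.n_patients), counts.T])
        coef, *_ = np.linalg.lstsq(design, train_loads, rcond=None)
        candidate = EstimationModel(
            gene_symbols=tuple(genes), weights=tuple(coef[1:]),
            intercept=float(coef[0]), name=f"random_{i}",
        )
        null_r2[i], null_auc[i], null_acc[i] = evaluate(candidate)
    maf_logger.setLevel(old_level)

    out = {
        "r_squared": NullDistribution("r_squared", null_r2, obs_r2, seed),
    }
    if label_vec is not None:
        out["auc"] = NullDistribution("auc", null_auc, obs_auc, seed)
        out["accuracy"] = NullDistribution("accuracy", null_acc, obs_acc, seed)
    return out


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV: patient_id, response (DCB/NDB), time, event."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"patient_id": str})
    required = {"patient_id", "response", "time", "event"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical column(s): {sorted(missing)}")
    return frame
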
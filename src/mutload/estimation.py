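"""Sparse linear mutation-load estimators: fitting, BIC model search, and
the published panels.

The estimator is affine in the per-gene mutation counts:

    y_hat_m = c + sum_i a_i * x_mi

where x_mi is the nonsynonymous point-mutation count of selected gene i in
patient m, a_i its weight and c the constant term. Parameters are fit by
ordinary least squares; subsets of the candidate genes are compared by the
Gaussian-likelihood BIC

    BIC = n * ln(RSS / n) + k * ln(n),    k = (#genes + 1)

(constant terms dropped, as they cancel across models). The full subset
space for q candidates has 2^q - 1 non-empty models, which is astronomically
large already at q = 62, so the default search is forward greedy selection;
exhaustive enumeration is available for small q as a verification oracle.

Two published panels are shipped: a 24-gene lung adenocarcinoma model and a
22-gene melanoma model, each with printed weights and constant term.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

from .maf_io import MutationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EstimationModel",
    "FitDiagnostics",
    "SearchConfig",
    "SingularDesignError",
    "fit_least_squares",
    "bic_score",
    "search_best_model",
    "predict_load",
    "published_model",
    "available_models",
    "model_space_size",
]

#: Designs with condition number above this are treated as collinear.
CONDITION_LIMIT = 1e10

PUBLISHED_MODELS = ("luad24", "melanoma22")


class SingularDesignError(ValueError):
    """The regression design is rank-deficient (collinear gene rows)."""


@dataclass(frozen=True)
class EstimationModel:
    """A fitted or published mutation-load panel model.

    Prediction for an all-zero count vector equals the intercept.
    """

    gene_symbols: tuple[str, ...]
    weights: tuple[float, ...]
    intercept: float
    name: str = "unnamed"

    def __post_init__(self) -> None:
        if len(self.gene_symbols) != len(self.weights):
            raise ValueError("one weight per gene is required")
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValueError("model gene symbols must be unique")

    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)

    def predict(self, counts: np.ndarray) -> np.ndarray:
        """Predict loads from a (n_model_genes, n_patients) count block."""
        counts = np.asarray(counts, dtype=float)
        return self.intercept + np.asarray(self.weights) @ counts

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "intercept": self.intercept,
            "genes": [
                {"symbol": g, "weight": w}
                for g, w in zip(self.gene_symbols, self.weights)
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, payload: dict) -> "EstimationModel":
        genes = payload["genes"]
        return cls(
            gene_symbols=tuple(g["symbol"] for g in genes),
            weights=tuple(float(g["weight"]) for g in genes),
            intercept=float(payload["intercept"]),
            name=str(payload.get("name", "unnamed")),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "EstimationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class FitDiagnostics:
    """Least-squares fit summary: residuals, RSS, BIC and training R^2.

    ``r2_train`` is the coefficient of determination on the training data;
    ``k_params`` counts the gene weights plus the intercept.
    """

    rss: float
    residuals: np.ndarray
    n_obs: int
    k_params: int
    bic: float
    r2_train: float


@dataclass(frozen=True)
class SearchConfig:
    """Subset-search settings.

    ``forward`` greedily adds the gene with the largest BIC decrease until no
    addition helps (or ``max_genes`` is reached); ``exhaustive`` scores every
    non-empty subset and is refused above ``exhaustive_limit`` candidates.
    Ties are broken lexicographically by gene symbol.
    """

    strategy: str = "forward"
    max_genes: int | None = None
    exhaustive_limit: int = 20

    def __post_init__(self) -> None:
        if self.strategy not in ("forward", "exhaustive"):
            raise ValueError(f"unknown search strategy {self.strategy!r}")


def model_space_size(n_candidates: int) -> int:
    """Number of non-empty gene subsets: 2^q - 1 (exact integer)."""
    if n_candidates < 0:
        raise ValueError("n_candidates must be non-negative")
    return 2**n_candidates - 1


def bic_score(rss: float, n_obs: int, k_params: int) -> float:
    """Gaussian-likelihood BIC up to model-independent constants.

    A perfect fit (RSS == 0) has no finite profile likelihood; it returns
    -inf with a warning so that it wins any comparison.
    """
    if n_obs <= k_params:
        raise ValueError("n_obs must exceed k_params")
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss == 0:
        warnings.warn("RSS is exactly zero (perfect fit); BIC is -inf")
        return float("-inf")
    return n_obs * math.log(rss / n_obs) + k_params * math.log(n_obs)


def _solve(design: np.ndarray, loads: np.ndarray, gene_symbols: Sequence[str]):
    """OLS via SVD with a collinearity check naming the offending genes."""
    n_obs, k = design.shape
    u, s, vt = np.linalg.svd(design, full_matrices=False)
    if s[0] == 0 or s[-1] == 0 or s[0] / s[-1] > CONDITION_LIMIT:
        rank = int(np.sum(s > s[0] / CONDITION_LIMIT)) if s[0] > 0 else 0
        # pivoted QR localizes which columns are redundant
        from scipy.linalg import qr

        _, _, pivots = qr(design, pivoting=True, mode="economic")
        redundant = [
            gene_symbols[j - 1] for j in pivots[rank:] if j >= 1
        ]  # column 0 is the intercept
        raise SingularDesignError(
            "design matrix is rank-deficient; collinear gene(s): "
            + (", ".join(sorted(redundant)) or "<intercept>")
        )
    coef = vt.T @ ((u.T @ loads) / s)
    return coef


def fit_least_squares(
    counts: np.ndarray,
    loads: np.ndarray,
    gene_symbols: Sequence[str] | None = None,
    name: str = "fitted",
) -> tuple[EstimationModel, FitDiagnostics]:
    """Fit weights and intercept by ordinary least squares.

    ``counts`` is the (n_genes, n_patients) candidate-gene count block and
    ``loads`` the per-patient actual mutation loads. Requires more patients
    than parameters and a full-rank design; duplicated (collinear) gene rows
    raise :class:`SingularDesignError` naming them.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    loads = np.asarray(loads, dtype=float)
    if counts.size == 0:
        counts = counts.reshape(0, loads.size)
    n_genes, n_patients = counts.shape
    if loads.shape != (n_patients,):
        raise ValueError("loads must align with the count matrix columns")
    k = n_genes + 1
    if n_patients <= k:
        raise ValueError(
            f"need more patients ({n_patients}) than parameters ({k}) to fit"
        )
    if gene_symbols is None:
        gene_symbols = [f"G{i}" for i in range(n_genes)]
    design = np.column_stack([np.ones(n_patients), counts.T])
    coef = _solve(design, loads, list(gene_symbols))
    fitted = design @ coef
    residuals = loads - fitted
    rss = float(residuals @ residuals)
    tss = float(((loads - loads.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bic = bic_score(rss, n_patients, k)
    model = EstimationModel(
        gene_symbols=tuple(gene_symbols),
        weights=tuple(coef[1:]),
        intercept=float(coef[0]),
        name=name,
    )
    diagnostics = FitDiagnostics(
        rss=rss, residuals=residuals, n_obs=n_patients, k_params=k,
        bic=bic, r2_train=r2,
    )
    return model, diagnostics


def _fit_subset(matrix: MutationMatrix, genes: Sequence[str], loads: np.ndarray):
    counts = matrix.gene_counts(genes)
    return fit_least_squares(counts, loads, gene_symbols=genes)


def search_best_model(
    matrix: MutationMatrix,
    candidates: Sequence[str],
    config: SearchConfig = SearchConfig(),
) -> tuple[EstimationModel, FitDiagnostics]:
    """Select the candidate-gene subset minimizing BIC.

    With no candidates the intercept-only model (mean load) is returned.
    Singular subsets encountered during the search are skipped.
    """
    loads = matrix.loads().astype(float)
    candidates = sorted(set(candidates))
    if config.strategy == "exhaustive":
        if len(candidates) > config.exhaustive_limit:
            raise ValueError(
                f"exhaustive search refused for {len(candidates)} candidates "
                f"(limit {config.exhaustive_limit}); use the forward strategy"
            )
        return _exhaustive_search(matrix, candidates, loads, config)
    return _forward_search(matrix, candidates, loads, config)


def _intercept_only(matrix: MutationMatrix, loads: np.ndarray):
    n = matrix.n_patients
    residuals = loads - loads.mean()
    rss = float(residuals @ residuals)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bic = bic_score(rss, n, 1) if n > 1 else float("nan")
    model = EstimationModel(
        gene_symbols=(), weights=(), intercept=float(loads.mean()),
        name="intercept_only",
    )
    tss = rss
    diag = FitDiagnostics(
        rss=rss, residuals=residuals, n_obs=n, k_params=1, bic=bic,
        r2_train=0.0 if tss > 0 else float("nan"),
    )
    return model, diag


def _forward_search(matrix, candidates, loads, config):
    best_model, best_diag = _intercept_only(matrix, loads)
    selected: list[str] = []
    remaining = list(candidates)
    max_genes = config.max_genes or len(candidates)
    while remaining and len(selected) < max_genes:
        step_best = None  # (bic, gene, model, diag)
        for gene in remaining:  # remaining stays sorted => lexicographic ties
            trial = selected + [gene]
            if matrix.n_patients <= len(trial) + 1:
                continue
            try:
                model, diag = _fit_subset(matrix, sorted(trial), loads)
            except SingularDesignError:
                continue
            if step_best is None or diag.bic < step_best[0] - 1e-12:
                step_best = (diag.bic, gene, model, diag)
        if step_best is None or step_best[0] >= best_diag.bic - 1e-12:
            break
        _, gene, best_model, best_diag = step_best
        selected.append(gene)
        remaining.remove(gene)
    return best_model, best_diag


def _exhaustive_search(matrix, candidates, loads, config):
    best = _intercept_only(matrix, loads) if not candidates else None
    max_genes = config.max_genes or len(candidates)
    for size in range(1, min(max_genes, len(candidates)) + 1):
        for subset in combinations(candidates, size):
            if matrix.n_patients <= size + 1:
                continue
            try:
                model, diag = _fit_subset(matrix, list(subset), loads)
            except SingularDesignError:
                continue
            if best is None or diag.bic < best[1].bic - 1e-12:
                best = (model, diag)
    if best is None:
        best = _intercept_only(matrix, loads)
    return best


def predict_load(
    model: EstimationModel, matrix: MutationMatrix, clamp: bool = False
) -> np.ndarray:
    """Estimated mutation load per patient: c + sum_i a_i * x_mi.

    Model genes absent from the matrix contribute zero counts (warned).
    Predictions may be negative; ``clamp=True`` floors them at zero.
    """
    counts = matrix.gene_counts(model.gene_symbols)
    estimates = model.predict(counts)
    if clamp:
        estimates = np.maximum(estimates, 0.0)
    return estimates


def available_models() -> tuple[str, ...]:
    return PUBLISHED_MODELS


def published_model(name: str) -> EstimationModel:
    """Load a published panel model by name (``luad24`` or ``melanoma22``)."""
    if name not in PUBLISHED_MODELS:
        raise KeyError(
            f"unknown published model {name!r}; available: "
            + ", ".join(PUBLISHED_MODELS)
        )
    payload = json.loads(
        resources.files("mutload.models").joinpath(f"{name}.json").read_text()
    )
    return EstimationModel.from_dict(payload)
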
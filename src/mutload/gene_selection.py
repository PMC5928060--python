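"""Candidate gene selection for mutation-load estimation panels.

A gene is a useful panel member if it is mutated often enough to carry
signal (mutation frequency), cheap enough to sequence (CDS length of the
longest transcript), and informative about total burden (patients mutated in
the gene carry significantly higher loads than wild-type patients, by a
Bonferroni-corrected two-sided Wilcoxon rank-sum test). Genes passing all
three filters are the candidates handed to the model search.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .maf_io import MutationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAnnotation",
    "CandidateGeneReport",
    "UndefinedTestError",
    "read_annotations",
    "write_annotations",
    "mutation_frequency",
    "wilcoxon_rank_sum",
    "load_association_scan",
    "bonferroni",
    "select_candidates",
    "reports_to_frame",
]

#: Default selection thresholds: frequency >= 10% (inclusive), CDS length
#: <= 15,000 nt (inclusive), Bonferroni-corrected p < 0.05 (strict).
DEFAULT_FREQ_MIN = 0.10
DEFAULT_CDS_MAX = 15_000
DEFAULT_ALPHA = 0.05

#: Both groups at or below this size use exact permutation enumeration.
EXACT_LIMIT = 8


class UndefinedTestError(ValueError):
    """The rank-sum test is undefined (an empty comparison group)."""


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene symbol with the CDS length (nt) of its longest transcript."""

    gene_symbol: str
    cds_length: int

    def __post_init__(self) -> None:
        if self.cds_length <= 0:
            raise ValueError("cds_length must be positive")


@dataclass(frozen=True)
class CandidateGeneReport:
    """Audit record of the three selection criteria for one gene.

    ``p_raw``/``p_adjusted`` are NaN when the association test is undefined
    (gene mutated in all or no patients); an undefined test fails the
    association criterion.
    """

    gene_symbol: str
    mutation_frequency: float
    cds_length: int | None
    p_raw: float
    p_adjusted: float
    passed_frequency: bool
    passed_cds: bool
    passed_association: bool

    @property
    def is_candidate(self) -> bool:
        return self.passed_frequency and self.passed_cds and self.passed_association


def read_annotations(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV (gene_symbol, cds_length), BioMart-export shape."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene_symbol, cds_length)")
    symbols = frame.iloc[:, 0].astype(str).str.strip().str.upper()
    lengths = frame.iloc[:, 1].astype(int)
    return dict(zip(symbols, lengths))


def write_annotations(annotations: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"gene_symbol": list(annotations), "cds_length": list(annotations.values())}
    ).to_csv(path, sep="\t", index=False)


def mutation_frequency(matrix: MutationMatrix) -> pd.Series:
    """Fraction of patients with at least one mutation, per gene."""
    if matrix.n_patients == 0:
        raise ValueError("mutation frequency undefined for a matrix with no patients")
    freq = (matrix.counts > 0).mean(axis=1)
    return pd.Series(freq, index=matrix.genes, name="mutation_frequency")


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration over C(n, n_a) labelings.

    Midranks handle ties; the two-sided p is the probability, under uniform
    relabeling, of a rank sum at least as far from its null mean as observed.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n, n_a = len(pooled), len(a)
    observed = ranks[:n_a].sum()
    mean = n_a * (n + 1) / 2.0
    obs_dev = abs(observed - mean)
    hits = 0
    total = 0
    for idx in combinations(range(n), n_a):
        total += 1
        if abs(ranks[list(idx)].sum() - mean) >= obs_dev - 1e-12:
            hits += 1
    return hits / total


def wilcoxon_rank_sum(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact_limit: int = EXACT_LIMIT,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of ``group_a``.
    When both groups have at most ``exact_limit`` observations the p-value is
    computed by exact enumeration of all labelings (valid under ties);
    otherwise the tie-corrected normal approximation is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise UndefinedTestError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_stat = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    if a.size <= exact_limit and b.size <= exact_limit:
        p = _exact_rank_sum_p(a, b)
    else:
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(u_stat), float(min(p, 1.0))


def load_association_scan(matrix: MutationMatrix) -> pd.Series:
    """Per-gene two-sided rank-sum p comparing total mutation loads of the
    mutated group (count > 0) against the wild-type group (count == 0).

    Genes with a degenerate split (everyone mutated, or no one) get NaN.
    """
    loads = matrix.loads().astype(float)
    p_values = np.full(matrix.n_genes, np.nan)
    for i in range(matrix.n_genes):
        mutated = matrix.counts[i] > 0
        if not mutated.any() or mutated.all():
            continue
        if np.ptp(loads) == 0:
            p_values[i] = 1.0
            continue
        _, p_values[i] = wilcoxon_rank_sum(loads[mutated], loads[~mutated])
    return pd.Series(p_values, index=matrix.genes, name="p_raw")


def bonferroni(p_raw: float, family_size: int) -> float:
    """Bonferroni-adjusted p: min(1, family_size * p_raw)."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if math.isnan(p_raw):
        return float("nan")
    return min(1.0, family_size * p_raw)


def select_candidates(
    matrix: MutationMatrix,
    annotations: Mapping[str, int] | Sequence[GeneAnnotation],
    freq_min: float = DEFAULT_FREQ_MIN,
    cds_max: int = DEFAULT_CDS_MAX,
    alpha: float = DEFAULT_ALPHA,
    family_size: int | None = None,
) -> list[CandidateGeneReport]:
    """Evaluate all three selection criteria for every gene in the matrix.

    Criteria (all reported independently, never short-circuited):
    mutation frequency >= ``freq_min``; CDS length <= ``cds_max``
    (genes missing from the annotation table fail this criterion, with a
    warning); Bonferroni-corrected rank-sum p < ``alpha``. The Bonferroni
    family size defaults to the number of genes with a well-defined test.
    """
    if isinstance(annotations, Mapping):
        cds = {str(k).strip().upper(): int(v) for k, v in annotations.items()}
    else:
        cds = {a.gene_symbol.strip().upper(): a.cds_length for a in annotations}
    freq = mutation_frequency(matrix)
    p_raw = load_association_scan(matrix)
    if family_size is None:
        family_size = max(1, int(p_raw.notna().sum()))
    missing = [g for g in matrix.genes if g not in cds]
    if missing:
        logger.warning(
            "%d gene(s) missing from the annotation table fail the CDS "
            "criterion: %s", len(missing),
            ", ".join(missing[:10]) + ("..." if len(missing) > 10 else ""),
        )
    reports = []
    for gene in matrix.genes:
        p = float(p_raw[gene])
        p_adj = bonferroni(p, family_size)
        length = cds.get(gene)
        reports.append(
            CandidateGeneReport(
                gene_symbol=gene,
                mutation_frequency=float(freq[gene]),
                cds_length=length,
                p_raw=p,
                p_adjusted=p_adj,
                passed_frequency=bool(freq[gene] >= freq_min),
                passed_cds=length is not None and length <= cds_max,
                passed_association=bool(not math.isnan(p_adj) and p_adj < alpha),
            )
        )
    return reports


def reports_to_frame(reports: Sequence[CandidateGeneReport]) -> pd.DataFrame:
    """Flatten candidate reports into a DataFrame (TSV-ready)."""
    return pd.DataFrame(
        {
            "gene_symbol": [r.gene_symbol for r in reports],
            "mutation_frequency": [r.mutation_frequency for r in reports],
            "cds_length": [r.cds_length for r in reports],
            "p_raw": [r.p_raw for r in reports],
            "p_adjusted": [r.p_adjusted for r in reports],
            "passed_frequency": [r.passed_frequency for r in reports],
            "passed_cds": [r.passed_cds for r in reports],
            "passed_association": [r.passed_association for r in reports],
            "is_candidate": [r.is_candidate for r in reports],
        }
    )
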
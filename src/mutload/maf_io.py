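"""Reading MAF-style somatic mutation tables and building mutation matrices.

Tumor mutational burden (mutation load) here means the total number of
nonsynonymous point mutations in a tumor: missense, nonsense and nonstop
substitutions of one, two or three consecutive nucleotides (SNP/DNP/TNP),
counted as 1, 2 and 3 mutations respectively. This module reads somatic
variant calls in Mutation Annotation Format (MAF)-style TSV, filters them to
nonsynonymous point mutations, and aggregates them into a genes-by-patients
count matrix whose column sums are the per-patient mutation loads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantType",
    "VariantRecord",
    "MafDialect",
    "MutationMatrix",
    "MafFormatError",
    "ExcludedVariantTypeError",
    "NONSYNONYMOUS_CLASSES",
    "POINT_MUTATION_WEIGHTS",
    "read_maf",
    "filter_nonsynonymous",
    "variant_weight",
    "build_mutation_matrix",
    "mutation_load",
]


class MafFormatError(ValueError):
    """The input file does not conform to the expected MAF-style layout."""


class ExcludedVariantTypeError(ValueError):
    """Variant type is not a point mutation (SNP/DNP/TNP) and carries no count."""


class VariantType(str, Enum):
    SNP = "SNP"
    DNP = "DNP"
    TNP = "TNP"
    INS = "INS"
    DEL = "DEL"
    ONP = "ONP"
    OTHER = "OTHER"

    @classmethod
    def parse(cls, token: "str | VariantType") -> "VariantType":
        if isinstance(token, cls):
            return token
        token = str(token).strip().upper()
        try:
            return cls(token)
        except ValueError:
            return cls.OTHER


#: Variant_Classification tokens counted as nonsynonymous point mutations,
#: normalized to lowercase. TCGA MAF spelling; matching is case-insensitive.
NONSYNONYMOUS_CLASSES = frozenset(
    {"missense_mutation", "nonsense_mutation", "nonstop_mutation"}
)

#: Mutation count contributed by each point-mutation type: substitutions of
#: one, two or three consecutive nucleotides.
POINT_MUTATION_WEIGHTS: Mapping[VariantType, int] = {
    VariantType.SNP: 1,
    VariantType.DNP: 2,
    VariantType.TNP: 3,
}


@dataclass(frozen=True)
class VariantRecord:
    """One somatic mutation call.

    ``variant_classification`` is stored as the normalized lowercase token
    (e.g. ``"missense_mutation"``); ``patient_id`` is derived from the sample
    barcode by the active :class:`MafDialect`.
    """

    gene_symbol: str
    variant_classification: str
    variant_type: VariantType
    sample_barcode: str
    patient_id: str

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty after normalization")


@dataclass(frozen=True)
class MafDialect:
    """Column naming and barcode conventions of a MAF-style file.

    ``barcode_prefix`` gives the number of leading barcode characters that
    identify the patient (12 for TCGA barcodes such as
    ``TCGA-05-4244-01A-01D-1105-08``); ``None`` uses the barcode verbatim, so
    the patient-id rule is total for every barcode.
    """

    name: str = "generic"
    gene_column: str = "Hugo_Symbol"
    classification_column: str = "Variant_Classification"
    type_column: str = "Variant_Type"
    barcode_column: str = "Tumor_Sample_Barcode"
    barcode_prefix: int | None = None

    def patient_id(self, barcode: str) -> str:
        barcode = str(barcode).strip()
        if self.barcode_prefix is None:
            return barcode
        return barcode[: self.barcode_prefix]

    @property
    def required_columns(self) -> tuple[str, str, str, str]:
        return (
            self.gene_column,
            self.classification_column,
            self.type_column,
            self.barcode_column,
        )


GENERIC_DIALECT = MafDialect(name="generic")
TCGA_DIALECT = MafDialect(name="tcga", barcode_prefix=12)


def _normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


def read_maf(
    path: str | Path, dialect: MafDialect = GENERIC_DIALECT
) -> list[VariantRecord]:
    """Read a MAF-style TSV into variant records.

    Lines starting with ``#`` are treated as comments. The header must contain
    the four required columns under the dialect's naming; a missing column
    raises :class:`MafFormatError` naming it, as does an empty data section.
    """
    path = Path(path)
    table = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    missing = [c for c in dialect.required_columns if c not in table.columns]
    if missing:
        raise MafFormatError(
            f"{path}: missing required MAF column(s): {', '.join(missing)}"
        )
    if len(table) == 0:
        raise MafFormatError(f"{path}: no data rows")
    records = []
    for row in table.itertuples(index=False):
        barcode = str(getattr(row, dialect.barcode_column)).strip()
        records.append(
            VariantRecord(
                gene_symbol=_normalize_symbol(getattr(row, dialect.gene_column)),
                variant_classification=str(
                    getattr(row, dialect.classification_column)
                ).strip().lower(),
                variant_type=VariantType.parse(getattr(row, dialect.type_column)),
                sample_barcode=barcode,
                patient_id=dialect.patient_id(barcode),
            )
        )
    return records


def filter_nonsynonymous(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Keep only missense, nonsense and nonstop calls, preserving order.

    Classification tokens outside the known nonsynonymous set are dropped;
    unrecognized tokens are additionally reported at WARNING level so silent
    misspellings do not go unnoticed.
    """
    kept: list[VariantRecord] = []
    unknown: set[str] = set()
    known_excluded = {
        "silent", "splice_site", "intron", "3'utr", "5'utr", "3'flank",
        "5'flank", "igr", "rna", "frame_shift_ins", "frame_shift_del",
        "in_frame_ins", "in_frame_del", "translation_start_site",
        "de_novo_start_inframe", "de_novo_start_outofframe", "targeted_region",
    }
    for record in records:
        if record.variant_classification in NONSYNONYMOUS_CLASSES:
            kept.append(record)
        elif record.variant_classification not in known_excluded:
            unknown.add(record.variant_classification)
    if unknown:
        logger.warning(
            "excluded %d unrecognized Variant_Classification token(s): %s",
            len(unknown), ", ".join(sorted(unknown)),
        )
    return kept


def variant_weight(variant_type: VariantType) -> int:
    """Mutation count for a point mutation: SNP=1, DNP=2, TNP=3.

    Indels and other non-point types raise :class:`ExcludedVariantTypeError`;
    callers skip such records (with a warning) rather than counting them.
    """
    try:
        return POINT_MUTATION_WEIGHTS[VariantType.parse(variant_type)]
    except KeyError:
        raise ExcludedVariantTypeError(
            f"variant type {variant_type!r} is not a point mutation"
        ) from None


@dataclass
class MutationMatrix:
    """Genes-by-patients matrix of nonsynonymous point-mutation counts.

    ``counts[i, j]`` is the number of nonsynonymous point mutations of gene
    ``genes[i]`` in patient ``patients[j]``; column sums are the per-patient
    mutation loads.
    """

    genes: list[str]
    patients: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.patients)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.patients)} patients"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols must be unique")
        if len(set(self.patients)) != len(self.patients):
            raise ValueError("patient ids must be unique")
        if self.counts.size and (
            np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer)
        ):
            raise ValueError("counts must be non-negative integers")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def loads(self) -> np.ndarray:
        """Per-patient mutation load (column sums), aligned to ``patients``."""
        return self.counts.sum(axis=0)

    def gene_counts(self, genes: Sequence[str]) -> np.ndarray:
        """Count rows for ``genes`` (in the given order); absent genes are
        all-zero rows, reported with a warning."""
        index = {g: i for i, g in enumerate(self.genes)}
        out = np.zeros((len(genes), self.n_patients), dtype=self.counts.dtype)
        absent = []
        for k, gene in enumerate(genes):
            i = index.get(gene)
            if i is None:
                absent.append(gene)
            else:
                out[k] = self.counts[i]
        if absent:
            logger.warning(
                "%d gene(s) absent from matrix, counted as zero: %s",
                len(absent), ", ".join(absent),
            )
        return out

    def subset_patients(self, patient_ids: Sequence[str]) -> "MutationMatrix":
        """Column subset in the given order (e.g. a train/validation split)."""
        index = {p: j for j, p in enumerate(self.patients)}
        missing = [p for p in patient_ids if p not in index]
        if missing:
            raise KeyError(f"patient(s) not in matrix: {', '.join(missing)}")
        cols = [index[p] for p in patient_ids]
        return MutationMatrix(
            genes=list(self.genes),
            patients=list(patient_ids),
            counts=self.counts[:, cols].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.patients)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MutationMatrix":
        return cls(
            genes=[str(g) for g in frame.index],
            patients=[str(p) for p in frame.columns],
            counts=frame.to_numpy(dtype=np.int64),
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_symbol")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MutationMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(frame)


def build_mutation_matrix(records: Iterable[VariantRecord]) -> MutationMatrix:
    """Aggregate nonsynonymous-filtered records into a mutation matrix.

    Entry (gene, patient) is the sum of SNP/DNP/TNP weights over that cell's
    records; worked example: 3 SNPs + 2 DNPs + 1 TNP in one gene of one
    patient gives 10. Records with non-point variant types are skipped with a
    warning. Gene and patient axes are sorted lexicographically so the result
    is independent of input order. Multiple samples of one patient collapse
    into a single column (counts summed).
    """
    cells: dict[tuple[str, str], int] = {}
    skipped = 0
    for record in records:
        weight = POINT_MUTATION_WEIGHTS.get(record.variant_type)
        if weight is None:
            skipped += 1
            continue
        key = (record.gene_symbol, record.patient_id)
        cells[key] = cells.get(key, 0) + weight
    if skipped:
        logger.warning(
            "skipped %d record(s) with non-point variant types (INS/DEL/ONP/other)",
            skipped,
        )
    genes = sorted({g for g, _ in cells})
    patients = sorted({p for _, p in cells})
    counts = np.zeros((len(genes), len(patients)), dtype=np.int64)
    gene_index = {g: i for i, g in enumerate(genes)}
    patient_index = {p: j for j, p in enumerate(patients)}
    for (gene, patient), total in cells.items():
        counts[gene_index[gene], patient_index[patient]] = total
    return MutationMatrix(genes=genes, patients=patients, counts=counts)


def mutation_load(matrix: MutationMatrix) -> np.ndarray:
    """Per-patient mutation load: the column sums of the mutation matrix."""
    return matrix.loads()
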
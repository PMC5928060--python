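"""Synthetic somatic-mutation cohorts for exercising the full pipeline.

The generator emulates the statistical shape of an exome-wide somatic
mutation study without any real data: per-patient mutation loads are heavy
tailed (log-normal); each load is allocated across genes by a multinomial
whose propensities scale with CDS length, with a configurable enrichment
for a planted set of "signal" genes; variant types follow an SNV-dominated
SNP/DNP/TNP mixture; immunotherapy response (DCB/NDB) is Bernoulli with a
logistic dependence on log load; survival is exponential with hazard
decreasing in load, under independent exponential censoring.

Loads are allocated event by event so that the per-patient sum of generated
SNP/DNP/TNP weights equals the latent true load exactly, which makes
pipeline invariants sharp. Extra silent and indel rows (which the
nonsynonymous filter must discard) are added on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .estimation import EstimationModel
from .maf_io import VariantRecord, VariantType

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "generate_from_model"]

#: Canonical MAF spellings for the tokens this generator emits.
_CLASS_SPELLING = {
    "missense_mutation": "Missense_Mutation",
    "nonsense_mutation": "Nonsense_Mutation",
    "nonstop_mutation": "Nonstop_Mutation",
    "silent": "Silent",
    "frame_shift_ins": "Frame_Shift_Ins",
    "frame_shift_del": "Frame_Shift_Del",
}


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters of a synthetic cohort.

    Defaults mimic a lung-adenocarcinoma-like cohort at desk scale: median
    true load 150 nonsynonymous mutations with a long right tail
    (log-normal, scale 1.0), 200 genes of which 5 are signal genes whose
    per-nucleotide mutation propensity is enriched 8-fold, and an
    SNP/DNP/TNP mix of 0.95/0.04/0.01. The default enrichment keeps signal
    genes in the recurrently-mutated regime (mutated in roughly a fifth to
    three-quarters of patients) rather than saturating at 100% frequency, where
    the mutated-vs-wild-type association split would be degenerate.

    ``n_background_genes`` emulates the exome remainder: a large pool of
    genes that soak up most of each patient's load but are individually
    rarely mutated (their per-nucleotide propensity is scaled down by
    ``background_factor``), the way most of the ~20,000 genes in a real
    exome-wide mutation matrix are hit in only a few percent of patients.
    Without it every modeled gene would be mutated in most patients and a
    randomly drawn gene panel would estimate load almost as well as a
    selected one.
    """

    n_patients: int = 300
    n_genes: int = 200
    n_signal_genes: int = 5
    n_background_genes: int = 3000
    background_factor: float = 0.1
    load_location: float = math.log(150.0)
    load_scale: float = 1.0
    signal_enrichment: float = 8.0
    variant_type_mix: tuple[float, float, float] = (0.95, 0.04, 0.01)
    classification_mix: tuple[float, float, float] = (0.85, 0.13, 0.02)
    noise_cds_range: tuple[int, int] = (300, 30_000)
    signal_cds_range: tuple[int, int] = (1_000, 8_000)
    nonkept_fraction: float = 0.3
    response_slope: float = 2.0
    survival_scale: float = 12.0
    survival_beta: float = 1.0
    censoring_fraction: float = 0.3
    patient_prefix: str = "P"
    seed: int = 0

    def __post_init__(self) -> None:
        for mix, name in (
            (self.variant_type_mix, "variant_type_mix"),
            (self.classification_mix, "classification_mix"),
        ):
            if any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        if self.n_patients <= 0 or self.n_genes <= 0:
            raise ValueError("n_patients and n_genes must be positive")
        if not 0 <= self.n_signal_genes <= self.n_genes:
            raise ValueError("n_signal_genes must lie in [0, n_genes]")
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must lie in [0, 1)")


@dataclass
class SyntheticCohort:
    """A generated cohort with its ground truth.

    ``clinical`` has columns patient_id, true_load, response, time, event;
    ``truth`` records the planted signal genes and generating parameters.
    """

    maf_records: list[VariantRecord]
    clinical: pd.DataFrame
    annotations: dict[str, int]
    truth: dict

    def write_maf(self, path: str | Path) -> None:
        rows = [
            {
                "Hugo_Symbol": r.gene_symbol,
                "Variant_Classification": _CLASS_SPELLING.get(
                    r.variant_classification, r.variant_classification
                ),
                "Variant_Type": r.variant_type.value,
                "Tumor_Sample_Barcode": r.sample_barcode,
            }
            for r in self.maf_records
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def write_annotations(self, path: str | Path) -> None:
        from .gene_selection import write_annotations

        write_annotations(self.annotations, path)

    def write_clinical(self, path: str | Path) -> None:
        self.clinical.to_csv(path, sep="\t", index=False)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"SYNG{i:0{width}d}" for i in range(1, n + 1)]


def _draw_events(rng: np.random.Generator, load: int, mix) -> list[int]:
    """Decompose an integer load into SNP/DNP/TNP weights summing to it."""
    weights = []
    remaining = load
    while remaining > 0:
        w = int(rng.choice((1, 2, 3), p=mix))
        if w > remaining:
            w = 1
        weights.append(w)
        remaining -= w
    return weights


def _response_and_survival(
    rng: np.random.Generator, loads: np.ndarray, config: CohortConfig
) -> pd.DataFrame:
    log_dev = np.log(np.maximum(loads, 1.0)) - config.load_location
    p_dcb = 1.0 / (1.0 + np.exp(-config.response_slope * log_dev))
    response = np.where(rng.random(len(loads)) < p_dcb, "DCB", "NDB")
    # hazard decreases with load: scale grows as exp(beta * log deviation)
    scales = config.survival_scale * np.exp(config.survival_beta * log_dev)
    event_times = rng.exponential(scales)
    if config.censoring_fraction > 0:
        f = config.censoring_fraction
        censor_times = rng.exponential(scales * (1 - f) / f)
        times = np.minimum(event_times, censor_times)
        events = event_times <= censor_times
    else:
        times, events = event_times, np.ones(len(loads), dtype=bool)
    return pd.DataFrame({"time": times, "event": events.astype(int), "p_dcb": p_dcb,
                         "response": response})


def generate_cohort(config: CohortConfig = CohortConfig()) -> SyntheticCohort:
    """Generate a full synthetic cohort, reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    modeled = _gene_names(config.n_genes)
    width = max(4, len(str(config.n_background_genes)))
    background = [f"BKGD{i:0{width}d}" for i in range(1, config.n_background_genes + 1)]
    genes = modeled + background
    signal_genes = sorted(
        str(g) for g in rng.choice(modeled, size=config.n_signal_genes, replace=False)
    )
    signal_set = set(signal_genes)

    cds = {}
    for gene in genes:
        lo, hi = (
            config.signal_cds_range if gene in signal_set else config.noise_cds_range
        )
        cds[gene] = int(rng.integers(lo, hi + 1))

    def _factor(gene: str) -> float:
        if gene in signal_set:
            return config.signal_enrichment
        if gene.startswith("BKGD"):
            return config.background_factor
        return 1.0

    propensity = np.array([cds[g] * _factor(g) for g in genes], dtype=float)
    propensity /= propensity.sum()

    loads = np.maximum(
        1,
        np.round(
            rng.lognormal(config.load_location, config.load_scale, config.n_patients)
        ).astype(int),
    )

    width = max(4, len(str(config.n_patients)))
    patient_ids = [
        f"{config.patient_prefix}{i:0{width}d}" for i in range(1, config.n_patients + 1)
    ]

    class_tokens = ("missense_mutation", "nonsense_mutation", "nonstop_mutation")
    type_by_weight = {1: VariantType.SNP, 2: VariantType.DNP, 3: VariantType.TNP}
    nonkept_pool = (
        ("silent", VariantType.SNP),
        ("frame_shift_ins", VariantType.INS),
        ("frame_shift_del", VariantType.DEL),
    )

    records: list[VariantRecord] = []
    for patient, load in zip(patient_ids, loads):
        weights = _draw_events(rng, int(load), config.variant_type_mix)
        gene_idx = rng.choice(len(genes), size=len(weights), p=propensity)
        classes = rng.choice(3, size=len(weights), p=config.classification_mix)
        for w, gi, ci in zip(weights, gene_idx, classes):
            records.append(
                VariantRecord(
                    gene_symbol=genes[gi],
                    variant_classification=class_tokens[ci],
                    variant_type=type_by_weight[w],
                    sample_barcode=patient,
                    patient_id=patient,
                )
            )
        n_extra = rng.poisson(config.nonkept_fraction * len(weights))
        extra_genes = rng.choice(len(genes), size=n_extra, p=propensity)
        extra_kind = rng.choice(len(nonkept_pool), size=n_extra)
        for gi, ki in zip(extra_genes, extra_kind):
            token, vtype = nonkept_pool[ki]
            records.append(
                VariantRecord(
                    gene_symbol=genes[gi],
                    variant_classification=token,
                    variant_type=vtype,
                    sample_barcode=patient,
                    patient_id=patient,
                )
            )

    outcome = _response_and_survival(rng, loads.astype(float), config)
    clinical = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "true_load": loads,
            "response": outcome["response"],
            "time": outcome["time"],
            "event": outcome["event"],
        }
    )
    return SyntheticCohort(
        maf_records=records,
        clinical=clinical,
        annotations=cds,
        truth={
            "signal_genes": list(signal_genes),
            "config": config,
            "p_dcb": outcome["p_dcb"].to_numpy(),
        },
    )


def generate_from_model(
    model: EstimationModel,
    noise_sd: float,
    config: CohortConfig = CohortConfig(),
) -> SyntheticCohort:
    """Generate a cohort whose true loads follow a given linear model.

    Model-gene counts are independent Poisson draws (per-gene rates spread
    over [0.1, 0.6] so every model gene varies in the cohort); the true load
    is intercept + sum(weight * count) + Gaussian(0, noise_sd), recorded
    exactly in ``clinical.true_load``. Counts are emitted as SNP missense
    rows; filler SNPs in dedicated filler genes bring each patient's column
    sum to the rounded true load when the gap is non-negative.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(config.seed)
    model_genes = list(model.gene_symbols)
    rates = rng.uniform(0.1, 0.6, size=len(model_genes))
    counts = rng.poisson(rates[:, None], size=(len(model_genes), config.n_patients))
    loads = (
        model.intercept
        + np.asarray(model.weights) @ counts
        + (rng.normal(0.0, noise_sd, config.n_patients) if noise_sd > 0 else 0.0)
    )

    width = max(4, len(str(config.n_patients)))
    patient_ids = [
        f"{config.patient_prefix}{i:0{width}d}" for i in range(1, config.n_patients + 1)
    ]
    filler_genes = [f"FILLER{i:03d}" for i in range(1, 6)]

    records: list[VariantRecord] = []
    for j, patient in enumerate(patient_ids):
        for i, gene in enumerate(model_genes):
            for _ in range(int(counts[i, j])):
                records.append(
                    VariantRecord(
                        gene_symbol=gene,
                        variant_classification="missense_mutation",
                        variant_type=VariantType.SNP,
                        sample_barcode=patient,
                        patient_id=patient,
                    )
                )
        gap = int(round(loads[j])) - int(counts[:, j].sum())
        if gap > 0:
            filler_idx = rng.integers(0, len(filler_genes), size=gap)
            for fi in filler_idx:
                records.append(
                    VariantRecord(
                        gene_symbol=filler_genes[fi],
                        variant_classification="missense_mutation",
                        variant_type=VariantType.SNP,
                        sample_barcode=patient,
                        patient_id=patient,
                    )
                )

    outcome = _response_and_survival(rng, np.maximum(loads, 1.0), config)
    clinical = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "true_load": loads,
            "response": outcome["response"],
            "time": outcome["time"],
            "event": outcome["event"],
        }
    )
    annotations = {g: 3000 for g in model_genes + filler_genes}
    return SyntheticCohort(
        maf_records=records,
        clinical=clinical,
        annotations=annotations,
        truth={
            "model": model,
            "noise_sd": noise_sd,
            "config": config,
            "model_counts": pd.DataFrame(
                counts, index=model_genes, columns=patient_ids
            ),
        },
    )
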
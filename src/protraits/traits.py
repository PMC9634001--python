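"""Per-genome extraction of the 11 life-history-proxy genomic traits.

The traits are: genome size, %GC, gene richness (distinct gene families),
gene duplication level (CDS per family), %TF (fraction of regulatory genes),
the codon-usage-bias index F, a generation-time estimate derived from F,
rRNA operon copy number (annotated or genus-imputed from a curated
reference), and two externally supplied columns (%HGT and prophage counts)
that are ingested, never computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .codons import CodonCounts, background_codon_probs, enc_prime
from .io import GenomeRecord, RrnReference, TraitTable, TRAIT_COLUMNS

logger = logging.getLogger(__name__)

#: generation time above which CUB-based estimates are only qualitative
GENERATION_TIME_RELIABLE_MAX_H = 5.0


@dataclass
class ExtractionConfig:
    """Tunable knobs of the trait extractor.

    ``gt_intercept``/``gt_slope`` are the (a, b) coefficients of the
    log-linear map ``log(d_hours) = a + b * F``; the shipped defaults are
    calibration values in the spirit of published CUB-vs-doubling-time
    regressions, not estimates made by this package, and nothing downstream
    depends on them quantitatively.
    """

    min_codons_per_gene: int = 80
    min_total_codons: int = 100
    min_he_genes: int = 10
    gt_intercept: float = 1.5
    gt_slope: float = -6.0
    rrn_source: str = "imputed"  # imputed | annotated


DEFAULT_CONFIG = ExtractionConfig()


@dataclass
class TraitVector:
    """One genome's trait values plus per-trait provenance."""

    genome_id: str
    values: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)  # computed|imputed|external|missing
    generation_time_unreliable: bool = False

    def as_series(self) -> pd.Series:
        return pd.Series(
            {c: self.values.get(c, float("nan")) for c in TRAIT_COLUMNS},
            name=self.genome_id,
        )


def compute_composition(genome: GenomeRecord) -> tuple[int, float]:
    """Genome size (bp) and %GC over unambiguous bases of all contigs."""
    if not genome.contigs:
        raise ValueError(f"genome {genome.genome_id}: no contigs")
    size = genome.genome_size
    gc = at = 0
    for seq in genome.contigs.values():
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if gc + at == 0:
        return size, float("nan")
    return size, 100.0 * gc / (gc + at)


def gene_family_stats(genome: GenomeRecord) -> tuple[float, float]:
    """(gene richness, gene duplication) = (#families, #CDS / #families)."""
    cds = genome.cds()
    if not cds:
        return float("nan"), float("nan")
    families = {g.family_id for g in cds}
    richness = len(families)
    return float(richness), len(cds) / richness


def tf_fraction(genome: GenomeRecord) -> float:
    """Percent of CDS flagged as transcription factors / regulatory genes."""
    cds = genome.cds()
    if not cds:
        return float("nan")
    return 100.0 * sum(g.is_tf for g in cds) / len(cds)


def cub_F(genome: GenomeRecord, config: ExtractionConfig = DEFAULT_CONFIG) -> float:
    """Codon-usage-bias index F = (ENC'_all - ENC'_HE) / ENC'_all.

    Pools codon counts over all CDS (the background gene set) and over the
    ribosomal-protein CDS (the highly expressed set); the null codon
    distribution is estimated from the all-CDS counts.  Requires at least
    ``config.min_he_genes`` ribosomal-protein CDS with usable sequences.
    """
    all_seqs = [g.coding_sequence for g in genome.cds() if g.coding_sequence]
    he_seqs = [
        g.coding_sequence
        for g in genome.cds()
        if g.coding_sequence and g.is_ribosomal_protein
    ]
    if len(he_seqs) < config.min_he_genes:
        logger.info(
            "genome %s: only %d ribosomal-protein CDS (< %d); F not computed",
            genome.genome_id, len(he_seqs), config.min_he_genes,
        )
        return float("nan")
    all_counts = CodonCounts.from_sequences(all_seqs, min_codons=config.min_codons_per_gene)
    he_counts = CodonCounts.from_sequences(he_seqs, min_codons=config.min_codons_per_gene)
    if all_counts.n_codons == 0 or he_counts.n_codons == 0:
        return float("nan")
    background = background_codon_probs(all_counts)
    enc_all = enc_prime(all_counts, background, min_total_codons=config.min_total_codons)
    enc_he = enc_prime(he_counts, background, min_total_codons=config.min_total_codons)
    if not (np.isfinite(enc_all) and np.isfinite(enc_he)):
        return float("nan")
    return (enc_all - enc_he) / enc_all


def predict_generation_time(
    f_value: float, config: ExtractionConfig = DEFAULT_CONFIG
) -> tuple[float, bool]:
    """Generation time d = exp(a + b*F) in hours, plus an unreliability flag.

    The flag is set when the estimate exceeds 5 h, where CUB-based
    generation-time prediction is known to lose quantitative accuracy.
    """
    if f_value is None or not np.isfinite(f_value):
        return float("nan"), False
    d = math.exp(config.gt_intercept + config.gt_slope * f_value)
    return d, d > GENERATION_TIME_RELIABLE_MAX_H


def rrn_count(genome: GenomeRecord) -> int:
    """Number of annotated 16S rRNA features (other rRNAs are not counted)."""
    n = sum(g.feature_type == "rRNA_16S" for g in genome.genes)
    if n == 0:
        logger.warning(
            "genome %s: no annotated 16S rRNA features (every real genome has >=1)",
            genome.genome_id,
        )
    return n


def impute_rrn(genus: str, ref: RrnReference) -> float:
    """Genus-level rRNA copy number: mean of curated reference values."""
    if not genus:
        raise ValueError("genus must be non-empty")
    return ref.mean(genus)


def extract_traits(
    genome: GenomeRecord,
    ref: RrnReference | None = None,
    config: ExtractionConfig = DEFAULT_CONFIG,
) -> TraitVector:
    """Assemble the full trait vector for one genome.

    Per-trait failures yield missing values, never abort the extraction.
    %HGT and prophage counts are copied from ``genome.external_traits``; the
    rRNA copy number comes from genus imputation by default (annotation-based
    16S counts are notoriously unreliable) unless
    ``config.rrn_source == "annotated"``.
    """
    tv = TraitVector(genome.genome_id)

    def put(name: str, value: float, prov: str) -> None:
        missing = value is None or (isinstance(value, float) and not np.isfinite(value))
        tv.values[name] = float("nan") if missing else float(value)
        tv.provenance[name] = "missing" if missing else prov

    size, gc = compute_composition(genome)
    put("genome_size", size, "computed")
    put("pct_gc", gc, "computed")
    richness, duplication = gene_family_stats(genome)
    put("gene_richness", richness, "computed")
    put("gene_duplication", duplication, "computed")
    put("pct_tf", tf_fraction(genome), "computed")
    f_value = cub_F(genome, config)
    put("cub_f", f_value, "computed")
    gt, unreliable = predict_generation_time(f_value, config)
    put("generation_time", gt, "computed")
    tv.generation_time_unreliable = unreliable

    if config.rrn_source == "annotated":
        put("rrn", float(rrn_count(genome)), "computed")
    else:
        genus = genome.taxonomy.get("genus")
        if genus and ref is not None:
            put("rrn", impute_rrn(genus, ref), "imputed")
        else:
            put("rrn", float("nan"), "missing")

    for name in ("pct_hgt", "prophages"):
        put(name, genome.external_traits.get(name, float("nan")), "external")
    return tv


def extract_trait_table(
    genomes: list[GenomeRecord],
    ref: RrnReference | None = None,
    config: ExtractionConfig = DEFAULT_CONFIG,
) -> TraitTable:
    """Extract traits for a cohort into a genome-level :class:`TraitTable`."""
    rows = [extract_traits(g, ref, config).as_series() for g in genomes]
    df = pd.DataFrame(rows)
    df["habitat"] = [g.habitat_string for g in genomes]
    df.index.name = "id"
    return TraitTable(df, level="genome")
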
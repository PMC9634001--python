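"""Readers and writers for the pipeline's external formats.

Annotated genomes arrive as FASTA (contigs) plus GFF3 (CDS and rRNA features
with ``ID``/``product``/``family`` attributes); trait tables, ANI matrices and
the genus-level rRNA-copy-number reference are tab-separated text with the
literal ``NA`` as the missing-value code.  Coordinates follow the GFF3
convention throughout: 1-based, inclusive on both ends.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: canonical numeric trait columns, in table order
TRAIT_COLUMNS = [
    "genome_size",
    "pct_gc",
    "gene_richness",
    "gene_duplication",
    "pct_tf",
    "cub_f",
    "generation_time",
    "rrn",
    "pct_hgt",
    "prophages",
]

#: the nine traits entering the multivariate covariation analysis
ANALYSIS_TRAITS = [
    "genome_size",
    "pct_tf",
    "gene_duplication",
    "gene_richness",
    "cub_f",
    "rrn",
    "pct_hgt",
    "prophages",
    "pct_gc",
]

DEFAULT_TF_KEYWORDS = (
    "transcriptional regulator",
    "transcription factor",
    "sigma factor",
)
DEFAULT_RIBOSOMAL_REGEX = r"ribosomal protein"


class GenomeFormatError(ValueError):
    """Raised for structurally invalid genome inputs."""


@dataclass
class GeneRecord:
    """One annotated gene feature on a contig (1-based inclusive coords)."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    feature_type: str  # CDS | rRNA_16S | rRNA_other | other
    family_id: str | None = None
    product: str | None = None
    is_tf: bool = False
    is_ribosomal_protein: bool = False
    coding_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise GenomeFormatError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in {"+", "-"}:
            raise GenomeFormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """One annotated genome: contig sequences plus typed gene features."""

    genome_id: str
    contigs: dict[str, str]
    genes: list[GeneRecord] = field(default_factory=list)
    taxonomy: dict[str, str] = field(default_factory=dict)
    habitat_string: str | None = None
    external_traits: dict[str, float] = field(default_factory=dict)

    @property
    def genome_size(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def cds(self) -> list[GeneRecord]:
        return [g for g in self.genes if g.feature_type == "CDS"]

    def validate(self) -> None:
        if self.genome_size <= 0:
            raise GenomeFormatError(f"genome {self.genome_id}: empty contigs")
        for g in self.genes:
            if g.contig_id not in self.contigs:
                raise GenomeFormatError(
                    f"gene {g.gene_id}: unknown contig {g.contig_id!r}"
                )
            if g.end > len(self.contigs[g.contig_id]):
                raise GenomeFormatError(
                    f"gene {g.gene_id}: coordinates exceed contig {g.contig_id}"
                )


@dataclass
class RrnReference:
    """Genus -> observed rRNA operon copy numbers (curated reference data)."""

    copies: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for genus, values in self.copies.items():
            if not values:
                raise ValueError(f"genus {genus}: empty copy-number list")
            for v in values:
                if int(v) != v or v < 1:
                    raise ValueError(
                        f"genus {genus}: copy number {v!r} must be an integer >= 1"
                    )

    def mean(self, genus: str) -> float:
        """Mean copy number for a genus; NaN when the genus is absent."""
        values = self.copies.get(genus)
        return float(np.mean(values)) if values else float("nan")


@dataclass
class TraitTable:
    """Rectangular unit x trait table with missing values and provenance."""

    data: pd.DataFrame
    level: str = "genome"  # genome | species
    transform_state: str = "raw"  # raw | transformed | standardized
    log_shifted: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate row id {dup!r}")

    @property
    def traits(self) -> list[str]:
        return [c for c in TRAIT_COLUMNS if c in self.data.columns]

    def validate(self) -> None:
        """Check the raw-scale column invariants where applicable."""
        if self.transform_state != "raw":
            return
        df = self.data
        checks = {
            "gene_duplication": lambda s: (s >= 1).all(),
            "rrn": lambda s: (s >= 0).all(),
            "cub_f": lambda s: (s < 1).all(),
        }
        for col in df.columns:
            if col.startswith("pct_") and not df[col].dropna().between(0, 100).all():
                raise ValueError(f"column {col}: values outside [0, 100]")
            if col in checks and not checks[col](df[col].dropna()):
                raise ValueError(f"column {col}: invariant violated")

    def copy(self) -> "TraitTable":
        return TraitTable(
            self.data.copy(), self.level, self.transform_state, self.log_shifted
        )


def _first_attr(feat, *keys: str) -> str | None:
    for key in keys:
        vals = feat.attributes.get(key)
        if vals:
            return vals[0]
    return None


def read_genome(
    fasta_path: str | Path,
    gff_path: str | Path,
    *,
    genome_id: str | None = None,
    tf_keywords: Sequence[str] = DEFAULT_TF_KEYWORDS,
    tf_families: Sequence[str] = (),
    ribosomal_regex: str = DEFAULT_RIBOSOMAL_REGEX,
    taxonomy: Mapping[str, str] | None = None,
    habitat_string: str | None = None,
    external_traits: Mapping[str, float] | None = None,
) -> GenomeRecord:
    """Load an annotated genome from FASTA + GFF3 into a :class:`GenomeRecord`.

    CDS and rRNA features are loaded; coding sequences are extracted
    strand-aware (minus-strand genes are reverse-complemented to 5'->3').
    ``is_tf`` is set when the ``product`` contains any of ``tf_keywords``
    (case-insensitive) or the ``regulatory_family`` attribute is listed in
    ``tf_families``; ``is_ribosomal_protein`` by ``ribosomal_regex`` on CDS
    products.  A CDS whose length is not a multiple of 3 is kept with its
    coding sequence withheld (logged); a feature on an unknown contig is a
    hard error naming that contig.
    """
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not contigs:
        raise GenomeFormatError(f"{fasta_path}: no contigs found")
    ribo_re = re.compile(ribosomal_regex, re.IGNORECASE)
    tf_family_set = set(tf_families)

    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneRecord] = []
    for feat in db.all_features():
        if feat.featuretype not in {"CDS", "rRNA"}:
            continue
        if feat.seqid not in contigs:
            raise GenomeFormatError(
                f"feature {feat.id or '?'} references unknown contig {feat.seqid!r}"
            )
        contig = contigs[feat.seqid]
        if feat.end > len(contig) or feat.start < 1:
            raise GenomeFormatError(
                f"feature {feat.id or '?'}: coordinates {feat.start}..{feat.end} "
                f"outside contig {feat.seqid} (length {len(contig)})"
            )
        product = _first_attr(feat, "product")
        gene_id = _first_attr(feat, "ID") or f"{feat.seqid}:{feat.start}-{feat.end}"
        strand = feat.strand if feat.strand in {"+", "-"} else "+"

        if feat.featuretype == "rRNA":
            ftype = "rRNA_16S" if product and "16S" in product else "rRNA_other"
            genes.append(
                GeneRecord(gene_id, feat.seqid, feat.start, feat.end, strand, ftype,
                           product=product)
            )
            continue

        seq = contig[feat.start - 1 : feat.end]
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        if len(seq) % 3 != 0:
            logger.warning(
                "CDS %s length %d not a multiple of 3; coding sequence withheld",
                gene_id, len(seq),
            )
            seq = None
        prod_lc = (product or "").lower()
        reg_family = _first_attr(feat, "regulatory_family")
        family = (
            _first_attr(feat, "family")
            or _first_attr(feat, "ortholog")
            or (prod_lc.strip() or None)
            or f"_singleton_{gene_id}"
        )
        genes.append(
            GeneRecord(
                gene_id, feat.seqid, feat.start, feat.end, strand, "CDS",
                family_id=family,
                product=product,
                is_tf=any(k.lower() in prod_lc for k in tf_keywords)
                or (reg_family in tf_family_set if reg_family else False),
                is_ribosomal_protein=bool(product and ribo_re.search(product)),
                coding_sequence=seq,
            )
        )

    record = GenomeRecord(
        genome_id=genome_id or fasta_path.stem,
        contigs=contigs,
        genes=genes,
        taxonomy=dict(taxonomy or {}),
        habitat_string=habitat_string,
        external_traits=dict(external_traits or {}),
    )
    record.validate()
    return record


def write_genome(genome: GenomeRecord, fasta_path: str | Path, gff_path: str | Path) -> None:
    """Serialize a genome back to FASTA + GFF3 (inverse of :func:`read_genome`)."""
    with open(fasta_path, "w") as fh:
        for cid, seq in genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            ftype = "rRNA" if g.feature_type.startswith("rRNA") else g.feature_type
            attrs = [f"ID={g.gene_id}"]
            if g.product:
                attrs.append(f"product={g.product}")
            if g.family_id and not g.family_id.startswith("_singleton_"):
                attrs.append(f"family={g.family_id}")
            fh.write(
                "\t".join(
                    [g.contig_id, "protraits", ftype, str(g.start), str(g.end),
                     ".", g.strand, "0" if ftype == "CDS" else ".", ";".join(attrs)]
                )
                + "\n"
            )


def read_trait_table(tsv_path: str | Path, *, level: str = "genome") -> TraitTable:
    """Read a TSV trait table; ``NA`` is the only missing-value code."""
    df = pd.read_csv(
        tsv_path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False
    )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{tsv_path}: duplicate row id {dup!r}")
    for col in df.columns:
        if col in TRAIT_COLUMNS:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
                raise ValueError(
                    f"{tsv_path}: non-numeric value in column {col!r}, "
                    f"row {bad.index[0]!r}"
                ) from None
    return TraitTable(df, level=level)


def write_trait_table(table: TraitTable, tsv_path: str | Path) -> None:
    table.data.to_csv(tsv_path, sep="\t", na_rep="NA", index_label="id")


def read_rrn_reference(tsv_path: str | Path) -> RrnReference:
    """Read a two-column (genus, copy_number) TSV into an :class:`RrnReference`."""
    df = pd.read_csv(tsv_path, sep="\t")
    if df.empty:
        return RrnReference({})
    genus_col, copy_col = df.columns[0], df.columns[1]
    copies: dict[str, list[int]] = {}
    for _, row in df.iterrows():
        value = row[copy_col]
        if float(value) != int(float(value)) or int(float(value)) < 1:
            raise ValueError(
                f"{tsv_path}: copy number {value!r} for genus {row[genus_col]!r} "
                "must be an integer >= 1"
            )
        copies.setdefault(str(row[genus_col]), []).append(int(float(value)))
    return RrnReference(copies)


def read_ani_table(tsv_path: str | Path) -> pd.DataFrame:
    """Read a long-format ANI TSV (id_a, id_b, ani) into a symmetric matrix."""
    df = pd.read_csv(tsv_path, sep="\t", names=["id_a", "id_b", "ani"], header=0)
    ids = sorted(set(df["id_a"]) | set(df["id_b"]))
    mat = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    for _, row in df.iterrows():
        mat.loc[row["id_a"], row["id_b"]] = row["ani"]
        mat.loc[row["id_b"], row["id_a"]] = row["ani"]
    np.fill_diagonal(mat.values, 100.0)
    return mat
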
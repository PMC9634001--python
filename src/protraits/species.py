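"""Species delineation, species-level trait aggregation and habitat labels.

Genomes with a species-level taxonomy label share a species unit; the
remainder are clustered by single-linkage connected components of the
average-nucleotide-identity (ANI) graph at >94% identity — the operational
species definition for asexual prokaryotes.  Trait values are then averaged
per species to remove phylogenetic redundancy before any covariation
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomeRecord, TraitTable, TRAIT_COLUMNS

logger = logging.getLogger(__name__)

ANI_SPECIES_THRESHOLD = 94.0

HABITAT_RULES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("soil", ("soil", "rhizosphere")),
    ("aquatic", ("aquatic", "marine", "water")),
    ("digestive_tract", ("oral", "stomach", "gut", "intestinal", "feces")),
)
HABITAT_LABELS = tuple(label for label, _ in HABITAT_RULES) + ("unclassified",)


@dataclass
class SpeciesClustering:
    """Partition of genome ids into species units."""

    members: dict[str, list[str]]  # species_id -> genome ids
    method: dict[str, str] = field(default_factory=dict)  # species_id -> taxonomy|ani

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for sp, ids in self.members.items():
            for gid in ids:
                if gid in seen:
                    raise ValueError(f"genome {gid!r} assigned to multiple species")
                seen.add(gid)

    @property
    def genome_to_species(self) -> dict[str, str]:
        return {gid: sp for sp, ids in self.members.items() for gid in ids}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (gid, sp, self.method.get(sp, ""))
            for sp, ids in self.members.items()
            for gid in ids
        ]
        return pd.DataFrame(rows, columns=["genome_id", "species_id", "method"])


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical (strand-symmetric) k-mer codes of a sequence as uint64."""
    arr = _encode(seq)
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = arr[j : j + n]
        valid &= col >= 0
        fwd = (fwd << np.uint64(2)) | col.astype(np.uint64)
        comp = (3 - col).astype(np.uint64)
        rev |= comp << np.uint64(2 * j)
    canon = np.minimum(fwd[valid], rev[valid])
    return np.unique(canon)


def estimate_ani(
    a: GenomeRecord,
    b: GenomeRecord,
    k: int = 16,
    *,
    sketch_size: int | None = None,
    seed: int = 0,
) -> float:
    """Mash-style ANI estimate from k-mer set Jaccard similarity.

    ANI = 100 * (1 + (1/k) * ln(2J / (1 + J))), clamped to [0, 100].  With
    ``sketch_size`` set, a seeded bottom-s hash sketch replaces the exact
    k-mer sets (deterministic given the seed).  Genomes shorter than 10*k bp
    yield NaN.
    """
    if a.genome_size < 10 * k or b.genome_size < 10 * k:
        return float("nan")
    sets = []
    for genome in (a, b):
        km = np.unique(
            np.concatenate(
                [_canonical_kmers(s, k) for s in genome.contigs.values()]
                or [np.empty(0, dtype=np.uint64)]
            )
        )
        if sketch_size is not None:
            # splitmix64-style seeded mix (uint64 wraparound intended), then
            # keep the bottom sketch_size hashes
            with np.errstate(over="ignore"):
                h = km + np.uint64(0x9E3779B97F4A7C15) * np.uint64(seed * 2 + 1)
                h = (h ^ (h >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
                h = (h ^ (h >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
                h ^= h >> np.uint64(31)
            order = np.argsort(h)
            km = km[order[: min(sketch_size, len(km))]]
        sets.append(set(km.tolist()))
    sa, sb = sets
    if not sa or not sb:
        return float("nan")
    j = len(sa & sb) / len(sa | sb)
    if j == 0:
        return 0.0
    ani = 100.0 * (1.0 + (1.0 / k) * np.log(2.0 * j / (1.0 + j)))
    return float(np.clip(ani, 0.0, 100.0))


def cluster_species(
    genome_ids: list[str],
    taxonomy: dict[str, str | None],
    ani: pd.DataFrame | None = None,
    threshold: float = ANI_SPECIES_THRESHOLD,
) -> SpeciesClustering:
    """Group genomes into species units.

    Genomes with a species-level taxonomy label group by that label; the
    remainder form single-linkage connected components of the graph whose
    edges are ANI > ``threshold``.  Missing ANI values for an unlabeled pair
    are treated as no edge (logged).
    """
    if not 0 < threshold < 100:
        raise ValueError("threshold must be in (0, 100)")
    members: dict[str, list[str]] = {}
    method: dict[str, str] = {}
    unlabeled = []
    for gid in genome_ids:
        label = taxonomy.get(gid)
        if label:
            sp = f"sp_tax:{label}"
            members.setdefault(sp, []).append(gid)
            method[sp] = "taxonomy"
        else:
            unlabeled.append(gid)

    if unlabeled:
        uf = _UnionFind(unlabeled)
        for i, ga in enumerate(unlabeled):
            for gb in unlabeled[i + 1 :]:
                value = np.nan
                if ani is not None and ga in ani.index and gb in ani.columns:
                    value = ani.loc[ga, gb]
                if np.isnan(value):
                    logger.debug("ANI missing for pair (%s, %s); no edge", ga, gb)
                    continue
                if value > threshold:
                    uf.union(ga, gb)
        roots: dict[str, list[str]] = {}
        for gid in unlabeled:
            roots.setdefault(uf.find(gid), []).append(gid)
        for n, (_, ids) in enumerate(sorted(roots.items()), start=1):
            sp = f"sp_ani:{n:05d}"
            members[sp] = ids
            method[sp] = "ani"
    return SpeciesClustering(members, method)


def aggregate_species_traits(
    table: TraitTable, clustering: SpeciesClustering
) -> TraitTable:
    """Mean-aggregate a genome-level trait table to the species level.

    Numeric traits take the arithmetic mean over non-missing member values;
    a habitat column is aggregated by majority label with ties resolved to
    ``unclassified``.
    """
    if table.level != "genome":
        raise ValueError("aggregation expects a genome-level table")
    g2s = clustering.genome_to_species
    missing = [gid for gid in table.data.index if gid not in g2s]
    if missing:
        raise ValueError(f"rows not covered by the clustering: {missing[:5]}")
    df = table.data.copy()
    groups = pd.Series({gid: g2s[gid] for gid in df.index})

    numeric = [c for c in df.columns if c in TRAIT_COLUMNS]
    agg = df[numeric].groupby(groups).mean()

    if "habitat" in df.columns:
        def majority(series: pd.Series) -> str | float:
            counts = series.dropna().value_counts()
            if counts.empty:
                return np.nan
            top = counts[counts == counts.max()]
            return top.index[0] if len(top) == 1 else "unclassified"

        agg["habitat"] = df["habitat"].groupby(groups).agg(majority)
    agg.index.name = "id"
    return TraitTable(agg, level="species", transform_state=table.transform_state,
                      log_shifted=table.log_shifted)


def complete_cases(table: TraitTable, traits: list[str]) -> TraitTable:
    """Rows with no missing value in the listed traits."""
    unknown = [t for t in traits if t not in table.data.columns]
    if unknown:
        raise ValueError(f"traits not in table: {unknown}")
    kept = table.data.dropna(subset=traits)
    logger.info("complete_cases: %d of %d rows retained", len(kept), len(table.data))
    if kept.empty:
        raise ValueError(
            "no complete cases for the requested traits; consider a smaller subset"
        )
    return TraitTable(kept, level=table.level, transform_state=table.transform_state,
                      log_shifted=table.log_shifted)


def classify_habitat(habitat_string: str | None) -> str:
    """Keyword-based habitat label from free-text metadata.

    Case-insensitive substring groups are tested in a fixed order (soil,
    aquatic, digestive tract); the first matching group wins, no match means
    ``unclassified``.  Total and idempotent.
    """
    if not habitat_string:
        return "unclassified"
    text = habitat_string.lower()
    if text in HABITAT_LABELS:
        return text  # already a label
    for label, keywords in HABITAT_RULES:
        if any(kw in text for kw in keywords):
            return label
    return "unclassified"
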
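"""Seeded generators for every input the pipeline consumes.

Three layers of realism are emulated here:

* random phylogenies (Yule or coalescent-like) and multivariate
  Brownian-motion tip traits with a per-trait lambda transform;
* species-level trait tables with the bimodal genome-size structure seen
  across habitats (an aquatic-like ~3 Mbp component and a soil-like
  ~6.5 Mbp component) and a piecewise size-vs-codon-usage-bias regime whose
  correlation flips sign between the two components;
* toy annotated genomes (FASTA + GFF3) whose extracted traits hit
  prescribed targets, including a tunable codon-usage-bias parameter theta
  for the ribosomal-protein gene set.

Every generator is a pure function of its arguments plus a seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .codons import SENSE_CODONS, STOP_CODONS, SYNONYMOUS_FAMILIES
from .io import GeneRecord, GenomeRecord, TraitTable, write_genome
from .phylo import Phylogeny


def sim_tree(n: int, model: str = "yule", seed: int = 0) -> Phylogeny:
    """Random rooted binary tree with ``n`` tips and positive branch lengths."""
    if n < 2:
        raise ValueError("need at least 2 tips")
    rng = random.Random(seed)
    if model == "yule":
        tree = treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n, rng=rng
        )
        # the simulator stops exactly at the n-th speciation, leaving two
        # zero-length terminal branches (and a singular covariance); extend
        # all tips by the waiting time to the next event
        tail = rng.expovariate(n * 1.0)
        for leaf in tree.leaf_node_iter():
            leaf.edge.length = (leaf.edge.length or 0.0) + tail
    elif model == "coalescent":
        taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n)])
        tree = treesim.pure_kingman_tree(taxon_namespace=taxa, pop_size=1.0, rng=rng)
    else:
        raise ValueError(f"unknown tree model {model!r}")
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        if leaf.taxon is None:
            leaf.taxon = tree.taxon_namespace.new_taxon(label=f"t{i}")
        leaf.taxon.label = f"t{i}"
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return Phylogeny(tree)


def sim_bm_traits(
    phylo: Phylogeny,
    sigma: np.ndarray,
    lam: float | np.ndarray = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Multivariate Brownian tip traits with a per-trait lambda transform.

    Trait t's among-tip covariance is ``V(lam_t)`` (off-diagonal of the
    phylogenetic covariance scaled by lambda); across traits the innovations
    follow ``sigma``.  With a common lambda the tip x trait covariance is
    exactly ``V(lam) (x) sigma``; with per-trait lambdas the cross-trait
    structure is an approximation formed through per-trait Cholesky factors
    applied to sigma-correlated innovations.
    """
    V, _, labels = phylo.vcv()
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    p = sigma.shape[0]
    lam_vec = np.broadcast_to(np.asarray(lam, dtype=float), (p,))
    if np.any((lam_vec < 0) | (lam_vec > 1)):
        raise ValueError("lambda must be in [0, 1]")
    try:
        L_sigma = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as err:
        raise ValueError("sigma must be positive definite") from err
    rng = np.random.default_rng(seed)
    n = len(labels)
    Z = rng.standard_normal((n, p)) @ L_sigma.T
    X = np.empty((n, p))
    diag = np.diag(np.diag(V))
    for t in range(p):
        W = lam_vec[t] * V + (1.0 - lam_vec[t]) * diag
        X[:, t] = np.linalg.cholesky(W) @ Z[:, t]
    return pd.DataFrame(X, index=labels, columns=[f"trait{i + 1}" for i in range(p)])


@dataclass
class TraitRegime:
    """Two-component genome-size mixture with component-specific
    size-vs-CUB correlation signs and habitat preferences."""

    weights: tuple[float, float] = (0.5, 0.5)
    size_log_mean: tuple[float, float] = (np.log(3.0e6), np.log(6.5e6))
    size_log_sd: tuple[float, float] = (0.25, 0.18)
    size_cub_rho: tuple[float, float] = (0.5, -0.5)
    habitat_probs: tuple[dict[str, float], ...] = (
        {"aquatic": 0.55, "soil": 0.10, "digestive_tract": 0.15, "unclassified": 0.20},
        {"soil": 0.55, "aquatic": 0.10, "digestive_tract": 0.15, "unclassified": 0.20},
    )
    noise_sd: float = 0.6

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        for rho in self.size_cub_rho:
            if not -1.0 < rho < 1.0:
                raise ValueError("correlation magnitudes must be in (-1, 1)")


_HABITAT_STRINGS = {
    "aquatic": "marine water column",
    "soil": "agricultural soil",
    "digestive_tract": "human gut",
    "unclassified": "laboratory isolate",
}


def sim_trait_table(
    regime: TraitRegime,
    n: int,
    seed: int = 0,
    missing_rate: float = 0.0,
    missing_traits: tuple[str, ...] = ("rrn",),
) -> tuple[TraitTable, pd.DataFrame]:
    """Species-level trait table with planted regime structure.

    Within each mixture component the (genome size, CUB) correlation equals
    the regime's sign/magnitude in expectation; gene duplication, gene
    richness and %TF co-increase with genome size; RRN tracks CUB; the
    remaining traits carry the loose qualitative structure of real data.
    Returns the table plus a truth frame with the planted component and
    habitat of every species.
    """
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(regime.weights), size=n, p=np.asarray(regime.weights))
    z_size = rng.standard_normal(n)
    mu = np.asarray(regime.size_log_mean)[comp]
    sd = np.asarray(regime.size_log_sd)[comp]
    size = np.exp(mu + sd * z_size)

    rho = np.asarray(regime.size_cub_rho)[comp]
    z_f = rho * z_size + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    cub = np.clip(0.18 + 0.07 * z_f, 0.001, 0.8)

    size_m = size / 1e6
    dup = np.maximum(1.0, 1.0 + 0.12 * size_m + 0.05 * rng.standard_normal(n))
    richness = np.maximum(200.0, size * 0.88 / 606.0 / dup
                          * np.exp(0.05 * rng.standard_normal(n)))
    pct_tf = np.clip(0.8 + 0.75 * size_m + 0.35 * rng.standard_normal(n), 0.0, 20.0)
    rrn = np.clip(np.exp(0.5 + 0.75 * z_f + 0.35 * rng.standard_normal(n)), 1.0, 16.0)
    pct_gc = np.clip(45.0 + 2.5 * size_m + 4.0 * rng.standard_normal(n), 20.0, 80.0)
    pct_hgt = np.clip(np.exp(0.8 + regime.noise_sd * rng.standard_normal(n)) - 1.0,
                      0.0, 40.0)
    prophages = rng.poisson(np.clip(1.0 + 1.2 * z_f, 0.05, None))
    generation_time = np.exp(1.6 - 6.0 * cub + 0.25 * rng.standard_normal(n))

    habitats = np.empty(n, dtype=object)
    for c, probs in enumerate(regime.habitat_probs):
        idx = np.flatnonzero(comp == c)
        labels = list(probs)
        habitats[idx] = rng.choice(labels, size=len(idx), p=[probs[k] for k in labels])

    ids = [f"sp{i + 1:05d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "genome_size": size,
            "pct_gc": pct_gc,
            "gene_richness": richness,
            "gene_duplication": dup,
            "pct_tf": pct_tf,
            "cub_f": cub,
            "generation_time": generation_time,
            "rrn": rrn,
            "pct_hgt": pct_hgt,
            "prophages": prophages.astype(float),
            "habitat": [_HABITAT_STRINGS[h] for h in habitats],
        },
        index=pd.Index(ids, name="id"),
    )
    if missing_rate > 0:
        for col in missing_traits:
            mask = rng.random(n) < missing_rate
            df.loc[mask, col] = np.nan
    truth = pd.DataFrame({"component": comp, "habitat": habitats},
                         index=df.index)
    return TraitTable(df, level="species"), truth


@dataclass
class SyntheticGenomeSpec:
    """Targets for one toy genome."""

    genome_size: int = 1_000_000
    pct_gc: float = 50.0
    n_families: int = 500
    duplication: float = 1.0
    pct_tf: float = 5.0
    rrn: int = 3
    theta: float = 0.0
    n_ribosomal: int = 25
    gene_length_codons: int = 200  # body codons, excluding start/stop
    genus: str | None = None
    species: str | None = None
    habitat_string: str | None = None
    external_traits: dict[str, float] = field(default_factory=dict)


_RRNA_LENGTH = 1500


def _positional_codon_probs(gc_fraction: float) -> np.ndarray:
    """Sense-codon probabilities from independent per-position base draws
    with P(G) = P(C) = gc/2, renormalized over the 61 sense codons."""
    base_p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )  # A C G T
    order = "ACGT"
    q = np.array(
        [
            base_p[order.index(c[0])] * base_p[order.index(c[1])] * base_p[order.index(c[2])]
            for c in SENSE_CODONS
        ]
    )
    return q / q.sum()


def _bias_he_probs(q: np.ndarray, theta: float) -> np.ndarray:
    """Sharpen within-family codon probabilities by e^theta on each family's
    preferred codon, keeping the per-family (amino acid) mass unchanged."""
    idx = {c: i for i, c in enumerate(SENSE_CODONS)}
    out = q.copy()
    for codons in SYNONYMOUS_FAMILIES.values():
        ii = [idx[c] for c in codons]
        fam = q[ii]
        total = fam.sum()
        if len(ii) < 2 or total == 0:
            continue
        w = fam.copy()
        w[np.argmax(fam)] *= np.exp(theta)
        out[ii] = total * w / w.sum()
    return out


def _random_bases(rng: np.random.Generator, n: int, gc_fraction: float) -> str:
    base_p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(alphabet, size=n, p=base_p).tobytes().decode("ascii")


_REVCOMP = str.maketrans("ACGT", "TGCA")


def build_synthetic_genome(
    spec: SyntheticGenomeSpec,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> GenomeRecord:
    """Construct a single-contig toy genome hitting the prescribed targets.

    Gene families get copy numbers summing to ``round(duplication *
    n_families)`` (identical copies — the duplication semantics); the first
    ``n_ribosomal`` families are ribosomal-protein genes whose codons are
    drawn from the theta-sharpened distribution; ``rrn`` identical 16S rRNA
    features are inserted; TF products are assigned to hit ``pct_tf`` within
    one gene; intergenic filler brings the contig to ``genome_size`` exactly
    with its GC content solved to meet ``pct_gc``.  When ``out_dir`` is
    given, FASTA and GFF3 files are also written (byte-identical per seed).
    """
    rng = np.random.default_rng(seed)
    n_cds = int(round(spec.duplication * spec.n_families))
    if spec.duplication < 1 or n_cds < spec.n_families:
        raise ValueError("duplication must be >= 1")
    if not 0 <= spec.pct_tf <= 100:
        raise ValueError("pct_tf must be in [0, 100]")
    if spec.n_ribosomal > spec.n_families:
        raise ValueError("n_ribosomal exceeds n_families")
    gene_len = 3 * (spec.gene_length_codons + 2)
    total_gene_bp = n_cds * gene_len + spec.rrn * _RRNA_LENGTH
    if total_gene_bp > spec.genome_size:
        raise ValueError(
            f"infeasible targets: genes need {total_gene_bp} bp > genome_size "
            f"{spec.genome_size}"
        )

    gc = spec.pct_gc / 100.0
    q = _positional_codon_probs(gc)
    q_he = _bias_he_probs(q, spec.theta)
    codon_arr = np.array(SENSE_CODONS)

    # one sequence per family; copies are identical.  Codon draws are batched
    # (ribosomal families from the sharpened distribution, the rest from the
    # background) for speed.
    L = spec.gene_length_codons
    n_he, n_bg = spec.n_ribosomal, spec.n_families - spec.n_ribosomal
    he_idx = rng.choice(61, size=(n_he, L), p=q_he) if n_he else np.empty((0, L), int)
    bg_idx = rng.choice(61, size=(n_bg, L), p=q) if n_bg else np.empty((0, L), int)
    all_idx = np.vstack([he_idx, bg_idx])
    family_seqs = ["ATG" + "".join(codon_arr[row]) + "TAA" for row in all_idx]

    copies = np.ones(spec.n_families, dtype=int)
    extra = n_cds - spec.n_families
    if extra > 0:
        for f in rng.choice(spec.n_families, size=extra, replace=True):
            copies[f] += 1

    # assemble the gene roster: (family, product)
    roster: list[tuple[int, str]] = []
    for f in range(spec.n_families):
        product = (
            f"50S ribosomal protein L{f + 1}" if f < spec.n_ribosomal
            else f"hypothetical protein {f + 1}"
        )
        roster.extend((f, product) for _ in range(copies[f]))
    n_tf = int(round(spec.pct_tf / 100.0 * n_cds))
    non_ribo = [i for i, (f, _) in enumerate(roster) if f >= spec.n_ribosomal]
    if n_tf > len(non_ribo):
        raise ValueError("pct_tf target exceeds the non-ribosomal gene count")
    for i in rng.choice(len(non_ribo), size=n_tf, replace=False):
        f, _ = roster[non_ribo[i]]
        roster[non_ribo[i]] = (f, f"transcriptional regulator family {f + 1}")

    order = rng.permutation(len(roster))
    rrna_seq = _random_bases(rng, _RRNA_LENGTH, gc)
    # interleave rRNA features at deterministic positions in the gene order
    items: list[tuple[str, str | int]] = [("cds", int(i)) for i in order]
    if spec.rrn > 0:
        step = max(1, len(items) // (spec.rrn + 1))
        for r in range(spec.rrn):
            items.insert(min(len(items), (r + 1) * step + r), ("rrna", r))

    # intergenic filler: solve its GC fraction so the whole contig hits pct_gc
    feature_bp = n_cds * gene_len + spec.rrn * _RRNA_LENGTH
    filler_bp = spec.genome_size - feature_bp
    gc_features = sum(
        (family_seqs[f].count("G") + family_seqs[f].count("C")) * c
        for f, c in enumerate(copies)
    ) + spec.rrn * (rrna_seq.count("G") + rrna_seq.count("C"))
    gc_needed = gc * spec.genome_size - gc_features
    filler_gc = float(np.clip(gc_needed / filler_bp, 0.0, 1.0)) if filler_bp else 0.0

    n_gaps = len(items) + 1
    gap = filler_bp // n_gaps
    gap_last = filler_bp - gap * (len(items))

    parts: list[str] = []
    genes: list[GeneRecord] = []
    pos = 0
    filler = _random_bases(rng, filler_bp, filler_gc)
    fpos = 0

    def take_filler(k: int) -> str:
        nonlocal fpos
        s = filler[fpos : fpos + k]
        fpos += k
        return s

    strand_draws = rng.random(len(items))
    for j, (kind, payload) in enumerate(items):
        parts.append(take_filler(gap if j < len(items) else gap_last))
        pos += gap
        if kind == "cds":
            f, product = roster[payload]
            seq = family_seqs[f]
            strand = "+" if strand_draws[j] < 0.5 else "-"
            placed = seq if strand == "+" else seq.translate(_REVCOMP)[::-1]
            start = pos + 1
            end = pos + len(seq)
            genes.append(
                GeneRecord(
                    gene_id=f"gene{j + 1:05d}",
                    contig_id="contig1",
                    start=start,
                    end=end,
                    strand=strand,
                    feature_type="CDS",
                    family_id=f"fam{f + 1:05d}",
                    product=product,
                    is_tf="transcriptional regulator" in product,
                    is_ribosomal_protein="ribosomal protein" in product,
                    coding_sequence=seq,
                )
            )
            parts.append(placed)
            pos += len(seq)
        else:
            start = pos + 1
            end = pos + _RRNA_LENGTH
            genes.append(
                GeneRecord(
                    gene_id=f"rrna{payload + 1:03d}",
                    contig_id="contig1",
                    start=start,
                    end=end,
                    strand="+",
                    feature_type="rRNA_16S",
                    product="16S ribosomal RNA",
                )
            )
            parts.append(rrna_seq)
            pos += _RRNA_LENGTH
    parts.append(take_filler(filler_bp - fpos))

    contig = "".join(parts)
    assert len(contig) == spec.genome_size
    taxonomy = {}
    if spec.genus:
        taxonomy["genus"] = spec.genus
    if spec.species:
        taxonomy["species"] = spec.species
    genome = GenomeRecord(
        genome_id=f"synth_{seed}",
        contigs={"contig1": contig},
        genes=genes,
        taxonomy=taxonomy,
        habitat_string=spec.habitat_string,
        external_traits=dict(spec.external_traits),
    )
    genome.validate()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_genome(genome, out_dir / f"{genome.genome_id}.fna",
                     out_dir / f"{genome.genome_id}.gff")
    return genome


def sim_genome_cohort(
    regime: TraitRegime,
    n: int,
    seed: int = 0,
    *,
    size_scale: float = 1.0,
    theta_max: float = 3.0,
) -> tuple[list[GenomeRecord], TraitTable, pd.DataFrame]:
    """A cohort of toy genomes whose targets follow a planted trait regime.

    Draws a species-level regime table, converts each row into genome-build
    targets (theta is the within-cohort percentile of the planted CUB scaled
    to [0, theta_max], preserving ranks), and builds the genomes.
    ``size_scale`` < 1 shrinks physical sequence lengths (gene counts scale
    along) while keeping the planted genome_size trait values; extraction
    then reports the scaled size, so leave it at 1.0 when absolute sizes
    matter.
    """
    table, truth = sim_trait_table(regime, n, seed=seed)
    cub = table.data["cub_f"].to_numpy()
    theta = theta_max * (pd.Series(cub).rank(pct=True).to_numpy())
    genomes = []
    for i, (sid, row) in enumerate(table.data.iterrows()):
        size = int(round(row["genome_size"] * size_scale))
        rrn_copies = max(1, int(round(row["rrn"])))
        # keep >=3% of the genome intergenic so the targets stay feasible
        fam_cap = (0.97 * size - rrn_copies * _RRNA_LENGTH) / (
            606.0 * row["gene_duplication"]
        )
        n_fam = max(60, min(int(round(row["gene_richness"] * size_scale)),
                            int(fam_cap)))
        build = SyntheticGenomeSpec(
            genome_size=size,
            pct_gc=row["pct_gc"],
            n_families=n_fam,
            duplication=row["gene_duplication"],
            pct_tf=row["pct_tf"],
            rrn=rrn_copies,
            theta=float(theta[i]),
            n_ribosomal=min(25, n_fam),
            species=sid,
            habitat_string=row["habitat"],
            external_traits={
                "pct_hgt": float(row["pct_hgt"]),
                "prophages": float(row["prophages"]),
            },
        )
        genome = build_synthetic_genome(build, seed=seed + 1000 + i)
        genome.genome_id = f"g_{sid}"
        genomes.append(genome)
    return genomes, table, truth
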
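"""Codon counting and composition-corrected codon usage bias (ENC').

The effective number of codons (ENC) summarizes how unevenly a gene set uses
synonymous codons: 20 means one codon per amino acid (maximal bias), 61 means
all sense codons used at their expected frequencies (no bias).  The corrected
variant implemented here (ENC') replaces the uniform expectation with a
background codon distribution, so that bias driven purely by nucleotide
composition (e.g. genomic GC content) does not register as codon selection.

The F index compares ENC' of a highly expressed gene set (ribosomal proteins)
against ENC' of the whole coding genome:

    F = (ENC'_all - ENC'_HE) / ENC'_all

F near 0 means the highly expressed genes are no more biased than the genomic
background; larger F indicates translational selection and is used downstream
as a maximal-growth-rate proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: the 61 sense codons of the standard code, in fixed lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.forward_table))
STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))
AMINO_ACID_OF: dict[str, str] = dict(_STANDARD.forward_table)

#: amino acid -> tuple of synonymous codons (sorted); includes 1-fold families
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_STANDARD.forward_table.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

_BASE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _BASE_LUT[_b] = _i

# 64-slot table mapping 16*b1+4*b2+b3 -> sense-codon index (-1 for stops)
_CODON64_TO_SENSE = np.full(64, -1, dtype=np.int16)
_BASES = "ACGT"
for _i1 in range(4):
    for _i2 in range(4):
        for _i3 in range(4):
            _c = _BASES[_i1] + _BASES[_i2] + _BASES[_i3]
            if _c in _CODON_INDEX:
                _CODON64_TO_SENSE[16 * _i1 + 4 * _i2 + _i3] = _CODON_INDEX[_c]

#: redundancy class (family size) of each sense codon's family
FAMILY_SIZE = {aa: len(cods) for aa, cods in SYNONYMOUS_FAMILIES.items()}
REDUNDANCY_CLASSES = (2, 3, 4, 6)
#: Wright's weights: number of amino-acid families per redundancy class
CLASS_WEIGHTS = {2: 9, 3: 1, 4: 5, 6: 3}


@dataclass
class CodonCounts:
    """Counts of the 61 sense codons, as a vector in ``SENSE_CODONS`` order."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (61,):
            raise ValueError("counts must be a length-61 vector in SENSE_CODONS order")
        if (self.counts < 0).any():
            raise ValueError("codon counts must be non-negative")

    @property
    def n_codons(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict[str, int]:
        return {c: int(n) for c, n in zip(SENSE_CODONS, self.counts)}

    @classmethod
    def from_dict(cls, counts: Mapping[str, int]) -> "CodonCounts":
        vec = np.zeros(61, dtype=np.int64)
        for codon, n in counts.items():
            cu = codon.upper()
            if cu in _CODON_INDEX:
                vec[_CODON_INDEX[cu]] = n
            elif cu in STOP_CODONS:
                raise ValueError(f"stop codon {cu} cannot be counted")
            else:
                raise ValueError(f"unknown codon {codon!r}")
        return cls(vec)

    @classmethod
    def from_sequences(
        cls,
        sequences: Iterable[str],
        *,
        min_codons: int = 80,
        drop_ends: bool = True,
    ) -> "CodonCounts":
        """Pool codon counts over coding sequences.

        Start and stop codons are removed when ``drop_ends`` is set; sequences
        shorter than ``min_codons`` codons after trimming are ignored, as are
        codons containing ambiguous bases and in-frame stop codons.
        """
        vec = np.zeros(61, dtype=np.int64)
        for seq in sequences:
            if seq is None:
                continue
            n = len(seq) - len(seq) % 3
            if n == 0:
                continue
            arr = _BASE_LUT[np.frombuffer(seq[:n].encode("ascii"), dtype=np.uint8)]
            arr = arr.reshape(-1, 3)
            if drop_ends and arr.shape[0] >= 2:
                arr = arr[1:-1]
            if arr.shape[0] < min_codons:
                continue
            ok = (arr >= 0).all(axis=1)
            idx64 = arr[ok] @ np.array([16, 4, 1])
            sense = _CODON64_TO_SENSE[idx64]
            sense = sense[sense >= 0]
            vec += np.bincount(sense, minlength=61)
        return cls(vec)

    def positional_nucleotide_freqs(self) -> np.ndarray:
        """3x4 matrix of nucleotide frequencies at each codon position."""
        freqs = np.zeros((3, 4))
        for i, codon in enumerate(SENSE_CODONS):
            n = self.counts[i]
            for pos, base in enumerate(codon):
                freqs[pos, "ACGT".index(base)] += n
        tot = freqs.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            freqs = np.where(tot > 0, freqs / np.where(tot == 0, 1, tot), np.nan)
        return freqs


def background_codon_probs(counts: CodonCounts) -> dict[str, float]:
    """Null codon probabilities from position-specific nucleotide frequencies.

    Each sense codon gets the product of the three positional base frequencies
    observed in ``counts``; probabilities are then renormalized within each
    synonymous family, which is the only scale at which ENC' uses them.
    """
    if counts.n_codons == 0:
        raise ValueError("cannot estimate background from empty codon counts")
    pos = counts.positional_nucleotide_freqs()
    raw = {}
    for codon in SENSE_CODONS:
        p = 1.0
        for j, base in enumerate(codon):
            p *= pos[j, "ACGT".index(base)]
        raw[codon] = p
    probs: dict[str, float] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        tot = sum(raw[c] for c in codons)
        for c in codons:
            probs[c] = raw[c] / tot if tot > 0 else np.nan
    return probs


def corrected_family_homozygosity(
    n_obs: np.ndarray, e_probs: np.ndarray
) -> float:
    """Composition-corrected homozygosity F' of one synonymous family.

    With ``n`` codons observed at frequencies ``p`` and background family
    frequencies ``e``::

        chi2 = n * sum_i (p_i - e_i)^2 / e_i
        F'   = (chi2 + n - k) / (k * (n - 1))
    """
    n = int(n_obs.sum())
    k = len(n_obs)
    if n < 2:
        raise ValueError("family needs at least 2 observed codons")
    p = n_obs / n
    chi2 = n * float(np.sum((p - e_probs) ** 2 / e_probs))
    return (chi2 + n - k) / (k * (n - 1))


def enc_prime(
    obs: CodonCounts,
    background: Mapping[str, float] | None = None,
    *,
    min_total_codons: int = 100,
) -> float:
    """Composition-corrected effective number of codons.

    Per amino acid with >=2 synonymous codons and >=2 observations the
    corrected homozygosity is computed against ``background`` (family-wise
    renormalized probabilities; estimated from ``obs`` itself when omitted),
    averaged within redundancy classes, and combined as::

        ENC' = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

    clamped to [20, 61].  A missing 3-fold class mean is imputed as the mean
    of the 2- and 4-fold means; a missing 6-fold mean falls back to the 4-fold
    mean; a missing 2- or 4-fold mean makes the result NaN, as does a total
    codon count below ``min_total_codons``.
    """
    if obs.n_codons < min_total_codons:
        return float("nan")
    if background is None:
        background = background_codon_probs(obs)

    class_values: dict[int, list[float]] = {c: [] for c in REDUNDANCY_CLASSES}
    counts = obs.as_dict()
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        k = len(codons)
        if k < 2:
            continue
        n_vec = np.array([counts[c] for c in codons], dtype=float)
        e_vec = np.array([background[c] for c in codons], dtype=float)
        if n_vec.sum() < 2 or not np.all(np.isfinite(e_vec)) or (e_vec <= 0).any():
            continue
        f_hat = corrected_family_homozygosity(n_vec, e_vec)
        if f_hat <= 0:  # possible only when n < k; unusable for 1/F averaging
            continue
        class_values[k].append(f_hat)

    class_means: dict[int, float] = {
        c: float(np.mean(v)) for c, v in class_values.items() if v
    }
    if 2 not in class_means or 4 not in class_means:
        return float("nan")
    if 3 not in class_means:
        class_means[3] = 0.5 * (class_means[2] + class_means[4])
    if 6 not in class_means:
        class_means[6] = class_means[4]

    enc = 2.0 + sum(
        CLASS_WEIGHTS[c] / class_means[c] for c in REDUNDANCY_CLASSES
    )
    return float(np.clip(enc, 20.0, 61.0))
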
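import math

import numpy as np
import pytest

from protraits import (
    ExtractionConfig,
    GeneRecord,
    GenomeRecord,
    RrnReference,
    compute_composition,
    cub_F,
    extract_traits,
    gene_family_stats,
    impute_rrn,
    predict_generation_time,
    rrn_count,
    tf_fraction,
)
from protraits.codons import (
    CodonCounts,
    SENSE_CODONS,
    SYNONYMOUS_FAMILIES,
    background_codon_probs,
    corrected_family_homozygosity,
    enc_prime,
)
from protraits.simulate import SyntheticGenomeSpec, build_synthetic_genome

from oracles import enc_prime_bruteforce


def _genome_with_cds(families, tf_flags=None):
    tf_flags = tf_flags or [False] * len(families)
    genes = [
        GeneRecord(f"g{i}", "c1", 1 + 9 * i, 9 + 9 * i, "+", "CDS",
                   family_id=fam, is_tf=tf)
        for i, (fam, tf) in enumerate(zip(families, tf_flags))
    ]
    return GenomeRecord("G", {"c1": "A" * (9 * len(families) + 9)}, genes)


class TestComposition:
    @pytest.mark.parametrize(
        "contigs,size,gc",
        [
            ({"c1": "ATGC"}, 4, 50.0),
            ({"c1": "GGCC", "c2": "AT"}, 6, 100 * 4 / 6),
            ({"c1": "NNNN"}, 4, np.nan),
        ],
    )
    def test_size_and_gc(self, contigs, size, gc):
        got_size, got_gc = compute_composition(GenomeRecord("G", contigs))
        assert got_size == size
        if np.isnan(gc):
            assert np.isnan(got_gc)
        else:
            assert got_gc == pytest.approx(gc)


class TestGeneFamilies:
    @pytest.mark.parametrize(
        "families,richness,duplication",
        [
            (["A", "A", "B", "C"], 3, 4 / 3),
            ([f"f{i}" for i in range(10)], 10, 1.0),
            (["A"] * 5, 1, 5.0),
        ],
    )
    def test_richness_and_duplication(self, families, richness, duplication):
        r, d = gene_family_stats(_genome_with_cds(families))
        assert (r, d) == (richness, pytest.approx(duplication))

    def test_no_cds_gives_missing(self):
        r, d = gene_family_stats(GenomeRecord("G", {"c1": "ACGT"}))
        assert np.isnan(r) and np.isnan(d)

    def test_duplication_at_least_one_and_richness_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            fams = [f"f{i}" for i in rng.integers(0, 8, size=rng.integers(1, 30))]
            r, d = gene_family_stats(_genome_with_cds(fams))
            assert d >= 1.0 and r <= len(fams)


class TestTfFraction:
    @pytest.mark.parametrize("n_tf,n_total,expect", [(5, 100, 5.0), (0, 10, 0.0), (7, 7, 100.0)])
    def test_percentages(self, n_tf, n_total, expect):
        genome = _genome_with_cds(
            [f"f{i}" for i in range(n_total)],
            [i < n_tf for i in range(n_total)],
        )
        assert tf_fraction(genome) == pytest.approx(expect)


class TestEncPrime:
    def test_corrected_homozygosity_hand_example(self):
        # one 2-fold family, n=10, p=(0.9,0.1), e=(0.5,0.5):
        # chi2 = 10*(0.4^2/0.5 + 0.4^2/0.5) = 6.4 ; F' = (6.4+10-2)/(2*9) = 0.8
        f = corrected_family_homozygosity(np.array([9.0, 1.0]), np.array([0.5, 0.5]))
        assert f == pytest.approx(0.8, abs=1e-12)

    def test_single_codon_per_family_gives_maximal_bias(self):
        counts = {cods[0]: 500 for cods in SYNONYMOUS_FAMILIES.values()}
        bg = {c: 1 / len(SYNONYMOUS_FAMILIES[a])
              for a, cods in SYNONYMOUS_FAMILIES.items() for c in cods}
        assert enc_prime(CodonCounts.from_dict(counts), bg) == pytest.approx(20.0)

    def test_background_matching_frequencies_give_no_bias(self):
        counts = {c: 600 for c in SENSE_CODONS}
        bg = {c: 1 / len(SYNONYMOUS_FAMILIES[a])
              for a, cods in SYNONYMOUS_FAMILIES.items() for c in cods}
        assert enc_prime(CodonCounts.from_dict(counts), bg) == pytest.approx(61.0)

    def test_matches_bruteforce_oracle_on_random_counts(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            vec = rng.integers(0, 60, size=61)
            cc = CodonCounts(vec)
            if cc.n_codons < 100:
                continue
            bg = background_codon_probs(cc)
            fast = enc_prime(cc, bg)
            slow = enc_prime_bruteforce(cc.as_dict(), bg)
            assert fast == pytest.approx(slow, abs=1e-9)

    def test_count_scaling_moves_toward_asymptote_monotonically(self):
        rng = np.random.default_rng(7)
        vec = rng.integers(1, 40, size=61)
        bg = background_codon_probs(CodonCounts(vec))
        asymptote = enc_prime(CodonCounts(vec * 10**6), bg)
        gaps = [
            abs(enc_prime(CodonCounts(vec * scale), bg) - asymptote)
            for scale in (1, 10, 100)
        ]
        assert gaps[0] >= gaps[1] >= gaps[2]

    def test_counting_skips_short_genes_and_ambiguous_codons(self):
        long_gene = "ATG" + "AAA" * 100 + "TAA"
        short_gene = "ATG" + "AAA" * 10 + "TAA"
        ambiguous = "ATG" + "AAN" * 100 + "TAA"
        cc = CodonCounts.from_sequences([long_gene, short_gene, ambiguous])
        assert cc.n_codons == 100  # only the long clean gene's body


class TestCubF:
    def test_f_monotone_in_bias_parameter(self):
        f_values = []
        for theta in (0.0, 1.0, 2.5):
            genome = build_synthetic_genome(
                SyntheticGenomeSpec(genome_size=400_000, n_families=250,
                                    n_ribosomal=20, theta=theta),
                seed=11,
            )
            f_values.append(cub_F(genome))
        assert f_values[0] == pytest.approx(0.0, abs=0.05)
        assert f_values[0] < f_values[1] < f_values[2]

    def test_too_few_ribosomal_genes_gives_missing(self):
        genome = build_synthetic_genome(
            SyntheticGenomeSpec(genome_size=200_000, n_families=100, n_ribosomal=3),
            seed=1,
        )
        assert np.isnan(cub_F(genome, ExtractionConfig(min_he_genes=10)))

    def test_f_invariant_to_gene_order(self):
        genome = build_synthetic_genome(
            SyntheticGenomeSpec(genome_size=400_000, n_families=250,
                                n_ribosomal=20, theta=1.5),
            seed=3,
        )
        f1 = cub_F(genome)
        shuffled = GenomeRecord(
            genome.genome_id, genome.contigs, genome.genes[::-1]
        )
        assert cub_F(shuffled) == f1

    def test_he_enc_invariant_to_duplicating_pooled_counts(self):
        # duplicating the highly expressed set leaves its pooled frequencies
        # unchanged; ENC' moves only through the finite-sample correction
        genome = build_synthetic_genome(
            SyntheticGenomeSpec(genome_size=400_000, n_families=250,
                                n_ribosomal=20, theta=1.5),
            seed=3,
        )
        he = [g.coding_sequence for g in genome.cds() if g.is_ribosomal_protein]
        all_counts = CodonCounts.from_sequences(
            [g.coding_sequence for g in genome.cds() if g.coding_sequence]
        )
        bg = background_codon_probs(all_counts)
        once = CodonCounts.from_sequences(he)
        twice = CodonCounts.from_sequences(he + he)
        assert enc_prime(twice, bg) == pytest.approx(enc_prime(once, bg), abs=0.2)


class TestGenerationTime:
    def test_zero_slope_gives_constant(self):
        config = ExtractionConfig(gt_intercept=1.0, gt_slope=0.0)
        d1, _ = predict_generation_time(0.1, config)
        d2, _ = predict_generation_time(0.9, config)
        assert d1 == d2 == pytest.approx(math.exp(1.0))

    def test_negative_slope_is_monotone_decreasing(self):
        config = ExtractionConfig(gt_slope=-4.0)
        assert predict_generation_time(0.6, config)[0] < predict_generation_time(0.2, config)[0]

    def test_above_five_hours_is_flagged_unreliable(self):
        config = ExtractionConfig(gt_intercept=math.log(6.0), gt_slope=0.0)
        d, unreliable = predict_generation_time(0.3, config)
        assert d == pytest.approx(6.0) and unreliable
        config_fast = ExtractionConfig(gt_intercept=math.log(2.0), gt_slope=0.0)
        assert predict_generation_time(0.3, config_fast)[1] is False

    def test_missing_f_propagates(self):
        d, flag = predict_generation_time(float("nan"))
        assert np.isnan(d) and flag is False


class TestRrn:
    def test_only_16s_features_counted(self):
        genes = [
            GeneRecord("r1", "c1", 1, 10, "+", "rRNA_16S"),
            GeneRecord("r2", "c1", 11, 20, "+", "rRNA_16S"),
            GeneRecord("r3", "c1", 21, 30, "+", "rRNA_other"),
            GeneRecord("r4", "c1", 31, 40, "+", "rRNA_other"),
        ]
        assert rrn_count(GenomeRecord("G", {"c1": "A" * 40}, genes)) == 2

    @pytest.mark.parametrize(
        "ref,genus,expect",
        [
            ({"Escherichia": [7, 7, 7]}, "Escherichia", 7.0),
            ({"X": [1, 2]}, "X", 1.5),
            ({"X": [1, 2]}, "Absent", np.nan),
        ],
    )
    def test_genus_imputation(self, ref, genus, expect):
        got = impute_rrn(genus, RrnReference(ref))
        if np.isnan(expect):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expect)


class TestExtractTraits:
    def test_missing_external_traits_stay_missing(self):
        genome = build_synthetic_genome(
            SyntheticGenomeSpec(genome_size=200_000, n_families=100), seed=5
        )
        tv = extract_traits(genome, config=ExtractionConfig(rrn_source="annotated"))
        assert np.isnan(tv.values["pct_hgt"]) and np.isnan(tv.values["prophages"])
        assert tv.provenance["pct_hgt"] == "missing"

    def test_annotated_rrn_source_counts_16s(self):
        genome = build_synthetic_genome(
            SyntheticGenomeSpec(genome_size=200_000, n_families=100, rrn=3), seed=5
        )
        tv = extract_traits(genome, config=ExtractionConfig(rrn_source="annotated"))
        assert tv.values["rrn"] == 3.0

    def test_imputed_rrn_uses_genus_reference(self):
        genome = build_synthetic_genome(
            SyntheticGenomeSpec(genome_size=200_000, n_families=100, genus="Vibrio"),
            seed=5,
        )
        tv = extract_traits(genome, ref=RrnReference({"Vibrio": [8, 10]}))
        assert tv.values["rrn"] == pytest.approx(9.0)
        assert tv.provenance["rrn"] == "imputed"
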
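from __future__ import annotations

import textwrap

import numpy as np
import pandas as pd
import pytest

from protraits import TraitTable


@pytest.fixture
def tiny_genome_files(tmp_path):
    """A 1-contig genome with one CDS on each strand and rRNA features."""

    def make(cds_strand="+", contig_for_cds="c1", extra_gff_lines=()):
        fasta = tmp_path / "g.fna"
        gff = tmp_path / "g.gff"
        fasta.write_text(">c1\nATGAAATAG\n")
        lines = [
            "##gff-version 3",
            f"c1\t.\tCDS\t1\t9\t.\t{cds_strand}\t0\tID=cds1;product=hypothetical protein"
            .replace("c1\t", f"{contig_for_cds}\t", 1),
            *extra_gff_lines,
        ]
        gff.write_text("\n".join(lines) + "\n")
        return fasta, gff

    return make


@pytest.fixture
def small_table():
    df = pd.DataFrame(
        {
            "genome_size": [4e6, 6e6, 2e6],
            "pct_gc": [50.0, 60.0, 40.0],
            "rrn": [7.0, np.nan, 2.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="id"),
    )
    return TraitTable(df)
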
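"""Shared fixtures: a small annotated GenBank record and simulated families."""

from __future__ import annotations

import textwrap

import pytest

from plastcub.simulate import SimConfig, generate_family

GENBANK_FIXTURE = textwrap.dedent(
    """\
    LOCUS       minifix                  120 bp    DNA     circular PLN 01-JAN-2024
    DEFINITION  synthetic mini plastome fixture.
    ACCESSION   minifix
    VERSION     minifix.1
    SOURCE      synthetic
      ORGANISM  synthetic
    FEATURES             Location/Qualifiers
         CDS             4..15
                         /gene="fwd1"
         CDS             complement(join(20..28,40..48))
                         /gene="rev2x"
         tRNA            60..85
                         /gene="trnX"
         CDS             join(115..120,1..3)
                         /gene="wrap"
    ORIGIN
            1 aaaatggcgg catagccccc atttacttac ccccccccct gcacgggtac ccccccccca
           61 acacacacac acacacacac acacattttt tttttttttt tttttttttt tttttttttt
    //
    """
)


@pytest.fixture()
def genbank_file(tmp_path):
    path = tmp_path / "minifix.gb"
    path.write_text(GENBANK_FIXTURE)
    return path


@pytest.fixture(scope="session")
def mini_family():
    """Default-scale synthetic family used by several recovery tests."""
    return generate_family(SimConfig(seed=1))


@pytest.fixture(scope="session")
def biased_family():
    """Strong-effect codon-bias family: high-bias subset prefers CTG/CGC."""
    cfg = SimConfig(
        seed=7, n_genes=12, gene_length_range=(4500, 6000),
        preferred_codons=("CTG", "CGC"), high_bias_weight=30.0,
        high_bias_fraction=0.25, high_bias_gc3=0.08,
        gc3_target=0.20, gc3_jitter=0.02, aa_alpha=50.0,
        genome_size=100_000, ir_length=12_000, ssc_length=6_000,
        ir_gene=False, n_taxa=2,
    )
    return generate_family(cfg)
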
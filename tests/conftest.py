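"""Shared fixtures: tiny hand-built FASTA/GFF3/VCF files and small seeded
synthetic datasets.  Everything is generated at test time; nothing binary is
stored in the repository."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

import sweepmeth as sm


@pytest.fixture
def write_text(tmp_path):
    """Write dedented text to a temp file and return its path."""

    def _write(name: str, content: str):
        p = tmp_path / name
        p.write_text(textwrap.dedent(content).lstrip("\n"))
        return p

    return _write


@pytest.fixture
def toy_genome(write_text):
    """1 kb contig 'c1' of repeated ACGT plus contig 'm1' carrying a
    hand-built minus-strand 9-codon gene."""
    c1 = "ACGT" * 250
    # coding sequence (minus strand): ATG GCT TAC AAA CCC GGG TTT AGC TAA
    coding = "ATGGCTTACAAACCCGGGTTTAGCTAA"
    m1 = "A" * 10 + sm.io.revcomp(coding) + "A" * 13
    path = write_text("toy.fa", f">c1\n{c1}\n>m1\n{m1}\n")
    return sm.read_fasta(path)


MINUS_GENE_CODING = "ATGGCTTACAAACCCGGGTTTAGCTAA"  # M A Y K P G F S *


@pytest.fixture
def toy_gff3(write_text):
    """3-exon plus-strand gene without UTR features (UTRs derived) plus a
    single-exon minus-strand gene; 1-based closed GFF coordinates."""
    return write_text(
        "toy.gff3",
        """
        ##gff-version 3
        c1\ttest\tgene\t101\t600\t.\t+\t.\tID=G1
        c1\ttest\tmRNA\t101\t600\t.\t+\t.\tID=G1.t1;Parent=G1
        c1\ttest\texon\t101\t200\t.\t+\t.\tParent=G1.t1
        c1\ttest\texon\t301\t400\t.\t+\t.\tParent=G1.t1
        c1\ttest\texon\t501\t600\t.\t+\t.\tParent=G1.t1
        c1\ttest\tCDS\t151\t200\t.\t+\t0\tParent=G1.t1
        c1\ttest\tCDS\t301\t400\t.\t+\t1\tParent=G1.t1
        c1\ttest\tCDS\t501\t548\t.\t+\t0\tParent=G1.t1
        c1\ttest\tgene\t701\t800\t.\t-\t.\tID=G2
        c1\ttest\tmRNA\t701\t800\t.\t-\t.\tID=G2.t1;Parent=G2
        c1\ttest\texon\t701\t800\t.\t-\t.\tParent=G2.t1
        m1\ttest\tgene\t6\t45\t.\t-\t.\tID=GM
        m1\ttest\tmRNA\t6\t45\t.\t-\t.\tID=GM.t1;Parent=GM
        m1\ttest\texon\t6\t45\t.\t-\t.\tParent=GM.t1
        m1\ttest\tCDS\t11\t37\t.\t-\t0\tParent=GM.t1
        """,
    )


@pytest.fixture
def toy_vcf(write_text):
    """5 records: 4 biallelic SNPs plus one indel (skipped)."""
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=c1,length=1000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
    )
    rows = [
        "c1\t10\t.\tA\tG\t.\tPASS\t.\tGT:DP:GQ\t0/1:12:50\t0/0:15:60",
        "c1\t20\t.\tC\tT\t.\tPASS\t.\tGT:DP:GQ\t1/1:8:40\t0/1:9:45",
        "c1\t30\t.\tG\tGA\t.\tPASS\t.\tGT:DP:GQ\t0/1:10:50\t0/0:10:50",  # indel
        "c1\t40\t.\tT\tA\t.\tPASS\t.\tGT:DP:GQ\t./.:3:5\t0/1:20:70",
        "c1\t50\t.\tG\tC\t.\tPASS\t.\tGT:DP:GQ\t0/0:30:80\t1/1:25:75",
    ]
    return write_text("toy.vcf", header + "\n".join(rows) + "\n")


def make_table(gt, dp=None, gq=None, pos=None, contig="c1"):
    """Build a VariantTable from a dosage matrix for unit tests."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples = gt.shape
    dp = np.full_like(gt, 30, dtype=np.int32) if dp is None else np.asarray(dp, np.int32)
    gq = np.full_like(gt, 60, dtype=np.int32) if gq is None else np.asarray(gq, np.int32)
    pos = np.arange(n_sites) * 10 if pos is None else np.asarray(pos)
    return sm.VariantTable(
        samples=[f"S{i}" for i in range(n_samples)],
        contig=np.array([contig] * n_sites, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["G"] * n_sites, dtype=object),
        gt=gt,
        dp=dp,
        gq=gq,
    )


@pytest.fixture(scope="session")
def sweep_sim():
    """One default synthetic sweep dataset, reused across tests."""
    return sm.simulate_sweep_genotypes(seed=7)


@pytest.fixture(scope="session")
def methyl_sim():
    """One default synthetic methylome, reused across tests."""
    return sm.simulate_methylomes(seed=7)
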
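"""Readers and writers for the genomic file formats the pipeline consumes.

All coordinates are 0-based half-open internally; conversion to and from the
1-based conventions of VCF and GFF3 happens only at the I/O boundary.
FASTA parsing is delegated to Biopython, GFF3 parsing to gffutils and VCF
parsing to cyvcf2; this module only normalises their output into the
package's internal containers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string over {A,C,G,T,N}."""
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genome


@dataclass
class Genome:
    """A collection of contig sequences, upper-cased, alphabet {A,C,G,T,N}."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.sequences.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences

    def __getitem__(self, contig: str) -> str:
        return self.sequences[contig]

    def base(self, contig: str, pos: int) -> str:
        """Plus-strand base at 0-based ``pos``."""
        return self.sequences[contig][pos]


def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Sequences are upper-cased; characters outside {A,C,G,T,N} are mapped to
    N with a logged warning.  Duplicate contig ids or an empty file raise
    :class:`FormatError`.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate contig id {record.id!r} in {path}")
        seq = str(record.seq).upper()
        if set(seq) - VALID_BASES:
            bad = sorted(set(seq) - VALID_BASES)
            logger.warning(
                "contig %s: non-ACGTN characters %s mapped to N", record.id, bad
            )
            seq = "".join(c if c in VALID_BASES else "N" for c in seq)
        sequences[record.id] = seq
    if not sequences:
        raise FormatError(f"no FASTA records found in {path}")
    return Genome(sequences)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene models


Interval = tuple[int, int]  # 0-based half-open


@dataclass
class Transcript:
    """A transcript: ordered exon/CDS/UTR intervals, 0-based half-open."""

    tx_id: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[Interval]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def is_coding(self) -> bool:
        return bool(self.cds)


@dataclass
class Gene:
    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    transcripts: list[Transcript]

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def tss(self) -> int:
        """Transcription start site; on the minus strand this is the maximum
        coordinate of the gene span (the last base, 0-based)."""
        return self.start if self.strand == "+" else self.end - 1


def _merge_sorted(intervals: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _derive_utrs(tx: Transcript, strand: str) -> None:
    """Derive UTR intervals as exon minus CDS when the GFF3 lacks them."""
    if not tx.cds or (tx.utr5 or tx.utr3):
        return
    cds_lo = min(s for s, _ in tx.cds)
    cds_hi = max(e for _, e in tx.cds)
    left: list[Interval] = []
    right: list[Interval] = []
    for s, e in tx.exons:
        if s < cds_lo:
            left.append((s, min(e, cds_lo)))
        if e > cds_hi:
            right.append((max(s, cds_hi), e))
    if strand == "+":
        tx.utr5, tx.utr3 = left, right
    else:
        tx.utr5, tx.utr3 = right, left


_TRANSCRIPT_TYPES = ("mRNA", "transcript")


def read_gff3(
    path: str | Path, contig_lengths: Mapping[str, int] | None = None
) -> list[Gene]:
    """Read gene models from a GFF3 file.

    1-based closed GFF intervals become 0-based half-open.  Transcripts are
    attached to genes through their ``Parent`` attributes.  UTRs absent from
    the file are derived as exon minus CDS.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    tx_ids = set()
    for ttype in _TRANSCRIPT_TYPES:
        tx_ids.update(f.id for f in db.features_of_type(ttype))
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents or not any(p in tx_ids for p in parents):
            raise FormatError(
                f"CDS at {cds.seqid}:{cds.start}-{cds.end} has no parent transcript"
            )

    genes: list[Gene] = []
    for g in db.features_of_type("gene"):
        if contig_lengths is not None and g.seqid in contig_lengths:
            if g.end > contig_lengths[g.seqid] or g.start < 1:
                raise FormatError(
                    f"gene {g.id}: interval {g.start}-{g.end} outside contig "
                    f"{g.seqid} (length {contig_lengths[g.seqid]})"
                )
        transcripts: list[Transcript] = []
        for ttype in _TRANSCRIPT_TYPES:
            for t in db.children(g, featuretype=ttype, order_by="start"):
                exons = _merge_sorted(
                    [(c.start - 1, c.end) for c in db.children(t, featuretype="exon")]
                )
                cds = _merge_sorted(
                    [(c.start - 1, c.end) for c in db.children(t, featuretype="CDS")]
                )
                utr5 = _merge_sorted(
                    [
                        (c.start - 1, c.end)
                        for c in db.children(t, featuretype="five_prime_UTR")
                    ]
                )
                utr3 = _merge_sorted(
                    [
                        (c.start - 1, c.end)
                        for c in db.children(t, featuretype="three_prime_UTR")
                    ]
                )
                if not exons:
                    exons = _merge_sorted(cds + utr5 + utr3)
                tx = Transcript(t.id, exons, cds, utr5, utr3)
                _derive_utrs(tx, g.strand)
                transcripts.append(tx)
        if transcripts:
            genes.append(Gene(g.id, g.seqid, g.strand, transcripts))
    return genes


# ---------------------------------------------------------------------------
# Variants


@dataclass
class VariantTable:
    """Biallelic SNP genotypes for a fixed sample panel.

    ``gt`` holds alt-allele dosage (0/1/2) with -1 for missing; ``dp`` and
    ``gq`` carry per-genotype read depth and phred genotype quality.
    Positions are 0-based internally (1-based in VCF).
    """

    samples: list[str]
    contig: np.ndarray  # dtype object/str, shape (n_sites,)
    pos: np.ndarray  # int64, 0-based
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray  # int8, (n_sites, n_samples), -1 = missing
    dp: np.ndarray  # int32, (n_sites, n_samples)
    gq: np.ndarray  # int32, (n_sites, n_samples)
    skipped: dict[str, int] = field(default_factory=dict)
    contig_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(
            self.samples,
            self.contig[mask],
            self.pos[mask],
            self.ref[mask],
            self.alt[mask],
            self.gt[mask],
            self.dp[mask],
            self.gq[mask],
            dict(self.skipped),
            dict(self.contig_lengths),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": self.contig,
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
            }
        )


_SNP_BASES = {"A", "C", "G", "T"}


def _has_seqlens(vcf) -> bool:
    try:
        return bool(vcf.seqlens)
    except Exception:
        return False


def read_vcf(path: str | Path) -> VariantTable:
    """Read biallelic SNPs from a VCF 4.x file with GT/DP/GQ FORMAT fields.

    Multi-allelic and non-SNP records are skipped and counted in
    ``VariantTable.skipped``.  A missing DP or GQ FORMAT field raises
    :class:`ValidationError` naming the field.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    contigs, poss, refs, alts = [], [], [], []
    gts, dps, gqs = [], [], []
    skipped = {"multiallelic": 0, "non_snp": 0}
    for v in vcf:
        if len(v.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if v.REF not in _SNP_BASES or v.ALT[0] not in _SNP_BASES:
            skipped["non_snp"] += 1
            continue
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is None:
            raise ValidationError(
                f"VCF record {v.CHROM}:{v.POS} lacks the DP FORMAT field"
            )
        try:
            gq = v.format("GQ")
        except KeyError:
            gq = None
        if gq is None:
            raise ValidationError(
                f"VCF record {v.CHROM}:{v.POS} lacks the GQ FORMAT field"
            )
        gt = v.gt_types.astype(np.int8)  # gts012: 0/1/2 dosage, 3 = unknown
        gt[gt == 3] = -1
        contigs.append(v.CHROM)
        poss.append(v.POS - 1)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        gts.append(gt)
        dps.append(np.clip(dp.reshape(-1).astype(np.int64), 0, None).astype(np.int32))
        gqs.append(np.clip(gq.reshape(-1).astype(np.int64), 0, None).astype(np.int32))
    n = len(poss)
    return VariantTable(
        samples,
        np.array(contigs, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        np.vstack(gts) if n else np.empty((0, len(samples)), np.int8),
        np.vstack(dps) if n else np.empty((0, len(samples)), np.int32),
        np.vstack(gqs) if n else np.empty((0, len(samples)), np.int32),
        skipped,
        {
            name: int(length)
            for name, length in zip(vcf.seqnames, vcf.seqlens or [])
        }
        if _has_seqlens(vcf)
        else {},
    )


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(
    table: VariantTable,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a :class:`VariantTable` as an uncompressed VCF 4.2 file."""
    if contig_lengths is None and table.contig_lengths:
        contig_lengths = table.contig_lengths
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepmeth\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in dict.fromkeys(table.contig.tolist()):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for i in range(table.n_sites):
            cells = [
                f"{_GT_STRINGS[int(table.gt[i, j])]}:{int(table.dp[i, j])}:{int(table.gq[i, j])}"
                for j in range(table.n_samples)
            ]
            fh.write(
                f"{table.contig[i]}\t{table.pos[i] + 1}\t.\t{table.ref[i]}\t"
                f"{table.alt[i]}\t.\tPASS\t.\tGT:DP:GQ\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Bismark-style cytosine reports


def read_cytosine_report(
    path: str | Path, genome: Genome | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read a per-cytosine report (contig, 1-based pos, strand, meth count,
    unmeth count, context).

    When a genome is supplied the declared context is cross-checked against
    the reference: mismatches are re-assigned from the genome (counted in the
    report), and positions whose strand-adjusted reference base is not C are
    rejected.  Returns a DataFrame with 0-based positions plus a counter
    report.
    """
    from .methylation import assign_context

    df = pd.read_csv(
        str(path),
        sep="\t",
        header=None,
        names=["contig", "pos", "strand", "meth", "unmeth", "context"],
        dtype={"contig": str, "pos": np.int64, "strand": str, "context": str},
        comment="#",
    )
    if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
        raise FormatError(f"negative counts in cytosine report {path}")
    df["pos"] = df["pos"] - 1  # to 0-based
    report = {"n_records": len(df), "reassigned": 0, "rejected": 0, "no_context": 0}
    if genome is not None:
        keep = np.ones(len(df), dtype=bool)
        contexts = df["context"].to_numpy(dtype=object)
        for i, (contig, pos, strand) in enumerate(
            zip(df["contig"], df["pos"], df["strand"])
        ):
            if contig not in genome:
                raise FormatError(f"cytosine report contig {contig!r} not in genome")
            base = genome.base(contig, int(pos))
            ref_c = base if strand == "+" else base.translate(COMPLEMENT)
            if ref_c != "C":
                keep[i] = False
                report["rejected"] += 1
                continue
            ctx = assign_context(genome, contig, int(pos), strand)
            if ctx is None:
                keep[i] = False
                report["no_context"] += 1
                continue
            if ctx != contexts[i]:
                contexts[i] = ctx
                report["reassigned"] += 1
        df["context"] = contexts
        df = df[keep].reset_index(drop=True)
        if report["rejected"]:
            logger.warning(
                "%s: rejected %d records at non-cytosine reference positions",
                path,
                report["rejected"],
            )
        if report["reassigned"]:
            logger.warning(
                "%s: re-assigned %d contexts from the genome", path, report["reassigned"]
            )
    return df, report


def write_cytosine_report(df: pd.DataFrame, path: str | Path) -> None:
    """Write a per-cytosine report (positions converted back to 1-based)."""
    out = df.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(
        str(path),
        sep="\t",
        header=False,
        index=False,
        columns=["contig", "pos", "strand", "meth", "unmeth", "context"],
    )


# ---------------------------------------------------------------------------
# Tabular output

_TSV_KINDS = {"window_tsv", "dmr_tsv", "annotation_tsv"}


def write_table(records, path: str | Path, kind: str) -> None:
    """Write results as TSV (with header) or BED (0-based half-open).

    ``kind`` selects the convention: ``bed`` writes contig/start/end columns
    without a header; the ``*_tsv`` kinds write a header line and format
    floats to 6 decimals so round-trips are stable at that precision.
    """
    if kind not in _TSV_KINDS and kind != "bed":
        raise ValidationError(f"unknown table kind {kind!r}")
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if kind == "bed":
        cols = [c for c in ("contig", "start", "end", "name") if c in df.columns]
        if df.empty:
            Path(path).write_text("")
            return
        df.to_csv(str(path), sep="\t", header=False, index=False, columns=cols)
    else:
        df.to_csv(str(path), sep="\t", index=False, float_format="%.6f")


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column sample-to-group table (sample TAB label)."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"groups file line is not 2 columns: {line!r}")
            groups[parts[0]] = parts[1]
    labels = list(dict.fromkeys(groups.values()))
    if len(labels) != 2:
        raise ValidationError(
            f"groups file must define exactly 2 group labels, found {labels}"
        )
    return groups
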
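"""Functional classification of SNPs against gene models.

Each SNP receives exactly one category, resolved by precedence in the
ANNOVAR style: coding (exonic) effects outrank splicing, which outranks
UTRs, introns and the flanking categories; a site near two different genes
can be jointly Upstream/Downstream.  Coding effects are computed by
rebuilding the affected codon from the reference sequence, substituting the
alternate allele (reverse-complemented for minus-strand transcripts) and
translating with the standard genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .errors import DataConsistencyError, ValidationError
from .io import COMPLEMENT, Gene, Genome, Transcript, VariantTable

CATEGORY_UPSTREAM = "Upstream"
CATEGORY_UTR5 = "5'UTR"
CATEGORY_STOP_GAIN = "Exonic-stop-gain"
CATEGORY_STOP_LOSS = "Exonic-stop-loss"
CATEGORY_SYNONYMOUS = "Exonic-synonymous"
CATEGORY_NONSYNONYMOUS = "Exonic-nonsynonymous"
CATEGORY_INTRONIC = "Intronic"
CATEGORY_SPLICING = "Splicing"
CATEGORY_UTR3 = "3'UTR"
CATEGORY_UTR5_UTR3 = "5'UTR/3'UTR"
CATEGORY_DOWNSTREAM = "Downstream"
CATEGORY_UP_DOWN = "Upstream/Downstream"
CATEGORY_INTERGENIC = "Intergenic"

CATEGORIES = [
    CATEGORY_UPSTREAM,
    CATEGORY_UTR5,
    CATEGORY_STOP_GAIN,
    CATEGORY_STOP_LOSS,
    CATEGORY_SYNONYMOUS,
    CATEGORY_NONSYNONYMOUS,
    CATEGORY_INTRONIC,
    CATEGORY_SPLICING,
    CATEGORY_UTR3,
    CATEGORY_UTR5_UTR3,
    CATEGORY_DOWNSTREAM,
    CATEGORY_UP_DOWN,
    CATEGORY_INTERGENIC,
]

_EFFECT_TO_CATEGORY = {
    "stop-gain": CATEGORY_STOP_GAIN,
    "stop-loss": CATEGORY_STOP_LOSS,
    "nonsynonymous": CATEGORY_NONSYNONYMOUS,
    "synonymous": CATEGORY_SYNONYMOUS,
}
# most severe first, used when a SNP hits several transcripts
_EFFECT_SEVERITY = ["stop-gain", "stop-loss", "nonsynonymous", "synonymous"]


@dataclass
class AnnotationParams:
    upstream_bp: int = 1000
    downstream_bp: int = 1000
    splice_bp: int = 2

    def __post_init__(self) -> None:
        if min(self.upstream_bp, self.downstream_bp, self.splice_bp) < 0:
            raise ValidationError("annotation distances must be >= 0")


@dataclass
class SnpAnnotation:
    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    category: str
    genes: tuple[str, ...]
    is_transition: bool


class GeneIndex:
    """Interval index over gene spans padded by the flanking distances."""

    def __init__(self, genes: list[Gene], params: AnnotationParams):
        self.params = params
        pad = max(params.upstream_bp, params.downstream_bp)
        self.trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self.trees.setdefault(g.contig, IntervalTree())
            tree.addi(max(0, g.start - pad), g.end + pad, g)

    def query(self, contig: str, pos: int) -> list[Gene]:
        tree = self.trees.get(contig)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]

    def __contains__(self, contig: str) -> bool:
        return contig in self.trees


def is_transition(ref: str, alt: str) -> bool:
    """True for A<->G or C<->T substitutions, False for transversions."""
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        raise ValidationError(f"invalid substitution {ref}->{alt}")
    return {ref, alt} in ({"A", "G"}, {"C", "T"})


def _in_intervals(pos: int, intervals) -> bool:
    return any(s <= pos < e for s, e in intervals)


def coding_effect(
    pos: int, ref: str, alt: str, transcript: Transcript, strand: str,
    genome: Genome, contig: str,
) -> str:
    """Effect of a SNP inside the CDS of a protein-coding transcript.

    The affected codon is rebuilt from the reference genome in coding
    orientation, the alternate allele substituted at the in-codon offset and
    both codons translated.  Returns one of synonymous / nonsynonymous /
    stop-gain / stop-loss.
    """
    seq = genome[contig]
    if seq[pos] != ref:
        raise DataConsistencyError(
            f"reference base {seq[pos]} at {contig}:{pos + 1} disagrees with "
            f"VCF REF {ref}"
        )
    plus_offset = 0
    found = False
    for s, e in transcript.cds:
        if s <= pos < e:
            plus_offset += pos - s
            found = True
            break
        plus_offset += e - s
    if not found:
        raise ValidationError(f"site {contig}:{pos + 1} is not inside the CDS")
    coding_plus = "".join(seq[s:e] for s, e in transcript.cds)
    if strand == "+":
        coding = coding_plus
        off = plus_offset
        c_ref, c_alt = ref, alt
    else:
        coding = coding_plus.translate(COMPLEMENT)[::-1]
        off = len(coding) - 1 - plus_offset
        c_ref = ref.translate(COMPLEMENT)
        c_alt = alt.translate(COMPLEMENT)
    codon_start = 3 * (off // 3)
    codon = coding[codon_start : codon_start + 3]
    if len(codon) < 3:
        raise ValidationError("CDS length is not a multiple of 3 at this codon")
    i = off % 3
    assert codon[i] == c_ref
    mutant = codon[:i] + c_alt + codon[i + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutant).translate())
    if aa_ref != "*" and aa_alt == "*":
        return "stop-gain"
    if aa_ref == "*" and aa_alt != "*":
        return "stop-loss"
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def _near_splice(pos: int, tx: Transcript, splice_bp: int) -> bool:
    """True when pos sits in an intron within splice_bp of an exon boundary."""
    for s, e in tx.introns:
        if s <= pos < e:
            dist = min(pos - s + 1, e - pos)
            return dist <= splice_bp
    return False


def classify_site(
    contig: str, pos: int, ref: str, alt: str,
    index: GeneIndex, genome: Genome,
) -> SnpAnnotation:
    """Assign the single functional category of a biallelic SNP.

    Precedence: Exonic > Splicing > 5'UTR/3'UTR > 5'UTR > 3'UTR > Intronic >
    Upstream/Downstream > Upstream > Downstream > Intergenic.
    """
    if contig not in index and contig not in genome:
        raise ValidationError(f"contig {contig!r} unknown to gene models and genome")
    params = index.params
    exonic: dict[str, str] = {}  # gene -> most severe effect
    splicing: set[str] = set()
    utr5: set[str] = set()
    utr3: set[str] = set()
    intronic: set[str] = set()
    upstream: set[str] = set()
    downstream: set[str] = set()

    for gene in index.query(contig, pos):
        for tx in gene.transcripts:
            if _in_intervals(pos, tx.cds):
                eff = coding_effect(pos, ref, alt, tx, gene.strand, genome, contig)
                prev = exonic.get(gene.gene_id)
                if prev is None or _EFFECT_SEVERITY.index(eff) < _EFFECT_SEVERITY.index(prev):
                    exonic[gene.gene_id] = eff
            elif _in_intervals(pos, tx.utr5):
                utr5.add(gene.gene_id)
            elif _in_intervals(pos, tx.utr3):
                utr3.add(gene.gene_id)
            elif tx.start <= pos < tx.end:
                if _near_splice(pos, tx, params.splice_bp):
                    splicing.add(gene.gene_id)
                else:
                    intronic.add(gene.gene_id)
        # gene-level flanks, strand-aware
        if gene.strand == "+":
            if gene.start - params.upstream_bp <= pos < gene.start:
                upstream.add(gene.gene_id)
            if gene.end <= pos < gene.end + params.downstream_bp:
                downstream.add(gene.gene_id)
        else:
            if gene.end <= pos < gene.end + params.upstream_bp:
                upstream.add(gene.gene_id)
            if gene.start - params.downstream_bp <= pos < gene.start:
                downstream.add(gene.gene_id)

    ts = is_transition(ref, alt)
    if exonic:
        worst = min(exonic.values(), key=_EFFECT_SEVERITY.index)
        genes = tuple(sorted(g for g, e in exonic.items() if e == worst))
        category = _EFFECT_TO_CATEGORY[worst]
    elif splicing:
        category, genes = CATEGORY_SPLICING, tuple(sorted(splicing))
    elif utr5 and utr3:
        category, genes = CATEGORY_UTR5_UTR3, tuple(sorted(utr5 | utr3))
    elif utr5:
        category, genes = CATEGORY_UTR5, tuple(sorted(utr5))
    elif utr3:
        category, genes = CATEGORY_UTR3, tuple(sorted(utr3))
    elif intronic:
        category, genes = CATEGORY_INTRONIC, tuple(sorted(intronic))
    elif upstream and downstream and (upstream != downstream or len(upstream) > 1):
        category, genes = CATEGORY_UP_DOWN, tuple(sorted(upstream | downstream))
    elif upstream:
        category, genes = CATEGORY_UPSTREAM, tuple(sorted(upstream))
    elif downstream:
        category, genes = CATEGORY_DOWNSTREAM, tuple(sorted(downstream))
    else:
        category, genes = CATEGORY_INTERGENIC, ()
    return SnpAnnotation(contig, pos, ref, alt, category, genes, ts)


def annotate_table(
    table: VariantTable, genes: list[Gene], genome: Genome,
    params: AnnotationParams | None = None,
) -> list[SnpAnnotation]:
    """Classify every site of a filtered VariantTable."""
    params = params or AnnotationParams()
    index = GeneIndex(genes, params)
    return [
        classify_site(
            str(table.contig[i]), int(table.pos[i]), str(table.ref[i]),
            str(table.alt[i]), index, genome,
        )
        for i in range(table.n_sites)
    ]


def _round_half_up(num: int, den: int, places: str) -> float:
    return float((Decimal(num) / Decimal(den)).quantize(Decimal(places), ROUND_HALF_UP))


def summarize_annotation(
    annotations: list[SnpAnnotation] | None = None,
    counts: dict[str, int] | None = None,
    ts: int | None = None,
    tv: int | None = None,
    total: int | None = None,
) -> dict:
    """Category counts and percentages plus the transition/transversion ratio.

    Either pass annotations, or pass pre-tabulated category counts together
    with ts/tv (and optionally an explicit total for the percentage
    denominator).  Percentages are half-up rounded to 2 decimals and the
    ts/tv ratio to 3; a zero transversion count reports the ratio as "NA".
    """
    if annotations is not None:
        if not annotations:
            raise ValidationError("summarize_annotation needs at least one annotation")
        counts = {c: 0 for c in CATEGORIES}
        ts = tv = 0
        for a in annotations:
            counts[a.category] += 1
            if a.is_transition:
                ts += 1
            else:
                tv += 1
        total = len(annotations)
    if counts is None or ts is None or tv is None:
        raise ValidationError("need annotations or (counts, ts, tv)")
    if total is None:
        total = sum(counts.values())
    ordered = [c for c in CATEGORIES if c in counts] + [
        c for c in counts if c not in CATEGORIES
    ]
    rows = [
        {
            "category": cat,
            "count": counts[cat],
            "percent": _round_half_up(100 * counts[cat], total, "0.01"),
        }
        for cat in ordered
    ]
    ratio = "NA" if tv == 0 else _round_half_up(ts, tv, "0.001")
    return {
        "categories": pd.DataFrame(rows),
        "total": total,
        "ts": ts,
        "tv": tv,
        "ts_tv_ratio": ratio,
    }
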
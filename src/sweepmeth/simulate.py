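"""Seeded synthetic-data generators with machine-readable truth.

Two generators cover the pipeline's two arms:

* a two-population biallelic-SNP generator under the Balding-Nichols model
  (group allele frequencies Beta-distributed around an ancestral frequency
  with divergence parameter F, so E[Fst] is tunable analytically), with
  elevated F plus near-fixation in one group inside planted sweep windows;
* a binomial bisulfite-count generator emitting Bismark-style per-cytosine
  reports with tile-level methylation differences planted on the 200 bp
  grid.

Both also emit a reference genome with valid gene models (CDS divisible by
3, no internal stops, UTRs present) so annotation and feature mapping can
run end-to-end.  All outputs are pure functions of (params, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    Gene,
    Genome,
    Transcript,
    VariantTable,
    revcomp,
    write_cytosine_report,
    write_fasta,
    write_vcf,
)

_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


# ---------------------------------------------------------------------------
# Reference + gene models


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(np.array(list("ACGT")), size=length)


def _inject_cpgs(
    seq: np.ndarray, rng: np.random.Generator, density: float
) -> None:
    """Overwrite dinucleotides with CG roughly every 1/density bases."""
    spacing = int(round(1.0 / density))
    pos = 0
    while pos + 2 < len(seq):
        p = pos + int(rng.integers(0, max(1, spacing // 2)))
        if p + 2 < len(seq):
            seq[p] = "C"
            seq[p + 1] = "G"
        pos += spacing


def _make_gene(
    seq: np.ndarray,
    contig: str,
    gene_id: str,
    anchor: int,
    strand: str,
    rng: np.random.Generator,
) -> Gene:
    """Place one protein-coding gene with 3-6 exons at ``anchor`` and write
    its CDS into the sequence (start codon, non-stop interior, stop codon)."""
    n_ex = int(rng.integers(3, 7))
    exon_lens = rng.integers(150, 401, size=n_ex)
    intron_lens = rng.integers(300, 1501, size=n_ex - 1)
    start = anchor + int(rng.integers(1000, 3001))
    exons = []
    p = start
    for i in range(n_ex):
        exons.append((p, p + int(exon_lens[i])))
        p += int(exon_lens[i])
        if i < n_ex - 1:
            p += int(intron_lens[i])
    u5 = int(rng.integers(50, 121))
    u3 = min(int(rng.integers(80, 201)), int(exon_lens[-1]) - 30)
    cds_lo = exons[0][0] + u5
    cds_hi = exons[-1][1] - u3
    cds = []
    for s, e in exons:
        cs, ce = max(s, cds_lo), min(e, cds_hi)
        if cs < ce:
            cds.append((cs, ce))
    total = sum(e - s for s, e in cds)
    trim = total % 3
    if trim:  # shrink the 3' end so the CDS is a whole number of codons
        s, e = cds[-1]
        cds[-1] = (s, e - trim)
        cds_hi -= trim
    total = sum(e - s for s, e in cds)
    n_codons = total // 3
    interior = rng.choice(_NONSTOP_CODONS, size=n_codons - 2)
    coding = "ATG" + "".join(interior) + "TAA"
    plus_text = coding if strand == "+" else revcomp(coding)
    off = 0
    for s, e in cds:
        seq[s:e] = list(plus_text[off : off + (e - s)])
        off += e - s
    # strand-aware UTR intervals (exon minus CDS)
    left = []
    right = []
    for s, e in exons:
        if s < cds_lo:
            left.append((s, min(e, cds_lo)))
        if e > cds_hi:
            right.append((max(s, cds_hi), e))
    utr5, utr3 = (left, right) if strand == "+" else (right, left)
    tx = Transcript(f"{gene_id}.t1", exons, cds, utr5, utr3)
    return Gene(gene_id, contig, strand, [tx])


def simulate_reference_and_genes(
    contig_lengths: dict[str, int],
    seed: int,
    gene_spacing: int = 20_000,
    cpg_density: float | None = None,
) -> tuple[Genome, list[Gene]]:
    """I.i.d. uniform ACGT contigs with genes tiled every ~gene_spacing bp.

    When cpg_density is given, CpG dinucleotides are injected at that
    density before gene placement (methylation runs).  Deterministic for a
    fixed (params, seed).
    """
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    genes: list[Gene] = []
    for contig, length in contig_lengths.items():
        seq = _random_sequence(rng, length)
        if cpg_density:
            _inject_cpgs(seq, rng, cpg_density)
        n_genes = length // gene_spacing
        for k in range(n_genes):
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _make_gene(
                seq, contig, f"{contig}_g{k + 1}", k * gene_spacing, strand, rng
            )
            genes.append(gene)
        sequences[contig] = "".join(seq)
    return Genome(sequences), genes


def write_gff3(genes: list[Gene], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based closed intervals, with UTRs)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for tx in g.transcripts:
                fh.write(
                    f"{g.contig}\tsim\tmRNA\t{tx.start + 1}\t{tx.end}\t.\t{g.strand}\t.\t"
                    f"ID={tx.tx_id};Parent={g.gene_id}\n"
                )
                for s, e in tx.exons:
                    fh.write(
                        f"{g.contig}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"Parent={tx.tx_id}\n"
                    )
                cds_tx_order = tx.cds if g.strand == "+" else tx.cds[::-1]
                phase = 0
                for s, e in cds_tx_order:
                    fh.write(
                        f"{g.contig}\tsim\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{phase}\t"
                        f"Parent={tx.tx_id}\n"
                    )
                    phase = (3 - ((e - s) - phase) % 3) % 3
                for s, e in tx.utr5:
                    fh.write(
                        f"{g.contig}\tsim\tfive_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"Parent={tx.tx_id}\n"
                    )
                for s, e in tx.utr3:
                    fh.write(
                        f"{g.contig}\tsim\tthree_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"Parent={tx.tx_id}\n"
                    )


# ---------------------------------------------------------------------------
# Sweep-arm generator


def _default_sweep_windows() -> list[tuple[str, int, int]]:
    return [
        ("chr1", 200_000, 300_000),
        ("chr1", 600_000, 700_000),
        ("chr2", 400_000, 500_000),
    ]


@dataclass
class SweepSimParams:
    n_contigs: int = 2
    contig_length: int = 1_000_000
    n_samples_per_group: int = 10
    snp_density: float = 1 / 200
    background_f: float = 0.02
    sweep_f: float = 0.4
    sweep_windows: list[tuple[str, int, int]] = field(
        default_factory=_default_sweep_windows
    )
    sweep_fixation_prob: float = 0.8
    sweep_fixation_freq: float = 0.98
    depth_mean: float = 10.0
    gq_mean: float = 60.0
    missing_rate: float = 0.02
    group_labels: tuple[str, str] = ("accepts_diet", "refuses_diet")

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.contig_length for i in range(self.n_contigs)}


@dataclass
class SweepSim:
    params: SweepSimParams
    genome: Genome
    genes: list[Gene]
    table: VariantTable
    groups: dict[str, str]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "reference.fa",
            "gff3": outdir / "genes.gff3",
            "vcf": outdir / "variants.vcf",
            "groups": outdir / "groups.tsv",
            "truth_json": outdir / "truth.json",
            "truth_bed": outdir / "truth_windows.bed",
        }
        write_fasta(self.genome, paths["fasta"])
        write_gff3(self.genes, paths["gff3"])
        write_vcf(self.table, paths["vcf"], self.params.contig_lengths)
        with open(paths["groups"], "w") as fh:
            for s, g in self.groups.items():
                fh.write(f"{s}\t{g}\n")
        with open(paths["truth_json"], "w") as fh:
            json.dump(self.truth, fh, indent=1)
        with open(paths["truth_bed"], "w") as fh:
            for contig, s, e in self.params.sweep_windows:
                fh.write(f"{contig}\t{s}\t{e}\n")
        return paths


def simulate_sweep_genotypes(
    params: SweepSimParams | None = None, seed: int = 0
) -> SweepSim:
    """Two-population Balding-Nichols genotypes with planted sweep windows.

    Outside truth windows both group frequencies are Beta-distributed around
    the ancestral frequency with F = background_f; inside, F = sweep_f and
    group 1 is additionally near-fixed with probability sweep_fixation_prob,
    which both elevates Fst and collapses group-1 pooled heterozygosity.
    """
    params = params or SweepSimParams()
    rng = np.random.default_rng(seed)
    genome, genes = simulate_reference_and_genes(
        params.contig_lengths, seed=int(rng.integers(2**31))
    )
    n = params.n_samples_per_group
    samples = [f"{params.group_labels[0]}_{i + 1}" for i in range(n)] + [
        f"{params.group_labels[1]}_{i + 1}" for i in range(n)
    ]
    groups = {s: params.group_labels[0] for s in samples[:n]}
    groups.update({s: params.group_labels[1] for s in samples[n:]})

    spacing = int(round(1.0 / params.snp_density))
    contigs, poss, refs, alts = [], [], [], []
    truth_sites = {"contig": [], "pos": [], "p_anc": [], "p1": [], "p2": [], "swept": []}
    gts, dps, gqs = [], [], []
    bases = np.array(list("ACGT"))
    for contig, length in params.contig_lengths.items():
        wins = [
            (s, e) for (c, s, e) in params.sweep_windows if c == contig
        ]
        positions = np.arange(0, length - spacing, spacing) + rng.integers(
            0, spacing // 2, size=len(np.arange(0, length - spacing, spacing))
        )
        for pos in positions:
            pos = int(pos)
            in_sweep = any(s <= pos < e for s, e in wins)
            f = params.sweep_f if in_sweep else params.background_f
            p_anc = float(rng.uniform(0.1, 0.9))
            shape = (1.0 - f) / f
            p1 = float(rng.beta(p_anc * shape, (1.0 - p_anc) * shape))
            p2 = float(rng.beta(p_anc * shape, (1.0 - p_anc) * shape))
            if in_sweep and rng.random() < params.sweep_fixation_prob:
                p1 = params.sweep_fixation_freq
            g1 = rng.binomial(2, p1, size=n)
            g2 = rng.binomial(2, p2, size=n)
            gt = np.concatenate([g1, g2]).astype(np.int8)
            miss = rng.random(2 * n) < params.missing_rate
            gt[miss] = -1
            dp = rng.poisson(params.depth_mean, size=2 * n).astype(np.int32)
            gq = np.clip(
                rng.normal(params.gq_mean, 10.0, size=2 * n), 0, 99
            ).astype(np.int32)
            ref = genome.base(contig, pos)
            if ref == "N":
                continue
            alt = str(rng.choice(bases[bases != ref]))
            contigs.append(contig)
            poss.append(pos)
            refs.append(ref)
            alts.append(alt)
            gts.append(gt)
            dps.append(dp)
            gqs.append(gq)
            truth_sites["contig"].append(contig)
            truth_sites["pos"].append(pos)
            truth_sites["p_anc"].append(round(p_anc, 6))
            truth_sites["p1"].append(round(p1, 6))
            truth_sites["p2"].append(round(p2, 6))
            truth_sites["swept"].append(bool(in_sweep))
    table = VariantTable(
        samples,
        np.array(contigs, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        np.vstack(gts),
        np.vstack(dps),
        np.vstack(gqs),
        contig_lengths=dict(params.contig_lengths),
    )
    truth = {
        "sweep_windows": [list(w) for w in params.sweep_windows],
        "sites": truth_sites,
        "seed": seed,
    }
    return SweepSim(params, genome, genes, table, groups, truth)


# ---------------------------------------------------------------------------
# Methylation-arm generator


@dataclass
class MethylSimParams:
    contig_length: int = 200_000
    cpg_density: float = 1 / 25
    n_samples_per_group: int = 3
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0
    baseline_high: float = 0.85
    baseline_low: float = 0.05
    baseline_high_weight: float = 0.8
    dmr_baseline: float = 0.5  # baseline inside truth tiles, so +-delta/2 stays in [0,1]
    chg_chh_level: float = 0.006
    n_chg_chh_sites: int = 1000
    n_dmr_tiles: int = 40
    dmr_delta: float = 0.4
    tile_size: int = 200
    extreme_coverage_fraction: float = 0.0005
    extreme_coverage: int = 500
    group_labels: tuple[str, str] = ("accepts_diet", "refuses_diet")

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {"chrM1": self.contig_length}


@dataclass
class MethylSim:
    params: MethylSimParams
    genome: Genome
    genes: list[Gene]
    reports: dict[str, pd.DataFrame]
    groups: dict[str, str]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {
            "fasta": outdir / "reference.fa",
            "gff3": outdir / "genes.gff3",
            "groups": outdir / "groups.tsv",
            "truth_json": outdir / "truth.json",
            "truth_bed": outdir / "truth_tiles.bed",
        }
        write_fasta(self.genome, paths["fasta"])
        write_gff3(self.genes, paths["gff3"])
        paths["reports"] = {}
        for s, df in self.reports.items():
            p = outdir / f"{s}.cov.tsv"
            write_cytosine_report(df, p)
            paths["reports"][s] = p
        with open(paths["groups"], "w") as fh:
            for s, g in self.groups.items():
                fh.write(f"{s}\t{g}\n")
        with open(paths["truth_json"], "w") as fh:
            json.dump(self.truth, fh, indent=1)
        with open(paths["truth_bed"], "w") as fh:
            for t in self.truth["dmr_tiles"]:
                fh.write(f"{t['contig']}\t{t['start']}\t{t['end']}\t{t['direction']}\n")
        return paths


def simulate_methylomes(
    params: MethylSimParams | None = None, seed: int = 0
) -> MethylSim:
    """Binomial bisulfite counts over a CpG-seeded reference with planted
    tile-level differences.

    CpG baselines follow a bimodal vertebrate-like landscape (most sites
    highly methylated, a fraction near zero); inside truth tiles the
    baseline is 0.5 and the two groups sit at baseline +- delta/2.  CHG/CHH
    sites are emitted near zero methylation, and a small fraction of sites
    gets extreme coverage to exercise the percentile cap.
    """
    params = params or MethylSimParams()
    rng = np.random.default_rng(seed)
    genome, genes = simulate_reference_and_genes(
        params.contig_lengths,
        seed=int(rng.integers(2**31)),
        cpg_density=params.cpg_density,
    )
    contig = next(iter(params.contig_lengths))
    seq = genome[contig]

    # CpG dinucleotide positions: + strand C at i, - strand C at i+1
    cpg_pos = np.array(
        [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"],
        dtype=np.int64,
    )
    n_tiles = params.contig_length // params.tile_size
    dmr_idx = rng.choice(n_tiles, size=params.n_dmr_tiles, replace=False)
    signs = np.ones(params.n_dmr_tiles)
    signs[params.n_dmr_tiles // 2 :] = -1.0
    tile_delta = dict(zip(dmr_idx.tolist(), (signs * params.dmr_delta).tolist()))

    base_levels = np.where(
        rng.random(cpg_pos.size) < params.baseline_high_weight,
        np.clip(rng.normal(params.baseline_high, 0.05, cpg_pos.size), 0.0, 1.0),
        np.clip(rng.normal(params.baseline_low, 0.03, cpg_pos.size), 0.0, 1.0),
    )
    tile_of = cpg_pos // params.tile_size
    in_dmr = np.isin(tile_of, dmr_idx)
    base_levels[in_dmr] = params.dmr_baseline
    delta = np.array([tile_delta.get(int(t), 0.0) for t in tile_of])

    # sparse non-CpG cytosines (both strands), near-zero methylation
    non_cpg_plus = np.array(
        [
            i
            for i in range(0, len(seq) - 2, 37)
            if seq[i] == "C" and seq[i + 1] != "G"
        ],
        dtype=np.int64,
    )
    if non_cpg_plus.size > params.n_chg_chh_sites:
        non_cpg_plus = non_cpg_plus[
            rng.choice(non_cpg_plus.size, params.n_chg_chh_sites, replace=False)
        ]
        non_cpg_plus.sort()

    from .methylation import assign_context

    n = params.n_samples_per_group
    samples = [f"{params.group_labels[0]}_m{i + 1}" for i in range(n)] + [
        f"{params.group_labels[1]}_m{i + 1}" for i in range(n)
    ]
    groups = {s: params.group_labels[0] for s in samples[:n]}
    groups.update({s: params.group_labels[1] for s in samples[n:]})

    nb_n = params.depth_dispersion
    nb_p = nb_n / (nb_n + params.depth_mean)
    reports: dict[str, pd.DataFrame] = {}
    for si, sample in enumerate(samples):
        is_group1 = si < n
        level = np.clip(
            base_levels + (delta / 2.0 if is_group1 else -delta / 2.0), 0.0, 1.0
        )
        rows_pos, rows_strand, rows_ctx, rows_m, rows_u = [], [], [], [], []
        for strand_offset, strand in ((0, "+"), (1, "-")):
            pos = cpg_pos + strand_offset
            cov = rng.negative_binomial(nb_n, nb_p, size=pos.size)
            extreme = rng.random(pos.size) < params.extreme_coverage_fraction
            cov[extreme] = params.extreme_coverage
            meth = rng.binomial(cov, level)
            rows_pos.append(pos)
            rows_strand.append(np.full(pos.size, strand, dtype=object))
            rows_ctx.append(np.full(pos.size, "CG", dtype=object))
            rows_m.append(meth)
            rows_u.append(cov - meth)
        # non-CpG sites
        ctxs = [
            assign_context(genome, contig, int(p), "+") or "CHH"
            for p in non_cpg_plus
        ]
        cov = rng.negative_binomial(nb_n, nb_p, size=non_cpg_plus.size)
        meth = rng.binomial(cov, params.chg_chh_level)
        rows_pos.append(non_cpg_plus)
        rows_strand.append(np.full(non_cpg_plus.size, "+", dtype=object))
        rows_ctx.append(np.array(ctxs, dtype=object))
        rows_m.append(meth)
        rows_u.append(cov - meth)
        df = pd.DataFrame(
            {
                "contig": contig,
                "pos": np.concatenate(rows_pos),
                "strand": np.concatenate(rows_strand),
                "meth": np.concatenate(rows_m),
                "unmeth": np.concatenate(rows_u),
                "context": np.concatenate(rows_ctx),
            }
        ).sort_values(["pos", "strand"], kind="stable", ignore_index=True)
        reports[sample] = df

    truth = {
        "dmr_tiles": [
            {
                "contig": contig,
                "start": int(t) * params.tile_size,
                "end": (int(t) + 1) * params.tile_size,
                "delta": float(d),
                "direction": "hyper" if d > 0 else "hypo",
            }
            for t, d in sorted(tile_delta.items())
        ],
        "baseline_levels": {
            "pos": cpg_pos.tolist(),
            "level": [round(float(x), 6) for x in base_levels],
        },
        "seed": seed,
    }
    return MethylSim(params, genome, genes, reports, groups, truth)
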
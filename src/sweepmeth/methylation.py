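"""WGBS methylation analysis: site QC, context assignment, global summaries,
fixed-width tiling, per-tile group testing, DMR calling and gene-feature
mapping.

The per-tile test is the binomial-GLM likelihood-ratio test of a group
effect.  With a single binary covariate the maximum-likelihood fits are the
group-pooled methylation proportions, so the deviance is evaluated in closed
form; when either group contributes only one sample the test falls back to
Fisher's exact test on the pooled 2x2 table.  Multiple testing is controlled
with Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import COMPLEMENT, Gene, Genome

DMR_FEATURE_LABELS = (
    "promoter-2kb-upstream",
    "5utr-exon",
    "5utr-intron",
    "cds-exon",
    "intron",
    "3utr-exon",
    "downstream-1kb",
    "intergenic",
)


@dataclass
class MethylParams:
    min_site_depth: int = 10
    coverage_cap_percentile: float = 99.9  # per sample, after the depth filter
    tile_size: int = 200
    tile_step: int = 200
    min_diff: float = 25.0  # percentage points, strict
    max_q: float = 0.01  # strict
    min_covered_cytosines_per_tile: int = 3
    promoter_bp: int = 2000
    downstream_bp: int = 1000
    methylated_site_error_rate: float = 0.005
    methylated_site_alpha: float = 0.05
    tile_contexts: tuple[str, ...] = ("CG",)

    def __post_init__(self) -> None:
        if self.tile_step > self.tile_size:
            raise ValidationError("tile_step must be <= tile_size")
        if self.min_diff <= 0 or self.max_q <= 0:
            raise ValidationError("min_diff and max_q must be positive")


# ---------------------------------------------------------------------------
# Context assignment


def assign_context(
    genome: Genome, contig: str, pos: int, strand: str
) -> str | None:
    """Methylation context of the cytosine at ``pos`` (0-based).

    On the plus strand the two downstream bases are inspected; on the minus
    strand the reverse complement of the two upstream bases.  Returns CG,
    CHG or CHH, or None when the context runs off the contig or contains N.
    """
    seq = genome[contig]
    if strand == "+":
        ctx = seq[pos + 1 : pos + 3]
    elif strand == "-":
        ctx = seq[max(0, pos - 2) : pos].translate(COMPLEMENT)[::-1]
    else:
        raise ValidationError(f"invalid strand {strand!r}")
    if len(ctx) < 1 or ctx[0] == "N":
        return None
    if ctx[0] == "G":
        return "CG"
    if len(ctx) < 2 or ctx[1] == "N":
        return None
    return "CHG" if ctx[1] == "G" else "CHH"


# ---------------------------------------------------------------------------
# Dataset container


@dataclass
class MethylDataset:
    """Per-cytosine counts for a sample panel.

    ``meth``/``unmeth`` are (n_sites, n_samples) count matrices; ``covered``
    marks, per sample, the sites that survived the coverage filters.
    """

    samples: list[str]
    sites: pd.DataFrame  # columns contig, pos (0-based), strand, context
    meth: np.ndarray
    unmeth: np.ndarray
    covered: np.ndarray  # bool, same shape

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth


def combine_reports(reports: dict[str, pd.DataFrame]) -> MethylDataset:
    """Merge per-sample cytosine reports on (contig, pos, strand)."""
    samples = list(reports)
    keyed = []
    for s in samples:
        df = reports[s].set_index(["contig", "pos", "strand"])
        keyed.append(df)
    all_idx = keyed[0].index
    for df in keyed[1:]:
        all_idx = all_idx.union(df.index)
    all_idx = all_idx.sortlevel()[0] if hasattr(all_idx, "sortlevel") else all_idx
    n = len(all_idx)
    meth = np.zeros((n, len(samples)), dtype=np.int64)
    unmeth = np.zeros((n, len(samples)), dtype=np.int64)
    context = pd.Series(index=all_idx, dtype=object)
    for j, df in enumerate(keyed):
        sub = df.reindex(all_idx)
        meth[:, j] = sub["meth"].fillna(0).to_numpy(np.int64)
        unmeth[:, j] = sub["unmeth"].fillna(0).to_numpy(np.int64)
        context = context.where(context.notna(), sub["context"])
    sites = pd.DataFrame(
        {
            "contig": all_idx.get_level_values(0),
            "pos": all_idx.get_level_values(1),
            "strand": all_idx.get_level_values(2),
            "context": context.to_numpy(object),
        }
    )
    covered = (meth + unmeth) > 0
    return MethylDataset(samples, sites, meth, unmeth, covered)


def filter_cytosines(
    ds: MethylDataset, params: MethylParams | None = None
) -> tuple[MethylDataset, dict]:
    """Apply the per-sample depth floor and coverage-percentile cap.

    Per sample, sites below min_site_depth are dropped; the coverage
    percentile is then computed over that sample's remaining sites and sites
    with coverage strictly above it are dropped.  A site survives for group
    analysis only in samples where it passed.
    """
    params = params or MethylParams()
    cov = ds.coverage
    report: dict = {"per_sample": {}}
    covered = np.zeros_like(ds.covered)
    for j, sample in enumerate(ds.samples):
        c = cov[:, j]
        pass_depth = c >= params.min_site_depth
        if not pass_depth.any():
            raise ValidationError(
                f"sample {sample!r} has no sites at depth >= {params.min_site_depth}"
            )
        cap = float(np.percentile(c[pass_depth], params.coverage_cap_percentile))
        keep = pass_depth & (c <= cap)
        covered[:, j] = keep
        report["per_sample"][sample] = {
            "n_input": int((c > 0).sum()),
            "n_below_depth": int(((c > 0) & ~pass_depth).sum()),
            "coverage_cap": cap,
            "n_capped": int((pass_depth & ~keep).sum()),
            "n_retained": int(keep.sum()),
        }
    out = MethylDataset(ds.samples, ds.sites, ds.meth, ds.unmeth, covered)
    return out, report


# ---------------------------------------------------------------------------
# Global summaries


def global_summary(
    ds: MethylDataset,
    genome: Genome,
    groups: dict[str, str],
    params: MethylParams | None = None,
) -> dict:
    """Per-group methylated-cytosine percentage and per-context levels.

    A covered site counts as methylated when a one-sided binomial test of
    its pooled methylated calls against the bisulfite error rate survives
    Benjamini-Hochberg adjustment.  The percentage denominator is the number
    of cytosines in the reference (C and G bases, i.e. both strands).
    Context levels are reported call-weighted (pooled counts) and
    site-averaged.
    """
    params = params or MethylParams()
    n_genomic_c = sum(
        seq.count("C") + seq.count("G") for seq in genome.sequences.values()
    )
    labels = list(dict.fromkeys(groups.values()))
    col = {s: j for j, s in enumerate(ds.samples)}
    out: dict = {"n_genomic_cytosines": n_genomic_c, "groups": {}}
    contexts = ds.sites["context"].to_numpy(object)
    for label in labels:
        idx = [col[s] for s, g in groups.items() if g == label]
        m = np.where(ds.covered[:, idx], ds.meth[:, idx], 0).sum(axis=1)
        u = np.where(ds.covered[:, idx], ds.unmeth[:, idx], 0).sum(axis=1)
        cov = m + u
        has = cov > 0
        pvals = stats.binom.sf(
            m[has] - 1, cov[has], params.methylated_site_error_rate
        )
        if pvals.size:
            rej = multipletests(pvals, params.methylated_site_alpha, "fdr_bh")[0]
        else:
            rej = np.zeros(0, dtype=bool)
        methylated = np.zeros(ds.n_sites, dtype=bool)
        methylated[np.flatnonzero(has)] = rej
        ctx_levels = {}
        for ctx in ("CG", "CHG", "CHH"):
            sel = has & (contexts == ctx)
            calls = cov[sel].sum()
            cw = float(m[sel].sum() / calls) if calls else float("nan")
            sa = float(np.mean(m[sel] / cov[sel])) if sel.any() else float("nan")
            ctx_levels[ctx] = {
                "call_weighted": cw,
                "site_averaged": sa,
                "n_sites": int(sel.sum()),
            }
        out["groups"][label] = {
            "n_covered_sites": int(has.sum()),
            "n_methylated_sites": int(methylated.sum()),
            "pct_methylated_of_genomic": 100.0 * methylated.sum() / n_genomic_c,
            "context_levels": ctx_levels,
        }
    return out


# ---------------------------------------------------------------------------
# Tiling


@dataclass
class TileSet:
    """Fixed-width tiles with per-sample pooled counts."""

    samples: list[str]
    tiles: pd.DataFrame  # contig, start, end, n_cytosines
    meth: np.ndarray  # (n_tiles, n_samples)
    unmeth: np.ndarray
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)


def tile_counts(ds: MethylDataset, params: MethylParams | None = None) -> TileSet:
    """Pool per-sample counts over the surviving cytosines of each tile.

    Only contexts in params.tile_contexts enter the tiles (CpG by default;
    both strands of a CpG pool into the same tile).  Tiles where any sample
    has fewer than min_covered_cytosines_per_tile covered cytosines are
    excluded from testing.
    """
    params = params or MethylParams()
    in_ctx = ds.sites["context"].isin(params.tile_contexts).to_numpy()
    rows = []
    meth_rows = []
    unmeth_rows = []
    pos = ds.sites["pos"].to_numpy(np.int64)
    for contig in dict.fromkeys(ds.sites["contig"]):
        on_contig = (ds.sites["contig"] == contig).to_numpy() & in_ctx
        if not on_contig.any():
            continue
        max_pos = int(pos[on_contig].max())
        start = 0
        while start <= max_pos:
            end = start + params.tile_size
            sel = on_contig & (pos >= start) & (pos < end)
            if sel.any():
                cov_counts = ds.covered[sel].sum(axis=0)  # covered Cs per sample
                m = np.where(ds.covered[sel], ds.meth[sel], 0).sum(axis=0)
                u = np.where(ds.covered[sel], ds.unmeth[sel], 0).sum(axis=0)
                if cov_counts.min() >= params.min_covered_cytosines_per_tile:
                    rows.append(
                        {
                            "contig": contig,
                            "start": start,
                            "end": end,
                            "n_cytosines": int(sel.sum()),
                        }
                    )
                    meth_rows.append(m)
                    unmeth_rows.append(u)
            start += params.tile_step
    n = len(rows)
    return TileSet(
        ds.samples,
        pd.DataFrame(rows, columns=["contig", "start", "end", "n_cytosines"]),
        np.vstack(meth_rows) if n else np.empty((0, len(ds.samples)), np.int64),
        np.vstack(unmeth_rows) if n else np.empty((0, len(ds.samples)), np.int64),
    )


# ---------------------------------------------------------------------------
# Group test


def _binom_ll(m: float, u: float, p: float) -> float:
    ll = 0.0
    if m > 0:
        ll += m * math.log(p)
    if u > 0:
        ll += u * math.log(1.0 - p)
    return ll


def tile_test(
    meth1: np.ndarray, unmeth1: np.ndarray,
    meth2: np.ndarray, unmeth2: np.ndarray,
) -> tuple[float, bool]:
    """Likelihood-ratio p-value for a group difference in one tile.

    The binomial GLM with a single group indicator has group-pooled
    proportions as its maximum-likelihood fit, so the likelihood-ratio
    statistic against the intercept-only model is computed in closed form
    and referred to chi-square on 1 df.  When either group has exactly one
    contributing sample the pooled 2x2 Fisher exact test is used instead
    (returned flag True).
    """
    meth1, unmeth1 = np.asarray(meth1, float), np.asarray(unmeth1, float)
    meth2, unmeth2 = np.asarray(meth2, float), np.asarray(unmeth2, float)
    contrib1 = (meth1 + unmeth1) > 0
    contrib2 = (meth2 + unmeth2) > 0
    if not contrib1.any() or not contrib2.any():
        raise ValidationError("tile_test needs >= 1 covered sample per group")
    m1, u1 = meth1.sum(), unmeth1.sum()
    m2, u2 = meth2.sum(), unmeth2.sum()
    if contrib1.sum() == 1 or contrib2.sum() == 1:
        table = [[m1, u1], [m2, u2]]
        return float(stats.fisher_exact(table)[1]), True
    p1 = m1 / (m1 + u1)
    p2 = m2 / (m2 + u2)
    p0 = (m1 + m2) / (m1 + u1 + m2 + u2)
    g = 2.0 * (
        _binom_ll(m1, u1, p1) + _binom_ll(m2, u2, p2) - _binom_ll(m1 + m2, u1 + u2, p0)
    )
    g = max(g, 0.0)
    return float(stats.chi2.sf(g, 1)), False


def test_tiles(
    tiles: TileSet, groups: dict[str, str]
) -> pd.DataFrame:
    """Per-tile group means, difference and likelihood-ratio p-value.

    Group means are coverage-weighted (pooled counts across the group's
    samples); diff = group1 - group2 where group1 is the first label in the
    groups table.
    """
    labels = list(dict.fromkeys(groups.values()))
    if len(labels) != 2:
        raise ValidationError(f"exactly 2 group labels required, found {labels}")
    col = {s: j for j, s in enumerate(tiles.samples)}
    idx1 = [col[s] for s, g in groups.items() if g == labels[0]]
    idx2 = [col[s] for s, g in groups.items() if g == labels[1]]
    m1 = tiles.meth[:, idx1]
    u1 = tiles.unmeth[:, idx1]
    m2 = tiles.meth[:, idx2]
    u2 = tiles.unmeth[:, idx2]
    out = tiles.tiles.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["m1"] = m1.sum(axis=1) / (m1.sum(axis=1) + u1.sum(axis=1))
        out["m2"] = m2.sum(axis=1) / (m2.sum(axis=1) + u2.sum(axis=1))
    out["diff"] = out["m1"] - out["m2"]
    ps = np.empty(len(out))
    fallback = np.zeros(len(out), dtype=bool)
    for i in range(len(out)):
        ps[i], fallback[i] = tile_test(m1[i], u1[i], m2[i], u2[i])
    out["p"] = ps
    out["fisher_fallback"] = fallback
    return out


def adjust_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dmrs(
    tested: pd.DataFrame, params: MethylParams | None = None
) -> tuple[pd.DataFrame, dict]:
    """Classify tested tiles as hyper / hypo / ns.

    hyper: diff > min_diff/100 and q < max_q (group1 more methylated);
    hypo is the mirror image; both thresholds strict.
    """
    params = params or MethylParams()
    out = tested.copy()
    out["q"] = adjust_fdr(out["p"].to_numpy())
    thr = params.min_diff / 100.0
    status = np.full(len(out), "ns", dtype=object)
    sig = out["q"].to_numpy() < params.max_q
    status[sig & (out["diff"].to_numpy() > thr)] = "hyper"
    status[sig & (out["diff"].to_numpy() < -thr)] = "hypo"
    out["status"] = status
    counts = {
        "hyper": int((status == "hyper").sum()),
        "hypo": int((status == "hypo").sum()),
        "ns": int((status == "ns").sum()),
        "total_dmrs": int((status != "ns").sum()),
        "tested": len(out),
    }
    return out, counts


# ---------------------------------------------------------------------------
# Gene-feature mapping


def _overlaps(s1: int, e1: int, s2: int, e2: int) -> bool:
    return s1 < e2 and e1 > s2


def dmr_gene_features(
    contig: str, start: int, end: int,
    genes: list[Gene], params: MethylParams | None = None,
) -> list[tuple[str, str]]:
    """Map a DMR interval to gene features, strand-aware.

    Returns (gene_id, label) pairs; labels come from DMR_FEATURE_LABELS.  A
    DMR overlapping several features carries one label per feature; a DMR
    touching no gene (within the promoter/downstream reach) is intergenic.
    An intron lying entirely 5' of the translation start is a 5'UTR intron.
    """
    params = params or MethylParams()
    out: list[tuple[str, str]] = []
    for g in genes:
        if g.contig != contig:
            continue
        if g.strand == "+":
            promoter = (g.start - params.promoter_bp, g.start)
            down = (g.end, g.end + params.downstream_bp)
        else:
            promoter = (g.end, g.end + params.promoter_bp)
            down = (g.start - params.downstream_bp, g.start)
        labels: set[str] = set()
        if _overlaps(start, end, *promoter):
            labels.add("promoter-2kb-upstream")
        if _overlaps(start, end, *down):
            labels.add("downstream-1kb")
        for tx in g.transcripts:
            for s, e in tx.utr5:
                if _overlaps(start, end, s, e):
                    labels.add("5utr-exon")
            for s, e in tx.utr3:
                if _overlaps(start, end, s, e):
                    labels.add("3utr-exon")
            for s, e in tx.cds:
                if _overlaps(start, end, s, e):
                    labels.add("cds-exon")
            if tx.cds:
                cds_lo = min(s for s, _ in tx.cds)
                cds_hi = max(e for _, e in tx.cds)
            else:
                cds_lo = cds_hi = None
            for s, e in tx.introns:
                if _overlaps(start, end, s, e):
                    if cds_lo is not None and (
                        (g.strand == "+" and e <= cds_lo)
                        or (g.strand == "-" and s >= cds_hi)
                    ):
                        labels.add("5utr-intron")
                    else:
                        labels.add("intron")
        out.extend((g.gene_id, lab) for lab in sorted(labels))
    if not out:
        out.append(("", "intergenic"))
    return out


def map_dmr_features(
    dmrs: pd.DataFrame, genes: list[Gene], params: MethylParams | None = None
) -> pd.DataFrame:
    """Feature-map every DMR row (status != ns) of a called tile table."""
    params = params or MethylParams()
    rows = []
    for _, r in dmrs[dmrs["status"] != "ns"].iterrows():
        feats = dmr_gene_features(
            r["contig"], int(r["start"]), int(r["end"]), genes, params
        )
        for gene_id, label in feats:
            rows.append(
                {
                    "contig": r["contig"],
                    "start": int(r["start"]),
                    "end": int(r["end"]),
                    "status": r["status"],
                    "diff": r["diff"],
                    "q": r["q"],
                    "gene": gene_id,
                    "feature": label,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["contig", "start", "end", "status", "diff", "q", "gene", "feature"],
    )
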
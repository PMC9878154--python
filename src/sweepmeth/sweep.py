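"""Sliding-window selective-sweep scan.

For each window the scan reports the pooled heterozygosity Hp of each group,

    Hp = 2 * sum(nMAJ) * sum(nMIN) / (sum(nMAJ) + sum(nMIN))^2,

with per-SNP major/minor allele counts summed over the window, and the
two-population Weir-Cockerham (1984) Fst as the ratio of summed variance
components a / (a + b + c).  Candidate swept regions are windows that are
simultaneously in the extreme empirical tails of Hp and Fst.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import Gene, VariantTable


@dataclass
class WindowSpec:
    size: int = 100_000
    step: int = 50_000
    min_snps: int = 10

    def __post_init__(self) -> None:
        if self.step > self.size:
            raise ValidationError("window step must be <= window size")
        if self.min_snps < 1:
            raise ValidationError("min_snps must be >= 1")


@dataclass
class SweepThresholds:
    """Empirical-quantile outlier rules.

    hp_tail selects whether low or high Hp counts as an outlier (a sweep
    depletes diversity, so the default is the low tail of the selected
    group's Hp); hp_group selects which group's Hp is ranked.
    report_quantile adds an auxiliary high-tail Fst threshold to the report.
    """

    hp_quantile: float = 0.10
    fst_quantile: float = 0.10
    hp_tail: str = "low"
    hp_group: int = 1  # 1-based group index
    report_quantile: float = 0.05

    def __post_init__(self) -> None:
        for q in (self.hp_quantile, self.fst_quantile, self.report_quantile):
            if not 0.0 < q < 1.0:
                raise ValidationError("quantiles must lie in (0, 1)")
        if self.hp_tail not in ("low", "high"):
            raise ValidationError("hp_tail must be 'low' or 'high'")
        if self.hp_group not in (1, 2):
            raise ValidationError("hp_group must be 1 or 2")


def make_windows(
    contig_lengths: dict[str, int], spec: WindowSpec
) -> list[tuple[str, int, int]]:
    """Sliding windows starting at 0, step, 2*step, ... while start < length;
    the trailing window is truncated at the contig end."""
    windows = []
    for contig, length in contig_lengths.items():
        if length <= 0:
            raise ValidationError(f"contig {contig} has non-positive length")
        start = 0
        while start < length:
            windows.append((contig, start, min(start + spec.size, length)))
            start += spec.step
    return windows


def pooled_hp(nmaj: np.ndarray, nmin: np.ndarray) -> float:
    """Pooled heterozygosity from per-SNP major/minor allele counts."""
    smaj = float(np.sum(nmaj))
    smin = float(np.sum(nmin))
    tot = smaj + smin
    if tot == 0:
        return float("nan")
    return 2.0 * smaj * smin / (tot * tot)


def wc_fst_components(
    gt: np.ndarray, group1: np.ndarray, group2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham (1984) variance components for two groups.

    gt is the (n_sites, n_samples) dosage matrix with -1 missing.  A site
    contributes only when both groups have >= 2 non-missing diploid
    genotypes.  Returns (a, b, c, valid) arrays; a+b+c is the per-site
    denominator contribution.
    """
    r = 2.0
    a_out = np.zeros(gt.shape[0])
    b_out = np.zeros(gt.shape[0])
    c_out = np.zeros(gt.shape[0])

    g1 = gt[:, group1]
    g2 = gt[:, group2]
    n1 = (g1 >= 0).sum(axis=1).astype(float)  # diploid individuals
    n2 = (g2 >= 0).sum(axis=1).astype(float)
    valid = (n1 >= 2) & (n2 >= 2)

    ac1 = np.where(g1 >= 0, g1, 0).sum(axis=1).astype(float)
    ac2 = np.where(g2 >= 0, g2, 0).sum(axis=1).astype(float)
    het1 = (g1 == 1).sum(axis=1).astype(float)
    het2 = (g2 == 1).sum(axis=1).astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = ac1 / (2.0 * n1)
        p2 = ac2 / (2.0 * n2)
        nbar = (n1 + n2) / r
        nsum = n1 + n2
        nc = (nsum - (n1**2 + n2**2) / nsum) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / nsum
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (het1 + het2) / nsum
        inner = pbar * (1.0 - pbar) - s2 * (r - 1.0) / r
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
        c = hbar / 2.0

    valid &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    a_out[valid] = a[valid]
    b_out[valid] = b[valid]
    c_out[valid] = c[valid]
    return a_out, b_out, c_out, valid


def hudson_fst_components(
    gt: np.ndarray, group1: np.ndarray, group2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Hudson Fst components (numerator, denominator, valid).

    Hudson's estimator with the standard sample-size correction:
    N = (p1-p2)^2 - p1(1-p1)/(a1-1) - p2(1-p2)/(a2-1), D = p1(1-p2)+p2(1-p1)
    with a_i the number of called alleles.  Offered as a sensitivity check
    next to the default Weir-Cockerham estimator; windows combine sites as
    a ratio of sums.
    """
    g1 = gt[:, group1]
    g2 = gt[:, group2]
    a1 = 2.0 * (g1 >= 0).sum(axis=1)
    a2 = 2.0 * (g2 >= 0).sum(axis=1)
    valid = (a1 >= 4) & (a2 >= 4)
    ac1 = np.where(g1 >= 0, g1, 0).sum(axis=1).astype(float)
    ac2 = np.where(g2 >= 0, g2, 0).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = ac1 / a1
        p2 = ac2 / a2
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (a1 - 1)
            - p2 * (1 - p2) / (a2 - 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(valid, num, 0.0)
    den = np.where(valid, den, 0.0)
    return num, den, valid


def _group_allele_counts(gt_group: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (nMAJ, nMIN) allele counts within one group."""
    called = gt_group >= 0
    n_alleles = 2 * called.sum(axis=1)
    alt = np.where(called, gt_group, 0).sum(axis=1)
    ref = n_alleles - alt
    return np.maximum(ref, alt).astype(float), np.minimum(ref, alt).astype(float)


def scan_windows(
    table: VariantTable,
    groups: dict[str, str],
    contig_lengths: dict[str, int],
    spec: WindowSpec | None = None,
    estimator: str = "wc",
) -> pd.DataFrame:
    """Compute per-window SNP counts, per-group Hp and windowed Fst.

    The default Fst estimator is Weir-Cockerham (1984); estimator='hudson'
    switches to Hudson's for sensitivity analysis.  Returns a DataFrame
    with one row per window; windows with fewer than min_snps SNPs are kept
    but flagged analyzed=False and carry NaN statistics.
    """
    spec = spec or WindowSpec()
    if estimator not in ("wc", "hudson"):
        raise ValidationError("estimator must be 'wc' or 'hudson'")
    labels = list(dict.fromkeys(groups.values()))
    if len(labels) != 2:
        raise ValidationError(f"exactly 2 group labels required, found {labels}")
    sample_idx = {s: i for i, s in enumerate(table.samples)}
    missing = [s for s in groups if s not in sample_idx]
    if missing:
        raise ValidationError(f"samples in groups file absent from VCF: {missing}")
    group1 = np.array([sample_idx[s] for s, g in groups.items() if g == labels[0]])
    group2 = np.array([sample_idx[s] for s, g in groups.items() if g == labels[1]])

    if estimator == "wc":
        a, b, c, valid = wc_fst_components(table.gt, group1, group2)
        abc = a + b + c
    else:
        a, abc, valid = hudson_fst_components(table.gt, group1, group2)
    maj1, min1 = _group_allele_counts(table.gt[:, group1])
    maj2, min2 = _group_allele_counts(table.gt[:, group2])

    windows = make_windows(contig_lengths, spec)
    rows = []
    pos = table.pos
    contig = table.contig
    # per-contig sorted index for fast window slicing
    order = np.lexsort((pos, contig.astype(str)))
    by_contig: dict[str, np.ndarray] = {}
    for name in contig_lengths:
        sel = order[contig[order].astype(str) == name]
        by_contig[name] = sel
    for (cname, start, end) in windows:
        sel = by_contig.get(cname, np.array([], dtype=int))
        if sel.size:
            p = pos[sel]
            sub = sel[(p >= start) & (p < end)]
        else:
            sub = sel
        n_snps = int(sub.size)
        row = {
            "contig": cname, "start": start, "end": end, "n_snps": n_snps,
            "hp_group1": np.nan, "hp_group2": np.nan,
            "fst": np.nan, "fst_num": np.nan, "fst_den": np.nan,
            "analyzed": False,
        }
        if n_snps >= spec.min_snps:
            row["hp_group1"] = pooled_hp(maj1[sub], min1[sub])
            row["hp_group2"] = pooled_hp(maj2[sub], min2[sub])
            vsub = sub[valid[sub]]
            num = float(a[vsub].sum())
            den = float(abc[vsub].sum())
            row["fst_num"] = num
            row["fst_den"] = den
            if den != 0.0 and vsub.size > 0 and not (
                math.isnan(row["hp_group1"]) or math.isnan(row["hp_group2"])
            ):
                row["fst"] = num / den
                row["analyzed"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def empirical_threshold(
    values: np.ndarray, q: float, direction: str = "high"
) -> tuple[float, int]:
    """Empirical tail threshold and the count of values strictly beyond it.

    For direction='high' the threshold is the order statistic at 1-based rank
    ceil((1-q)*N) of the ascending sort; n_beyond counts values strictly
    beyond the threshold (equal to N - ceil((1-q)*N) when values are
    distinct).  The low tail is the mirror image.  Ties share the threshold
    value and are not counted as beyond.
    """
    if not 0.0 < q < 1.0:
        raise ValidationError("tail fraction q must lie in (0, 1)")
    vals = np.sort(np.asarray(values, dtype=float))
    vals = vals[np.isfinite(vals)]
    n = vals.size
    if n == 0:
        raise ValidationError("empirical_threshold needs >= 1 finite value")
    rank = math.ceil((1.0 - q) * n)  # 1-based
    rank = min(max(rank, 1), n)
    if direction == "high":
        threshold = float(vals[rank - 1])
        n_beyond = int((vals > threshold).sum())
    elif direction == "low":
        threshold = float(vals[n - rank])
        n_beyond = int((vals < threshold).sum())
    else:
        raise ValidationError("direction must be 'high' or 'low'")
    return threshold, n_beyond


def select_candidates(
    windows: pd.DataFrame, thresholds: SweepThresholds | None = None
) -> tuple[pd.DataFrame, dict]:
    """Flag Hp and Fst outlier windows and their conjunction as candidates.

    Fst outliers are the strict high tail; Hp outliers follow hp_tail on the
    configured group's Hp.  Returns the annotated window table and a report
    holding the thresholds, including the auxiliary report_quantile Fst
    threshold and count.
    """
    thresholds = thresholds or SweepThresholds()
    out = windows.copy()
    analyzed = out["analyzed"].to_numpy(bool)
    if analyzed.sum() < 10:
        import logging

        logging.getLogger(__name__).warning(
            "only %d analyzed windows; empirical quantiles are unstable",
            int(analyzed.sum()),
        )
    hp_col = f"hp_group{thresholds.hp_group}"
    hp_vals = out.loc[analyzed, hp_col].to_numpy(float)
    fst_vals = out.loc[analyzed, "fst"].to_numpy(float)
    hp_thr, _ = empirical_threshold(hp_vals, thresholds.hp_quantile, thresholds.hp_tail)
    fst_thr, _ = empirical_threshold(fst_vals, thresholds.fst_quantile, "high")
    aux_thr, aux_n = empirical_threshold(fst_vals, thresholds.report_quantile, "high")

    hp_out = np.zeros(len(out), dtype=bool)
    fst_out = np.zeros(len(out), dtype=bool)
    if thresholds.hp_tail == "low":
        hp_out[analyzed] = out.loc[analyzed, hp_col].to_numpy(float) < hp_thr
    else:
        hp_out[analyzed] = out.loc[analyzed, hp_col].to_numpy(float) > hp_thr
    fst_out[analyzed] = out.loc[analyzed, "fst"].to_numpy(float) > fst_thr
    out["hp_outlier"] = hp_out
    out["fst_outlier"] = fst_out
    out["candidate"] = hp_out & fst_out
    report = {
        "n_analyzed": int(analyzed.sum()),
        "hp_threshold": hp_thr,
        "hp_tail": thresholds.hp_tail,
        "hp_group": thresholds.hp_group,
        "fst_threshold": fst_thr,
        "n_candidates": int(out["candidate"].sum()),
        "report_fst_quantile": thresholds.report_quantile,
        "report_fst_threshold": aux_thr,
        "report_fst_n_beyond": aux_n,
    }
    return out, report


def genes_in_windows(
    candidates: pd.DataFrame, genes: list[Gene]
) -> list[str]:
    """Genes whose span intersects any candidate window, deduplicated."""
    cand = candidates[candidates.get("candidate", True) == True]  # noqa: E712
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for _, row in cand.iterrows():
        by_contig.setdefault(row["contig"], []).append(
            (int(row["start"]), int(row["end"]))
        )
    hits = []
    for g in genes:
        for s, e in by_contig.get(g.contig, []):
            if g.start < e and g.end > s:
                hits.append(g.gene_id)
                break
    return hits
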
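"""Genotype and site-level SNP quality control.

The filter stage masks individual genotypes that fail read-depth or
genotype-quality thresholds, then removes whole sites by missing rate and
minor allele frequency.  Masking precedes the site-level filters so that a
genotype failing DP/GQ contributes to the missing rate but never to allele
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import VariantTable


@dataclass
class QcParams:
    """Thresholds for the SNP filter.

    min_depth and min_gq are inclusive per-genotype bounds; the missing-rate
    bound is strict (< max_missing_rate) while the MAF bound is inclusive
    (>= min_maf).
    """

    min_depth: int = 4
    min_gq: int = 10
    max_missing_rate: float = 0.1
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ValidationError("max_missing_rate must be in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValidationError("min_maf must be in [0, 0.5]")
        if self.min_depth < 0 or self.min_gq < 0:
            raise ValidationError("min_depth and min_gq must be non-negative")


@dataclass
class QcReport:
    """Per-reason removal counts; reasons applied in order."""

    n_input: int = 0
    n_masked_genotypes: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {"all-missing": 0, "missing-rate": 0, "MAF": 0}
    )
    n_retained: int = 0

    def to_rows(self) -> list[dict]:
        rows = [
            {"metric": "sites_input", "value": self.n_input},
            {"metric": "genotypes_masked", "value": self.n_masked_genotypes},
        ]
        rows += [
            {"metric": f"removed_{k}", "value": v} for k, v in self.removed.items()
        ]
        rows.append({"metric": "sites_retained", "value": self.n_retained})
        return rows


def mask_genotypes(table: VariantTable, params: QcParams) -> VariantTable:
    """Set genotypes with DP < min_depth or GQ < min_gq to missing.

    Site-level fields are untouched; bounds are inclusive (DP >= min_depth
    and GQ >= min_gq are retained).
    """
    gt = table.gt.copy()
    called = gt >= 0
    fail = called & ((table.dp < params.min_depth) | (table.gq < params.min_gq))
    gt[fail] = -1
    out = table.subset(np.ones(table.n_sites, dtype=bool))
    out.gt = gt
    return out


def compute_maf(gt_row: np.ndarray) -> float:
    """Minor allele frequency from one site's dosages (-1 = missing).

    MAF = min(f_alt, 1 - f_alt) with f_alt = sum(dosage) / (2 * n_nonmissing).
    Returns NaN when every genotype is missing.
    """
    called = gt_row >= 0
    n = int(called.sum())
    if n == 0:
        return float("nan")
    f_alt = float(gt_row[called].sum()) / (2 * n)
    return min(f_alt, 1.0 - f_alt)


def _site_stats(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (missing_rate, maf) across sites; maf NaN when all missing."""
    called = gt >= 0
    n_called = called.sum(axis=1)
    missing_rate = 1.0 - n_called / gt.shape[1]
    alt = np.where(called, gt, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_alt = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    maf = np.minimum(f_alt, 1.0 - f_alt)
    return missing_rate, maf


def filter_sites(
    table: VariantTable, params: QcParams, pre_masked: bool = False
) -> tuple[VariantTable, QcReport]:
    """Mask genotypes, then keep sites with missing_rate < max_missing_rate
    and MAF >= min_maf.

    Removal reasons are counted in order: all-missing, missing-rate, MAF
    (a site is charged to the first reason it fails).
    """
    report = QcReport(n_input=table.n_sites)
    masked = table if pre_masked else mask_genotypes(table, params)
    report.n_masked_genotypes = int(
        ((table.gt >= 0) & (masked.gt < 0)).sum()
    )
    missing_rate, maf = _site_stats(masked.gt)
    all_missing = np.isnan(maf)
    fail_missing = (~all_missing) & (missing_rate >= params.max_missing_rate)
    fail_maf = (~all_missing) & (~fail_missing) & (maf < params.min_maf)
    keep = ~(all_missing | fail_missing | fail_maf)
    report.removed["all-missing"] = int(all_missing.sum())
    report.removed["missing-rate"] = int(fail_missing.sum())
    report.removed["MAF"] = int(fail_maf.sum())
    report.n_retained = int(keep.sum())
    return masked.subset(keep), report
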
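"""Config-driven end-to-end runs of the two analysis arms.

Each run writes its artifacts into the output directory together with a
manifest recording the package version, every parameter value and an MD5
checksum of every input file, so a rerun with an identical config is
byte-reproducible and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation import AnnotationParams, annotate_table, summarize_annotation
from .enrichment import hypergeom_enrich, read_term_map
from .errors import ValidationError
from .io import (
    read_cytosine_report,
    read_fasta,
    read_gff3,
    read_groups,
    read_vcf,
    write_table,
    write_vcf,
)
from .methylation import (
    MethylParams,
    call_dmrs,
    combine_reports,
    filter_cytosines,
    global_summary,
    map_dmr_features,
    test_tiles,
    tile_counts,
)
from .qc import QcParams, filter_sites
from .sweep import (
    SweepThresholds,
    WindowSpec,
    genes_in_windows,
    scan_windows,
    select_candidates,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    vcf: str | None = None
    fasta: str | None = None
    gff3: str | None = None
    groups: str | None = None
    reports: dict[str, str] = field(default_factory=dict)  # sample -> path
    term_map: str | None = None
    outdir: str = "results"
    qc: QcParams = field(default_factory=QcParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    window: WindowSpec = field(default_factory=WindowSpec)
    thresholds: SweepThresholds = field(default_factory=SweepThresholds)
    methyl: MethylParams = field(default_factory=MethylParams)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, klass in (
            ("qc", QcParams),
            ("annotation", AnnotationParams),
            ("window", WindowSpec),
            ("thresholds", SweepThresholds),
            ("methyl", MethylParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)

    def validate(self, require: tuple[str, ...]) -> None:
        for name in require:
            value = getattr(self, name)
            if not value:
                raise ValidationError(f"config is missing required path {name!r}")
            paths = value.values() if isinstance(value, dict) else [value]
            for p in paths:
                if not Path(p).exists():
                    raise ValidationError(f"{name} path does not exist: {p}")


def _md5(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_dict(obj) -> dict:
    return dataclasses.asdict(obj)


def _write_manifest(config: PipelineConfig, outdir: Path, inputs: dict[str, str],
                    stages: dict) -> None:
    manifest = {
        "package_version": __version__,
        "parameters": {
            "qc": _params_dict(config.qc),
            "annotation": _params_dict(config.annotation),
            "window": _params_dict(config.window),
            "thresholds": _params_dict(config.thresholds),
            "methyl": _params_dict(config.methyl),
            "seed": config.seed,
        },
        "input_checksums": {k: _md5(v) for k, v in inputs.items()},
        "stages": stages,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def run_sweep_pipeline(config: PipelineConfig) -> dict:
    """QC -> annotate -> windowed Hp/Fst scan -> candidates -> genes ->
    optional enrichment; every artifact written under config.outdir."""
    config.validate(("vcf", "groups"))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {"vcf": config.vcf, "groups": config.groups}

    groups = read_groups(config.groups)
    table = read_vcf(config.vcf)
    stages: dict = {"read_vcf": {"sites": table.n_sites, "skipped": table.skipped}}

    filtered, qc_report = filter_sites(table, config.qc)
    write_table(qc_report.to_rows(), outdir / "qc_report.tsv", "annotation_tsv")
    write_vcf(filtered, outdir / "filtered.vcf")
    stages["qc"] = {
        "masked_genotypes": qc_report.n_masked_genotypes,
        "removed": qc_report.removed,
        "retained": qc_report.n_retained,
    }

    genes = genome = None
    if config.gff3 and config.fasta:
        config.validate(("gff3", "fasta"))
        inputs["gff3"] = config.gff3
        inputs["fasta"] = config.fasta
        genome = read_fasta(config.fasta)
        genes = read_gff3(config.gff3, genome.lengths)
        annotations = annotate_table(filtered, genes, genome, config.annotation)
        summary = summarize_annotation(annotations)
        rows = [
            {
                "contig": a.contig, "pos": a.pos + 1, "ref": a.ref, "alt": a.alt,
                "category": a.category, "genes": ",".join(a.genes),
                "is_transition": a.is_transition,
            }
            for a in annotations
        ]
        write_table(rows, outdir / "annotation.tsv", "annotation_tsv")
        cat = summary["categories"].copy()
        write_table(cat, outdir / "annotation_summary.tsv", "annotation_tsv")
        stages["annotation"] = {
            "total": summary["total"], "ts": summary["ts"], "tv": summary["tv"],
            "ts_tv_ratio": summary["ts_tv_ratio"],
        }

    if config.fasta:
        config.validate(("fasta",))
        inputs["fasta"] = config.fasta
        genome = genome or read_fasta(config.fasta)
        contig_lengths = genome.lengths
    elif table.contig_lengths:
        contig_lengths = table.contig_lengths
    else:
        raise ValidationError(
            "contig lengths unavailable: provide a FASTA or a VCF with "
            "contig length headers"
        )

    windows = scan_windows(filtered, groups, contig_lengths, config.window)
    windows, sweep_report = select_candidates(windows, config.thresholds)
    write_table(windows, outdir / "windows.tsv", "window_tsv")
    cand = windows[windows["candidate"]]
    write_table(cand, outdir / "candidates.bed", "bed")
    stages["sweep"] = sweep_report

    gene_list: list[str] = []
    if genes is not None:
        gene_list = genes_in_windows(cand, genes)
        (outdir / "genes.txt").write_text("".join(g + "\n" for g in gene_list))
        stages["genes"] = {"n_candidate_genes": len(gene_list)}

    if config.term_map and genes is not None:
        config.validate(("term_map",))
        inputs["term_map"] = config.term_map
        term_map = read_term_map(config.term_map)
        population = {g.gene_id for g in genes}
        enr = hypergeom_enrich(set(gene_list), population, term_map)
        write_table(enr, outdir / "enrichment.tsv", "annotation_tsv")
        stages["enrichment"] = {"n_terms": len(enr)}

    _write_manifest(config, outdir, inputs, stages)
    return {
        "windows": windows,
        "candidates": cand,
        "genes": gene_list,
        "qc_report": qc_report,
        "sweep_report": sweep_report,
        "stages": stages,
    }


def run_methyl_pipeline(config: PipelineConfig) -> dict:
    """Site filter -> context check -> global summary -> 200 bp tiles ->
    group test -> BH -> DMR call -> gene-feature mapping."""
    config.validate(("fasta", "groups", "reports"))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {"fasta": config.fasta, "groups": config.groups}
    inputs.update({f"report:{s}": p for s, p in config.reports.items()})

    groups = read_groups(config.groups)
    missing = [s for s in groups if s not in config.reports]
    if missing:
        raise ValidationError(f"no cytosine report given for samples: {missing}")
    genome = read_fasta(config.fasta)
    per_sample = {}
    read_reports = {}
    for sample in groups:
        df, rep = read_cytosine_report(config.reports[sample], genome)
        per_sample[sample] = df
        read_reports[sample] = rep
    ds = combine_reports(per_sample)
    stages: dict = {"read_reports": read_reports, "n_sites": ds.n_sites}

    ds, filter_report = filter_cytosines(ds, config.methyl)
    stages["filter"] = filter_report

    summary = global_summary(ds, genome, groups, config.methyl)
    with open(outdir / "global_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    stages["global_summary"] = {
        g: {
            "pct_methylated_of_genomic": v["pct_methylated_of_genomic"],
            "n_methylated_sites": v["n_methylated_sites"],
        }
        for g, v in summary["groups"].items()
    }

    genes = read_gff3(config.gff3, genome.lengths) if config.gff3 else []
    if config.gff3:
        inputs["gff3"] = config.gff3

    tiles = tile_counts(ds, config.methyl)
    tested = test_tiles(tiles, groups)
    called, counts = call_dmrs(tested, config.methyl)
    write_table(called, outdir / "tiles.tsv", "window_tsv")
    dmrs = called[called["status"] != "ns"]
    write_table(dmrs, outdir / "dmrs.tsv", "dmr_tsv")
    stages["dmrs"] = counts
    logger.info(
        "DMRs: %d hyper + %d hypo = %d total (of %d tested tiles)",
        counts["hyper"], counts["hypo"], counts["total_dmrs"], counts["tested"],
    )

    features = map_dmr_features(called, genes, config.methyl)
    write_table(features, outdir / "dmr_features.tsv", "dmr_tsv")
    stages["features"] = {"n_rows": len(features)}

    _write_manifest(config, outdir, inputs, stages)
    return {
        "dataset": ds,
        "summary": summary,
        "tiles": called,
        "dmrs": dmrs,
        "dmr_counts": counts,
        "features": features,
        "stages": stages,
    }
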
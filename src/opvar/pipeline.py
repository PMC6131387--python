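"""End-to-end orchestration of the calling stages with one config."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .formats_io import (
    LibraryAlignments,
    read_alignments,
    read_annotation,
    read_annotated_operons,
    write_sites,
)
from .operon_builder import (
    build_operons,
    count_contexts,
    find_antisense_operons,
    find_extended_operons,
)
from .quantify_qc import gene_expression
from .tss_calling import call_tss
from .tts_calling import call_tts, compute_readthrough, merge_tts, tally_three_prime_ends

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.

    Threshold defaults are the published calling parameters: 5-bp TSS
    clustering, >4 reads per TSS, enrichment ratio >1, 200-fold
    termination criterion, >=10 reads per TTS, alpha 0.05, 5-bp TTS
    merge, 5-bp read-through margin.
    """

    alignments: str = ""
    control: str | None = None
    genome: str | None = None
    genes: str | None = None
    annotated_operons: str | None = None
    alignment_format: str = "bed12"
    annotation_format: str = "gff3"
    out_dir: str = "opvar_out"
    window: int = 5
    min_tss_reads: int = 4
    min_ratio: float = 1.0
    fold: float = 200.0
    min_tts_reads: int = 10
    alpha: float = 0.05
    merge_window: int = 5
    readthrough_margin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window", "min_tss_reads", "fold", "min_tts_reads",
                     "alpha", "merge_window", "readthrough_margin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_all(config: PipelineConfig) -> dict:
    """Run TSS -> TTS -> read-through -> operons -> contexts -> expression.

    Writes per-stage BED/TSV tables plus a JSON run report under
    ``config.out_dir`` and returns the report. Re-running with the same
    inputs reproduces identical outputs (every stage is deterministic).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "parameters": asdict(config), "stages": {}}

    enriched = read_alignments(config.alignments, config.alignment_format)
    control: LibraryAlignments | None = None
    if config.control:
        control = read_alignments(config.control, config.alignment_format)
    elif config.min_ratio > 0:
        logger.warning("no control library given: enrichment-ratio filter skipped")
    genes = (
        read_annotation(config.genes, config.annotation_format) if config.genes else []
    )

    tss = call_tss(
        enriched,
        control,
        window=config.window,
        min_reads=config.min_tss_reads,
        min_ratio=config.min_ratio,
    )
    write_sites(tss, out / "tss.bed", out / "tss.tsv")
    report["stages"]["tss"] = {"n": len(tss)}

    tallies = tally_three_prime_ends(enriched, tss)
    tts = merge_tts(
        call_tts(
            tallies,
            fold=config.fold,
            min_reads=config.min_tts_reads,
            alpha=config.alpha,
        ),
        window=config.merge_window,
    )
    write_sites(tts, out / "tts.bed", out / "tts.tsv")
    report["stages"]["tts"] = {"n": len(tts)}

    rt_rows = []
    for call in tts:
        stat = compute_readthrough(
            call, enriched, margin=config.readthrough_margin, genes=genes
        )
        if stat is None:
            continue
        rt_rows.append(
            {
                "chrom": call.chrom,
                "position_1based": call.position + 1,
                "strand": call.strand,
                "n_covering": stat.n_covering,
                "n_through": stat.n_through,
                "percent_through": stat.percent_through,
                "median_extension": stat.median_extension,
                "genes_included": ",".join(stat.genes_included),
            }
        )
    pd.DataFrame(
        rt_rows,
        columns=["chrom", "position_1based", "strand", "n_covering", "n_through",
                 "percent_through", "median_extension", "genes_included"],
    ).to_csv(out / "readthrough.tsv", sep="\t", index=False)
    report["stages"]["readthrough"] = {"n": len(rt_rows)}

    variants = build_operons(
        enriched, tss, tts, genes, merge_window=config.merge_window
    )
    op_rows = [
        {
            "gene_ids": ",".join(v.gene_ids),
            "chrom": v.chrom,
            "start": v.span[0],
            "end": v.span[1],
            "strand": v.strand,
            "n_units": len(v.units),
            "total_support": v.total_support,
        }
        for v in variants
    ]
    pd.DataFrame(
        op_rows,
        columns=["gene_ids", "chrom", "start", "end", "strand", "n_units", "total_support"],
    ).to_csv(out / "operons.tsv", sep="\t", index=False)
    report["stages"]["operons"] = {"n": len(variants)}

    contexts = count_contexts(variants)
    pd.DataFrame(
        [
            {"gene_id": c.gene_id, "n_contexts": c.n_contexts,
             "contexts": ";".join(",".join(t) for t in c.contexts)}
            for c in contexts
        ],
        columns=["gene_id", "n_contexts", "contexts"],
    ).to_csv(out / "contexts.tsv", sep="\t", index=False)
    report["stages"]["contexts"] = {"n": len(contexts)}

    antisense = find_antisense_operons(variants, genes)
    report["stages"]["antisense_operons"] = {"n": len(antisense)}

    if config.annotated_operons:
        annotated = read_annotated_operons(config.annotated_operons, genes)
        extensions = find_extended_operons(enriched, annotated, genes)
        pd.DataFrame(
            [
                {
                    "operon_id": e.operon.operon_id,
                    "extended": e.extended,
                    "sides": ",".join(e.sides),
                    "extra_genes": ",".join(e.extra_genes),
                    "n_supporting_reads": e.n_supporting_reads,
                }
                for e in extensions
            ],
            columns=["operon_id", "extended", "sides", "extra_genes", "n_supporting_reads"],
        ).to_csv(out / "extensions.tsv", sep="\t", index=False)
        report["stages"]["extensions"] = {
            "n": len(extensions),
            "n_extended": sum(e.extended for e in extensions),
        }

    if genes:
        expr = gene_expression(enriched, genes)
        pd.DataFrame(
            [{"gene_id": e.gene_id, "read_count": e.read_count, "rpkm": e.rpkm}
             for e in expr],
            columns=["gene_id", "read_count", "rpkm"],
        ).to_csv(out / "expression.tsv", sep="\t", index=False)
        report["stages"]["expression"] = {"n": len(expr)}

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
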
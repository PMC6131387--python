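"""Shared genomic record types and readers/writers for external formats.

All internal coordinates are 0-based half-open, BED-style. GFF3 input
(1-based inclusive) is converted on read; TSV site reports print 1-based
positions. A read's oriented ends are derived from its span and strand:
on ``+`` the 5' end is ``start`` and the 3' end is ``end - 1``; on ``-``
they swap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in the named format."""


class AnnotationError(ValueError):
    """Raised for inconsistent gene annotation (e.g. duplicate gene ids)."""


@dataclass(frozen=True)
class GeneRecord:
    """A gene body interval.

    Coordinates are 0-based half-open; ``biotype`` distinguishes rRNA
    from protein-coding features where the annotation provides it.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "CDS"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AnnotatedOperon:
    """An operon from an external annotation: an ordered gene list on one strand."""

    operon_id: str
    gene_ids: tuple[str, ...]
    strand: str
    chrom: str = ""
    start: int = 0
    end: int = 0

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"operon {self.operon_id}: empty gene list")
        if self.strand not in STRANDS:
            raise ValueError(f"operon {self.operon_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class AlignedReadRecord:
    """One mapped full-length transcript.

    ``five_prime``/``three_prime`` are the biological end positions
    (single-base coordinates) implied by the aligned span and strand.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"read {self.read_id}: start must be < end")
        if self.strand not in STRANDS:
            raise ValueError(f"read {self.read_id}: bad strand {self.strand!r}")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LibraryAlignments:
    """A library of aligned reads plus the mappable-read total used for TPM.

    ``total_mappable`` may exceed ``len(reads)`` when the stored reads are
    a filtered subset of all primary alignments.
    """

    label: str
    reads: list[AlignedReadRecord] = field(default_factory=list)
    total_mappable: int = 0

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("library label must be non-empty")
        if self.total_mappable == 0:
            self.total_mappable = len(self.reads)
        if self.total_mappable < len(self.reads):
            raise ValueError("total_mappable cannot be below the stored read count")

    def __len__(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# Alignments

_BED12_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thick_start", "thick_end", "rgb", "block_count", "block_sizes", "block_starts",
]


def _read_bed12(path: str | Path, label: str) -> LibraryAlignments:
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=_BED12_COLS, usecols=range(6),
            dtype={"chrom": str, "start": int, "end": int, "name": str, "strand": str},
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path} as BED12: {exc}") from exc
    reads = [
        AlignedReadRecord(str(r.name), r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples(index=False)
    ]
    return LibraryAlignments(label=label, reads=reads, total_mappable=len(reads))


def _read_bam(path: str | Path, label: str) -> LibraryAlignments:
    try:
        import pysam
    except ImportError as exc:  # pragma: no cover
        raise FormatError("BAM input requires pysam; install opvar[bam]") from exc
    reads = []
    with pysam.AlignmentFile(str(path), "rb", check_sq=False) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            reads.append(
                AlignedReadRecord(
                    aln.query_name,
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    "-" if aln.is_reverse else "+",
                )
            )
    return LibraryAlignments(label=label, reads=reads, total_mappable=len(reads))


def read_alignments(
    path: str | Path, format: str = "bed12", label: str | None = None
) -> LibraryAlignments:
    """Load one alignment per primary mapped read from BAM or BED12.

    Secondary and supplementary alignments are skipped; ``total_mappable``
    is set to the number of primary alignments kept.
    """
    label = label or Path(path).stem
    if format == "bed12":
        lib = _read_bed12(path, label)
    elif format == "bam":
        lib = _read_bam(path, label)
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    if not lib.reads:
        warnings.warn(f"{path}: no primary alignments found", stacklevel=2)
    return lib


def write_bed12(reads: Iterable[AlignedReadRecord], path: str | Path) -> None:
    """Write reads as single-block BED12 records."""
    with open(path, "w") as fh:
        for r in reads:
            size = r.end - r.start
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.read_id}\t0\t{r.strand}\t"
                f"{r.start}\t{r.end}\t0,0,0\t1\t{size},\t0,\n"
            )


# ---------------------------------------------------------------------------
# Gene annotation

_GFF_GENE_TYPES = {"gene", "pseudogene"}


def _gff3_records(path: str | Path) -> Iterable[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    feature_types = set(db.featuretypes())
    wanted = _GFF_GENE_TYPES & feature_types or feature_types
    for ftype in sorted(wanted):
        for feat in db.features_of_type(ftype):
            if feat.strand not in STRANDS:
                warnings.warn(
                    f"skipping {feat.id}: missing strand", stacklevel=3
                )
                continue
            attrs = feat.attributes
            gene_id = (
                attrs.get("gene_id", [None])[0]
                or attrs.get("Name", [None])[0]
                or attrs.get("locus_tag", [None])[0]
                or feat.id
            )
            biotype = attrs.get("gene_biotype", attrs.get("biotype", ["CDS"]))[0]
            # GFF3 is 1-based inclusive; convert to 0-based half-open
            yield GeneRecord(gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand, biotype)


def _bed6_records(path: str | Path) -> Iterable[GeneRecord]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6), dtype={"chrom": str, "name": str, "strand": str},
    )
    for r in df.itertuples(index=False):
        if r.strand not in STRANDS:
            warnings.warn(f"skipping {r.name}: missing strand", stacklevel=3)
            continue
        yield GeneRecord(str(r.name), r.chrom, int(r.start), int(r.end), r.strand)


def read_annotation(path: str | Path, format: str = "gff3") -> list[GeneRecord]:
    """Read a gene annotation (GFF3 or BED6) into 0-based half-open records.

    Duplicate gene ids are rejected; records without a strand are skipped
    with a warning.
    """
    if format == "gff3":
        genes = list(_gff3_records(path))
    elif format == "bed6":
        genes = list(_bed6_records(path))
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise AnnotationError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    return genes


def read_annotated_operons(
    path: str | Path, genes: Sequence[GeneRecord] | None = None
) -> list[AnnotatedOperon]:
    """Read a RegulonDB-style operon table.

    Expected TSV columns: operon_id, gene_ids (comma-separated), strand.
    When a gene annotation is supplied the span is derived from the member
    genes; operons naming unknown genes are skipped with a warning.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["operon_id", "gene_ids", "strand"], dtype=str,
    )
    by_id: Mapping[str, GeneRecord] = {g.gene_id: g for g in genes} if genes else {}
    out = []
    for r in df.itertuples(index=False):
        ids = tuple(x for x in str(r.gene_ids).split(",") if x)
        if by_id:
            missing = [g for g in ids if g not in by_id]
            if missing:
                warnings.warn(
                    f"operon {r.operon_id}: unknown genes {missing}, skipped",
                    stacklevel=2,
                )
                continue
            members = [by_id[g] for g in ids]
            chrom = members[0].chrom
            start = min(g.start for g in members)
            end = max(g.end for g in members)
        else:
            chrom, start, end = "", 0, 0
        out.append(AnnotatedOperon(str(r.operon_id), ids, str(r.strand), chrom, start, end))
    return out


# ---------------------------------------------------------------------------
# Site tables (TSS / TTS output)


def write_sites(sites: Sequence, bed_path: str | Path, tsv_path: str | Path) -> None:
    """Write single-base sites as BED6 plus a full-evidence TSV.

    Works for any object exposing ``chrom``, ``position``, ``strand`` and a
    score (``T_total`` or ``k``); extra public scalar fields land in the
    TSV. BED positions are 0-based half-open single-base intervals; the
    TSV ``position_1based`` column is 1-based.
    """
    rows = []
    with open(bed_path, "w") as bed:
        for i, s in enumerate(sites):
            score = getattr(s, "T_total", getattr(s, "k", 0))
            bed.write(
                f"{s.chrom}\t{s.position}\t{s.position + 1}\t"
                f"site_{i}\t{score}\t{s.strand}\n"
            )
            row = {"chrom": s.chrom, "position_1based": s.position + 1, "strand": s.strand}
            for name in vars(s) if hasattr(s, "__dict__") else s.__dataclass_fields__:
                val = getattr(s, name)
                if name in ("chrom", "position", "strand"):
                    continue
                if isinstance(val, (int, float, str, bool)) or val is None:
                    row[name] = val
                elif isinstance(val, (tuple, list, frozenset, set)):
                    row[name] = ",".join(str(v) for v in sorted(val))
            rows.append(row)
    cols = list(rows[0]) if rows else ["chrom", "position_1based", "strand"]
    pd.DataFrame(rows, columns=cols).to_csv(tsv_path, sep="\t", index=False)


def read_sites_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6 site table back into a DataFrame with 0-based positions."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "strand": str},
    )
    df["position"] = df["start"]
    return df
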
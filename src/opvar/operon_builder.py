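"""Operon-variant enumeration and per-gene transcriptional contexts.

An operon variant is a unique strand-oriented combination of genes fully
covered by transcripts sharing a start and end: reads from one retained
TSS are grouped by the termination site they end at (or, lacking one, by
the group's longest 3' end), each group becomes a transcript unit, and
units with identical gene tuples collapse into one variant. A gene's
transcriptional contexts are the distinct variants containing it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import AlignedReadRecord, AnnotatedOperon, GeneRecord, LibraryAlignments
from .tss_calling import TSSCluster, assign_reads_to_clusters
from .tts_calling import TTSCall


@dataclass(frozen=True)
class TranscriptUnit:
    """Transcripts sharing a TSS cluster and a 3' boundary.

    ``end`` is a called TTS position when ``end_is_tts``, otherwise the
    longest observed 3' end of the group; ``gene_ids`` are the genes
    fully covered by the unit span, ordered 5' to 3'.
    """

    tss: TSSCluster
    end: int
    end_is_tts: bool
    gene_ids: tuple[str, ...]
    support: int

    @property
    def strand(self) -> str:
        return self.tss.strand

    @property
    def chrom(self) -> str:
        return self.tss.chrom

    @property
    def span(self) -> tuple[int, int]:
        lo, hi = sorted((self.tss.position, self.end))
        return lo, hi + 1


@dataclass(frozen=True)
class OperonVariant:
    """A unique gene combination with its supporting transcript units."""

    gene_ids: tuple[str, ...]
    strand: str
    chrom: str
    units: tuple[TranscriptUnit, ...]
    total_support: int

    @property
    def span(self) -> tuple[int, int]:
        lo = min(u.span[0] for u in self.units)
        hi = max(u.span[1] for u in self.units)
        return lo, hi


@dataclass(frozen=True)
class ContextRecord:
    """The distinct operon variants a gene is transcribed within."""

    gene_id: str
    n_contexts: int
    contexts: tuple[tuple[str, ...], ...]


def genes_fully_covered(
    read: AlignedReadRecord | tuple[str, int, int, str],
    genes: Sequence[GeneRecord],
) -> tuple[str, ...]:
    """Same-strand genes entirely inside the read span, ordered 5' to 3'."""
    if isinstance(read, AlignedReadRecord):
        chrom, start, end, strand = read.chrom, read.start, read.end, read.strand
    else:
        chrom, start, end, strand = read
    hits = [
        g
        for g in genes
        if g.chrom == chrom
        and g.strand == strand
        and start <= g.start
        and g.end <= end
    ]
    hits.sort(key=lambda g: g.start, reverse=(strand == "-"))
    return tuple(g.gene_id for g in hits)


def _tts_index(tts_calls: Sequence[TTSCall]) -> dict[tuple[str, str], list[int]]:
    idx: dict[tuple[str, str], list[int]] = {}
    for c in tts_calls:
        idx.setdefault((c.chrom, c.strand), []).append(c.position)
    for positions in idx.values():
        positions.sort()
    return idx


def _nearest_tts(
    idx: Mapping[tuple[str, str], list[int]],
    chrom: str,
    strand: str,
    three_prime: int,
    window: int,
) -> int | None:
    """The called TTS within ``window`` bp of a read 3' end, if any."""
    positions = idx.get((chrom, strand))
    if not positions:
        return None
    best: int | None = None
    for pos in positions:  # lists are short; linear scan is fine
        d = abs(pos - three_prime)
        if d <= window and (best is None or d < abs(best - three_prime)):
            best = pos
    return best


def build_operons(
    library: LibraryAlignments | Iterable[AlignedReadRecord],
    tss_clusters: Sequence[TSSCluster],
    tts_calls: Sequence[TTSCall],
    genes: Sequence[GeneRecord],
    merge_window: int = 5,
    exclude_rrna: bool = True,
) -> list[OperonVariant]:
    """Enumerate operon variants from reads with a retained TSS.

    Each read joins the group of (its TSS cluster, the called TTS within
    ``merge_window`` bp of its 3' end); reads terminating at no called
    TTS form one fallback group per TSS whose boundary is the longest
    observed 3' end. Each group becomes a transcript unit whose gene
    tuple is taken over the unit span; units sharing a non-empty tuple
    merge into one variant. rRNA genes are excluded from tuples unless
    ``exclude_rrna`` is False.
    """
    reads = library.reads if isinstance(library, LibraryAlignments) else library
    if exclude_rrna:
        genes = [g for g in genes if g.biotype.lower() != "rrna"]
    assigned = assign_reads_to_clusters(reads, tss_clusters)
    idx = _tts_index(tts_calls)

    units: list[TranscriptUnit] = []
    for cluster, cluster_reads in assigned.items():
        groups: dict[int, list[AlignedReadRecord]] = {}
        fallback: list[AlignedReadRecord] = []
        for read in cluster_reads:
            tts = _nearest_tts(
                idx, cluster.chrom, cluster.strand, read.three_prime, merge_window
            )
            if tts is None:
                fallback.append(read)
            else:
                groups.setdefault(tts, []).append(read)
        for tts_pos, members in groups.items():
            units.append(_unit(cluster, tts_pos, True, members, genes))
        if fallback:
            longest = (
                max(r.three_prime for r in fallback)
                if cluster.strand == "+"
                else min(r.three_prime for r in fallback)
            )
            units.append(_unit(cluster, longest, False, fallback, genes))

    variants: dict[tuple[tuple[str, ...], str, str], list[TranscriptUnit]] = {}
    for u in units:
        if not u.gene_ids:
            continue
        variants.setdefault((u.gene_ids, u.strand, u.chrom), []).append(u)
    out = [
        OperonVariant(
            gene_ids=key[0],
            strand=key[1],
            chrom=key[2],
            units=tuple(us),
            total_support=sum(u.support for u in us),
        )
        for key, us in variants.items()
    ]
    out.sort(key=lambda v: (v.chrom, v.span[0], v.strand, v.gene_ids))
    return out


def _unit(
    cluster: TSSCluster,
    end: int,
    end_is_tts: bool,
    members: Sequence[AlignedReadRecord],
    genes: Sequence[GeneRecord],
) -> TranscriptUnit:
    lo, hi = sorted((cluster.position, end))
    tuple_genes = genes_fully_covered(
        (cluster.chrom, lo, hi + 1, cluster.strand), genes
    )
    return TranscriptUnit(cluster, end, end_is_tts, tuple_genes, len(members))


@dataclass(frozen=True)
class ExtensionReport:
    """Whether reads extend an annotated operon by additional genes."""

    operon: AnnotatedOperon
    extended: bool
    sides: tuple[str, ...] = ()
    extra_genes: tuple[str, ...] = ()
    n_supporting_reads: int = 0


def reduce_to_maximal(operons: Sequence[AnnotatedOperon]) -> list[AnnotatedOperon]:
    """Drop operons whose gene set is contained in another on the same strand."""
    keep = []
    for op in operons:
        s = set(op.gene_ids)
        if any(
            other is not op
            and other.strand == op.strand
            and s < set(other.gene_ids)
            for other in operons
        ):
            continue
        # among identical gene sets keep the first occurrence only
        if any(
            k.strand == op.strand and set(k.gene_ids) == s for k in keep
        ):
            continue
        keep.append(op)
    return keep


def find_extended_operons(
    library: LibraryAlignments | Iterable[AlignedReadRecord],
    annotated: Sequence[AnnotatedOperon],
    genes: Sequence[GeneRecord],
) -> list[ExtensionReport]:
    """Detect annotated operons extended by fully covering reads.

    Sub-operons (gene sets contained in a longer annotated operon on the
    same strand) are removed first. An operon is extended when at least
    one read fully covers every member gene plus at least one additional
    gene; the side(s) of extension are recorded relative to the strand.
    """
    reads = library.reads if isinstance(library, LibraryAlignments) else library
    by_id = {g.gene_id: g for g in genes}
    maximal = reduce_to_maximal(annotated)
    reports = []
    for op in maximal:
        missing = [g for g in op.gene_ids if g not in by_id]
        if missing:
            import warnings

            warnings.warn(
                f"operon {op.operon_id}: genes {missing} absent from annotation, skipped",
                stacklevel=2,
            )
            continue
        members = [by_id[g] for g in op.gene_ids]
        chrom = members[0].chrom
        op_start = min(g.start for g in members)
        op_end = max(g.end for g in members)
        member_set = set(op.gene_ids)
        sides: set[str] = set()
        extra: set[str] = set()
        n_support = 0
        for read in reads:
            if read.chrom != chrom or read.strand != op.strand:
                continue
            if not (read.start <= op_start and op_end <= read.end):
                continue
            covered = genes_fully_covered(read, genes)
            extra_here = [g for g in covered if g not in member_set]
            if not set(op.gene_ids) <= set(covered) or not extra_here:
                continue
            n_support += 1
            extra.update(extra_here)
            for gid in extra_here:
                g = by_id[gid]
                downstream = g.start >= op_end if op.strand == "+" else g.end <= op_start
                upstream = g.end <= op_start if op.strand == "+" else g.start >= op_end
                if downstream:
                    sides.add("3'")
                elif upstream:
                    sides.add("5'")
        reports.append(
            ExtensionReport(
                operon=op,
                extended=n_support > 0,
                sides=tuple(sorted(sides)),
                extra_genes=tuple(sorted(extra)),
                n_supporting_reads=n_support,
            )
        )
    return reports


def count_contexts(variants: Sequence[OperonVariant]) -> list[ContextRecord]:
    """Per-gene count of distinct variant tuples containing the gene."""
    contexts: dict[str, set[tuple[str, ...]]] = {}
    for v in variants:
        for gid in v.gene_ids:
            contexts.setdefault(gid, set()).add(v.gene_ids)
    return [
        ContextRecord(gid, len(tuples), tuple(sorted(tuples)))
        for gid, tuples in sorted(contexts.items())
    ]


def compare_contexts(
    records_a: Sequence[ContextRecord],
    records_b: Sequence[ContextRecord],
    expression_a: Mapping[str, float] | None = None,
    expression_b: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Outer-join context counts between two conditions.

    Genes absent from one condition get 0 contexts there. Optional
    per-gene expression maps add mean expression and a B/A ratio.
    """
    a = {r.gene_id: r.n_contexts for r in records_a}
    b = {r.gene_id: r.n_contexts for r in records_b}
    gene_ids = sorted(set(a) | set(b))
    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "n_contexts_a": [a.get(g, 0) for g in gene_ids],
            "n_contexts_b": [b.get(g, 0) for g in gene_ids],
        }
    )
    if expression_a is not None and expression_b is not None:
        ea = df["gene_id"].map(lambda g: expression_a.get(g, 0.0))
        eb = df["gene_id"].map(lambda g: expression_b.get(g, 0.0))
        df["mean_expression"] = (ea + eb) / 2
        df["expression_ratio"] = eb / ea.where(ea > 0)
    return df


def find_antisense_operons(
    variants: Sequence[OperonVariant], genes: Sequence[GeneRecord]
) -> list[OperonVariant]:
    """Variants whose genomic span fully contains a gene on the other strand."""
    out = []
    for v in variants:
        lo, hi = v.span
        opposite = "-" if v.strand == "+" else "+"
        if any(
            g.chrom == v.chrom
            and g.strand == opposite
            and lo <= g.start
            and g.end <= hi
            for g in genes
        ):
            out.append(v)
    return out
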
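"""Transcription start site calling from 5'-end pileups.

In a cap-enriched library the 5' ends of full-length reads fall exactly
on true start sites, while a non-enriched control also contains processed
transcripts whose 5' ends do not. TSS are therefore called by (i)
tallying per-position 5'-end counts ``T`` and their library-size
normalisation TPM (tags per million mappable reads), (ii) requiring the
enriched/control TPM ratio (with a pseudo-count of 1 on ``T``) to exceed
1, (iii) clustering retained positions within 5 bp on the same strand
around the highest-count position, and (iv) keeping clusters with more
than four supporting reads.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .formats_io import AlignedReadRecord, LibraryAlignments

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EndTally:
    """Read-end count at one (chrom, position, strand).

    ``T`` is the number of same-orientation reads whose relevant end sits
    exactly here; ``TPM`` is ``T`` per million mappable reads.
    """

    chrom: str
    position: int
    strand: str
    T: int
    TPM: float


@dataclass(frozen=True)
class TSSCluster:
    """A clustered start site.

    The representative position is the member with the largest count;
    ``T_total`` sums counts over all members; ``smrt_ratio`` is the
    enriched/control enrichment at the representative (None when no
    control library was used).
    """

    chrom: str
    position: int
    strand: str
    members: tuple[int, ...]
    T_total: int
    smrt_ratio: float | None = None
    TPM: float = 0.0


def tally_five_prime_ends(library: LibraryAlignments) -> list[EndTally]:
    """Per-position, per-strand counts of read 5' ends with TPM."""
    if library.total_mappable == 0:
        raise ValueError("library has no mappable reads")
    counts: dict[tuple[str, int, str], int] = {}
    for read in library.reads:
        key = (read.chrom, read.five_prime, read.strand)
        counts[key] = counts.get(key, 0) + 1
    scale = 1e6 / library.total_mappable
    return [
        EndTally(chrom, pos, strand, T, T * scale)
        for (chrom, pos, strand), T in sorted(counts.items())
    ]


def smrt_ratio(
    T_enriched: int,
    N_enriched: int,
    T_control: int,
    N_control: int,
    pseudocount: int = 1,
) -> float:
    """Enrichment ratio of cap-enriched over control 5'-end TPM.

    A pseudo-count (default 1) is added to both counts so the ratio is
    defined at positions absent from the control.
    """
    if N_enriched <= 0 or N_control <= 0:
        raise ValueError("library sizes must be positive")
    return ((T_enriched + pseudocount) / N_enriched) / (
        (T_control + pseudocount) / N_control
    )


def _is_upstream(a: int, b: int, strand: str) -> bool:
    """True if position a is 5' of position b in transcript orientation."""
    return a < b if strand == "+" else a > b


def cluster_tss(
    candidates: Sequence[EndTally],
    window: int = 5,
    min_reads: int = 4,
    ratios: dict[tuple[str, int, str], float] | None = None,
) -> list[TSSCluster]:
    """Greedy clustering of candidate start positions.

    Repeatedly seed on the unassigned position with the highest ``T``
    (ties to the 5'-most position on the strand), absorb unassigned
    positions within ``window`` bp on the same strand, and emit the
    cluster. Clusters need ``T_total > min_reads`` to be kept. ``ratios``
    optionally attaches each representative's enrichment ratio.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    by_group: dict[tuple[str, str], list[EndTally]] = {}
    for t in candidates:
        by_group.setdefault((t.chrom, t.strand), []).append(t)

    clusters: list[TSSCluster] = []
    for (chrom, strand), tallies in sorted(by_group.items()):
        sign = 1 if strand == "+" else -1
        order = sorted(tallies, key=lambda t: (-t.T, sign * t.position))
        assigned: set[int] = set()
        pos_sorted = sorted(tallies, key=lambda t: t.position)
        positions = [t.position for t in pos_sorted]
        for seed in order:
            if seed.position in assigned:
                continue
            lo = seed.position - window
            hi = seed.position + window
            i = np.searchsorted(positions, lo, side="left")
            j = np.searchsorted(positions, hi, side="right")
            members = [
                t for t in pos_sorted[i:j] if t.position not in assigned
            ]
            assigned.update(t.position for t in members)
            clusters.append(
                TSSCluster(
                    chrom=chrom,
                    position=seed.position,
                    strand=strand,
                    members=tuple(sorted(t.position for t in members)),
                    T_total=sum(t.T for t in members),
                    smrt_ratio=(ratios or {}).get((chrom, seed.position, strand)),
                    TPM=seed.TPM,
                )
            )
    kept = [c for c in clusters if c.T_total > min_reads]
    kept.sort(key=lambda c: (c.chrom, c.position, c.strand))
    return kept


def call_tss(
    enriched: LibraryAlignments,
    control: LibraryAlignments | None = None,
    window: int = 5,
    min_reads: int = 4,
    min_ratio: float = 1.0,
    pseudocount: int = 1,
) -> list[TSSCluster]:
    """End-to-end TSS calling for one enriched library.

    Without a control library the enrichment-ratio filter is skipped with
    a warning; otherwise only positions with ratio strictly above
    ``min_ratio`` enter clustering.
    """
    tallies = tally_five_prime_ends(enriched)
    ratios: dict[tuple[str, int, str], float] | None = None
    if control is None:
        logger.warning("no control library: enrichment-ratio filter skipped")
        candidates = tallies
    else:
        control_T = {
            (t.chrom, t.position, t.strand): t.T
            for t in tally_five_prime_ends(control)
        }
        ratios = {}
        candidates = []
        for t in tallies:
            key = (t.chrom, t.position, t.strand)
            r = smrt_ratio(
                t.T, enriched.total_mappable,
                control_T.get(key, 0), control.total_mappable,
                pseudocount,
            )
            ratios[key] = r
            if r > min_ratio:
                candidates.append(t)
    return cluster_tss(candidates, window=window, min_reads=min_reads, ratios=ratios)


def assign_reads_to_clusters(
    reads: Iterable[AlignedReadRecord], clusters: Sequence[TSSCluster]
) -> dict[TSSCluster, list[AlignedReadRecord]]:
    """Map each read to the cluster containing its 5' end, if any.

    A read belongs to a cluster when its 5' end equals one of the
    cluster's member positions; member sets are disjoint by construction
    so the assignment is unique. Unassigned reads are omitted.
    """
    lookup: dict[tuple[str, int, str], TSSCluster] = {}
    for c in clusters:
        for m in c.members:
            lookup[(c.chrom, m, c.strand)] = c
    out: dict[TSSCluster, list[AlignedReadRecord]] = {c: [] for c in clusters}
    for read in reads:
        c = lookup.get((read.chrom, read.five_prime, read.strand))
        if c is not None:
            out[c].append(read)
    return out


def compare_tss_conditions(
    set_a: Sequence[TSSCluster], set_b: Sequence[TSSCluster]
) -> tuple[list[tuple[TSSCluster, TSSCluster]], float]:
    """Match TSS between two conditions and correlate their scores.

    TSS are common when (chrom, representative position, strand) are
    identical; Pearson correlation is computed over the common sites'
    TPM scores and reported as NaN when fewer than three sites match or
    either score vector is constant.
    """
    index_b = {(c.chrom, c.position, c.strand): c for c in set_b}
    common = [
        (a, index_b[(a.chrom, a.position, a.strand)])
        for a in set_a
        if (a.chrom, a.position, a.strand) in index_b
    ]
    if len(common) < 3:
        return common, math.nan
    x = np.array([a.TPM for a, _ in common])
    y = np.array([b.TPM for _, b in common])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return common, math.nan
    return common, float(np.corrcoef(x, y)[0, 1])
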
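"""Transcription termination site calling and read-through quantification.

Full-length reads sharing a TSS end either at a terminator or at random
positions produced by incomplete transcription and degradation. Under
the null, a transcript of length D ends at any given base with
probability 1/D, so a position where k of the n reads from one TSS end
is a termination site when the observed fraction k/n exceeds 200 x (1/D),
at least 10 reads end there, and the one-tailed binomial probability
P(X >= k), X ~ Binom(n, 1/D), is below 0.05. Nearby calls within 5 bp
are merged to the most-3' position. Read-through at a called TTS is the
fraction of covering transcripts extending beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .formats_io import AlignedReadRecord, GeneRecord, LibraryAlignments
from .tss_calling import TSSCluster, assign_reads_to_clusters


@dataclass(frozen=True)
class TTSCall:
    """A called termination site with its binomial evidence.

    ``k`` reads end here out of ``n`` sharing the source TSS; ``D`` is
    the inclusive TSS-to-terminus distance (the transcript length).
    When several TSSs support one site after merging, ``k``/``n`` pool
    the per-TSS counts, ``D`` and ``p_value`` come from the source TSS
    contributing the most reads, and ``per_tss`` retains each source's
    (k, n, D) triple.
    """

    chrom: str
    position: int
    strand: str
    source_tss: tuple[int, ...]
    k: int
    n: int
    D: int
    percent: float
    p_value: float
    per_tss: Mapping[int, tuple[int, int, int]] = field(default_factory=dict)


@dataclass(frozen=True)
class ReadthroughStat:
    """Read-through at one termination site.

    ``percent_through`` is n_through / n_covering; ``median_extension``
    is the median 3'-extension length (bp past the site) among
    read-through reads, None when nothing reads through;
    ``genes_included`` are genes fully covered by the extended regions.
    """

    tts: TTSCall
    n_covering: int
    n_through: int
    percent_through: float
    median_extension: float | None = None
    genes_included: tuple[str, ...] = ()


def tally_three_prime_ends(
    library: LibraryAlignments | Iterable[AlignedReadRecord],
    tss_clusters: Sequence[TSSCluster],
) -> dict[TSSCluster, dict[int, int]]:
    """Per-TSS-cluster counts of read 3'-end positions.

    Only reads whose 5' end falls on a cluster member are counted; each
    read contributes to exactly one cluster.
    """
    reads = library.reads if isinstance(library, LibraryAlignments) else library
    assigned = assign_reads_to_clusters(reads, tss_clusters)
    out: dict[TSSCluster, dict[int, int]] = {}
    for cluster, cluster_reads in assigned.items():
        tally: dict[int, int] = {}
        for read in cluster_reads:
            tally[read.three_prime] = tally.get(read.three_prime, 0) + 1
        out[cluster] = tally
    return out


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p); stable up to n ~ 1e6."""
    if not 0 < p < 1:
        raise ValueError("p must lie strictly between 0 and 1")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def _distance(tss_position: int, three_prime: int) -> int:
    """Inclusive TSS-to-3'-end distance: equals the transcript length."""
    return abs(three_prime - tss_position) + 1


def call_tts(
    three_prime_tallies: Mapping[TSSCluster, Mapping[int, int]],
    fold: float = 200.0,
    min_reads: int = 10,
    alpha: float = 0.05,
    correction: str = "none",
) -> list[TTSCall]:
    """Apply the termination criterion to every 3'-end position.

    A position passes when k/n > fold/D, k >= min_reads, and the upper
    binomial tail at p = 1/D is below alpha. Positions downstream of a
    TSS at D <= fold can never pass (k/n <= 1). Calls at the same
    position from different TSSs are unioned with evidence accumulated
    per source TSS. With ``correction="bh"`` the tail probabilities of
    all positions passing the fold and support rules are
    Benjamini-Hochberg adjusted before the alpha cut; the default
    applies alpha per test.
    """
    if correction not in ("none", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    candidates: list[tuple[TSSCluster, int, int, int, int, float]] = []
    for cluster, tally in three_prime_tallies.items():
        n = sum(tally.values())
        if n == 0:
            continue
        for pos, k in tally.items():
            if not _is_downstream(cluster.position, pos, cluster.strand):
                continue
            D = _distance(cluster.position, pos)
            if k / n <= fold / D or k < min_reads:
                continue
            candidates.append(
                (cluster, pos, k, n, D, binomial_upper_tail(k, n, 1.0 / D))
            )
    if candidates and correction == "bh":
        adjusted = stats.false_discovery_control(
            [c[-1] for c in candidates], method="bh"
        )
    else:
        adjusted = [c[-1] for c in candidates]
    by_site: dict[tuple[str, int, str], dict[int, tuple[int, int, int]]] = {}
    for (cluster, pos, k, n, D, _), p_adj in zip(candidates, adjusted):
        if p_adj >= alpha:
            continue
        site = (cluster.chrom, pos, cluster.strand)
        by_site.setdefault(site, {})[cluster.position] = (k, n, D)
    calls = [
        _make_call(chrom, pos, strand, per_tss)
        for (chrom, pos, strand), per_tss in sorted(by_site.items())
    ]
    return calls


def _is_downstream(tss_position: int, pos: int, strand: str) -> bool:
    """A 3' end is usable when at or past its TSS in transcript orientation."""
    return pos >= tss_position if strand == "+" else pos <= tss_position


def _make_call(
    chrom: str,
    position: int,
    strand: str,
    per_tss: Mapping[int, tuple[int, int, int]],
) -> TTSCall:
    k = sum(v[0] for v in per_tss.values())
    n = sum(v[1] for v in per_tss.values())
    # evidence scale (D, p-value) from the best-supported source TSS
    lead = max(per_tss, key=lambda t: per_tss[t][1])
    k_l, n_l, D_l = per_tss[lead]
    return TTSCall(
        chrom=chrom,
        position=position,
        strand=strand,
        source_tss=tuple(sorted(per_tss)),
        k=k,
        n=n,
        D=D_l,
        percent=k / n,
        p_value=binomial_upper_tail(k_l, n_l, 1.0 / D_l),
        per_tss=dict(per_tss),
    )


def merge_tts(calls: Sequence[TTSCall], window: int = 5) -> list[TTSCall]:
    """Merge same-strand calls within ``window`` bp to the most-3' position.

    Per-source-TSS counts are summed and the evidence fields recomputed
    at the merged position's distance. Merging is idempotent: a second
    pass leaves the output unchanged because surviving calls are farther
    than ``window`` apart.
    """
    out: list[TTSCall] = []
    by_group: dict[tuple[str, str], list[TTSCall]] = {}
    for c in calls:
        by_group.setdefault((c.chrom, c.strand), []).append(c)
    for (chrom, strand), group in sorted(by_group.items()):
        group.sort(key=lambda c: c.position)
        runs: list[list[TTSCall]] = []
        for c in group:
            if runs and c.position - runs[-1][-1].position <= window:
                runs[-1].append(c)
            else:
                runs.append([c])
        for run in runs:
            if len(run) == 1:
                out.append(run[0])
                continue
            # most 3' member: largest coordinate on +, smallest on -
            pos = run[-1].position if strand == "+" else run[0].position
            merged: dict[int, list[int]] = {}
            for c in run:
                for tss, (k, n, _) in c.per_tss.items():
                    if tss in merged:
                        merged[tss][0] += k
                        merged[tss][1] = max(merged[tss][1], n)
                    else:
                        merged[tss] = [k, n]
            per_tss = {
                tss: (k, n, _distance(tss, pos)) for tss, (k, n) in merged.items()
            }
            out.append(_make_call(chrom, pos, strand, per_tss))
    out.sort(key=lambda c: (c.chrom, c.position, c.strand))
    return out


def _covering(read: AlignedReadRecord, tts: TTSCall) -> bool:
    """Same-strand read spanning the site with its 5' end upstream of it."""
    if read.strand != tts.strand or read.chrom != tts.chrom:
        return False
    if not read.start <= tts.position < read.end:
        return False
    if read.strand == "+":
        return read.five_prime < tts.position
    return read.five_prime > tts.position


def _extension(read: AlignedReadRecord, tts: TTSCall) -> int:
    """Signed distance of the read's 3' end past the site (bp; >0 = beyond)."""
    if tts.strand == "+":
        return read.three_prime - tts.position
    return tts.position - read.three_prime


def compute_readthrough(
    tts: TTSCall,
    library: LibraryAlignments | Iterable[AlignedReadRecord],
    margin: int = 5,
    genes: Sequence[GeneRecord] | None = None,
) -> ReadthroughStat | None:
    """Read-through fraction at one termination site.

    Covering reads are same-strand reads spanning the site whose 5' end
    lies upstream of it; a read counts as reading through when its 3'
    end extends more than ``margin`` bp past the site (reads ending
    within the merge window count as terminated). Returns None when no
    read covers the site.
    """
    reads = library.reads if isinstance(library, LibraryAlignments) else library
    covering = [r for r in reads if _covering(r, tts)]
    if not covering:
        return None
    extensions = [
        ext for r in covering if (ext := _extension(r, tts)) > margin
    ]
    through = [r for r in covering if _extension(r, tts) > margin]
    genes_included: tuple[str, ...] = ()
    if genes and through:
        found: set[str] = set()
        for r in through:
            if tts.strand == "+":
                lo, hi = tts.position + 1, r.end
            else:
                lo, hi = r.start, tts.position
            for g in genes:
                if (
                    g.chrom == tts.chrom
                    and g.strand == tts.strand
                    and lo <= g.start
                    and g.end <= hi
                ):
                    found.add(g.gene_id)
        genes_included = tuple(sorted(found))
    return ReadthroughStat(
        tts=tts,
        n_covering=len(covering),
        n_through=len(through),
        percent_through=len(through) / len(covering),
        median_extension=float(np.median(extensions)) if extensions else None,
        genes_included=genes_included,
    )


def readthrough_by_tss(
    tts: TTSCall,
    library: LibraryAlignments | Iterable[AlignedReadRecord],
    tss_clusters: Sequence[TSSCluster],
    margin: int = 5,
    genes: Sequence[GeneRecord] | None = None,
) -> dict[int, ReadthroughStat]:
    """Read-through at one site computed separately per source TSS.

    Reads are first partitioned by TSS cluster; clusters whose reads do
    not cover the site contribute no entry.
    """
    reads = library.reads if isinstance(library, LibraryAlignments) else library
    assigned = assign_reads_to_clusters(reads, tss_clusters)
    out: dict[int, ReadthroughStat] = {}
    for cluster, cluster_reads in assigned.items():
        if cluster.chrom != tts.chrom or cluster.strand != tts.strand:
            continue
        stat = compute_readthrough(tts, cluster_reads, margin=margin, genes=genes)
        if stat is not None:
            out[cluster.position] = stat
    return out
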
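"""Gene-level quantification, primary/processed classification and
sequence-window extraction.

Expression is RPKM over strand-aware read overlap. Reads whose 5' end
sits within a small tolerance of a known start site retain the original
initiation end (primary transcripts); all others are processed. Window
extraction produces transcript-oriented sequences around called sites
for motif, hairpin and attenuator analyses, plus a position frequency
matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import AlignedReadRecord, GeneRecord, LibraryAlignments
from .preprocess import reverse_complement

NUCLEOTIDES = "ACGT"

#: Window presets as inclusive (start, end) offsets around a site;
#: offset 0 is the site base, negative offsets are upstream in
#: transcript orientation.
WINDOW_PRESETS: dict[str, tuple[int, int]] = {
    "tss": (-45, 5),
    "tts-motif": (-30, 10),
    "tts-structure": (-40, -1),
    "attenuator": (-100, -1),
}


@dataclass(frozen=True)
class ExpressionRecord:
    """Strand-aware read count and RPKM for one gene."""

    gene_id: str
    read_count: int
    rpkm: float


@dataclass
class PositionFrequencyMatrix:
    """Per-offset nucleotide counts accumulated over site windows.

    ``counts`` has one row per offset in ``window`` (inclusive) and one
    column per nucleotide in ACGT order; each row sums to ``n_sites``
    less any sites skipped at chromosome edges.
    """

    window: tuple[int, int]
    counts: np.ndarray
    n_sites: int

    @property
    def offsets(self) -> list[int]:
        return list(range(self.window[0], self.window[1] + 1))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.counts, index=self.offsets, columns=list(NUCLEOTIDES)
        ).rename_axis("offset")


def gene_expression(
    library: LibraryAlignments, genes: Sequence[GeneRecord]
) -> list[ExpressionRecord]:
    """RPKM per gene from same-strand reads overlapping the gene body.

    A read counts toward a gene when it overlaps it by at least 1 bp on
    the same strand; RPKM = count / (gene length in kb x mappable reads
    in millions).
    """
    if library.total_mappable == 0:
        raise ValueError("library has no mappable reads")
    by_group: dict[tuple[str, str], list[AlignedReadRecord]] = {}
    for r in library.reads:
        by_group.setdefault((r.chrom, r.strand), []).append(r)
    # sort once per group; count overlaps via start/end arrays
    arrays: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for key, rs in by_group.items():
        starts = np.sort(np.array([r.start for r in rs]))
        ends = np.sort(np.array([r.end for r in rs]))
        arrays[key] = (starts, ends)
    out = []
    denom = library.total_mappable / 1e6
    for g in genes:
        starts, ends = arrays.get((g.chrom, g.strand), (np.array([]), np.array([])))
        n = len(starts)
        if n:
            # overlap iff read.start < g.end and read.end > g.start
            count = int(
                np.searchsorted(starts, g.end, side="left")
                - np.searchsorted(ends, g.start, side="right")
            )
        else:
            count = 0
        rpkm = count / ((g.length / 1000.0) * denom)
        out.append(ExpressionRecord(g.gene_id, count, rpkm))
    return out


def classify_primary_processed(
    library: LibraryAlignments | Iterable[AlignedReadRecord],
    known_tss: Sequence[tuple[str, int, str]],
    rrna_genes: Sequence[GeneRecord] = (),
    tolerance: int = 5,
) -> dict[str, float]:
    """Partition mapped reads into non-rRNA / primary rRNA / processed rRNA.

    A read is primary when its 5' end lies within ``tolerance`` bp of a
    known same-strand TSS. rRNA reads are those overlapping an rRNA gene
    on the same strand; they split into primary and processed, and all
    other reads are reported together with their primary fraction.
    Returned fractions over all mapped reads sum to 1.
    """
    reads = library.reads if isinstance(library, LibraryAlignments) else library
    reads = list(reads)
    if not known_tss:
        warnings.warn("empty known TSS set: all reads classified processed", stacklevel=2)
    tss_by_strand: dict[tuple[str, str], np.ndarray] = {}
    for chrom, pos, strand in known_tss:
        tss_by_strand.setdefault((chrom, strand), []).append(pos)  # type: ignore[attr-defined]
    tss_by_strand = {k: np.sort(np.array(v)) for k, v in tss_by_strand.items()}

    def is_primary(r: AlignedReadRecord) -> bool:
        positions = tss_by_strand.get((r.chrom, r.strand))
        if positions is None or len(positions) == 0:
            return False
        i = np.searchsorted(positions, r.five_prime)
        for j in (i - 1, i):
            if 0 <= j < len(positions) and abs(int(positions[j]) - r.five_prime) <= tolerance:
                return True
        return False

    def is_rrna(r: AlignedReadRecord) -> bool:
        return any(
            g.chrom == r.chrom
            and g.strand == r.strand
            and r.start < g.end
            and g.start < r.end
            for g in rrna_genes
        )

    n = len(reads)
    if n == 0:
        return {"non_rrna": 0.0, "primary_rrna": 0.0, "processed_rrna": 0.0,
                "primary_fraction": 0.0}
    n_rrna_primary = n_rrna_processed = n_other = n_primary = 0
    for r in reads:
        primary = is_primary(r)
        n_primary += primary
        if is_rrna(r):
            if primary:
                n_rrna_primary += 1
            else:
                n_rrna_processed += 1
        else:
            n_other += 1
    return {
        "non_rrna": n_other / n,
        "primary_rrna": n_rrna_primary / n,
        "processed_rrna": n_rrna_processed / n,
        "primary_fraction": n_primary / n,
    }


def extract_site_windows(
    sites: Sequence[tuple[str, int, str]],
    genome: Mapping[str, str],
    window: tuple[int, int] | str = "tss",
) -> tuple[list[tuple[str, str]], PositionFrequencyMatrix]:
    """Transcript-oriented sequence windows around single-base sites.

    ``window`` is an inclusive (start, end) offset pair or a preset name
    from :data:`WINDOW_PRESETS`. Offset 0 is the site base; negative
    offsets are upstream in transcript orientation, so minus-strand
    windows are taken from the reverse complement. Sites whose window
    runs off a chromosome edge are skipped for the PFM. Returns
    (site_id, sequence) pairs and the accumulated PFM.
    """
    if isinstance(window, str):
        window = WINDOW_PRESETS[window]
    off_start, off_end = window
    if off_start > off_end:
        raise ValueError("window start offset must not exceed end offset")
    width = off_end - off_start + 1
    counts = np.zeros((width, 4), dtype=int)
    index = {b: i for i, b in enumerate(NUCLEOTIDES)}
    seqs: list[tuple[str, str]] = []
    n_used = 0
    for chrom, pos, strand in sites:
        ref = genome[chrom]
        if strand == "+":
            lo, hi = pos + off_start, pos + off_end + 1
        else:
            lo, hi = pos - off_end, pos - off_start + 1
        if lo < 0 or hi > len(ref):
            warnings.warn(
                f"site {chrom}:{pos}:{strand} window exceeds chromosome edge, skipped",
                stacklevel=2,
            )
            continue
        seq = str(ref[lo:hi]).upper()
        if strand == "-":
            seq = reverse_complement(seq)
        name = f"{chrom}:{pos + 1}:{strand}"
        seqs.append((name, seq))
        n_used += 1
        for i, base in enumerate(seq):
            col = index.get(base)
            if col is not None:
                counts[i, col] += 1
    return seqs, PositionFrequencyMatrix((off_start, off_end), counts, n_used)


def write_fasta(seqs: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
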
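"""Raw-read filtering and trimming for full-length CCS libraries.

Library construction leaves three decorations on a circular-consensus
read: a ligation adapter, a 5' poly(C) tail added by the template-switch
step, and the transcript's 3' poly(A) tail. Chimeric molecules carry the
adapter more than once and are discarded; reads without the adapter are
library artefacts and are also discarded. After mapping, untemplated
poly(A) remaining at the aligned 3' end is walked back against the
reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import AlignedReadRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RawRead:
    """An unaligned read: id, sequence, optional per-base qualities."""

    read_id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")


@dataclass
class PreprocessReport:
    """Counts from chimera filtering and tail trimming.

    Invariant: ``n_input == n_chimeric + n_no_adaptor + n_kept``.
    """

    n_input: int = 0
    n_chimeric: int = 0
    n_no_adaptor: int = 0
    n_kept: int = 0
    bases_trimmed_5p: int = 0
    bases_trimmed_3p: int = 0

    def as_dict(self) -> dict:
        return dict(vars(self))


def _match_positions(seq: str, pattern: str, max_mismatches: int) -> list[int]:
    """Start offsets of non-overlapping matches of pattern in seq.

    A match allows up to ``max_mismatches`` substitutions; overlapping
    candidates are resolved greedily left to right.
    """
    m, n = len(pattern), len(seq)
    if n < m:
        return []
    s = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    p = np.frombuffer(pattern.upper().encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    mism = (windows != p).sum(axis=1)
    hits = np.flatnonzero(mism <= max_mismatches)
    out: list[int] = []
    last_end = -1
    for h in hits:
        if h >= last_end:
            out.append(int(h))
            last_end = h + m
    return out


def count_adaptors(seq: str, adaptor: str, max_mismatches: int = 0) -> int:
    """Occurrences of the adapter in a read, scanning both orientations."""
    return len(_match_positions(seq, adaptor, max_mismatches)) + len(
        _match_positions(seq, reverse_complement(adaptor), max_mismatches)
    )


def filter_chimeras(
    reads: Iterable[RawRead],
    adaptor_sequence: str,
    max_mismatches: int = 0,
) -> tuple[list[RawRead], PreprocessReport]:
    """Keep reads bearing exactly one adapter occurrence.

    Reads with more than one occurrence (either orientation) are chimeric;
    reads with none lack the ligation adapter. Both classes are discarded
    and tallied in the report.
    """
    if not adaptor_sequence:
        raise ValueError("adaptor sequence must be non-empty")
    if len(adaptor_sequence) < 10:
        raise ValueError("adaptor sequence must be at least 10 bases")
    report = PreprocessReport()
    kept: list[RawRead] = []
    for read in reads:
        report.n_input += 1
        n = count_adaptors(read.sequence, adaptor_sequence, max_mismatches)
        if n == 0:
            report.n_no_adaptor += 1
        elif n > 1:
            report.n_chimeric += 1
        else:
            report.n_kept += 1
            kept.append(read)
    return kept, report


def strip_adaptor(
    read: RawRead, adaptor_sequence: str, max_mismatches: int = 0
) -> RawRead:
    """Remove the single adapter occurrence and any sequence 5' of it.

    The read is reverse-complemented first if the adapter is found on the
    opposite strand, so output reads share the transcript orientation.
    Reads without an adapter are returned unchanged.
    """
    fwd = _match_positions(read.sequence, adaptor_sequence, max_mismatches)
    if not fwd:
        rev = _match_positions(
            read.sequence, reverse_complement(adaptor_sequence), max_mismatches
        )
        if not rev:
            return read
        seq = reverse_complement(read.sequence)
        fwd = _match_positions(seq, adaptor_sequence, max_mismatches)
        read = replace(read, sequence=seq, qualities=None)
    cut = fwd[0] + len(adaptor_sequence)
    quals = read.qualities[cut:] if read.qualities else None
    return replace(read, sequence=read.sequence[cut:], qualities=quals)


def _terminal_run_length(
    seq: str, base: str, from_end: bool, min_run: int, max_mismatch_per_10: int
) -> int:
    """Longest terminal stretch trimmable as a ``base`` homopolymer tail.

    The stretch must start at the terminus, end on a matching base, keep
    its mismatch density at or below ``max_mismatch_per_10`` per 10 bases,
    and reach ``min_run``; returns 0 if no stretch qualifies.
    """
    s = seq[::-1] if from_end else seq
    if not s or s[0].upper() != base:
        return 0  # a terminal run must begin at the terminus itself
    best = 0
    mismatches = 0
    for i, ch in enumerate(s):
        if ch.upper() != base:
            mismatches += 1
            # density can no longer recover within the read: stop scanning
            if mismatches * 10 > max_mismatch_per_10 * len(s):
                break
            continue
        length = i + 1
        if mismatches * 10 <= max_mismatch_per_10 * length and length >= min_run:
            best = length
    return best


def trim_poly_tails(
    read: RawRead, min_run: int = 8, max_mismatch_per_10: int = 1
) -> RawRead | None:
    """Trim the 3' poly(A) and 5' poly(C) tails off a read.

    Trimming is maximal and terminal-only; internal homopolymers are left
    alone. Returns None (with a warning) if trimming consumes the whole
    read.
    """
    seq = read.sequence
    tail3 = _terminal_run_length(seq, "A", True, min_run, max_mismatch_per_10)
    if tail3:
        seq = seq[: len(seq) - tail3]
    tail5 = _terminal_run_length(seq, "C", False, min_run, max_mismatch_per_10)
    if tail5:
        seq = seq[tail5:]
    if not seq:
        warnings.warn(f"read {read.read_id} fully consumed by tail trimming", stacklevel=2)
        return None
    if seq == read.sequence:
        return read
    quals = None
    if read.qualities:
        quals = read.qualities[tail5 : len(read.sequence) - tail3 or None]
    return replace(read, sequence=seq, qualities=quals)


def _ref_base(genome: Mapping[str, str], chrom: str, pos: int) -> str:
    return str(genome[chrom][pos : pos + 1]).upper()


def adjust_three_prime(
    alignment: AlignedReadRecord,
    genome: Mapping[str, str],
    run_min: int = 3,
) -> AlignedReadRecord | None:
    """Walk the aligned 3' end back over a templated poly(A) run.

    Residual poly(A) that happens to match the reference survives
    read-level trimming and inflates the 3' position; a terminal run of
    at least ``run_min`` template-sense A's (reference A on ``+`` reads,
    reference T on ``-`` reads) is removed from the aligned span. The 5'
    end never moves. Returns None if the adjustment would empty the
    alignment.
    """
    if alignment.strand == "+":
        pos = alignment.end - 1
        run = 0
        while pos >= alignment.start and _ref_base(genome, alignment.chrom, pos) == "A":
            run += 1
            pos -= 1
        if run < run_min:
            return alignment
        new_end = alignment.end - run
        if new_end <= alignment.start:
            warnings.warn(f"read {alignment.read_id} emptied by 3' adjustment", stacklevel=2)
            return None
        return replace(alignment, end=new_end)
    pos = alignment.start
    run = 0
    while pos < alignment.end and _ref_base(genome, alignment.chrom, pos) == "T":
        run += 1
        pos += 1
    if run < run_min:
        return alignment
    new_start = alignment.start + run
    if new_start >= alignment.end:
        warnings.warn(f"read {alignment.read_id} emptied by 3' adjustment", stacklevel=2)
        return None
    return replace(alignment, start=new_start)


def preprocess_reads(
    reads: Sequence[RawRead],
    adaptor_sequence: str,
    max_mismatches: int = 0,
    min_run: int = 8,
    max_mismatch_per_10: int = 1,
) -> tuple[list[RawRead], PreprocessReport]:
    """Full raw-read pipeline: chimera filter, adapter strip, tail trim."""
    kept, report = filter_chimeras(reads, adaptor_sequence, max_mismatches)
    out: list[RawRead] = []
    for read in kept:
        stripped = strip_adaptor(read, adaptor_sequence, max_mismatches)
        trimmed = trim_poly_tails(stripped, min_run, max_mismatch_per_10)
        if trimmed is None:
            continue
        report.bases_trimmed_5p += _count_leading_trim(stripped, trimmed, True)
        report.bases_trimmed_3p += _count_leading_trim(stripped, trimmed, False)
        out.append(trimmed)
    return out, report


def _count_leading_trim(before: RawRead, after: RawRead, five_prime: bool) -> int:
    if five_prime:
        return before.sequence.find(after.sequence)
    cut5 = before.sequence.find(after.sequence)
    return len(before.sequence) - cut5 - len(after.sequence)
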
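"""Seeded simulator for full-length transcript libraries with known truth.

Generates a random genome with planted operons, then draws reads per
the generative model the end-calling statistics assume: an enriched
read starts exactly at a TSS chosen by weight and walks 3'-wards,
stopping at each base with a small memoryless premature hazard
(incomplete transcription / degradation), at each terminator with
probability 1 - read_through, and otherwise at the operon's terminal
end. Control-library reads additionally have their 5' end resampled
uniformly inside the transcript with a configurable probability,
mimicking processed transcripts whose starts are not initiation sites.
Every read carries a provenance record (source TSS and stop cause) so
recovery tests can score calls against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .formats_io import AlignedReadRecord, GeneRecord, LibraryAlignments, write_bed12


@dataclass(frozen=True)
class SimTSS:
    position: int
    weight: float = 1.0


@dataclass(frozen=True)
class SimTTS:
    position: int
    read_through: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.read_through <= 1.0:
            raise ValueError("read_through must lie in [0, 1]")


@dataclass(frozen=True)
class SimOperonSpec:
    """Layout of one simulated operon.

    Genes, start sites and terminators are given in genomic coordinates;
    transcription runs from each TSS towards ``terminal_end``. On the
    minus strand the TSS has the largest coordinate and ``terminal_end``
    the smallest.
    """

    operon_id: str
    chrom: str
    strand: str
    genes: tuple[GeneRecord, ...]
    tss_list: tuple[SimTSS, ...]
    tts_list: tuple[SimTTS, ...]
    terminal_end: int

    def __post_init__(self) -> None:
        sign = 1 if self.strand == "+" else -1
        for tss in self.tss_list:
            for tts in self.tts_list:
                if sign * (tts.position - tss.position) <= 0:
                    raise ValueError(
                        f"operon {self.operon_id}: TSS {tss.position} not upstream "
                        f"of TTS {tts.position}"
                    )
        for g in self.genes:
            lo = min(t.position for t in self.tss_list) if self.strand == "+" else self.terminal_end
            hi = self.terminal_end if self.strand == "+" else max(t.position for t in self.tss_list)
            if not (lo <= g.start and g.end <= hi + 1):
                raise ValueError(f"operon {self.operon_id}: gene {g.gene_id} outside span")

    def ordered_tts(self) -> list[SimTTS]:
        return sorted(
            self.tts_list,
            key=lambda t: t.position,
            reverse=self.strand == "-",
        )


@dataclass
class SimConfig:
    """Study conditions for one simulation run.

    Defaults reflect a deeply sequenced bacterial library: 50 reads per
    start site, a premature-stop hazard of 5e-4 per base, and a control
    library in which 60% of reads are processed (resampled 5' ends).
    """

    genome_length: int = 60_000
    n_operons: int = 6
    depth_per_tss: int = 50
    premature_stop_hazard: float = 5e-4
    control_processed_fraction: float = 0.6
    genes_per_operon: tuple[int, int] = (2, 4)
    gene_length: tuple[int, int] = (300, 900)
    spacer_length: tuple[int, int] = (40, 120)
    utr_length: tuple[int, int] = (30, 80)
    n_tss_per_operon: tuple[int, int] = (1, 2)
    read_through_range: tuple[float, float] = (0.05, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.premature_stop_hazard <= 0.01:
            raise ValueError("premature_stop_hazard must lie in [0, 0.01]")
        if not 0.0 <= self.control_processed_fraction <= 1.0:
            raise ValueError("control_processed_fraction must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class ReadProvenance:
    """Truth for one simulated read: where it started and why it stopped."""

    read_id: str
    operon_id: str
    tss: int
    stop_cause: str  # "tts:<position>", "premature" or "terminal"
    resampled_five_prime: bool = False


@dataclass
class SimGroundTruth:
    """True sites and parameters for a simulated data set."""

    operons: list[SimOperonSpec] = field(default_factory=list)
    provenance: list[ReadProvenance] = field(default_factory=list)

    @property
    def tss_positions(self) -> list[tuple[str, int, str]]:
        return [
            (op.chrom, tss.position, op.strand)
            for op in self.operons
            for tss in op.tss_list
        ]

    @property
    def tts_positions(self) -> list[tuple[str, int, str]]:
        return [
            (op.chrom, tts.position, op.strand)
            for op in self.operons
            for tts in op.tts_list
        ]

    def read_through_of(self, chrom: str, position: int, strand: str) -> float:
        for op in self.operons:
            if op.chrom != chrom or op.strand != strand:
                continue
            for tts in op.tts_list:
                if tts.position == position:
                    return tts.read_through
        raise KeyError((chrom, position, strand))

    def stop_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.provenance:
            cause = p.stop_cause.split(":")[0]
            counts[cause] = counts.get(cause, 0) + 1
        return counts


def _layout_operons(config: SimConfig, rng: np.random.Generator) -> list[SimOperonSpec]:
    """Place non-overlapping operons along the genome, alternating strands."""
    specs: list[SimOperonSpec] = []
    cursor = 500
    gene_counter = 0
    for i in range(config.n_operons):
        strand = "+" if i % 2 == 0 else "-"
        n_genes = int(rng.integers(config.genes_per_operon[0], config.genes_per_operon[1] + 1))
        utr5 = int(rng.integers(*config.utr_length))
        utr3 = int(rng.integers(*config.utr_length))
        gene_spans = []
        pos = cursor + utr5
        boundaries = []  # intergenic TTS anchor points (gene 3' boundaries)
        for _ in range(n_genes):
            glen = int(rng.integers(*config.gene_length))
            gene_spans.append((pos, pos + glen))
            pos += glen
            boundaries.append(pos)
            pos += int(rng.integers(*config.spacer_length))
        terminal_right = pos - int(rng.integers(*config.spacer_length)) // 2 + utr3
        start = cursor
        end = terminal_right
        n_tss = int(rng.integers(config.n_tss_per_operon[0], config.n_tss_per_operon[1] + 1))
        # internal TSSs sit in spacers upstream of later genes
        tss_anchor = [start] + [
            gene_spans[j][1] + 5 for j in range(min(n_tss - 1, n_genes - 1))
        ]
        # terminators: candidate after each non-final gene, plus the terminal end
        internal_tts = boundaries[:-1]
        rts = rng.uniform(*config.read_through_range, size=len(internal_tts))
        if strand == "+":
            genes = tuple(
                GeneRecord(f"g{gene_counter + j}", "chrSim", s, e, strand)
                for j, (s, e) in enumerate(gene_spans)
            )
            tss = tuple(
                SimTSS(p, w)
                for p, w in zip(tss_anchor[:n_tss], _weights(n_tss))
            )
            tts = tuple(
                SimTTS(p + 10, float(r)) for p, r in zip(internal_tts, rts)
            )
            terminal = end - 1
        else:
            # mirror the layout: transcription right-to-left
            genes = tuple(
                GeneRecord(f"g{gene_counter + j}", "chrSim", s, e, strand)
                for j, (s, e) in enumerate(gene_spans)
            )
            right = end - 1
            tss = tuple(
                SimTSS(right - (p - start), w)
                for p, w in zip(tss_anchor[:n_tss], _weights(n_tss))
            )
            tts = tuple(
                SimTTS(right - (p - start) - 10, float(r))
                for p, r in zip(internal_tts, rts)
            )
            terminal = start
        gene_counter += n_genes
        specs.append(
            SimOperonSpec(
                operon_id=f"op{i}",
                chrom="chrSim",
                strand=strand,
                genes=genes,
                tss_list=tss,
                tts_list=tts,
                terminal_end=terminal,
            )
        )
        cursor = end + 300
    if cursor + 500 > config.genome_length:
        raise ValueError(
            f"genome_length {config.genome_length} too short for layout "
            f"(needs about {cursor + 500})"
        )
    return specs


def _weights(n: int) -> list[float]:
    """Decreasing TSS strengths summing to 1 (major TSS first)."""
    raw = [2.0 ** -i for i in range(n)]
    total = sum(raw)
    return [w / total for w in raw]


def simulate_genome(
    config: SimConfig,
) -> tuple[str, list[GeneRecord], list[SimOperonSpec]]:
    """Random genome sequence with planted operons.

    Returns (sequence, gene records, operon specs); deterministic under
    ``config.seed``. On the minus strand the mirrored layout keeps each
    TSS upstream (rightwards) of its terminators.
    """
    rng = np.random.default_rng(config.seed)
    specs = _layout_operons(config, rng)
    seq = rng.choice(list("ACGT"), size=config.genome_length)
    genome = "".join(seq)
    genes = [g for op in specs for g in op.genes]
    return genome, genes, specs


def _simulate_read_ends(
    op: SimOperonSpec,
    tss: SimTSS,
    n: int,
    hazard: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    """Vectorised 3'-end draw for n reads from one TSS.

    The stop boundary is the first terminator the polymerase does not
    read through, else the terminal end; a geometric premature stop
    preempts the boundary when it lands strictly before it.
    """
    sign = 1 if op.strand == "+" else -1
    tts_after = [t for t in op.ordered_tts() if sign * (t.position - tss.position) > 0]
    # distance (in bases transcribed, >= 1 at the TSS base itself) to each stop
    boundary_dist = np.full(n, abs(op.terminal_end - tss.position) + 1)
    boundary_label = ["terminal"] * n
    undecided = np.ones(n, dtype=bool)
    for t in tts_after:
        stop_here = undecided & (rng.random(n) >= t.read_through)
        d = abs(t.position - tss.position) + 1
        boundary_dist[stop_here] = d
        for i in np.flatnonzero(stop_here):
            boundary_label[i] = f"tts:{t.position}"
        undecided &= ~stop_here
    if hazard > 0:
        premature = rng.geometric(hazard, size=n)
    else:
        premature = np.full(n, np.iinfo(np.int64).max)
    lengths = np.minimum(boundary_dist, premature)
    labels = [
        "premature" if premature[i] < boundary_dist[i] else boundary_label[i]
        for i in range(n)
    ]
    three_prime = tss.position + sign * (lengths - 1)
    return three_prime, labels


def simulate_library(
    specs: Sequence[SimOperonSpec],
    config: SimConfig,
    mode: Literal["enriched", "control"] = "enriched",
    label: str | None = None,
) -> tuple[LibraryAlignments, SimGroundTruth]:
    """Draw a full-length read library with per-read provenance.

    Enriched reads start exactly at their TSS; in control mode a
    ``control_processed_fraction`` of reads have the 5' end resampled
    uniformly inside the transcript. The library seed is offset by mode
    so enriched and control libraries are independent draws.
    """
    rng = np.random.default_rng((config.seed, {"enriched": 1, "control": 2}[mode]))
    truth = SimGroundTruth(operons=list(specs))
    reads: list[AlignedReadRecord] = []
    counter = 0
    for op in specs:
        weights = np.array([t.weight for t in op.tss_list], dtype=float)
        weights /= weights.sum()
        sign = 1 if op.strand == "+" else -1
        for tss, w in zip(op.tss_list, weights):
            n = int(round(config.depth_per_tss * w * len(op.tss_list)))
            if n == 0:
                continue
            ends, labels = _simulate_read_ends(
                op, tss, n, config.premature_stop_hazard, rng
            )
            for j in range(n):
                five = tss.position
                three = int(ends[j])
                resampled = False
                if mode == "control" and rng.random() < config.control_processed_fraction:
                    length = abs(three - five) + 1
                    if length > 1:
                        offset = int(rng.integers(1, length))
                        five = tss.position + sign * offset
                        resampled = True
                start, end = (min(five, three), max(five, three) + 1)
                read_id = f"{mode[0]}r{counter}"
                counter += 1
                reads.append(
                    AlignedReadRecord(read_id, op.chrom, start, end, op.strand)
                )
                truth.provenance.append(
                    ReadProvenance(read_id, op.operon_id, tss.position, labels[j], resampled)
                )
    library = LibraryAlignments(
        label=label or mode, reads=reads, total_mappable=len(reads)
    )
    return library, truth


# ---------------------------------------------------------------------------
# Raw-read emission for preprocess testing


@dataclass
class TailParams:
    """Decoration lengths for raw-read emission."""

    polya_length: int = 12
    polyc_length: int = 10
    chimera_fraction: float = 0.0
    no_adaptor_fraction: float = 0.0


def emit_raw_reads(
    library: LibraryAlignments,
    genome: str | dict[str, str],
    adapter: str,
    tail_params: TailParams | None = None,
    seed: int = 0,
) -> list:
    """Decorate simulated transcripts into raw CCS-like reads.

    Each read is adapter + 5' poly(C) + transcript + 3' poly(A).
    A seeded fraction of reads is emitted as chimeras (two decorated
    inserts concatenated) or without the adapter.
    """
    from .preprocess import RawRead, reverse_complement

    tail_params = tail_params or TailParams()
    rng = np.random.default_rng(seed)

    def ref(chrom: str) -> str:
        return genome if isinstance(genome, str) else genome[chrom]

    def decorated(read: AlignedReadRecord) -> str:
        seq = ref(read.chrom)[read.start : read.end]
        if read.strand == "-":
            seq = reverse_complement(seq)
        return (
            adapter
            + "C" * tail_params.polyc_length
            + seq
            + "A" * tail_params.polya_length
        )

    out = []
    reads = library.reads
    for i, read in enumerate(reads):
        u = rng.random()
        if u < tail_params.chimera_fraction:
            partner = reads[int(rng.integers(len(reads)))]
            seq = decorated(read) + decorated(partner)
            rid = f"{read.read_id}_chimera"
        elif u < tail_params.chimera_fraction + tail_params.no_adaptor_fraction:
            seq = decorated(read)[len(adapter):]
            rid = f"{read.read_id}_noadaptor"
        else:
            seq = decorated(read)
            rid = read.read_id
        out.append(RawRead(rid, seq))
    return out


# ---------------------------------------------------------------------------
# File emission


def write_fasta_genome(genome: str, path: str | Path, chrom: str = "chrSim") -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome), 70):
            fh.write(genome[i : i + 70] + "\n")


def write_gff3(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};gene_id={g.gene_id};gene_biotype={g.biotype}\n"
            )


def write_truth_tsv(truth: SimGroundTruth, path: str | Path) -> None:
    import pandas as pd

    rows = []
    for op in truth.operons:
        for tss in op.tss_list:
            rows.append(
                dict(operon_id=op.operon_id, chrom=op.chrom, strand=op.strand,
                     kind="tss", position=tss.position, value=tss.weight)
            )
        for tts in op.tts_list:
            rows.append(
                dict(operon_id=op.operon_id, chrom=op.chrom, strand=op.strand,
                     kind="tts", position=tts.position, value=tts.read_through)
            )
        rows.append(
            dict(operon_id=op.operon_id, chrom=op.chrom, strand=op.strand,
                 kind="terminal", position=op.terminal_end, value=np.nan)
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def simulate_to_dir(config: SimConfig, out_dir: str | Path, raw_reads: bool = False,
                    adapter: str = "ATCTCTCTCAACAACAACAACGGAGG") -> dict[str, Path]:
    """Run the full simulation and write genome, annotation, libraries, truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, genes, specs = simulate_genome(config)
    enriched, truth = simulate_library(specs, config, "enriched")
    control, control_truth = simulate_library(specs, config, "control")
    paths = {
        "genome": out / "genome.fa",
        "genes": out / "genes.gff3",
        "enriched": out / "enriched.bed12",
        "control": out / "control.bed12",
        "truth": out / "truth.tsv",
    }
    write_fasta_genome(genome, paths["genome"])
    write_gff3(genes, paths["genes"])
    write_bed12(enriched.reads, paths["enriched"])
    write_bed12(control.reads, paths["control"])
    write_truth_tsv(truth, paths["truth"])
    if raw_reads:
        raw = emit_raw_reads(enriched, genome, adapter, seed=config.seed)
        paths["raw"] = out / "raw.fastq"
        with open(paths["raw"], "w") as fh:
            for r in raw:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
    return paths
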
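# opvar

Operon variants, transcription start/termination sites and terminator
read-through from full-length prokaryotic long reads.

## The problem

Bacterial genes are transcribed in polycistronic units, but a single locus
rarely produces a single transcript: alternative start sites, terminators
that are read through, and premature ends generate families of overlapping
transcripts whose gene content differs. Short-read RNA-seq cannot connect a
transcript's 5' end to its 3' end, so operon structure has historically
been inferred indirectly. Long-read sequencing of cap-enriched,
full-length transcripts changes that: each read is one transcript, with
its true initiation site at the 5' end and its termination point at the
3' end. `opvar` turns a set of such aligned reads into:

* **TSS calls** — clustered 5'-end pileups, filtered by enrichment over a
  non-enriched control;
* **TTS calls** — 3'-end accumulation points tested against a random-ending
  null;
* **read-through** — the fraction of transcripts continuing past each
  terminator, overall and per start site;
* **operon variants** — the unique strand-oriented combinations of genes
  fully covered by transcripts sharing a start and end, and per-gene
  *transcriptional contexts* (how many distinct variants carry each gene);
* supporting quantities: gene-level RPKM, primary/processed read
  classification, and oriented sequence windows around called sites for
  motif and RNA-structure analyses.

A seeded simulator generates genomes, annotations and read libraries with
known ground truth, so the whole pipeline is testable without sequencing
data.

## The statistics at the core

**TSS.** For each genomic position and strand, `T` is the number of reads
starting there and `TPM = T / N × 10⁶` its library-size normalisation
(`N` = mappable reads). With an enriched and a control library the
enrichment ratio is

    SMRTratio = ((T_e + 1) / N_e) / ((T_c + 1) / N_c)

(pseudo-count 1 on both counts). Positions with ratio > 1 are clustered
within 5 bp on the same strand around the highest-count position, and
clusters with more than 4 reads are reported.

**TTS.** For the `n` reads sharing a TSS, a transcript of length `D` ends
at any given base with probability `1/D` under the random-ending null
(incomplete transcription or degradation). A position where `k` reads end
is called a terminator when

    k/n > 200 × (1/D)   and   k ≥ 10   and   P(X ≥ k) < 0.05,  X ~ Binom(n, 1/D).

Calls within 5 bp merge to the most-3' position. Read-through at a called
TTS is `n_through / n_covering` over same-strand reads spanning the site
with their 5' end upstream; a read "reads through" when its 3' end extends
more than 5 bp past the site.

**Operons.** Reads from each retained TSS are grouped by the called TTS
they terminate at (3' end within 5 bp), or — lacking one — into a single
group bounded by the longest observed 3' end. Each group's span defines a
transcript unit; the genes fully contained in that span (strand-aware)
form its gene tuple, and units with identical tuples collapse into one
operon variant. A gene's number of transcriptional contexts is the number
of distinct variants containing it.

## Worked example

Simulate a small study and run every stage:

```bash
opvar simulate --out demo --seed 11 --n-operons 4 --depth 40 --genome-length 50000
opvar run-all --alignments demo/enriched.bed12 --control demo/control.bed12 \
              --genes demo/genes.gff3 --out-dir demo_out
```

The run report prints per-stage record counts:

```json
{
  "antisense_operons": {"n": 0},
  "contexts": {"n": 8},
  "expression": {"n": 10},
  "operons": {"n": 8},
  "readthrough": {"n": 4},
  "tss": {"n": 6},
  "tts": {"n": 4}
}
```

Six TSS were called (the simulation planted six across four operons), four
terminators passed the binomial criterion, and the reads group into eight
operon variants over the ten genes. `demo_out/tss.tsv` holds the evidence
per site — e.g. the first cluster:

```
chrom   position_1based  strand  members  T_total  smrt_ratio  TPM
chrSim  501              +       500      40       2.28        166666.7
```

40 reads start at this position and the site is 2.3-fold enriched over the
control, so it is a confident initiation site. `demo_out/operons.tsv`
lists the variants with their boundaries and support:

```
gene_ids  chrom   start  end   strand  n_units  total_support
g0        chrSim  500    1146  +       1        15
g0,g1     chrSim  500    2026  +       1        25
```

Here the same start site yields both a monocistronic `g0` transcript
(15 reads stopping at the terminator after `g0`) and a `g0,g1`
read-through form (25 reads) — an operon variant pair.

Individual stages are available as `opvar preprocess`, `call-tss`,
`call-tts`, `readthrough`, `qc` and `windows`; `opvar COMMAND --help`
lists the thresholds, which default to the calling parameters above.

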
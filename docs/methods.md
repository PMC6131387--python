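# Methods

## Scope and data model

`opvar` consumes one alignment per full-length transcript (BED12 or BAM;
secondary and supplementary records are dropped) plus a gene annotation
(GFF3 or BED6) and, optionally, a genome FASTA and an annotated operon
table. All internal coordinates are 0-based half-open; GFF3 is converted
on input and TSV reports print 1-based positions. A read's biological
ends follow from span and strand: on `+` the 5' end is `start` and the 3'
end `end − 1`; on `−` they swap. Reads on contigs absent from the
annotation still participate in end calling; gene-aware operations ignore
them.

## Raw-read preprocessing

Library construction decorates each circular-consensus read with a
ligation adapter, a 5' poly(C) tail and the transcript's 3' poly(A) tail.
`filter_chimeras` counts non-overlapping adapter matches (both
orientations, up to `max_mismatches` substitutions, default 0) and keeps
reads with exactly one: zero means a library artefact, more than one a
chimeric fusion. `strip_adaptor` then removes the matched adapter and any
bases 5' of it, reorienting reads whose adapter lies on the reverse
strand, so poly-tail trimming sees the tails at the termini.

`trim_poly_tails` removes a maximal *terminal* homopolymer run: the run
must start at the terminus with a matching base, end on a matching base,
reach `min_run` (default 8) and keep its mismatch density at or below 1
per 10 bases. This definition is idempotent (a second pass can never
remove more) and leaves internal homopolymers untouched. One consequence
worth knowing: genomic A's (or C's) directly adjoining the tail are
indistinguishable from it and are trimmed with it. After mapping,
`adjust_three_prime` walks the aligned 3' end back over a templated
poly(A) run of ≥ 3 reference bases (reference T's on `−` reads), because
residual tail bases that happen to match the genome survive read-level
trimming and would shift 3'-end positions. The original trimming scripts'
thresholds are unpublished, so all of these are parameters; the defaults
above are what we consider sensible for CCS-quality reads.

## TSS calling

Per (position, strand), `T` counts reads starting there and
`TPM = T/N × 10⁶` normalises by mappable reads `N`. The enrichment ratio
against a non-enriched control is
`((T_e + 1)/N_e) / ((T_c + 1)/N_c)`; the pseudo-count keeps it defined
where the control is empty. Positions with ratio > 1 enter clustering;
the reported TPM stays un-pseudo-counted (the pseudo-count exists only to
stabilise the ratio). Without a control the filter is skipped with a
warning — calls are then unvalidated against processed-transcript
contamination.

Clustering is greedy: repeatedly seed on the unassigned position with the
highest `T` (ties to the 5'-most position on the strand, for
determinism), absorb unassigned same-strand positions within ±5 bp, and
emit. Greedy seeding — rather than single-linkage chaining — guarantees
every member lies within 5 bp of its representative; chaining does not.
"Within 5 bp" is inclusive (distance ≤ 5). Clusters with more than four
supporting reads (sum over members) are kept. Between conditions, TSS
match on exact (chrom, position, strand) and the Pearson correlation is
computed over common sites' TPM; with fewer than three common sites, or a
constant score vector, it is reported as NaN.

## TTS calling

Reads are assigned to the TSS cluster containing their 5' end (member
sets are disjoint, so assignment is unique; unassigned reads are excluded
— termination evidence is only interpretable relative to a known start).
For each cluster, 3'-end positions are tallied. With `n` reads in the
cluster and `k` ending at a position at inclusive distance `D` from the
representative (so `D` equals transcript length; the TSS base and the
terminal base both count), the position is called when

* `k/n > 200/D` — the observed ending fraction exceeds 200× the uniform
  null `1/D`;
* `k ≥ 10`;
* the upper binomial tail `P(X ≥ k)`, `X ~ Binom(n, 1/D)`, is below 0.05
  (one-tailed; computed with the scipy survival function, which a test
  checks against exact rational summation to 1e-12).

No multiple-testing correction is applied by default, matching the
calling recipe; the α parameter is exposed. Note the fold criterion makes
positions with `D ≤ 200` uncallable (`k/n ≤ 1`), an intrinsic property of
the rule: terminators very close to their start site cannot be
distinguished from the null at any depth.

Calls within 5 bp on one strand merge to the most-3' member (largest
coordinate on `+`, smallest on `−`); per-source-TSS counts are summed and
evidence recomputed at the merged position. When several TSSs support one
site, the pooled `k` and `n` are reported while `D` and the p-value come
from the source TSS contributing the most reads — a single evidence scale
is ill-defined across different `D`s, so per-TSS triples are retained on
the call.

**Read-through.** Covering reads are same-strand reads spanning the site
whose 5' end lies upstream; a covering read reads through when its 3' end
extends more than 5 bp past the site (the merge window — ends inside it
count as terminated). `percent_through = n_through / n_covering`;
`median_extension` is the median extension among read-through reads, and
`genes_included` the genes fully covered by an extension region.
`readthrough_by_tss` repeats the computation per source TSS, which is how
start-site-dependent termination is measured.

## Operon variants and contexts

Only reads from retained TSS clusters participate. Within a cluster,
reads whose 3' end lies within 5 bp of a called TTS form one group per
TTS; the rest form a single fallback group bounded by the longest
observed 3' end. Each group is a transcript unit spanning representative
TSS → boundary, and its gene tuple is the strand-aware set of genes fully
contained in that span, ordered 5'→3'. Units with identical non-empty
tuples merge into one operon variant; empty tuples are dropped. rRNA
genes are excluded from tuples by default (they are analysed separately
via the primary/processed classification) — a flag restores them.

Annotated-operon extension: the annotated set is first reduced to maximal
operons (gene-set inclusion on the same strand removes sub-operons); an
operon is extended when ≥ 1 read fully covers all member genes plus at
least one additional fully covered gene, with the extension side(s)
recorded relative to the strand. Context counting reports, per gene, the
number of distinct variant tuples containing it; condition comparison is
an outer join with absent genes at 0. Antisense detection flags variants
whose genomic span fully contains an opposite-strand gene.

## Quantification and windows

Gene expression counts same-strand reads overlapping the gene body by
≥ 1 bp; `RPKM = count / (gene kb × N/10⁶)`. Primary/processed
classification calls a read primary when its 5' end lies within ±5 bp of
a known start site on the same strand; reads overlapping rRNA genes split
into primary/processed rRNA, everything else is reported as non-rRNA, and
the three fractions partition all mapped reads (read-count weighted).

Window extraction is transcript-oriented: offset 0 is the site base,
negative offsets upstream; minus-strand windows are reverse-complemented.
Presets: TSS motif −45..+5, TTS motif −30..+10, TTS hairpin −40..−1,
attenuator −100..−1. Windows crossing a chromosome edge are skipped for
the position frequency matrix (so column sums equal contributing sites).
Hairpin folding and attenuator scoring are external steps: the package
emits their input FASTA and can filter on a returned free-energy table
(−10 kcal/mol cutoff) rather than folding itself.

## Simulator

The generator plants non-overlapping operons (alternating strands) on a
random genome: 2-4 genes of 300-900 bp with 40-120 bp spacers, 1-2 start
sites with geometrically decreasing weights, a terminator 10 bp after
each non-final gene with read-through drawn uniformly from [0.05, 0.6],
and a terminal end. A read chooses a TSS by weight, starts exactly there
(cap-enriched chemistry), and walks 3'-wards: each terminator stops it
with probability 1 − read-through, the terminal end always stops it, and
a memoryless per-base hazard (default 5×10⁻⁴) models premature ending —
the geometric law is the discrete counterpart of the uniform-ending null
the TTS test assumes. Sampling is exact without a per-base walk: the stop
boundary is the first non-read-through terminator, preempted by a
geometric premature draw when that lands earlier. Control libraries
resample the 5' end uniformly inside the transcript with probability
`control_processed_fraction` (default 0.6), emulating processed
transcripts. Every read carries a provenance record (source TSS, stop
cause), and identical seeds reproduce identical output bytes.

Defaults represent a deeply sequenced bacterial study at desk scale:
depth 50 reads per TSS (2000 in the read-through accuracy study, where
binomial noise at ±3 percentage points matters), 6-20 operons, genome
60-250 kb. What the simulator does **not** model: sequencing error,
alignment artefacts, soft-clipping, transcription units that overlap on
one strand, rho-dependent pausing profiles, or abundance skew beyond the
2:1 TSS weights. Passing recovery tests therefore demonstrate the
statistical machinery and bookkeeping are correct under the generative
assumptions, not robustness to real-data artefacts.

## Numerical and design choices

* Binomial tails via `scipy.stats.binom.sf(k−1, n, p)`; stable to
  `n ~ 10⁶`, oracle-checked against exact `Fraction` summation.
* Ties in cluster seeding break toward the 5'-most position; merge runs
  chain left-to-right per strand; all outputs sort on (chrom, position,
  strand) so reruns are byte-identical.
* `D` is inclusive; at `D ≫ 1` the off-by-one is immaterial, but tests
  pin it.
* Degenerate inputs: empty libraries error in tally/expression (TPM and
  RPKM are undefined at `N = 0`); empty site lists write header-only
  tables; a TTS with no covering reads yields no read-through record
  rather than 0/0.
* Reads ending between two called TTSs more than 5 bp from both join the
  longest-transcript fallback group — the tolerance is the merge window,
  kept as one shared parameter.

## Known limitations

Soft-clipped bases are invisible (the aligned span defines the ends), so
heavy clipping at transcript termini would shift calls. The ≥ 10-read and
200-fold criteria make shallow libraries insensitive to weak terminators
near their TSS — by design, as the same thresholds govern the published
calling recipe. Variant enumeration trusts the TSS/TTS calls; a missed
TTS folds its reads into the longest-transcript group and can merge two
variants. Multiple-testing correction for TTS p-values is available
(`alpha` is per-test otherwise) but off by default.
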
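# Methods

## The measurement problem

A multi-promoter gene produces transcripts that differ only at their 5′
end: each alternative first exon splices onto the same downstream exon
backbone and selects a different first in-frame start codon, hence a
different N-terminal protein isoform. Three consequences shape the design:

* gene-level read counting cannot distinguish isoforms, but each
  alternative first exon contributes exactly one *diagnostic* splice
  junction (first exon → backbone), so junction-crossing reads can;
* a shared backbone exists (here exons 10–20), whose junctions are crossed
  by essentially all transcripts, giving a promoter-independent measure of
  total gene output;
* two transcription starts sit *inside* extensions of internal exons
  ("extended exons" 4c and 7bII). Transcripts from them are collinear with
  the backbone and have no diagnostic junction; they are instead counted
  over a 1 bp window 2 bp upstream (transcript 5′ direction) of the
  internal exon boundary, which only reads from the extended start can
  cover.

## Gene model

The model is a single YAML document: exon catalogue (name, class, genomic
interval, splice-site variants with roman-numeral labels, upstream start
extensions), junction list (transcript-ordered exon pairs; coordinates are
derived from exon boundaries at load time, so the file cannot contradict
itself), isoform definitions (initiating exon, diagnostic junctions,
extended exon, full transcript exon chain), the constitutive backbone
chain, and the two declared splicing features: Δ (skip of exons 8–9) and
+/− (alternative acceptor at exon 8; the plus variant extends the exon by
12 bp, adding the RSRS tetrapeptide). Validation is eager and reports
every violation at once.

Coordinates are 0-based half-open on the forward genomic strand; STAR's
1-based inclusive intron convention is converted at the reader/writer
boundary. Junction keys are genomic intron intervals plus strand, so
minus-strand genes need no special cases downstream (exercised by a
minus-strand model in the tests). The packaged mouse model is + strand,
consistent with the public mm10 annotation of the locus.

The packaged mouse fixture encodes the published locus architecture —
32 exons: 13 five-prime (including the novel 3e/3f starts that still
encode TCF4-B), 18 internal, one long 3′ terminal exon — with isoform
anchors where they are established (exon 3 → TCF4-B, exon 10a → TCF4-A,
TCF4-D starting in internal exon 8 via the 7bII extended start). Exact
exon coordinates/sizes and the TCF4-C and TCF4-I assignments are fixture
metadata marked `provisional: true`; they fix a concrete, internally
consistent geometry for simulation and testing rather than claiming
base-accurate annotation.

## Long-read classification

Aberrance is judged first: every intron implied by a read's block
structure (after closing alignment gaps < `gap_merge`, default 10 bp, to
absorb nanopore micro-indels) must match an annotated junction exactly
(`junction_tolerance`, default 0 bp — appropriate for simulated reads;
raise it for real nanopore alignments), and consecutive junctions must
chain (each junction's downstream exon starts the next). This codifies
"aberrant transcript" reproducibly: any unannotated junction, or any
backbone exon skipped other than via the declared Δ feature.

Full-length calling is then purely geometric: the 3′ end must lie inside
the 3′ terminal exon, and the 5′ end must lie inside an annotated 5′ exon
(≥ `min_overlap`, default 1 bp) or up to `upstream_slack` (default 50 bp)
upstream of it. For extended exons the 5′ end must lie *strictly within
the extension region*: a read starting at or past the internal exon
boundary is a truncation of some longer transcript, not evidence of the
extended start, so truncated reads are never promoted. A consequence is
monotonicity (tested): shortening a read from its 5′ end can only move it
full-length → truncated.

Full-length reads take their isoform from the first exon; 5′ exons with no
known isoform yield an explicit `unassigned` call (counted, flagged, never
silently dropped). Percentages are over full-length assigned reads;
truncated/aberrant/unassigned/strand-discordant counts are reported
alongside. Direct RNA is stranded, so strand-discordant reads are excluded
up front and counted.

## Short-read junction quantification

Filtering follows three rules: mitochondrial contigs (`chrM`/`MT`/`chrMT`,
configurable) removed; non-canonical intron motifs removed (STAR motif
code 0); junctions kept only if detected (count > 0 — a presence rule, not
a count threshold) in at least ⌈0.10 × n_samples⌉ samples. The rule is
idempotent, and the per-sample denominator — all junction-crossing reads
as parsed, genome-wide — is deliberately not recomputed after filtering.

Normalisation is junction reads per million total junction reads; the
scale is arbitrary (it cancels in all compositions) and per-million is
chosen for familiarity. Samples with zero junction reads are dropped with
a warning rather than zero-divided.

Exon-level summaries *sum* junctions sharing an exon label (variants I/II
of one junction pool together; summing rather than averaging keeps the
value interpretable as reads supporting the exon pair). Total expression
is the arithmetic mean of the ten backbone junction summaries. Isoform
composition sums each annotated isoform's diagnostic-junction signal,
averages across a group's samples *before* converting to percentages
(so deep samples don't dominate ratios), and divides by the sum over
annotated isoforms. Junctions shared by several isoforms carry no isoform
label and contribute only to exon-level and total quantities. All-zero
groups are flagged undefined instead of emitting NaN. Group aggregation
reports mean and SEM = sd/√n, with SEM missing (not 0) for n = 1.

## Densitometry

Per lane: band signal / Coomassie total-protein signal, summed over the
measured band groups (long = B+C, medium = D, short = A+I, by apparent
molecular weight). Per blot: divide by the blot's calibrator lane, making
the result exactly invariant to any per-blot multiplicative gain
(exposure, antibody batch) — the property the tests verify by simulating
gain factors and checking cancellation. Whole-lane Coomassie signal is
assumed. Replicate lanes average after calibration. Values at or below
`detection_floor` (default 0) become an explicit not-detected mask,
distinct from never-measured cells (NaN).

## Synthetic data: what it emulates, what it does not

Long reads: isoform ~ mixture; the transcript is laid over the model's
exon chain (extended start for 7bII-initiated transcripts, +/− drawn with
probability `plus_fraction` = 0.5, Δ optional); retained length =
min(L, ⌈Exponential(`truncation_mean_bp`)⌉) measured from the 3′ end, the
simplest memoryless 3′-anchored termination model (pluggable); aberrant
reads (rate 0.01 by default — the published analysis excluded aberrant
transcripts without printing a count) skip one random backbone exon.

Defaults are the study conditions: 1,336 locus reads, mixture
0.2/0.1/0.3/0.3/0.1 for B/C/D/A/I, and `truncation_mean_bp` = 3300,
obtained by solving Σᵢ wᵢ·exp(−(Lᵢ−windowᵢ)/τ) for the fixture's
transcript lengths so that the expected full-length yield matches the
observed ≈163/1336 ≈ 12 %. With this τ most reads stay inside the ~5.6 kb
terminal exon, reproducing the observed preponderance of last-exon-only
reads.

One statistical subtlety is handled explicitly: 3′-anchored truncation
conditions the *full-length subset* toward shorter transcripts. The
closed-form conditional mixture wᵢpᵢ/Σwⱼpⱼ (exposed as
`conditional_full_length_weights`) is therefore the correct oracle for
full-length composition recovery, and with the packaged geometry it sits
within ~2 percentage points of the input mixture. Note the published
percentages are themselves a full-length-read tally, carrying the same
conditioning.

Junction counts: counts ~ Poisson(depth × library factor × Σᵢ
incidence(i,j)·wᵢ), with the exon-8 acceptor mass split between variants
by `plus_fraction`; one large aggregate background junction keeps totals
≫ gene signal; decoy junctions (chrM, non-canonical, single-sample) are
included so filtering is exercised end to end. Blot tables: truth × fixed
band-group split × per-blot gain × log-normal noise, Coomassie sharing
the gain.

Not emulated: base-level sequences and error profiles, alignment
ambiguity, junction-coordinate wobble (simulated junctions are exact,
hence the zero default tolerance), overdispersion beyond Poisson, batch
effects beyond scalar library size/gain. Passing tests demonstrate the
*arithmetic and logic* of the pipeline on data satisfying the model's
assumptions, not robustness to alignment noise in real nanopore data.

## Problem sizes and determinism

The test suite simulates at n = 150–2000 reads, depth 10⁴–10⁵, ≤ 12
samples; `scripts/acceptance.py` uses 25 replicates of 1,336 reads, one
12-sample depth-10⁵ junction table, and a 3-blot, 20-replicate
densitometry run — sizes chosen so the whole suite completes in seconds
while leaving Monte-Carlo error well inside the asserted tolerances. All
randomness flows from a single integer seed through
`numpy.random.default_rng`; outputs carry no timestamps, so identical
config + seed reruns are byte-identical (asserted in the tests).

## Known limitations

* Fixture geometry is provisional where the literature gives no printed
  coordinates; real-data analyses should load a locus-accurate model file.
* Exact junction matching (tolerance 0) will call real nanopore reads
  aberrant near wobbly splice sites; set `junction_tolerance` ≈ 5–10 bp
  for real alignments.
* The 10 % detection rule uses presence (count > 0), one of several
  readings of "detected"; a minimum-count variant would need only a
  parameter change.
* Extended-exon point counts require alignment-level input and are kept
  out of the default composition (added via `point_counts=` when
  available); compositions are then over junction-diagnosable isoforms
  only.
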
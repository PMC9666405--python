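# isojunct

Isoform-resolved expression analysis for multi-promoter genes.

Many genes — the motivating case is *TCF4*, the class I bHLH E-protein
mutated in Pitt–Hopkins syndrome and associated with schizophrenia — are
transcribed from many alternative first ("5′") exons. Each alternative 5′
exon places a different first in-frame start codon, so promoter choice
selects an N-terminally distinct protein isoform (TCF4-B, -C, -D, -A, -I …)
with its own activation domains and transactivation behaviour. Standard
gene-level RNA-seq quantification collapses all of this into one number.
`isojunct` implements the three measurements that resolve it:

1. **Long-read transcript classification** (`isojunct.longread`).
   Direct RNA nanopore sequencing reads each transcript from its 3′ end, so
   many reads terminate before reaching the 5′ exon that identifies the
   isoform. Reads (BED12) are filtered to the gene locus, called
   *full-length* (3′ terminal exon → an annotated 5′ exon or extended-exon
   transcription start), *truncated*, or *aberrant* (junction chain
   inconsistent with the gene model); full-length reads are assigned an
   isoform from their first exon, the Δ (cassette-exon skip) and +/−
   (alternative acceptor, RSRS tetrapeptide) splice features are called,
   and the isoform distribution is tabulated in percent.

2. **Splice-junction quantification of short reads**
   (`isojunct.junction_quant`). Per-sample junction counts (STAR
   `SJ.out.tab` or generic TSV) are filtered (mitochondrial contigs and
   non-canonical intron motifs removed; junctions kept only if detected in
   ≥ ⌈10 % of samples⌉), normalised to junction reads per million total
   junction-crossing reads in the sample, and summarised: splice-site
   variants pool by exon label; *total* gene expression is the mean of the
   ten constitutive-backbone junctions (exons 10–11 … 19–20); isoform
   composition is the isoform-diagnostic junction signal divided by the sum
   over all annotated isoforms, in percent, aggregated per tissue × age
   group with SEM. Extended exons (4c, 7bII), which have no diagnostic
   junction, are counted over a 1 bp window 2 bp upstream of the internal
   exon boundary.

3. **Western-blot densitometry** (`isojunct.densitometry`). Band signals
   (long/medium/short isoform groups) are divided by the Coomassie
   total-protein loading control, summed per lane, and scaled to a
   calibrator lane re-run on every blot (e.g. P10 cerebral cortex ≡ 1), so
   values are comparable across blots and exposures; undetectable signal is
   an explicit *not detected* state, distinct from unmeasured.

Everything is driven by one declarative **gene model**
(`isojunct.gene_model`): exon catalogue, splice-site variants,
junction → Exon → Isoform annotation, isoform definitions. A mouse *Tcf4*
model (32 exons: 13 five-prime, 18 internal, 1 three-prime) and a minimal
toy model ship with the package. The **synthetic-data generator**
(`isojunct.simulate`) produces ground-truth-labelled inputs for all three
stages — 3′-anchored exponentially truncated long reads, Poisson junction
counts over library-size-varying samples, and noisy gain-varying blot
tables — so the entire pipeline is testable without any data download.

## Worked example

Simulate a study-scale direct-RNA experiment and classify it:

```bash
isojunct simulate longread --seed 4 --n-reads 1336 --out sim/
isojunct longread classify --reads sim/reads.bed --model tcf4_mouse --out calls/
```

which prints

```
142 full-length of 1336 locus reads
```

and writes `calls/calls.tsv` (per-read status, isoform, Δ, +/−),
`calls/distribution.tsv` and a provenance manifest. The distribution for
that run:

```
isoform	count	percent
TCF4-A	49	34.50704225
TCF4-B	29	20.42253521
TCF4-C	10	7.042253521
TCF4-D	40	28.16901408
TCF4-I	14	9.85915493
```

Only ~11 % of simulated reads are full-length — the rest terminate early,
most of them inside the long 3′ terminal exon, exactly the behaviour that
makes 3′-anchored direct RNA sequencing of this gene hard. Percentages are
taken over full-length, isoform-assigned reads and sum to 100.

The short-read and blot stages work the same way
(`isojunct simulate junctions` → `isojunct junctions quantify`,
`isojunct simulate blot` → `isojunct blot normalize --calibrator CTX:P10`);
as a library, each stage is a handful of pure functions over pandas
objects (see the module docstrings).

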
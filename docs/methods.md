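# Methods

`lncflora` reimplements, as a reusable and fully testable library, the
standard computational route from an assembled transcriptome of stranded
RNA-seq to an annotated long non-coding RNA (lncRNA) catalogue: positional
classification against a reference annotation, coding-potential filtering,
differential expression between two conditions, cross-species sequence
conservation, cis/trans target inference, and term enrichment.  The package
starts from assembled transcript models (GTF), transcript sequences (FASTA)
and a read-count matrix; read trimming, alignment and assembly are upstream
of its scope.

## Coordinates and data model

Internally every interval is 0-based half-open; GTF I/O converts from the
1-based inclusive convention exactly once, at the file boundary, so all
interval arithmetic lives in a single convention.  A transcript is a
stranded chain of sorted, disjoint exons; its `length` is the spliced
length (sum of exon lengths) and its `span` the genomic footprint from
first to last exon.  Strandedness is a prerequisite: the pipeline is built
for strand-specific libraries, and unstranded (`.`) transcripts are
rejected at classification with a logged error rather than silently
misclassified.

## Positional classification

Each novel transcript receives one class code relative to the reference
annotation, mirroring the assembler-comparison vocabulary restricted to the
five codes this analysis needs:

* `=` — complete match: identical intron chain on the same strand
  (identical exon coordinates for monoexonic pairs, with zero slack);
* `o` — sense exonic overlap (any same-strand exon intersection > 0 bp);
* `i` — intronic: the query span falls entirely inside one intron of a
  same-strand reference transcript;
* `x` — antisense exonic overlap;
* `u` — intergenic: none of the above.

When several relations hold the precedence is `=` > `o` > `i` > `x` > `u`.
Sense overlap is deliberately ranked above antisense so that a transcript
touching exons on both strands is not labelled antisense.  A transcript
contained in an *opposite-strand* intron without exon overlap is classified
`u` (with a log note): calling it intronic would contradict the
strand-specific definition of an intronic lncRNA, and calling it antisense
would require exon-level evidence that is absent.  The class-code map is
`u -> lincRNA`, `x -> antisense (NAT)`, `o -> sense`, `i -> intronic`.

Queries are answered from interval trees over reference exons, introns and
gene spans; the test suite proves the indexed classifier equal to an
exhaustive all-pairs classifier on every synthetic instance.

## Coding potential

Three built-in predictors stand in for the CPC2 / CNCI / Pfam trio, and a
transcript is accepted as non-coding only when **all three** agree (the
intersection of the three tools' non-coding sets, as in the original
screening design):

1. **Longest ORF.**  Sense-strand scan in three frames (the library is
   stranded; a six-frame mode is a threshold away for unstranded data);
   the longest ATG-to-stop span, stop included.  Call: coding if
   >= 300 nt (100 codons), the conventional ORF cut-off.
2. **TESTCODE (Fickett) statistic.**  The eight published parameters —
   per-base positional asymmetry max/(min+1) over the three frame
   positions, and per-base content fractions — each binned through the
   original lookup tables and combined with the published weights
   (tables transcribed in `fickett_tables.py` with a provenance note).
   Call: coding if >= 0.95, the published "probably coding" region.
3. **Hexamer log-likelihood ratio.**  Mean over in-frame (step-3) hexamers
   of log(P_coding/P_noncoding).  The coding model is trained on the
   annotated mRNA sequences of the reference (first-order evidence of
   codon usage); the non-coding model is the *analytic zero-order
   background* of the same corpus: P(hexamer) = product of the corpus'
   mononucleotide frequencies.  This background is exactly what an
   infinitely shuffled corpus would converge to, and being deterministic
   it removes the only RNG influence on verdicts.  Call: coding if > 0.

Thresholds are configurable (`Thresholds`), and tables produced by the real
external tools can be ingested instead (`ingest_external_predictions`),
with CPC2 labels, CNCI score signs, and Pfam any-hit semantics.

## Filter cascade

Candidates pass four ordered, audited steps: (0) unannotated positional
classes only ({u, x, i, o}; `=` matches are known transcripts); (1) length
>= 200 nt and >= 1 exon record; (2) maximum FPKM across all samples >= 0.5;
(3) non-coding by the intersection vote.  Each step logs (input, removed,
surviving), and the audit chain is checked (`surviving(k) == input(k+1)`).
Two documented interpretation choices: the expression rule uses the
**maximum** FPKM over samples, so a stage-specific lncRNA expressed in only
one condition is retained (the source protocol states the threshold but
not the aggregate); the default threshold is 0.5 FPKM (the protocol's
Methods value; a 0.1 variant appears elsewhere in the same work, so the
knob is prominent and the audit records the value used).  Survivors get
deterministic `TCONS_` serial names in genomic sort order (chromosome,
start, transcript id).

## FPKM and differential expression

FPKM[f, s] = counts[f, s] * 1e9 / (length[f] * library_size[s]); counts are
integers read from disk, FPKM is always derived, never ingested.

DE between the two conditions (flower bud FB vs full-bloom FF in the
motivating design; any two labelled groups in general) uses an in-house
**negative-binomial exact test** rather than calling out to edgeR:

* counts are scaled to a common effective library size (geometric mean;
  pseudo-counts rounded to integers);
* within each group the replicate sum of n iid NB(mu, phi) variables is
  NB(n mu, phi/n);
* conditioning on the pooled total T, the two-sided p-value is the sum of
  conditional probabilities of all splits (a, T-a) no more likely than the
  observed one.  At phi = 0 this reduces exactly to the conditional
  binomial split test, which the tests verify to 1e-6.

Dispersion is a pooled within-group method-of-moments estimate on
library-size-normalized counts, phi = max(floor, pooled (s^2 - m)/m^2),
with floor 1e-6 and **no empirical-Bayes shrinkage**.  This keeps the
estimator transparent, but at n = 3 per group the per-feature estimate is
noisy and the resulting p-values are mildly anti-conservative (the reason
edgeR moderates dispersions); simulation places the exact test itself at
nominal level when the dispersion is known, and the end-to-end DE stage is
validated by planted-change recovery (sensitivity and empirical FDR)
rather than by p-value calibration alone.  Multiple testing is controlled
by Benjamini-Hochberg (via statsmodels), and a feature is called up/down
with strict inequalities |log2FC| > 1 and q < 0.05, with log2FC computed on
normalized group means with a 0.5 pseudo-count.  Normalization is plain
library-size scaling (no TMM); a hook accepts user-supplied factors.

## Conservation

Homology hits arrive as 12-column BLAST tabular files per species (the
aligner itself is out of scope).  A hit is kept iff E-value < 1e-10
(strict, reading the protocol's "e-10" as the conventional 1e-10) and
query coverage >= 0.30 (non-strict), where coverage = alignment length /
jasmine query length (subject-coverage mode available).  A query with any
kept one-way hit is *conserved* in that species; *highly conserved* means a
reciprocal best hit, with best = max bitscore, ties by min E-value then
lexicographic subject id (fully deterministic).  Multiple HSPs per pair are
not merged; the best HSP represents the pair.

## Targets and enrichment

*Cis*: a protein-coding gene is a candidate target when the gap between
locus spans is <= 100 kb (strand-agnostic; 0 when overlapping).  Distance
is span-to-span, not TSS-to-TSS, since the motivating protocol specifies
only "upstream or downstream"; a 10 kb preset covers the stricter
"adjacent" analysis.  *Trans*: Pearson correlation of expression profiles
across samples, kept iff |r| >= 0.95 (non-strict) and two-sided t-test
p < 0.05 (n - 2 df).  The 0.95 default is deliberately conservative — with
six samples, weaker cut-offs admit large co-expression sets — and is
recorded in the run log; the source protocol does not state its cut-off.
Zero-variance profiles are skipped with a warning.

Enrichment of target gene sets is a one-sided hypergeometric test
P(X >= k) per term against the **expressed-PCG universe** (max FPKM above
the expression threshold), BH-corrected, q < 0.05 flagged.  This replaces
ontology-specific engines; no GO DAG propagation or length-bias (Wallenius)
correction is attempted, and term maps are generic TSV inputs.

qPCR support: the 2^-ddCt operation computes dCt = Ct(target) -
Ct(reference gene) per sample, ddCt against the calibrator group's mean
dCt, and relative expression 2^-ddCt; the calibrator group is an explicit
argument.

## Synthetic data generator

The generator emits every input the pipeline reads, plus truth tables, as
a pure function of a seeded config.  Defaults emulate the motivating study
design: two conditions (FB, FF) x 3 replicates; a 2-chromosome, 2 Mb
genome with 100 disjoint multi-exon reference genes; 400 novel transcripts
planted across the positional classes (190 u, 80 x, 40 i, 60 o, 30 `=`);
lncRNA-like lengths (log-normal, median ~650 nt, ~800 nt mean, 77/18/5%
with 1/2/3 exons) against mRNA-like lengths (median ~2.5 kb, ~5 exons);
25% of novel transcripts planted as coding; NB counts with dispersion 0.1
and median expression 50, 15% planted |log2FC| = 2; five species with 30
planted reciprocal homologs, 10 one-way homologs and 100 decoys each at
10% substitution rate; 20 planted co-expression pairs.

Design points worth knowing when interpreting test results:

* **Separability is constructed.**  Planted coding sequences embed a
  codon-biased ORF >= 300 nt (position-specific nucleotide preferences,
  ~50% GC); planted non-coding sequences are i.i.d. draws at the matched
  base composition, rejection-sampled until all three built-in predictors
  score them non-coding.  Exact recovery of the planted lncRNA set is
  therefore a *correct-plumbing* test — it shows the pipeline applies its
  own rules without loss, not that the predictors would separate real
  transcripts perfectly.  Real data have ambiguous transcripts; the
  predictors' discriminative behaviour is tested separately (e.g. coding
  sequences outscore their dinucleotide shuffles on TESTCODE).
* **Co-expression plants are exact linear maps** (gene counts = 2x the
  lncRNA's, or an anti-linear reflection), giving |r| = 1; the default
  per-sample size factors are 1.0 so the affine negative map survives
  FPKM's per-sample scaling.  Decoy genes are independent NB draws, and
  planted trans-driver lncRNAs are strongly stage-regulated (as real
  co-expressed pairs over a two-stage contrast must be).
* **Homology tables are fabricated, not aligned.**  E-values follow a
  fixed monotone formula of alignment length and identity (bits =
  len * (pident/100 - 0.25) * 1.6; E = qlen * 1e3 * 2^-bits, clamped).
  The conservation stage only consumes the table, so the formula's realism
  is irrelevant to the logic it exercises; decoy hits are constructed to
  fail both filters, one-way homologs to fail only the reciprocal test.
* Counts are reported against a nominal library size of 2e7 so that the
  0.5-FPKM filter bites at realistic depths; ~10% of non-coding candidates
  are planted at near-zero expression and ~5% below 200 nt to exercise the
  corresponding filter steps.

Everything (annotation, placement, sequences, counts, homology) derives
from one `SeedSequence` with fixed spawn order, so the same seed gives
byte-identical files.  What the generator does **not** emulate: splice
graph ambiguity, assembly artifacts, positional biases of real coverage,
read-level noise (no FASTQ), and real lncRNA sequence families.

## Numerical and degenerate-input choices

* Exact-test splits compare probabilities with a relative tolerance of
  1e-12 to keep the "<= observed" rule stable under floating-point noise;
  an all-zero feature returns p = 1.
* BH is computed once per feature family (lncRNAs and PCGs are corrected
  separately, as their catalogues are reported separately).
* Empty stages propagate cleanly: a filter that removes everything yields
  empty (but well-formed, headered) downstream tables and a zero report.
* The density summary counts each feature once, in the bin of its start.
* Problem sizes in the shipped tests — 400 novel transcripts, 2000-feature
  DE simulations, five species — run the whole suite in well under a
  minute while leaving every planted structure at least ~20 instances; all
  are config knobs, not constants.

## Known limitations

* No transcript merging or fuzzy `=` matching: assembly slop must be
  resolved upstream (the monoexonic match slack is 0 bp by design).
* The NB exact test equalizes libraries by rounding pseudo-counts; for
  grossly unequal library sizes an offset-GLM approach would be
  preferable.
* Without dispersion moderation, small-n per-feature dispersion estimates
  inflate the raw false-positive rate (see above); calls are still guarded
  by the BH/|log2FC| double threshold.
* Enrichment ignores ontology structure and gene-length bias.
* Conservation is sequence-only (no synteny), and the RBH criterion is
  one-best-hit-per-direction; paralogous families can suppress true pairs.
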
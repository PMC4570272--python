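# Methods

## The problem and the model

A PUF-family RNA-binding protein is crosslinked to its RNA targets in
vivo, the protein is immunoprecipitated, and the bound RNA fragments are
sequenced (HITS-CLIP). Two signatures identify genuine binding: local read
enrichment (peaks) within genes, and 1–2 nt deletions introduced when
reverse transcriptase skips the crosslinked base. The binding element
itself is bipartite — a 5'-UGUA anchor and a 3'-UA terminus separated by a
2–6 nt spacer, so the full element is 8–12 nt. A single anchor can be
readable at more than one length when several downstream UA dinucleotides
are admissible (UGUAAAUAUA is both an 8- and a 10-nt element); such sites
are kept as one site with a set of length classes rather than being
double-counted as two sites.

All coordinates are 0-based half-open internally. mRNA gene models are an
ORF extended by fixed UTRs — 200 nt upstream as 5'UTR, 300 nt downstream
as 3'UTR — the standard convention for yeast, where most annotated UTRs
are unavailable.

## Synthetic data generator

The generator emulates the study's data shape at desk scale and carries
exact ground truth.

* **Genome**: 50 genes by default (uniform ORF lengths 300–900 nt, random
  strand) laid on one chromosome with 200-nt intergenic spacers, so
  extended footprints never overlap and peak-to-gene assignment is
  unambiguous by construction.
* **Elements**: one per gene by default; lengths uniform over 8–12;
  regions drawn 3'UTR 68% / ORF 28% / 5'UTR 4%, the observed distribution
  of CLIP peaks over mRNA features. Spacer bases are A-biased and
  G-depleted (P(A)=0.55, P(G)=0.05), reflecting the modest adenosine
  enrichment and scarcity of guanosine seen between the anchors; fully
  configurable. Each element receives a relative affinity drawn
  log-uniformly from 0.6–16×. The affinity scales expected read depth and
  is shared between replicates: it is the biological signal that makes
  replicate peak heights correlate, while counting noise stays
  independent. The lower bound keeps every element at ≥30 expected reads
  so replicate thresholds are a test of the method, not of coverage.
* **Reads**: per-element counts are negative binomial (mean 50 × affinity,
  dispersion 10 — a documented assumption; no per-element depth law is
  established for this protocol). Inserts are 28–45 nt genomic substrings
  containing the element, reverse-complemented for minus-strand genes.
  With probability 0.3 a read carries a 1–2 nt deletion placed uniformly
  within the element footprint ±3 nt (crosslinks sit in or next to the
  bound site). Background reads are Poisson (0.005/genic nt), uniform
  within gene footprints, never intergenic. Each read gets a 5-nt random
  barcode; PCR duplicates are exact copies appended at rate 0.3; the
  printed 3' adaptor fills the read out to 50 nt; qualities are Gaussian
  (mean 35, sd 3) clipped to [2, 40], Phred+33.
* **Selection rounds**: round 0 is a uniform random 20-mer library; each
  subsequent round resamples with replacement, weighting each sequence by
  the affinity of the best element it contains (1.0 if none). Read counts
  per length class across rounds are then an affinity proxy.

What the generator does **not** model: sequencing substitution errors,
ligation and RNase biases, transcript abundance variation independent of
binding, overlapping genes, splicing, and real yeast sequence composition.
Passing tests therefore show the pipeline's inferential machinery is
correct under its stated error model, not that it is robust to every
artefact of real libraries.

## Preprocessing

Trimming searches for the 3' adaptor as a full match anywhere or a
≥5 nt prefix at the read's 3' end (exact matching; no mismatch-tolerant
trimming). Reads containing the 5' adaptor anywhere are discarded. The
first 5 nt of the trimmed read are the random barcode; the remainder is
the insert. Filtering drops inserts < 15 nt or with mean Phred < 20
(boundaries inclusive; a per-base mode is available — the mean
interpretation is the default because the upstream tool's threshold
semantics are ambiguous). Duplicates are collapsed on the exact
(barcode, insert) key keeping the first copy; a drop-all switch removes
every copy instead, since the original pipeline's wording ("discarding
any read with a perfect duplicate") admits both readings. A read kept
with 1–4 nt of residual adaptor (below the trim overlap) survives here
and is handled by the aligner's mismatch allowance or dropped as
unmapped.

## Alignment

A bespoke seed-and-extend aligner replaces a general-purpose mapper so the
crosslink deletion is first-class: alignments allow ≤2 mismatches and at
most one deletion of 1–2 nt, scored as mismatches + deleted bases
(1 per base). Seeds are exact 12-mers taken at every read offset against a
both-strand k-mer index; candidate starts are seed position minus offset,
also shifted by 1–2 to catch seeds downstream of a deletion. Every
placement containing one error-free 12-mer window is found — guaranteed
under the simulator's error model (deletions only) for reads ≥ 26 nt.
When no seeded placement passes, an optional exhaustive scan evaluates
every position (on by default for single reads, off in bulk mapping where
rescuing adaptor-tailed reads is not worth quadratic cost). Reads tying at
best score across distinct locations are declared multi-mapping and
excluded; insertions are not modelled.

Score ties at one location prefer the reading with fewer mismatches, so a
clean terminal deletion beats an equal-cost mismatch reading. A genuine
ambiguity remains: a deletion inside locally repetitive (A-rich) sequence
can admit a strictly cheaper mismatch reading, so ~2–3% of simulated
deletion reads are reported ungapped; an exhaustive oracle makes the same
call, as this is a property of parsimony scoring, not of the heuristic.

## Peak calling and replicate merging

Coverage is computed per gene and strand over the extended footprint;
deletions inside a read do not interrupt its span. Observed clusters are
maximal runs of coverage ≥ 1. The null re-places the same reads (same
spans) uniformly within the gene 1,000 times (500 in the faster test
configuration); modFDR(h) is the mean null count of clusters reaching
height h divided by the observed count, clipped to [0, 1], and clusters
with modFDR < 0.01 become peaks. This permutation scheme is an explicit
reconstruction — the original tool's internals are not restated in the
literature — and it is calibrated: on element-free genes with uniform
background reads, ≤3% of genes yield any peak at α = 0.01 (0% observed at
the tested seeds). Summit ties break leftmost. Peak shape is the Pearson
kurtosis m4/m2² of the coverage profile (uniform → 1.8, triangular → 2.4,
two-point → 1.0); width-1 profiles are reported missing.

High-confidence peaks require, in both replicates: summits within 10 nt
(inclusive), ≥1 gapped read, and height > 10 (fixed threshold by default;
a data-driven third-quartile mode is provided because the source of the
"10" is ambiguous). Matching is greedy by nearest summit within a gene;
the consensus summit is the rounded mean. Replicate agreement is the
Pearson r of log2(reads-per-million + 1) per merged peak; RPM is our
normalization choice.

## Elements, length profiles, networks

A 51-nt sense-strand window (25 nt each side of the summit, truncated
with a warning at chromosome ends) is scanned for the bipartite element.
The 5' anchor is UGUA by default with a UGUN switch (the two forms both
appear in the field's usage). Length distributions count each site once
per admissible length class by default (a longest-only mode is provided;
how overlapping lengths were apportioned originally is not stated).
Enrichment is normalized to the predominant class = 1. Selection-round
profiles count each read once per class it contains. PWMs use pseudocount
0.5 per base per position. The network export emits one edge per
(peak, length class) as a SIF-compatible edge list plus a node attribute
table; element-free peaks appear only among the nodes.

## Enrichment

Per length class, each term annotated to ≥1 target gene is tested with the
hypergeometric upper tail P(X ≥ k) (scipy's survival function) against the
whole feature table as background; genes with several peaks count once per
class; terms absent from the background are dropped. Holm–Bonferroni is
applied within each length class (matching the per-class presentation of
the original analysis; a global-family switch is provided). Under random
gene–term assignment the familywise error stays below α, as Holm
guarantees.

## Problem sizes and numerical choices

Defaults throughout are the desk-scale study conditions: 50 genes /
50 planted elements / two replicates (~12k reads each) for recovery and
correlation; 200 element-free genes for calibration; 20-mer libraries of
15–20k sequences over 5 selection rounds; 1,000 permutations per gene for
the modFDR null in the analysis drivers and 500 in the test suite. All
generators and analyses are deterministic given their seeds. Weights must
sum to 1 within 1e-9; PWM rows sum to 1 within 1e-9; element placement
retries are bounded (100 attempts) before raising a placement error.

## Known limitations

The aligner's sensitivity guarantee assumes the CLIP error model; short
reads carrying both substitutions and a deletion can lack a clean seed.
Genes are non-overlapping by construction, so peak-to-gene assignment
ambiguity in real, compact genomes is untested here (real-data mode
assigns by strand and distance to the nearest ORF). The modFDR null
assumes reads are placeable uniformly within a gene, ignoring positional
coverage biases of real libraries. No BAM, paired-end, splicing or
soft-clipping support.
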
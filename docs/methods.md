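# Methods

## Scope and data model

The pipeline starts from per-position, strand-specific coverage rather than
reads: for each growth condition and replicate it expects TEX-treated and
untreated dRNA-seq 5'-end tracks plus a fragmented strand-specific RNA-seq
(ssRNA-seq) full-coverage track, all normalized to reads-per-million
(`normalize_coverage` divides by the library's aligned total and multiplies
by 10^6, which preserves all ratios between positions). Coordinates are
1-based inclusive everywhere; conversions happen only at file boundaries
(wiggle is 1-based, bedGraph half-open and converted on load). A single
replicon is assumed; multi-record FASTA inputs are handled as independent
per-record tracks.

## Site calling

Replicate tracks are averaged per condition before calling; a position is a
candidate when either library's averaged 5'-end signal reaches `min_height`
(default 5 per-million). The TEX enrichment ratio uses a pseudocount of 1
per-million unit in numerator and denominator, which bounds the ratio for
empty positions and mirrors the stabilization used by the standard TSS
annotation tools. The enrichment factor defaults to 2.0 — the common default
of those tools; the source study does not state its exact parameterization,
so both are explicit configuration. A PSS additionally requires the
untreated library itself to reach `min_height`: a TEX+-only spike without
enrichment is not a coherent observation of either a primary or a processed
end and is discarded as noise. Calls within 3 nt are merged keeping the
highest peak (tie on height broken by position). Across conditions the union
of calls is taken, keeping the maximum height and both condition labels;
when one condition supports a TSS and the other a PSS at the same position
the TSS wins, since genuine initiation explains both observations. This
replaces the study-style manual genome-browser curation with reproducible
rules.

Transcripts are maximal runs of ssRNA-seq coverage ≥ 2 per-million, merged
across sub-threshold gaps ≤ 5 nt, discarding runs < 20 nt. 3'-end "sharp
decreases" are found by scanning downstream for the first position where the
mean coverage over the next 5 nt drops to ≤ 0.5× the previous 5 nt, then
refining to the local minimum of that ratio so a clean step is reported
exactly at its last high-coverage position.

## sRNA detection and classification

Candidates are anchored on called sites. For each 5' anchor the 3'-end is
the nearest downstream evidence giving a length in [50, 500] nt, chosen among
downstream PSS calls and sharp-decrease positions (PSS preferred on a tie —
a measured cleavage beats a heuristic step). The three admission criteria
are applied as: interval contained (±3 nt slack) in a detected ssRNA-seq
transcript in ≥ 1 condition; any dRNA-seq 5'-end signal over the interval;
and mean ssRNA-seq coverage ≥ 10 per-million in ≥ 1 condition — the
abundance unit is per-million coverage because that is the only
normalization the workflow defines. Origin is ts/ps by the anchor kind. Note
that anchor-driven detection also emits genuine processed fragments of
mRNAs (a 3'-side PSS of one transcript is the 5' anchor of the downstream
fragment); the catalog is therefore a superset of "clean" sRNAs exactly as
an automated coverage-based caller's is, and truth-based evaluation matches
candidates to planted sRNAs by their strand-aware 5' position.

Location classification compares the candidate interval to per-gene
transcript footprints: the detected ssRNA-seq transcript when a unique
same-strand transcript covers the CDS and no other CDS, else the CDS plus
fixed UTR allowances (5'UTR 50 nt, 3'UTR 80 nt — the study never defines UTR
extents) truncated at same-strand neighbors; rRNA/tRNA footprints are their
annotations. Overlap means ≥ 1 shared nucleotide. Decision order: no overlap
→ intergenic; opposite-strand only → antisense; same-strand only →
intragenic; both → intra&as. Intragenic subtypes are evaluated in a fixed
order (3'rRNA; two CDS bodies → 2CDSs; 5'UTR-only overlap; 5' body boundary;
strictly inside; 3' body boundary; 3'UTR-only overlap), first match wins —
so an interval crossing the CDS start from the 5'UTR is 5'CDS, not 5'UTR.
The UTR subtypes require no gene-body overlap rather than strict
containment, and body-boundary subtypes apply to any same-strand gene body
(e.g. a tRNA), so the subtype axis partitions every intragenic candidate;
these two generalizations close gaps the named subtypes alone leave open.
Names are `sRNA` + the strand-aware 5'-end genomic position, with an `m`
suffix when opposite-strand candidates collide on one position. Redundancy
clustering is greedy longest-first at CD-HIT-style thresholds: join a
cluster when local-alignment identity ≥ 0.70 over ≥ 0.90 of the shorter
sequence against the representative.

## Sequence/structure features and motifs

GC content counts ambiguous bases as non-GC. Folding has two backends:
thermodynamic (ViennaRNA, kcal/mol) and a built-in Nussinov
maximum-base-pairing proxy (pairs AU/GC/GU, minimum loop 3, score = −pairs),
which is exactly testable against exhaustive enumeration and is what the
test suite asserts on; absolute kcal/mol values are never asserted. NMFE is
the folding score divided by length. Group comparisons use the two-sided
Wilcoxon rank-sum test on length/GC/NMFE for every class pair (groups with
n < 3 excluded with a warning); GC-vs-NMFE association uses Spearman rank
correlation.

Motif profiles are position frequency matrices over strand-aware windows
with the anchor base at offset +1 and no offset 0 (logo convention);
information content is 2 + Σf·log2 f bits. The consensus rule emits a single
base when its frequency is ≥ 0.5 and ≥ 2× the runner-up, a two-letter IUPAC
code when the top two sum to ≥ 0.75 with each ≥ 0.25, else N — a
deterministic reconstruction of degenerate consensus strings like RNWUU
from frequencies (no published rule exists). The PSS coordinate convention
places the cut immediately 5' of the site: offsets −2,−1 are the last bases
of the upstream fragment and +1..+3 the first of the retained one. De novo
motif discovery is replaced by the PFM/IC profile plus a
strongest-hexamer report in the −15..−5 and −40..−28 windows (the −10/−35
promoter boxes); this is deterministic and dependency-free. sORFs are
AUG-initiated, stop-terminated frames ≥ 20 aa (stop excluded from the
count), one report per (frame, stop) keeping the longest. GGA motifs are
classified against a dot-bracket structure: 3 unpaired positions →
unpaired, 0 → paired, otherwise partially paired — the 1–2-unpaired cutoff
for "partially paired" is our decision, the source material defines none.

## Homology and conservation

`homology_search` is seed-and-extend: exact 11-mer seeds on both strands,
seeds clustered by diagonal (band 20), and each seeded neighborhood aligned
with an affine-gap local aligner (match +1, mismatch −2, gap open −5,
extend −2; BLAST-style "first gap position pays open+extend"). Identity is
matches over alignment columns including gaps; coverage is aligned query
fraction; both in percent against the named profiles strict 75/75, loose
60/50, known-family 50/50. E-values are not computed — at these scales the
identity/coverage gates subsume an e-value cutoff. Overlapping subject hits
collapse to the best; disjoint passing hits in one genome count as copies.
Species count is the number of reference genomes with ≥ 1 passing hit;
categories: specific (0 reference genomes), broad (≥ `broad_min`, default
all — "broadly conserved" has no operational definition in the source, so
the bound is configurable), local otherwise. Identity-vs-phylogeny uses
Spearman correlation of best identity against negated patristic distance,
per sRNA, skipping sRNAs with < 4 informative genomes or constant vectors.

## Expression and regulatory candidates

TPM is (count/length) normalized to sum 10^6 per sample. Differential
expression uses median-of-ratios size factors, log2 fold change
log2((meanA+0.5)/(meanB+0.5)) on normalized counts (pseudocount 0.5 — the
standard small-count stabilization), a two-sided Welch t-test on
log2(normalized+0.5), and BH adjustment; status up/down requires padj < 0.05
and |log2FC| ≥ 1. This self-contained test replaces an external
count-model fitter; its calibration is asserted by simulation (type-I error
on planted-null negative-binomial counts, and median recovered log2FC of
planted 4× features) rather than by parity with any specific tool. It is
slightly conservative at n = 3 (~0.03–0.04 empirical type-I at nominal
0.05), which is the expected behavior of Welch on log-transformed counts.
The numerator condition is the generator's declared treatment condition
when known, else the first label.

CsrA target scanning counts ANGGA occurrences in the strand-aware window
−25..+10 around the start codon (fixed relative to the start rather than to
a detected Shine–Dalgarno; the window is configurable), ranking by count
then nearest-motif distance. Trans-acting target prediction finds gap-free
antisense duplexes between the sRNA and per-gene windows (−150..+100 around
the start codon): runs of consecutive pairs along anti-diagonals, scored
GC +3, AU +2, GU +1, qualifying only when they contain ≥ 7 consecutive
seed pairs (GU allowed in seeds by default, `allow_gu=False` to restrict);
a mismatch terminates extension, so scored duplexes are exactly the maximal
runs. This documented score stands in for full hybridization/accessibility
thermodynamics; the claims built on it concern criteria and rank plumbing,
not energies. Direct-relation calls against a key-gene list: (i) intragenic
sRNA whose parental (same-strand) gene is a key gene, (ii) antisense
overlap of a key gene, (iii) intergenic/intragenic sRNA ranking the key
gene within its top 10 predicted targets.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
read-level sequencing. A genome (default 200 kb, GC 0.616 — the GC level of
the motivating marine strain) is assembled from shuffled "cassettes"
separated by ≥ 120 nt gaps that share the remaining length: plain genes
(CDS with 50/80 nt UTRs, rRNA, tRNA) and sRNA cassettes realizing each
location class by construction — intragenic subtypes cycle through mCDS,
5'CDS, 3'CDS, 3'UTR inside a host gene; antisense sRNAs sit opposite a host
CDS; intergenic sRNAs are padded by ≥ 150 nt; intra&as uses convergent gene
pairs whose 3'UTR allowances overlap. An internal checker re-derives every
planted class with the production classifier before tracks are written.
Default class counts (intra 40, as 12, inter 4, intra&as 4 of 60) follow
the observed proportions (intragenic ~2/3, antisense ~1/5). Exactly
round(0.634 × n) sRNAs are ts (the observed ts share); ts 5'-ends carry
planted −35 TTGACA and −10 TATAAT boxes and a +1 purine, ps 5'-ends and all
intragenic 3'-ends carry the RN↓WUU cleavage motif (R and W drawn
uniformly from their two bases; the N position drawn uniformly over four
bases, as the cleavage context is unconstrained there). Intergenic and
antisense sRNA 3'-ends rely on the sharp coverage decrease instead, so both
3'-evidence paths are exercised.

TEX effects are modeled at the 5'-end-track level: a site of strength *s*
contributes (s, s/10) to (TEX+, TEX−) for a TSS and (0.2·s, s) for a PSS —
enrichment 10× and depletion 0.2× by default. Strength is
max(10, 0.5 × expression), the floor keeping every planted site above the
calling threshold under replicate noise. Expression is log-uniform over
[10, 10^6]: log-uniform reproduces the several-orders-of-magnitude spread
without assuming an abundance law, and the lower bound equals the
abundance-≥10 admission criterion because planted sRNAs represent the
catalog, which is defined by that filter; condition-specific fold changes
(23% up, 22% down, |log2FC| uniform in [1, 4]) still drive the depleted
condition below the floor. Tracks are emitted per replicate as
Poisson(signal + 0.2) — per-position Poisson with background mean 0.2
per-million units; with `noise=0` tracks are exact, and the no-noise
pipeline recovers every planted site and interval exactly. Homolog genomes
are derived by i.i.d. substitutions (every substitution changes the base,
so expected locus identity is 1 − rate) with selected sRNA loci replaced by
random sequence; a negative-binomial count simulator (gamma–Poisson,
variance μ + αμ²) provides calibration data for the differential test.

What the generator does not emulate — mapping artifacts, coverage bias,
operonic read-through, transcription noise correlated along the genome,
terminator structures — bounds what passing tests show: they validate the
inference machinery against its own generative assumptions, not performance
on real libraries.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full study at 200 kb / 60
sRNAs / 3 replicates × 2 conditions (the smaller conservation study at
40 kb with 5 mutated references, rates 0.02–0.16), sizes at which every
stage's behavior is already asymptotic while a complete run takes seconds.
Nussinov folding uses a numba-compiled kernel (O(n³), exact); pairings are
verified against exhaustive enumeration for n ≤ 25. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; identical
seeds give byte-identical outputs. Ranking ties break by identifier
everywhere, so all outputs are order-invariant to input permutation.

## Known limitations

Terminator-based 3'-end evidence is accepted in the data model but no
hairpin predictor is included; intrinsic terminators must be supplied or
the PSS/sharp-decrease paths used. The duplex score ignores target
accessibility and intramolecular structure. The redundancy clusterer is
greedy (like its inspiration) and not order-free across length ties beyond
the documented id tie-break. Percentages use round-half-away-from-zero, the
convention of the reported ratios, which differs from banker's rounding.
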
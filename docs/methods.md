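# Methods

## The problem

During oocyte growth, de novo DNA methylation (DNAme) is laid down over
transcribed territory: gene bodies and any other region crossed by RNA
polymerase II accumulate H3K36me3 and, downstream of it, CpG
methylation. A large share of oocyte transcripts initiate not at
canonical promoters but inside long terminal repeats (LTRs) of
endogenous retroviruses. Because LTR insertions differ between species
and even between strains of one species, LTR-initiated transcription
units (LITs) are a candidate mechanism for lineage-specific methylation
— including at CpG-island (CGI) promoters, where methylation acquired
in the oocyte can persist after fertilization.

`litmeth` implements the comparative analysis that links these pieces:
methylome segmentation, LIT calling, cross-genome syntenic mapping,
CGI methylation attribution, and persistence classification, exercised
end to end on synthetic multi-species cohorts whose ground truth is
known exactly.

## Methylome segmentation

Per-CpG calls (methylated / total read counts) are averaged into
fixed-width bins (default 1 kb). A bin passes coverage when at least
`min_cpgs` CpGs (default 5) each have at least `min_depth` reads
(default 5); a low-resolution preset (3 CpGs at 1 read) serves sparse
libraries. Bin means are unweighted means of per-CpG fractions.

Domains of constant mean methylation are found by exact penalized
changepoint detection: PELT with the squared-error cost
`sum_i (y_i - mean)^2` and a per-changepoint penalty, solved on the
ordered series of passing bins per chromosome. Failed bins are bridged
— the observation series skips them, and the genomic gap reappears
inside the output spans. The default penalty is an MBIC-like
`2 log(n) sigma^2` with `sigma` estimated from the median absolute
deviation of first differences (robust to the step structure the
penalty is meant to find); it is floored at `1e-10 n` so that a
noiseless constant series is never split by floating-point
cancellation in the cumulative-sum cost. The solver is validated
against an exhaustive O(n^2) dynamic program in the test suite.

Domains (and any methylation value) are classed with strict
inequalities: hypomethylated below 0.30, hypermethylated above 0.70,
intermediate otherwise — values exactly at a boundary are
intermediate. Every other printed cutoff in the pipeline is likewise
strict: active LTRs need FPKM > 1, chimeras need isoform share > 0.10,
syntenic CGIs need identity > 0.5, strain calls need a methylation
difference > 0.40, retention needs > 0.45, and the maternal-DMR rule
is sperm < 0.01 together with biparental blastocyst > 0.30.

## LIT calling

A transcript's strand-aware 5' base (TSS) is classified against
LTR-class repeats (MaLR, ERV1, ERVK, ERVL; internal segments count as
initiating elements too):

* **Up** — the TSS lies strictly inside a repeat and exon 1 extends 3'
  beyond it;
* **UpEdge** — the TSS falls within a configurable window (default
  100 bp) of a repeat edge without being inside it;
* **EInside** — a repeat overlaps the transcript without containing
  the TSS (kept only as a manual-inspection tier);
* **none** otherwise.

Only Up and UpEdge are accepted as LITs. When several repeats qualify,
the one containing (else nearest to) the TSS wins. These operational
definitions, including the edge window, are this package's
reimplementation choices; the widely used chimeric-transcript caller
this mirrors does not publish its exact thresholds.

A LIT is *sense-chimeric* with a gene when a non-first exon shares at
least 1 bp with an exon of a same-strand gene **and** the LIT's
isoform share — LIT FPKM over the summed FPKM of all of the gene's
isoforms, the LTR-driven one included — strictly exceeds 0.10. A LIT
overlapping an opposite-strand gene is *antisense*; otherwise
*intergenic*. The LTR contribution ratio is mean per-base read
coverage of exon 1 over the first canonical exon (mean, not total, so
the ratio is length-independent); ratios above 1 are mapped to
`r/(1+r)`, and a zero canonical denominator yields 1.0 with a
degeneracy flag.

## Syntenic mapping

Liftover projects an interval through UCSC-style chains
(forward-strand, colinear blocks) and returns the minimal target
interval covering all aligned bases; it returns nothing when the
aligned fraction falls below `min_match` (default 0.5) or the blocks
touch two target chromosomes. The implementation is checked
base-for-base against a per-base projection oracle.

Syntenic bins are reciprocal-best: bin *a* pairs with *b* iff *a*'s
projection overlaps *b* more than any other bin and *b*'s
back-projection prefers *a*; ties disqualify. Multi-species units run
through a hub genome (default the first species, mouse-like) and keep
only units with defined methylation in every species.

CGI orthology is scored by *identity* after projection. Identity is
not formally defined in the source analysis; Jaccard
(`|proj(a) ∩ b| / |proj(a) ∪ b|`) is the default because it is
symmetric, bounded in [0, 1], and makes the 0.5 threshold meaningful.
Overlap-of-smaller and reciprocal-overlap variants are implemented and
selectable; the choice is recorded in run manifests.

CGI context uses a promoter window of TSS ± 500 bp by default (± 100
bp available), *intragenic* requires lying in a gene body more than
500 bp from every TSS, and the geometric dead zone between those two
rules is reported as *proximal*, never silently merged. Genic
territory for bin-level analyses is TSS..TTS + 2 kb.

## Comparative classifications

Hypermethylated syntenic units are partitioned by which species exceed
0.70 (a 7-category Venn for three species); the LIT stratum contains
units overlapping a called LIT in *any* species (the alternative —
requiring overlap in the hypermethylated species — is available).
Hyper domains are attributed to {LIT only, gene only, both, neither}
by any-overlap, weighted by domain length. meCGIs (CGI mean > 0.70,
computed over at least 6 covered CpGs) are labelled shared vs
species-specific and LIT-embedded when the CGI lies within a called
LIT's transcript span, with the initiating repeat grouped as MTA /
other-MT / other-LTR.

Cross-species expression is compared with
`z = (FPKM_A − FPKM_B) / (sqrt(FPKM_A + FPKM_B) + 0.01)`,
exactly as printed; the 0.01 stabilizes the zero-expression case.

Strain-differential CGIs require a methylation difference strictly
above 0.40 **and** a concordant H3K36me3 excess. "Enrichment" has no
printed threshold, so it is implemented as sign concordance plus a
magnitude above a genome-wide quantile of |ΔH3K36me3| (default 75th);
both knobs appear in output headers.

## Persistence

Two maternal-origin inferences are named presets rather than one
merged rule, because they encode different logic. `pg_mode` applies to
maternal-only material (parthenogenetic blastocysts, maternal-allele
ICM): an oocyte-hypermethylated CGI (> 0.70) is *retained* iff the
blastocyst keeps > 0.45. `biparental_mode` applies to biparental
tissue: a CGI is a *maternal-DMR candidate* iff sperm is < 0.01 while
the tissue keeps > 0.30 — the remaining methylation can then only sit
on the maternal genome. A TET-sensitivity annotation is set only when
a TET-null epiblast profile is supplied and exceeds wild type by a
margin (default 0.20).

## The synthetic cohort

Genomes are coordinate-only: every downstream stage consumes intervals
and counts, so nucleotide sequence would add cost without exercising
any code path. Species genomes derive from one ancestral frame by
insertion-only indels (the planted LTRs, 400–800 bp), so pairwise
chains are exact by construction and a per-base projection oracle can
verify them. Insertions carry presence vectors (all species / the
close pair / one species), echoing subfamily biology: MTA-like
elements are private to the mouse-like lineage, MTB/C/D-like shared by
the rodent pair, ERV1-like private to the human-like outgroup.

Each gene (all on the plus strand; antisense LITs supply the
minus-strand cases) gets a 600 bp promoter CGI at its TSS and, with
probability 0.3, an intragenic CGI in its last intron. A configurable
fraction of LTRs is transcriptionally active per species; active LTRs
emit transcripts starting inside the repeat (a fraction just outside
it, exercising UpEdge), splicing into downstream genic exons
(chimeric), running antisense, or standing alone. An upstream LIT
suppresses the canonical TSS with probability 0.8; suppression is a
property of the LIT, applied identically in every species where it is
active. Orphan transcribed territory — hypermethylated spans
overlapping neither a gene nor any LIT — is planted at roughly 15% of
hyper territory, mirroring the unexplained-domain fraction real
methylomes show; intergenic LTRs are kept out of a margin around
orphans so the class stays clean.

Oocyte methylation is Beta-distributed per CpG: mean `m_high` = 0.85
inside transcribed territory (trimmed by a 500 bp promoter pad at each
unit's 5' end, so promoter CGIs of active canonical genes stay
unmethylated), `m_low` = 0.05 elsewhere; concentration 30 gives
realistic per-CpG scatter while keeping the genome-wide density
bimodal at the two means. Read depth is an overdispersed Poisson
(gamma-Poisson, mean 15, shape 5) and counts are Binomial(depth, p).
Sperm is high (0.90) everywhere except CGIs (0.003). The
parthenogenetic blastocyst attenuates the oocyte signal (× 0.55)
outside CGIs and draws per-CGI retention (probability 0.4 for
oocyte-hyper CGIs, LIT-embedded or not): retained CGIs sit at 0.70,
erased at 0.05. The biparental blastocyst averages the maternal track
with a sperm-like paternal track. Epiblast erasure removes retained
CGI methylation with probability 0.7, 40% of the erased set being
TET-sensitive (restored in the TET-null track). The H3K36me3 track is
baseline noise plus a constant +2.5 over transcribed territory —
difference-of-means only, no peak structure.

CGI annotations drift by ± 30 bp per species, emulating independent
CGI calling across genomes. This, not insertion load, is what drives
CGI identity below 1: insertions are barred from CGI interiors so the
methylation geometry stays interpretable, and identity monotonicity is
therefore tested against the drift axis.

### What the generator does not model

Sequence-level realism (no motifs, no mappability structure), read
alignment artifacts, bisulfite conversion failure, inversions or
duplications in chains (colinear blocks only), methylation spreading
past transcript 3' ends (hypermethylation truncates at the unit
boundary; a taper is not implemented), copy-number variation, and
allele-level reads (allele-resolved input is accepted as a precomputed
track). Passing tests therefore demonstrate the pipeline's logic under
the stated statistical model, not robustness to alignment- or
sequence-level pathologies of real WGBS.

## Study conditions used by tests and the reproduction script

* **Segmentation**: solver-vs-oracle agreement on 100 random
  instances of ≤ 30 bins; step recovery (Δ = 0.8, sd = 0.05,
  penalty `2 log(n) sd^2`) within ± 2 bins in ≥ 99/100 replicates.
* **Liftover**: 1,000 random intervals against the per-base oracle on
  chains from a three-species cohort (insertions on both sides).
* **LIT recovery**: one deep-coverage species planting ~120 LITs among
  ~1,000 transcripts; precision and recall ≥ 0.95; a zero-LIT cohort
  must yield zero calls.
* **Headline mechanism**: twenty three-species cohorts (1.2 Mb, 45
  genes, 8 shared + 6 pair + 8 private LTRs per species at activity
  0.5). (a) ≥ 95% of planted species-specific LIT-driven meCGIs must
  receive the correct label; (b) the single-species-hyper fraction of
  LIT-overlapping syntenic bins must exceed the non-LIT fraction
  (one-sided two-proportion z at α = 0.01 plus a per-seed sign test);
  (c) in a control where every LTR is shared and active everywhere and
  canonical expression is fully conserved, the two strata must be
  equivalent within a 5-point margin (TOST at α = 0.01). The control
  must hold expression conserved because species-specific canonical
  transcription is its own divergence mechanism and would contaminate
  the non-LIT stratum.
* **Demo**: the default three-species cohort (1.5 Mb, 60 genes) run
  end to end; conservation invariants are asserted on its outputs and
  the whole bundle must be byte-identical across reruns.

These sizes keep every check comfortably within a desktop-scale run
while leaving enough planted events for the stated tolerances.

## Numerical and degenerate-input choices

Undefined methylation (no covered CpG) is NaN, never 0, and NaN units
are excluded-and-counted, never silently dropped. Dyad merging is on
by default (symmetric CpG methylation assumed) and idempotent.
Reciprocal-best ties disqualify rather than picking arbitrarily.
`"> 4 CpGs with > 5x"`-style phrasing is read as ≥ 5 CpGs each with
≥ 5 reads; both knobs are explicit configuration. Chromosome naming
mismatches across inputs are an error (with a configurable alias map),
not an empty join.
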
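# Methods

## The model

Activation-induced cytidine deaminase (AID) deaminates cytosine in single-
stranded DNA with a strong preference for the degenerate tetranucleotide
WRCY (W = A/T, R = A/G, Y = C/T), mutating the underlined C of W R **C** Y.
Because DNA is double-stranded, the same physical site read from the other
strand is R G Y W with the targeted guanine at the second position.  A
somatic SNV is tagged *canonical-AID* (c-AID) when

* ref = C, alt ∈ {T, G}, and the plus-strand 4-mer covering positions
  [pos−2, pos+2) is one of the eight WRCY expansions
  (AACC, AACT, AGCC, AGCT, TACC, TACT, TGCC, TGCT), or
* ref = G, alt ∈ {A, C}, and the plus-strand 4-mer covering
  [pos−1, pos+3) is one of the eight RGYW expansions (their reverse
  complements).

Matched motifs are always reported in WRCY orientation.  Windows containing
N never match: an ambiguous base cannot certify a motif.  Overlapping motif
occurrences are all counted — each genomic C/G is a distinct potential
target — and plus/minus occurrences at palindromic-like sites are counted
separately.

All internal coordinates are 0-based half-open; MAF positions (1-based
inclusive) are converted at I/O time only.

## Per-sample enrichment score

No closed formula is published for the motif enrichment score, so the
package uses the fold-enrichment construction standard in the
APOBEC-signature literature.  For one sample let M_C be its C>T/G mutations
(strand-symmetric), M_motif those at the motif, and Motif_ctx / C_ctx the
motif-target positions and cytosine positions counted inside ±20 bp of
every eligible mutation (flank configurable).  Then

    E = (M_motif · C_ctx) / (M_C · Motif_ctx)

with a one-sided Fisher exact test on [[M_motif, M_C − M_motif],
[Motif_ctx, C_ctx − Motif_ctx]] and Benjamini–Hochberg correction across
samples.  E = 1 means motif mutations occur exactly in proportion to local
motif availability.

## The 768-channel substitution matrix

Twelve uncollapsed substitution types × 64 one-base contexts.  Pyrimidine
references use the frame (−2, −1, X, +1); purine references the mirrored
frame (−1, X, +1, +2), so reverse complementation maps purine channels
one-to-one onto pyrimidine channels and the WRCY target always sits at the
bracketed base.  The uncollapsed reading is the unique natural enumeration
reaching 768 (the collapsed one gives 384).

## The context-preserving null, and a resolution caveat

The null model re-places every mutation of a sample, within its own
chromosome, at a uniformly drawn position sharing the reference k-mer
context centered on the mutated base; the substituted base and the alt
allele travel with the mutation, so per-chromosome burden and the
context spectrum are preserved exactly in every replicate.  Observed c-AID
counts are compared with each replicate by a two-sided Fisher exact test,
and a sample is called significant when fewer than 5% of replicate
odds-ratio 95% intervals (conditional-MLE, the exact-test companion) cover
1.  The cohort-level observed/expected ratio is Σ observed / Σ mean
simulated, with a bootstrap-over-samples CI.

**Caveat.** The WRCY determinant occupies positions −2, −1, +1 of the
mutated C (and −1, +1, +2 of the G on the other strand) — entirely inside
the ±2 bp window.  A pentanucleotide-preserving shuffle (`flank=2`, the
SBS-1536 resolution) therefore *fixes* c-AID status: every replicate
reproduces the observed count and the enrichment ratio is identically 1.
This is asserted as a property test.  Detecting motif excess requires a
coarser context: at `flank=1` (trinucleotide) the R and Y neighbours are
preserved while the W base is free, so planted WRCY excess becomes visible
(observed/expected ≈ 1.4 under the default synthetic mix).  The default
remains `flank=2` — it is the stated resolution of the procedure the module
re-implements — and excess analyses pass `flank=1` explicitly.  Tools that
report >1 enrichment of a motif fully contained in their context window
are, in effect, not preserving that window exactly.

Mutations whose context cannot be indexed (N or contig edge) stay in place
and are counted.  Placement is with replacement across mutations (two
mutations may land on one position); at genome scale the collision
probability is negligible, and the analytic expectation used in tests —
Σ_j (motif positions in class k_j) / (class size) over eligible mutations —
is exact under this scheme.

## Clonality

CCF = VAF · (ρ·CNt + (1−ρ)·CNn) / (ρ·m), with multiplicity
m = round(VAF · (ρ·CNt + (1−ρ)·CNn)/ρ) clipped to [1, CNt].  The 95% CI is
Clopper–Pearson on the VAF (exact, conservative, reproducible — the
published description says only "binomial distribution") pushed through the
same linear map; the *uncapped* upper bound decides the call
(subclonal iff CI_high < 0.95).  CNn defaults to 2; reported CCFs are
capped at 1 for readability.  At depth 200 and purity 1 this calls planted
clonal mutations clonal >99% of the time and CCF-0.4 subclones subclonal
>95% of the time.

## Genomic-distribution analyses

* **Domain loads** — mutations are counted in 25-kb windows; each window is
  assigned to the chromatin-domain class (heterochromatin / inactive /
  repressed / low-active / active) covering the majority of it, ties going
  to the leftward domain (a deterministic rule; the source procedure is
  silent).  Class load = mutations / class length; the active:inactive
  ratio uses those two classes, with a zero inactive load reported as an
  infinite-ratio sentinel.
* **TSS profiles** — ±500 kb around each gene's transcription start (start
  for +, end for − genes), 10-kb bins oriented along transcription
  ("adjacent ∓50 bins" implies 50 bins per side; 2K+1 = 101 bins with bin 0
  centered on the TSS).  Genes are equally weighted by default (pooled
  counts by flag); the TSS bin is contrasted against the ±500-kb flank bins
  by two-sided rank-sum over per-gene loads.  Plus-strand profiles on a
  genome equal minus-strand profiles on its reverse complement exactly.
* **R-loop overlap** — half-open interval containment against G-skew
  regions; pairwise two-sided Fisher tests between process labels.  The
  published worked examples (c-AID 1130/629,871 vs SBS2 456/241,695 →
  p = 0.37; vs SBS13 400/204,922 → p = 0.15) reproduce to two decimals.
* **Rainfall** — distance to the previous mutation within a contig, plus
  1-Mb window densities.
* **Expression coupling** — per tumor type, Spearman correlation between a
  gene's c-AID mutation count and its own expression across samples; BH
  within tumor type; associated iff adjusted p < 0.05 and ρ > 0.

## Composite mutations

A composite is a (sample, gene) pair with ≥2 nonsynonymous SNVs; it is an
AID composite when any member is c-AID-flagged.

* **Permutation null** — gene labels are shuffled across all nonsynonymous
  mutations (per-sample burden preserved; the equivalent sample-label
  shuffle is available), recounting composite-carrying samples; the add-one
  p-value is (1 + #{n_i ≥ n_pos})/(N + 1).  The production default is
  100,000 permutations; tests use ≤10,000.  Because the count statistic is
  discrete, this p-value is superuniform when its null support is narrow —
  tie mass at n_pos is counted in full — so calibration checks use cohorts
  whose null count spreads over ~15+ values.
* **Expected AID-composite counts** — negative-binomial regression with log
  link on log-CDS-length, GC%, replication time, chromatin state
  (unordered categorical, most frequent level as reference), assay version,
  and mean copy number, with offset log(mutated samples); ML dispersion,
  Poisson GLM fallback on non-convergence, median imputation (reported)
  for missing numerics, and constant covariates dropped rather than
  failing rank checks.
* **Gene test** — one-sided binomial of observed AID-composite samples out
  of mutated samples against rate n_c/mutated samples; BH; significant iff
  q < 0.01.  Note the binomial variance is smaller than negative-binomial
  variance, so under strong overdispersion this test is anti-conservative;
  its calibration fixture uses Poisson counts.
* **Residue test** — per residue within a gene, right-sided Fisher of
  AID-composite mutations at the residue vs elsewhere against all other
  mutations; BH across residues; q < 0.01.
* **Hotspot utilization** — residues ranked by population recurrence
  (unique mutated samples per gene+protein position); cumulative fraction
  of each group's mutations (AID/other × composite/singleton) at the top-k
  residues, with two-proportion contrasts at the top residue.
* **Timing** — an event is orderable when exactly one member is clonal and
  one subclonal (clonal first) or an explicit order is supplied.  Globally,
  a two-sided binomial test of "more-recurrent residue first" against 0.5;
  per residue, a one-sided test of arriving second.  Fewer than 5 orderable
  events skips the test.  Phase (cis/trans) is consumed as input, never
  inferred from reads.

## Neoepitopes

%rank scores are inputs, never computed.  Samples are excluded for
incomplete HLA typing, microsatellite instability, or damaged/copy-lost
antigen-presentation genes (HLA-A/B/C, CIITA, IRF1, PSME1-3, ERAP1/2,
HSPA, HSPC, TAP1/2, TAPBP, CALR, CNX, PDIA3, B2M — the literal published
tokens, configurable).  Records need source-gene FPKM > 1; immunogenic iff
%rank ≤ 0.5 (inclusive); ICN additionally requires a clonal source
mutation; a sample is "Presence" for a process when it has ≥1 ICN from it.
Presence proportions are compared by a pooled two-proportion Z-test with
exact binomial CIs, over a common eligible-sample basis.

## Synthetic data: what it emulates, and what it does not

The generator makes an i.i.d. genome at a target GC (default 0.4, in the
human range), domain tilings, uniformly placed genes, and cohorts with a
per-sample NB mutation burden (default mean 500 per exome-scale sample,
dispersion 0.1) split between c-AID (placed uniformly over WRCY/RGYW
targets, C>T with probability 0.7 else C>G — the deamination-repair bias),
APOBEC-like at TCW, and uniform background.  Clonal mutations get CCF 1,
subclonal CCF ~ U(0.2, 0.7) (default clonal fraction 0.7); read counts are
Binomial(depth 80, CCF·ρ/2) under diploid multiplicity 1; purities
~ U(0.6, 1).  Expression coupling uses a Gaussian copula on the rank of the
per-sample AID count of a gene, which guarantees the target Spearman ρ
regardless of marginals; coupled genes are chosen among those whose AID
count actually varies.  Neoepitope %ranks are drawn so a configured
fraction of each process's records falls at ≤0.5.

Deliberately absent from the generator: real signature profiles and
trinucleotide composition biases, regional mutation-rate covariates
(replication timing, chromatin), linkage between neighbouring mutations,
copy-number variation, and sequencing artifacts.  Passing tests therefore
demonstrate the *statistical machinery* — recall by construction, null
calibration, estimator consistency — not performance on real tumor
genomes, where context composition and regional rate variation can move
enrichment scores substantially.

Background placement is uniform rather than signature-matched by design:
context preservation is owned by the null simulator, not the generator.

## Problem sizes and numerical choices

Test and acceptance runs use scaled-down cohorts chosen to exercise every
code path at stable statistics: a 5-Mb genome with 50 samples × ~2,000 SNVs
for parameter recovery, 200 pure-background samples (300-kb genome, ~150
SNVs each, 30 replicates) for null calibration, 200-gene panels ×100
simulations for NB coefficient coverage, and 2,000 draws for clonality
power.  Null-simulator replicates default to 1,000 in the CLI and 30–50 in
tests; the cohort ratio is insensitive to R beyond ~30 because it averages
over samples.  Fisher tests and odds-ratio CIs are cached per distinct
table, seeds are explicit everywhere (derived from a single root seed in
the CLI), and ties in rank-based couplings are broken with infinitesimal
jitter.
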
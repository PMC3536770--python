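# Methods

`andropipe` re-implements, as a tested library, a complete analysis chain for
an androgen-supplementation experiment on pubertal rainbow-trout testis
profiled on single-channel (radioactive) spotted cDNA arrays: normalization,
moderated differential-expression (DE) testing, k-medoids clustering of the
responsive clones, cross-tabulation against a spermatogenesis developmental
atlas, GO-term enrichment with redundancy filtering, and phylogenetic
footprinting for conserved androgen response elements (AREs).  A seeded
synthetic-data generator reproduces the statistical structure of every input,
so each stage is verifiable end to end without the deposited data.

## Normalization

Each spot reports a clone signal S_i and a vector-oligo signal V_i measuring
the amount of cDNA actually deposited.  The chain is:

1. **Non-informative filter.** A clone is dropped iff V < 3 × background in
   strictly more than 20% of arrays.  The background is one positive scalar
   per array.  "Oligonucleotide signal" is read as V (it measures spotted
   cDNA); the filter function accepts any matrix, so S can be substituted.
2. **Spotted-cDNA correction.** corrected = (S_i / V_i) × med_a V_i, the
   median taken over all arrays including the spot's own.
3. **log2**, flooring non-positive values at the smallest positive corrected
   value of the dataset (avoids −∞ without inventing an intensity unit;
   whether the original analysis floored or dropped such values is unknown,
   and the floor is configurable).
4. **Quantile normalization**: each column's k-th order statistic is replaced
   by the mean k-th order statistic across columns; ties receive the mean of
   the reference values at their tied ranks (deterministic; identical to the
   common tie convention).  With ties present the "identical sorted columns"
   property holds only up to tie-averaging, which the tests make explicit.

The filter depends only on V and background, so filtering commutes with the
correction; it is applied first.

## Moderated differential expression

The multi-class test is a moderated one-way F across the five groups
(control n=14; T1 day 7 n=5; T2 day 7 n=4; T2 day 14 n=5; 11KT day 7 n=7).
Per-clone residual variances s² (df d = N − G) are shrunk toward a prior:

    s̃² = (d0·s0² + d·s²) / (d0 + d)

(d0, s0²) are estimated by matching the mean and variance of log s² to the
moments of a scaled-F log-variance: e = log s² − ψ(d/2) + log(d/2);
trigamma(d0/2) = Var(e) − trigamma(d/2) is solved by Newton iteration on the
reciprocal-trigamma (tolerance 1e−8, ≤50 steps); s0² = exp(mean(e) + ψ(d0/2)
− log(d0/2)).  If Var(e) does not exceed the theoretical floor, d0 = +∞ and
every s̃² collapses to s0².  F = (between-group mean square)/s̃² with
(G−1, d0+d) df (χ² limit at d0 = ∞).  A test cross-checks d0, s0², F and p
against Bioconductor limma (`eBayes` + `topTable` over the group
coefficients) to ~1e−6 relative.

Multiplicity: clone-level calls use Benjamini–Hochberg step-up q-values with
q < 0.01 (strict; the original analysis does not state < vs ≤).  The three
day-7 pairwise comparisons (control vs T2 d7, control vs 11KT, 11KT vs T2 d7)
use moderated t with a Bonferroni-partitioned threshold p < 0.01/3 ≈ 0.0033,
strict.  Specificity labels: "T only" (control-vs-T significant, control-vs-KT
not), "11KT only" (converse), "T >11KT" (both control comparisons and the
direct 11KT-vs-T comparison significant, with |T effect| > |KT effect|),
"shared-equal" otherwise when both control comparisons fire, else "none".
The direction of regulation is the sign of (treated − control) at the
smallest-p control contrast.

## Clustering

Responsive clones are clustered by k-medoids (PAM) with Euclidean distance on
row-standardized log2 profiles ((x − row mean)/row sample-sd; constant rows
map to zero), k = 4.  Shape standardization matches the heatmap presentation;
raw log2 rows can be passed instead.

PAM is the deterministic BUILD + SWAP algorithm: BUILD seeds the first medoid
at the point minimizing total distance and adds each next medoid by minimal
marginal cost; SWAP repeatedly applies the best strictly cost-reducing
(medoid, non-medoid) exchange; all ties break to the lowest row index.
Because SWAP is a steepest-descent local search it can miss the global
optimum even on tiny inputs (measured ≈6% of random instances with n ≤ 7,
k = 2), so for n ≤ 60 BUILD is restarted from every point as the forced first
medoid and the cheapest converged solution is kept (0 failures in 3000 random
tiny instances against exhaustive enumeration); at larger n a single greedy
BUILD is used.

Clusters receive semantic labels from their mean unlogged fold change to
control at (T2 day 7, T2 day 14): (−,−) → 1 "down"; (+, max at d7) → 2;
(+, max at d14) → 3; (−,+) → 4.  The unmatched (+,−) pattern falls back to
the nearest pattern by sign agreement, ties resolved toward the time point
with the larger |log2 FC|, with a logged warning.  Per-cluster summaries are
arithmetic means of per-clone unlogged fold changes ± SEM.

## Developmental cross-tabulation

The atlas maps clones to nine developmental clusters: A–D somatic (A high
late, B low at spermiation, C very high at spermiation, D somatic +
spermatogonia), E–F spermatogonial (type A / type B), G germline-broad,
H meiotic/post-meiotic, I isolated-germ-cell-only.  Crossing these with the
four response clusters yields a 9×4 count table over clones carrying both
labels; compartment totals (somatic = A–D, germline = E–I) partition the
table.  The germline shift summary counts spermatogonial clones (E∪F) in the
down-regulated cluster 1 and meiotic clones (H) in the up-regulated clusters
2∪3.  Genes inherit their clones' labels; conflicting clones of one gene are
counted once per distinct (atlas, cluster) pair with a warning — clone-level
and gene-level totals therefore differ, as they do in the source data.

## GO enrichment

Exact hypergeometric over/under-representation of each GO term in a cluster
against the universe of well-measured genes ("Gaussian hypergeometric" is the
exact test; no normal approximation).  Annotations follow the true-path rule
(genes propagate to all ancestors before testing).  Redundancy is pruned with
an Ontology Specific Information Rate (OSIR): enriched terms are visited in
ascending-p order and OSIR(term) = 1 − max shared fraction of its
cluster-restricted gene set with an already-retained enriched ancestor or
descendant; terms with OSIR < 0.95 are dropped, so the smallest-p member of a
redundant set survives.  The OSIR formula is not published; this definition
implements its stated purpose and is a documented deviation risk.  A term is
reported iff p ≤ 1e−6, ≥3 cluster genes, and OSIR-retained.  No further
multiple-testing correction is applied across terms (the fixed 1e−6 cutoff
takes its place).

## ARE footprinting

Matrices are read from TRANSFAC flat files (counts normalized row-wise).  The
MATCH-style information vector is I(i) = Σ_b f(i,b)·ln(4·f(i,b)) with
0·ln 0 := 0; the core is the 5 consecutive most informative positions (ties
to the lowest start).  For a candidate window s, Current = Σ_i I(i)·f(i,s_i)
and MSS = (Current − Min)/(Max − Min) with Min/Max the anti-consensus and
consensus scores; CSS is the same restricted to the core; a degenerate
matrix (Max = Min) scores 1.  Promoter windows span −10000..+2000 around the
TSS in gene orientation (upstream = larger genomic coordinates on minus-strand
genes), truncated at contig bounds; both strands are scanned, CSS ≥ 0.8 first
and then MSS ≥ 0.8 (MATCH's two-stage filter).  Hits are reported at the
TSS-relative position of their 5′-most end in gene orientation; 0-based
half-open coordinates internally, BED conventions on disk.

Conservation: per-hit mean of per-base scores over the genomic interval;
positions missing from the track contribute 0 (conservative); retained iff
mean ≥ 0.8, with the boundary inclusive (guarded against floating-point error
in the mean).  Hits are binned into the half-open windows −10000/−5000,
−5000/−2000, −2000/−1000, −1000/0, 0/+200, +200/+400, +400/+1000,
+1000/+2000, and flagged proximal iff the position lies in [−2000, +400)
(the published window does not specify endpoints; half-open is adopted).
Candidate direct targets are genes that are androgen-responsive, somatic by
the atlas, and carry ≥1 conserved proximal hit, sorted by proximal-hit count
then name.  Hits of different matrices at the same locus count separately.

The shipped matrices are synthetic stand-ins built around the canonical
AR-dimer inverted repeat AGAACAnnnTGTTCT (and an ERE-like palindrome) with a
0.85 dominant base frequency — the validated TRANSFAC matrices are
proprietary and their cell values are not reproduced.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (config, seed).

* **Expression.** Clone abundances, vector signals and backgrounds are
  log-normal (positive, right-skewed, matching log2 analysis); the spot
  signal is S = abundance × V × multiplicative noise with ln-scale σ = 0.3
  (~30% CV).  Well-spotted clones sit far above 3× background; a dedicated
  fraction (default 5%) receives low vector signal to exercise the filter,
  drawn from the non-planted clones — planted responsive clones stay
  well-measured, as the study identified responsive genes among accurately
  measured cDNAs.  Planted clones (default 5%) get per-group multiplicative
  effects of 2–8 fold shaped by four response patterns (down / up-d7 /
  up-d14 / down-d7-up-d14, drawn at roughly the observed cluster
  proportions), with random direction.  At these settings the DE stage
  recovers ≥99% of planted clones at FDR 1% with observed false-discovery
  proportion ≈1.4% averaged over seeds.  The observed FDP sits above the
  nominal 1% because quantile normalization transfers a little planted-effect
  mass onto null clones in the treated arrays; this is a property of forcing
  identical distributions in the presence of real effects, not of the test.
* **Atlas.** Each clone gets one of the archetypal stage/germ-fraction
  profiles A–I (plus Gaussian noise, sd 0.1) or no label (30%).
* **Genome.** One contig per gene, i.i.d. uniform background sequence, genes
  alternating strands, TSS placed so the full window fits; planted motifs are
  exact matrix consensi at recorded TSS-relative offsets (reverse-complemented
  in genomic coordinates on minus-strand genes); conservation is 0.05–0.3
  background and 0.95 over planted instances, so the ≥0.8 filter passes
  exactly the planted sites.
* **Ontology.** A rooted random tree (optional index-increasing cross-links,
  hence acyclic) with Poisson-sized annotations; one designated term's gene
  set overlaps a designated cluster by construction.

Not emulated: spatial array artifacts, print-tip or batch effects, dye
chemistry, real trout (or stickleback) sequence composition, linked genes on
shared contigs, correlated probes, or realistic GO topology.  Passing tests
therefore demonstrate the correctness of the statistical machinery under the
stated model, not performance on the deposited arrays.

## Numerical and design choices

* Thresholds default to the published settings (FDR 1%; global pairwise risk
  1% over 3 comparisons; filter 3× / 20%; MATCH 0.8/0.8; conservation 0.8;
  enrichment 1e−6 / 3 genes / OSIR 0.95; k = 4) and overrides are logged.
* BH q-values are computed by statsmodels; hypergeometric tails by scipy;
  both are property-tested against brute-force enumerations.
* d0 estimation guards: variances are clipped to the smallest positive float
  before logging; trigamma inversion uses asymptotic branches for extreme
  arguments.
* Determinism: one config seed feeds every stage through a seeded generator;
  reruns are byte-identical, including report files.
* Problem sizes in the tests and the acceptance script (8000 clones × 35
  arrays × 20 seeds for DE recovery; 4-gene toy genomes × 10 seeds and
  50 random promoters for footprinting) were chosen as the smallest designs
  at which the Monte-Carlo estimates are stable to well within the asserted
  margins.

## Known limitations

* The OSIR definition is a reconstruction of an unpublished formula.
* The moderated pairwise t uses the pooled five-group residual variance, not
  a two-group refit (consistent with fitting one linear model and testing
  contrasts).
* PAM at n > 60 is a single-start local search and may return a slightly
  suboptimal partition (as classical PAM does).
* File-mode inputs assume one TSS per gene and per-base conservation already
  averaged across species; neither ortholog mapping nor phastCons
  computation is performed.
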
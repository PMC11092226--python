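# Methods

This note documents the statistical models, decision rules, defaults and
known limitations of the package. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Allelic-imbalance test and ASEG calling

Counts for a gene in one sample are the sums of its phased SNPs'
parental-allele counts (haplotype-level counting; a SNP counted with
reversed phase cancels instead of reinforcing, which is why phasing
quality upstream matters more than the test). The test is the 1-df
goodness-of-fit chi-square against a 50:50 null, χ² = (a − b)²/(a + b),
without continuity correction, significant at P < 0.05. Samples with
total allele-informative depth below 10 are untestable; the depth rule is
applied to the *total*, not per allele — a per-allele floor would discard
exactly the near-monoallelic genes that are the strongest ASE cases. No
multiple-testing correction is applied at this level by default (the
replicate-agreement rule is the guard); the gene is an ASEG in a
hybrid × condition cell when at least two replicates are individually
significant in the same direction. With four or more replicates both
directions could reach two votes; the strict majority wins and an exact
tie is not called — imbalance without a direction is not an ASEG.

Calibration (recomputed by the suite and the acceptance script): under
balanced binomial nulls with totals 30–100 the empirical rejection rate
at α = 0.05 sits near 0.05 (the χ² approximation is slightly liberal for
small even totals and conservative for odd ones; mixing totals averages
this out).

## Bias categories

Per hybrid, a gene's per-condition directions give: BC if every condition
is biased the same way, BR if both directions occur, BS if some but not
all conditions are biased (one direction), non-bias otherwise. The
combined call intersects the reciprocal hybrids: BC requires BC in both
with the same direction; BR results from a reversal within either hybrid
*or* opposing consensus directions between hybrids; any other bias is BS.
Conditions in which no replicate passes the depth gate are treated as "no
evidence", excluded from the rules and flagged — missing data is never
read as balance, and a gene biased in all *testable* conditions is still
BC (flagged).

## Expression-pattern typing

Three contrasts describe each gene: d_p = P1 vs P2, d_1 = H vs P1,
d_2 = H vs P2, each `up`/`down`/`ns` ("up" = first member higher;
different means FDR < 0.01 *and* fold change > 1.5). The twelve types:

| type | (d_p, d_1, d_2) | meaning |
|---|---|---|
| I | up, down, up | additive, P1 > H > P2 |
| II | down, up, down | additive, P2 > H > P1 |
| III | up, ns, up | H ≈ P1, the higher parent |
| IV | up, down, ns | H ≈ P2, the lower parent |
| V | down, ns, down | H ≈ P1, the lower parent |
| VI | down, up, ns | H ≈ P2, the higher parent |
| VII–IX | d_1 = d_2 = up; d_p = up/down/ns | overdominant-high (transgressive up) |
| X–XII | d_1 = d_2 = down; d_p = up/down/ns | overdominant-low (transgressive down) |

The remaining 15 of the 27 state triples (all-ns, and internally
contradictory ones such as (up, up, ns)) are unclassified. Labels within
each block are a documented convention; the partition itself is what the
classification literature fixes. Relabeling the parents (flip d_p, swap
d_1/d_2) maps I↔II, III↔VI, IV↔V, VII↔VIII, X↔XI and fixes IX, XII —
an involution that preserves super-groups. ELD-F/ELD-M labels for the
dominant types take the female parent as the first genotype of the cross
name (H12's female is P1).

The built-in contrast engine — Welch's t on log2(TPM + 1) with
Benjamini–Hochberg correction across genes, per contrast — exists so
synthetic pipelines run end to end; the classifier consumes
`ContrastResult` rows from any external differential-expression engine.
At three replicates the Welch–Satterthwaite df can collapse toward 2,
occasionally pushing a real hybrid-vs-parent difference above the FDR
gate; the single-condition typing therefore leaks a few additive and
overdominant genes into the dominant block. `consensus_patterns` (the
per-gene modal type over the 8 hybrid × condition calls) removes most of
this noise and is the recommended gene-level summary; both behaviours are
quantified in the test suite.

## Variant annotation

Impact tiers: frameshift (indel with length change not divisible by 3)
and start/stop-changing SNPs are HIGH; in-frame indels and missense are
MODERATE; synonymous is LOW; intron/UTR, promoter/upstream (3 kb),
downstream (1 kb) and intergenic placements are MODIFIER. SNPs are
decided codon-by-codon against the standard genetic code on the spliced
sense CDS; a reference/CDS disagreement or a CDS length not divisible by
3 is a model-integrity error, not a silent skip. Gene models are
single-transcript, so splice-site effects are out of scope. Promoters are
anchored at the TSS (not the start codon), strand-aware: positions
[tss − 3000, tss − 1] on `+`, [tss + 1, tss + 3000] on `−`; the
positional histogram uses 100-bp bins (fine enough to localize clustering
near the TSS over a 3-kb window).

## Nucleotide diversity and sweep contrast

Per-site π is the unbiased pairwise estimator: differing haplotype pairs
over C(m, 2) among the m non-missing calls (pair reduction, never
imputation; sites with m < 2 are skipped with a flag). Window π sums
per-site values over a sliding window and divides by the window *width*
in bp — monomorphic and unrepresented positions contribute zero — so
block averages are comparable across loci; defaults are width 1,000 bp,
jump 300 bp. The two-population contrast averages window π (windows
assigned to 100-kb-upstream / gene / 100-kb-downstream blocks by window
center, unweighted) and reports the wild/derived ratio per block plus a
one-sided rank-sum p comparing window values — the rank-sum test is an
added convenience statistic, labeled as such in output. A ratio well
above 1 in the gene block with flanks near 1 is the sweep signature.

## Enrichment

Upper-tail hypergeometric only (over-representation), exact via the
survival function; term enrichment applies Benjamini–Hochberg across
terms. The universe defaults to the genes present in the analysis and is
overridable — enrichment conclusions are sensitive to that choice.

## Synthetic-data generator

The generator emulates the target study design: 2 inbred parents + 2
reciprocal hybrids × 4 conditions (dark, far-red, red, blue) × 3
replicates. Defaults, chosen once as field-realistic values:

| parameter | default | why |
|---|---|---|
| depth_mean | 50 | typical per-gene allele-informative depth; the ≥10 gate is exercised in the negative-binomial tail |
| overdispersion | 0.05 | mild extra-Poisson noise of technical replicates |
| bias_ratio | 0.7 | moderate cis effect; detectable but not trivial at depth 50 |
| category mix | 4% BC-P1, 6% BC-P2, 20% BS, 5% BR, 65% none | BS ≫ BC ≫ BR ordering and an alternate-parent-ward skew, as reciprocal maize hybrids show |
| expression_cv | 0.1 | replicate-level TPM noise of clean seedling RNA-seq |
| pattern means | parents 6-fold apart; additive hybrid at the geometric mean; transgressive ≥ 2-fold outside | every planted contrast clears the 1.5-fold gate with margin at n = 3 |
| π background | 0.006 | per-bp diversity of the maize/teosinte range |
| sweep factor | 0.2 | strong artificial-selection signal |
| haplotypes | 23 vs 200 | wild baseline vs derived panel sizes of the emulated comparison |

Hybrid totals are negative-binomial (Var = μ + φμ²) split binomially at
the gene's planted per-condition ratio; both cross directions share each
gene's ratios (inbred parents ⇒ same cis landscape), so the reciprocal
R² is high by construction. Parents are fully homozygous. Haplotypes
segregate per-bp with probability tuned so expected per-bp π equals the
target (site frequencies Uniform(0.05, 0.95), binomial haplotype draws
make the pairwise estimator unbiased for the planted value); the sweep
multiplies the segregation rate inside the swept interval. All
randomness flows from a single seed; identical seed + config is
byte-identical.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: mapping bias and mappability holes, phasing
errors (SNPs within a gene are simulated phase-consistent), genuine
trans effects or maternal (cytoplasmic) differences between reciprocal
hybrids, condition-correlated library effects, linkage disequilibrium
within haplotype regions, and indel-driven alignment artifacts.

## Pipeline

Stages communicate only through files in the run directory, so any stage
can be re-run in isolation; a manifest written last records the config
hash, seed, per-stage record counts and a checksum of every output.
Problem sizes used by the default tests and the acceptance script —
200–400 genes, 4 conditions, 3 replicates, 210-kb diversity regions, 100
sweep replicates — are the package's default desk-scale study; all
recovery rates quoted anywhere are recomputed at run time at those sizes.

## Known limitations

Read-level processing (trimming, alignment, variant calling, phasing) is
out of scope: the pipeline starts at count tables and VCFs. The built-in
DE stand-in is not a replacement for a shrinkage-based engine on real
data. BED name columns are the only QTL linkage supported (intervals are
not intersected against gene models). The hypergeometric universe and
the per-allele-vs-total reading of the depth rule are documented choices
that materially affect results on real data.
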
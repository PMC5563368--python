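# Methods

## Study design being modeled

Rice roots exposed to eight rhizotoxins — Cu, As(V), Cd, Hg, Cr, V,
ferulic acid and juglone — sampled at 1 h and 3 h with three biological
replicates per (stress, timepoint, condition) cell, controls treated with
water in parallel. The analysis classifies genes by expression pattern
across all eight stresses and then characterizes the classes by promoter
composition, gene architecture, evolutionary rate, network position, and
qPCR biomarker behavior.

## Expression model and classification

**Fold change.** Per (stress, timepoint), FC is the treated/control ratio
of replicate means, reported on the signed convention (r if r ≥ 1 else
−1/r, so |FC| ≥ 1 and the boundary maps to +1). Per stress, the reported
FC is the one from the timepoint with the larger |FC|: the early response
is transient and either timepoint may carry the peak; this reproduces a
single per-stress FC from two arrays without averaging away the signal.

**Testing.** The per-stress test is a two-group Kruskal–Wallis
(chi-square approximation, midrank tie correction) comparing the pooled
control replicates against the pooled treated replicates of both
timepoints (6 vs 6 at the default design). Pooling the timepoints is a
deliberate choice: a 3-vs-3 rank test cannot produce a p below ~0.025
(ties) / ~0.05 (no ties), so after per-stress BH correction across ~2000
genes no gene could ever reach q < 0.05 and the class definitions that
require FDR-passing calls would be empty by construction. With 6 vs 6 a
completely separated gene reaches p ≈ 9·10⁻⁴ (ties) / 3.9·10⁻³ (no
ties), which survives BH at the planted-signal densities of this design.
Benjamini–Hochberg is applied per stress across genes (each stress was a
separate comparison in the source designs).

**Classes.** GSR (FC ≥ 2 under all stresses), generally down (FC ≤ −2
under all), uniquely up/down (|FC| ≥ 2 under exactly one stress, |FC| ≤
1.4 under the others), background (|FC| ≤ 1.2 everywhere), low-regulated
(1.2 < FC < 2 everywhere); all inequalities exactly as printed, inclusive
where printed inclusive. The FDR gate (q < 0.05) applies to DEG, GSR,
generally-down and unique calls; background and low-regulated are defined
by FC bounds alone, since those classes describe absence of regulation
rather than detected change. The predicates are mutually exclusive by
construction and the classifier asserts this on every input.

**Detection filter.** A gene is dropped only when its intensity is below
100 in *every* sample. The alternative (all-samples-above-threshold)
would delete exactly the genes the GSR analysis needs: silenced in
control, strongly induced by stress.

**Quantile normalization** (mean-of-sorted-columns, midrank ties) is
implemented for integrating separately scaled datasets and is off by
default for a single jointly generated matrix: rank-mixing the columns of
one matrix perturbs the very fold changes being classified (measured:
noise-free recovery drops from 100% to ~94% when applied needlessly).

## Motif enrichment

Motifs are IUPAC consensi scanned on both strands (PLACE-style elements
are double-stranded); `N` in a promoter never matches. The enrichment
statistic is the difference of per-gene presence percentages (a promoter
counts once regardless of occurrence count — the reported table
percentages are per-gene). The null shuffles group labels over the pooled
promoters preserving group sizes; the one-sided p uses the add-one rule
(1 + #{permuted ≥ observed}) / (1 + n), so p > 0 always. Default 10,000
permutations (resolution below the smallest nonzero published p of
0.0004); the presence vector is put in canonical order before shuffling
so the Monte-Carlo p is invariant to gene order within groups.

## Gene architecture

GFF3 (1-based inclusive) is parsed with gffutils; the representative
transcript is the first mRNA child per gene in file order (deterministic;
matches single-model locus annotations). Introns are gaps between
consecutive exons (length = next_start − prev_end − 1). Intronless
fractions are compared with the pooled two-proportion z-test; intron
number and total intron length with Kruskal–Wallis plus Dunn's post-hoc
z-tests (Bonferroni over pairs), intronless genes excluded as in the
source design. The top/bottom-50%-by-FC contrast uses the two-sided
Mann–Whitney U, exact for combined n ≤ 20 without ties, otherwise the
normal approximation with tie/continuity correction; with an odd gene
count the median gene joins neither half. The FC ranking value is the
gene's mean signed FC across the eight stresses (no aggregate is named in
the source; the mean is the least arbitrary).

## Ka/Ks estimation

Codon alignments are built by back-translating aligned proteins onto
their CDS (standard code; terminal stop stripped; any mismatch or
internal stop is an error naming the offending residue). Rates use
Nei–Gojobori (1986) counting: per-codon synonymous site counts from the
9 single-nucleotide mutants (mutants to stops count as nonsynonymous, so
n + s = 3 exactly), differences by equal-weight averaging over all k!
single-step paths for k-difference columns, excluding paths through stop
codons (falling back to all paths when every path is blocked), and
Jukes–Cantor correction K = −(3/4)ln(1 − 4p/3), flagged undefined at
p ≥ 3/4. Pairs with Ks = 0 have an undefined ratio and are excluded from
rank tests rather than contributing infinities. This counting estimator
deliberately stands in for likelihood methods: it is fully specifiable
and brute-force verifiable, and the category conclusions it feeds are
rank-based, so only rank behavior matters. Known property: for
same-residue codon pairs that differ at two positions across the
serine/arginine/leucine codon islands (e.g. AGA/CGC), pathway averaging
assigns Nd > 0 even though no amino-acid change ever occurred — so a
simulation that forbids amino-acid changes (ω = 0) still estimates a mean
Ka of order 10⁻⁴ at ~0.3 substitutions/codon divergence. That is a
property of the estimator, not a bug, and the test suite documents it.

## Networks

Edge lists are undirected, deduplicated, self-loops dropped, evidence
scores ignored (hubs are ranked by connection count). Hub ties break
lexicographically for determinism. Terminal regulators are regulator
nodes (TFs/kinases) with degree ≥ 1 whose neighborhoods contain no other
regulator — candidates for intervention at the end of signaling cascades.

## Biomarker screen

ΔΔCt with amplification efficiency fixed at 2 (the comparative-CT
assumption); technical replicate Ct values are averaged before ΔCt.
Stage 1 keeps genes induced ≥ 2-fold under exactly one non-excluded
stressor and ≤ 1.4-fold elsewhere (vanadate is excluded by default: its
assay concentration, 1 mM, does not occur in field soils). Stage 2, on
the five 4-of-5 metal leave-one-out panels, validates a candidate iff it
is induced ≥ 2-fold in every panel containing its target stressor and its
specificity ratio (min fold with target / max fold without) is ≥ 2. The
ratio threshold formalizes a contrast the source drew from a 17× vs 3.3×
observation (ratio ≈ 5) without stating a cutoff; it is exposed in the
configuration.

## Synthetic data

Intensities are log-normal around a per-gene baseline with multiplicative
treatment effects, so the noise-free limit satisfies every class-defining
inequality exactly. Effects per (stress, timepoint): GSR-up uniform in
[2.5, 6] (down-regulated classes reciprocal), low-regulated uniform in
[1.3, 1.9], unique classes get their effect only under their own stress,
background and filler stay at 1. Planted regulated genes draw baselines
log-uniform in [200, 2000] (stress-inducible genes have low basal
expression, and every planted gene stays above the detection filter);
planted background genes draw from [2000, 20000] (the constitutive bulk);
filler genes are log-normal around 1000 (sd 1 on the log scale) and can
legitimately fall below the filter. Default noise is 0.05 on the natural
log scale. Promoter sets plant exact motif-carrier counts
(round(fraction × n)) and rejection-sample the remaining sequences to be
motif-free on both strands, so scanner-measured fractions equal the
request exactly. Codon evolution proposes uniform single-nucleotide
changes, rejects stop-creating proposals, and accepts nonsynonymous
proposals with probability min(1, ω) — the neutral limit has dN/dS = 1;
each lineage of a pair receives Poisson(0.15 × codons) proposals by
default. Networks are Erdős–Rényi backgrounds (mean degree 3) with hubs
topped up to a fixed degree. Ct tables hold the reference gene constant
and lower the target Ct by one cycle per 2-fold planted induction, so
ΔΔCt recovery is exact to machine precision. One master seed feeds
deterministic named substreams, so partial runs are reproducible and two
runs with equal configuration are byte-identical.

What the generator does *not* emulate: probe-level microarray artifacts,
background correction, cross-hybridization, correlated noise between
genes, indels in ortholog alignments, and weighted network evidence.
Passing recovery tests therefore demonstrates correctness of the
statistics and plumbing under the stated noise model, not robustness to
raw-array pathologies.

## Problem sizes

The default analysis and acceptance scale — 2000 genes (350 planted), 20
noisy recovery seeds, 1000 permutation-calibration pairs of 100 + 100
promoters at 200 permutations, 100 ortholog pairs × 500 codons, 100
random graphs up to 200 nodes — was chosen to give stable Monte-Carlo
estimates (binomial SE ≤ 0.7 pp on calibration rates) at desk-scale
runtimes. The permutation-calibration group size of 100 promoters also
keeps the presence-count statistic fine-grained; with very small groups
the lattice of achievable differences makes the add-one permutation test
visibly conservative (rejection ~0.02–0.03 at groups of 30), which is a
property of discrete permutation tests, not an error.

## Known limitations

* The published headline numbers tied to the original microarrays (8737
  DEGs, 539 GSR genes, the exact Table percentages, the 426-node network)
  are not reproducible without the arrays and the proprietary
  normalization; the package reproduces the *arithmetic identities* of
  the published count table and the method behavior on ground-truthed
  synthetic data instead.
* The published count table contains two internal inconsistencies (Cd
  row: 17 + 20 ≠ 39 uniquely regulated; Cr row: 1801 + 688 ≠ 2498 DEGs);
  they are transcribed as printed and excluded from identity checks.
* NG86 + JC is a counting estimator; absolute Ka/Ks values differ from
  likelihood estimates, and the ω = 0 island-crossing artifact described
  above bounds how literally "Ka = 0" can be taken at nonzero divergence.
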
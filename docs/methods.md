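# Methods

## Statistical core

**Exact Mann–Whitney U.** With 6 vs 5 (methylation) or 5 vs 4 (expression)
samples, large-sample approximations are unreliable and ties are pervasive
(methylation percents at moderate depth take few distinct values). The test
therefore computes U with mid-ranks and obtains its null distribution by
enumerating all C(n₁+n₂, n₁) assignments of the pooled observed values to
the two groups — a permutation-exact test that remains valid under ties.
The two-sided p-value is min(1, 2·min(lower tail, upper tail)) at the
observed U. Enumeration is used whenever C(n₁+n₂, n₁) ≤ 200,000 (6 vs 5 is
462 assignments; the cap keeps the combination matrix, cached per group-size
pair, a few MB); beyond that a normal approximation with tie and continuity
corrections takes over. Consequences worth knowing: the smallest achievable
two-sided p for 6 vs 5 is 2/462 ≈ 0.0043, and for 5 vs 4 it is 2/126 ≈
0.016 — so a 5-vs-4 comparison can only reach p < 0.05 when the groups are
completely or almost completely separated. A reported p = 0.028 is not an
achievable exact level for 6 vs 5 without ties, so per-sample mean
comparisons may differ in the third decimal from software using the normal
approximation.

**Benjamini–Hochberg.** Step-up adjustment, delegated to
`statsmodels.stats.multitest` behind input validation; values are returned
in input order. Adjustment families are deliberately small ("within
regions"): a promoter's own CpGs for promoter calls, each merged fragment's
CpGs for gene-body calls.

**Exact binomial.** For the symmetric null p₀ = 0.5 the doubling rule
min(1, 2·min(P(X≤k), P(X≥k))) is used — this is what reproduces the
published concordance p-values (19/25 → 0.0146, printed 0.015; 233/370 →
6.85×10⁻⁷). For p₀ ≠ 0.5 the minimum-likelihood definition (scipy's
`binomtest`) applies.

## Methylation pipeline

Coordinates are 1-based closed throughout; BED input (0-based half-open) is
converted on read. CpGs are identified by the forward-strand C position and
assumed pre-collapsed across strands. Chromosomes sort naturally
(chr1 … chr22); only chr1–chr22 count as autosomes by default (the assembly
list is a parameter).

Filtering keeps a site when depth ≥ 10 in ≥ 3 samples of each group and
stores a per-sample level only where that sample's depth passes the cutoff —
shallow observations are treated as missing, never imputed, and are dropped
from means and rank tests site by site.

Region merging starts a new region when the gap between consecutive retained
CpGs is ≥ 500 bp ("closer than 500 bp" is strict) or the chromosome changes.
Regional and feature-level group means are unweighted means over member CpGs
of the per-CpG group means — depth weighting was considered and rejected
because it would let a single deep CpG dominate a feature's Δ; the unweighted
mean matches the "average methylation of the region" reading. Δ is always
oriented third-minus-first.

DMR criteria: |Δ| ≥ 10 pp and ≥ 2 CpGs at FDR < 0.05; gene bodies
additionally require all fragments containing a significant CpG to share one
direction. Features with fewer than 2 covered CpGs are reported untestable
rather than non-significant. Genes with several annotated TSSs get one
promoter per TSS; gene-level rollups count a gene once, using its largest-|Δ|
significant promoter.

## Expression pipeline

RPKM uses each sample's total aligned reads (the counts-column sum by
default, an explicit totals table when provided). The 0.5 floor applies only
to group averages, exactly where ratios are formed, so log₂ ratios are
always finite; the low-expression filter (both group averages < 0.5
pre-floor) runs before testing. The rank test runs on per-sample RPKM —
group averages enter only the fold-change rule. Thresholds are as printed:
p < 0.05 strict, ratio ≥ 2 or ≤ 0.5 inclusive.

## Integration

Expression bins are contiguous rank slices (sizes differ by ≤ 1; ties broken
by gene id for determinism), computed separately per trimester group since
the ranking group is not otherwise determined; genes without a covered
feature in a context are excluded from that bin's mean rather than imputed.
Concordance records require significance in both analyses; pairs with either
component exactly zero are excluded (unreachable for significant calls given
the thresholds, but guarded). The baseline-expression comparison between
anti- and positively-correlated classes is a two-sided Mann–Whitney on
log₁₀ first-trimester average RPKM. Dual-luciferase normalization is the
assay arithmetic only: firefly/Renilla minus the empty-vector ratio.

## Synthetic data generator

The generator emulates the study regime, not any particular genome:

- **Geometry.** Non-overlapping genes (spans 4–8 kb) on 2 chromosomes with
  2–4 exons; 60% of promoters carry a CpG island around the TSS. CpGs are
  placed densely in promoters (6–12 per promoter, gaps < 500 bp) and in two
  gene-body clusters ≥ 700 bp apart plus occasional singletons, so region
  merging exercises both multi-CpG fragments and singleton regions.
- **Methylation.** Per-CpG baselines are beta-distributed by context —
  Beta(0.6, 6) in CGIs (mode near 0%) and Beta(6, 0.6) outside (mode near
  100%), reproducing the bimodal marginal seen in RRBS. Per sample and CpG,
  the level is drawn from a beta with concentration 100 around the baseline
  (between-sample SD ≈ 5 pp, a typical biological scale) and reads are
  binomial at Poisson(30) depth — the standard beta-binomial RRBS noise
  model. Sample sizes default to 6 vs 5.
- **Planted methylation effects.** Selected promoters/bodies shift the
  third-trimester mean by ±20 pp (97% hyper by default, mirroring the
  hypermethylation dominance of late gestation). Baselines of planted CpGs
  are drawn from mid-range uniforms so the shifted mean stays inside [0, 1]
  and the realized Δ is unbiased.
- **Expression.** Baseline RPKM is log-normal (median 5, log-SD 1.6, so a
  realistic minority of genes fall below the 0.5 filter); lengths 0.5–5 kb;
  ~2M reads per sample; counts are gamma-Poisson (negative binomial,
  dispersion 0.1). Planted DE genes change 4-fold, 77% down, and are planted
  on expressed genes (baseline lifted above the filter regime when needed) —
  a planted fold change on an unexpressed gene would be unrecoverable by
  construction, not a property of the caller. Sample sizes default to 5 vs 4.
- **Coupling.** "Coupled" genes carry both a promoter/body DMR and a DE
  effect with sign agreement controlled by `anti_fraction` (default 0.75
  anti-correlated), which is what end-to-end concordance recovery measures.
- All randomness flows from one seed through named per-stage streams;
  identical configuration gives byte-identical datasets on disk.

**What passing tests do and do not show.** The generator has clean group
structure: no covariates, no cell-type mixture, no coverage bias, no
isoform complexity, one TSS per gene, and planted effects that are uniform
across a feature's CpGs. Calibration and sensitivity results on it bound the
procedure's behaviour under its own assumptions; they do not certify
performance on real placental data, where fragment-level heterogeneity and
confounding can only loosen them.

## Problem sizes and numerical choices

The shipped calibration runs use 250 genes (≈ 500 testable features, ≈ 5,500
CpGs) for null false-positive rates and 125 genes with 100 coupled for
recovery — sizes chosen so each check completes in seconds while leaving
binomial standard errors small relative to the margins being tested
(observed across seeds: null DMR rate 0%, null DE rate ≤ 1.3% against an
achievable exact level of 4.8%, DMR sensitivity ≥ 97%, DE sensitivity
≥ 93%, recovered anti fraction 71–78% around the planted 75%).

Degenerate inputs are handled explicitly: zero-depth CpG calls are retained
with undefined level; a CpG with fewer than two values in a group tests at
p = 1; genes shorter than 1 kb have no gene body; empty CGI tracks make
everything non-CGI; histograms clip to their outermost bins.

One bundled reference row (PSIMCT-1, averages 3.246 and 1.35) reproduces its
printed log₂ value only to 0.006 rather than 0.005 — the printed inputs are
themselves rounded to ~2 decimals, and first-order propagation of that
rounding allows up to ≈ 0.0055 for this row, so the tests compare table
arithmetic with the rounding-propagation bound.

## Known limitations

- The exact tests enumerate assignments; group sizes beyond ~15 total fall
  back to the normal approximation.
- Promoter/body intervals come from single TSS/TTS gene models; isoform
  structure is out of scope.
- The DMR caller implements the fixed-threshold regional criteria, not
  smoothing/HMM detection or beta-binomial dispersion modelling, and no
  covariate adjustment is available.
- Feature assignment is by member-CpG containment; a region is assigned to
  every feature containing at least one of its CpGs, so features of
  overlapping genes share regions.
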
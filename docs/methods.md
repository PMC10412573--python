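# Methods

`pharmacoepimap` implements a pharmacoepigenomic discovery pipeline for
drug-screened cancer cell-line cohorts: per-CpG drug-response models,
spatially-aware region calling, methylation–expression linking with a
permutation empirical null, replication in an independent tumour cohort,
and signalling-network path evidence. This note documents the statistical
model, the synthetic cohorts the test-bench runs on, and the numerical and
design choices that were genuinely open.

## Per-CpG drug-response model

For one drug and one cancer type, each probe's beta-value m is related to
the drug's area-under-the-dose-response-curve y by ordinary least squares:

    y = β0 + β1·m + β2·c1 + β3·c2 + β4·c3 + β5·pc1 + β6·pc2 + ε

where c1–c3 are the categorical screen covariates (screening medium,
growth property, microsatellite-instability status; one-hot encoded with
the lexicographically first level as reference, constant columns dropped)
and pc1/pc2 are the first two principal components of the cancer type's
sample × probe beta matrix, which absorb global methylation differences
between lines. The per-probe p-value is the two-sided t-test on β1 with
residual degrees of freedom n − rank(X). PCs are computed once per cancer
type on all retained probes, after probe filtering, with missing values
mean-imputed for the decomposition only; the component sign is fixed by
making the largest-magnitude loading positive.

Implementation: when a probe sub-matrix is complete, all probes are fitted
in one vectorised pass via Frisch–Waugh–Lovell residualisation (the
covariate block is shared); probes with missing values fall back to a
per-probe solve. Both paths are algebraically exact OLS and are tested
against a normal-equations oracle at 1e-8. Probes with fewer than 8
complete (beta, AUC) pairs are skipped, as are probes whose beta is
collinear with the covariate block.

Eligibility: a cancer type is scanned when it has at least 16
characterised lines; a drug when at least 3 lines show partial response
(AUC ≤ 0.7, inclusive).

## Region calling

Neighbouring CpG sites carry correlated evidence, so per-site p-values are
combined before region extraction:

1. **ACF.** Association z-scores (z = Φ⁻¹(1 − p/2)·sign(t)) are correlated
   in distance bins (0,250], (250,500], (500,750], (750,1000] bp, pooled
   across chromosomes. Bins with fewer than 10 pairs inherit the previous
   bin's value (first bin defaults to 0); estimates are clipped to
   [0, 0.99] — negative spatial correlation is treated as noise, which
   keeps the combined-z denominator valid and is conservative.
2. **SLK correction.** Each site's raw p is combined with all raw p within
   ±1000 bp by the Stouffer–Liptak–Kechris statistic
   Σ Φ⁻¹(1 − pᵢ) / sqrt(Σᵢⱼ Cᵢⱼ), with C looked up from the ACF by
   pairwise distance. The denominator is floored at the number of sites,
   which also guards non-positive-definite C. P-values are clipped to
   [1e-300, 1 − 1e-16] before quantile transforms.
3. **Extraction.** Sites with corrected p < 0.05 are chained while
   successive sites are within 1000 bp (this both extends peaks and merges
   nearby ones); a chain is kept if it contains a seed below 0.05.
4. **Region score.** The region p is the SLK combination of the
   constituent raw p-values; the Šidák adjustment 1 − (1 − p)^n_eff uses
   n_eff = max(1, n_total_probes // n_region_probes) — a probe-count
   dialect rather than base-pair coverage, which is well defined on sparse
   arrays (the original region software uses bp coverage; the two are not
   asserted equivalent).
5. **Post-filters.** A region is reported as a dDMR when adj. p < 1e-6,
   every constituent probe has raw p < 0.01 (strictest reading of the
   contained-sites filter; configurable), and at least 4 samples sit in
   each methylation extreme (region-mean beta < 0.3 and > 0.7), so both
   methylation states are populated. The effect size is the mean β1 across
   the region's probes, in AUC units per beta unit; negative effects mean
   hypermethylation sensitises.

All thresholds live in `DmrCallingConfig` and the coordinates are 0-based
half-open internally (manifest positions are read as 1-based single-base
and converted on load), so BED export is direct.

## Expression linking

For each dDMR the samples are ranked by region-mean beta; the lowest 20%
form the U (unmethylated) and the highest 20% the M (methylated) group, at
least 4 samples each (pairs with 2g > n or constant beta are untestable).
Candidate genes are either promoter-mode (strand-aware window 2000 bp
upstream to 200 bp downstream of the TSS overlapping the region) or
distal-mode (the 20 nearest TSS, up to 10 per side). Each pair is scored
by a two-sided Mann–Whitney U test of expression between M and U — exact
by exhaustive label enumeration when both groups have ≤ 8 samples (correct
under ties), tie-corrected normal approximation with continuity correction
otherwise — with a direction field (negative = M expresses less).

Pairs with raw p < 0.05 enter the permutation stage: the null is the same
test applied to genes drawn uniformly with replacement from the cohort
transcriptome (excluding the linked gene), using the link's own M/U
groups; emp_p = (1 + #{null ≤ observed}) / (n_permutations + 1). Because
the null p of a pool gene is deterministic given the groups, the pool is
scored once and indices are sampled — identical results, much faster.
Empirical p-values are then Benjamini–Hochberg adjusted across tested
links and a link is significant iff emp. adj. p < 0.001. The default
permutation count is 50 000; the test-bench runs 2 000, which keeps the
attainable floor (1/2001 ≈ 5e-4) below the 0.001 cutoff.

Mechanism cases combine sign(dDMR effect) × sign(Pearson r of region-mean
beta vs expression over all samples, not only M/U): Case 1 (−,−),
Case 2 (−,+), Case 3 (+,−), Case 4 (+,+).

An additional model tests whether the proximal gene's expression
associates with drug response independently of the region, using the same
OLS machinery with expression PCs in place of methylation PCs.

## Tumour replication and concordance

Significant cell-line links are retested in an independent tumour cohort:
M/U groups are re-derived from the tumour cohort's own region-mean
methylation quantiles (the alternative — reusing cell-line beta cutoffs —
is not used), the rank test and empirical FDR are rerun without drug data
or covariates, and a region is a tgdDMR only when significant in both
cohorts with the same direction. Tumour cohorts below 8 samples are
skipped with a warning. `effect_concordance` summarises paired effect
sizes across cohorts (sign-consistency fraction, Pearson r; r is reported
as NaN below 3 pairs, zeros are excluded from the sign count).

## Network evidence

Drug-target connectivity uses Yen's K-shortest loopless paths (K = 10) on
a directed signalling edge list, unweighted hop count by default (edge
weights honoured when present) with a deterministic lexicographic
tie-break among equal-cost paths. Forward gene→target paths are tried
first; the reversed direction only when none exist. Paths through other
drug targets are allowed. A biomarker is network-supported iff any path is
found. The tie-break and the induced-subnetwork report are this package's
additions; path enumeration is delegated to networkx and cross-checked
against brute-force enumeration in the tests.

## Alteration and enrichment statistics

Somatic alterations are binarised per gene (mutation, amplification and
deletion as separate features) and features altered in fewer than 4
samples dropped. The alteration/CRISPR scan is univariate OLS of
region-mean methylation on each feature with BH across all tests in the
scan. Enrichment tests are one-sided ("greater") hypergeometric tails on
2×2 tables (annotation enrichment, per-cancer-type drug-class enrichment
with the screened drugs of that type as universe) and a one-sided binomial
tail for signature over-representation with the background rate estimated
from all genes. The cancer-gene enrichment background restriction (genes
with ≥ 10 proximal CpG sites) is a caller-supplied filter.

## Synthetic cohorts

The generator produces the statistical structure the pipeline assumes,
with defaults chosen as one coherent set of study conditions:

- **Probe geometry.** Probes fall in island-like clusters (sizes
  1 + Poisson(6), consecutive probes 30–80 bp apart) separated by ≥ 2 kb,
  spread over ~200 kb — the clustered layout of promoter-focused arrays,
  and the geometry under which distance-based merging is meaningful. Each
  planted region occupies a dedicated cluster.
- **Beta values.** Logit-scale model: a bimodal baseline per probe (modes
  ~0.1/0.9 with jitter), two latent global factors with per-probe loadings
  (sd 1.5 and 1.0) emulating the global methylation differences that pc1
  and pc2 remove, an Ornstein–Uhlenbeck spatial residual whose correlation
  at distance d is spatial_rho^(d/250) (default rho = 0.6 at the 250 bp
  reference distance; sd 0.5), and white noise (sd 0.3); the sum is passed
  through the inverse logit, so beta stays in (0, 1).
- **Planted regions.** A fraction of samples (default 25%) has the
  region's probes flipped to the opposite mode; AUC for the region's drug
  is 0.8 + auc_effect·(region-mean beta) + covariate offsets + N(0,
  0.03²), clipped to (0, 1]. The technical noise sd of 0.03 sits at the
  optimistic end of the reproducibility range of large drug screens and
  makes the default planted effect (−0.15 AUC per beta unit) clearly
  detectable. Covariates (medium, growth, MSI) carry small additive AUC
  offsets — the medium offset (−0.12) also guarantees drugs without a
  planted effect still have enough responders to be scanned.
- **Expression.** Genes are N(mean_g, 1) noise except planted linked
  genes: mean + b·(region-mean beta) + N(0, 0.35²) with |b| = 1.5 and
  sign(b) set by the requested Case; this yields meth–expression r ≈ 0.8,
  the strength of the clear promoter-driven biomarkers the linking stage
  is designed to flag. Linked genes sit just downstream of their region so
  promoter-mode candidate search finds them; decoy genes are placed
  sparsely on the same chromosome and densely on a second one.
- **Tumour cohorts** are regenerated from the truth record (same probe
  baselines and noise parameters, fresh samples), with the linked gene's
  slope sign kept or flipped depending on the concordance flag, and no
  drug screen.

What the generator does **not** emulate: probe chemistry and detection
noise, copy-number-driven methylation artefacts, cell-type composition,
non-linear dose–response summaries, correlated expression programs
(decoy genes are independent noise), and multi-gene regulation of one
region. Passing calibration therefore demonstrates the pipeline's
statistical behaviour under its own model assumptions, not performance on
real arrays.

## Calibration harnesses and problem sizes

`pharmacoepimap.calibration` reruns the pipeline end to end:

- **Null calibration**: 100 cohorts of 40 lines × 500 probes × 3 drugs
  with no planted effect; the caller is expected to stay silent at adj. p
  < 1e-6 in ≥ 95 scans. The per-CpG p-value uniformity check thins to a
  few well-separated islands per drug before a KS test: within one scan
  all probes share the realized response vector and residual-variance
  estimate, so a KS test pooled over all probes is over-dispersed even
  though each p is marginally exact (verified against a white-noise
  design); sparse harvesting restores the KS test's independence
  assumption.
- **Planted recovery**: 20 cohorts with one 8-probe region, effect −0.15,
  10/40 samples shifted; detection requires ≥ 1 bp truth overlap.
- **Linking FDR**: 100 no-link cohorts (60 lines), 500 (region, gene)
  pairs each, 2 000 permutations; and 20 Case-1 planted cohorts run
  through discovery → linking → concordant and sign-flipped tumour
  replication. Linking simulations use 60 lines so the 20% tails hold 12
  samples — large enough that the normal-approximation p floor is rarely
  tied by a chance-separating null gene, which at groups of 10 happens
  often enough to disturb the 0.001 bound.

These sizes keep the whole bench in a few CPU-minutes while leaving the
published thresholds untouched.

## Degenerate inputs and tie-breaks

- Constant or covariate-collinear probes, zero-variance features and
  rank-deficient designs are skipped and logged, never fatal for a scan.
- ACF bins whose z-scores are numerically constant return 0 with a
  warning (detected with a relative tolerance — exactly-equal floats still
  carry epsilon-level variance).
- M/U ties are broken by stable input order; equal one-sided U tails give
  direction 0; identical expression in both groups gives p = 1.
- Equal-cost network paths are ordered lexicographically; duplicate edges
  keep the minimum weight; self-loops are dropped on load.
- BED scores are capped at 1000; p-values never reported below 1e-300.

## Known limitations

- The Šidák probe-count dialect differs from the bp-coverage dialect of
  the original region software; counts calibrate correctly under the
  generator but absolute region p-values are not comparable across
  dialects.
- The empirical-FDR stage tests each link against random genes, not
  against permuted sample labels, so it calibrates gene-specificity rather
  than group-assignment noise (the standard random-gene null of methylation-expression linking tools).
- With 2 000 permutations the empirical p floor (5e-4) is close to the
  0.001 significance cutoff; when several co-tested links share a region
  the BH correction can push a floor-level link above the cutoff. The
  50 000-permutation default gives a floor of 2e-5 and does not have this
  problem.
- The exact U test is limited to groups of ≤ 8 (C(16,8) ≈ 1.3e4
  enumerated assignments); larger groups use the tie-corrected normal
  approximation, whose error is negligible at those sizes.
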
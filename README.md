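# pharmacoepimap

Discovery of DNA-methylation biomarkers of drug response in cancer cell
lines, and the downstream evidence chain that turns them into candidate
mechanisms: region calling, gene-expression linking, tumour replication
and signalling-network paths.

## The problem

Large drug screens characterise hundreds of cancer cell lines with
genome-wide CpG methylation (beta-values in [0, 1]), normalized gene
expression and a per-drug area under the dose–response curve (AUC; low
AUC = sensitive). The question is which *regions* of coordinated
methylation change predict response to which drug, and whether those
regions act through their proximal gene — the profile of a usable
biomarker.

The pipeline implemented here:

1. **Per-CpG models** (per drug, per cancer type):
   `y = β0 + β1·m + β2·c1 + β3·c2 + β4·c3 + β5·pc1 + β6·pc2`, where `y` is
   the AUC, `m` the probe beta-value, `c1–c3` the screen covariates
   (medium, growth, MSI) and `pc1`, `pc2` the first two methylation
   principal components; the p-value is the two-sided t-test on `β1`.
2. **dDMR calling**: per-site p-values are combined under a
   distance-binned autocorrelation estimate (Stouffer–Liptak–Kechris),
   peaks are extracted and merged within 1000 bases, Šidák-adjusted
   (`1 − (1 − p)^n_eff`), and post-filtered: adj. p < 1e-6, every probe
   raw p < 0.01, and ≥ 4 samples in each methylation extreme
   (region-mean beta < 0.3 and > 0.7). Effect size = mean `β1` over the
   region.
3. **Expression linking**: samples are split into the 20% most (M) and
   least (U) methylated tails of the region; a two-sided Mann–Whitney U
   test compares proximal-gene expression between them, calibrated
   against an empirical null of random genes (default 50 000
   permutations, raw p < 0.05, BH-adjusted empirical p < 0.001). Links
   are classed by sign(effect) × sign(meth–expression correlation) into
   Cases 1–4.
4. **Tumour replication**: the link is retested in an independent tumour
   cohort (its own M/U quantiles, no drug data); regions significant in
   both cohorts with the same direction are tumour-generalisable
   (tgdDMRs).
5. **Network evidence**: Yen's 10 shortest loopless paths on a directed
   signalling network connect the biomarker gene to the drug's targets
   (reverse direction as fallback).

A first-class synthetic-cohort generator (`synthetic_data`) produces
bimodal, spatially correlated methylation with island-like probe
geometry, planted effect regions, the four mechanism cases and matched
tumour cohorts, so every stage is testable without downloads. See
`docs/methods.md` for the full model and all defaults.

## Worked example

Simulate a 60-line cohort with one planted Case-1 region (8 probes,
effect −0.15 AUC per beta unit, 30% of lines shifted), then run discovery
and linking:

```bash
cat > sim.yaml <<EOF
n_samples: 60
n_probes: 300
n_genes: 120
n_genes_on_chrom: 15
planted_regions:
  - fraction_shifted: 0.3
EOF
pharmacoepimap simulate --config sim.yaml --out cohort --seed 3
pharmacoepimap call-ddmr --cohort cohort --out ddmrs.tsv --bed ddmrs.bed \
    --summary summary.json
pharmacoepimap link-expression --ddmrs ddmrs.tsv --cohort cohort \
    --permutations 2000 --seed 5 --out links.tsv
```

prints

```
simulated cohort: 60 samples x 300 probes -> cohort
called 1 dDMRs
tested 1 links; 1 significant
```

and `ddmrs.tsv` contains the recovered region (truth: chr1:71365–71823,
gene GENE_P1, drug_1):

```
dmr_id                       drug    n_probes  sidak_p   effect_size  n_hypo  n_hyper
drug_1:CT1:chr1:71365-71823  drug_1  8         1.8e-18   -0.151       15      41
```

The Šidák-adjusted p (1.8e-18) is far below the 1e-6 call threshold; the
effect size −0.151 recovers the planted −0.15 (AUC units per beta unit:
methylated lines are more sensitive), and 15/41 lines sit in the hypo-/
hyper-methylated extremes. `links.tsv` holds the expression link:

```
gene     direction  mwu_p    emp_p    emp_adj_p  pearson_r  case
GENE_P1  -1         6.0e-05  5.0e-04  5.0e-04    -0.78      1
```

a Case-1 link — the methylated lines both respond to the drug and
under-express the gene (r = −0.78); the empirical p sits at the floor of
the 2000-permutation null. A concordant tumour cohort
(`pharmacoepimap generalize`) then flags it as a tgdDMR, and
`pharmacoepimap network` reports shortest-path evidence between the gene
and the drug's targets.

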
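"""Synthetic pharmaco-methylation cohorts with known ground truth.

The generator emulates the statistical structure a drug-screen methylation
scan assumes:

* bimodal beta-values (low mode ~0.1, high mode ~0.9) produced on the logit
  scale and squashed through the inverse logit;
* array-like probe geometry: probes fall in tight clusters (CpG-island-like
  runs of a few probes 30-80 bp apart) separated by multi-kilobase gaps, the
  layout the distance-based region merging assumes;
* spatial correlation along the chromosome, modelled as a continuous AR(1)
  (Ornstein-Uhlenbeck) process in the logit residuals whose correlation at
  base-pair distance d is ``spatial_rho ** (d / 250)`` — ``spatial_rho`` is
  the correlation at the 250 bp reference distance;
* global methylation factors shared by all probes (what the first two
  principal components of a methylation matrix capture in real arrays),
  implemented as latent per-sample factors with per-probe loadings;
* planted regions: runs of consecutive probes whose methylation is flipped
  to the opposite mode in a subset of samples, with a linear effect of the
  region-mean beta on one drug's AUC and on one proximal gene's expression
  (the slope signs encode the four mechanism cases);
* categorical covariates (screening medium, growth property, MSI) with
  additive AUC offsets, so the per-CpG model has something to correct.

Every draw flows from one :class:`numpy.random.Generator` seeded from the
config, so identical configs give bit-identical cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from pharmacoepimap.cohort_data import MethylationCohort, ProbeManifest

#: Reference distance (bp) at which ``spatial_rho`` is the residual
#: correlation between two probes.
SPATIAL_REF_BP = 250.0

#: Mechanism case -> (sign of AUC effect, sign of methylation-expression slope)
CASE_SIGNS: Mapping[int, tuple[int, int]] = {
    1: (-1, -1),  # hypermethylation-sensitive, expression down with beta
    2: (-1, +1),
    3: (+1, -1),  # hypomethylation-sensitive, expression up when unmethylated
    4: (+1, +1),
}

_LOW_MODE = 0.1
_HIGH_MODE = 0.9


@dataclass
class PlantedRegion:
    """A ground-truth dDMR to embed in the simulated cohort."""

    n_region_probes: int = 8
    fraction_shifted: float = 0.25
    auc_effect: float = -0.15   # AUC units per region-mean-beta unit
    case: int = 1
    linked_gene: str = "GENE_P1"
    drug: str = "drug_1"
    expr_effect: float = 1.5    # magnitude of expression slope; sign from case


@dataclass
class SimulationConfig:
    """All knobs of the simulated drug-screen cohort (defaults = study scale
    used throughout the test-bench: one cancer type of 40 lines, 500 probes
    in island-like clusters over ~200 kb)."""

    n_samples: int = 40
    n_probes: int = 500
    span_bp: int = 200_000
    chromosome: str = "chr1"
    planted_regions: list[PlantedRegion] = field(default_factory=list)
    cluster_size_mean: float = 7.0       # probes per CpG-island-like cluster
    within_cluster_gap: tuple[int, int] = (30, 80)   # bp between neighbours
    min_cluster_gap: int = 2000          # bp between clusters
    n_drugs: int = 3
    auc_baseline: float = 0.8
    noise_sd_auc: float = 0.03
    spatial_rho: float = 0.6
    spatial_sd: float = 0.5     # logit-scale sd of the spatial residual
    iid_sd: float = 0.3         # logit-scale sd of the white residual
    global_factor_sd: tuple[float, ...] = (1.5, 1.0)
    covariate_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "medium": {"A": 0.0, "B": -0.12},
            "growth": {"adherent": 0.0, "suspension": -0.03},
            "msi": {"MSS": 0.0, "MSI": -0.02},
        })
    cancer_type: str = "CT1"
    n_genes: int = 300
    n_genes_on_chrom: int = 40
    expr_noise_sd: float = 0.35  # residual sd of a linked gene's expression
    seed: int = 0


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_pharmaco_cohort`."""

    cohort: MethylationCohort
    manifest: ProbeManifest
    genes: pd.DataFrame
    truth: dict[str, Any]


def _validate(config: SimulationConfig) -> None:
    total = sum(r.n_region_probes for r in config.planted_regions)
    if total > config.n_probes:
        raise ValueError(
            f"planted regions need {total} probes but only "
            f"{config.n_probes} are simulated")
    if config.n_probes > config.span_bp:
        raise ValueError("span_bp must be at least n_probes")
    for r in config.planted_regions:
        if r.case not in CASE_SIGNS:
            raise ValueError(f"unknown case {r.case}")
        want_sign, _ = CASE_SIGNS[r.case]
        if r.auc_effect != 0 and np.sign(r.auc_effect) != want_sign:
            raise ValueError(
                f"case {r.case} implies sign({want_sign}) for auc_effect, "
                f"got {r.auc_effect}")
        n_shift = int(round(r.fraction_shifted * config.n_samples))
        if r.auc_effect != 0 and n_shift < 4:
            raise ValueError(
                "fraction_shifted * n_samples must be >= 4 for a "
                f"detectable region (got {n_shift})")
        if not 1 <= r.n_region_probes:
            raise ValueError("n_region_probes must be >= 1")


def _probe_layout(
    rng: np.random.Generator, config: SimulationConfig,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Clustered probe positions and the planted-region index arrays.

    Probes come in runs (clusters) whose sizes are 1 + Poisson draws around
    ``cluster_size_mean``; each planted region occupies a dedicated cluster
    of exactly its probe count, and clusters are separated by at least
    ``min_cluster_gap`` bp so regions cannot bleed into their neighbours.
    Returns 1-based positions (ascending) and, per planted region, the
    probe indices it covers.
    """
    planted_sizes = [r.n_region_probes for r in config.planted_regions]
    remaining = config.n_probes - sum(planted_sizes)
    base: list[int] = []
    while remaining > 0:
        s = int(min(remaining,
                    1 + rng.poisson(max(config.cluster_size_mean - 1.0, 0))))
        base.append(s)
        remaining -= s
    k = len(planted_sizes)
    slots = [(i + 1) * (len(base) + 1) // (k + 1) for i in range(k)]
    sizes: list[int] = []
    planted_cluster: dict[int, int] = {}  # cluster index -> region index
    next_region = 0
    for i in range(len(base) + 1):
        while next_region < k and slots[next_region] == i:
            planted_cluster[len(sizes)] = next_region
            sizes.append(planted_sizes[next_region])
            next_region += 1
        if i < len(base):
            sizes.append(base[i])

    lo, hi = config.within_cluster_gap
    gaps_within = [rng.integers(lo, hi + 1, size=max(s - 1, 0))
                   for s in sizes]
    total_extent = int(sum(int(g.sum()) for g in gaps_within))
    budget = (config.span_bp - total_extent
              - len(sizes) * config.min_cluster_gap)
    extra = max(1, budget // max(len(sizes), 1))

    positions: list[int] = []
    region_idx: list[np.ndarray | None] = [None] * k
    cur = 0
    for c, size in enumerate(sizes):
        cur += config.min_cluster_gap + int(rng.integers(0, extra))
        cluster_pos = cur + np.concatenate(
            [[0], np.cumsum(gaps_within[c])]).astype(np.int64)
        if c in planted_cluster:
            region_idx[planted_cluster[c]] = np.arange(
                len(positions), len(positions) + size)
        positions.extend(int(p) for p in cluster_pos)
        cur = int(cluster_pos[-1])
    return np.asarray(positions, dtype=np.int64), [r for r in region_idx]


def _spatial_noise(rng: np.random.Generator, positions: np.ndarray,
                   rho: float, sd: float, n_samples: int) -> np.ndarray:
    """Continuous AR(1) residual along the chromosome, samples x probes."""
    n = positions.size
    e = np.empty((n_samples, n))
    e[:, 0] = rng.normal(0.0, sd, size=n_samples)
    if rho <= 0.0:
        e[:, 1:] = rng.normal(0.0, sd, size=(n_samples, n - 1))
        return e
    gaps = np.diff(positions).astype(float)
    phis = rho ** (gaps / SPATIAL_REF_BP)
    innov = rng.normal(0.0, 1.0, size=(n_samples, n - 1))
    for j in range(1, n):
        phi = phis[j - 1]
        e[:, j] = phi * e[:, j - 1] + sd * np.sqrt(1.0 - phi * phi) * innov[:, j - 1]
    return e


def _draw_covariates(rng: np.random.Generator,
                     config: SimulationConfig,
                     samples: list[str]) -> pd.DataFrame:
    probs = {"medium": [0.5, 0.5], "growth": [0.7, 0.3], "msi": [0.8, 0.2]}
    cov = {"cancer_type": [config.cancer_type] * len(samples)}
    for name, effects in config.covariate_effects.items():
        levels = sorted(effects)
        p = probs.get(name, [1.0 / len(levels)] * len(levels))
        p = (p + [0.0] * len(levels))[: len(levels)]
        p = np.asarray(p) / np.sum(p)
        cov[name] = rng.choice(levels, size=len(samples), p=p)
    return pd.DataFrame(cov, index=pd.Index(samples, name="sample"))


def _covariate_offsets(cov: pd.DataFrame,
                       effects: Mapping[str, Mapping[str, float]]) -> np.ndarray:
    off = np.zeros(len(cov))
    for name, levels in effects.items():
        off += cov[name].map(levels).to_numpy(dtype=float)
    return off


def simulate_pharmaco_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate a drug-screened methylation cohort with planted dDMRs.

    Returns the cohort (beta, covariates, AUC, expression), the probe
    manifest, the gene annotation table and a JSON-serializable truth record
    holding everything needed to audit recovery or to regenerate a matched
    tumour cohort.
    """
    _validate(config)
    rng = np.random.default_rng(config.seed)

    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    probe_ids = [f"cg{i:06d}" for i in range(config.n_probes)]
    positions, region_idx = _probe_layout(rng, config)

    # Baseline probe means: bimodal around the two modes with logit jitter.
    high = rng.random(config.n_probes) < 0.5
    base_logit = np.where(high, logit(_HIGH_MODE), logit(_LOW_MODE))
    base_logit = base_logit + rng.normal(0.0, 0.3, size=config.n_probes)
    for idx in region_idx:
        # planted probes start in the high mode; shifted samples flip low
        base_logit[idx] = logit(_HIGH_MODE) + rng.normal(0.0, 0.1,
                                                         size=idx.size)

    # Latent global methylation factors (what PC correction removes).
    n_fac = len(config.global_factor_sd)
    loadings = np.column_stack([
        rng.normal(0.0, sd, size=config.n_probes)
        for sd in config.global_factor_sd]) if n_fac else np.zeros(
            (config.n_probes, 0))
    factors = rng.normal(0.0, 1.0, size=(config.n_samples, n_fac))

    logit_beta = (base_logit[None, :]
                  + factors @ loadings.T
                  + _spatial_noise(rng, positions, config.spatial_rho,
                                   config.spatial_sd, config.n_samples)
                  + rng.normal(0.0, config.iid_sd,
                               size=(config.n_samples, config.n_probes)))

    shift_amount = logit(_LOW_MODE) - logit(_HIGH_MODE)
    shifted_by_region: list[np.ndarray] = []
    for region, idx in zip(config.planted_regions, region_idx):
        n_shift = int(round(region.fraction_shifted * config.n_samples))
        who = np.sort(rng.choice(config.n_samples, size=n_shift,
                                 replace=False))
        logit_beta[np.ix_(who, idx)] += shift_amount
        shifted_by_region.append(who)

    beta = pd.DataFrame(expit(logit_beta), index=pd.Index(samples,
                                                          name="sample"),
                        columns=probe_ids)

    covariates = _draw_covariates(rng, config, samples)
    cov_offset = _covariate_offsets(covariates, config.covariate_effects)

    drugs = [f"drug_{i + 1}" for i in range(config.n_drugs)]
    auc = np.tile(config.auc_baseline + cov_offset[:, None],
                  (1, config.n_drugs))
    auc += rng.normal(0.0, config.noise_sd_auc,
                      size=(config.n_samples, config.n_drugs))
    for region, idx in zip(config.planted_regions, region_idx):
        if region.drug not in drugs:
            raise ValueError(f"planted drug {region.drug!r} not among "
                             f"the {config.n_drugs} simulated drugs")
        region_mean = beta.iloc[:, idx].mean(axis=1).to_numpy()
        auc[:, drugs.index(region.drug)] += region.auc_effect * region_mean
    auc = np.clip(auc, 1e-6, 1.0)
    auc = pd.DataFrame(auc, index=beta.index, columns=drugs)

    manifest = ProbeManifest(pd.DataFrame({
        "probe_id": probe_ids,
        "chromosome": config.chromosome,
        "position": positions,
        "gene": "",
        "feature": "Intergenic",
        "cgi": False, "dhs": False, "enhancer": False,
        "cross_reactive": False,
    }))

    genes, gene_means, expr = _simulate_expression(
        rng, config, beta, manifest, region_idx, shifted_by_region)

    truth_regions = []
    for region, idx, who in zip(config.planted_regions, region_idx,
                                shifted_by_region):
        pos0 = positions[idx] - 1
        _, expr_sign = CASE_SIGNS[region.case]
        truth_regions.append({
            "chrom": config.chromosome,
            "start": int(pos0[0]),
            "end": int(pos0[-1]) + 1,
            "probe_ids": [probe_ids[j] for j in idx],
            "probe_indices": [int(j) for j in idx],
            "shifted_samples": [samples[s] for s in who],
            "fraction_shifted": region.fraction_shifted,
            "auc_effect": region.auc_effect,
            "expr_slope": expr_sign * region.expr_effect,
            "case": region.case,
            "linked_gene": region.linked_gene,
            "drug": region.drug,
        })

    truth = {
        "seed": config.seed,
        "chromosome": config.chromosome,
        "cancer_type": config.cancer_type,
        "positions": [int(p) for p in positions],
        "probe_ids": probe_ids,
        "probe_baseline_logit": [float(v) for v in base_logit],
        "factor_loadings": [[float(v) for v in row] for row in loadings],
        "regions": truth_regions,
        "genes": {g: float(m) for g, m in gene_means.items()},
        "params": {
            "spatial_rho": config.spatial_rho,
            "spatial_sd": config.spatial_sd,
            "iid_sd": config.iid_sd,
            "expr_noise_sd": config.expr_noise_sd,
            "global_factor_sd": list(config.global_factor_sd),
        },
    }

    cohort = MethylationCohort(beta=beta, covariates=covariates, auc=auc,
                               expression=expr, cohort_tag="cell_lines")
    cohort.validate()
    return SimulatedCohort(cohort=cohort, manifest=manifest, genes=genes,
                           truth=truth)


def _simulate_expression(rng, config, beta, manifest, region_idx,
                         shifted_by_region):
    """Gene table + expression matrix; linked genes respond to region beta."""
    linked = [r.linked_gene for r in config.planted_regions]
    n_decoy_chrom = max(0, config.n_genes_on_chrom - len(linked))
    n_far = max(0, config.n_genes - len(linked) - n_decoy_chrom)

    names, chroms, tss, strands = [], [], [], []
    for region, idx in zip(config.planted_regions, region_idx):
        end0 = int(manifest.df["pos0"].iloc[idx[-1]]) + 1
        names.append(region.linked_gene)
        chroms.append(config.chromosome)
        tss.append(end0 + 500 + 1)  # 1-based TSS just downstream of region
        strands.append("+")
    decoy_tss = np.sort(rng.choice(10 * config.span_bp, size=n_decoy_chrom,
                                   replace=False)) + 1
    for i in range(n_decoy_chrom):
        names.append(f"GENE_C{i:04d}")
        chroms.append(config.chromosome)
        tss.append(int(decoy_tss[i]))
        strands.append("+" if rng.random() < 0.5 else "-")
    far_tss = np.sort(rng.choice(10 * config.span_bp, size=n_far,
                                 replace=False)) + 1
    for i in range(n_far):
        names.append(f"GENE_F{i:04d}")
        chroms.append("chr_null")
        tss.append(int(far_tss[i]))
        strands.append("+" if rng.random() < 0.5 else "-")

    genes = pd.DataFrame({"gene": names, "chromosome": chroms, "tss": tss,
                          "strand": strands})

    gene_means = {g: float(m) for g, m in
                  zip(names, rng.normal(8.0, 1.0, size=len(names)))}
    expr = rng.normal(0.0, 1.0, size=(config.n_samples, len(names)))
    expr += np.array([gene_means[g] for g in names])[None, :]
    for region, idx in zip(config.planted_regions, region_idx):
        _, expr_sign = CASE_SIGNS[region.case]
        b = expr_sign * region.expr_effect
        region_mean = beta.iloc[:, idx].mean(axis=1).to_numpy()
        col = names.index(region.linked_gene)
        expr[:, col] = (gene_means[region.linked_gene]
                        + b * region_mean
                        + rng.normal(0.0, config.expr_noise_sd,
                                     size=config.n_samples))
    expr = pd.DataFrame(expr, index=beta.index, columns=names)
    return genes, gene_means, expr


def simulate_null_scan(config: SimulationConfig) -> SimulatedCohort:
    """A cohort with no planted regions: AUC is independent of all beta."""
    if config.planted_regions:
        raise ValueError("null scan config must not contain planted regions")
    return simulate_pharmaco_cohort(config)


def simulate_tumour_cohort(
    truth: Mapping[str, Any],
    n_tumours: int = 60,
    concordant: bool = True,
    seed: int = 0,
) -> tuple[MethylationCohort, pd.DataFrame]:
    """Independent 'tumour' samples sharing the discovery cohort's truth.

    Methylation is regenerated from the truth record's probe baselines and
    spatial parameters; planted regions are again flipped in a
    ``fraction_shifted`` subset.  Linked-gene expression keeps the discovery
    slope sign when ``concordant`` and is flipped otherwise.  No AUC table is
    produced (tumours are not drug-screened).  Returns the cohort and the
    gene annotation table.
    """
    if n_tumours < 8:
        warnings.warn(
            f"tumour cohort of n={n_tumours} is below the minimum cohort "
            "size of 8 and would be excluded from replication",
            UserWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    params = truth["params"]
    positions = np.asarray(truth["positions"], dtype=np.int64)
    probe_ids = list(truth["probe_ids"])
    base_logit = np.asarray(truth["probe_baseline_logit"], dtype=float)
    loadings = np.asarray(truth["factor_loadings"], dtype=float)
    if loadings.size == 0:
        loadings = loadings.reshape(len(probe_ids), 0)
    n_fac = loadings.shape[1]

    samples = [f"T{i:04d}" for i in range(n_tumours)]
    factors = rng.normal(0.0, 1.0, size=(n_tumours, n_fac))
    logit_beta = (base_logit[None, :]
                  + factors @ loadings.T
                  + _spatial_noise(rng, positions, params["spatial_rho"],
                                   params["spatial_sd"], n_tumours)
                  + rng.normal(0.0, params["iid_sd"],
                               size=(n_tumours, len(probe_ids))))

    shift_amount = logit(_LOW_MODE) - logit(_HIGH_MODE)
    region_means_needed = []
    for region in truth["regions"]:
        idx = np.asarray(region["probe_indices"], dtype=int)
        n_shift = max(1, int(round(region["fraction_shifted"] * n_tumours)))
        who = np.sort(rng.choice(n_tumours, size=n_shift, replace=False))
        logit_beta[np.ix_(who, idx)] += shift_amount
        region_means_needed.append(idx)

    beta = pd.DataFrame(expit(logit_beta),
                        index=pd.Index(samples, name="sample"),
                        columns=probe_ids)

    gene_means = truth["genes"]
    names = list(gene_means)
    expr = rng.normal(0.0, 1.0, size=(n_tumours, len(names)))
    expr += np.array([gene_means[g] for g in names])[None, :]
    for region, idx in zip(truth["regions"], region_means_needed):
        b = region["expr_slope"] if concordant else -region["expr_slope"]
        region_mean = beta.iloc[:, idx].mean(axis=1).to_numpy()
        col = names.index(region["linked_gene"])
        expr[:, col] = (gene_means[region["linked_gene"]]
                        + b * region_mean
                        + rng.normal(0.0, params["expr_noise_sd"],
                                     size=n_tumours))
    expr = pd.DataFrame(expr, index=beta.index, columns=names)

    covariates = pd.DataFrame(
        {"cancer_type": [truth["cancer_type"]] * n_tumours},
        index=beta.index)
    cohort = MethylationCohort(beta=beta, covariates=covariates, auc=None,
                               expression=expr, cohort_tag="tumours")
    cohort.validate()
    genes = pd.DataFrame({"gene": names})
    return cohort, genes


def make_toy_network(
    biomarker_gene: str,
    drug_targets: Sequence[str],
    path_length: int = 5,
    decoys: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Directed edge list with exactly one forward path of ``path_length``
    hops from the biomarker to each drug target, plus dead-end decoys.

    Decoy nodes hang off the biomarker in a chain that never reaches a
    target, so they cannot create shorter alternative paths.
    """
    if path_length < 1:
        raise ValueError("path_length must be >= 1")
    edges: list[tuple[str, str]] = []
    for target in drug_targets:
        chain = ([biomarker_gene]
                 + [f"{target}_step{i}" for i in range(1, path_length)]
                 + [target])
        edges.extend(zip(chain[:-1], chain[1:]))
    if decoys:
        decoy_nodes = [f"decoy_{i}" for i in range(decoys)]
        edges.append((biomarker_gene, decoy_nodes[0]))
        edges.extend(zip(decoy_nodes[:-1], decoy_nodes[1:]))
    df = pd.DataFrame(edges, columns=["source", "target"])
    df["weight"] = 1.0
    return df
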
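"""Simulation-based calibration checks of the discovery pipeline.

These harnesses run the full pipeline on generated cohorts with known
truth and summarise its operating characteristics: the false-call rate of
the region caller under a global null, uniformity of the per-CpG p-values,
recovery of a planted region at the study's effect size, and the
empirical-FDR behaviour of the expression-linking stage with and without a
planted regulatory link.

Note on the uniformity check: p-values within one scan share the realized
response vector and residual-variance estimate, so a KS test pooled over
all probes is over-dispersed even though each p is marginally exact.  The
harness therefore thins to a few well-separated islands per drug, which
makes the pooled draws approximately independent and the KS test
calibrated.
"""

from __future__ import annotations

import warnings
import numpy as np
from scipy import stats

from pharmacoepimap import dmr_calling as dc
from pharmacoepimap import expression_linking as el
from pharmacoepimap import synthetic_data as sd
from pharmacoepimap import tumour_generalisation as tg


def _spawn_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def null_scan_calibration(n_scans: int = 100, seed: int = 0,
                          harvest_per_drug: int = 10) -> dict:
    """Run ``n_scans`` no-effect cohorts through the full caller.

    Returns the number of scans that produced any dDMR at the adj. p <
    1e-6 default, and a KS uniformity p-value for per-CpG raw p-values
    harvested sparsely (one probe from every few islands per drug).
    """
    fp_scans = 0
    harvested: list[np.ndarray] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in _spawn_seeds(seed, n_scans):
            sim = sd.simulate_null_scan(sd.SimulationConfig(seed=s))
            ddmrs, _ = dc.call_ddmrs(sim.cohort, sim.manifest)
            fp_scans += len(ddmrs) > 0
            pcs = dc.methylation_pcs(sim.cohort.beta)
            cov = sim.cohort.covariates.drop(columns=["cancer_type"])
            n_drugs = sim.cohort.auc.shape[1]
            for k, drug in enumerate(sim.cohort.auc.columns):
                assoc = dc.fit_cpg_models(sim.cohort.beta,
                                          sim.cohort.auc[drug], cov, pcs)
                assoc = assoc.join(sim.manifest.df[["pos0"]])
                assoc = assoc.sort_values("pos0")
                pos = assoc["pos0"].to_numpy()
                island_starts = np.flatnonzero(
                    np.r_[True, np.diff(pos) > 1000])
                pick = island_starts[k::n_drugs * 2][:harvest_per_drug]
                harvested.append(assoc["p_raw"].to_numpy()[pick])
    pooled = np.concatenate(harvested)
    return {
        "n_scans": n_scans,
        "scans_with_false_ddmr": int(fp_scans),
        "ks_uniformity_p": float(stats.kstest(pooled, "uniform").pvalue),
        "n_harvested_p": int(pooled.size),
    }


def planted_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """Recovery of an 8-probe planted region (effect -0.15 AUC per beta
    unit, 10/40 samples shifted) with at least 1 bp of truth overlap."""
    detected = 0
    negative_signs = 0
    effects: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in _spawn_seeds(seed, n_seeds):
            cfg = sd.SimulationConfig(
                planted_regions=[sd.PlantedRegion()], seed=s)
            sim = sd.simulate_pharmaco_cohort(cfg)
            tr = sim.truth["regions"][0]
            ddmrs, _ = dc.call_ddmrs(sim.cohort, sim.manifest)
            hits = [d for d in ddmrs if d.drug == tr["drug"]
                    and d.start < tr["end"] and d.end > tr["start"]]
            if hits:
                detected += 1
                negative_signs += all(d.effect_size < 0 for d in hits)
                effects.append(float(np.mean([d.effect_size
                                              for d in hits])))
    return {
        "n_seeds": n_seeds,
        "n_detected": detected,
        "n_detected_negative_effect": negative_signs,
        "mean_effect_size": float(np.mean(effects)) if effects else
        float("nan"),
    }


def _island_index_arrays(manifest, merge_dist: int = 1000):
    pos = manifest.df["pos0"].to_numpy()
    order = np.argsort(pos)
    breaks = np.flatnonzero(np.diff(pos[order]) > merge_dist)
    return np.split(order, breaks + 1)


def no_link_false_discoveries(
    n_seeds: int = 100,
    n_pairs: int = 500,
    n_permutations: int = 2000,
    seed: int = 0,
) -> dict:
    """Expression linking on cohorts where expression is independent of
    methylation: counts seeds with any link at emp. adj. p < 0.001."""
    seeds_with_hit = 0
    total_sig = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in _spawn_seeds(seed, n_seeds):
            cfg = sd.SimulationConfig(n_samples=60, seed=s)
            sim = sd.simulate_null_scan(cfg)
            rng = np.random.default_rng(s)
            islands = _island_index_arrays(sim.manifest)
            genes = list(sim.cohort.expression.columns)
            links: list[el.RegulatoryLink] = []
            i = 0
            while len(links) < n_pairs:
                island = islands[i % len(islands)]
                i += 1
                probes = [sim.manifest.df["probe_id"].iloc[j]
                          for j in island]
                rmb = sim.cohort.beta[probes].mean(axis=1)
                groups = el.define_mu_groups(rmb)
                if groups is None:
                    continue
                m, u = groups
                for gene in rng.choice(genes, size=min(
                        8, n_pairs - len(links)), replace=False):
                    p, direction = el.mwu_link_test(
                        sim.cohort.expression[gene], m, u)
                    links.append(el.RegulatoryLink(
                        dmr_id=f"island{i}", gene=str(gene),
                        mode="distal", direction=direction, mwu_p=p,
                        m_samples=m, u_samples=u))
            links = el.empirical_adjust(links, sim.cohort.expression,
                                        n_permutations=n_permutations,
                                        seed=s)
            n_sig = sum(lk.significant for lk in links)
            total_sig += n_sig
            seeds_with_hit += n_sig > 0
    return {
        "n_seeds": n_seeds,
        "n_pairs_per_seed": n_pairs,
        "seeds_with_false_link": int(seeds_with_hit),
        "total_false_links": int(total_sig),
    }


def planted_link_pipeline(
    n_seeds: int = 20,
    n_permutations: int = 2000,
    seed: int = 0,
) -> dict:
    """Full discovery -> linking -> tumour replication on Case-1 planted
    cohorts (60 lines, 30% shifted), with both a concordant and a
    sign-flipped tumour cohort per seed."""
    n_case1 = n_tg = n_disc_reject = n_complete = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in _spawn_seeds(seed, n_seeds):
            cfg = sd.SimulationConfig(
                n_samples=60,
                planted_regions=[sd.PlantedRegion(fraction_shifted=0.3)],
                seed=s)
            sim = sd.simulate_pharmaco_cohort(cfg)
            tr = sim.truth["regions"][0]
            ddmrs, _ = dc.call_ddmrs(sim.cohort, sim.manifest)
            hits = [d for d in ddmrs if d.drug == tr["drug"]
                    and d.start < tr["end"] and d.end > tr["start"]]
            if not hits:
                continue
            links = el.link_ddmrs(hits, sim.cohort, sim.genes,
                                  mode="promoter",
                                  n_permutations=n_permutations, seed=s)
            sig = [lk for lk in links if lk.significant]
            planted = [lk for lk in sig if lk.gene == tr["linked_gene"]]
            if not planted:
                continue
            n_complete += 1
            n_case1 += planted[0].case == 1

            tum, _ = sd.simulate_tumour_cohort(sim.truth, n_tumours=60,
                                               concordant=True,
                                               seed=s + 1)
            rep = tg.replicate_links(sig, tum,
                                     n_permutations=n_permutations,
                                     seed=s)
            n_tg += any(lk.gene == tr["linked_gene"] for lk in rep)

            disc, _ = sd.simulate_tumour_cohort(sim.truth, n_tumours=60,
                                                concordant=False,
                                                seed=s + 2)
            anti = tg.replicate_links(sig, disc,
                                      n_permutations=n_permutations,
                                      seed=s)
            n_disc_reject += not any(lk.gene == tr["linked_gene"]
                                     for lk in anti)
    return {
        "n_seeds": n_seeds,
        "n_link_recovered": n_complete,
        "n_case1": n_case1,
        "n_tgddmr_concordant": n_tg,
        "n_rejected_discordant": n_disc_reject,
    }
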
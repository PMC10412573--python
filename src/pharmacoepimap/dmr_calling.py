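"""Drug differentially methylated region (dDMR) calling.

Two-step scan, run separately per cancer type and drug:

1. **Per-CpG model.** For each probe, ordinary least squares of the drug's
   AUC ``y`` on the probe beta-value ``m`` with the categorical screen
   covariates (medium, growth, MSI) and the first two methylation principal
   components::

       y = b0 + b1*m + b2*c1 + b3*c2 + b4*c3 + b5*pc1 + b6*pc2

   The per-probe p-value is the two-sided t-test on ``b1``.

2. **Region extraction.** Neighbouring probes carry correlated evidence, so
   raw p-values are combined with the Stouffer-Liptak-Kechris (SLK)
   correction under a distance-binned autocorrelation (ACF) estimate, peaks
   are extracted and merged within ``merge_dist`` bases, the region p-value
   is Sidak-adjusted for the effective number of region-sized tests, and
   surviving regions are post-filtered: every constituent probe must pass
   the raw-p cutoff and at least ``min_aberrant`` samples must sit in each
   methylation extreme (region-mean beta < 0.3 and > 0.7).

The per-probe association results are carried as a DataFrame (one row per
CpG: ``probe_id, beta1, se, t_stat, p_raw, n_used, intercept`` plus one
``coef_*`` column per covariate/PC column) rather than one object per probe.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pharmacoepimap.cohort_data import DDMR, MethylationCohort, ProbeManifest

logger = logging.getLogger(__name__)

#: Numeric guards applied to p-values before normal-quantile transforms.
P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16


@dataclass
class DmrCallingConfig:
    """All thresholds of the dDMR scan (defaults are the published cutoffs
    where the study states them, and the documented region-dialect values
    otherwise)."""

    auc_thresh: float = 0.7        # responder definition: AUC <= 0.7
    min_responders: int = 3        # drug needs >= 3 responding lines
    min_lines: int = 16            # cancer type needs > 15 lines
    min_samples: int = 8           # per-probe complete pairs required
    n_components: int = 2          # methylation PCs in the model
    max_lag: int = 1000            # ACF range, bp
    bin_width: int = 250           # ACF bin width, bp
    min_pairs: int = 10            # pairs needed to trust an ACF bin
    window: int = 1000             # SLK neighbourhood, bp
    seed_p: float = 0.05           # region seed threshold on corrected p
    extend_p: float = 0.05         # region extension threshold
    merge_dist: int = 1000         # merge peaks within this many bases
    sidak_cut: float = 1e-6        # adj. p cutoff for calling a dDMR
    raw_p_cut: float = 0.01        # every region probe must beat this
    min_aberrant: int = 4          # lines required in each methylation mode


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

def eligible_drugs(auc_table: pd.DataFrame, auc_thresh: float = 0.7,
                   min_responders: int = 3) -> list[str]:
    """Drugs with at least ``min_responders`` samples at AUC <= ``auc_thresh``
    (partial response); the bound is inclusive."""
    n_resp = (auc_table <= auc_thresh).sum(axis=0)
    return [d for d in auc_table.columns if n_resp[d] >= min_responders]


def eligible_cancer_types(covariates: pd.DataFrame,
                          min_lines: int = 16) -> list[str]:
    """Cancer types with more than ``min_lines - 1`` characterised lines."""
    if len(covariates) == 0 or "cancer_type" not in covariates.columns:
        return []
    counts = covariates["cancer_type"].value_counts()
    return sorted(counts.index[counts >= min_lines])


# ---------------------------------------------------------------------------
# per-CpG models
# ---------------------------------------------------------------------------

def methylation_pcs(beta: pd.DataFrame,
                    n_components: int = 2) -> pd.DataFrame:
    """Per-sample scores on the top principal components of the beta matrix.

    The sample x probe matrix is column-centered (missing values imputed
    with the probe mean first) and decomposed by SVD; scores are the
    projections onto the top right-singular directions.  Sign convention:
    the largest-magnitude loading of each component is made positive, so the
    scores are reproducible across SVD implementations.
    """
    if beta.shape[0] < 3:
        raise ValueError("principal components need at least 3 samples")
    x = beta.to_numpy(dtype=float).copy()
    col_mean = np.nanmean(x, axis=0)
    nan_rows, nan_cols = np.where(np.isnan(x))
    x[nan_rows, nan_cols] = col_mean[nan_cols]
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, s.size)
    scores = np.zeros((x.shape[0], n_components))
    for comp in range(k):
        flip = np.sign(vt[comp, np.argmax(np.abs(vt[comp]))]) or 1.0
        scores[:, comp] = flip * u[:, comp] * s[comp]
    return pd.DataFrame(scores, index=beta.index,
                        columns=[f"pc{i + 1}" for i in range(n_components)])


def build_design(covariates: pd.DataFrame,
                 pcs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Covariate design block: one-hot categoricals (lexicographically first
    level as reference) plus PC scores; constant columns dropped."""
    blocks = []
    if covariates is not None and covariates.shape[1]:
        cov = covariates.astype(str)
        dummies = []
        for col in cov.columns:
            levels = sorted(cov[col].unique())
            for level in levels[1:]:
                dummies.append((cov[col] == level).astype(float)
                               .rename(f"{col}[{level}]"))
        if dummies:
            blocks.append(pd.concat(dummies, axis=1))
    if pcs is not None and pcs.shape[1]:
        blocks.append(pcs.astype(float))
    if not blocks:
        return pd.DataFrame(index=covariates.index
                            if covariates is not None else pcs.index)
    design = pd.concat(blocks, axis=1)
    keep = design.std(axis=0, ddof=0) > 0
    return design.loc[:, keep]


def _t_pvalue(t: np.ndarray, df: float | np.ndarray) -> np.ndarray:
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.clip(p, P_FLOOR, 1.0)


def fit_cpg_models(
    beta: pd.DataFrame,
    auc_for_drug: pd.Series,
    covariates: pd.DataFrame,
    pcs: pd.DataFrame | None = None,
    min_samples: int = 8,
) -> pd.DataFrame:
    """Per-probe OLS of one drug's AUC on beta plus covariates and PCs.

    Samples missing the AUC are dropped for the whole scan; samples missing
    a probe's beta are dropped for that probe only.  Probes with fewer than
    ``min_samples`` complete pairs, or whose beta is collinear with the
    covariate block, are skipped (and logged).  Returns one row per fitted
    probe; the two-sided p on the beta slope uses residual degrees of
    freedom.
    """
    y_all = auc_for_drug.astype(float)
    keep = y_all.notna()
    y = y_all[keep].to_numpy()
    b = beta.loc[keep.index[keep]]
    design = build_design(covariates.loc[b.index],
                          None if pcs is None else pcs.loc[b.index])
    z = np.column_stack([np.ones(len(b))] + (
        [design.to_numpy(dtype=float)] if design.shape[1] else []))
    z_names = ["intercept"] + [f"coef_{c}" for c in design.columns]

    bx = b.to_numpy(dtype=float)
    if not np.isnan(bx).any():
        out = _fit_complete_case(bx, y, z, z_names, list(b.columns),
                                 min_samples)
    else:
        out = _fit_per_probe(bx, y, z, z_names, list(b.columns), min_samples)
    return out


def _slope_stats(m_res: np.ndarray, y_res: np.ndarray, df: float):
    """Slope, se, t from FWL residuals (covariates projected out)."""
    mtm = np.sum(m_res * m_res, axis=0)
    slope = np.sum(m_res * y_res[:, None], axis=0) / mtm
    rss = np.sum(y_res * y_res) - slope ** 2 * mtm
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / mtm)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / se, np.sign(slope) * np.inf)
    return slope, se, t


def _fit_complete_case(bx, y, z, z_names, probes, min_samples):
    """Vectorised path when no beta values are missing: the covariate block
    is shared, so the slope comes from Frisch-Waugh-Lovell residuals and the
    remaining coefficients from one pseudoinverse solve."""
    n, k = z.shape
    rank_z = np.linalg.matrix_rank(z)
    df = n - rank_z - 1
    if n < min_samples or df < 1:
        logger.info("scan skipped: %d samples leave %d residual df", n, df)
        return _empty_assoc(z_names)
    z_pinv = np.linalg.pinv(z)
    proj = lambda a: a - z @ (z_pinv @ a)
    m_res = proj(bx)
    y_res = proj(y)
    mtm = np.sum(m_res * m_res, axis=0)
    scale = np.maximum(np.sum(bx * bx, axis=0), 1.0)
    ok = mtm > 1e-12 * scale
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.info("%d probes skipped (beta collinear with covariates)",
                    n_skipped)
    slope, se, t = _slope_stats(m_res[:, ok], y_res, df)
    cov_coefs = z_pinv @ (y[:, None] - bx[:, ok] * slope[None, :])
    out = pd.DataFrame({
        "probe_id": np.asarray(probes)[ok],
        "beta1": slope, "se": se, "t_stat": t,
        "p_raw": _t_pvalue(t, df), "n_used": n,
    })
    for j, name in enumerate(z_names):
        out[name] = cov_coefs[j]
    return out.set_index("probe_id", drop=False)


def _fit_per_probe(bx, y, z, z_names, probes, min_samples):
    rows = []
    for j, probe in enumerate(probes):
        m = bx[:, j]
        keep = ~np.isnan(m)
        n = int(keep.sum())
        if n < min_samples:
            continue
        zj, yj, mj = z[keep], y[keep], m[keep]
        const = zj.std(axis=0) == 0
        const[0] = False  # keep the intercept
        zj = zj[:, ~const]
        names = [nm for nm, c in zip(z_names, const) if not c]
        rank_z = np.linalg.matrix_rank(zj)
        df = n - rank_z - 1
        if df < 1:
            logger.info("probe %s skipped: no residual df", probe)
            continue
        z_pinv = np.linalg.pinv(zj)
        m_res = mj - zj @ (z_pinv @ mj)
        y_res = yj - zj @ (z_pinv @ yj)
        mtm = float(m_res @ m_res)
        if mtm <= 1e-12 * max(1.0, float(mj @ mj)):
            logger.info("probe %s skipped: beta collinear with covariates",
                        probe)
            continue
        slope, se, t = _slope_stats(m_res[:, None], y_res, df)
        coefs = z_pinv @ (yj - mj * slope[0])
        row = {"probe_id": probe, "beta1": slope[0], "se": se[0],
               "t_stat": t[0], "p_raw": _t_pvalue(t, df)[0], "n_used": n}
        row.update({nm: c for nm, c in zip(names, coefs)})
        rows.append(row)
    if not rows:
        return _empty_assoc(z_names)
    return pd.DataFrame(rows).set_index("probe_id", drop=False)


def _empty_assoc(z_names):
    cols = ["probe_id", "beta1", "se", "t_stat", "p_raw", "n_used"] + z_names
    return pd.DataFrame(columns=cols).set_index(
        pd.Index([], name="probe_id"))


# ---------------------------------------------------------------------------
# spatial correlation and p-value combination
# ---------------------------------------------------------------------------

@dataclass
class ACFEstimate:
    """Distance-binned autocorrelation of per-CpG association z-scores.

    ``bin_edges[i] = (lo, hi]`` in bp; ``correlations`` are clipped to
    [0, 0.99]; distance 0 maps to 1 and distances past the last bin to 0.
    """

    bin_edges: list[tuple[int, int]]
    correlations: np.ndarray
    pair_counts: np.ndarray

    def lookup(self, distances: np.ndarray) -> np.ndarray:
        d = np.asarray(distances, dtype=float)
        his = np.array([hi for _, hi in self.bin_edges], dtype=float)
        idx = np.searchsorted(his, d, side="left")
        vals = np.append(self.correlations, 0.0)
        out = vals[np.minimum(idx, len(self.correlations))]
        return np.where(d <= 0, 1.0, out)


def p_to_z(p_raw: np.ndarray, t_stat: np.ndarray) -> np.ndarray:
    """Signed association z-score: Phi^-1(1 - p/2) carrying the t sign."""
    p = np.clip(np.asarray(p_raw, dtype=float), P_FLOOR, P_CEIL)
    return stats.norm.isf(p / 2.0) * np.sign(t_stat)


def estimate_acf(
    associations: pd.DataFrame,
    positions: Mapping[str, np.ndarray] | None = None,
    max_lag: int = 1000,
    bin_width: int = 250,
    min_pairs: int = 10,
) -> ACFEstimate:
    """Estimate the ACF of association z-scores in distance bins.

    ``associations`` needs columns ``p_raw``, ``t_stat``, ``chromosome`` and
    ``pos0`` (or pass ``positions`` as chrom -> sorted 0-based positions in
    the same per-chromosome row order).  Pairs are pooled across
    chromosomes; a bin with fewer than ``min_pairs`` pairs inherits the
    previous bin's value (the first bin defaults to 0).  Correlations are
    clipped to [0, 0.99] — negative spatial correlation is treated as noise.
    """
    edges = [(lo, lo + bin_width) for lo in range(0, max_lag, bin_width)]
    n_bins = len(edges)
    pairs_a: list[list[np.ndarray]] = [[] for _ in range(n_bins)]
    pairs_b: list[list[np.ndarray]] = [[] for _ in range(n_bins)]

    for chrom, sub in associations.groupby("chromosome", sort=True):
        sub = sub.sort_values("pos0")
        pos = sub["pos0"].to_numpy(dtype=np.int64)
        z = p_to_z(sub["p_raw"].to_numpy(), sub["t_stat"].to_numpy())
        for k in range(1, len(pos)):
            d = pos[k:] - pos[:-k]
            mask = (d > 0) & (d <= max_lag)
            if not mask.any():
                break
            bins = np.minimum((d[mask] - 1) // bin_width, n_bins - 1)
            za, zb = z[:-k][mask], z[k:][mask]
            for b in np.unique(bins):
                sel = bins == b
                pairs_a[b].append(za[sel])
                pairs_b[b].append(zb[sel])

    corrs = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    any_pairs = False
    for b in range(n_bins):
        if pairs_a[b]:
            a = np.concatenate(pairs_a[b])
            c = np.concatenate(pairs_b[b])
            counts[b] = a.size
            any_pairs = True
            tol = 1e-10 * (np.abs(a).max() + 1.0)
            if counts[b] >= min_pairs and a.std() > tol and c.std() > tol:
                corrs[b] = np.corrcoef(a, c)[0, 1]
            elif counts[b] >= min_pairs:
                warnings.warn("degenerate (zero-variance) z-scores in ACF "
                              "bin; using 0", UserWarning, stacklevel=2)
                corrs[b] = 0.0
            else:
                corrs[b] = corrs[b - 1] if b > 0 else 0.0
        else:
            counts[b] = 0
            corrs[b] = corrs[b - 1] if b > 0 else 0.0
    if not any_pairs:
        warnings.warn("no probe pairs within the ACF range; all-zero ACF",
                      UserWarning, stacklevel=2)
    corrs = np.clip(corrs, 0.0, 0.99)
    return ACFEstimate(bin_edges=edges, correlations=corrs,
                       pair_counts=counts)


def stouffer_liptak(p_values: Sequence[float],
                    correlation_matrix: np.ndarray | None = None) -> float:
    """Combine p-values under known correlation (Stouffer-Liptak-Kechris).

    ``z_i = Phi^-1(1 - p_i)``; the combined statistic is
    ``sum(z) / sqrt(sum(C))`` where C is the correlation matrix, and the
    combined p is its upper normal tail.  The denominator is floored at the
    number of tests, which also guards non-positive-definite C.  With a
    single p (or identity C) this reduces to the input / classic Stouffer.
    """
    p = np.clip(np.asarray(p_values, dtype=float), P_FLOOR, P_CEIL)
    k = p.size
    if k == 0:
        raise ValueError("no p-values to combine")
    z = stats.norm.isf(p)
    if correlation_matrix is None:
        denom = float(k)
    else:
        c = np.asarray(correlation_matrix, dtype=float)
        if c.shape != (k, k):
            raise ValueError(f"correlation matrix shape {c.shape} does not "
                             f"match {k} p-values")
        denom = max(float(c.sum()), float(k))
    combined = z.sum() / np.sqrt(denom)
    return float(np.clip(stats.norm.sf(combined), P_FLOOR, 1.0))


def slk_correct_sites(
    p_raw: np.ndarray,
    positions: np.ndarray,
    acf: ACFEstimate,
    window: int = 1000,
) -> np.ndarray:
    """SLK-corrected p per site: combine raw p of all sites within
    ``window`` bp (self included) under ACF-derived correlations.

    ``positions`` must be sorted (one chromosome).  Isolated sites keep
    their raw p.
    """
    p = np.asarray(p_raw, dtype=float)
    pos = np.asarray(positions, dtype=np.int64)
    out = np.empty_like(p)
    lo = np.searchsorted(pos, pos - window, side="left")
    hi = np.searchsorted(pos, pos + window, side="right")
    for i in range(p.size):
        idx = np.arange(lo[i], hi[i])
        if idx.size == 1:
            out[i] = p[i]
            continue
        d = np.abs(pos[idx][:, None] - pos[idx][None, :])
        c = acf.lookup(d)
        np.fill_diagonal(c, 1.0)
        out[i] = stouffer_liptak(p[idx], c)
    return out


# ---------------------------------------------------------------------------
# region extraction and post-filters
# ---------------------------------------------------------------------------

def extract_regions(
    corrected_p: np.ndarray,
    positions: np.ndarray,
    seed_p: float = 0.05,
    extend_p: float = 0.05,
    merge_dist: int = 1000,
) -> list[np.ndarray]:
    """Candidate regions as arrays of site indices (sorted positions, one
    chromosome).

    Sites below ``extend_p`` are chained while successive sites are within
    ``merge_dist`` bp (this both extends peaks and merges nearby ones); a
    chain is kept only if it contains at least one seed below ``seed_p``.
    """
    p = np.asarray(corrected_p, dtype=float)
    pos = np.asarray(positions, dtype=np.int64)
    marked = np.flatnonzero(p < extend_p)
    regions: list[np.ndarray] = []
    chain: list[int] = []
    for i in marked:
        if chain and pos[i] - pos[chain[-1]] > merge_dist:
            regions.append(np.asarray(chain))
            chain = []
        chain.append(int(i))
    if chain:
        regions.append(np.asarray(chain))
    return [r for r in regions if (p[r] < seed_p).any()]


def sidak_adjust(region_p: float, n_region_probes: int,
                 n_total_probes: int) -> float:
    """Family-wise adjustment 1 - (1 - p)^n_eff with
    ``n_eff = max(1, n_total_probes // n_region_probes)`` — the number of
    region-sized windows the scanned probe set could tile."""
    if not 0.0 < region_p <= 1.0:
        region_p = min(max(region_p, P_FLOOR), 1.0)
    n_eff = max(1, int(n_total_probes) // int(n_region_probes))
    return float(-np.expm1(n_eff * np.log1p(-min(region_p, P_CEIL))))


def filter_and_score_regions(
    regions: Sequence[np.ndarray],
    associations: pd.DataFrame,
    beta: pd.DataFrame,
    acf: ACFEstimate,
    n_total_probes: int,
    chrom: str,
    drug: str,
    cancer_type: str,
    config: DmrCallingConfig | None = None,
) -> list[DDMR]:
    """Score candidate regions and apply the dDMR post-filters.

    ``associations`` must be the per-chromosome table sorted by ``pos0``
    with the candidate index arrays referring to its rows.  The region p is
    the SLK combination of the constituent raw p-values; regions are kept
    when the Sidak-adjusted p beats ``sidak_cut``, every probe beats
    ``raw_p_cut`` and both methylation extremes hold at least
    ``min_aberrant`` samples.
    """
    cfg = config or DmrCallingConfig()
    pos = associations["pos0"].to_numpy(dtype=np.int64)
    p_raw = associations["p_raw"].to_numpy(dtype=float)
    probe_ids = associations["probe_id"].to_numpy()
    out: list[DDMR] = []
    for idx in regions:
        d = np.abs(pos[idx][:, None] - pos[idx][None, :])
        c = acf.lookup(d)
        np.fill_diagonal(c, 1.0)
        region_p = stouffer_liptak(p_raw[idx], c)
        sidak_p = sidak_adjust(region_p, idx.size, n_total_probes)
        if sidak_p >= cfg.sidak_cut:
            continue
        if (p_raw[idx] >= cfg.raw_p_cut).any():
            continue
        probes = [str(probe_ids[i]) for i in idx]
        region_mean = beta[probes].mean(axis=1, skipna=True)
        n_hypo = int((region_mean < 0.3).sum())
        n_hyper = int((region_mean > 0.7).sum())
        if min(n_hypo, n_hyper) < cfg.min_aberrant:
            continue
        out.append(DDMR(
            chrom=chrom, start=int(pos[idx[0]]), end=int(pos[idx[-1]]) + 1,
            probe_ids=probes, drug=drug, cancer_type=cancer_type,
            region_p=region_p, sidak_p=sidak_p,
            effect_size=float(associations["beta1"].to_numpy()[idx].mean()),
            n_hypo=n_hypo, n_hyper=n_hyper))
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def call_ddmrs(
    cohort: MethylationCohort,
    manifest: ProbeManifest,
    config: DmrCallingConfig | None = None,
) -> tuple[list[DDMR], dict]:
    """Run the full dDMR scan over every eligible (cancer type, drug) pair.

    Per cancer type: subset samples, compute methylation PCs once on all
    retained probes, then per eligible drug fit per-CpG models, estimate the
    ACF, SLK-correct, extract and filter regions.  A failing scan is logged
    and skipped.  Deterministic given inputs.  Returns the called regions
    and a per-stage summary (counts per scan).
    """
    cfg = config or DmrCallingConfig()
    if cohort.auc is None:
        raise ValueError("dDMR calling needs an AUC table")
    summary: dict = {"scans": [], "n_ddmrs": 0}
    ddmrs: list[DDMR] = []

    for cancer_type in eligible_cancer_types(cohort.covariates,
                                             cfg.min_lines):
        sub = cohort.subset_samples(
            cohort.covariates.index[
                cohort.covariates["cancer_type"] == cancer_type])
        pcs = methylation_pcs(sub.beta, cfg.n_components)
        cov = sub.covariates.drop(columns=["cancer_type"], errors="ignore")
        for drug in eligible_drugs(sub.auc, cfg.auc_thresh,
                                   cfg.min_responders):
            try:
                found = _scan_one(sub, manifest, cov, pcs, drug,
                                  cancer_type, cfg)
            except Exception:
                logger.exception("scan failed for %s/%s; skipping",
                                 cancer_type, drug)
                continue
            ddmrs.extend(found)
            summary["scans"].append({"cancer_type": cancer_type,
                                     "drug": drug,
                                     "n_ddmrs": len(found)})
            logger.info("scan %s/%s: %d dDMRs", cancer_type, drug,
                        len(found))
    summary["n_ddmrs"] = len(ddmrs)
    return ddmrs, summary


def _scan_one(sub: MethylationCohort, manifest: ProbeManifest,
              covariates: pd.DataFrame, pcs: pd.DataFrame, drug: str,
              cancer_type: str, cfg: DmrCallingConfig) -> list[DDMR]:
    assoc = fit_cpg_models(sub.beta, sub.auc[drug], covariates, pcs,
                           cfg.min_samples)
    if assoc.empty:
        return []
    assoc = assoc.join(manifest.df[["chromosome", "pos0"]], how="left")
    acf = estimate_acf(assoc, max_lag=cfg.max_lag, bin_width=cfg.bin_width,
                       min_pairs=cfg.min_pairs)
    n_total = len(assoc)
    out: list[DDMR] = []
    for chrom, sub_assoc in assoc.groupby("chromosome", sort=True):
        sub_assoc = sub_assoc.sort_values("pos0")
        pos = sub_assoc["pos0"].to_numpy(dtype=np.int64)
        corrected = slk_correct_sites(sub_assoc["p_raw"].to_numpy(), pos,
                                      acf, cfg.window)
        regions = extract_regions(corrected, pos, cfg.seed_p, cfg.extend_p,
                                  cfg.merge_dist)
        out.extend(filter_and_score_regions(
            regions, sub_assoc, sub.beta, acf, n_total, str(chrom), drug,
            cancer_type, cfg))
    return out
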
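"""Link dDMR methylation to proximal gene expression.

For each called region the samples are split into the most methylated (M)
and least methylated (U) tails of the region-mean beta (20% tails, at least
4 samples each), candidate proximal genes are collected (promoter-overlap
or the 20 nearest TSS), and each (region, gene) pair is scored with a
two-sided Mann-Whitney U test of expression between M and U.  Raw-level
hits are then calibrated against an empirical null built by re-running the
same test on genes drawn at random from the cohort's transcriptome, and the
empirical p-values are step-up (Benjamini-Hochberg) adjusted across links.

Mechanism cases combine the sign of the region's drug-response effect with
the sign of the methylation-expression correlation:

====  ==================  ==========================
case  AUC-on-beta slope   beta-expression correlation
====  ==================  ==========================
1     negative            negative
2     negative            positive
3     positive            negative
4     positive            positive
====  ==================  ==========================
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from pharmacoepimap.cohort_data import DDMR, MethylationCohort
from pharmacoepimap.dmr_calling import fit_cpg_models, methylation_pcs

logger = logging.getLogger(__name__)

#: Group sizes at or below which the U test is computed by exhaustive
#: enumeration of label assignments (exact even under ties).
EXACT_MAX_GROUP = 8

UNTESTABLE = None  # sentinel returned by define_mu_groups


@dataclass
class RegulatoryLink:
    """A (dDMR, gene) pair with its methylation-expression evidence."""

    dmr_id: str
    gene: str
    mode: str                    # "promoter" or "distal"
    direction: int = 0           # sign of the meth-expression association
    mwu_p: float = np.nan
    emp_p: float = np.nan
    emp_adj_p: float = np.nan
    pearson_r: float = np.nan
    case: int = 0                # 1..4, 0 = unset
    cohort_tag: str = "cell_lines"
    significant: bool = False
    effect_size: float = np.nan  # the region's drug-response effect
    probe_ids: list[str] = field(default_factory=list)
    m_samples: list[str] = field(default_factory=list)
    u_samples: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# candidate genes
# ---------------------------------------------------------------------------

def promoter_interval(tss: int, strand: str,
                      promoter_window: tuple[int, int] = (2000, 200)
                      ) -> tuple[int, int]:
    """Strand-aware promoter window around a 1-based TSS, 0-based half-open."""
    up, down = promoter_window
    tss0 = tss - 1
    if strand == "-":
        return tss0 - down, tss0 + up + 1
    return tss0 - up, tss0 + down + 1


def candidate_gene_pairs(
    ddmr: DDMR,
    gene_annotation: pd.DataFrame,
    mode: str = "promoter",
    n_nearest: int = 20,
    promoter_window: tuple[int, int] = (2000, 200),
) -> list[str]:
    """Candidate proximal genes for one region.

    ``promoter`` mode returns genes whose strand-aware promoter window
    (default 2000 bp upstream to 200 bp downstream of the TSS) overlaps the
    region; ``distal`` mode returns the ``n_nearest`` genes by TSS distance,
    up to half taken from each side when available.
    """
    genes = gene_annotation[gene_annotation["chromosome"] == ddmr.chrom]
    if genes.empty:
        return []
    if mode == "promoter":
        hits = []
        for row in genes.itertuples(index=False):
            lo, hi = promoter_interval(int(row.tss), str(row.strand),
                                       promoter_window)
            if lo < ddmr.end and hi > ddmr.start:
                hits.append(str(row.gene))
        return sorted(hits)
    if mode != "distal":
        raise ValueError(f"unknown mode {mode!r}")

    tss0 = genes["tss"].to_numpy(dtype=np.int64) - 1
    names = genes["gene"].astype(str).to_numpy()
    inside = (tss0 >= ddmr.start) & (tss0 < ddmr.end)
    dist = np.where(inside, 0,
                    np.minimum(np.abs(tss0 - ddmr.start),
                               np.abs(tss0 - (ddmr.end - 1))))
    left = tss0 < ddmr.start
    right = tss0 >= ddmr.end
    order = np.lexsort((names, dist))
    per_side = n_nearest // 2
    chosen: list[int] = [i for i in order if inside[i]]
    left_sel = [i for i in order if left[i]][:per_side]
    right_sel = [i for i in order if right[i]][:per_side]
    chosen += left_sel + right_sel
    if len(chosen) < n_nearest:  # top up from whichever side has more
        rest = [i for i in order if i not in set(chosen)]
        chosen += rest[: n_nearest - len(chosen)]
    chosen = chosen[:n_nearest]
    return [names[i] for i in sorted(chosen,
                                     key=lambda i: (dist[i], names[i]))]


# ---------------------------------------------------------------------------
# M/U groups and the rank test
# ---------------------------------------------------------------------------

def define_mu_groups(
    region_mean_beta: pd.Series,
    fraction: float = 0.2,
    min_group: int = 4,
):
    """Split samples into the least (U) and most (M) methylated tails.

    Group size ``g = max(min_group, floor(fraction * n))``.  Returns
    ``(M_samples, U_samples)`` as lists, or the UNTESTABLE sentinel when
    ``2 g > n`` or the region-mean beta has zero variance.  Ties are broken
    by stable input order.
    """
    vals = region_mean_beta.to_numpy(dtype=float)
    n = vals.size
    g = max(min_group, int(np.floor(fraction * n)))
    if 2 * g > n or np.nanstd(vals) == 0 or np.isnan(vals).any():
        return UNTESTABLE
    order = np.argsort(vals, kind="stable")
    u = [str(region_mean_beta.index[i]) for i in order[:g]]
    m = [str(region_mean_beta.index[i]) for i in order[-g:]]
    return m, u


@lru_cache(maxsize=32)
def _combo_matrix(n: int, k: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)


def _rank_with_ties(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, axis=-1)


def _mwu_exact_batch(values: np.ndarray, n1: int) -> np.ndarray:
    """Exact two-sided MWU p for each row; first n1 columns are group M.

    Enumerates every assignment of n1 of the n labels to M and compares the
    M rank-sum against the permutation distribution — exact under ties.
    """
    values = np.atleast_2d(values)
    n = values.shape[1]
    ranks = _rank_with_ties(values)
    combos = _combo_matrix(n, n1)
    obs = ranks[:, :n1].sum(axis=1)
    out = np.empty((2, values.shape[0]))
    chunk = max(1, 2_000_000 // combos.shape[0])
    for start in range(0, values.shape[0], chunk):
        r = ranks[start:start + chunk]
        sums = r[:, combos].sum(axis=2)          # (rows, n_combos)
        o = obs[start:start + chunk, None]
        out[0, start:start + chunk] = (sums <= o + 1e-9).mean(axis=1)
        out[1, start:start + chunk] = (sums >= o - 1e-9).mean(axis=1)
    return out  # rows: p_less, p_greater


def _mwu_normal_batch(values: np.ndarray, n1: int) -> np.ndarray:
    """Tie-corrected normal-approximation one-sided p's, with continuity
    correction; first n1 columns are group M."""
    values = np.atleast_2d(values)
    n = values.shape[1]
    n2 = n - n1
    ranks = _rank_with_ties(values)
    r1 = ranks[:, :n1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie_term = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        _, counts = np.unique(values[i], return_counts=True)
        tie_term[i] = np.sum(counts ** 3 - counts)
    sigma2 = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1.0)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z_greater = (u1 - 0.5 - mu) / sigma
        z_less = (u1 + 0.5 - mu) / sigma
    p_less = np.where(sigma > 0, stats.norm.cdf(z_less), 1.0)
    p_greater = np.where(sigma > 0, stats.norm.sf(z_greater), 1.0)
    return np.vstack([np.minimum(p_less, 1.0), np.minimum(p_greater, 1.0)])


def _mwu_batch(values: np.ndarray, n1: int) -> np.ndarray:
    n2 = np.atleast_2d(values).shape[1] - n1
    if n1 <= EXACT_MAX_GROUP and n2 <= EXACT_MAX_GROUP:
        return _mwu_exact_batch(values, n1)
    return _mwu_normal_batch(values, n1)


def mwu_link_test(
    expression: pd.Series,
    m_samples: Sequence[str],
    u_samples: Sequence[str],
) -> tuple[float, int]:
    """Two-sided Mann-Whitney U test of expression between M and U groups.

    Returns ``(p, direction)`` with ``p = min(1, 2 * min(one-sided p's))``
    and ``direction = -1`` when the M (methylated) group expresses less,
    ``+1`` when more, 0 on a dead tie.  Exact by enumeration when both
    groups have at most 8 samples, tie-corrected normal approximation
    otherwise.
    """
    m_set, u_set = set(m_samples), set(u_samples)
    if m_set & u_set:
        raise ValueError(f"M and U groups overlap: {sorted(m_set & u_set)}")
    vals = np.concatenate([
        expression.loc[list(m_samples)].to_numpy(dtype=float),
        expression.loc[list(u_samples)].to_numpy(dtype=float)])
    p_less, p_greater = _mwu_batch(vals[None, :], len(m_samples))[:, 0]
    p = min(1.0, 2.0 * min(p_less, p_greater))
    if p_less < p_greater:
        direction = -1
    elif p_greater < p_less:
        direction = 1
    else:
        direction = 0
    return float(p), direction


# ---------------------------------------------------------------------------
# empirical null and case labels
# ---------------------------------------------------------------------------

def empirical_adjust(
    observed_links: Sequence[RegulatoryLink],
    expression_matrix: pd.DataFrame,
    n_permutations: int = 50_000,
    raw_cut: float = 0.05,
    emp_adj_cut: float = 0.001,
    seed: int = 0,
) -> list[RegulatoryLink]:
    """Attach empirical and BH-adjusted empirical p-values to links.

    Only links with ``mwu_p < raw_cut`` enter the permutation stage; the
    rest are flagged non-significant.  For each tested link the null is the
    two-sided U p-value of ``n_permutations`` genes drawn uniformly with
    replacement from the cohort transcriptome (excluding the linked gene),
    compared on the link's own M/U groups;
    ``emp_p = (1 + #{null <= observed}) / (n_permutations + 1)``.  The
    BH step-up adjustment runs across all tested links and a link is
    significant iff ``emp_adj_p < emp_adj_cut``.
    """
    rng = np.random.default_rng(seed)
    links = list(observed_links)
    tested = [lk for lk in links if np.isfinite(lk.mwu_p)
              and lk.mwu_p < raw_cut]
    for lk in links:
        lk.emp_p = np.nan
        lk.emp_adj_p = np.nan
        lk.significant = False

    all_genes = list(expression_matrix.columns)
    for lk in tested:
        pool = [g for g in all_genes if g != lk.gene]
        if len(pool) < 10:
            raise ValueError(
                f"only {len(pool)} candidate null genes; need >= 10")
        group_samples = list(lk.m_samples) + list(lk.u_samples)
        vals = expression_matrix.loc[group_samples, pool]\
            .to_numpy(dtype=float).T          # pool genes x samples
        p_less, p_greater = _mwu_batch(vals, len(lk.m_samples))
        pool_p = np.minimum(1.0, 2.0 * np.minimum(p_less, p_greater))
        draws = rng.integers(0, len(pool), size=n_permutations)
        null_p = pool_p[draws]
        lk.emp_p = float((1 + np.sum(null_p <= lk.mwu_p))
                         / (n_permutations + 1))

    if tested:
        emp = np.array([lk.emp_p for lk in tested])
        _, adj, _, _ = multipletests(emp, method="fdr_bh")
        for lk, a in zip(tested, adj):
            lk.emp_adj_p = float(a)
            lk.significant = bool(a < emp_adj_cut)
    return links


def classify_case(ddmr_effect_size: float, pearson_r: float) -> int:
    """Mechanism case from the signs of the drug-response effect and the
    methylation-expression correlation; 0 (unset) when either is zero or
    not finite."""
    if (not np.isfinite(ddmr_effect_size) or not np.isfinite(pearson_r)
            or ddmr_effect_size == 0 or pearson_r == 0):
        return 0
    if ddmr_effect_size < 0:
        return 1 if pearson_r < 0 else 2
    return 3 if pearson_r < 0 else 4


def expression_drug_model(
    expression_gene: pd.Series,
    auc_for_drug: pd.Series,
    covariates: pd.DataFrame,
    expression_pcs: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """OLS of AUC on one gene's expression with covariates and the first two
    expression PCs; returns (slope, two-sided p).  NaNs on failure."""
    x = pd.DataFrame({"expr": expression_gene.astype(float)})
    assoc = fit_cpg_models(x, auc_for_drug, covariates, expression_pcs,
                           min_samples=3)
    if assoc.empty:
        logger.info("expression-drug model skipped (rank deficiency or "
                    "too few samples)")
        return float("nan"), float("nan")
    row = assoc.iloc[0]
    return float(row["beta1"]), float(row["p_raw"])


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def region_mean_beta(cohort: MethylationCohort,
                     probe_ids: Sequence[str]) -> pd.Series:
    probes = [p for p in probe_ids if p in cohort.beta.columns]
    if not probes:
        raise KeyError(f"no region probes present in cohort beta: "
                       f"{list(probe_ids)[:3]}...")
    return cohort.beta[probes].mean(axis=1, skipna=True)


def link_ddmrs(
    ddmrs: Sequence[DDMR],
    cohort: MethylationCohort,
    gene_annotation: pd.DataFrame,
    mode: str = "promoter",
    fraction: float = 0.2,
    min_group: int = 4,
    n_nearest: int = 20,
    n_permutations: int = 50_000,
    raw_cut: float = 0.05,
    emp_adj_cut: float = 0.001,
    seed: int = 0,
) -> list[RegulatoryLink]:
    """Full linking stage: candidate genes, M/U rank tests, empirical FDR
    and mechanism case labels, for every region against the cohort's
    expression matrix."""
    if cohort.expression is None:
        raise ValueError("expression linking needs an expression matrix")
    links: list[RegulatoryLink] = []
    for ddmr in ddmrs:
        try:
            rmb = region_mean_beta(cohort, ddmr.probe_ids)
        except KeyError as exc:
            logger.warning("skipping %s: %s", ddmr.dmr_id, exc)
            continue
        groups = define_mu_groups(rmb, fraction, min_group)
        if groups is UNTESTABLE:
            logger.info("region %s untestable (degenerate M/U groups)",
                        ddmr.dmr_id)
            continue
        m_samples, u_samples = groups
        for gene in candidate_gene_pairs(ddmr, gene_annotation, mode,
                                         n_nearest):
            if gene not in cohort.expression.columns:
                logger.info("gene %s absent from expression matrix", gene)
                continue
            expr = cohort.expression[gene]
            p, direction = mwu_link_test(expr, m_samples, u_samples)
            ok = expr.notna() & rmb.notna()
            r = (stats.pearsonr(rmb[ok], expr[ok]).statistic
                 if ok.sum() >= 3 and expr[ok].std() > 0 else np.nan)
            links.append(RegulatoryLink(
                dmr_id=ddmr.dmr_id, gene=gene, mode=mode,
                direction=direction, mwu_p=p, pearson_r=r,
                cohort_tag=cohort.cohort_tag,
                effect_size=ddmr.effect_size,
                probe_ids=list(ddmr.probe_ids),
                m_samples=m_samples, u_samples=u_samples))
    links = empirical_adjust(links, cohort.expression, n_permutations,
                             raw_cut, emp_adj_cut, seed)
    for lk in links:
        if lk.significant:
            lk.case = classify_case(lk.effect_size, lk.pearson_r)
    return links


_LINK_COLUMNS = ["dmr_id", "gene", "mode", "direction", "mwu_p", "emp_p",
                 "emp_adj_p", "pearson_r", "case", "cohort_tag",
                 "significant", "effect_size", "probe_ids"]


def links_to_frame(links: Sequence[RegulatoryLink]) -> pd.DataFrame:
    rows = [{**{c: getattr(lk, c) for c in _LINK_COLUMNS[:-1]},
             "probe_ids": ",".join(lk.probe_ids)} for lk in links]
    return pd.DataFrame(rows, columns=_LINK_COLUMNS)


def write_links(links: Sequence[RegulatoryLink], path) -> None:
    links_to_frame(links).to_csv(path, sep="\t", index=False)


def read_links(path) -> list[RegulatoryLink]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(RegulatoryLink(
            dmr_id=row.dmr_id, gene=str(row.gene), mode=row.mode,
            direction=int(row.direction), mwu_p=float(row.mwu_p),
            emp_p=float(row.emp_p), emp_adj_p=float(row.emp_adj_p),
            pearson_r=float(row.pearson_r), case=int(row.case),
            cohort_tag=row.cohort_tag, significant=bool(row.significant),
            effect_size=float(row.effect_size),
            probe_ids=str(row.probe_ids).split(",")))
    return out
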
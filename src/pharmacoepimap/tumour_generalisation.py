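"""Replication of methylation-expression links in an independent tumour
cohort (tgdDMR nomination) and cross-cohort effect-size concordance.

The tumour stage re-derives the M/U tails from the tumour cohort's own
region-mean methylation, reruns the rank test and the permutation empirical
FDR, and nominates a region as tumour-generalisable (tgdDMR) only when the
link is significant in both cohorts with the same direction.  Tumour
cohorts below the minimum size are skipped entirely.  No drug data and no
covariate correction enter the tumour stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pharmacoepimap.cohort_data import MethylationCohort
from pharmacoepimap.expression_linking import (
    UNTESTABLE,
    RegulatoryLink,
    classify_case,
    define_mu_groups,
    empirical_adjust,
    mwu_link_test,
    region_mean_beta,
)

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceReport:
    """Cross-cohort agreement of paired effect sizes."""

    n_overlapping: int
    n_consistent_sign: int
    pearson_r: float   # NaN when fewer than 3 pairs
    p: float

    @property
    def consistency_fraction(self) -> float:
        if self.n_overlapping == 0:
            return float("nan")
        return self.n_consistent_sign / self.n_overlapping


def replicate_links(
    candidate_links: Sequence[RegulatoryLink],
    tumour_cohort: MethylationCohort,
    n_permutations: int = 50_000,
    raw_cut: float = 0.05,
    emp_adj_cut: float = 0.001,
    min_cohort: int = 8,
    fraction: float = 0.2,
    min_group: int = 4,
    seed: int = 0,
) -> list[RegulatoryLink]:
    """Retest significant cell-line links in a tumour cohort.

    Returns the tgdDMR links: tumour-cohort results for candidate pairs
    that are significant in the tumour cohort with the same direction as in
    the discovery cohort.  The returned links carry the tumour cohort tag,
    the tumour-side statistics and a case label recomputed from the
    discovery effect size and the tumour methylation-expression
    correlation.
    """
    if tumour_cohort.expression is None:
        raise ValueError("tumour replication needs an expression matrix")
    if tumour_cohort.n_samples < min_cohort:
        warnings.warn(
            f"tumour cohort has n={tumour_cohort.n_samples} < "
            f"{min_cohort} samples; skipping replication",
            UserWarning, stacklevel=2)
        return []

    candidates = [lk for lk in candidate_links if lk.significant]
    tumour_links: list[RegulatoryLink] = []
    source_dir: dict[tuple[str, str], int] = {}
    for lk in candidates:
        if lk.gene not in tumour_cohort.expression.columns:
            logger.warning("gene %s absent from tumour expression; link "
                           "%s skipped", lk.gene, lk.dmr_id)
            continue
        try:
            rmb = region_mean_beta(tumour_cohort, lk.probe_ids)
        except KeyError as exc:
            logger.warning("link %s skipped in tumours: %s", lk.dmr_id, exc)
            continue
        groups = define_mu_groups(rmb, fraction, min_group)
        if groups is UNTESTABLE:
            logger.info("link %s untestable in tumours", lk.dmr_id)
            continue
        m_samples, u_samples = groups
        expr = tumour_cohort.expression[lk.gene]
        p, direction = mwu_link_test(expr, m_samples, u_samples)
        ok = expr.notna() & rmb.notna()
        r = (stats.pearsonr(rmb[ok], expr[ok]).statistic
             if ok.sum() >= 3 and expr[ok].std() > 0 else np.nan)
        source_dir[(lk.dmr_id, lk.gene)] = lk.direction
        tumour_links.append(RegulatoryLink(
            dmr_id=lk.dmr_id, gene=lk.gene, mode=lk.mode,
            direction=direction, mwu_p=p, pearson_r=r,
            cohort_tag=tumour_cohort.cohort_tag,
            effect_size=lk.effect_size, probe_ids=list(lk.probe_ids),
            m_samples=m_samples, u_samples=u_samples))

    tumour_links = empirical_adjust(tumour_links,
                                    tumour_cohort.expression,
                                    n_permutations, raw_cut, emp_adj_cut,
                                    seed)
    tgddmrs = []
    for lk in tumour_links:
        same_dir = (lk.direction != 0
                    and lk.direction == source_dir[(lk.dmr_id, lk.gene)])
        if lk.significant and same_dir:
            lk.case = classify_case(lk.effect_size, lk.pearson_r)
            tgddmrs.append(lk)
    return tgddmrs


def effect_concordance(
    effects_a: Mapping[object, float] | pd.Series,
    effects_b: Mapping[object, float] | pd.Series,
) -> ConcordanceReport:
    """Sign consistency and correlation of effect sizes paired by key.

    Pairs with a missing side are dropped; zero effects are excluded from
    the sign count.  With fewer than 3 pairs the correlation is reported
    as NaN.
    """
    a = pd.Series(dict(effects_a)) if not isinstance(effects_a, pd.Series) \
        else effects_a
    b = pd.Series(dict(effects_b)) if not isinstance(effects_b, pd.Series) \
        else effects_b
    keys = a.index.intersection(b.index)
    a, b = a[keys].astype(float), b[keys].astype(float)
    ok = a.notna() & b.notna()
    a, b = a[ok], b[ok]
    n = len(a)
    nonzero = (a != 0) & (b != 0)
    n_consistent = int((np.sign(a[nonzero]) == np.sign(b[nonzero])).sum())
    if n >= 3 and a.std() > 0 and b.std() > 0:
        res = stats.pearsonr(a, b)
        r, p = float(res.statistic), float(res.pvalue)
    else:
        r, p = float("nan"), float("nan")
    return ConcordanceReport(n_overlapping=n, n_consistent_sign=n_consistent,
                             pearson_r=r, p=p)
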
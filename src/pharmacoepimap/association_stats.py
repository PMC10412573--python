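"""Association scans and enrichment statistics around called regions.

Covers the downstream evidence layers: binarised somatic-alteration
association with region methylation (univariate OLS + BH), one-sided
Fisher / hypergeometric enrichment of region annotation (open chromatin,
CpG islands, promoter features, drug classes) and a binomial test for
over-representation of a gene in a set of transcriptomic signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class AlterationMatrix:
    """Samples x binary alteration features with per-feature metadata
    (source gene and alteration type)."""

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        bad = ~self.values.isin([0, 1]).all(axis=0)
        if bad.any():
            raise ValueError(
                f"non-binary alteration columns: "
                f"{list(self.values.columns[bad])[:5]}")


_CNA_ALIASES = {"amp": "amp", "amplification": "amp",
                "del": "del", "deletion": "del"}


def binarize_alterations(
    mutation_calls: pd.DataFrame,
    cna_calls: pd.DataFrame | None = None,
    samples: Iterable[str] | None = None,
    min_altered: int = 4,
) -> AlterationMatrix:
    """One binary feature per gene-mutation and per gene-amplification /
    gene-deletion; features altered in fewer than ``min_altered`` samples
    are dropped.

    ``mutation_calls`` is long format with columns (sample, gene);
    ``cna_calls`` adds a ``status`` column (amplification/deletion).  The
    sample universe defaults to every sample seen in either table.
    """
    calls: list[tuple[str, str, str]] = []  # (sample, gene, kind)
    for row in mutation_calls.itertuples(index=False):
        calls.append((str(row.sample), str(row.gene), "mut"))
    if cna_calls is not None:
        for row in cna_calls.itertuples(index=False):
            kind = _CNA_ALIASES.get(str(row.status).lower())
            if kind is None:
                raise ValueError(f"unknown CNA status {row.status!r}")
            calls.append((str(row.sample), str(row.gene), kind))

    if samples is None:
        sample_index = pd.Index(sorted({s for s, _, _ in calls}),
                                name="sample")
    else:
        sample_index = pd.Index(list(samples), name="sample")

    features: dict[str, set[str]] = {}
    for sample, gene, kind in calls:
        features.setdefault(f"{gene}:{kind}", set()).add(sample)

    cols, meta = {}, []
    for feat in sorted(features):
        altered = features[feat] & set(sample_index)
        if len(altered) < min_altered:
            continue
        cols[feat] = sample_index.isin(altered).astype(int)
        gene, kind = feat.rsplit(":", 1)
        meta.append({"feature": feat, "gene": gene, "type": kind,
                     "n_altered": len(altered)})
    values = pd.DataFrame(cols, index=sample_index, dtype=int)
    metadata = pd.DataFrame(meta, columns=["feature", "gene", "type",
                                           "n_altered"])
    return AlterationMatrix(values=values, metadata=metadata)


def feature_association_scan(
    region_mean_beta_table: pd.DataFrame,
    feature_matrix: pd.DataFrame,
) -> pd.DataFrame:
    """Univariate OLS of each region's mean methylation on each feature.

    Features may be binary (alteration status) or continuous (e.g. CRISPR
    gene effects).  Returns a tidy table (feature, region, slope, p,
    bh_adjusted_p) with BH run across every test in the scan; zero-variance
    features are skipped and logged.
    """
    common = region_mean_beta_table.index.intersection(feature_matrix.index)
    y = region_mean_beta_table.loc[common].to_numpy(dtype=float)
    x = feature_matrix.loc[common].to_numpy(dtype=float)
    n = len(common)
    if n < 3:
        raise ValueError("association scan needs at least 3 shared samples")

    xc = x - x.mean(axis=0, keepdims=True)
    yc = y - y.mean(axis=0, keepdims=True)
    sx = xc.std(axis=0, ddof=0)
    sy = yc.std(axis=0, ddof=0)
    keep = sx > 0
    if (~keep).any():
        logger.info("skipping %d zero-variance features", int((~keep).sum()))
    xc, sx = xc[:, keep], sx[keep]
    feat_names = feature_matrix.columns[keep]

    # slope and correlation for every (feature, region) pair at once
    cov = xc.T @ yc / n                          # features x regions
    slope = cov / (sx ** 2)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.outer(sx, sy)
    r = np.clip(np.nan_to_num(r), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df), P_FLOOR, 1.0)

    rows = pd.DataFrame({
        "feature": np.repeat(feat_names, y.shape[1]),
        "region": np.tile(region_mean_beta_table.columns, len(feat_names)),
        "slope": slope.ravel(),
        "p": p.ravel(),
    })
    rows["bh_adjusted_p"] = bh_adjust(rows["p"].to_numpy())
    return rows


def fisher_enrichment(
    in_set_and_annotated: int,
    in_set_total: int,
    background_annotated: int,
    background_total: int,
) -> tuple[float, float]:
    """One-sided ("greater") Fisher/hypergeometric enrichment.

    The foreground set of size ``in_set_total`` is drawn from a background
    of ``background_total`` items of which ``background_annotated`` carry
    the annotation; ``in_set_and_annotated`` of the set carry it.  Returns
    the sample odds ratio of the 2x2 table (NaN on degenerate margins,
    where the p-value is 1 under "greater" whenever no enrichment is
    expressible).
    """
    k, n = int(in_set_and_annotated), int(in_set_total)
    big_k, big_n = int(background_annotated), int(background_total)
    if not (0 <= k <= n <= big_n and k <= big_k <= big_n):
        raise ValueError("inconsistent 2x2 counts")
    a, b = k, n - k
    c, d = big_k - k, (big_n - n) - (big_k - k)
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
    return odds, min(p, 1.0)


def drug_class_enrichment(
    hits_by_type: Mapping[str, Iterable[str]],
    universe_by_type: Mapping[str, Iterable[str]],
    class_membership: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per-(cancer type, drug class) one-sided hypergeometric enrichment of
    drugs with at least one called region among all drugs screened in that
    cancer type, BH-adjusted across all pairs.  Classes absent from a
    type's screened universe are skipped."""
    rows = []
    for cancer_type in sorted(universe_by_type):
        universe = set(universe_by_type[cancer_type])
        hits = set(hits_by_type.get(cancer_type, ())) & universe
        for cls in sorted(class_membership):
            members = set(class_membership[cls]) & universe
            if not members:
                continue
            k = len(members & hits)
            odds, p = fisher_enrichment(k, len(hits), len(members),
                                        len(universe))
            rows.append({"cancer_type": cancer_type, "drug_class": cls,
                         "n_class_hits": k, "n_hits": len(hits),
                         "n_class": len(members),
                         "n_universe": len(universe),
                         "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows, columns=["cancer_type", "drug_class",
                                      "n_class_hits", "n_hits", "n_class",
                                      "n_universe", "odds_ratio", "p"])
    out["fdr"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def signature_enrichment(
    signature_hits: Mapping[str, int],
    n_signatures: int,
    gene_set: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Binomial over-representation of genes in a signature collection.

    ``signature_hits`` maps every gene to the number of signatures it
    appears in; the background success probability is estimated from all
    genes.  One-sided ("greater") binomial tail per gene in ``gene_set``
    (default: all genes), BH-adjusted.
    """
    if n_signatures <= 0:
        raise ValueError("n_signatures must be positive")
    all_hits = pd.Series(dict(signature_hits), dtype=float)
    if (all_hits < 0).any() or (all_hits > n_signatures).any():
        raise ValueError("per-gene hit counts must lie in [0, n_signatures]")
    p0 = float(all_hits.sum() / (len(all_hits) * n_signatures))
    genes = sorted(gene_set) if gene_set is not None else list(all_hits.index)
    ks = all_hits.reindex(genes).fillna(0).astype(int)
    p = np.clip(stats.binom.sf(ks.to_numpy() - 1, n_signatures, p0),
                P_FLOOR, 1.0)
    out = pd.DataFrame({"gene": genes, "hits": ks.to_numpy(),
                        "background_rate": p0, "p": p})
    out["bh_adjusted_p"] = bh_adjust(out["p"].to_numpy())
    return out
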
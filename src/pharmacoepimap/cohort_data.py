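"""Cohort data model, TSV readers/writers, probe filtering and region output.

The on-disk dialect is plain TSV with header rows:

* ``beta.tsv``        probes x samples, values in [0, 1] (blank = missing)
* ``manifest.tsv``    one row per probe: probe_id, chromosome, position
                      (1-based), gene, feature, cgi, dhs, enhancer,
                      cross_reactive (booleans written as 0/1)
* ``auc.tsv``         samples x drugs, values in (0, 1] (blank = missing)
* ``covariates.tsv``  samples x {cancer_type, medium, growth, msi}
* ``expression.tsv``  genes x samples (normalized, unitless)
* ``genes.tsv``       one row per gene: gene, chromosome, tss (1-based), strand

In memory all matrices are pandas DataFrames indexed by sample; genomic
coordinates are converted to 0-based half-open on load (a probe at 1-based
position P occupies the interval [P-1, P)), which makes BED export direct.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Functional feature labels in precedence order: a probe annotated with
#: several categories receives the first one that applies.
FEATURE_PRECEDENCE = ("TSS200", "TSS1500", "UTR5", "FirstExon", "Body", "UTR3",
                      "Intergenic")

#: Probe-removal reasons, checked in this order; a probe matching several
#: reasons is counted only under the first.
FILTER_REASONS = ("blacklist", "cross_reactive", "sex_chromosome")

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})

_MANIFEST_COLUMNS = ["probe_id", "chromosome", "position", "gene", "feature",
                     "cgi", "dhs", "enhancer", "cross_reactive"]
_BOOL_COLUMNS = ["cgi", "dhs", "enhancer", "cross_reactive"]


class ProbeManifest:
    """Genomic and functional annotation of methylation probes.

    Wraps a DataFrame with one row per probe (unique ``probe_id``), the
    1-based ``position`` as read from disk and the derived 0-based ``pos0``.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if df["probe_id"].duplicated().any():
            dupes = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
            raise ValueError(f"duplicate probe ids in manifest: {dupes[:5]}")
        df["position"] = df["position"].astype(np.int64)
        if (df["position"] < 1).any():
            raise ValueError("manifest positions must be >= 1 (1-based)")
        for col in _BOOL_COLUMNS:
            df[col] = df[col].astype(int).astype(bool)
        df["gene"] = df["gene"].fillna("").astype(str)
        df["pos0"] = df["position"] - 1
        df = df.set_index("probe_id", drop=False)
        df.index.name = None  # avoid index/column name ambiguity
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.df.index

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    def subset(self, probe_ids: Iterable[str]) -> "ProbeManifest":
        keep = self.df.index.intersection(pd.Index(probe_ids))
        return ProbeManifest(self.df.loc[keep].reset_index(drop=True))

    def by_chromosome(self, chrom: str) -> pd.DataFrame:
        """Rows on one chromosome, sorted by position."""
        sub = self.df[self.df["chromosome"] == chrom]
        return sub.sort_values(["pos0", "probe_id"])

    def chromosomes(self) -> list[str]:
        return sorted(self.df["chromosome"].unique())

    def positions(self, probe_ids: Sequence[str]) -> np.ndarray:
        """0-based positions for the given probes, in the given order."""
        return self.df.loc[list(probe_ids), "pos0"].to_numpy()

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ProbeManifest":
        df = pd.read_csv(path, sep="\t", dtype={"probe_id": str,
                                                "chromosome": str})
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        out = self.df[_MANIFEST_COLUMNS].copy()
        for col in _BOOL_COLUMNS:
            out[col] = out[col].astype(int)
        out.to_csv(path, sep="\t", index=False)


@dataclass
class MethylationCohort:
    """Aligned per-cohort tables sharing one ordered sample index.

    ``beta`` and ``expression`` are stored samples x features; ``auc`` is
    samples x drugs; ``covariates`` holds the categorical sample annotation
    (cancer_type, medium, growth, msi).  ``auc`` and ``expression`` may be
    None (e.g. a tumour cohort has no drug screen).
    """

    beta: pd.DataFrame
    covariates: pd.DataFrame
    auc: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None
    cohort_tag: str = "cell_lines"

    @property
    def samples(self) -> pd.Index:
        return self.beta.index

    @property
    def n_samples(self) -> int:
        return len(self.beta.index)

    def validate(self) -> None:
        vals = self.beta.to_numpy(dtype=float)
        bad = np.where((vals < 0) | (vals > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValueError(
                "beta value out of [0, 1]: "
                f"probe {self.beta.columns[j]!r}, sample "
                f"{self.beta.index[i]!r} = {vals[i, j]}")
        for name, tbl in (("covariates", self.covariates),
                          ("auc", self.auc),
                          ("expression", self.expression)):
            if tbl is not None and not tbl.index.equals(self.beta.index):
                raise ValueError(f"{name} sample index not aligned with beta")

    def subset_samples(self, samples: Sequence[str]) -> "MethylationCohort":
        idx = pd.Index(samples)
        return MethylationCohort(
            beta=self.beta.loc[idx],
            covariates=self.covariates.loc[idx],
            auc=None if self.auc is None else self.auc.loc[idx],
            expression=(None if self.expression is None
                        else self.expression.loc[idx]),
            cohort_tag=self.cohort_tag,
        )


@dataclass
class DDMR:
    """A called drug differentially methylated region.

    ``start``/``end`` are 0-based half-open; ``effect_size`` is the mean
    per-CpG regression slope of AUC on beta (AUC units per beta unit);
    ``n_hypo``/``n_hyper`` count samples with region-mean beta below 0.3 /
    above 0.7.
    """

    chrom: str
    start: int
    end: int
    probe_ids: list[str]
    drug: str
    cancer_type: str
    region_p: float
    sidak_p: float
    effect_size: float
    n_hypo: int
    n_hyper: int
    dmr_id: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if not self.dmr_id:
            self.dmr_id = (f"{self.drug}:{self.cancer_type}:"
                           f"{self.chrom}:{self.start}-{self.end}")


_DDMR_TSV_COLUMNS = ["dmr_id", "chrom", "start", "end", "drug", "cancer_type",
                     "n_probes", "probe_ids", "region_p", "sidak_p",
                     "effect_size", "n_hypo", "n_hyper"]


def _read_matrix(path: str | Path, rows_are_features: bool) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.T if rows_are_features else df


def load_cohort(
    beta_path: str | Path,
    manifest_path: str | Path,
    auc_path: str | Path | None = None,
    covariate_path: str | Path | None = None,
    expression_path: str | Path | None = None,
    cohort_tag: str = "cell_lines",
) -> tuple[MethylationCohort, ProbeManifest]:
    """Read cohort TSVs, align samples and drop unannotated probes.

    Samples are intersected across all provided tables and ordered by the
    beta table's sample order.  Probes absent from the manifest are dropped
    (counted in the log).  An empty sample intersection or a beta value
    outside [0, 1] is fatal.
    """
    beta = _read_matrix(beta_path, rows_are_features=True)
    manifest = ProbeManifest.read_tsv(manifest_path)

    unknown = beta.columns.difference(manifest.probe_ids)
    if len(unknown):
        logger.info("dropping %d probes absent from manifest", len(unknown))
        beta = beta.drop(columns=unknown)
    if beta.shape[1] == 0:
        raise ValueError("no probes left after manifest intersection")

    tables: dict[str, pd.DataFrame] = {}
    if covariate_path is not None:
        cov = pd.read_csv(covariate_path, sep="\t", index_col=0, dtype=str)
        cov.index = cov.index.astype(str)
        tables["covariates"] = cov
    if auc_path is not None:
        tables["auc"] = _read_matrix(auc_path, rows_are_features=False)
    if expression_path is not None:
        tables["expression"] = _read_matrix(expression_path,
                                            rows_are_features=True)

    samples = beta.index
    for tbl in tables.values():
        samples = samples.intersection(tbl.index)
    samples = pd.Index([s for s in beta.index if s in set(samples)])
    if len(samples) == 0:
        raise ValueError("empty sample intersection across cohort tables")

    cohort = MethylationCohort(
        beta=beta.loc[samples],
        covariates=tables.get(
            "covariates",
            pd.DataFrame(index=samples.copy())).loc[samples],
        auc=tables["auc"].loc[samples] if "auc" in tables else None,
        expression=(tables["expression"].loc[samples]
                    if "expression" in tables else None),
        cohort_tag=cohort_tag,
    )
    cohort.validate()
    manifest = manifest.subset(cohort.beta.columns)
    return cohort, manifest


def filter_probes(
    cohort: MethylationCohort,
    manifest: ProbeManifest,
    drop_sex: bool = True,
    blacklist: Iterable[str] | None = None,
) -> tuple[MethylationCohort, ProbeManifest, dict[str, int]]:
    """Remove blacklisted, cross-reactive and (optionally) sex-chromosome probes.

    Each probe is counted under the first matching reason in
    :data:`FILTER_REASONS` order.  Removing every probe is fatal.
    Idempotent: re-applying with the same arguments is a no-op.
    """
    blacklist = frozenset(blacklist or ())
    counts = {reason: 0 for reason in FILTER_REASONS}
    keep: list[str] = []
    mf = manifest.df
    for probe in cohort.beta.columns:
        if probe in blacklist:
            counts["blacklist"] += 1
        elif bool(mf.at[probe, "cross_reactive"]):
            counts["cross_reactive"] += 1
        elif drop_sex and mf.at[probe, "chromosome"] in SEX_CHROMOSOMES:
            counts["sex_chromosome"] += 1
        else:
            keep.append(probe)
    if not keep:
        raise ValueError("probe filtering removed every probe")
    logger.info("probe filtering removed %s", counts)
    reduced = replace(cohort, beta=cohort.beta[keep])
    return reduced, manifest.subset(keep), counts


def bed_score(sidak_p: float) -> int:
    """BED score: -10*log10(p) rounded, capped at 1000."""
    if sidak_p <= 0:
        return 1000
    return min(1000, int(round(-10.0 * math.log10(sidak_p))))


def write_ddmr_outputs(
    ddmrs: Sequence[DDMR],
    bed_path: str | Path,
    tsv_path: str | Path,
) -> None:
    """Write called regions as BED6 (0-based half-open) and as a full TSV.

    BED name is ``drug:cancer_type``, score ``min(1000,
    round(-10*log10(sidak_p)))``, strand ".".  The BED file has no header;
    the TSV always carries one, even when the region list is empty.
    """
    with open(bed_path, "w") as bed:
        for d in ddmrs:
            bed.write(f"{d.chrom}\t{d.start}\t{d.end}\t"
                      f"{d.drug}:{d.cancer_type}\t{bed_score(d.sidak_p)}\t.\n")
    rows = [{
        "dmr_id": d.dmr_id, "chrom": d.chrom, "start": d.start, "end": d.end,
        "drug": d.drug, "cancer_type": d.cancer_type,
        "n_probes": len(d.probe_ids), "probe_ids": ",".join(d.probe_ids),
        "region_p": d.region_p, "sidak_p": d.sidak_p,
        "effect_size": d.effect_size, "n_hypo": d.n_hypo, "n_hyper": d.n_hyper,
    } for d in ddmrs]
    pd.DataFrame(rows, columns=_DDMR_TSV_COLUMNS).to_csv(
        tsv_path, sep="\t", index=False)


def read_ddmr_tsv(path: str | Path) -> list[DDMR]:
    """Read regions written by :func:`write_ddmr_outputs`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "drug": str,
                                            "cancer_type": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(DDMR(
            chrom=row.chrom, start=int(row.start), end=int(row.end),
            probe_ids=str(row.probe_ids).split(","), drug=row.drug,
            cancer_type=row.cancer_type, region_p=float(row.region_p),
            sidak_p=float(row.sidak_p), effect_size=float(row.effect_size),
            n_hypo=int(row.n_hypo), n_hyper=int(row.n_hyper),
            dmr_id=row.dmr_id))
    return out


def write_cohort(
    cohort: MethylationCohort,
    manifest: ProbeManifest,
    out_dir: str | Path,
    genes: pd.DataFrame | None = None,
) -> None:
    """Write a cohort directory in the TSV dialect :func:`load_cohort` reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.beta.T.to_csv(out / "beta.tsv", sep="\t", index_label="probe_id")
    cohort.covariates.to_csv(out / "covariates.tsv", sep="\t",
                             index_label="sample")
    if cohort.auc is not None:
        cohort.auc.to_csv(out / "auc.tsv", sep="\t", index_label="sample")
    if cohort.expression is not None:
        cohort.expression.T.to_csv(out / "expression.tsv", sep="\t",
                                   index_label="gene")
    manifest.write_tsv(out / "manifest.tsv")
    if genes is not None:
        genes.to_csv(out / "genes.tsv", sep="\t", index=False)


def load_cohort_dir(
    cohort_dir: str | Path,
    cohort_tag: str = "cell_lines",
) -> tuple[MethylationCohort, ProbeManifest, pd.DataFrame | None]:
    """Load a cohort directory written by :func:`write_cohort`."""
    d = Path(cohort_dir)
    auc = d / "auc.tsv"
    expr = d / "expression.tsv"
    cohort, manifest = load_cohort(
        d / "beta.tsv", d / "manifest.tsv",
        auc_path=auc if auc.exists() else None,
        covariate_path=d / "covariates.tsv",
        expression_path=expr if expr.exists() else None,
        cohort_tag=cohort_tag)
    genes_path = d / "genes.tsv"
    genes = (pd.read_csv(genes_path, sep="\t", dtype={"gene": str,
                                                      "chromosome": str,
                                                      "strand": str})
             if genes_path.exists() else None)
    return cohort, manifest, genes
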
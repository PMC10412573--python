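import warnings

import numpy as np
import pandas as pd
import pytest

from pharmacoepimap import synthetic_data as sd


@pytest.fixture(scope="session")
def planted_sim():
    """One Case-1 planted cohort shared by read-only tests."""
    cfg = sd.SimulationConfig(
        n_samples=60,
        planted_regions=[sd.PlantedRegion(fraction_shifted=0.3)],
        seed=7,
    )
    return sd.simulate_pharmaco_cohort(cfg)


@pytest.fixture(scope="session")
def null_sim():
    """A cohort with no planted regions (AUC independent of methylation)."""
    return sd.simulate_null_scan(sd.SimulationConfig(seed=11))


@pytest.fixture()
def toy_manifest_frame():
    return pd.DataFrame({
        "probe_id": [f"cg{i}" for i in range(6)],
        "chromosome": ["chr1", "chr1", "chr1", "chr2", "chrX", "chrX"],
        "position": [101, 151, 2001, 50, 10, 20],
        "gene": ["G1", "G1", "", "G2", "", ""],
        "feature": ["TSS200", "TSS1500", "Body", "Intergenic", "Body",
                    "Body"],
        "cgi": [1, 1, 0, 0, 0, 0],
        "dhs": [0, 1, 0, 0, 0, 0],
        "enhancer": [0] * 6,
        "cross_reactive": [0, 0, 1, 0, 0, 0],
    })


def write_matrix_tsv(path, df, index_label):
    df.to_csv(path, sep="\t", index_label=index_label)


@pytest.fixture()
def toy_cohort_files(tmp_path, toy_manifest_frame):
    """Tiny on-disk cohort: 3 samples, 6 probes, 2 drugs."""
    rng = np.random.default_rng(0)
    samples = ["A", "B", "C"]
    probes = toy_manifest_frame["probe_id"].tolist()
    beta = pd.DataFrame(rng.random((3, 6)), index=samples, columns=probes)
    auc = pd.DataFrame(rng.uniform(0.4, 1.0, (3, 2)), index=samples,
                       columns=["d1", "d2"])
    cov = pd.DataFrame({"cancer_type": ["CT1"] * 3,
                        "medium": ["A", "B", "A"],
                        "growth": ["adherent"] * 3,
                        "msi": ["MSS", "MSS", "MSI"]}, index=samples)
    toy_manifest_frame.to_csv(tmp_path / "manifest.tsv", sep="\t",
                              index=False)
    write_matrix_tsv(tmp_path / "beta.tsv", beta.T, "probe_id")
    write_matrix_tsv(tmp_path / "auc.tsv", auc, "sample")
    write_matrix_tsv(tmp_path / "covariates.tsv", cov, "sample")
    return tmp_path
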
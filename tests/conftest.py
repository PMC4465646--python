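import numpy as np
import pandas as pd
import pytest

from foxgbs import genotyping, simulate as sim
from foxgbs.core import GenotypeMatrix


@pytest.fixture(scope="session")
def small_config():
    return sim.SimulationConfig(
        n_loci=1500,
        seed=11,
        fst_target=0.05,
        divergence_regions=[("2", 40_000_000, 44_000_000, 0.9)],
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Simulated allele depths + truth for a 20+20 cohort with 7 replicates."""
    depths, truth = sim.simulate(small_config)
    return depths, truth


@pytest.fixture(scope="session")
def called_cohort(small_config, small_cohort):
    depths, truth = small_cohort
    return genotyping.call_genotypes(depths, small_config.error_rate), truth


@pytest.fixture(scope="session")
def populations(small_cohort):
    _, truth = small_cohort
    man = truth.manifest.table
    base = man[man.replicate_of == ""]
    return (
        list(base.loc[base.population == "tame", "sample"]),
        list(base.loc[base.population == "aggressive", "sample"]),
    )


def genotype_matrix_from_codes(gt, chrom=None, pos=None, samples=None, gq=None):
    """Hand-built GenotypeMatrix for unit tests (dummy depths and PLs)."""
    gt = np.asarray(gt, dtype=np.int8)
    n_loci, n_samples = gt.shape
    loci = pd.DataFrame(
        {
            "locus_id": [f"T{i:04d}" for i in range(n_loci)],
            "chrom": chrom if chrom is not None else ["1"] * n_loci,
            "pos": pos if pos is not None else (np.arange(n_loci) + 1) * 1000,
            "allele1": "A",
            "allele2": "C",
        }
    )
    depth = np.where(gt == -1, 0, 20).astype(np.int64)
    gq_arr = (
        np.asarray(gq, dtype=np.int64)
        if gq is not None
        else np.where(gt == -1, 0, 99).astype(np.int64)
    )
    return GenotypeMatrix(
        loci=loci,
        samples=samples or [f"s{j}" for j in range(n_samples)],
        gt=gt,
        ad1=depth,
        ad2=np.zeros_like(depth),
        gq=gq_arr,
        pl=np.zeros((n_loci, n_samples, 3), dtype=np.int64),
    )
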
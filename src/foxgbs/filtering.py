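"""Two-tier SNP filtering of a called genotype matrix.

The first tier ("filtered") keeps a SNP iff, over non-missing genotypes:

1. call rate >= 0.5,
2. minor allele frequency > 0.025 (strict),
3. exactly two alleles segregate,
4. mean read depth over called samples <= 150,
5. heterozygous-individual fraction < 0.60 on autosomes and the X
   pseudoautosomal region (PAR, positions 1..par_end); on X beyond the PAR
   the SNP is removed when more than 30% of individuals are heterozygous
   (excess X heterozygosity in a mixed-sex panel marks artifacts).

The second tier ("stringently filtered") additionally masks genotypes with
GQ < 98 as missing and removes any SNP that then has missing data, leaving
a matrix with zero missing entries.

The attrition report attributes each removed SNP to the FIRST failing rule
in the order above, and conserves counts:
retained + sum(removed per rule) = input SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HET, MISSING, GenotypeMatrix, InvalidConfigError

RULES = ("call_rate", "maf", "allele_count", "mean_depth", "het_fraction")


@dataclass
class FilterConfig:
    min_call_rate: float = 0.5
    min_maf: float = 0.025  # strict >
    max_mean_depth: float = 150.0
    max_het_fraction_autosome: float = 0.60  # strict <
    max_het_fraction_x: float = 0.30  # inclusive <=; removal when exceeded
    par_end: int = 6_650_000
    x_chrom: str = "X"
    stringent_min_gq: int = 98
    stringent_max_missing: int = 0

    def validate(self) -> None:
        for frac in (
            self.min_call_rate,
            self.min_maf,
            self.max_het_fraction_autosome,
            self.max_het_fraction_x,
        ):
            if not 0.0 <= frac <= 1.0:
                raise InvalidConfigError("filter fractions must lie in [0, 1]")
        if self.max_mean_depth <= 0 or self.par_end < 0:
            raise InvalidConfigError("thresholds must be positive")


def site_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP call rate, MAF, het fraction, mean depth and allele count.

    Computed over non-missing genotypes only.  SNPs with zero called
    samples get NaN stats and fail every threshold downstream.
    """
    called = gm.is_called
    n_called = called.sum(axis=1)
    n_samples = gm.n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        call_rate = n_called / n_samples
        n_het = ((gm.gt == HET) & called).sum(axis=1)
        dose2 = np.where(called, gm.gt, 0).sum(axis=1)  # codes equal dosage
        p2 = np.where(n_called > 0, dose2 / np.maximum(2 * n_called, 1), np.nan)
        maf = np.minimum(p2, 1.0 - p2)
        het_fraction = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
        depth_called = np.where(called, gm.depth, 0).sum(axis=1)
        mean_depth = np.where(n_called > 0, depth_called / np.maximum(n_called, 1), np.nan)
    # alleles observed among called genotypes
    has1 = (((gm.gt == 0) | (gm.gt == 1)) & called).any(axis=1)
    has2 = (((gm.gt == 2) | (gm.gt == 1)) & called).any(axis=1)
    allele_count = has1.astype(int) + has2.astype(int)
    maf = np.where(n_called > 0, maf, np.nan)
    return pd.DataFrame(
        {
            "locus_id": gm.loci["locus_id"],
            "call_rate": call_rate,
            "maf": maf,
            "het_fraction": het_fraction,
            "mean_depth": mean_depth,
            "allele_count": allele_count,
            "n_called": n_called,
        }
    )


def apply_filtered(gm: GenotypeMatrix, config: FilterConfig | None = None):
    """First-tier filter.  Returns (filtered matrix, attrition report).

    The report is a dict rule -> SNPs removed by that rule (first-failing
    attribution, rules in the documented order) plus "retained".
    """
    config = config or FilterConfig()
    config.validate()
    if "chrom" not in gm.loci.columns or "pos" not in gm.loci.columns:
        raise InvalidConfigError("loci lack chromosome/position metadata")
    stats = site_stats(gm)
    chrom = gm.loci["chrom"].to_numpy()
    pos = gm.loci["pos"].to_numpy()
    on_x_nonpar = (chrom == config.x_chrom) & (pos > config.par_end)

    with np.errstate(invalid="ignore"):
        fail = {
            "call_rate": ~(stats.call_rate.to_numpy() >= config.min_call_rate),
            "maf": ~(stats.maf.to_numpy() > config.min_maf),
            "allele_count": stats.allele_count.to_numpy() != 2,
            "mean_depth": ~(stats.mean_depth.to_numpy() <= config.max_mean_depth),
            "het_fraction": np.where(
                on_x_nonpar,
                ~(stats.het_fraction.to_numpy() <= config.max_het_fraction_x),
                ~(stats.het_fraction.to_numpy() < config.max_het_fraction_autosome),
            ),
        }
    undefined = stats.n_called.to_numpy() == 0
    fail["call_rate"] |= undefined

    removed_by = np.full(gm.n_loci, "", dtype=object)
    for rule in RULES:
        newly = (removed_by == "") & fail[rule]
        removed_by[newly] = rule
    keep = removed_by == ""
    report = {rule: int((removed_by == rule).sum()) for rule in RULES}
    report["retained"] = int(keep.sum())
    report["input"] = gm.n_loci
    return gm.subset_loci(keep), report


def apply_stringent(gm: GenotypeMatrix, config: FilterConfig | None = None):
    """Second-tier filter on an already-filtered matrix.

    Masks genotypes with GQ below the stringent cutoff as missing, then
    removes every SNP with any missing genotype.  The result contains no
    missing entries.
    """
    config = config or FilterConfig()
    config.validate()
    low = gm.gq < config.stringent_min_gq
    gt = np.where(low, np.int8(MISSING), gm.gt)
    complete = (gt != MISSING).all(axis=1)
    out = GenotypeMatrix(
        loci=gm.loci.copy(),
        samples=list(gm.samples),
        gt=gt,
        ad1=gm.ad1.copy(),
        ad2=gm.ad2.copy(),
        gq=gm.gq.copy(),
        pl=gm.pl.copy(),
    )
    return out.subset_loci(complete)
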
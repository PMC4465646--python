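"""Core in-memory containers shared across the pipeline.

Loci are described by a pandas DataFrame (one row per locus, columns
``locus_id, chrom, pos, allele1, allele2``) and per-sample data by dense
numpy arrays with shape ``(n_loci, n_samples)``.  Genotypes are coded as
small integers: 0 = homozygous allele1, 1 = heterozygous, 2 = homozygous
allele2, -1 = missing.  Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1
HOM1, HET, HOM2 = 0, 1, 2

LOCUS_COLUMNS = ["locus_id", "chrom", "pos", "allele1", "allele2"]


class InvalidConfigError(ValueError):
    """A configuration value is outside its documented domain."""


def _check_locus_frame(loci: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LOCUS_COLUMNS if c not in loci.columns]
    if missing:
        raise ValueError(f"locus table lacks columns: {missing}")
    return loci.reset_index(drop=True)


@dataclass
class AlleleDepthMatrix:
    """Per-sample, per-locus read counts for the two retained alleles."""

    loci: pd.DataFrame
    samples: list[str]
    ad1: np.ndarray  # reads supporting allele1, shape (n_loci, n_samples)
    ad2: np.ndarray  # reads supporting allele2

    def __post_init__(self) -> None:
        self.loci = _check_locus_frame(self.loci)
        self.ad1 = np.asarray(self.ad1, dtype=np.int64)
        self.ad2 = np.asarray(self.ad2, dtype=np.int64)
        shape = (len(self.loci), len(self.samples))
        if self.ad1.shape != shape or self.ad2.shape != shape:
            raise ValueError("allele-depth arrays do not match loci x samples")
        if (self.ad1 < 0).any() or (self.ad2 < 0).any():
            raise ValueError("negative allele depths")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def depth(self) -> np.ndarray:
        return self.ad1 + self.ad2


@dataclass
class GenotypeMatrix:
    """Called genotypes with per-call quality annotations.

    ``pl`` holds Phred-scaled, min-normalised genotype likelihoods ordered
    (hom-allele1, het, hom-allele2).
    """

    loci: pd.DataFrame
    samples: list[str]
    gt: np.ndarray  # int8, codes HOM1/HET/HOM2/MISSING
    ad1: np.ndarray
    ad2: np.ndarray
    gq: np.ndarray  # int, 0..99
    pl: np.ndarray  # (n_loci, n_samples, 3)

    def __post_init__(self) -> None:
        self.loci = _check_locus_frame(self.loci)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        shape = (len(self.loci), len(self.samples))
        for name in ("gt", "ad1", "ad2", "gq"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape mismatch")
        if self.pl.shape != shape + (3,):
            raise ValueError("pl shape mismatch")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def depth(self) -> np.ndarray:
        return self.ad1 + self.ad2

    @property
    def is_called(self) -> np.ndarray:
        return self.gt != MISSING

    def sample_index(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample {exc}") from exc

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return GenotypeMatrix(
            loci=self.loci.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            gt=self.gt[idx],
            ad1=self.ad1[idx],
            ad2=self.ad2[idx],
            gq=self.gq[idx],
            pl=self.pl[idx],
        )

    def subset_samples(self, names) -> "GenotypeMatrix":
        idx = self.sample_index(names)
        return GenotypeMatrix(
            loci=self.loci.copy(),
            samples=[self.samples[i] for i in idx],
            gt=self.gt[:, idx],
            ad1=self.ad1[:, idx],
            ad2=self.ad2[:, idx],
            gq=self.gq[:, idx],
            pl=self.pl[:, idx],
        )

    def dosage(self) -> np.ndarray:
        """Allele2 dosage per call (0/1/2), NaN where missing."""
        d = self.gt.astype(float)
        d[self.gt == MISSING] = np.nan
        return d


@dataclass
class SampleManifest:
    """Population / sex / replicate bookkeeping for a cohort."""

    table: pd.DataFrame  # columns: sample, population, sex, replicate_of

    def __post_init__(self) -> None:
        need = {"sample", "population", "sex", "replicate_of"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"manifest lacks columns {need - set(self.table.columns)}")
        self.table = self.table.reset_index(drop=True)

    def samples_in(self, population: str) -> list[str]:
        t = self.table
        return list(t.loc[t.population == population, "sample"])

    def replicate_pairs(self) -> list[tuple[str, str]]:
        t = self.table
        dup = t[t.replicate_of.notna() & (t.replicate_of != "")]
        return [(row.replicate_of, row.sample) for row in dup.itertuples()]

    def sex_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample"], self.table["sex"]))
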
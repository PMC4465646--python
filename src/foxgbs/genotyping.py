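"""Diploid genotype calling from per-allele read depths.

The per-read model at a biallelic site with alleles (a, b) and sequencing
error rate ``eps``:

* homozygote ``aa`` emits ``a`` with probability ``1 - eps`` and ``b`` with
  probability ``eps`` (errors land on the other modelled allele);
* heterozygote ``ab`` emits each allele with probability 1/2 (the error
  flow between the two alleles cancels).

Reads are independent, so for allele depths ``(n1, n2)`` the likelihoods
are binomial kernels; the shared multinomial coefficient cancels in the
Phred-scaled, min-normalised PL values.  The caller and the depth
simulator share this model, which makes the calling error rates directly
testable against simulated truth.

Genotype quality follows the conventional rule: GQ is the second-smallest
PL, capped at 99 (a second-best PL above 99 still yields GQ = 99).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    HET,
    HOM1,
    HOM2,
    MISSING,
    AlleleDepthMatrix,
    GenotypeMatrix,
    InvalidConfigError,
)

GQ_CAP = 99
# PLs are clipped here before integer conversion; only relative order and
# the <99 range matter downstream.
_PL_CLIP = 100000


def _check_error_rate(error_rate: float) -> None:
    if not 0.0 <= error_rate < 0.25:
        raise InvalidConfigError(f"error_rate {error_rate} outside [0, 0.25)")


def _loglik(n1: np.ndarray, n2: np.ndarray, error_rate: float) -> np.ndarray:
    """Stacked log-likelihoods, shape (..., 3) ordered (hom1, het, hom2)."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    with np.errstate(divide="ignore"):
        log_e = np.log(error_rate) if error_rate > 0 else -np.inf
        log_1me = np.log1p(-error_rate)
    # 0 * -inf -> 0: zero-depth terms contribute nothing
    t_hom1 = n1 * log_1me + np.where(n2 > 0, n2 * log_e, 0.0)
    t_hom2 = np.where(n1 > 0, n1 * log_e, 0.0) + n2 * log_1me
    t_het = (n1 + n2) * np.log(0.5)
    return np.stack([t_hom1, t_het, t_hom2], axis=-1)


def site_likelihoods(ad, error_rate: float = 0.01) -> np.ndarray:
    """Phred-scaled, min-normalised PL triple(s) for allele depths.

    ``ad`` is a length-2 sequence or an (..., 2) array.  Returns an integer
    array of shape (..., 3) ordered (hom-allele1, het, hom-allele2) with the
    minimum PL equal to 0.  Sites with zero total depth get an all-zero PL
    triple and must be treated as missing by the caller.
    """
    _check_error_rate(error_rate)
    ad = np.asarray(ad)
    if ad.shape[-1] != 2:
        raise ValueError("allele depths must have final dimension 2")
    if (ad < 0).any():
        raise ValueError("negative allele depths")
    ll = _loglik(ad[..., 0], ad[..., 1], error_rate)
    best = ll.max(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):
        pl = -10.0 / np.log(10.0) * (ll - best)
    pl = np.where(np.isfinite(pl), pl, _PL_CLIP)
    pl = np.rint(np.clip(pl, 0, _PL_CLIP)).astype(np.int64)
    # zero-depth: all genotypes tie at 0 already (ll all 0)
    return pl


def call_from_pl(pl: np.ndarray, depth: np.ndarray):
    """GT and GQ from PL triples; zero-depth calls are missing.

    Ties at PL 0 resolve to the first genotype in the fixed order
    (hom-allele1 < het < hom-allele2) with GQ 0.
    """
    pl = np.asarray(pl)
    depth = np.asarray(depth)
    gt = np.argmin(pl, axis=-1).astype(np.int8)  # argmin takes first on ties
    part = np.partition(pl, 1, axis=-1)
    gq = np.minimum(part[..., 1] - part[..., 0], GQ_CAP).astype(np.int64)
    missing = depth == 0
    gt = np.where(missing, np.int8(MISSING), gt)
    gq = np.where(missing, 0, gq)
    return gt, gq


def call_genotypes(
    depths: AlleleDepthMatrix, error_rate: float = 0.01
) -> GenotypeMatrix:
    """Call every sample x locus from an allele-depth matrix."""
    ad = np.stack([depths.ad1, depths.ad2], axis=-1)
    pl = site_likelihoods(ad, error_rate)
    gt, gq = call_from_pl(pl, depths.depth)
    return GenotypeMatrix(
        loci=depths.loci.copy(),
        samples=list(depths.samples),
        gt=gt,
        ad1=depths.ad1.copy(),
        ad2=depths.ad2.copy(),
        gq=gq,
        pl=pl,
    )


def merge_duplicate_samples(
    depths: AlleleDepthMatrix,
    replicate_pairs: list[tuple[str, str]],
    het_freq: float = 0.8,
    error_rate: float = 0.01,
) -> AlleleDepthMatrix:
    """Collapse technical replicate pairs by summing their allele depths.

    Returns a matrix in which the first member of each pair keeps its name
    and carries the summed depths; the second member is dropped.  Genotypes
    re-called from the merged depths follow the ``het_freq`` convention: the
    merged call is heterozygous iff each allele carries more than
    ``1 - het_freq`` of the summed depth (see :func:`merged_genotype`).
    """
    if not 0.5 <= het_freq <= 1.0:
        raise InvalidConfigError("het_freq must lie in [0.5, 1]")
    index = {s: i for i, s in enumerate(depths.samples)}
    drop = set()
    ad1 = depths.ad1.copy()
    ad2 = depths.ad2.copy()
    for keep, dup in replicate_pairs:
        if keep not in index or dup not in index:
            raise KeyError(f"replicate pair ({keep}, {dup}) not in matrix")
        i, j = index[keep], index[dup]
        ad1[:, i] += ad1[:, j]
        ad2[:, i] += ad2[:, j]
        drop.add(j)
    keep_idx = [i for i in range(depths.n_samples) if i not in drop]
    return AlleleDepthMatrix(
        loci=depths.loci.copy(),
        samples=[depths.samples[i] for i in keep_idx],
        ad1=ad1[:, keep_idx],
        ad2=ad2[:, keep_idx],
    )


def merged_genotype(ad_pairs, het_freq: float = 0.8) -> np.ndarray:
    """Genotype of summed replicate depths under the het-fraction cutoff.

    ``ad_pairs``: (..., 2) summed allele depths.  Heterozygous iff both
    alleles exceed a ``1 - het_freq`` share of the total; otherwise
    homozygous for the majority allele; missing at zero depth.
    """
    ad = np.asarray(ad_pairs, dtype=float)
    total = ad.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac1 = ad[..., 0] / total
        frac2 = ad[..., 1] / total
    minor_cut = 1.0 - het_freq
    gt = np.where(frac1 >= frac2, HOM1, HOM2).astype(np.int8)
    het = (frac1 > minor_cut) & (frac2 > minor_cut)
    gt = np.where(het, np.int8(HET), gt)
    gt = np.where(total == 0, np.int8(MISSING), gt)
    return gt


def merge_duplicate_snps(
    records: list[dict], max_alleles: int = 3, error_rate: float = 0.01
):
    """Merge allele-depth records reported at the same chrom:pos.

    Each record is a dict with keys ``chrom``, ``pos``, ``ref``, ``alleles``
    (list of allele strings) and ``depths`` (mapping sample -> list of read
    counts aligned with ``alleles``).  Depths are summed per sample and
    allele, alleles ranked by total depth, at most ``max_alleles`` kept and
    the top two used for biallelic re-calling.

    Returns ``(merged record, flagged)``; ``flagged`` is True when the
    records disagree on the reference allele, in which case the first record
    is returned unmerged.
    """
    if not records:
        raise ValueError("no records to merge")
    first = records[0]
    if any((r["chrom"], r["pos"]) != (first["chrom"], first["pos"]) for r in records):
        raise ValueError("records are not at one position")
    refs = {r["ref"] for r in records}
    if len(refs) > 1:
        return dict(first), True

    totals: dict[str, int] = {}
    per_sample: dict[str, dict[str, int]] = {}
    for rec in records:
        for sample, counts in rec["depths"].items():
            slot = per_sample.setdefault(sample, {})
            for allele, n in zip(rec["alleles"], counts):
                slot[allele] = slot.get(allele, 0) + int(n)
                totals[allele] = totals.get(allele, 0) + int(n)
    ref = first["ref"]
    # rank by summed depth, reference first on ties, then lexicographic
    ranked = sorted(totals, key=lambda a: (-totals[a], a != ref, a))[:max_alleles]
    if ref in ranked:
        ranked.remove(ref)
        ranked.insert(0, ref)
    merged = {
        "chrom": first["chrom"],
        "pos": first["pos"],
        "ref": ref,
        "alleles": ranked,
        "depths": {
            s: [slot.get(a, 0) for a in ranked] for s, slot in per_sample.items()
        },
    }
    # biallelic genotype calls on the top two alleles
    a_top = ranked[: 2]
    calls = {}
    for sample, counts in merged["depths"].items():
        ad = np.array([counts[0], counts[1] if len(counts) > 1 else 0])
        pl = site_likelihoods(ad, error_rate)
        gt, gq = call_from_pl(pl, ad.sum())
        calls[sample] = {"gt": int(gt), "gq": int(gq), "ad": ad.tolist()}
    merged["calls"] = calls
    merged["called_alleles"] = a_top
    return merged, False
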
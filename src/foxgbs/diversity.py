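"""Per-population diversity, LD decay, LD-based Ne, and replicate QC.

Observed heterozygosity at a SNP is the fraction of heterozygous
individuals among those with a genotype call.  Expected heterozygosity is
the unbiased small-sample form (2N/(2N-1)) * 2 p q with p estimated from
called alleles and N the number of called individuals — i.e. the expected
number of heterozygotes under random mating divided by N.

LD is measured as the squared Pearson correlation of 0/1/2 genotype
dosages (composite LD; needs no phasing).  Effective population size uses
the LD (drift) method: mean r^2 over unlinked (cross-chromosome) SNP
pairs, corrected for the sampling contribution expected at harmonic-mean
sample size S, then inverted through the bias-adjusted random-mating
expectation; the confidence interval is a delete-one jackknife over pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HET, MISSING, GenotypeMatrix

# 14 default distance bins (bp, inclusive lower edge, exclusive upper)
DEFAULT_LD_BIN_EDGES = [
    1,
    1_000,
    5_000,
    10_000,
    50_000,
    100_000,
    500_000,
    1_000_000,
    5_000_000,
    10_000_000,
    20_000_000,
    50_000_000,
    75_000_000,
    100_000_000,
    210_000_000,
]


def expected_het_unbiased(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Unbiased expected heterozygote fraction, (2N/(2N-1)) * 2pq."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (2.0 * n / (2.0 * n - 1.0)) * 2.0 * p * (1.0 - p)
    return np.where(n > 0, out, np.nan)


def population_summary(gm: GenotypeMatrix, samples: list[str]) -> dict:
    """Table-1-style summary for one population's samples.

    Means/medians are taken over all SNPs in the matrix, fixed
    (monomorphic-in-population) SNPs included with MAF and heterozygosity 0.
    """
    if not samples:
        raise ValueError("empty population")
    sub = gm.subset_samples(samples)
    called = sub.is_called
    n_called = called.sum(axis=1)
    informative = n_called > 0
    dose2 = np.where(called, sub.gt, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p2 = dose2 / np.maximum(2 * n_called, 1)
        maf = np.minimum(p2, 1 - p2)
        h_obs = ((sub.gt == HET) & called).sum(axis=1) / np.maximum(n_called, 1)
    h_exp = expected_het_unbiased(p2, n_called)
    maf = maf[informative]
    h_obs = h_obs[informative]
    h_exp = h_exp[informative]
    return {
        "n_snps": int(informative.sum()),
        "mean_maf": float(np.mean(maf)),
        "median_maf": float(np.median(maf)),
        "sd_maf": float(np.std(maf, ddof=1)),
        "n_fixed": int((maf == 0).sum()),
        "mean_expected_het": float(np.mean(h_exp)),
        "mean_observed_het": float(np.mean(h_obs)),
        "median_observed_het": float(np.median(h_obs)),
        "sd_observed_het": float(np.std(h_obs, ddof=1)),
    }


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared dosage correlation over jointly called individuals.

    NaN marks missing calls.  Returns NaN when fewer than two joint calls
    remain or either SNP is monomorphic in the joint subset.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    joint = ~(np.isnan(a) | np.isnan(b))
    a, b = a[joint], b[joint]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _pairwise_r2(dosage: np.ndarray) -> np.ndarray:
    """r^2 for all SNP pairs (rows of ``dosage``), complete-case per pair.

    Missing dosages (NaN) are handled pairwise; monomorphic-in-subset pairs
    come out NaN.
    """
    x = dosage.copy()
    m = (~np.isnan(x)).astype(np.float64)
    x = np.nan_to_num(x)
    n = m @ m.T  # joint call counts
    sx = x @ m.T
    sxx = (x * x) @ m.T
    sxy = x @ x.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        var_a = sxx - sx * sx / n
        var_b = sxx.T - sx.T * sx.T / n
        r2 = (cov * cov) / (var_a * var_b)
    r2[n < 2] = np.nan
    return r2


@dataclass
class LDBinSummary:
    label: str
    low: int
    high: int
    n_pairs: int
    mean_r2: float
    median_r2: float
    q25_r2: float
    q75_r2: float
    frac_r2_one: float


def ld_decay_bins(
    gm: GenotypeMatrix, bin_edges: list[int] | None = None
) -> list[LDBinSummary]:
    """Mean/median/quartile r^2 of intra-chromosome pairs by distance bin.

    All same-chromosome SNP pairs are assigned to distance bins by the
    positions carried in ``gm.loci``.  Pairs with undefined r^2
    (monomorphic in the jointly called subset) are excluded from the
    summaries but do not silently vanish: they are counted out of the
    conservation identity via the returned n_pairs values.
    """
    edges = np.asarray(bin_edges or DEFAULT_LD_BIN_EDGES)
    dosage = gm.dosage()
    chrom = gm.loci["chrom"].to_numpy()
    pos = gm.loci["pos"].to_numpy()
    dist_all: list[np.ndarray] = []
    r2_all: list[np.ndarray] = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if idx.size < 2:
            continue
        r2 = _pairwise_r2(dosage[idx])
        iu = np.triu_indices(idx.size, k=1)
        dist_all.append(np.abs(pos[idx][iu[0]] - pos[idx][iu[1]]))
        r2_all.append(r2[iu])
    if not dist_all:
        return []
    dist = np.concatenate(dist_all)
    r2 = np.concatenate(r2_all)
    which = np.digitize(dist, edges[1:], right=False)  # bin index per pair
    out = []
    for k in range(len(edges) - 1):
        sel = which == k
        vals = r2[sel]
        vals = vals[~np.isnan(vals)]
        label = f"{edges[k]:,}-{edges[k + 1]:,}"
        if vals.size == 0:
            out.append(LDBinSummary(label, int(edges[k]), int(edges[k + 1]),
                                    int(sel.sum()), np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        out.append(
            LDBinSummary(
                label=label,
                low=int(edges[k]),
                high=int(edges[k + 1]),
                n_pairs=int(sel.sum()),
                mean_r2=float(vals.mean()),
                median_r2=float(np.median(vals)),
                q25_r2=float(np.percentile(vals, 25)),
                q75_r2=float(np.percentile(vals, 75)),
                frac_r2_one=float(np.mean(np.isclose(vals, 1.0))),
            )
        )
    return out


def interchromosome_ld_null(
    gm: GenotypeMatrix, max_pairs: int | None = None, seed: int = 0
):
    """Mean and SD of r^2 over cross-chromosome SNP pairs.

    With ``max_pairs`` set, a seeded uniform subsample of pairs is scored.
    Returns (mean, sd, n_pairs_used).
    """
    chrom = gm.loci["chrom"].to_numpy()
    if len(pd.unique(chrom)) < 2:
        raise ValueError("need at least two chromosomes")
    r2 = _cross_chrom_r2(gm, max_pairs=max_pairs, seed=seed)
    return float(np.mean(r2)), float(np.std(r2)), int(r2.size)


def _r2_for_pairs(dosage: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    """Complete-case r^2 for explicit SNP index pairs (vectorised)."""
    a = dosage[ii]
    b = dosage[jj]
    m = ~(np.isnan(a) | np.isnan(b))
    a = np.where(m, a, 0.0)
    b = np.where(m, b, 0.0)
    n = m.sum(axis=1)
    sa, sb = a.sum(axis=1), b.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = (a * b).sum(axis=1) - sa * sb / n
        va = (a * a).sum(axis=1) - sa * sa / n
        vb = (b * b).sum(axis=1) - sb * sb / n
        r2 = (cov * cov) / (va * vb)
    r2[n < 2] = np.nan
    return r2


def _cross_chrom_r2(gm, max_pairs=None, seed=0, return_index=False):
    dosage = gm.dosage()
    chrom = gm.loci["chrom"].to_numpy()
    n = len(chrom)
    iu = np.triu_indices(n, k=1)
    cross = chrom[iu[0]] != chrom[iu[1]]
    ii, jj = iu[0][cross], iu[1][cross]
    if max_pairs is not None and ii.size > max_pairs:
        rng = np.random.default_rng(seed)
        keep = rng.choice(ii.size, size=max_pairs, replace=False)
        keep.sort()
        ii, jj = ii[keep], jj[keep]
    r2 = _r2_for_pairs(dosage, ii, jj)
    ok = ~np.isnan(r2)
    if return_index:
        return r2[ok], ii[ok], jj[ok]
    return r2[ok]


@dataclass
class NeEstimate:
    ne: float
    ci_low: float
    ci_high: float
    s_harmonic: float
    maf_cutoff: float
    r2_mean: float
    r2_corrected: float
    n_pairs: int
    infinite: bool


def _sampling_expectation(s: float) -> float:
    if s >= 30:
        return 1.0 / s + 3.19 / (s * s)
    return 0.0018 + 0.907 / s + 4.44 / (s * s)


def _ne_from_r2prime(r2p: np.ndarray, s: float) -> np.ndarray:
    """Bias-adjusted random-mating inversion of drift r^2 (comparisons of
    unlinked loci)."""
    r2p = np.asarray(r2p, dtype=float)
    if s >= 30:
        disc = 1.0 / 9.0 - 2.76 * r2p
        num = 1.0 / 3.0 + np.sqrt(np.maximum(disc, 0.0))
    else:
        disc = 0.308**2 - 2.08 * r2p
        num = 0.308 + np.sqrt(np.maximum(disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        ne = num / (2.0 * r2p)
    return np.where(r2p > 0, ne, np.inf)


def estimate_ne_ld(
    gm: GenotypeMatrix,
    maf_cutoff: float = 0.05,
    max_pairs: int | None = 200_000,
    seed: int = 0,
) -> NeEstimate:
    """LD-based effective population size from cross-chromosome pairs.

    SNPs below the MAF cutoff are screened out first.  The point estimate
    inverts the corrected mean r^2; the 95% CI is a delete-one jackknife
    over the pair r^2 values.
    """
    called = gm.is_called
    n_called = called.sum(axis=1)
    dose2 = np.where(called, gm.gt, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p2 = dose2 / np.maximum(2 * n_called, 1)
    maf = np.minimum(p2, 1 - p2)
    keep = (maf >= maf_cutoff) & (n_called >= 2)
    sub = gm.subset_loci(keep)
    if len(pd.unique(sub.loci["chrom"])) < 2:
        raise ValueError("need SNPs on at least two chromosomes after MAF screen")
    r2, ii, jj = _cross_chrom_r2(sub, max_pairs=max_pairs, seed=seed, return_index=True)
    if r2.size < 2:
        raise ValueError("too few informative cross-chromosome pairs")
    # harmonic-mean sample size over pairs (jointly called individuals)
    called_sub = sub.is_called
    joint = (called_sub[ii] & called_sub[jj]).sum(axis=1).astype(float)
    s = 1.0 / np.mean(1.0 / joint)
    r2_mean = float(np.mean(r2))
    r2p = r2_mean - _sampling_expectation(s)
    ne = float(_ne_from_r2prime(np.array([r2p]), s)[0])
    # delete-one jackknife on the pair list
    n = r2.size
    loo_mean = (r2.sum() - r2) / (n - 1)
    loo_ne = _ne_from_r2prime(loo_mean - _sampling_expectation(s), s)
    finite = np.isfinite(loo_ne)
    if np.isfinite(ne) and finite.sum() > 1:
        theta = loo_ne[finite]
        se = np.sqrt((n - 1) / n * np.sum((theta - theta.mean()) ** 2))
        ci = (max(ne - 1.96 * se, 0.0), ne + 1.96 * se)
    else:
        ci = (np.inf, np.inf) if not np.isfinite(ne) else (ne, ne)
    return NeEstimate(
        ne=ne,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        s_harmonic=float(s),
        maf_cutoff=maf_cutoff,
        r2_mean=r2_mean,
        r2_corrected=float(r2p),
        n_pairs=int(n),
        infinite=not np.isfinite(ne),
    )


def concordance_report(gm: GenotypeMatrix, replicate_pairs: list[tuple[str, str]]):
    """Replicate-pair concordance and depth by concordance class.

    Per pair: percent concordant (identical calls, both-missing included),
    percent discordant due to missing data (exactly one member called) and
    percent discordant genotypes (both called, calls differ).  Depth
    statistics pool the per-SNP mean depth of the two replicates across
    pairs, for concordant-called vs genotype-discordant SNPs only (missing
    discordances excluded).  The mean-depth ratio is reported to 1 decimal.
    """
    if not replicate_pairs:
        raise ValueError("no replicate pairs")
    index = {s: i for i, s in enumerate(gm.samples)}
    for a, b in replicate_pairs:
        if a not in index or b not in index:
            raise KeyError(f"unpaired replicate id in ({a}, {b})")
    rows = []
    depth_conc: list[np.ndarray] = []
    depth_disc: list[np.ndarray] = []
    for a, b in replicate_pairs:
        ga, gb = gm.gt[:, index[a]], gm.gt[:, index[b]]
        called_a, called_b = ga != MISSING, gb != MISSING
        both = called_a & called_b
        one_missing = called_a ^ called_b
        disc_gt = both & (ga != gb)
        conc = ~one_missing & ~disc_gt
        n = gm.n_loci
        rows.append(
            {
                "replicate": a,
                "pct_concordant": 100.0 * conc.sum() / n,
                "pct_discordant_missing": 100.0 * one_missing.sum() / n,
                "pct_discordant_genotype": 100.0 * disc_gt.sum() / n,
            }
        )
        pair_depth = (gm.depth[:, index[a]] + gm.depth[:, index[b]]) / 2.0
        depth_conc.append(pair_depth[both & (ga == gb)])
        depth_disc.append(pair_depth[disc_gt])
    conc_d = np.concatenate(depth_conc)
    disc_d = np.concatenate(depth_disc)
    summary = {
        "mean_depth_concordant": float(conc_d.mean()) if conc_d.size else np.nan,
        "sd_depth_concordant": float(conc_d.std(ddof=1)) if conc_d.size > 1 else np.nan,
        "mean_depth_discordant": float(disc_d.mean()) if disc_d.size else np.nan,
        "sd_depth_discordant": float(disc_d.std(ddof=1)) if disc_d.size > 1 else np.nan,
    }
    summary["depth_ratio"] = depth_ratio(
        summary["mean_depth_concordant"], summary["mean_depth_discordant"]
    )
    return pd.DataFrame(rows), summary


def depth_ratio(mean_concordant: float, mean_discordant: float) -> float:
    """Concordant/discordant mean-depth ratio, reported to one decimal."""
    return round(float(mean_concordant) / float(mean_discordant), 1)


def x_het_by_sex(
    gm: GenotypeMatrix,
    sexes: dict[str, str],
    par_end: int = 6_650_000,
    x_chrom: str = "X",
) -> pd.DataFrame:
    """Mean heterozygosity of X SNPs outside the PAR, per sex.

    For each SNP and sex: fraction of called individuals of that sex that
    are heterozygous; averaged over SNPs with data for that sex.
    """
    on_x = (gm.loci["chrom"] == x_chrom) & (gm.loci["pos"] > par_end)
    sub = gm.subset_loci(on_x.to_numpy())
    rows = []
    for sex in ("M", "F"):
        cols = [i for i, s in enumerate(sub.samples) if sexes.get(s) == sex]
        if not cols or sub.n_loci == 0:
            rows.append({"sex": sex, "mean_het": np.nan, "n_snps": 0})
            continue
        g = sub.gt[:, cols]
        called = g != MISSING
        n_called = called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            het = ((g == HET) & called).sum(axis=1) / np.maximum(n_called, 1)
        has = n_called > 0
        rows.append(
            {
                "sex": sex,
                "mean_het": float(het[has].mean()) if has.any() else np.nan,
                "n_snps": int(has.sum()),
            }
        )
    return pd.DataFrame(rows)
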
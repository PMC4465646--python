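"""Two-population divergence scan.

Per-SNP basic allelic association: a 1-df chi-square on the 2x2 table of
allele counts (no continuity correction), Bonferroni-adjusted over the
number of SNPs tested.  Significant SNPs are chain-linked per chromosome:
consecutive significant SNPs at most ``gap`` (default 2 Mb, inclusive)
apart join one chain; chains of at least two SNPs form clusters, the rest
are isolated.  Windowed differentiation uses the Weir & Cockerham (1984)
variance components with weighted window F_ST = sum(a) / sum(a + b + c)
over the sites in each 1 Mb window stepped by 500 kb — the ratio of sums,
never the mean of per-site ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import HET, MISSING, GenotypeMatrix, InvalidConfigError

GAP_DEFAULT = 2_000_000
ALPHA_DEFAULT = 1e-6  # adjusted-p cutoff consistent with a -log10 = 6 line
WINDOW_DEFAULT = 1_000_000
STEP_DEFAULT = 500_000
HIGH_FST = 0.5
FLANK_DEFAULT = 50_000


def allele_counts(gm: GenotypeMatrix, samples: list[str]) -> np.ndarray:
    """Per-SNP (allele1, allele2) counts over called genotypes, shape (L, 2)."""
    sub = gm.subset_samples(samples)
    called = sub.is_called
    n_called = called.sum(axis=1)
    dose2 = np.where(called, sub.gt, 0).sum(axis=1)
    return np.stack([2 * n_called - dose2, dose2], axis=1)


def allelic_test(counts1, counts2):
    """1-df chi-square on a 2x2 allele-count table, no continuity correction.

    ``counts1``/``counts2``: (..., 2) allele counts for the two populations.
    Returns (chi2, p).  Tables with a zero margin are untestable: chi2 = 0,
    p = 1.
    """
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    a, b = c1[..., 0], c1[..., 1]
    c, d = c2[..., 0], c2[..., 1]
    n = a + b + c + d
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        chi2 = n * (a * d - b * c) ** 2 / denom
    untestable = ~np.isfinite(chi2)
    chi2 = np.where(untestable, 0.0, chi2)
    p = sps.chi2.sf(chi2, df=1)
    p = np.where(untestable, 1.0, p)
    return chi2, p


def scan_allele_frequencies(
    gm: GenotypeMatrix, pop1: list[str], pop2: list[str]
) -> pd.DataFrame:
    """Per-SNP allelic test with Bonferroni adjustment over tested SNPs."""
    c1 = allele_counts(gm, pop1)
    c2 = allele_counts(gm, pop2)
    chi2, p = allelic_test(c1, c2)
    m = len(p)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = c1[:, 1] / np.maximum(c1.sum(axis=1), 1)
        f2 = c2[:, 1] / np.maximum(c2.sum(axis=1), 1)
    out = gm.loci[["locus_id", "chrom", "pos"]].copy()
    out["freq_diff"] = np.abs(f1 - f2)
    out["chi2"] = chi2
    out["p_raw"] = p
    out["p_adj"] = np.minimum(1.0, m * p)
    return out


def bonferroni_select(
    results: pd.DataFrame, alpha: float = ALPHA_DEFAULT
) -> pd.DataFrame:
    """Rows with adjusted p below alpha, sorted in map order."""
    if not 0.0 < alpha < 1.0:
        raise InvalidConfigError("alpha must lie in (0, 1)")
    sig = results[results["p_adj"] < alpha]
    return sig.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


@dataclass
class ClusterReport:
    table: pd.DataFrame  # per-SNP: chrom, pos, cluster (0 = isolated), dist_prev
    n_clusters: int
    n_clustered: int
    n_isolated: int
    cluster_spans: pd.DataFrame  # cluster, chrom, start, end, n_snps, span_bp


def cluster_significant(
    snps: pd.DataFrame,
    gap: int = GAP_DEFAULT,
    min_size: int = 2,
    chrom_col: str = "chrom",
    pos_col: str = "pos",
) -> ClusterReport:
    """Chain-link significant SNPs within ``gap`` bp on one chromosome.

    The gap comparison is inclusive (a pair exactly ``gap`` apart stays in
    one chain).  Chains of ``min_size`` or more SNPs are clusters, numbered
    in map order; smaller chains are isolated (cluster id 0).  The report
    is invariant under permutation of the input rows.
    """
    df = snps.sort_values([chrom_col, pos_col], kind="mergesort").reset_index(drop=True)
    chrom = df[chrom_col].to_numpy()
    pos = df[pos_col].to_numpy()
    n = len(df)
    dist_prev = np.full(n, np.nan)
    chain = np.zeros(n, dtype=int)
    current = 0
    for i in range(n):
        if i == 0 or chrom[i] != chrom[i - 1]:
            current += 1
        else:
            dist_prev[i] = pos[i] - pos[i - 1]
            if pos[i] - pos[i - 1] > gap:
                current += 1
        chain[i] = current
    sizes = pd.Series(chain).value_counts()
    is_clustered = np.array([sizes[c] >= min_size for c in chain])
    cluster_id = np.zeros(n, dtype=int)
    next_id = 0
    seen: dict[int, int] = {}
    for i in range(n):
        if is_clustered[i]:
            if chain[i] not in seen:
                next_id += 1
                seen[chain[i]] = next_id
            cluster_id[i] = seen[chain[i]]
    out = df.copy()
    out["dist_prev"] = dist_prev
    out["cluster"] = cluster_id
    spans = (
        out[out.cluster > 0]
        .groupby("cluster")
        .agg(
            chrom=(chrom_col, "first"),
            start=(pos_col, "min"),
            end=(pos_col, "max"),
            n_snps=(pos_col, "size"),
        )
        .reset_index()
    )
    spans["span_bp"] = spans["end"] - spans["start"]
    return ClusterReport(
        table=out,
        n_clusters=int(next_id),
        n_clustered=int(is_clustered.sum()),
        n_isolated=int((~is_clustered).sum()),
        cluster_spans=spans,
    )


def genes_near(
    clusters: pd.DataFrame,
    annotation: pd.DataFrame,
    flank: int = FLANK_DEFAULT,
) -> dict[int, list[str]]:
    """Genes overlapping [cluster start - flank, cluster end + flank].

    ``clusters`` needs columns cluster, chrom, start, end (1-based
    inclusive); ``annotation`` needs chrom, start, end, gene.  Boundary
    contact is inclusive: a gene starting exactly ``flank`` bp beyond the
    cluster end is reported.  Clusters on chromosomes unknown to the
    annotation get an empty list.
    """
    out: dict[int, list[str]] = {}
    ann_by_chrom = {c: g for c, g in annotation.groupby("chrom")}
    for row in clusters.itertuples():
        genes: list[str] = []
        g = ann_by_chrom.get(row.chrom)
        if g is not None:
            lo, hi = row.start - flank, row.end + flank
            hit = g[(g["end"] >= lo) & (g["start"] <= hi)]
            genes = list(hit["gene"])
        out[int(row.cluster)] = genes
    return out


def fst_site_components(g1: np.ndarray, g2: np.ndarray):
    """Weir & Cockerham (1984) variance components for biallelic sites.

    ``g1``/``g2``: genotype codes (0/1/2, -1 missing) per population,
    shape (L, n_i).  Returns arrays (a, b, c); sites with fewer than two
    called diploids in either population come out NaN.
    """
    comps = []
    ns, ps, hs = [], [], []
    for g in (g1, g2):
        called = g != MISSING
        n = called.sum(axis=1).astype(float)
        dose = np.where(called, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = dose / (2.0 * n)
            h = ((g == HET) & called).sum(axis=1) / n
        ns.append(n)
        ps.append(p)
        hs.append(h)
    n1, n2 = ns
    p1, p2 = ps
    h1, h2 = hs
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - 1.0 / (nbar - 1.0)
            * (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    bad = (n1 < 2) | (n2 < 2)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def fst_weighted(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Multi-site weighted theta: ratio of sums of components."""
    ok = ~(np.isnan(a) | np.isnan(b) | np.isnan(c))
    denom = (a + b + c)[ok].sum()
    return float(a[ok].sum() / denom) if denom != 0 else np.nan


@dataclass
class FstWindow:
    chrom: str
    start: int  # half-open [start, start + window)
    end: int
    n_snps: int
    fst: float
    high: bool


def fst_windows(
    loci: pd.DataFrame,
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    window: int = WINDOW_DEFAULT,
    step: int = STEP_DEFAULT,
    high_threshold: float = HIGH_FST,
) -> pd.DataFrame:
    """Weighted F_ST in sliding windows anchored at position 1.

    Windows are half-open [start, start + window), stepped by ``step``;
    windows containing no usable site are omitted.
    """
    rows = []
    ok = ~(np.isnan(a) | np.isnan(b) | np.isnan(c))
    for chrom, grp in loci.groupby("chrom", sort=True):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        usable = ok[idx]
        if not usable.any():
            continue
        last = int(pos.max())
        start = 1
        while start <= last:
            in_win = (pos >= start) & (pos < start + window) & usable
            if in_win.any():
                sel = idx[in_win]
                denom = (a[sel] + b[sel] + c[sel]).sum()
                theta = a[sel].sum() / denom if denom != 0 else np.nan
                rows.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": start + window,
                        "n_snps": int(in_win.sum()),
                        "fst": theta,
                        "high": bool(theta >= high_threshold)
                        if np.isfinite(theta)
                        else False,
                    }
                )
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "fst", "high"])


def fst_scan(
    gm: GenotypeMatrix,
    pop1: list[str],
    pop2: list[str],
    window: int = WINDOW_DEFAULT,
    step: int = STEP_DEFAULT,
) -> pd.DataFrame:
    """Site components + windowed weighted F_ST in one call."""
    i1 = gm.sample_index(pop1)
    i2 = gm.sample_index(pop2)
    a, b, c = fst_site_components(gm.gt[:, i1], gm.gt[:, i2])
    return fst_windows(gm.loci, a, b, c, window=window, step=step)


def overlap_report(clusters: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Interval intersections between clusters and (flagged) F_ST windows.

    Clusters are closed intervals [start, end]; windows half-open
    [start, end).  A window merely abutting a cluster end shares no base
    pair and does not overlap.
    """
    rows = []
    for w in windows.itertuples():
        for cl in clusters.itertuples():
            if w.chrom != cl.chrom:
                continue
            if max(w.start, cl.start) < min(w.end, cl.end + 1):
                rows.append(
                    {
                        "chrom": w.chrom,
                        "window_start": w.start,
                        "window_end": w.end,
                        "window_high": bool(getattr(w, "high", False)),
                        "cluster": int(cl.cluster),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["chrom", "window_start", "window_end", "window_high", "cluster"],
    )
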
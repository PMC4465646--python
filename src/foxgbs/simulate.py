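"""Synthetic GBS cohorts with full ground truth.

Emulates the statistical structure of a two-strain design: two populations
drifted from a common founder stock to a target F_ST (Balding–Nichols
per-locus Beta sampling), a few planted high-divergence regions, ~20
diploid samples per population plus technical replicates, heavy per-sample
and per-locus sequencing-depth variation with base-calling error, and
X-chromosome hemizygosity in males outside a pseudoautosomal region
(PAR, 0–6.65 Mb by default).

All randomness flows from a single master seed; each stage draws from a
deterministically derived substream, so identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import HET, HOM1, HOM2, AlleleDepthMatrix, InvalidConfigError, SampleManifest
from .coordmap import ComparativeMap, SyntenyBlock, build_map

DEFAULT_CHROMOSOMES = {
    "1": 150_000_000,
    "2": 120_000_000,
    "3": 100_000_000,
    "X": 125_000_000,
}

PAR_END_DEFAULT = 6_650_000


@dataclass
class DepthModel:
    """Total depth at sample s, locus l ~ Poisson(scale_s * mean_l).

    ``scale_s`` is lognormal (median 1) capturing library-size variation
    between samples; ``mean_l`` is Gamma distributed capturing tag-level
    amplification differences.  Defaults give ~30x mean coverage with the
    strong inter-sample dispersion characteristic of multiplexed GBS
    libraries.
    """

    sample_sigma: float = 0.6
    locus_shape: float = 2.0
    locus_mean: float = 30.0

    def validate(self) -> None:
        if self.sample_sigma < 0 or self.locus_shape <= 0 or self.locus_mean < 0:
            raise InvalidConfigError("negative depth-model parameters")


@dataclass
class SimulationConfig:
    n_loci: int = 5000
    n_per_pop: int = 20
    n_replicate_samples: int = 7
    fst_target: float = 0.2
    ancestral_maf_beta: tuple[float, float] = (0.8, 0.8)
    divergence_regions: list[tuple[str, int, int, float]] = field(default_factory=list)
    depth_model: DepthModel = field(default_factory=DepthModel)
    error_rate: float = 0.01
    sex_ratio: float = 0.5
    par_end: int = PAR_END_DEFAULT
    chromosomes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROMOSOMES)
    )
    populations: tuple[str, str] = ("tame", "aggressive")
    seed: int = 0

    def validate(self) -> None:
        if self.n_loci <= 0:
            raise InvalidConfigError("n_loci must be positive")
        if self.n_per_pop <= 0:
            raise InvalidConfigError("n_per_pop must be positive")
        if not 0.0 < self.fst_target < 1.0:
            raise InvalidConfigError("fst_target must lie in (0, 1)")
        if not 0.0 <= self.error_rate < 0.25:
            raise InvalidConfigError("error_rate must lie in [0, 0.25)")
        if any(b <= 0 for b in self.ancestral_maf_beta):
            raise InvalidConfigError("beta shape parameters must be positive")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise InvalidConfigError("sex_ratio must lie in [0, 1]")
        if self.n_replicate_samples > 2 * self.n_per_pop:
            raise InvalidConfigError("more replicates than samples")
        self.depth_model.validate()
        seen: list[tuple[str, int, int]] = []
        for chrom, start, end, gap in self.divergence_regions:
            if chrom not in self.chromosomes:
                raise InvalidConfigError(f"region on undeclared chromosome {chrom}")
            if not 1 <= start <= end <= self.chromosomes[chrom]:
                raise InvalidConfigError("region outside chromosome bounds")
            if not 0.0 < gap <= 1.0:
                raise InvalidConfigError("frequency gap must lie in (0, 1]")
            for c, s, e in seen:
                if c == chrom and start <= e and s <= end:
                    raise InvalidConfigError("overlapping divergence regions")
            seen.append((chrom, start, end))


@dataclass
class TruthSet:
    """Ground-truth record accompanying a simulated allele-depth matrix."""

    loci: pd.DataFrame  # locus_id, chrom, pos, allele1, allele2, in_region
    ancestral_freqs: np.ndarray
    pop_freqs: dict[str, np.ndarray]  # allele2 frequency per locus
    genotypes: np.ndarray  # (n_loci, n_samples) codes HOM1/HET/HOM2
    manifest: SampleManifest
    regions: list[tuple[str, int, int, float]]
    par_end: int = PAR_END_DEFAULT

    @property
    def samples(self) -> list[str]:
        return list(self.manifest.table["sample"])


def _substream(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def draw_ancestral_freqs(n_loci: int, beta_params=(0.8, 0.8), seed: int = 0):
    """Founder allele-2 frequencies, Beta-distributed and clipped to (0,1)."""
    if n_loci <= 0:
        raise InvalidConfigError("n_loci must be positive")
    a, b = beta_params
    if a <= 0 or b <= 0:
        raise InvalidConfigError("beta shape parameters must be positive")
    rng = _substream(seed, 1)
    p = rng.beta(a, b, size=n_loci)
    return np.clip(p, 1e-6, 1.0 - 1e-6)


def drift_split(ancestral_freqs, fst_target: float, seed: int = 0):
    """Balding–Nichols drift of two daughter populations.

    Each population's per-locus frequency is drawn independently from
    Beta(p(1-F)/F, (1-p)(1-F)/F), whose mean is the ancestral p and whose
    variance F p (1-p) matches a Wright-style F_ST of ``fst_target``.
    """
    if not 0.0 < fst_target < 1.0:
        raise InvalidConfigError("fst_target must lie in (0, 1)")
    p = np.asarray(ancestral_freqs, dtype=float)
    rng = _substream(seed, 2)
    ratio = (1.0 - fst_target) / fst_target
    out = []
    for _ in range(2):
        q = rng.beta(np.maximum(p * ratio, 1e-12), np.maximum((1 - p) * ratio, 1e-12))
        out.append(np.clip(q, 0.0, 1.0))
    return out[0], out[1]


def place_loci(config: SimulationConfig) -> pd.DataFrame:
    """Uniformly place loci on the declared chromosomes (sorted within each)."""
    rng = _substream(config.seed, 3)
    names = list(config.chromosomes)
    lengths = np.array([config.chromosomes[c] for c in names], dtype=float)
    chrom_idx = rng.choice(len(names), size=config.n_loci, p=lengths / lengths.sum())
    pos = np.empty(config.n_loci, dtype=np.int64)
    for i, name in enumerate(names):
        mask = chrom_idx == i
        n = int(mask.sum())
        pos[mask] = np.sort(rng.integers(1, config.chromosomes[name] + 1, size=n))
    order = np.lexsort((pos, chrom_idx))
    bases = np.array(list("ACGT"))
    a1 = rng.integers(0, 4, size=config.n_loci)
    a2 = (a1 + rng.integers(1, 4, size=config.n_loci)) % 4
    loci = pd.DataFrame(
        {
            "chrom": np.array(names, dtype=object)[chrom_idx][order],
            "pos": pos[order],
            "allele1": bases[a1],
            "allele2": bases[a2],
        }
    )
    loci.insert(0, "locus_id", [f"L{i:06d}" for i in range(config.n_loci)])
    return loci


def plant_divergence_regions(pop_freqs, loci: pd.DataFrame, regions, seed: int = 0):
    """Force |p1 - p2| >= gap for loci inside each declared region.

    Frequencies outside the regions are untouched.  Inside a region the two
    populations are pushed toward opposite fixation: p1 drawn in
    [0, (1-gap)/2], p2 = p1 + gap + a uniform share of the remaining room,
    with the direction of divergence randomised per region.
    """
    p1, p2 = (np.array(p, dtype=float, copy=True) for p in pop_freqs)
    seen: list[tuple[str, int, int]] = []
    for chrom, start, end, gap in regions:
        for c, s, e in seen:
            if c == chrom and start <= e and s <= end:
                raise InvalidConfigError("overlapping divergence regions")
        seen.append((chrom, start, end))
    rng = _substream(seed, 4)
    for k, (chrom, start, end, gap) in enumerate(regions):
        mask = (
            (loci["chrom"] == chrom) & (loci["pos"] >= start) & (loci["pos"] <= end)
        ).to_numpy()
        n = int(mask.sum())
        if n == 0:
            continue
        low = rng.uniform(0.0, (1.0 - gap) / 2.0, size=n)
        high = low + gap + rng.uniform(0.0, 1.0, size=n) * (1.0 - gap - low - low)
        flip = rng.random() < 0.5
        p1[mask] = high if flip else low
        p2[mask] = low if flip else high
    return p1, p2


def _make_manifest(config: SimulationConfig) -> SampleManifest:
    rng = _substream(config.seed, 5)
    rows = []
    for pop in config.populations:
        n_male = int(round(config.sex_ratio * config.n_per_pop))
        for i in range(config.n_per_pop):
            rows.append(
                {
                    "sample": f"{pop[0].upper()}{i + 1:02d}",
                    "population": pop,
                    "sex": "M" if i < n_male else "F",
                    "replicate_of": "",
                }
            )
    base = pd.DataFrame(rows)
    dup_idx = rng.choice(len(base), size=config.n_replicate_samples, replace=False)
    for j, i in enumerate(sorted(dup_idx)):
        src = base.iloc[i]
        rows.append(
            {
                "sample": f"{src['sample']}r",
                "population": src["population"],
                "sex": src["sex"],
                "replicate_of": src["sample"],
            }
        )
    return SampleManifest(pd.DataFrame(rows))


def sample_cohort(pop_freqs, loci: pd.DataFrame, config: SimulationConfig) -> TruthSet:
    """Draw true genotypes: HWE within population; male X non-PAR haploid.

    Replicate samples copy the genotypes of the sample they duplicate.
    Hemizygous male calls on X beyond ``par_end`` are stored as the
    homozygote of the carried allele (never heterozygous).
    """
    config.validate()
    manifest = _make_manifest(config)
    rng = _substream(config.seed, 6)
    freqs = {pop: np.asarray(f, dtype=float) for pop, f in
             zip(config.populations, pop_freqs)}
    n_loci = len(loci)
    on_x = (loci["chrom"] == "X").to_numpy()
    non_par = on_x & (loci["pos"].to_numpy() > config.par_end)
    table = manifest.table
    genotypes = np.empty((n_loci, len(table)), dtype=np.int8)
    col_of = {s: i for i, s in enumerate(table["sample"])}
    for row in table.itertuples():
        j = col_of[row.sample]
        if row.replicate_of:
            genotypes[:, j] = genotypes[:, col_of[row.replicate_of]]
            continue
        p = freqs[row.population]
        g = rng.binomial(2, p).astype(np.int8)  # dosage of allele2 under HWE
        if row.sex == "M":
            hap = (rng.random(n_loci) < p).astype(np.int8) * 2
            g = np.where(non_par, hap, g)
        genotypes[:, j] = g
    loci = loci.copy()
    loci["in_region"] = False
    for chrom, start, end, _gap in config.divergence_regions:
        m = (loci["chrom"] == chrom) & (loci["pos"] >= start) & (loci["pos"] <= end)
        loci.loc[m, "in_region"] = True
    return TruthSet(
        loci=loci,
        ancestral_freqs=np.full(n_loci, np.nan),
        pop_freqs=freqs,
        genotypes=genotypes,
        manifest=manifest,
        regions=list(config.divergence_regions),
        par_end=config.par_end,
    )


def simulate_allele_depths(
    truth: TruthSet,
    depth_model: DepthModel | None = None,
    error_rate: float = 0.01,
    seed: int = 0,
) -> AlleleDepthMatrix:
    """Draw read depths per sample x locus under the shared read model.

    Total depth ~ Poisson(scale_s * mean_l); allele-1 reads are binomial
    with success probability 1-eps (hom allele1), 1/2 (het) or eps
    (hom allele2).  Replicates share genotypes but draw depths
    independently.
    """
    depth_model = depth_model or DepthModel()
    depth_model.validate()
    if not 0.0 <= error_rate < 0.25:
        raise InvalidConfigError("error_rate must lie in [0, 0.25)")
    rng = _substream(seed, 7)
    n_loci, n_samples = truth.genotypes.shape
    scale = rng.lognormal(mean=0.0, sigma=depth_model.sample_sigma, size=n_samples)
    mean_l = rng.gamma(
        depth_model.locus_shape,
        depth_model.locus_mean / depth_model.locus_shape,
        size=n_loci,
    )
    total = rng.poisson(np.outer(mean_l, scale))
    p1 = np.empty_like(truth.genotypes, dtype=float)
    p1[truth.genotypes == HOM1] = 1.0 - error_rate
    p1[truth.genotypes == HET] = 0.5
    p1[truth.genotypes == HOM2] = error_rate
    ad1 = rng.binomial(total, p1)
    return AlleleDepthMatrix(
        loci=truth.loci[["locus_id", "chrom", "pos", "allele1", "allele2"]].copy(),
        samples=truth.samples,
        ad1=ad1,
        ad2=total - ad1,
    )


def simulate(config: SimulationConfig):
    """End-to-end: config -> (AlleleDepthMatrix, TruthSet)."""
    config.validate()
    loci = place_loci(config)
    anc = draw_ancestral_freqs(config.n_loci, config.ancestral_maf_beta, config.seed)
    p1, p2 = drift_split(anc, config.fst_target, config.seed)
    p1, p2 = plant_divergence_regions(
        (p1, p2), loci, config.divergence_regions, config.seed
    )
    truth = sample_cohort((p1, p2), loci, config)
    truth.ancestral_freqs = anc
    depths = simulate_allele_depths(
        truth, config.depth_model, config.error_rate, config.seed
    )
    return depths, truth


def write_config(config: SimulationConfig, path) -> None:
    """Serialise a SimulationConfig as a YAML key-value file."""
    import yaml

    payload = {
        "n_loci": config.n_loci,
        "n_per_pop": config.n_per_pop,
        "n_replicate_samples": config.n_replicate_samples,
        "fst_target": config.fst_target,
        "ancestral_maf_beta": list(config.ancestral_maf_beta),
        "divergence_regions": [list(r) for r in config.divergence_regions],
        "depth_model": {
            "sample_sigma": config.depth_model.sample_sigma,
            "locus_shape": config.depth_model.locus_shape,
            "locus_mean": config.depth_model.locus_mean,
        },
        "error_rate": config.error_rate,
        "sex_ratio": config.sex_ratio,
        "par_end": config.par_end,
        "chromosomes": dict(config.chromosomes),
        "populations": list(config.populations),
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_config(path) -> SimulationConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["ancestral_maf_beta"] = tuple(raw["ancestral_maf_beta"])
    raw["divergence_regions"] = [tuple(r) for r in raw.get("divergence_regions", [])]
    raw["populations"] = tuple(raw["populations"])
    raw["depth_model"] = DepthModel(**raw["depth_model"])
    cfg = SimulationConfig(**raw)
    cfg.validate()
    return cfg


def wright_fisher_cohort(
    ne: int,
    generations: int,
    n_loci: int,
    n_chromosomes: int = 12,
    seed: int = 0,
):
    """Discrete Wright–Fisher drift of unlinked loci; returns a GenotypeMatrix.

    A population of ``ne`` diploids mates randomly for ``generations``
    generations (each offspring draws two parents uniformly; every locus
    transmits one uniformly chosen allele per parent, i.e. free
    recombination).  Founder frequencies are uniform on (0.2, 0.8).  The
    whole final population is returned as called genotypes with dummy
    depth/quality fields — the parameter-recovery target for the LD-based
    Ne estimator, which only reads genotypes and chromosome labels.
    """
    from .core import GenotypeMatrix

    if ne < 2 or generations < 0 or n_loci < 2:
        raise InvalidConfigError("degenerate Wright-Fisher configuration")
    rng = _substream(seed, 8)
    p0 = rng.uniform(0.2, 0.8, n_loci)
    g = (rng.random((ne, n_loci, 2)) < p0[None, :, None]).astype(np.int8)
    ii = np.arange(ne)[:, None]
    jj = np.arange(n_loci)[None, :]
    for _ in range(generations):
        mothers = rng.integers(0, ne, ne)
        fathers = rng.integers(0, ne, ne)
        a = g[mothers][ii, jj, rng.integers(0, 2, (ne, n_loci))]
        b = g[fathers][ii, jj, rng.integers(0, 2, (ne, n_loci))]
        g = np.stack([a, b], axis=-1)
    gt = g.sum(axis=-1).T.astype(np.int8)  # (n_loci, ne)
    per = int(np.ceil(n_loci / n_chromosomes))
    chroms = np.array(
        [f"WF{k + 1}" for k in range(n_chromosomes) for _ in range(per)]
    )[:n_loci]
    pos = np.tile(np.arange(1, per + 1) * 1000, n_chromosomes)[:n_loci]
    loci = pd.DataFrame(
        {
            "locus_id": [f"W{i:05d}" for i in range(n_loci)],
            "chrom": chroms,
            "pos": pos,
            "allele1": "A",
            "allele2": "C",
        }
    )
    z = np.zeros_like(gt, dtype=np.int64)
    return GenotypeMatrix(
        loci=loci,
        samples=[f"wf{i:03d}" for i in range(ne)],
        gt=gt,
        ad1=z,
        ad2=z,
        gq=np.full_like(z, 99),
        pl=np.zeros(gt.shape + (3,), dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# synthetic dog-like -> fox-like comparative map


def make_synthetic_comparative_map(config: SimulationConfig, anchor_spacing: int = 10_000_000):
    """Anchor table + built map covering the simulated target genome.

    Source ("dog-like") chromosomes are laid over the target ("fox-like")
    chromosomes of ``config``; one source chromosome (D2) is split across
    two targets so the boundary-interval duplication rule is exercised, and
    an unplaceable source ("Un") is declared.  Returns
    ``(anchor table, ComparativeMap, source_lengths)``.
    """
    targets = [c for c in config.chromosomes]
    if len(targets) < 2:
        raise InvalidConfigError("need at least two target chromosomes")
    split_a, split_b = targets[0], targets[1]
    rest = targets[2:]
    len_a = config.chromosomes[split_a]
    len_b = config.chromosomes[split_b]
    rows = []
    # D2 carries split_a then split_b, split at len_a
    src_len_d2 = len_a + len_b + anchor_spacing
    for pos in range(1, len_a + 1, anchor_spacing):
        rows.append(("D2", pos, split_a))
    for pos in range(len_a + anchor_spacing, src_len_d2 + 1, anchor_spacing):
        rows.append(("D2", pos, split_b))
    source_lengths = {"D2": src_len_d2}
    for k, tgt in enumerate(rest):
        name = f"D{k + 3}"
        for pos in range(1, config.chromosomes[tgt] + 1, anchor_spacing):
            rows.append((name, pos, tgt))
        source_lengths[name] = config.chromosomes[tgt]
    anchors = pd.DataFrame(rows, columns=["source_chrom", "source_pos", "target_chrom"])
    cmap = build_map(anchors, source_lengths, unplaceable={"Un"})
    return anchors, cmap, source_lengths


def source_coordinates(loci: pd.DataFrame, cmap: ComparativeMap) -> pd.DataFrame:
    """Inverse-lift target (fox-like) loci onto source (dog-like) coordinates.

    Target positions are unique within the map's target space even across
    duplicated boundary intervals, so the inverse is single-valued.  Loci on
    target chromosomes the map does not cover keep chrom "Un", pos 0.
    """
    src_chrom = np.full(len(loci), "Un", dtype=object)
    src_pos = np.zeros(len(loci), dtype=np.int64)
    for i, (chrom, pos) in enumerate(zip(loci["chrom"], loci["pos"])):
        for block in cmap.blocks:
            if block.target_chrom != chrom:
                continue
            t_start = block.source_start + block.target_offset
            t_end = block.source_end + block.target_offset
            if t_start <= pos <= t_end:
                src_chrom[i] = block.source_chrom
                src_pos[i] = pos - block.target_offset
                break
    out = loci.copy()
    out["source_chrom"] = src_chrom
    out["source_pos"] = src_pos
    return out
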
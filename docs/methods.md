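# Methods

`foxgbs` re-implements, as a tested pipeline, a reduced-representation
(GBS) population-genetic analysis of two selectively bred fox strains: a
"tame" and an "aggressive" line maintained separately for decades and
genotyped at restriction-site tags.  Because no raw data for the original
cohort are publicly deposited, the pipeline is exercised end-to-end on
synthetic cohorts with full ground truth, plus on the published table of
68 significant SNPs, which is shipped as a packaged fixture.

## Read model and genotype calling

At a biallelic site with alleles (a, b) and per-read error rate ε
(default 0.01, typical of short-read base calling):

* hom `aa`: each read is `a` with probability 1 − ε, `b` with probability ε
  (errors land on the other modelled allele);
* het `ab`: each read is `a` or `b` with probability ½.

Reads are independent, so allele depths (n₁, n₂) give binomial likelihood
kernels; the shared multinomial coefficient cancels in the Phred-scaled,
min-normalised PLs, PL_g = round(−10·log₁₀(L_g / max L)).  GT is the
genotype with PL 0 (ties resolved hom-ref < het < hom-alt); GQ is the
second-smallest PL capped at 99; zero depth is a missing call.  The exact
placement of the ε mass (onto the other modelled allele rather than all
three alternatives) is a deliberate choice: the depth simulator uses the
same model, which makes calling error rates directly checkable against
simulated truth.  A consequence worth knowing: a homozygous call needs
≈33 unanimous reads to reach GQ 98 (≈3 Phred per read), so the stringent
tier retains only consistently deep loci.

Technical replicates are merged by summing allele depths; the merged call
is heterozygous iff each allele carries more than 1 − het_freq of the
summed depth (het_freq = 0.8, i.e. homozygous when the majority allele
holds ≥ 80%).  Duplicate records at one position are merged by summing
per-sample depths, ranking alleles by total depth, keeping at most three,
and re-calling from the summed depths; records disagreeing on the
reference allele are flagged and left unmerged.

## Filter tiers

First tier, per SNP over non-missing calls: call rate ≥ 0.5; MAF > 0.025
(strict); exactly two alleles; mean depth over called samples ≤ 150;
heterozygous-individual fraction < 0.60 on autosomes and the X
pseudoautosomal region (PAR, 1–6,650,000 bp), and ≤ 0.30 on X beyond the
PAR (excess X heterozygosity in a mixed-sex panel marks artifacts — in a
half-male panel true X het tops out near 30% even at MAF 0.5, so more
indicates error).  The 60% boundary is treated as strict and the X rule
as "remove when above 30%"; both readings of the published criteria are
ambiguous at the boundary, and the chosen conventions are exercised by
boundary tests.  Attrition is attributed to the first failing rule in the
order above, so retained + Σ per-rule removals = input SNPs.

Second tier: calls with GQ < 98 are set missing, then every SNP with any
missing call is dropped, leaving a matrix with zero missingness.

## Synthetic cohorts

The generator emulates the study design rather than any particular locus:

* **Genome** — three autosome-like chromosomes (150, 120, 100 Mb) plus an
  X (125 Mb) with PAR at 1–6.65 Mb; loci placed uniformly,
  length-proportionally.
* **Frequencies** — founder allele frequencies Beta(0.8, 0.8) (a U-ish
  shape typical of SNP panels); the two strains drift independently via
  Balding–Nichols sampling, Beta(p(1−F)/F, (1−p)(1−F)/F), whose variance
  F·p(1−p) ties the parameter F directly to Wright-style F_ST.  The
  default F = 0.2 matches expectations for two closed lines separated for
  ~40 generations at effective sizes near 10²; a generational
  Wright–Fisher split is deliberately not simulated for the drift stage —
  the endpoint distribution is what the analyses consume.
* **Planted divergence** — declared regions overwrite drifted frequencies
  with a deterministic between-strain gap (≥ 0.9 by default), emulating a
  sweep-like region approaching fixation for different alleles; endpoint
  divergence is all the scan measures, so selection dynamics are not
  modelled.
* **Cohort** — 20 diploids per strain (sex ratio ½), HWE within strain;
  male X beyond the PAR is drawn haploid and stored as the homozygote of
  the carried allele; 7 replicate samples duplicate genotypes but draw
  depths independently.
* **Depths** — total depth ~ Poisson(scale_s · mean_l) with lognormal
  per-sample scale (σ = 0.6) and Gamma per-locus mean (shape 2, mean 30×):
  ~30× coverage with the strong library-size dispersion characteristic of
  multiplexed GBS.  The true per-locus depth law of the original libraries
  is unpublished; these defaults are plausible, not calibrated.
* **Seeds** — one master seed; each stage draws from a deterministically
  derived substream, so a config is byte-reproducible.

What the generator does **not** emulate: PCR duplicates, restriction-site
polymorphism dropout (depth 0 is the only dropout mode), base-quality
strings, linked-locus haplotype structure within chromosomes (background
loci are exchangeable given their frequencies), or reference-alignment
error.  Passing tests therefore validate the statistical machinery, not
robustness to those artefacts.

A companion Wright–Fisher generator (random mating, unlinked loci, free
recombination) provides the parameter-recovery target for the LD-based Ne
estimator, where genuine drift-generated associations between individuals
are required.

## Comparative map and lifting

Anchor markers of known source-genome position and known target
chromosome are sorted per source chromosome; runs with one target merge
into blocks; at a run boundary the inter-anchor interval is emitted into
the blocks of **both** targets, so markers far apart in the target genome
cannot appear spuriously close.  Target coordinates accumulate block by
block (sorted by source chromosome then start, making construction
independent of anchor row order), so distances within a block are
preserved exactly — the property the LD distance bins rely on.  Lifting
returns 0 (unplaceable), 1, or 2 (split-boundary) locations; downstream
per-chromosome analyses use both copies.  Inverted segments are supported
by an orientation flag but default to forward, as no inversion handling
is described for the original map.

## Diversity, LD, Ne

Observed SNP heterozygosity is the heterozygote fraction among called
individuals; expected heterozygosity uses the small-sample unbiased form
(2N/(2N−1))·2p̂q̂ — the expected heterozygote count divided by N.  Strain
summaries average over all SNPs including fixed ones.

LD is the squared Pearson correlation of 0/1/2 dosages over jointly
called individuals (composite LD; no phasing).  Decay is summarised in 14
distance bins spanning 1 bp–210 Mb (edges 1 kb, 5 kb, 10 kb, 50 kb,
100 kb, 500 kb, 1 Mb, 5 Mb, 10 Mb, 20 Mb, 50 Mb, 75 Mb, 100 Mb, 210 Mb;
the original bin table is unpublished, so these are configurable
defaults).  The cross-chromosome null — E[r²] ≈ 1/n for independent
loci — doubles as a sanity check on the "unlinked" assumption.

Ne uses the LD (drift) method: mean dosage-r² over cross-chromosome pairs
only (a clean unlinked set; including within-chromosome pairs is a known
divergence from the reference implementation), minus the expected
sampling contribution at harmonic-mean sample size S (1/S + 3.19/S² for
S ≥ 30, else 0.0018 + 0.907/S + 4.44/S²), inverted through the
bias-adjusted random-mating expectation
N̂e = (1/3 + √(1/9 − 2.76·r̂²′))/(2·r̂²′) (S ≥ 30 form).  Non-positive
corrected r²′ flags an unbounded estimate.  The 95% CI is a delete-one
jackknife over pair r² values — computationally exact here because the
point estimate is a smooth function of the pair mean.

## Divergence scan

Per SNP, a 1-df chi-square on the 2×2 allele-count table over called
genotypes (no continuity correction); zero-margin tables are untestable
(p = 1).  Bonferroni adjustment multiplies by the number of SNPs tested;
the significance cutoff defaults to adjusted p < 10⁻⁶ (the published
account states 10⁻⁷ in one place but draws its significance line at
−log₁₀ = 6, and every listed SNP has adjusted p < 10⁻⁶; the cutoff is
configurable).  Significant SNPs on one chromosome chain when consecutive
gaps are ≤ 2 Mb **inclusive** — the published distance column breaks a
chain at a 2,040,665 bp gap, consistent with inclusive linking; chains of
≥ 2 SNPs are clusters.  Windowed differentiation sums Weir–Cockerham
(1984) site components a (among-population), b (among-individual) and c
(within-individual) over 1 Mb windows stepped by 500 kb (half-open,
anchored at 1) and reports Σa/Σ(a+b+c) — the ratio of sums, never the
mean of per-site ratios, a distinction a regression test pins down.
Windows at weighted F_ST ≥ 0.5 are flagged; gene proximity uses a ±50 kb
inclusive flank.

## Scenario sizes and numerical conventions

The packaged analyses and acceptance checks run at 1,500–5,000 loci and
20 + 20 samples — the cohort size of the original design with a locus
count chosen to keep desk-scale runs fast while leaving dozens of loci in
a planted 4 Mb region.  The scan-specificity scenario uses background
F = 0.05 with one planted region (gap 0.9): at the default F = 0.2,
drift alone fixes alternative alleles at some background loci (exactly as
in the real strains), so a zero-false-positive expectation is only
meaningful against a quieter background.  Tolerances mirror the
statistical noise of each estimate: realized F_ST within ±0.05 of target
(3-seed median), Ne within a factor of two of truth, planted-region
recovery in ≥ 9/10 seeds.

Degenerate inputs are handled explicitly rather than by exception where
the field's tools do the same: all-missing SNPs fail filters with
undefined stats; monomorphic pairs are skipped and counted in LD
summaries; PL ties resolve in fixed genotype order with GQ 0.
Coordinates are 1-based inclusive everywhere except window intervals
(half-open) and BED export.

## Known limitations

* The likelihood uses depths only; per-base qualities are not modelled.
* Background loci are exchangeable given their frequencies, so LD decay
  within chromosomes is flat in simulated data except in planted/block
  constructions; decay-shape tests use explicit block structure.
* The Ne jackknife treats pairs as independent; overlapping pairs share
  loci, so the CI is mildly anti-conservative.
* The merged-replicate het rule and the X het boundary follow one reading
  of under-documented conventions; both are isolated behind single
  functions and covered by boundary tests.
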
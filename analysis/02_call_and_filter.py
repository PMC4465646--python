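#!/usr/bin/env python
"""Call genotypes from allele depths and produce the two filter tiers.

Reads the simulated allele depths from 01, calls genotypes under the
shared read model (eps = 0.01), then applies the first-tier filter
(call rate >= 0.5, MAF > 0.025, biallelic, mean depth <= 150, het-fraction
rules with the X PAR convention) and the stringent tier (GQ >= 98,
no missing data).  Writes the filtered VCFs to scratch/ and the attrition
table to results/.
"""

from pathlib import Path

import pandas as pd

from foxgbs import filtering, gbs_io, genotyping

SCRATCH = Path("scratch/pipeline")
RESULTS = Path("results")


def main() -> None:
    depths = gbs_io.read_allele_depths(SCRATCH / "allele_depths.tsv")
    gm = genotyping.call_genotypes(depths, error_rate=0.01)
    filt, report = filtering.apply_filtered(gm)
    strict = filtering.apply_stringent(filt)

    gbs_io.write_vcf(filt, SCRATCH / "filtered.vcf")
    gbs_io.write_vcf(strict, SCRATCH / "stringent.vcf")
    pd.DataFrame([report]).to_csv(RESULTS / "filter_attrition.tsv", sep="\t", index=False)

    print(f"called {gm.n_loci} loci; missing-call fraction "
          f"{(~gm.is_called).mean():.3f}")
    print("attrition by first failing rule:",
          {k: v for k, v in report.items() if k in filtering.RULES})
    print(f"filtered set: {filt.n_loci} SNPs; stringent set: {strict.n_loci} SNPs")
    print(f"stringent missingness: {(strict.gt == -1).mean():.0%} (by construction 0)")


if __name__ == "__main__":
    main()
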
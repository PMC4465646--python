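"""Readers/writers and read-level QC for the pipeline's formats.

Handles: FASTQ demultiplexing with the barcode / cut-site-remnant / N
filter applied before tag counting; tag tallies; the TSV allele-depth and
manifest exchange formats; VCF 4.2 with FORMAT GT:AD:DP:GQ:PL (written
directly, read back through cyvcf2); and the packaged table of the 68
significant SNPs used by the clustering reproduction.

Coordinates in all tabular formats are 1-based inclusive.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import MISSING, AlleleDepthMatrix, GenotypeMatrix, InvalidConfigError, SampleManifest


# ---------------------------------------------------------------------------
# demultiplexing / QC

@dataclass
class BarcodeSet:
    """Sample barcodes plus the expected cut-site remnant.

    Barcodes must be unique and prefix-free (no barcode may be a prefix of
    another), so the longest-match rule is unambiguous.
    """

    barcodes: dict[str, str]  # sample id -> barcode sequence
    remnant: str = "TGCAT"  # EcoT22I-style cut-site remnant
    tag_length: int = 64

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise InvalidConfigError("empty barcode set")
        seqs = list(self.barcodes.values())
        if len(set(seqs)) != len(seqs):
            raise InvalidConfigError("duplicate barcode sequences")
        for x in seqs:
            for y in seqs:
                if x != y and y.startswith(x):
                    raise InvalidConfigError(f"barcode {x} is a prefix of {y}")


def demultiplex_and_qc(reads, barcode_set: BarcodeSet):
    """Assign reads to samples and apply the read-level QC filter.

    A read is kept iff a barcode matches exactly at the 5' end, the
    cut-site remnant immediately follows it, and the retained tag (remnant
    onward, trimmed to ``tag_length``) contains no 'N'.  Returns
    ``(tags per sample, qc report)``; the report counts kept reads and
    discards by reason ("barcode", "remnant", "N"), an exhaustive and
    exclusive partition of the input.
    """
    by_barcode = sorted(
        ((seq, sample) for sample, seq in barcode_set.barcodes.items()),
        key=lambda t: -len(t[0]),
    )
    tags: dict[str, list[str]] = {s: [] for s in barcode_set.barcodes}
    report = {"kept": 0, "barcode": 0, "remnant": 0, "N": 0, "total": 0}
    L = barcode_set.tag_length
    for read in reads:
        read = str(read)
        report["total"] += 1
        hit = next((t for t in by_barcode if read.startswith(t[0])), None)
        if hit is None:
            report["barcode"] += 1
            continue
        barcode, sample = hit
        rest = read[len(barcode):]
        if not rest.startswith(barcode_set.remnant):
            report["remnant"] += 1
            continue
        tag = rest[:L]
        if "N" in tag:
            report["N"] += 1
            continue
        tags[sample].append(tag)
        report["kept"] += 1
    return tags, report


def read_fastq_sequences(path):
    """Yield read sequences (uppercase strings) from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield str(rec.seq).upper()


def tally_tags(tags_per_sample: dict[str, list[str]], min_taxa_count: int = 1):
    """Tag -> per-sample counts, keeping tags seen in >= min_taxa_count samples."""
    lengths = {len(t) for tags in tags_per_sample.values() for t in tags}
    if len(lengths) > 1:
        raise ValueError(f"non-uniform tag lengths: {sorted(lengths)}")
    table: dict[str, dict[str, int]] = {}
    for sample, tags in tags_per_sample.items():
        for t in tags:
            slot = table.setdefault(t, {})
            slot[sample] = slot.get(sample, 0) + 1
    return {
        tag: counts
        for tag, counts in table.items()
        if len(counts) >= min_taxa_count
    }


def alignment_summary(n_single: int, n_multiple: int, n_unaligned: int) -> dict:
    """Fractions of tags by alignment outcome, in percent to 1 decimal."""
    total = n_single + n_multiple + n_unaligned
    if total <= 0:
        raise ValueError("no tags")
    return {
        "total": total,
        "pct_single": round(100.0 * n_single / total, 1),
        "pct_multiple": round(100.0 * n_multiple / total, 1),
        "pct_unaligned": round(100.0 * n_unaligned / total, 1),
    }


# ---------------------------------------------------------------------------
# TSV formats

def write_allele_depths(adm: AlleleDepthMatrix, path) -> None:
    """TSV: locus_id, chrom, pos, allele1, allele2, then per-sample "n1,n2"."""
    df = adm.loci.copy()
    for j, sample in enumerate(adm.samples):
        df[sample] = [f"{a},{b}" for a, b in zip(adm.ad1[:, j], adm.ad2[:, j])]
    df.to_csv(path, sep="\t", index=False)


def read_allele_depths(path) -> AlleleDepthMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["locus_id", "chrom", "pos", "allele1", "allele2"]
    samples = [c for c in df.columns if c not in meta_cols]
    pairs = np.array(
        [df[s].str.split(",", expand=True).to_numpy(dtype=np.int64) for s in samples]
    )  # (S, L, 2)
    return AlleleDepthMatrix(
        loci=df[meta_cols],
        samples=samples,
        ad1=pairs[:, :, 0].T,
        ad2=pairs[:, :, 1].T,
    )


def write_manifest(manifest: SampleManifest, path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> SampleManifest:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return SampleManifest(df)


# ---------------------------------------------------------------------------
# VCF 4.2

# dog-style renaming dialect: applied only at the I/O boundary
DOG_DIALECT = {"X": "39", "M": "40"}


def _rename(chrom: str, dialect: dict[str, str] | None) -> str:
    return dialect.get(chrom, chrom) if dialect else chrom


def write_vcf(gm: GenotypeMatrix, path, dialect: dict[str, str] | None = None) -> None:
    """Write a GenotypeMatrix as VCF 4.2 with FORMAT GT:AD:DP:GQ:PL."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">\n')
        for chrom in pd.unique(gm.loci["chrom"]):
            fh.write(f"##contig=<ID={_rename(str(chrom), dialect)}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i, locus in enumerate(gm.loci.itertuples()):
            fields = [
                _rename(str(locus.chrom), dialect),
                str(locus.pos),
                str(locus.locus_id),
                str(locus.allele1),
                str(locus.allele2),
                ".",
                "PASS",
                ".",
                "GT:AD:DP:GQ:PL",
            ]
            for j in range(gm.n_samples):
                gt = gt_strings[int(gm.gt[i, j])]
                ad = f"{gm.ad1[i, j]},{gm.ad2[i, j]}"
                dp = gm.ad1[i, j] + gm.ad2[i, j]
                pl = ",".join(str(int(x)) for x in gm.pl[i, j])
                fields.append(f"{gt}:{ad}:{dp}:{gm.gq[i, j]}:{pl}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF with FORMAT GT:AD:DP:GQ:PL back into a GenotypeMatrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci_rows = []
    gt_rows, ad1_rows, ad2_rows, gq_rows, pl_rows = [], [], [], [], []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        loci_rows.append(
            {
                "locus_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "allele1": var.REF,
                "allele2": alt,
            }
        )
        gts = var.genotype.array()  # (S, 3): a1, a2, phased
        a1, a2 = gts[:, 0], gts[:, 1]
        gt = np.where((a1 < 0) | (a2 < 0), MISSING, a1 + a2).astype(np.int8)
        ad = var.format("AD")
        gq = var.format("GQ")
        pl = var.format("PL")
        gt_rows.append(gt)
        ad1_rows.append(ad[:, 0])
        ad2_rows.append(ad[:, 1])
        gq_rows.append(gq.reshape(-1))
        pl_rows.append(pl)
    vcf.close()
    n = len(loci_rows)
    loci = pd.DataFrame(
        loci_rows, columns=["locus_id", "chrom", "pos", "allele1", "allele2"]
    )
    if n == 0:
        shape = (0, len(samples))
        z = np.zeros(shape, dtype=np.int64)
        return GenotypeMatrix(
            loci=loci,
            samples=samples,
            gt=z.astype(np.int8),
            ad1=z,
            ad2=z,
            gq=z,
            pl=np.zeros(shape + (3,), dtype=np.int64),
        )
    return GenotypeMatrix(
        loci=loci,
        samples=samples,
        gt=np.vstack(gt_rows),
        ad1=np.vstack(ad1_rows).astype(np.int64),
        ad2=np.vstack(ad2_rows).astype(np.int64),
        gq=np.vstack(gq_rows).astype(np.int64),
        pl=np.stack(pl_rows).astype(np.int64),
    )


# ---------------------------------------------------------------------------
# packaged fixtures

def load_significant_snp_table() -> pd.DataFrame:
    """The 68 SNPs with significant between-strain frequency differences.

    Columns: snp, cfa (dog chromosome), cfa_pos, vvu (fox chromosome),
    vvu_pos (inferred), freq_diff, p_adj, cluster (printed cluster label,
    NaN for isolated SNPs).
    """
    ref = importlib.resources.files("foxgbs.data") / "table2_significant_snps.tsv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", dtype={"cfa": str, "vvu": str})
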
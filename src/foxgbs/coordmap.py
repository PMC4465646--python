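"""Comparative-map construction and cross-species coordinate lifting.

A source ("dog-like") genome is carved into synteny blocks assigned to
target ("fox-like") chromosomes by anchor markers of known location in the
source genome and known target chromosome.  Where two consecutive anchors
on one source chromosome disagree on the target, the whole inter-anchor
interval is assigned to BOTH targets — a deliberate duplication that keeps
markers that may be far apart in the target genome from appearing close
together.  Target coordinates accumulate block by block along each target
chromosome, so distances within a block are preserved exactly.

Coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANCHOR_COLUMNS = ["source_chrom", "source_pos", "target_chrom"]
MAP_COLUMNS = [
    "source_chrom",
    "source_start",
    "source_end",
    "target_chrom",
    "target_offset",
    "orientation",
]


@dataclass(frozen=True)
class SyntenyBlock:
    source_chrom: str
    source_start: int  # 1-based inclusive
    source_end: int
    target_chrom: str
    target_offset: int  # target_pos = source_pos + target_offset (forward)
    orientation: int = 1  # +1 forward, -1 reverse

    def __post_init__(self):
        if self.source_start > self.source_end:
            raise ValueError("block start exceeds end")
        if self.orientation not in (1, -1):
            raise ValueError("orientation must be +1 or -1")

    def covers(self, pos: int) -> bool:
        return self.source_start <= pos <= self.source_end

    def lift_pos(self, pos: int) -> int:
        if self.orientation == 1:
            return pos + self.target_offset
        # reverse: source_end maps to the block's first target position
        return (self.source_end - pos) + (self.source_start + self.target_offset)


@dataclass
class ComparativeMap:
    blocks: list[SyntenyBlock]
    unplaceable: set[str] = field(default_factory=set)

    def blocks_on_source(self, chrom: str) -> list[SyntenyBlock]:
        return sorted(
            (b for b in self.blocks if b.source_chrom == chrom),
            key=lambda b: (b.source_start, b.target_chrom),
        )

    def target_chromosomes(self) -> list[str]:
        return sorted({b.target_chrom for b in self.blocks})

    def target_length(self, chrom: str) -> int:
        return max(
            b.source_end + b.target_offset
            for b in self.blocks
            if b.target_chrom == chrom and b.orientation == 1
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    b.source_chrom,
                    b.source_start,
                    b.source_end,
                    b.target_chrom,
                    b.target_offset,
                    b.orientation,
                )
                for b in self.blocks
            ],
            columns=MAP_COLUMNS,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, unplaceable=()) -> "ComparativeMap":
        blocks = [
            SyntenyBlock(
                str(r.source_chrom),
                int(r.source_start),
                int(r.source_end),
                str(r.target_chrom),
                int(r.target_offset),
                int(r.orientation),
            )
            for r in frame.itertuples()
        ]
        return cls(blocks=blocks, unplaceable=set(unplaceable))


def build_map(
    anchors: pd.DataFrame,
    source_lengths: dict[str, int],
    unplaceable=("Un",),
) -> ComparativeMap:
    """Build a comparative map from an anchor-marker table.

    ``anchors`` needs columns source_chrom, source_pos, target_chrom.  The
    result is independent of the input row order: anchors are sorted by
    (source_chrom, source_pos) and consecutive same-target runs merged into
    one block.  The first block of a source chromosome starts at 1 and the
    last ends at the declared source length.  At a run boundary the interval
    between the flanking anchors is emitted in the blocks of BOTH targets.
    Target offsets accumulate along each target chromosome in sorted
    (source_chrom, source_start) order.

    Source chromosomes declared in ``source_lengths`` but absent from the
    anchor table are recorded as unplaceable.
    """
    missing = [c for c in ANCHOR_COLUMNS if c not in anchors.columns]
    if missing:
        raise ValueError(f"anchor table lacks columns: {missing}")
    unplace = set(unplaceable)
    anchors = anchors.sort_values(["source_chrom", "source_pos"]).reset_index(drop=True)

    raw: list[tuple[str, int, int, str]] = []  # (src, start, end, target)
    for chrom, grp in anchors.groupby("source_chrom", sort=True):
        length = source_lengths.get(chrom)
        if length is None:
            length = int(grp["source_pos"].max())
        # collapse anchors into runs of identical target
        runs: list[tuple[str, int, int]] = []  # (target, first_anchor, last_anchor)
        for r in grp.itertuples():
            tgt, pos = str(r.target_chrom), int(r.source_pos)
            if runs and runs[-1][0] == tgt:
                runs[-1] = (tgt, runs[-1][1], pos)
            else:
                runs.append((tgt, pos, pos))
        for j, (tgt, first, last) in enumerate(runs):
            start = 1 if j == 0 else runs[j - 1][2]  # previous run's last anchor
            end = length if j == len(runs) - 1 else runs[j + 1][1]
            raw.append((str(chrom), start, end, tgt))
    for chrom in source_lengths:
        if chrom not in set(anchors["source_chrom"]):
            unplace.add(chrom)

    # cumulative offsets along each target chromosome
    blocks: list[SyntenyBlock] = []
    by_target: dict[str, list[tuple[str, int, int, str]]] = {}
    for rec in raw:
        by_target.setdefault(rec[3], []).append(rec)
    for tgt in sorted(by_target):
        cum = 0
        for src, start, end, _ in sorted(by_target[tgt], key=lambda r: (r[0], r[1])):
            offset = cum - (start - 1)
            blocks.append(SyntenyBlock(src, start, end, tgt, offset))
            cum += end - start + 1
    blocks.sort(key=lambda b: (b.source_chrom, b.source_start, b.target_chrom))
    return ComparativeMap(blocks=blocks, unplaceable=unplace)


def lift(
    source_chrom: str, pos: int, cmap: ComparativeMap
) -> list[tuple[str, int]]:
    """Target locations of one source coordinate.

    Usually a single (chrom, pos) pair; two in duplicated boundary
    intervals; empty for unplaceable sources or uncovered coordinates.
    """
    if pos < 1:
        raise ValueError("positions are 1-based")
    if source_chrom in cmap.unplaceable:
        return []
    on_chrom = cmap.blocks_on_source(source_chrom)
    if not on_chrom:
        return []
    if pos > max(b.source_end for b in on_chrom):
        raise ValueError(f"position {pos} beyond declared end of {source_chrom}")
    return [(b.target_chrom, b.lift_pos(pos)) for b in on_chrom if b.covers(pos)]


def lift_matrix(records: pd.DataFrame, cmap: ComparativeMap):
    """Annotate SNP records carrying source coordinates with target ones.

    ``records`` needs columns source_chrom, source_pos; any other columns
    are carried through.  Each input row yields 0, 1 or 2 output rows with
    columns target_chrom, target_pos appended.  Returns
    ``(lifted frame, report)`` where the report counts mapped / unmapped
    records and the unmapped fraction.
    """
    for col in ("source_chrom", "source_pos"):
        if col not in records.columns:
            raise ValueError(f"records lack column {col}")
    rows = []
    n_unmapped = 0
    for i, rec in enumerate(records.itertuples(index=False)):
        hits = lift(str(rec.source_chrom), int(rec.source_pos), cmap)
        if not hits:
            n_unmapped += 1
            continue
        base = rec._asdict()
        for tgt_chrom, tgt_pos in hits:
            rows.append({**base, "target_chrom": tgt_chrom, "target_pos": tgt_pos})
    lifted = pd.DataFrame(
        rows, columns=list(records.columns) + ["target_chrom", "target_pos"]
    )
    n = len(records)
    report = {
        "n_records": n,
        "n_unmapped": n_unmapped,
        "unmapped_fraction": n_unmapped / n if n else 0.0,
    }
    return lifted, report


def read_anchor_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"source_chrom": str, "target_chrom": str})


def write_map(cmap: ComparativeMap, path) -> None:
    cmap.to_frame().to_csv(path, sep="\t", index=False)


def read_map(path, unplaceable=("Un",)) -> ComparativeMap:
    return ComparativeMap.from_frame(pd.read_csv(path, sep="\t", dtype={"source_chrom": str, "target_chrom": str}), unplaceable)
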
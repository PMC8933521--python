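"""Site-level read-count matrices (pileups) and their TSV dialect.

A PileupMatrix is the per-sample summary the caller consumes: for every
position of every contig, counts of reads supporting A, C, G, T, an insertion
or a deletion.  Site depth is defined as A+C+G+T+DEL (a deleted read still
spans the site; an inserted allele does not add a spanning read).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BASES, GenomeAssembly

COLUMNS = ("A", "C", "G", "T", "INS", "DEL")
COL_INDEX = {c: i for i, c in enumerate(COLUMNS)}


@dataclass
class PileupMatrix:
    """Per-contig (L, 6) count arrays plus the reference sequence."""

    sample_id: str
    counts: dict[str, np.ndarray]
    ref: dict[str, str]

    def __post_init__(self) -> None:
        for contig, arr in self.counts.items():
            if arr.shape != (len(self.ref[contig]), len(COLUMNS)):
                raise ValueError(
                    f"{contig}: counts shape {arr.shape} inconsistent with reference"
                )
            if (arr < 0).any():
                raise ValueError(f"{contig}: negative counts")

    def depth(self, contig: str) -> np.ndarray:
        """Spanning-read depth per site: A+C+G+T+DEL."""
        arr = self.counts[contig]
        return arr[:, :4].sum(axis=1) + arr[:, COL_INDEX["DEL"]]

    def site(self, contig: str, pos: int) -> dict[str, int]:
        """Counts at 1-based `pos` as a column->count mapping."""
        row = self.counts[contig][pos - 1]
        return {c: int(row[i] ) for i, c in enumerate(COLUMNS)}

    def covers(self, contig: str, pos: int) -> bool:
        if contig not in self.counts:
            return False
        if not 1 <= pos <= len(self.ref[contig]):
            return False
        return bool(self.depth(contig)[pos - 1] > 0)

    @classmethod
    def empty(cls, genome: GenomeAssembly, sample_id: str) -> "PileupMatrix":
        return cls(
            sample_id=sample_id,
            counts={
                c: np.zeros((len(seq), len(COLUMNS)), dtype=np.int32)
                for c, seq in genome.contigs.items()
            },
            ref=dict(genome.contigs),
        )

    # -- TSV dialect: contig pos ref A C G T INS DEL (pos 1-based) ------------

    def to_tsv(self, path: str | Path) -> None:
        frames = []
        for contig, arr in self.counts.items():
            df = pd.DataFrame(arr, columns=list(COLUMNS))
            df.insert(0, "ref", list(self.ref[contig]))
            df.insert(0, "pos", np.arange(1, len(arr) + 1))
            df.insert(0, "contig", contig)
            frames.append(df)
        pd.concat(frames).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None) -> "PileupMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str})
        counts: dict[str, np.ndarray] = {}
        ref: dict[str, str] = {}
        for contig, sub in df.groupby("contig", sort=False):
            sub = sub.sort_values("pos")
            if not (sub["pos"].to_numpy() == np.arange(1, len(sub) + 1)).all():
                raise ValueError(f"{contig}: pileup TSV has missing/duplicate positions")
            counts[contig] = sub[list(COLUMNS)].to_numpy(dtype=np.int32)
            ref[contig] = "".join(sub["ref"])
        return cls(sample_id=sample_id or Path(path).stem, counts=counts, ref=ref)


def base_index(base: str) -> int:
    i = BASES.find(base)
    if i < 0:
        raise ValueError(f"not a base: {base!r}")
    return i
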
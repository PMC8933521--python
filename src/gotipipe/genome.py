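"""Genome assemblies, annotation intervals and base-editor targets.

The analysis operates on a small synthetic assembly: a handful of nuclear
contigs plus one circular mitochondrial contig.  Annotation intervals use
BED-style 0-based half-open coordinates; all user-facing positions are
1-based, matching the "m.<pos>" convention used for mitochondrial variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

ANNOTATION_KINDS = ("transcribed", "CDS", "NUMT")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Annotation:
    """One interval: 0-based half-open [start, end) on `contig`."""

    contig: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "transcribed"
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAssembly:
    """Nuclear contigs plus one circular mitochondrial contig.

    Parameters
    ----------
    contigs
        Mapping contig name -> uppercase ACGT sequence.
    mito_name
        Name of the (single) mitochondrial contig.
    circular
        Per-contig circularity flags; only the mito contig is circular.
    annotations
        Interval annotations (transcribed regions, CDS, NUMT copies).
    """

    contigs: dict[str, str]
    mito_name: str
    circular: dict[str, bool] = field(default_factory=dict)
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mito_name not in self.contigs:
            raise ValueError(f"mito contig {self.mito_name!r} not in assembly")
        for name in self.contigs:
            self.circular.setdefault(name, name == self.mito_name)
        if sum(self.circular.values()) != 1 or not self.circular[self.mito_name]:
            raise ValueError("exactly the mito contig must be circular")
        for seq in self.contigs.values():
            if seq.strip("ACGT"):
                raise ValueError("sequences must be uppercase ACGT")
        for ann in self.annotations:
            if ann.contig not in self.contigs:
                raise ValueError(f"annotation on unknown contig {ann.contig!r}")
            if ann.end > len(self.contigs[ann.contig]):
                raise ValueError(f"annotation {ann} exceeds contig length")

    # -- convenience accessors -------------------------------------------------

    @property
    def nuclear_names(self) -> list[str]:
        return [c for c in self.contigs if c != self.mito_name]

    @property
    def mito_len(self) -> int:
        return len(self.contigs[self.mito_name])

    @property
    def nuclear_size(self) -> int:
        return sum(len(self.contigs[c]) for c in self.nuclear_names)

    def base(self, contig: str, pos: int) -> str:
        """Plus-strand base at 1-based `pos` (wraps on the circular contig)."""
        seq = self.contigs[contig]
        i = pos - 1
        if self.circular.get(contig, False):
            i %= len(seq)
        elif not 0 <= i < len(seq):
            raise IndexError(f"{contig}:{pos} outside contig")
        return seq[i]

    def window(self, contig: str, pos: int, half: int) -> str | None:
        """Plus-strand window of width 2*half+1 centered on 1-based `pos`.

        Circular contigs wrap; on linear contigs a window that runs off either
        end returns None.
        """
        seq = self.contigs[contig]
        lo, hi = pos - 1 - half, pos + half
        if self.circular.get(contig, False):
            n = len(seq)
            return "".join(seq[i % n] for i in range(lo, hi))
        if lo < 0 or hi > len(seq):
            return None
        return seq[lo:hi]

    def annotations_of(self, kind: str) -> list[Annotation]:
        return [a for a in self.annotations if a.kind == kind]

    def transcribed_fraction(self) -> float:
        covered = sum(a.length for a in self.annotations_of("transcribed"))
        return covered / self.nuclear_size if self.nuclear_size else 0.0


@dataclass(frozen=True)
class EditTarget:
    """A DdCBE target: programmed edit plus the two TALE binding intervals.

    Positions are 1-based on the mitochondrial contig; TALE intervals are
    inclusive.  The spacer is the gap between the two TALE footprints, where
    the split deaminase acts.
    """

    label: str
    position: int
    ref: str
    alt: str
    tale_left: tuple[int, int]
    tale_right: tuple[int, int]

    def __post_init__(self) -> None:
        if self.ref == self.alt or {self.ref, self.alt} - set(BASES):
            raise ValueError(f"bad edit {self.ref}>{self.alt}")
        if not self.tale_left[1] < self.tale_right[0] - 1:
            raise ValueError("TALE intervals leave no spacer gap")

    @property
    def spacer(self) -> tuple[int, int]:
        """1-based inclusive spacer interval between the TALE footprints."""
        return (self.tale_left[1] + 1, self.tale_right[0] - 1)

    @property
    def spacer_mid(self) -> float:
        lo, hi = self.spacer
        return (lo + hi) / 2

    def validate(self, genome: GenomeAssembly) -> None:
        got = genome.base(genome.mito_name, self.position)
        if got != self.ref:
            raise ValueError(
                f"target {self.label}: genome has {got} at m.{self.position}, "
                f"expected {self.ref}"
            )


def design_target(
    genome: GenomeAssembly,
    center: int | None = None,
    tale_len: int = 16,
    spacer_len: int = 14,
    seed: int = 0,
) -> EditTarget:
    """Design a C·G→T·A target in a spacer of `spacer_len` bp on the mito contig.

    Picks a C or G inside the spacer (nearest to its midpoint) as the
    programmed edit; mainly a convenience for simulations and examples.
    """
    rng = np.random.default_rng(seed)
    mito = genome.contigs[genome.mito_name]
    n = len(mito)
    if center is None:
        center = int(rng.integers(tale_len + spacer_len, n - tale_len - spacer_len))
    s_lo = center - spacer_len // 2
    s_hi = s_lo + spacer_len - 1
    # nearest editable pyrimidine-pair base to the spacer midpoint
    cands = [p for p in range(s_lo, s_hi + 1) if mito[p - 1] in "CG"]
    if not cands:
        raise ValueError("no C/G in the designed spacer; choose another center")
    pos = min(cands, key=lambda p: abs(p - center))
    ref = mito[pos - 1]
    alt = "T" if ref == "C" else "A"
    target = EditTarget(
        label=f"m.{ref}{pos}{alt}",
        position=pos,
        ref=ref,
        alt=alt,
        tale_left=(s_lo - tale_len, s_lo - 1),
        tale_right=(s_hi + 1, s_hi + tale_len),
    )
    target.validate(genome)
    return target


def generate_genome(
    n_nuclear: int = 2,
    nuclear_len: int = 2_000_000,
    mito_len: int = 16_000,
    n_numt: int = 5,
    n_genes: int = 40,
    gc: float = 0.42,
    seed: int = 0,
) -> GenomeAssembly:
    """Generate a synthetic nuclear + mitochondrial assembly.

    Bases are i.i.d. at the given GC content.  `nuclear_len` is the total
    nuclear size, split evenly over `n_nuclear` contigs.  NUMTs are made by
    copying random mitochondrial segments (100-2000 bp) into random nuclear
    positions, so each NUMT is an exact nuclear copy of mito sequence.
    `n_genes` non-overlapping "transcribed" intervals are scattered over the
    nuclear contigs; one CDS annotation (an ND5 stand-in) is placed on the
    mito contig for coding-consequence annotation.

    Deterministic for a fixed seed.
    """
    if nuclear_len <= 0 or mito_len <= 0:
        raise ValueError("contig lengths must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    if nuclear_len < 10 * mito_len:
        raise ValueError("nuclear_len must be at least 10x mito_len")
    if n_numt < 0:
        raise ValueError("n_numt must be non-negative")

    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    base_arr = np.frombuffer(BASES.encode(), dtype="S1")

    def random_seq(length: int) -> np.ndarray:
        return base_arr[rng.choice(4, size=length, p=probs)]

    per_contig = nuclear_len // n_nuclear
    contigs: dict[str, np.ndarray] = {
        f"chr{i + 1}": random_seq(per_contig) for i in range(n_nuclear)
    }
    mito = random_seq(mito_len)
    annotations: list[Annotation] = []

    # NUMTs: exact mito segments pasted into nuclear contigs, non-overlapping
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    for k in range(n_numt):
        for _ in range(200):
            length = int(rng.integers(100, min(2001, mito_len + 1)))
            m_start = int(rng.integers(0, mito_len - length + 1))
            contig = f"chr{int(rng.integers(0, n_nuclear)) + 1}"
            n_start = int(rng.integers(0, per_contig - length + 1))
            if all(
                n_start + length <= s or n_start >= e for s, e in placed[contig]
            ):
                break
        else:  # pragma: no cover - essentially impossible at spec scales
            raise RuntimeError("could not place NUMT without overlap")
        contigs[contig][n_start : n_start + length] = mito[m_start : m_start + length]
        placed[contig].append((n_start, n_start + length))
        annotations.append(
            Annotation(contig, n_start, n_start + length, "+", "NUMT", f"NUMT{k + 1}")
        )

    # transcribed intervals, non-overlapping within each contig
    gene_placed: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    for k in range(n_genes):
        for _ in range(200):
            length = int(rng.integers(2_000, min(20_001, per_contig // 2)))
            contig = f"chr{int(rng.integers(0, n_nuclear)) + 1}"
            start = int(rng.integers(0, per_contig - length + 1))
            if all(start + length <= s or start >= e for s, e in gene_placed[contig]):
                break
        else:  # pragma: no cover
            continue
        gene_placed[contig].append((start, start + length))
        strand = "+" if rng.random() < 0.5 else "-"
        annotations.append(
            Annotation(contig, start, start + length, strand, "transcribed", f"gene{k + 1}")
        )

    # one mito CDS (ND5 stand-in), frame-aligned, plus strand
    cds_start = 60
    cds_len = ((mito_len - 2 * cds_start) // 3) * 3
    annotations.append(
        Annotation("chrM", cds_start, cds_start + cds_len, "+", "CDS", "ND5")
    )

    assembly = GenomeAssembly(
        contigs={
            **{c: s.tobytes().decode() for c, s in contigs.items()},
            "chrM": mito.tobytes().decode(),
        },
        mito_name="chrM",
        annotations=annotations,
    )
    return assembly


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and merged."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged
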
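"""Mitochondrial editing analysis.

Quantifies on-target heteroplasmy directly from read counts, detects
low-frequency unintended C·G→T·A edits on the mitochondrial circle, maps
them relative to the TALE spacer, and annotates coding consequences under
the vertebrate mitochondrial genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq
from scipy import stats

from .calling import MITO_CALLER_CONFIG, CallerConfig
from .genome import Annotation, BASES, EditTarget, GenomeAssembly, revcomp
from .pileup import COL_INDEX, PileupMatrix

ZONES = ("spacer", "tale_binding", "proximal", "distal")

#: events below this allele fraction carry the low_frequency flag, the
#: ceiling under which unintended mtDNA edits are expected to fall
LOW_FREQUENCY_CEILING = 0.05


@dataclass(frozen=True)
class MitoSite:
    """One unintended C·G→T·A event on the mito contig."""

    position: int  # 1-based, reported as m.<position>
    ref: str
    alt: str
    af: float
    alt_count: int
    depth: int
    zone: str
    low_frequency: bool

    @property
    def label(self) -> str:
        return f"m.{self.ref}{self.position}{self.alt}"


@dataclass
class MitoEditProfile:
    """On-target heteroplasmy plus the zone-mapped off-target table."""

    target: EditTarget
    on_target_af: float
    offtargets: list[MitoSite]

    def in_zone(self, zone: str) -> list[MitoSite]:
        return [s for s in self.offtargets if s.zone == zone]


@dataclass(frozen=True)
class CodingEffect:
    """Consequence of a substitution inside a CDS."""

    gene: str
    codon_number: int  # 1-based from CDS start, honoring strand
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    category: str  # missense | nonsense | silent

    def __post_init__(self) -> None:
        if self.alt_aa == "*" and self.category != "nonsense":
            raise ValueError("stop gain must be nonsense")
        if self.alt_aa == self.ref_aa and self.category != "silent":
            raise ValueError("synonymous change must be silent")


def circular_distance(a: float, b: float, length: int) -> float:
    """Shortest distance between positions a and b on a circle of `length`."""
    d = abs(a - b) % length
    return min(d, length - d)


def classify_zone(
    pos: int,
    target: EditTarget,
    mito_len: int,
    proximal_window: int = 500,
) -> str:
    """Zone of a mito position relative to the target.

    spacer > tale_binding > proximal (within `proximal_window` bp of the
    spacer midpoint, circular distance) > distal; the zones partition the
    mitochondrial circle.
    """
    if not 1 <= pos <= mito_len:
        raise ValueError(f"position {pos} outside mito contig of {mito_len} bp")
    if target.spacer[0] <= pos <= target.spacer[1]:
        return "spacer"
    for lo, hi in (target.tale_left, target.tale_right):
        if lo <= pos <= hi:
            return "tale_binding"
    if circular_distance(pos, target.spacer_mid, mito_len) <= proximal_window:
        return "proximal"
    return "distal"


def ontarget_efficiency(mito_pileup: PileupMatrix, target: EditTarget) -> float:
    """Editing efficiency = alt fraction of the programmed allele at the target.

    This is the heteroplasmy of the installed edit as seen by sequencing.
    """
    name = _mito_contig(mito_pileup, target)
    row = mito_pileup.counts[name][target.position - 1]
    depth = int(row[:4].sum() + row[COL_INDEX["DEL"]])
    if depth == 0:
        raise ValueError(f"zero depth at target site m.{target.position}")
    return int(row[BASES.index(target.alt)]) / depth


def _mito_contig(mito_pileup: PileupMatrix, target: EditTarget) -> str:
    for name, ref in mito_pileup.ref.items():
        if target.position <= len(ref) and ref[target.position - 1] == target.ref:
            if name in ("chrM", "MT") or len(mito_pileup.ref) == 1:
                return name
    # fall back: single contig or conventional names
    for name in ("chrM", "MT"):
        if name in mito_pileup.counts:
            return name
    if len(mito_pileup.counts) == 1:
        return next(iter(mito_pileup.counts))
    raise ValueError("could not identify the mitochondrial contig in the pileup")


def mito_offtargets(
    mito_pileup: PileupMatrix,
    target: EditTarget,
    min_af: float = 0.01,
    cfg: CallerConfig = MITO_CALLER_CONFIG,
    proximal_window: int = 500,
) -> MitoEditProfile:
    """Detect unintended C·G→T·A events on the mitochondrial contig.

    Reports every non-target site whose C→T (or G→A) alt fraction is at least
    `min_af` and whose alt count passes the caller's evidence screen
    (min_alt_reads plus the binomial error-model tail at `cfg.alpha`).
    Events under 5% AF carry the low_frequency flag; each event is
    zone-classified relative to the TALE spacer.
    """
    if not 0 < min_af < 1:
        raise ValueError("min_af must be in (0, 1)")
    name = _mito_contig(mito_pileup, target)
    arr = mito_pileup.counts[name]
    ref = mito_pileup.ref[name]
    mito_len = len(ref)
    p_err = cfg.error_rate / 3

    sites: list[MitoSite] = []
    for i in range(mito_len):
        pos = i + 1
        if pos == target.position:
            continue
        base = ref[i]
        if base == "C":
            alt_base = "T"
        elif base == "G":
            alt_base = "A"
        else:
            continue
        row = arr[i]
        depth = int(row[:4].sum() + row[COL_INDEX["DEL"]])
        if depth < cfg.min_depth:
            continue
        alt = int(row[BASES.index(alt_base)])
        if alt < cfg.min_alt_reads:
            continue
        af = alt / depth
        if af < min_af:
            continue
        if stats.binom.sf(alt - 1, depth, p_err) >= cfg.alpha:
            continue
        sites.append(
            MitoSite(
                position=pos,
                ref=base,
                alt=alt_base,
                af=af,
                alt_count=alt,
                depth=depth,
                zone=classify_zone(pos, target, mito_len, proximal_window),
                low_frequency=af < LOW_FREQUENCY_CEILING,
            )
        )

    on_af = ontarget_efficiency(mito_pileup, target)
    return MitoEditProfile(target=target, on_target_af=on_af, offtargets=sites)


def annotate_coding_effect(
    genome: GenomeAssembly,
    cds: Annotation,
    pos: int,
    ref: str,
    alt: str,
) -> CodingEffect:
    """Codon-level consequence of a substitution inside a CDS.

    Translation uses the vertebrate mitochondrial genetic code (NCBI table 2).
    Codon numbers are 1-based from the CDS start honoring strand.
    """
    if cds.kind != "CDS":
        raise ValueError("annotation is not a CDS")
    seq = genome.contigs[cds.contig]
    i = pos - 1
    if not cds.start <= i < cds.end:
        raise ValueError(f"position {pos} outside CDS {cds.label}")
    if seq[i] != ref:
        raise ValueError(f"reference mismatch at {pos}: genome has {seq[i]}")
    if alt == ref or alt not in BASES:
        raise ValueError(f"bad alt {alt!r}")

    cds_seq = seq[cds.start : cds.end]
    if cds.strand == "+":
        offset = i - cds.start
        coding = cds_seq
        coding_alt_base = alt
    else:
        coding = revcomp(cds_seq)
        offset = (cds.end - 1) - i
        coding_alt_base = revcomp(alt)
    codon_number = offset // 3 + 1
    within = offset % 3
    c0 = (codon_number - 1) * 3
    ref_codon = coding[c0 : c0 + 3]
    alt_codon = ref_codon[:within] + coding_alt_base + ref_codon[within + 1 :]

    ref_aa = str(Seq(ref_codon).translate(table=2))
    alt_aa = str(Seq(alt_codon).translate(table=2))
    if alt_aa == ref_aa:
        category = "silent"
    elif alt_aa == "*":
        category = "nonsense"
    else:
        category = "missense"
    return CodingEffect(
        gene=cds.label,
        codon_number=codon_number,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        category=category,
    )
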
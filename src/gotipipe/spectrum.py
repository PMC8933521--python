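"""Mutation spectrum, sequence-context logos and 5'-TC-3' motif enrichment.

Substitutions are strand-collapsed onto the six pyrimidine-reference classes
(C>A, C>G, C>T, T>A, T>C, T>G); a purine-reference change is represented by
its reverse complement, so G→A counts as C>T.  Context windows around
C·G→T·A sites are oriented so the edited base always reads C at position 0;
information content per position is 2 − H (Shannon entropy in bits), as in a
standard sequence logo.  The deaminase's cognate 5'-TC-3' preference is
tested as T-at-(−1) enrichment against the genomic dinucleotide background
with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.special import betainc

from .calling import DeNovoSet, VariantCall
from .genome import BASES, GenomeAssembly, revcomp
from .simulate import SUB_CLASSES

_PYRIMIDINES = "CT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def classify_substitution(ref: str, alt: str) -> str:
    """Strand-collapsed class of a substitution; (G,A) maps to C>T etc."""
    if ref == alt or ref not in BASES or alt not in BASES:
        raise ValueError(f"bad substitution {ref!r}>{alt!r}")
    if ref in _PYRIMIDINES:
        return f"{ref}>{alt}"
    return f"{_COMP[ref]}>{_COMP[alt]}"


@dataclass
class SpectrumResult:
    """Counts and proportions per strand-collapsed class."""

    counts: dict[str, int]
    n: int
    empty: bool

    @property
    def proportions(self) -> dict[str, float]:
        if self.empty:
            return {c: float("nan") for c in SUB_CLASSES}
        return {c: self.counts[c] / self.n for c in SUB_CLASSES}


def spectrum(snvs: DeNovoSet | Iterable[VariantCall]) -> SpectrumResult:
    """Class counts/proportions over a variant set (indels ignored)."""
    counts = {c: 0 for c in SUB_CLASSES}
    n = 0
    for call in snvs:
        if call.is_indel:
            continue
        counts[classify_substitution(call.ref, call.alt)] += 1
        n += 1
    return SpectrumResult(counts=counts, n=n, empty=n == 0)


def ct_fraction(snvs: DeNovoSet | Iterable[VariantCall]) -> float:
    """Proportion of C·G→T·A changes among all SNVs."""
    result = spectrum(snvs)
    if result.empty:
        raise ValueError("empty SNV set")
    return result.proportions["C>T"]


@dataclass
class ContextMatrix:
    """Aligned plus-strand-oriented windows around edited cytosines.

    counts[k, b] is the number of windows with base BASES[b] at offset
    positions[k]; every row reads C at offset 0.  Windows that would run off
    a linear contig end are dropped and tallied in `n_dropped`.
    """

    half_width: int
    counts: np.ndarray  # (2f+1, 4) ints
    n_rows: int
    n_dropped: int = 0

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.half_width, self.half_width + 1)

    def column(self, offset: int) -> np.ndarray:
        return self.counts[offset + self.half_width]

    def base_fraction(self, offset: int, base: str) -> float:
        col = self.column(offset)
        return col[BASES.index(base)] / col.sum()


def extract_contexts(
    genome: GenomeAssembly,
    snvs: DeNovoSet | Iterable[VariantCall],
    half_width: int = 10,
) -> ContextMatrix:
    """Context matrix over the C·G→T·A records of a variant set.

    For a C-reference record the plus-strand window is taken as-is; for a
    G-reference record the reverse complement is taken, so the edited strand
    always reads C at offset 0.  Windows wrap on the circular mito contig;
    off-end windows on linear contigs are dropped and counted.
    """
    f = half_width
    counts = np.zeros((2 * f + 1, 4), dtype=np.int64)
    n_rows = 0
    n_dropped = 0
    for call in snvs:
        if call.is_indel or classify_substitution(call.ref, call.alt) != "C>T":
            continue
        win = genome.window(call.contig, call.pos, f)
        if win is None:
            n_dropped += 1
            continue
        if call.ref == "G":
            win = revcomp(win)
        for k, b in enumerate(win):
            counts[k, BASES.index(b)] += 1
        n_rows += 1
    return ContextMatrix(half_width=f, counts=counts, n_rows=n_rows,
                         n_dropped=n_dropped)


@dataclass
class LogoResult:
    """Per-position base frequencies and information content in bits."""

    positions: np.ndarray
    frequencies: np.ndarray  # (2f+1, 4)
    information: np.ndarray  # bits, in [0, 2]

    @property
    def letter_heights(self) -> np.ndarray:
        """freq × IC per base, the stack heights of a drawn logo."""
        return self.frequencies * self.information[:, None]


def logo_bits(contexts: ContextMatrix, small_sample_correction: bool = False) -> LogoResult:
    """Information content per position: IC = 2 − H, H the Shannon entropy.

    With `small_sample_correction`, the standard e(n) = 3/(2·ln2·n) penalty
    is subtracted (clipped at 0).
    """
    if contexts.n_rows == 0:
        raise ValueError("empty context matrix")
    totals = contexts.counts.sum(axis=1, keepdims=True)
    freq = contexts.counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = 2.0 - entropy
    if small_sample_correction:
        ic = np.clip(ic - 3 / (2 * np.log(2) * contexts.n_rows), 0.0, 2.0)
    return LogoResult(positions=contexts.positions, frequencies=freq, information=ic)


@dataclass
class EnrichmentResult:
    """T-at-(−1) enrichment of off-target contexts over background."""

    table: np.ndarray  # 2x2: rows (off-target, background), cols (T, not T)
    odds_ratio: float
    p_value: float
    continuity_corrected: bool


def genome_tc_background(genome: GenomeAssembly, nuclear_only: bool = True) -> tuple[int, int]:
    """Counts of C positions (both strands) preceded by T vs not.

    Scans TC dinucleotides on the plus strand and their G·A mirror images,
    giving the genomic background for the 5'-TC-3' motif test.
    """
    t_count = 0
    other = 0
    names = genome.nuclear_names if nuclear_only else list(genome.contigs)
    for name in names:
        seq = genome.contigs[name]
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        # plus strand: C at i, neighbour at i-1; minus strand: G at i, neighbour at i+1
        plus_t = is_c[1:] & (arr[:-1] == ord("T"))
        minus_t = is_g[:-1] & (arr[1:] == ord("A"))
        t_count += int(plus_t.sum() + minus_t.sum())
        other += int(is_c[1:].sum() - plus_t.sum() + is_g[:-1].sum() - minus_t.sum())
    return t_count, other


def tc_enrichment(
    contexts: ContextMatrix,
    background: float | tuple[int, int],
    background_n: int = 10_000,
) -> EnrichmentResult:
    """Fisher's exact test of 5'-T enrichment at position −1.

    `background` is either (T count, other count) from a genomic dinucleotide
    scan, or a fraction (then scaled to `background_n` pseudo-counts).  The
    odds ratio uses the Haldane–Anscombe +0.5 correction when any cell is 0;
    the p-value is the two-sided Fisher exact probability on the raw table.
    """
    if contexts.n_rows == 0:
        raise ValueError("no contexts")
    col = contexts.column(-1)
    t_off = int(col[BASES.index("T")])
    other_off = int(col.sum() - t_off)
    if isinstance(background, tuple):
        t_bg, other_bg = background
    else:
        t_bg = int(round(background * background_n))
        other_bg = background_n - t_bg
    table = np.array([[t_off, other_off], [t_bg, other_bg]], dtype=np.int64)
    corrected = bool((table == 0).any())
    t = table + 0.5 if corrected else table
    odds = float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(
        table=table, odds_ratio=odds, p_value=float(p), continuity_corrected=corrected
    )


@dataclass
class TTestResult:
    """Pooled-variance two-sample t statistic with two-tailed p."""

    t: float
    df: int
    p: float
    degenerate: str | None = None  # "infinite_t" when pooled variance is 0


def t_test_unpaired(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
) -> TTestResult:
    """Classic unpaired Student's t-test (two-tailed), pooled variance.

    df = n_a + n_b − 2.  Degenerate zero-variance inputs: equal means give
    t = 0, p = 1; unequal means are flagged "infinite_t" with p = 0.
    Welch's unequal-variance form is available behind the flag.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if welch:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        df = stats.ttest_ind(a, b, equal_var=False).df
        return TTestResult(t=float(t), df=float(df), p=float(p))
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return TTestResult(t=0.0, df=df, p=1.0)
        return TTestResult(
            t=float(np.inf if diff > 0 else -np.inf), df=df, p=0.0,
            degenerate="infinite_t",
        )
    t = diff / np.sqrt(sp2 * (1 / na + 1 / nb))
    # two-tailed p through the incomplete beta form of the t distribution
    p = float(betainc(df / 2, 0.5, df / (df + t * t)))
    return TTestResult(t=float(t), df=df, p=p)
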
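"""Genomic distribution of de-novo SNVs.

Covers four questions asked of an off-target set: does it track transcribed
regions; is it uniform over the genome; do independent samples share sites
(they should not, if editing is sequence-independent); and is it biased
toward sequences resembling the programmed target or toward NUMTs (nuclear
copies of mitochondrial DNA)?
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .calling import DeNovoSet, Key
from .genome import Annotation, GenomeAssembly, merge_intervals, revcomp
from .spectrum import TTestResult, t_test_unpaired


# ---------------------------------------------------------------------------
# transcribed vs untranscribed


@dataclass
class RegionBreakdown:
    """Per-sample in/out-of-transcribed counts and the group comparison."""

    per_sample: pd.DataFrame  # sample, group, n, n_in, n_out, in_fraction, p
    transcribed_fraction: float
    group_test: TTestResult | None = None


def _merged_by_contig(intervals: list[Annotation]) -> dict[str, list[tuple[int, int]]]:
    by: dict[str, list[tuple[int, int]]] = {}
    for a in intervals:
        by.setdefault(a.contig, []).append((a.start, a.end))
    return {c: merge_intervals(v) for c, v in by.items()}


def _in_intervals(pos: int, merged: list[tuple[int, int]]) -> bool:
    """0-based position membership in merged half-open intervals."""
    i = np.searchsorted([s for s, _ in merged], pos, side="right") - 1
    return i >= 0 and pos < merged[i][1]


def region_breakdown(
    snv_sets: DeNovoSet | list[DeNovoSet],
    transcribed: list[Annotation],
    genome: GenomeAssembly,
    groups: list[str] | None = None,
) -> RegionBreakdown:
    """Assign every nuclear SNV to transcribed vs untranscribed territory.

    The null expectation is n × (transcribed bp / nuclear bp); each sample
    gets a two-sided binomial p for its deviation.  With two groups of >= 2
    samples each, per-sample in-fractions are compared by the unpaired t-test.
    """
    sets = [snv_sets] if isinstance(snv_sets, DeNovoSet) else list(snv_sets)
    for a in transcribed:
        if a.contig not in genome.contigs:
            raise ValueError(f"interval on unknown contig {a.contig!r}")
    merged = _merged_by_contig(transcribed)
    frac = sum(
        e - s for ivs in merged.values() for s, e in ivs
    ) / genome.nuclear_size

    rows = []
    for idx, s in enumerate(sets):
        nuclear = [c for c in s.snvs if c.contig != genome.mito_name]
        n_in = sum(
            _in_intervals(c.pos - 1, merged.get(c.contig, [])) for c in nuclear
        )
        n = len(nuclear)
        p = float(stats.binomtest(n_in, n, frac).pvalue) if n else float("nan")
        rows.append(
            {
                "sample": s.sample_id,
                "group": groups[idx] if groups else "all",
                "n": n,
                "n_in": n_in,
                "n_out": n - n_in,
                "in_fraction": n_in / n if n else float("nan"),
                "binom_p": p,
            }
        )
    per_sample = pd.DataFrame(rows)

    group_test = None
    if groups is not None:
        by_group = per_sample.groupby("group")["in_fraction"].apply(list)
        if len(by_group) == 2 and all(len(v) >= 2 for v in by_group):
            group_test = t_test_unpaired(*by_group.tolist())
    return RegionBreakdown(
        per_sample=per_sample, transcribed_fraction=frac, group_test=group_test
    )


# ---------------------------------------------------------------------------
# genome-wide uniformity


@dataclass
class UniformityResult:
    statistic: float
    p_value: float
    n_bins: int
    df: int


def uniformity_test(
    snvs: DeNovoSet,
    genome: GenomeAssembly,
    bin_size: int = 100_000,
) -> UniformityResult:
    """Chi-square goodness of fit of nuclear SNV positions to uniformity.

    Bins tile the nuclear contigs half-open; expected counts are proportional
    to bin length.  Adjacent bins are merged until every expected count is at
    least 1; a single surviving bin has no degrees of freedom and reports
    p = 1 (non-rejecting).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    nuclear = [c for c in snvs.snvs if c.contig != genome.mito_name]
    n = len(nuclear)
    if n == 0:
        raise ValueError("no nuclear SNVs to test")

    observed: list[int] = []
    lengths: list[int] = []
    for contig in genome.nuclear_names:
        L = len(genome.contigs[contig])
        edges = list(range(0, L, bin_size)) + [L]
        pos = np.array([c.pos - 1 for c in nuclear if c.contig == contig])
        counts, _ = np.histogram(pos, bins=edges) if len(edges) > 1 else (np.array([len(pos)]), None)
        # merge bins left-to-right until expected >= 1 per merged bin
        G = sum(len(genome.contigs[c]) for c in genome.nuclear_names)
        acc_o, acc_l = 0, 0
        for o, (lo, hi) in zip(counts, zip(edges[:-1], edges[1:])):
            acc_o += int(o)
            acc_l += hi - lo
            if n * acc_l / G >= 1:
                observed.append(acc_o)
                lengths.append(acc_l)
                acc_o, acc_l = 0, 0
        if acc_l:
            if lengths:
                observed[-1] += acc_o
                lengths[-1] += acc_l
            else:
                observed.append(acc_o)
                lengths.append(acc_l)

    k = len(observed)
    if k <= 1:
        return UniformityResult(statistic=0.0, p_value=1.0, n_bins=k, df=0)
    total_len = sum(lengths)
    expected = np.array([n * l / total_len for l in lengths])
    stat, p = stats.chisquare(observed, expected)
    return UniformityResult(statistic=float(stat), p_value=float(p), n_bins=k, df=k - 1)


# ---------------------------------------------------------------------------
# cross-sample overlap


@dataclass
class OverlapReport:
    """Observed vs expected sharing of exact variant keys between samples."""

    sample_ids: list[str]
    set_sizes: list[int]
    pairwise: dict[tuple[int, int], int]
    expected_pairwise: dict[tuple[int, int], float]
    k_way: int  # keys present in every sample
    key_mode: str = "full"

    @property
    def max_pairwise(self) -> int:
        return max(self.pairwise.values()) if self.pairwise else 0


def cross_sample_overlap(
    sets: list[DeNovoSet],
    genome: GenomeAssembly,
    key_mode: str = "full",
) -> OverlapReport:
    """Exact-key intersections between de-novo sets, with the uniform null.

    `key_mode="full"` intersects (contig, pos, ref, alt) keys;
    `"position"` relaxes to (contig, pos).  The expected pairwise overlap
    under independent uniform placement is n_i × n_j / G with G the nuclear
    genome size.  Mitochondrial records are excluded: the programmed
    on-target edit is shared by every edited sample by construction and
    carries no information about sequence-independent placement.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    if key_mode not in ("full", "position"):
        raise ValueError("key_mode must be 'full' or 'position'")

    def keys_of(s: DeNovoSet) -> set:
        ks = {c.key for c in s.snvs if c.contig != genome.mito_name}
        if key_mode == "position":
            ks = {(k[0], k[1]) for k in ks}
        return ks

    key_sets = [keys_of(s) for s in sets]
    G = genome.nuclear_size
    pairwise: dict[tuple[int, int], int] = {}
    expected: dict[tuple[int, int], float] = {}
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            pairwise[(i, j)] = len(key_sets[i] & key_sets[j])
            expected[(i, j)] = len(key_sets[i]) * len(key_sets[j]) / G
    k_way = len(set.intersection(*key_sets))
    return OverlapReport(
        sample_ids=[s.sample_id for s in sets],
        set_sizes=[len(k) for k in key_sets],
        pairwise=pairwise,
        expected_pairwise=expected,
        k_way=k_way,
        key_mode=key_mode,
    )


# ---------------------------------------------------------------------------
# sequence similarity / NUMT screen

SW_MATCH = 1
SW_MISMATCH = -1
SW_GAP_OPEN = -2
SW_GAP_EXTEND = -1


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = SW_MATCH
    aligner.mismatch_score = SW_MISMATCH
    aligner.open_gap_score = SW_GAP_OPEN
    aligner.extend_gap_score = SW_GAP_EXTEND
    return aligner


def smith_waterman_score(a: str, b: str) -> float:
    """Best local-alignment score (match +1, mismatch −1, gap open/extend −2/−1)."""
    if not a or not b:
        return 0.0
    return max(0.0, float(_aligner().score(a, b)))


@dataclass
class SimilarityReport:
    """Flank-vs-target homology scores and NUMT membership per off-target."""

    per_snv: pd.DataFrame  # contig, pos, score, in_numt, clipped
    null_scores: np.ndarray
    flank: int
    n_numt_hits: int = 0

    @property
    def observed_scores(self) -> np.ndarray:
        return self.per_snv["score"].to_numpy()

    def summary(self) -> dict[str, float]:
        obs = self.observed_scores
        null = self.null_scores
        q99 = float(np.quantile(null, 0.99)) if len(null) else float("nan")
        return {
            "n": int(len(obs)),
            "mean_score": float(obs.mean()) if len(obs) else float("nan"),
            "null_mean_score": float(null.mean()) if len(null) else float("nan"),
            "null_q99": q99,
            "fraction_above_null_q99": float((obs > q99).mean()) if len(obs) else float("nan"),
            "n_numt_hits": self.n_numt_hits,
        }


def similarity_screen(
    snvs: DeNovoSet,
    genome: GenomeAssembly,
    target_seqs: list[str],
    numts: list[Annotation] | None = None,
    flank: int = 20,
    seed: int = 0,
    null_multiplier: int = 10,
) -> SimilarityReport:
    """Screen off-target flanks for homology to the target region and NUMTs.

    For each SNV the ±`flank` window is locally aligned (Smith–Waterman)
    against every target sequence and its reverse complement; the best score
    is kept.  The null distribution repeats the scoring at `null_multiplier`×
    as many random genomic positions.  NUMT membership is flagged by interval
    overlap.  Windows clipped at a linear contig end are flagged.
    """
    if not target_seqs:
        raise ValueError("need at least one target sequence")
    if flank < 10:
        raise ValueError("flank must be >= 10")
    numts = numts if numts is not None else genome.annotations_of("NUMT")
    numt_by_contig = _merged_by_contig(numts) if numts else {}
    aligner = _aligner()
    queries = [s for t in target_seqs for s in (t, revcomp(t))]

    def best_score(window: str) -> float:
        return max(max(0.0, float(aligner.score(window, q))) for q in queries)

    def clipped_window(contig: str, pos: int) -> tuple[str, bool]:
        win = genome.window(contig, pos, flank)
        if win is not None:
            return win, False
        seq = genome.contigs[contig]
        lo = max(0, pos - 1 - flank)
        hi = min(len(seq), pos + flank)
        return seq[lo:hi], True

    rows = []
    n_numt = 0
    for call in sorted(snvs.snvs, key=lambda c: (c.contig, c.pos)):
        win, clipped = clipped_window(call.contig, call.pos)
        in_numt = _in_intervals(call.pos - 1, numt_by_contig.get(call.contig, []))
        n_numt += int(in_numt)
        rows.append(
            {
                "contig": call.contig,
                "pos": call.pos,
                "score": best_score(win),
                "in_numt": in_numt,
                "clipped": clipped,
            }
        )
    per_snv = pd.DataFrame(
        rows, columns=["contig", "pos", "score", "in_numt", "clipped"]
    )

    rng = np.random.default_rng(seed)
    nuc = genome.nuclear_names
    weights = np.array([len(genome.contigs[c]) for c in nuc], dtype=float)
    weights /= weights.sum()
    null_scores = []
    for _ in range(null_multiplier * len(rows)):
        contig = nuc[int(rng.choice(len(nuc), p=weights))]
        pos = int(rng.integers(1, len(genome.contigs[contig]) + 1))
        win, _ = clipped_window(contig, pos)
        null_scores.append(best_score(win))
    return SimilarityReport(
        per_snv=per_snv,
        null_scores=np.array(null_scores),
        flank=flank,
        n_numt_hits=n_numt,
    )
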
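"""Per-sample variant calling and paired de-novo set derivation.

The GOTI design sequences two cell populations from the same embryo: the
edited (marker-positive) sample and its unedited sibling.  Variants are
called per sample with simple depth/allele-fraction/error-model filters, and
the de-novo set of the edited sample is everything called there that shows
essentially no support in the matched control — the control-absence filter is
the specificity mechanism, mirroring somatic tumor/normal subtraction.

External caller output (VCF) can be substituted for the built-in caller;
`consensus` intersects multiple call sets the way multi-caller somatic
pipelines do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .genome import BASES
from .pileup import COL_INDEX, COLUMNS, PileupMatrix

Key = tuple[str, int, str, str]


class UncoveredSiteError(ValueError):
    """The control pileup does not cover a site required by the edited calls."""


@dataclass(frozen=True)
class VariantCall:
    """A called substitution or indel allele at one site."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str  # base, or "INS"/"DEL"
    alt_count: int
    depth: int
    caller: str = "builtin"

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError("alt equals ref")
        if not 1 <= self.alt_count <= self.depth:
            raise ValueError("need depth >= alt_count >= 1")

    @property
    def af(self) -> float:
        return self.alt_count / self.depth

    @property
    def key(self) -> Key:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return self.alt in ("INS", "DEL")


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds of the built-in caller.

    A site/allele is called iff depth >= min_depth, alt_count >= min_alt_reads,
    alt fraction >= min_af, and the binomial upper tail
    P(X >= alt_count | n=depth, p=error_rate/3) < alpha.  The mitochondrial
    contig is typically called with a lower min_af (high coverage supports it).
    """

    min_depth: int = 10
    min_alt_reads: int = 3
    min_af: float = 0.1
    alpha: float = 1e-6
    error_rate: float = 0.002

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


#: mitochondrial variant of the defaults: 1% AF floor
MITO_CALLER_CONFIG = CallerConfig(min_af=0.01)


@dataclass(frozen=True)
class DeNovoFilters:
    """Control-absence thresholds for de-novo retention."""

    max_control_alt_reads: int = 1
    max_control_af: float = 0.02


@dataclass
class DeNovoSet:
    """The edited-minus-control variant set for one sample."""

    sample_id: str
    calls: dict[Key, VariantCall] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, call in self.calls.items():
            if call.key != key:
                raise ValueError("call keyed under wrong key")

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls.values())

    @property
    def keys(self) -> set[Key]:
        return set(self.calls)

    @property
    def snvs(self) -> list[VariantCall]:
        return [c for c in self.calls.values() if not c.is_indel]

    @property
    def indels(self) -> list[VariantCall]:
        return [c for c in self.calls.values() if c.is_indel]

    @classmethod
    def from_calls(
        cls, sample_id: str, calls: Iterable[VariantCall], provenance: dict | None = None
    ) -> "DeNovoSet":
        return cls(sample_id, {c.key: c for c in calls}, provenance or {})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "contig": c.contig, "pos": c.pos, "ref": c.ref, "alt": c.alt,
                "alt_count": c.alt_count, "depth": c.depth, "af": c.af,
            }
            for c in sorted(self.calls.values(), key=lambda c: (c.contig, c.pos, c.alt))
        ]
        return pd.DataFrame(
            rows, columns=["contig", "pos", "ref", "alt", "alt_count", "depth", "af"]
        )


def call_variants(pileup: PileupMatrix, cfg: CallerConfig = CallerConfig()) -> set[VariantCall]:
    """Call every non-reference allele passing the configured filters.

    Deterministic; the binomial screen asks how surprising the alt count is
    under a uniform-miscall error model (per-base miscall rate error_rate,
    split evenly across the three non-reference bases).
    """
    calls: set[VariantCall] = set()
    p_err = cfg.error_rate / 3
    for contig, arr in pileup.counts.items():
        ref = pileup.ref[contig]
        if arr.shape[0] != len(ref):
            raise ValueError(f"{contig}: pileup/reference length mismatch")
        depth = arr[:, :4].sum(axis=1) + arr[:, COL_INDEX["DEL"]]
        ref_idx = np.frombuffer(ref.encode(), dtype=np.uint8)
        lut = np.full(128, -1, dtype=np.int8)
        for i, b in enumerate(BASES):
            lut[ord(b)] = i
        ref_col = lut[ref_idx]
        for j, allele in enumerate(COLUMNS):
            alt = arr[:, j].astype(np.int64)
            with np.errstate(divide="ignore", invalid="ignore"):
                af = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
            mask = (
                (depth >= cfg.min_depth)
                & (alt >= cfg.min_alt_reads)
                & (af >= cfg.min_af)
            )
            if j < 4:
                mask &= ref_col != j
            idx = np.nonzero(mask)[0]
            if idx.size == 0:
                continue
            tail = stats.binom.sf(alt[idx] - 1, depth[idx], p_err)
            for i in idx[tail < cfg.alpha]:
                calls.add(
                    VariantCall(
                        contig=contig,
                        pos=int(i) + 1,
                        ref=ref[i],
                        alt=allele,
                        alt_count=int(alt[i]),
                        depth=int(depth[i]),
                    )
                )
    return calls


def consensus(call_sets: list[set[VariantCall]], k: int | None = None) -> set[VariantCall]:
    """Keep alleles present in at least `k` of the call sets.

    Defaults to k = len(call_sets), the strict multi-caller intersection.
    The merged record keeps the maximum-depth evidence for each key.
    """
    if not call_sets:
        raise ValueError("no call sets")
    if k is None:
        k = len(call_sets)
    if k > len(call_sets):
        raise ValueError("k exceeds number of call sets")
    best: dict[Key, VariantCall] = {}
    support: dict[Key, int] = {}
    for cs in call_sets:
        for call in cs:
            support[call.key] = support.get(call.key, 0) + 1
            prev = best.get(call.key)
            if prev is None or call.depth > prev.depth:
                best[call.key] = call
    return {best[key] for key, n in support.items() if n >= k}


def _control_evidence(
    control: PileupMatrix, call: VariantCall
) -> tuple[int, float]:
    """(alt reads, alt fraction) for `call`'s allele in the control sample."""
    if call.contig not in control.counts or not (
        1 <= call.pos <= len(control.ref[call.contig])
    ):
        raise UncoveredSiteError(
            f"control does not cover {call.contig}:{call.pos}"
        )
    row = control.counts[call.contig][call.pos - 1]
    depth = int(row[:4].sum() + row[COL_INDEX["DEL"]])
    if depth == 0:
        raise UncoveredSiteError(
            f"control has zero depth at {call.contig}:{call.pos}"
        )
    j = COL_INDEX[call.alt] if call.is_indel else BASES.index(call.alt)
    alt = int(row[j])
    return alt, alt / depth


def _de_novo(
    edited_calls: Iterable[VariantCall],
    control: PileupMatrix,
    germline: set[Key],
    filters: DeNovoFilters,
    indels: bool,
    sample_id: str,
) -> DeNovoSet:
    kept: list[VariantCall] = []
    for call in edited_calls:
        if call.is_indel != indels:
            continue
        if call.key in germline:
            continue
        alt, af = _control_evidence(control, call)
        if alt <= filters.max_control_alt_reads and af <= filters.max_control_af:
            kept.append(call)
    return DeNovoSet.from_calls(
        sample_id,
        kept,
        provenance={
            "control": control.sample_id,
            "filters": {
                "max_control_alt_reads": filters.max_control_alt_reads,
                "max_control_af": filters.max_control_af,
            },
            "germline_size": len(germline),
        },
    )


def de_novo_snvs(
    edited_calls: Iterable[VariantCall],
    control: PileupMatrix,
    germline: Iterable[VariantCall] | set[Key] = (),
    filters: DeNovoFilters = DeNovoFilters(),
    sample_id: str = "edited",
) -> DeNovoSet:
    """De-novo SNVs: edited-sample calls absent from the matched control.

    A call is retained iff its alt allele has at most `max_control_alt_reads`
    supporting reads AND control allele fraction <= `max_control_af` at the
    same site, and its key is not in the (optional) germline set.  Indel
    alleles are routed through :func:`de_novo_indels` instead.
    """
    germ = {c.key if isinstance(c, VariantCall) else c for c in germline}
    return _de_novo(edited_calls, control, germ, filters, indels=False,
                    sample_id=sample_id)


def de_novo_indels(
    edited_calls: Iterable[VariantCall],
    control: PileupMatrix,
    germline: Iterable[VariantCall] | set[Key] = (),
    filters: DeNovoFilters = DeNovoFilters(),
    sample_id: str = "edited",
) -> DeNovoSet:
    """De-novo insertion/deletion alleles; same contract as de_novo_snvs."""
    germ = {c.key if isinstance(c, VariantCall) else c for c in germline}
    return _de_novo(edited_calls, control, germ, filters, indels=True,
                    sample_id=sample_id)


@dataclass
class CountSummary:
    per_sample: pd.DataFrame
    per_group: pd.DataFrame


def count_summary(
    sets: list[DeNovoSet], group_labels: list[str] | None = None
) -> CountSummary:
    """Per-sample SNV/indel counts with per-group mean ± SEM (sd/sqrt(n)).

    A group of size 1 reports SEM 0 with its n flagging the degeneracy.
    """
    if not sets:
        raise ValueError("need at least one de-novo set")
    if group_labels is None:
        group_labels = ["all"] * len(sets)
    per_sample = pd.DataFrame(
        {
            "sample": [s.sample_id for s in sets],
            "group": group_labels,
            "n_snv": [len(s.snvs) for s in sets],
            "n_indel": [len(s.indels) for s in sets],
        }
    )
    rows = []
    for group, sub in per_sample.groupby("group", sort=False):
        n = len(sub)
        for kind in ("n_snv", "n_indel"):
            vals = sub[kind].to_numpy(dtype=float)
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            rows.append(
                {"group": group, "metric": kind, "mean": float(vals.mean()),
                 "sem": sem, "n": n}
            )
    return CountSummary(per_sample=per_sample, per_group=pd.DataFrame(rows))
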
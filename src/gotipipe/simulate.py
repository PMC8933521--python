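"""Synthetic paired-embryo data: edit injection and pileup simulation.

The generator emulates the statistical structure of a GOTI experiment with a
TALE-guided double-stranded-DNA cytosine deaminase (DdCBE):

* an on-target mtDNA edit at heteroplasmic allele fraction;
* low-frequency mtDNA bystander edits concentrated around the TALE spacer;
* Poisson-distributed nuclear off-target SNVs, predominantly C·G→T·A and
  biased toward a 5'-TC-3' dinucleotide context, at clonal allele fraction;
* a matched control sample carrying none of the edits;
* Poisson site depths with uniform-miscall binomial sequencing noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import BASES, EditTarget, GenomeAssembly
from .pileup import COL_INDEX, COLUMNS, PileupMatrix

logger = logging.getLogger(__name__)

#: strand-collapsed substitution classes, pyrimidine reference first
SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

COMPARTMENTS = ("on_target", "mito_bystander", "nuclear_offtarget", "indel")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: default class weights: strong C·G→T·A enrichment, residual weight spread
#: evenly over the other five classes
DEFAULT_SPECTRUM = {
    "C>A": 0.02, "C>G": 0.02, "C>T": 0.90, "T>A": 0.02, "T>C": 0.02, "T>G": 0.02,
}


@dataclass(frozen=True)
class TruthEdit:
    """One injected edit (ground truth)."""

    contig: str
    position: int  # 1-based
    ref: str
    alt: str  # base, or "DEL" for a 1-bp deletion
    af: float
    compartment: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref, self.alt)


@dataclass
class EditingModel:
    """Parameters of the editing process being simulated.

    on_target_af
        Heteroplasmy of the programmed edit in the edited sample.
    bystander_count
        Expected number of mtDNA bystander C·G→T·A edits (Poisson mean).
    bystander_min_af / bystander_max_af
        Uniform AF band for bystanders; the ceiling defaults to 0.05,
        the detection floor to 0.01.
    bystander_window
        Most bystanders fall within spacer ± this many bp.
    lambda_nuclear
        Expected number of nuclear off-target SNVs (Poisson mean).
    off_target_af
        Clonal allele fraction of nuclear off-targets (single-blastomere
        heterozygous-like, default 0.5).
    f_TC
        Probability that a C·G→T·A off-target carries T immediately 5' of
        the edited C on the edited strand.
    spectrum_weights
        Strand-collapsed substitution-class weights, summing to 1.
    indel_rate
        Expected number of 1-bp deletions (Poisson mean; default 0).
    """

    on_target_af: float = 0.46
    bystander_count: float = 6.0
    bystander_min_af: float = 0.01
    bystander_max_af: float = 0.05
    bystander_window: int = 15
    lambda_nuclear: float = 500.0
    off_target_af: float = 0.5
    f_TC: float = 0.7
    spectrum_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM)
    )
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.on_target_af <= 1:
            raise ValueError("on_target_af must be in (0, 1]")
        for name in ("f_TC", "off_target_af", "bystander_min_af", "bystander_max_af"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.lambda_nuclear < 0 or self.indel_rate < 0 or self.bystander_count < 0:
            raise ValueError("rates must be non-negative")
        total = sum(self.spectrum_weights.values())
        if abs(total - 1) > 1e-9:
            raise ValueError(f"spectrum_weights sum to {total}, expected 1")
        if set(self.spectrum_weights) - set(SUB_CLASSES):
            raise ValueError("unknown substitution class in spectrum_weights")


@dataclass
class SimTruth:
    """Ground-truth injected edits plus the model and seed that produced them."""

    edits: list[TruthEdit]
    model: EditingModel
    seed: int
    target: EditTarget | None = None

    def __post_init__(self) -> None:
        keys = [(e.contig, e.position) for e in self.edits]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (contig, position) in truth")

    def by_compartment(self, compartment: str) -> list[TruthEdit]:
        return [e for e in self.edits if e.compartment == compartment]

    @property
    def keys(self) -> set[tuple[str, int, str, str]]:
        return {e.key for e in self.edits}


_RESAMPLE_CAP = 1000


def _pick_site(
    rng: np.random.Generator,
    genome: GenomeAssembly,
    contig_names: list[str],
    contig_weights: np.ndarray,
    wanted_bases: str,
    taken: set[tuple[str, int]],
    context_5p: str | None = None,
) -> tuple[str, int, str] | None:
    """Uniform random (contig, pos, base) with the plus-strand base in
    `wanted_bases`, optionally requiring the 5'-neighbour on the edited strand
    to be T (context_5p == "T") or not-T (context_5p == "notT").

    Rejection-samples up to a cap; past the cap the context requirement is
    dropped (logged) and the last base-matching candidate is accepted.
    """
    fallback = None
    for attempt in range(_RESAMPLE_CAP):
        contig = contig_names[rng.choice(len(contig_names), p=contig_weights)]
        seq = genome.contigs[contig]
        pos = int(rng.integers(1, len(seq) + 1))
        if (contig, pos) in taken:
            continue
        base = seq[pos - 1]
        if base not in wanted_bases:
            continue
        if context_5p is None:
            return contig, pos, base
        # 5' neighbour on the strand where the pyrimidine sits
        if base in "CT":
            n_pos = pos - 1
            neighbour = seq[n_pos - 1] if n_pos >= 1 else None
        else:
            n_pos = pos + 1
            neighbour = _COMP[seq[n_pos - 1]] if n_pos <= len(seq) else None
        if neighbour is None:
            continue
        fallback = (contig, pos, base)
        if context_5p == "T" and neighbour == "T":
            return contig, pos, base
        if context_5p == "notT" and neighbour != "T":
            return contig, pos, base
    if fallback is not None:
        logger.warning(
            "context resampling cap (%d) reached; accepting %s:%d without the "
            "%s constraint", _RESAMPLE_CAP, fallback[0], fallback[1], context_5p,
        )
        return fallback
    return None


def inject_edits(
    genome: GenomeAssembly,
    target: EditTarget,
    model: EditingModel,
    seed: int,
) -> SimTruth:
    """Draw the ground-truth edit set for one edited blastomere.

    The on-target edit is placed at the programmed site at `on_target_af`.
    Bystanders (count ~ Poisson(bystander_count)) are C·G→T·A edits: 80% land
    uniformly within spacer ± bystander_window, 20% anywhere else on the mito
    circle, with AF uniform in (bystander_min_af, bystander_max_af).  Nuclear
    off-targets (count ~ Poisson(lambda_nuclear)) are placed uniformly over
    the nuclear contigs with class drawn from spectrum_weights; for the C>T
    class the 5' T context is present with probability exactly f_TC (forced
    present or forced absent per site).  All off-targets sit at
    `off_target_af`; indels are 1-bp deletions, count ~ Poisson(indel_rate).
    """
    target.validate(genome)
    rng = np.random.default_rng(seed)
    mito = genome.mito_name
    mito_seq = genome.contigs[mito]
    mito_len = len(mito_seq)

    edits: list[TruthEdit] = []
    taken: set[tuple[str, int]] = set()

    # on-target
    edits.append(
        TruthEdit(mito, target.position, target.ref, target.alt,
                  model.on_target_af, "on_target")
    )
    taken.add((mito, target.position))

    # mito bystanders
    n_bys = int(rng.poisson(model.bystander_count))
    s_lo, s_hi = target.spacer
    w = model.bystander_window
    for _ in range(n_bys):
        for _ in range(_RESAMPLE_CAP):
            if rng.random() < 0.80:
                pos = int(rng.integers(s_lo - w, s_hi + w + 1))
                pos = (pos - 1) % mito_len + 1
            else:
                pos = int(rng.integers(1, mito_len + 1))
            if (mito, pos) in taken:
                continue
            base = mito_seq[pos - 1]
            if base in "CG":
                break
        else:  # pragma: no cover
            continue
        alt = "T" if base == "C" else "A"
        af = float(rng.uniform(model.bystander_min_af, model.bystander_max_af))
        edits.append(TruthEdit(mito, pos, base, alt, af, "mito_bystander"))
        taken.add((mito, pos))

    # nuclear off-target SNVs
    nuc_names = genome.nuclear_names
    weights = np.array([len(genome.contigs[c]) for c in nuc_names], dtype=float)
    weights /= weights.sum()
    classes = list(model.spectrum_weights)
    class_p = np.array([model.spectrum_weights[c] for c in classes])
    n_off = int(rng.poisson(model.lambda_nuclear))
    for _ in range(n_off):
        sub = classes[int(rng.choice(len(classes), p=class_p))]
        pyr_ref, pyr_alt = sub[0], sub[2]
        wanted = pyr_ref + _COMP[pyr_ref]
        context = None
        if sub == "C>T":
            context = "T" if rng.random() < model.f_TC else "notT"
        picked = _pick_site(rng, genome, nuc_names, weights, wanted, taken, context)
        if picked is None:  # pragma: no cover
            continue
        contig, pos, base = picked
        alt = pyr_alt if base == pyr_ref else _COMP[pyr_alt]
        edits.append(
            TruthEdit(contig, pos, base, alt, model.off_target_af, "nuclear_offtarget")
        )
        taken.add((contig, pos))

    # 1-bp deletions
    n_indel = int(rng.poisson(model.indel_rate))
    for _ in range(n_indel):
        picked = _pick_site(rng, genome, nuc_names, weights, BASES, taken)
        if picked is None:  # pragma: no cover
            continue
        contig, pos, base = picked
        edits.append(
            TruthEdit(contig, pos, base, "DEL", model.off_target_af, "indel")
        )
        taken.add((contig, pos))

    return SimTruth(edits=edits, model=model, seed=seed, target=target)


def simulate_pileups(
    genome: GenomeAssembly,
    truth: SimTruth | None,
    depth: float = 40.0,
    mito_depth: float = 1000.0,
    error_rate: float = 0.002,
    seed: int = 0,
    sample_id: str = "sample",
) -> PileupMatrix:
    """Simulate site-level read counts for one sample.

    Per-site spanning depth is Poisson(depth) (Poisson(mito_depth) on the
    mitochondrial contig).  At a truth site, alt reads ~ Binomial(depth_i,
    AF·(1−error_rate)); every non-alt read is the reference base but miscalls
    uniformly to each of the three other bases with total probability
    `error_rate`.  `truth=None` gives a clean matched control.
    """
    if depth <= 0 or mito_depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    rng = np.random.default_rng(seed)

    counts: dict[str, np.ndarray] = {}
    for contig, seq in genome.contigs.items():
        n = len(seq)
        mean = mito_depth if contig == genome.mito_name else depth
        d = rng.poisson(mean, size=n).astype(np.int64)
        arr = np.zeros((n, len(COLUMNS)), dtype=np.int32)

        # sequencing errors: e_i ~ Binomial(d_i, error_rate), split uniformly
        # over the three non-reference bases via a binomial chain
        if error_rate > 0:
            e = rng.binomial(d, error_rate)
            e1 = rng.binomial(e, 1 / 3)
            e2 = rng.binomial(e - e1, 1 / 2)
            e3 = e - e1 - e2
        else:
            e = e1 = e2 = e3 = np.zeros(n, dtype=np.int64)

        ref_idx = np.frombuffer(seq.encode(), dtype=np.uint8)
        lut = np.zeros(128, dtype=np.int8)
        for i, b in enumerate(BASES):
            lut[ord(b)] = i
        ref_col = lut[ref_idx]

        for r in range(4):
            mask = ref_col == r
            others = [j for j in range(4) if j != r]
            arr[mask, r] = (d - e)[mask]
            for o, part in zip(others, (e1, e2, e3)):
                arr[mask, o] += part[mask]
        counts[contig] = arr

    if truth is not None:
        for edit in truth.edits:
            arr = counts[edit.contig]
            i = edit.position - 1
            d_i = int(arr[i, :4].sum())  # depth drawn above (DEL col still 0)
            alt_n = int(rng.binomial(d_i, edit.af * (1 - error_rate)))
            rest = d_i - alt_n
            row = np.zeros(len(COLUMNS), dtype=np.int32)
            ref_j = BASES.index(edit.ref)
            if error_rate > 0:
                err = int(rng.binomial(rest, error_rate))
            else:
                err = 0
            row[ref_j] = rest - err
            others = [j for j in range(4) if j != ref_j]
            split = rng.multinomial(err, [1 / 3] * 3) if err else np.zeros(3, int)
            for o, cnt in zip(others, split):
                row[o] += int(cnt)
            if edit.alt == "DEL":
                row[COL_INDEX["DEL"]] = alt_n
            elif edit.alt == "INS":
                row[COL_INDEX["INS"]] = alt_n
                row[ref_j] += alt_n  # inserted-allele reads still span the site
            else:
                row[BASES.index(edit.alt)] += alt_n
            arr[i] = row

    return PileupMatrix(sample_id=sample_id, counts=counts, ref=dict(genome.contigs))
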
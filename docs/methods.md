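# Methods

## The experimental design being modelled

A GOTI experiment injects a base editor plus a Cre/tdTomato lineage marker
into one blastomere of a two-cell embryo, leaves the sibling blastomere
untouched, and sequences the sorted marker-positive and marker-negative cell
populations of the resulting fetus. Both populations descend from the same
zygote, so their germline variation cancels: a variant confidently present in
the edited population and absent from the sibling is a de-novo event that
arose after injection. Marker-only embryos, processed identically, measure
the background of the procedure itself. `gotipipe` implements the
computational half of this design — from site-level read counts to the
characterization panels — together with a generator that produces synthetic
inputs with the same statistical structure, so that every stage has ground
truth to be tested against.

## Generative model (synthetic_data)

The generator emulates, per edited embryo:

- **Genome.** Nuclear contigs plus one circular mitochondrial contig, i.i.d.
  bases at a set GC content (default 0.42, mammalian-like). NUMTs are exact
  copies of random mito segments (100–2000 bp) pasted into nuclear contigs;
  "transcribed" intervals are non-overlapping random intervals (2–20 kb)
  whose summed fraction is recorded. Default scale is 2 Mb nuclear + 16 kb
  mito — the mito contig at its natural size, the nuclear genome scaled down
  ~1300× so a full experiment runs in seconds; the off-target *rate* scales
  with it (below).
- **On-target edit** at heteroplasmy `on_target_af` (default 0.46, an
  editing efficiency actually achievable by these editors).
- **Bystanders.** Count ~ Poisson(`bystander_count`, default 6). Placement:
  80% uniform within spacer ± `bystander_window` (15 bp), 20% uniform
  elsewhere on the circle — a concrete reading of "mostly around the target,
  some elsewhere" for which no distribution is stated anywhere; the split is
  config-exposed in code. Sites must carry C or G (the edit is always
  C·G→T·A); AF uniform in (`bystander_min_af`=0.01, `bystander_max_af`=0.05),
  the ceiling reflecting that observed unintended mtDNA events sit below 5%.
- **Nuclear off-targets.** Count ~ Poisson(`lambda_nuclear`, default 500 at
  the 2 Mb scale), positions uniform, substitution class from
  `spectrum_weights` (default 90% C>T, 2% each of the other five classes),
  clonal AF `off_target_af` = 0.5. A single-blastomere lineage that is
  heterozygous for each event is the natural model for sorted cells; no AF
  distribution is claimed by the source experiments, so 0.5 is a modelling
  choice. For the C>T class the 5′-TC-3′ context is present with probability
  exactly `f_TC` (default 0.7): a Bernoulli(f_TC) draw decides whether the
  site is rejection-sampled until the base 5′ of the edited C **is** T or
  until it is **not** T. Forcing both branches makes the realized TC fraction
  converge to `f_TC` rather than to `f_TC + (1−f_TC)·background`. Rejection
  is capped at 1000 attempts, after which the last base-compatible candidate
  is accepted and a warning logged.
- **Indels** are 1-bp deletions, count ~ Poisson(`indel_rate`, default 0) —
  enough to exercise the indel-counting path, which in the modelled
  experiments stays near zero.
- **Sequencing.** Per-site spanning depth ~ Poisson(40) nuclear /
  Poisson(1000) mito. At a truth site, alt reads ~ Binomial(d, AF·(1−e));
  every other read is the reference base with probability 1−e and otherwise
  miscalls uniformly to one of the three other bases (e = `error_rate`,
  default 0.002). Deleted reads are counted in the DEL column and in
  spanning depth; insertion-carrying reads also count toward their reference
  base.

What the generator does **not** model: read-level artifacts (mapping bias,
strand bias, base-quality structure), alignment around indels, mtDNA
copy-number variation, heteroplasmy drift, and clonal substructure. Passing
tests therefore demonstrate that the *statistical* machinery is correct
under the stated model, not that the pipeline is robust to alignment
artifacts in real BAMs — real-data use should feed externally-called VCFs
into the same de-novo subtraction.

## Calling and paired subtraction (goti_calling)

The built-in caller is deliberately simple and fully specified: a site/allele
is called iff depth ≥ `min_depth` (10), alt reads ≥ `min_alt_reads` (3),
alt fraction ≥ `min_af` (0.1 nuclear, 0.01 mito), and the binomial upper
tail P(X ≥ a | Bin(d, e/3)) < `alpha` (1e−6). The original protocol ran
three external somatic callers and intersected them; those settings are not
restated in the source and the callers are not re-run here — `consensus`
(keep keys in ≥ k of n call sets, default full intersection) provides the
intersection semantics for externally supplied VCFs, and the built-in caller
is an explicit, config-exposed stand-in. `alpha` is applied per site with no
genome-wide correction: the binomial screen is a pre-filter; the actual
specificity mechanism of the design is the control-absence filter.

De-novo retention requires ≤ `max_control_alt_reads` (1) supporting reads
*and* control AF ≤ `max_control_af` (0.02) at the same site, plus absence
from an optional germline set (empty by default — the sibling design already
subtracts germline variation). Note an interaction at moderate coverage: at
40× control depth, a single control error read gives AF 0.025 > 0.02, so the
AND of the two thresholds removes ~2.5% of true clonal off-targets (one
control miscall at the site occurs with probability ≈ 40·e/3). This is the
source of the ≈0.97 recall seen in the acceptance runs; both thresholds are
config-exposed.

Group summaries report per-sample SNV/indel counts with mean ± SEM
(sd/√n; a group of one reports SEM 0 and carries its n).

## Mitochondrial analysis (mito_analysis)

On-target efficiency is the alt fraction of the programmed allele at the
target site — heteroplasmy as seen by sequencing. Unintended events are
restricted to C→T / G→A sites (the chemistry of the editor), screened with
the mito caller's evidence thresholds, and flagged `low_frequency` below 5%
AF. Zones partition the circle: spacer ≻ TALE footprint ≻ proximal (within
`proximal_window` = 500 bp of the spacer midpoint by circular distance; the
width of the "near the target" window is not stated numerically anywhere, so
it is a config default) ≻ distal. Coding consequences translate ref and alt
codons under NCBI translation table 2 (vertebrate mitochondrial), honoring
strand; categories are silent (equal amino acids), nonsense (alt = stop),
else missense.

## Spectrum and motif (spectrum_motif)

The six strand-collapsed classes represent each purine-reference change by
its reverse complement; the exhaustive 12→2×6 map is tested. Context
windows (half-width 10 by default; the published logo's width is not stated)
are oriented so the edited base reads C at offset 0 — G-reference records
contribute the reverse complement of their plus-strand window — and wrap on
the circular contig; off-end windows on linear contigs are dropped and
counted. Information content is IC = 2 − H bits with 0·log 0 := 0; the
standard small-sample correction 3/(2·ln2·n) is available behind a flag but
off by default (no correction formula is implied by "bits"). TC enrichment
uses Fisher's exact test (appropriate at small counts) on T-at-(−1) vs the
genomic dinucleotide background (both strands: TC dinucleotides and their
GA mirror images, per cytosine); the odds ratio takes the Haldane–Anscombe
+0.5 correction when a cell is zero, flagged. The group-comparison statistic
is the classic pooled-variance unpaired Student's t (two-tailed, df =
n₁+n₂−2), computed through the incomplete-beta form of the t distribution;
Welch's form is behind a flag. Zero pooled variance with equal means gives
t = 0, p = 1; with unequal means the result is flagged `infinite_t` with
p = 0, outside the normal p ∈ (0,1] contract by construction.

## Genomic context (genome_context)

Transcribed-region assignment uses merged half-open intervals; the null
expectation is n × (transcribed bp / nuclear bp) with a two-sided binomial
p per sample, and a t-test on per-sample in-fractions across two groups.
Uniformity is a chi-square goodness of fit over bins tiling the nuclear
contigs (default 100 kb at the 2 Mb scale), expectations proportional to bin
length, adjacent bins merged until every expectation is ≥ 1; a single
surviving bin is defined as non-rejecting (p = 1). Cross-sample overlap
intersects exact (contig, pos, ref, alt) keys — "overlapping SNVs" read
strictly; a position-only mode is a flag — against the independent-uniform
expectation n_i·n_j/G. Mitochondrial records are excluded from the overlap:
the programmed on-target edit is shared by every edited sample by
construction and says nothing about sequence-independent placement. The
similarity screen scores each off-target's ±flank window (default 20 bp)
against the target-region sequence and its reverse complement by local
alignment (match +1, mismatch −1, gap open −2, extend −1, via Biopython's
PairwiseAligner) and compares the score distribution with scores at 10× as
many seeded random positions; NUMT membership is an interval-overlap flag.

## Orchestration and determinism

`run_pipeline` executes genome → target → per-embryo (inject, simulate,
call, subtract) → mito profile → spectrum/logo/enrichment → context →
similarity, for `replicates.edited` edited embryos and
`replicates.control` marker-only embryos (each an unedited sample called
against a second unedited sibling). Every stochastic stage draws from a
child seed derived via `SeedSequence([seed, stream])`, so reports are
byte-identical for a fixed (config, seed); the report embeds the seed, a
config hash and the package version. All thresholds above surface in the
single JSON config with these defaults.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the full experiment at the
default 2 Mb + 16 kb scale (λ = 500 off-targets, 40×/1000× coverage,
3 edited + 2 marker-only embryos in the script), with Monte-Carlo checks at
100–400 replicates on smaller assemblies; these sizes were chosen so a
complete run takes seconds while every binomial/Poisson tolerance retains a
≥3σ margin. The overlap-null check simulates with a flat substitution
spectrum so that placement is effectively uniform and the n²/G Poisson
envelope applies; under the default TC-concentrated spectrum the effective
site pool is smaller and random collisions are correspondingly more
frequent — the observed/expected comparison in `OverlapReport` is the
general-purpose tool.

## Known limitations

- The built-in caller is a stand-in for external somatic callers; real
  studies should supply caller VCFs and use `consensus`.
- Pileup simulation is site-level; artifacts that require read-level
  modelling are out of scope.
- The bystander placement mixture (80/20) and the nuclear off-target AF
  (0.5) are modelling choices where the underlying experiments state none.
- `similarity_screen` reports distributions and flags; it does not define a
  single "bias detected" decision rule.
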
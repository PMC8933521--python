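"""End-to-end orchestration: simulate → call → de-novo → characterize.

A run is described by a single JSON-serializable config; every stochastic
stage draws from a child seed derived from the run seed, so a run is
reproducible byte-for-byte from (config, seed).  The run emulates a GOTI
experiment: several edited embryos (edited sample vs matched unedited
sibling) and several marker-only control embryos (two unedited samples from
the same genome), mirroring the editor-injected vs Cre-only groups.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .calling import (
    CallerConfig,
    DeNovoFilters,
    DeNovoSet,
    MITO_CALLER_CONFIG,
    call_variants,
    count_summary,
    de_novo_indels,
    de_novo_snvs,
)
from .context import (
    cross_sample_overlap,
    region_breakdown,
    similarity_screen,
    uniformity_test,
)
from .genome import EditTarget, GenomeAssembly, design_target
from .io import (
    read_fasta,
    read_target_json,
    write_bed,
    write_calls_vcf,
    write_fasta,
    write_truth_vcf,
)
from .mito import mito_offtargets, ontarget_efficiency
from .simulate import EditingModel, inject_edits, simulate_pileups
from .spectrum import (
    extract_contexts,
    genome_tc_background,
    logo_bits,
    spectrum,
    tc_enrichment,
)

logger = logging.getLogger("gotipipe")

DEFAULT_CONFIG: dict[str, Any] = {
    "outdir": None,  # no file output unless set
    "seed": 0,
    "genome": {
        "fasta": None,  # path to load instead of simulating
        "n_nuclear": 2,
        "nuclear_len": 2_000_000,
        "mito_len": 16_000,
        "n_numt": 5,
        "n_genes": 40,
        "gc": 0.42,
    },
    "target": None,  # path to a target JSON, else auto-designed
    "model": {
        "on_target_af": 0.46,
        "bystander_count": 6.0,
        "bystander_min_af": 0.01,
        "bystander_max_af": 0.05,
        "bystander_window": 15,
        "lambda_nuclear": 500.0,
        "off_target_af": 0.5,
        "f_TC": 0.7,
        "indel_rate": 0.0,
    },
    "sequencing": {
        "depth": 40.0,
        "mito_depth": 1000.0,
        "error_rate": 0.002,
    },
    "replicates": {"edited": 2, "control": 2},
    "caller": {
        "min_depth": 10,
        "min_alt_reads": 3,
        "min_af": 0.1,
        "alpha": 1e-6,
        "error_rate": 0.002,
    },
    "mito_caller": {"min_af": 0.01},
    "denovo": {"max_control_alt_reads": 1, "max_control_af": 0.02},
    "analysis": {
        "logo_half_width": 10,
        "flank": 20,
        "bin_size": 100_000,
        "proximal_window": 500,
        "mito_min_af": 0.01,
        "similarity_null_multiplier": 10,
    },
}


def make_config(overrides: dict | None = None) -> dict:
    """Deep-merged copy of the defaults with `overrides` applied."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst: dict, src: dict) -> None:
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if overrides:
        merge(cfg, overrides)
    return cfg


def validate_config(config: dict) -> list[str]:
    """Return a list of violations; an empty list means runnable."""
    problems: list[str] = []
    known = set(DEFAULT_CONFIG)
    for key in config:
        if key not in known:
            problems.append(f"unknown config section {key!r}")
    seed = config.get("seed")
    if not isinstance(seed, int):
        problems.append("seed is mandatory and must be an integer")
    g = config.get("genome", {})
    if g.get("fasta") is not None and not Path(g["fasta"]).exists():
        problems.append(f"genome fasta not found: {g['fasta']}")
    elif g.get("fasta") is None:
        if g.get("nuclear_len", 1) < 10 * g.get("mito_len", 0):
            problems.append("genome.nuclear_len must be >= 10x genome.mito_len")
        if not 0 < g.get("gc", 0.42) < 1:
            problems.append("genome.gc must be in (0, 1)")
    if config.get("target") is not None and not Path(config["target"]).exists():
        problems.append(f"target file not found: {config['target']}")
    m = config.get("model", {})
    if not 0 < m.get("on_target_af", 0.46) <= 1:
        problems.append("model.on_target_af must be in (0, 1]")
    if m.get("lambda_nuclear", 0) < 0:
        problems.append("model.lambda_nuclear must be >= 0")
    s = config.get("sequencing", {})
    if s.get("depth", 40) <= 0:
        problems.append("sequencing.depth must be positive")
    if not 0 <= s.get("error_rate", 0) < 0.25:
        problems.append("sequencing.error_rate must be in [0, 0.25)")
    r = config.get("replicates", {})
    if r.get("edited", 1) < 1:
        problems.append("replicates.edited must be >= 1")
    if config.get("caller", {}).get("min_depth", 1) < 1:
        problems.append("caller.min_depth must be >= 1")
    return problems


def derive_seed(seed: int, stream: int) -> int:
    """Deterministic child seed (< 2^31) for one named stochastic stage."""
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


def run_pipeline(config: dict) -> dict:
    """Execute the full workflow and return the analysis report.

    Stages: genome (simulate or load) → target → per-embryo edit injection,
    pileup simulation, calling and de-novo derivation → mitochondrial
    profile → spectrum/logo/enrichment → genomic context → similarity screen.
    If `config["outdir"]` is set, standard-format outputs and report.json are
    written there.
    """
    config = make_config(config)
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    seed = config["seed"]

    # --- genome ----------------------------------------------------------
    g = config["genome"]
    if g["fasta"] is not None:
        genome = read_fasta(g["fasta"])
    else:
        genome = generate_stage_genome(g, derive_seed(seed, 0))
    logger.info("stage=genome contigs=%d nuclear_bp=%d mito_bp=%d",
                len(genome.contigs), genome.nuclear_size, genome.mito_len)

    # --- target ----------------------------------------------------------
    if config["target"] is not None:
        target = read_target_json(config["target"])[0]
    else:
        target = design_target(genome, seed=derive_seed(seed, 1))
    target.validate(genome)
    logger.info("stage=target label=%s spacer=%s", target.label, target.spacer)

    model = EditingModel(**config["model"])
    seq = config["sequencing"]
    caller_cfg = CallerConfig(**config["caller"])
    mito_cfg = CallerConfig(**{**config["caller"], **config["mito_caller"]})
    filters = DeNovoFilters(**config["denovo"])
    ana = config["analysis"]

    # --- per-embryo edited/control pairs ---------------------------------
    R = config["replicates"]["edited"]
    C = config["replicates"]["control"]
    edited_sets: list[DeNovoSet] = []
    indel_sets: list[DeNovoSet] = []
    truths = []
    mito_profiles = []
    for r in range(R):
        truth = inject_edits(genome, target, model, derive_seed(seed, 10 + r))
        edited = simulate_pileups(
            genome, truth, seq["depth"], seq["mito_depth"], seq["error_rate"],
            derive_seed(seed, 100 + r), sample_id=f"edited_{r + 1}",
        )
        control = simulate_pileups(
            genome, None, seq["depth"], seq["mito_depth"], seq["error_rate"],
            derive_seed(seed, 200 + r), sample_id=f"control_{r + 1}",
        )
        calls = call_variants(edited, caller_cfg)
        mito_calls_cfg = mito_cfg  # mito sites re-screened inside mito_offtargets
        snvs = de_novo_snvs(calls, control, filters=filters,
                            sample_id=edited.sample_id)
        indels = de_novo_indels(calls, control, filters=filters,
                                sample_id=edited.sample_id)
        profile = mito_offtargets(
            edited, target, min_af=ana["mito_min_af"], cfg=mito_calls_cfg,
            proximal_window=ana["proximal_window"],
        )
        edited_sets.append(snvs)
        indel_sets.append(indels)
        truths.append(truth)
        mito_profiles.append(profile)
        logger.info(
            "stage=pair sample=%s snvs=%d indels=%d mito_offtargets=%d",
            edited.sample_id, len(snvs), len(indels), len(profile.offtargets),
        )

    # control-only embryos: one unedited sample called against another
    control_sets: list[DeNovoSet] = []
    for r in range(C):
        a = simulate_pileups(
            genome, None, seq["depth"], seq["mito_depth"], seq["error_rate"],
            derive_seed(seed, 300 + r), sample_id=f"cre_{r + 1}",
        )
        b = simulate_pileups(
            genome, None, seq["depth"], seq["mito_depth"], seq["error_rate"],
            derive_seed(seed, 400 + r), sample_id=f"cre_sibling_{r + 1}",
        )
        calls = call_variants(a, caller_cfg)
        control_sets.append(
            de_novo_snvs(calls, b, filters=filters, sample_id=a.sample_id)
        )
        logger.info("stage=control sample=%s snvs=%d", a.sample_id,
                    len(control_sets[-1]))

    # merge per-sample SNV+indel records so counts cover both kinds
    full_sets = [
        DeNovoSet(s.sample_id, {**s.calls, **i.calls}, s.provenance)
        for s, i in zip(edited_sets, indel_sets)
    ]
    all_sets = full_sets + control_sets
    groups = ["edited"] * R + ["control"] * C
    counts = count_summary(all_sets, groups)

    # --- pooled characterization -----------------------------------------
    pooled_calls = {}
    for s in edited_sets:
        pooled_calls.update(s.calls)
    pooled = DeNovoSet("edited_pooled", pooled_calls)

    spec_res = spectrum(pooled)
    contexts = extract_contexts(genome, pooled, ana["logo_half_width"])
    report: dict[str, Any] = {}
    if contexts.n_rows:
        logo = logo_bits(contexts)
        enrich = tc_enrichment(contexts, genome_tc_background(genome))
        report["logo"] = {
            "positions": logo.positions,
            "information_bits": logo.information,
            "t_freq_minus1": contexts.base_fraction(-1, "T"),
        }
        report["tc_enrichment"] = {
            "table": enrich.table,
            "odds_ratio": enrich.odds_ratio,
            "p_value": enrich.p_value,
        }

    breakdown = region_breakdown(
        all_sets, genome.annotations_of("transcribed"), genome, groups
    )
    n_nuclear_snvs = sum(
        1 for c in pooled.snvs if c.contig != genome.mito_name
    )
    uniformity = (
        uniformity_test(pooled, genome, ana["bin_size"]) if n_nuclear_snvs else None
    )
    overlap = (
        cross_sample_overlap(edited_sets, genome) if R >= 2 else None
    )
    target_region = genome.window(
        genome.mito_name, int(target.spacer_mid),
        (target.tale_right[1] - target.tale_left[0]) // 2 + 1,
    )
    similarity = similarity_screen(
        pooled, genome, [target_region],
        flank=ana["flank"], seed=derive_seed(seed, 500),
        null_multiplier=ana["similarity_null_multiplier"],
    ) if len(pooled.snvs) else None

    report.update(
        {
            "provenance": {
                "version": __version__,
                "seed": seed,
                "config_hash": _config_hash(config),
            },
            "target": {
                "label": target.label,
                "position": target.position,
                "spacer": list(target.spacer),
            },
            "counts": {
                "per_sample": counts.per_sample.to_dict(orient="records"),
                "per_group": counts.per_group.to_dict(orient="records"),
            },
            "on_target_af": [p.on_target_af for p in mito_profiles],
            "mito_offtargets": [
                {
                    "sample": s.sample_id,
                    "events": [
                        {
                            "label": site.label,
                            "af": site.af,
                            "zone": site.zone,
                            "low_frequency": site.low_frequency,
                        }
                        for site in p.offtargets
                    ],
                }
                for s, p in zip(edited_sets, mito_profiles)
            ],
            "spectrum": {
                "counts": spec_res.counts,
                "proportions": spec_res.proportions,
                "n": spec_res.n,
                "ct_fraction": spec_res.proportions.get("C>T"),
            },
            "region_breakdown": {
                "per_sample": breakdown.per_sample.to_dict(orient="records"),
                "transcribed_fraction": breakdown.transcribed_fraction,
                "group_t": None
                if breakdown.group_test is None
                else {"t": breakdown.group_test.t, "p": breakdown.group_test.p},
            },
            "uniformity": None
            if uniformity is None
            else {
                "chi2": uniformity.statistic,
                "p": uniformity.p_value,
                "n_bins": uniformity.n_bins,
            },
            "overlap": None
            if overlap is None
            else {
                "pairwise": {f"{i}-{j}": v for (i, j), v in overlap.pairwise.items()},
                "expected_pairwise": {
                    f"{i}-{j}": v for (i, j), v in overlap.expected_pairwise.items()
                },
                "k_way": overlap.k_way,
            },
            "similarity": None if similarity is None else similarity.summary(),
            "truth_counts": [
                {c: len(t.by_compartment(c)) for c in
                 ("on_target", "mito_bystander", "nuclear_offtarget", "indel")}
                for t in truths
            ],
        }
    )
    report = _jsonable(report)

    # --- outputs ----------------------------------------------------------
    outdir = config.get("outdir")
    if outdir:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out / "genome.fa")
        write_bed(genome.annotations, out / "annotations.bed")
        for r, (t, s, i) in enumerate(zip(truths, edited_sets, indel_sets), 1):
            write_truth_vcf(t, out / f"truth_{r}.vcf", genome)
            write_calls_vcf(s, out / f"denovo_snv_{r}.vcf", genome)
            s.to_frame().to_csv(out / f"denovo_snv_{r}.tsv", sep="\t", index=False)
            write_calls_vcf(i, out / f"denovo_indel_{r}.vcf", genome)
        (out / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=2) + "\n"
        )
        logger.info("stage=report outdir=%s", out)

    return report


def generate_stage_genome(g: dict, seed: int) -> GenomeAssembly:
    from .genome import generate_genome

    return generate_genome(
        n_nuclear=g["n_nuclear"],
        nuclear_len=g["nuclear_len"],
        mito_len=g["mito_len"],
        n_numt=g["n_numt"],
        n_genes=g["n_genes"],
        gc=g["gc"],
        seed=seed,
    )
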
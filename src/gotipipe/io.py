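"""Standard-format readers and writers: FASTA, BED6, VCF v4.2, JSON targets.

Everything is plain text.  Truth sets and de-novo sets are written as minimal
VCF v4.2 (INFO keys TRUE_AF/COMPARTMENT for truth, AF/DP/AC for calls);
1-bp deletions are encoded as explicit ref/alt allele pairs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

from .calling import DeNovoSet, VariantCall
from .genome import Annotation, EditTarget, GenomeAssembly
from .simulate import SimTruth

FASTA_WIDTH = 60


def write_fasta(genome: GenomeAssembly, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WIDTH):
                fh.write(seq[i : i + FASTA_WIDTH] + "\n")


def read_fasta(path: str | Path, mito_name: str = "chrM") -> GenomeAssembly:
    contigs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    contigs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        contigs[name] = "".join(chunks)
    return GenomeAssembly(contigs=contigs, mito_name=mito_name)


def write_bed(annotations: Iterable[Annotation], path: str | Path) -> None:
    """BED6: chrom start end name score strand (name = kind:label)."""
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(
                f"{a.contig}\t{a.start}\t{a.end}\t{a.kind}:{a.label}\t0\t{a.strand}\n"
            )


def read_bed(path: str | Path) -> list[Annotation]:
    out: list[Annotation] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "transcribed:"
            strand = parts[5] if len(parts) > 5 else "+"
            kind, _, label = name.partition(":")
            out.append(Annotation(contig, start, end, strand, kind, label))
    return out


_VCF_HEADER = """\
##fileformat=VCFv4.2
{extra}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _indel_alleles(genome: GenomeAssembly | None, contig: str, pos: int,
                   ref: str, alt: str) -> tuple[int, str, str]:
    """VCF-encode a 1-bp deletion/insertion as anchored allele strings."""
    if alt == "DEL":
        if genome is not None and pos > 1:
            anchor = genome.base(contig, pos - 1)
            return pos - 1, anchor + ref, anchor
        return pos, ref + "N", ref  # no anchor available
    if alt == "INS":
        return pos, ref, ref + "N"
    return pos, ref, alt


def write_truth_vcf(truth: SimTruth, path: str | Path,
                    genome: GenomeAssembly | None = None) -> None:
    extra = (
        '##INFO=<ID=TRUE_AF,Number=1,Type=Float,Description="Injected allele fraction">\n'
        '##INFO=<ID=COMPARTMENT,Number=1,Type=String,Description="Edit compartment">\n'
    )
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(extra=extra))
        for e in sorted(truth.edits, key=lambda e: (e.contig, e.position)):
            pos, ref, alt = _indel_alleles(genome, e.contig, e.position, e.ref, e.alt)
            fh.write(
                f"{e.contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t"
                f"TRUE_AF={e.af:.6g};COMPARTMENT={e.compartment}\n"
            )


def write_truth_tsv(truth: SimTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\talt\taf\tcompartment\n")
        for e in sorted(truth.edits, key=lambda e: (e.contig, e.position)):
            fh.write(
                f"{e.contig}\t{e.position}\t{e.ref}\t{e.alt}\t{e.af:.6g}\t{e.compartment}\n"
            )


def write_calls_vcf(calls: DeNovoSet | Iterable[VariantCall], path: str | Path,
                    genome: GenomeAssembly | None = None) -> None:
    extra = (
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Alt allele fraction">\n'
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Spanning depth">\n'
        '##INFO=<ID=AC,Number=1,Type=Integer,Description="Alt read count">\n'
    )
    records = list(calls) if not isinstance(calls, DeNovoSet) else list(calls)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(extra=extra))
        for c in sorted(records, key=lambda c: (c.contig, c.pos, c.alt)):
            pos, ref, alt = _indel_alleles(genome, c.contig, c.pos, c.ref, c.alt)
            fh.write(
                f"{c.contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t"
                f"AF={c.af:.6g};DP={c.depth};AC={c.alt_count}\n"
            )


def read_calls_vcf(path: str | Path, caller: str = "external") -> set[VariantCall]:
    """Read a VCF call set (SNVs plus anchored 1-bp indels).

    INFO AC/DP are used when present; otherwise alt_count=1, depth=1 are
    recorded as placeholder evidence.
    """
    calls: set[VariantCall] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            contig, pos, _, ref, alt, _, _, info = line.rstrip("\n").split("\t")[:8]
            fields = dict(
                kv.split("=", 1) for kv in info.split(";") if "=" in kv
            )
            depth = int(fields.get("DP", 1))
            ac = int(fields.get("AC", 1))
            pos = int(pos)
            if len(ref) == 1 and len(alt) == 1:
                calls.add(VariantCall(contig, pos, ref, alt, ac, depth, caller))
            elif len(ref) == 2 and len(alt) == 1:  # anchored 1-bp deletion
                calls.add(VariantCall(contig, pos + 1, ref[1], "DEL", ac, depth, caller))
            elif len(ref) == 1 and len(alt) == 2:  # anchored 1-bp insertion
                calls.add(VariantCall(contig, pos, ref, "INS", ac, depth, caller))
    return calls


def write_target_json(targets: list[EditTarget], path: str | Path) -> None:
    payload = [
        {
            "label": t.label,
            "position": t.position,
            "ref": t.ref,
            "alt": t.alt,
            "tale_left": list(t.tale_left),
            "tale_right": list(t.tale_right),
        }
        for t in targets
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_target_json(path: str | Path) -> list[EditTarget]:
    payload = json.loads(Path(path).read_text())
    return [
        EditTarget(
            label=t["label"],
            position=t["position"],
            ref=t["ref"],
            alt=t["alt"],
            tale_left=tuple(t["tale_left"]),
            tale_right=tuple(t["tale_right"]),
        )
        for t in payload
    ]
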
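import numpy as np
import pytest

import gotipipe as gp


@pytest.fixture(scope="session")
def small_genome() -> gp.GenomeAssembly:
    """200 kb nuclear + 16 kb mito assembly shared by read-only tests."""
    return gp.generate_genome(
        n_nuclear=2, nuclear_len=200_000, mito_len=16_000,
        n_numt=3, n_genes=10, gc=0.42, seed=11,
    )


@pytest.fixture(scope="session")
def target(small_genome) -> gp.EditTarget:
    return gp.design_target(small_genome, seed=12)


@pytest.fixture()
def toy_genome() -> gp.GenomeAssembly:
    """Tiny hand-written assembly for exact-value checks.

    chrM carries the CDS ATG CAA GGA GAT TAA starting at 0-based position 6.
    """
    mito = "ACGTGA" + "ATGCAAGGAGAT" + "TAA" + "ACGTACGTACGTACGTACGTACGTACG"
    nuc = ("ACGT" * 40)[:150] + "TTCAG" + ("ACGT" * 40)[:145]
    return gp.GenomeAssembly(
        contigs={"chr1": nuc, "chrM": mito},
        mito_name="chrM",
        annotations=[gp.Annotation("chrM", 6, 21, "+", "CDS", "toy")],
    )


def make_pileup(genome: gp.GenomeAssembly, sample_id: str = "s") -> gp.PileupMatrix:
    """All-zero pileup over a genome, to be filled in by hand."""
    return gp.PileupMatrix.empty(genome, sample_id)


def set_site(pm: gp.PileupMatrix, contig: str, pos: int, **counts: int) -> None:
    """Overwrite one site's counts, e.g. set_site(pm, 'chrM', 5, C=54, T=46)."""
    row = np.zeros(6, dtype=np.int32)
    cols = {c: i for i, c in enumerate(("A", "C", "G", "T", "INS", "DEL"))}
    for col, v in counts.items():
        row[cols[col]] = v
    pm.counts[contig][pos - 1] = row


def fill_reference(pm: gp.PileupMatrix, depth: int = 50) -> None:
    """Give every site `depth` clean reference reads."""
    for contig, ref in pm.ref.items():
        arr = pm.counts[contig]
        arr[:] = 0
        for i, b in enumerate("ACGT"):
            arr[np.frombuffer(ref.encode(), dtype=np.uint8) == ord(b), i] = depth
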
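from __future__ import annotations

import numpy as np
import pytest

from bexplore.editors import get_editor
from bexplore.io import GenomeIndex, TargetSite
from bexplore.offtarget import uniform_cfd_table

# Hand-crafted downstream contexts for a plus-strand BE3 site. Offsets are
# counted from the target base; a placement with the target at protospacer
# position p needs an NGG PAM with its GG at offsets (22-p, 23-p).
UP19 = "ATCGATCGATCGATCGATC"               # inert upstream padding
DOWN_P5 = "ATCATCATCATCATCA" + "GG" + "TACAT"     # single AGG PAM, p=5
DOWN_NO_PAM = "ATCATCATCATCATCATCATCAT"[:23]       # GG-free
DOWN_P12 = "ATCATCATC" + "GG" + "TACATACATACT"     # PAM only at p=12
DOWN_RUN7 = "A" + "CCCCCCC" + "TACATACT" + "GG" + "TACAT"  # 7-C run, PAM p=5
UP4_GC = "GCGC"
DOWN_GC = "GCGCGCGCGCGCGCG" + "A" + "GG" + "TACAT"  # all-GC spacer, PAM p=5


def be3_genome(down: str, up: str = UP19, ref: str = "C") -> tuple[GenomeIndex, TargetSite]:
    """Genome with one target at position len(up)+1 and the given context."""
    seq = up + ref + down
    genome = GenomeIndex({"chr1": seq})
    pos = len(up) + 1
    alt = {"C": "T", "G": "A", "A": "G", "T": "C"}[ref]
    return genome, TargetSite("chr1", pos, ref, alt, f"chr1:{pos}")


@pytest.fixture(scope="session")
def be3():
    return get_editor("BE3")


@pytest.fixture(scope="session")
def abe():
    return get_editor("ABE7.10")


@pytest.fixture(scope="session")
def uniform_table():
    return uniform_cfd_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def random_genome(rng: np.random.Generator, n: int,
                  chrom: str = "chr1") -> GenomeIndex:
    seq = "".join(np.random.default_rng(rng.integers(2**31)).choice(
        list("ACGT"), size=n))
    return GenomeIndex({chrom: seq})
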
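import numpy as np
import pytest

from shmkit import motifs as mg
from shmkit import simulate as sim

# 22-nt worked-example substrates (strong CDR3-context and weak FWR3-context)
STRONG_SUBSTRATE = "TACGGTAGTAGCTACTTTGACT"
WEAK_SUBSTRATE = "CCTACATGCAGCTCAGCAGCCT"


@pytest.fixture(scope="session")
def strong_substrate():
    return STRONG_SUBSTRATE


@pytest.fixture(scope="session")
def weak_substrate():
    return WEAK_SUBSTRATE


@pytest.fixture(scope="session")
def default_germline():
    sequence, region_map = sim.make_germline(sim.default_layout(), seed=1)
    return sequence, region_map


def brute_force_scan(seq: str) -> set:
    """Independent two-strand matcher: try all 12 motifs at every offset."""
    wrch = mg.enumerate_wrch()
    length = len(seq)
    hits = set()
    for motif in wrch:
        for i in range(length - 3):
            if seq[i : i + 4] == motif:
                hits.add((i + 1, "top", motif, i + 3))
    rc = mg.reverse_complement(seq)
    for motif in wrch:
        for i in range(len(rc) - 3):
            if rc[i : i + 4] == motif:
                # rc 0-based window [i, i+4) maps to top-strand 1-based
                # start L-i-3; the motif C (rc index i+2) pairs with the
                # top-strand G at L-i-2.
                hits.add((length - i - 3, "bottom", motif, length - i - 2))
    return hits


def hits_as_tuples(hits) -> set:
    return {(h.start, h.strand, h.motif, h.target_c) for h in hits}
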
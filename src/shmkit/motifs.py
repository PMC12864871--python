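"""Degenerate hotspot-motif grammar.

Two-strand scanning for WRCH deamination motifs (W = A/T, R = A/G,
H = A/C/T), orientation classification, C-centered context-window
extraction, and pyrimidine-dimer (PyPy) counting.

Bottom-strand motif occurrences are detected as top-strand DGYW matches
(D = A/G/T, Y = C/T) and reported in top-strand coordinates, so a
palindromic motif such as AGCT yields the characteristic paired G/C
target sites.  All public coordinates are 1-based inclusive; internal
arithmetic is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional

from .errors import AlphabetError, MotifDomainError

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC degeneracy classes used by the WRCH / DGYW grammar.
IUPAC_CLASSES = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "W": "AT",
    "R": "AG",
    "Y": "CT",
    "D": "AGT",
    "H": "ACT",
}

UNIDIRECTIONAL = "unidirectional"
BIDIRECTIONAL = "bidirectional"
PALINDROMIC = "palindromic"


@dataclass(frozen=True)
class NucleotideSequence:
    """An upper-case DNA sequence over {A, C, G, T, N} with a name."""

    bases: str
    name: str = ""

    def __post_init__(self) -> None:
        bad = set(self.bases) - DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"sequence {self.name!r} contains non-nucleotide characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate 4-mer pattern and its concrete expansion."""

    symbols: str
    expanded_set: tuple[str, ...]


@dataclass(frozen=True, order=True)
class MotifHit:
    """One motif occurrence on either strand.

    ``start`` is the 1-based top-strand coordinate of the first base of
    the 4-mer window; ``target_c`` is the 1-based top-strand coordinate
    of the deaminated base (a C for top-strand hits, the G paired with
    the bottom-strand C for bottom-strand hits).  ``motif`` is the 4-mer
    read 5'->3' on its own strand, so it is always a WRCH member.
    """

    start: int
    strand: str  # "top" | "bottom"
    motif: str
    target_c: int


@dataclass(frozen=True)
class ContextWindow:
    """A k-mer centered on a top-strand (or strand-resolved) cytosine."""

    kmer: str
    central_c_pos: int
    motif: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.kmer) % 2 == 0:
            raise ValueError("context window length must be odd")
        center = len(self.kmer) // 2
        if self.kmer[center] != "C":
            raise ValueError("context window must be centered on a C")

    @property
    def wrch5_segment(self) -> str:
        """The motif +/- 5 nt slice (window positions 1..k-1)."""
        return self.kmer[:-1]


def _as_bases(seq: "str | NucleotideSequence") -> str:
    return seq.bases if isinstance(seq, NucleotideSequence) else seq


def expand_pattern(symbols: str) -> tuple[str, ...]:
    """Expand a degenerate IUPAC pattern into sorted concrete k-mers."""
    try:
        choices = [IUPAC_CLASSES[s] for s in symbols]
    except KeyError as exc:
        raise MotifDomainError(f"unsupported IUPAC symbol {exc.args[0]!r}") from exc
    return tuple(sorted("".join(p) for p in product(*choices)))


def enumerate_wrch() -> tuple[str, ...]:
    """All 12 concrete WRCH motifs, lexicographically ordered."""
    return expand_pattern("WRCH")


def enumerate_dgyw() -> tuple[str, ...]:
    """All 12 concrete DGYW motifs (reverse complements of WRCH)."""
    return expand_pattern("DGYW")


WRCH_PATTERN = MotifPattern("WRCH", enumerate_wrch())
DGYW_PATTERN = MotifPattern("DGYW", enumerate_dgyw())
_WRCH_SET = frozenset(WRCH_PATTERN.expanded_set)
_DGYW_SET = frozenset(DGYW_PATTERN.expanded_set)


def reverse_complement(seq: "str | NucleotideSequence") -> str:
    """Watson-Crick reverse complement; N maps to N."""
    bases = _as_bases(seq)
    bad = set(bases) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-nucleotide characters: {sorted(bad)}")
    return bases.translate(_COMPLEMENT)[::-1]


def is_wrch(kmer: str) -> bool:
    return kmer in _WRCH_SET


def classify_orientation(motif: str) -> str:
    """Classify a WRCH motif as palindromic, bidirectional or unidirectional.

    Palindromic: equals its own reverse complement (both strands carry a
    target C in the same window).  Bidirectional: the reverse complement
    is a different WRCH motif.  Unidirectional: the reverse complement
    is not a WRCH motif.
    """
    if motif not in _WRCH_SET:
        raise MotifDomainError(f"{motif!r} is not a WRCH motif")
    rc = reverse_complement(motif)
    if rc == motif:
        return PALINDROMIC
    if rc in _WRCH_SET:
        return BIDIRECTIONAL
    return UNIDIRECTIONAL


def scan_wrch(seq: "str | NucleotideSequence") -> list[MotifHit]:
    """All WRCH occurrences on both strands, in top-strand coordinates.

    Top-strand hits have ``target_c = start + 2`` (the motif C);
    bottom-strand hits are top-strand DGYW occurrences with
    ``target_c = start + 1`` (the G paired with the bottom-strand C).
    Windows containing N never produce hits.  Overlapping hits are all
    reported; output is sorted by start, then top before bottom.
    """
    bases = _as_bases(seq)
    hits: list[MotifHit] = []
    for i in range(len(bases) - 3):
        window = bases[i : i + 4]
        if window in _WRCH_SET:
            hits.append(MotifHit(i + 1, "top", window, i + 3))
        if window in _DGYW_SET:
            hits.append(MotifHit(i + 1, "bottom", reverse_complement(window), i + 2))
    hits.sort(key=lambda h: (h.start, 0 if h.strand == "top" else 1))
    return hits


def extract_context(
    seq: "str | NucleotideSequence", c_pos: int, k: int = 15
) -> Optional[ContextWindow]:
    """The k-mer centered at a C, or None when the window is unusable.

    Returns None when the window would run off either end of the
    sequence or contains a non-ACGT base (records with unknown bases are
    excluded from context statistics).  Raises when the base at
    ``c_pos`` (1-based) is not a C.
    """
    if k % 2 == 0 or k < 5:
        raise ValueError("window size must be odd and >= 5")
    bases = _as_bases(seq)
    if not 1 <= c_pos <= len(bases):
        raise ValueError(f"position {c_pos} outside sequence of length {len(bases)}")
    if bases[c_pos - 1] != "C":
        raise ValueError(f"base at position {c_pos} is {bases[c_pos - 1]!r}, not C")
    half = k // 2
    lo, hi = c_pos - 1 - half, c_pos + half  # 0-based half-open
    if lo < 0 or hi > len(bases):
        return None
    kmer = bases[lo:hi]
    if set(kmer) - set("ACGT"):
        return None
    center = k // 2
    motif = kmer[center - 2 : center + 2]
    return ContextWindow(kmer, c_pos, motif if motif in _WRCH_SET else None)


def count_pypy(segment: str) -> int:
    """Number of overlapping pyrimidine dimers (two consecutive C/T)."""
    bad = set(segment) - set("ACGT")
    if bad:
        raise AlphabetError(f"non-ACGT characters in segment: {sorted(bad)}")
    py = set("CT")
    return sum(1 for a, b in zip(segment, segment[1:]) if a in py and b in py)


def pypy_content(
    window: ContextWindow, mode: str = "wrch5", include_motif: bool = True
) -> int:
    """PyPy dimer count of a context window.

    ``mode="wrch5"`` (default) counts over window positions 1..k-1, i.e.
    the 5-nt flank + motif + 5-nt flank segment; ``mode="full"`` counts
    over the whole k-mer.  With ``include_motif=False``, dimers lying
    entirely inside the central 4-mer are skipped.
    """
    if mode == "wrch5":
        segment = window.wrch5_segment
    elif mode == "full":
        segment = window.kmer
    else:
        raise ValueError(f"unknown mode {mode!r}")
    total = count_pypy(segment)
    if not include_motif:
        center = len(window.kmer) // 2
        m_lo = center - 2  # 0-based motif span [m_lo, m_lo+4)
        py = set("CT")
        internal = sum(
            1
            for i in range(m_lo, m_lo + 3)
            if segment[i] in py and segment[i + 1] in py
        )
        total -= internal
    return total


def swap_interval(motif_start: int, motif_length: int = 4, flank: int = 9) -> tuple[int, int]:
    """1-based inclusive interval replaced in a symmetric context swap.

    A motif of ``motif_length`` exchanged together with ``flank`` nt on
    each side spans ``motif_length + 2 * flank`` nucleotides.
    """
    if motif_start < 1 or motif_length < 1 or flank < 0:
        raise ValueError("invalid swap geometry")
    return motif_start - flank, motif_start + motif_length - 1 + flank


def swap_context(
    seq: "str | NucleotideSequence",
    donor_start: int,
    acceptor_start: int,
    motif_length: int = 4,
    flank: int = 9,
) -> str:
    """Replace the flanks of the acceptor motif with the donor's flanks.

    Both starts are 1-based motif starts in the same sequence.  The
    motif itself is copied along with its flanks (the exchanged segment
    is the full ``motif_length + 2*flank`` window), mirroring a
    symmetric context-swap construct.
    """
    bases = _as_bases(seq)
    d_lo, d_hi = swap_interval(donor_start, motif_length, flank)
    a_lo, a_hi = swap_interval(acceptor_start, motif_length, flank)
    for lo, hi in ((d_lo, d_hi), (a_lo, a_hi)):
        if lo < 1 or hi > len(bases):
            raise ValueError("swap window runs off the sequence")
    donor_segment = bases[d_lo - 1 : d_hi]
    return bases[: a_lo - 1] + donor_segment + bases[a_hi:]


def hits_to_rows(name: str, hits: Iterable[MotifHit]) -> list[dict]:
    """Flatten hits for TSV export (1-based coordinates)."""
    return [
        {
            "seq_name": name,
            "motif": h.motif,
            "strand": h.strand,
            "start": h.start,
            "target_c": h.target_c,
            "orientation_class": classify_orientation(h.motif),
        }
        for h in hits
    ]
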
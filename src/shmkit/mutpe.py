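"""Amplicon deep-sequencing mutation quantification.

Native, simplified re-implementations of the read-processing chain for
paired-end amplicon mutation profiling: sliding-window quality trimming,
mate length filtering, overlap merging, merged-length gating, gapless
placement on a single short reference, a quality-filtered pileup,
per-position mutation frequencies, region-normalized frequencies, and
between-sample position tests.

The external trim/merge/align tools are replaced by native equivalents
implementing the same thresholds.  Gapless placement is adequate
because the reference is one short fixed amplicon and indel-bearing
reads are not interpreted by the per-position analysis; reads that fail
placement are dropped and counted in the run log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .motifs import reverse_complement
from .stats import two_sample_t


@dataclass(frozen=True)
class AmpliconReference:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 50:
            raise DataError("amplicon reference shorter than 50 nt")
        if set(self.sequence) - set("ACGT"):
            raise DataError("amplicon reference must be N-free ACGT")

    @property
    def expected_length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SequencedRead:
    read_id: str
    bases: str
    qualities: tuple[int, ...]
    mate: int = 1

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise DataError(f"read {self.read_id!r}: bases/qualities length mismatch")
        if any(q < 0 for q in self.qualities):
            raise DataError(f"read {self.read_id!r}: negative quality")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class MergedRead:
    read_id: str
    bases: str
    qualities: tuple[int, ...]
    overlap_length: int
    mismatch_fraction: float

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class Alignment:
    read: MergedRead
    offset: int  # 0-based reference offset of the read's first aligned base
    mismatches: int
    aligned_length: int


@dataclass(frozen=True)
class PileupColumn:
    position: int  # 1-based reference coordinate
    ref_base: str
    counts: dict  # base -> count, quality-filtered

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class MutationProfile:
    """Per-position substitution frequencies for one sample."""

    sample_id: str
    table: pd.DataFrame  # position, ref_base, depth, n_A..n_T, frequency, ...


@dataclass(frozen=True)
class PositionComparison:
    position: Optional[int]
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]
    t_statistic: float
    p_value: float
    significant: bool
    note: str = "ok"


def sliding_window_trim(
    read: SequencedRead, window: int = 5, min_mean_q: int = 25
) -> SequencedRead:
    """Truncate at the first 5'-scanned window whose mean quality drops.

    Windows of ``window`` bases slide 5'->3' one base at a time; at the
    first window with mean quality < ``min_mean_q`` the read is cut at
    that window's start, then extended over subsequent bases whose
    individual quality still meets the threshold (trimmomatic
    sliding-window semantics).  Reads shorter than one window are cut
    the same way on their single partial window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    quals = read.qualities
    n = len(quals)
    if n == 0:
        return read
    cut = None
    n_windows = max(1, n - window + 1)
    for i in range(n_windows):
        chunk = quals[i : i + window]
        if sum(chunk) / len(chunk) < min_mean_q:
            cut = i
            break
    if cut is None:
        return read
    keep = cut
    while keep < n and quals[keep] >= min_mean_q:
        keep += 1
    return replace(read, bases=read.bases[:keep], qualities=quals[:keep])


def length_filter(
    r1: SequencedRead, r2: SequencedRead, min_r1: int = 200, min_r2: int = 100
) -> bool:
    """Keep a mate pair iff both post-trim length minima are satisfied."""
    return len(r1) >= min_r1 and len(r2) >= min_r2


def merge_pair(
    r1: SequencedRead,
    r2: SequencedRead,
    max_mismatch_fraction: float = 0.10,
    min_overlap: int = 10,
) -> tuple[Optional[MergedRead], str]:
    """Overlap-merge a mate pair into one combined read.

    R2 is reverse-complemented, then the 3' end of R1 is slid over the
    5' end of R2 considering every overlap length >= ``min_overlap``.
    Overlaps are scored by matches minus mismatches (a raw match count
    would let long chance overlaps outscore a shorter perfect one); the
    best score wins, ties break toward the longer overlap.  The merge is
    accepted iff the mismatch fraction in the chosen overlap is <=
    ``max_mismatch_fraction``.  In the overlap,
    each output base comes from the mate with the higher quality (ties
    favor R1) and carries the max of the two qualities.

    Returns ``(merged, "ok")`` or ``(None, reason)``.
    """
    b1 = np.frombuffer(r1.bases.encode(), dtype="S1")
    rc2 = reverse_complement(r2.bases)
    b2 = np.frombuffer(rc2.encode(), dtype="S1")
    q1 = np.asarray(r1.qualities, dtype=np.int16)
    q2 = np.asarray(r2.qualities, dtype=np.int16)[::-1]
    l1, l2 = len(b1), len(b2)
    max_ov = min(l1, l2)
    if max_ov < min_overlap:
        return None, "no_overlap"
    best = None  # (score, ov, matches) with score = matches - mismatches
    for ov in range(min_overlap, max_ov + 1):
        matches = int((b1[l1 - ov :] == b2[:ov]).sum())
        score = 2 * matches - ov
        if best is None or (score, ov) > (best[0], best[1]):
            best = (score, ov, matches)
    _, ov, matches = best
    mismatch_fraction = (ov - matches) / ov
    if mismatch_fraction > max_mismatch_fraction:
        return None, "overlap_mismatch"
    head_b, head_q = b1[: l1 - ov], q1[: l1 - ov]
    tail_b, tail_q = b2[ov:], q2[ov:]
    ov1_b, ov1_q = b1[l1 - ov :], q1[l1 - ov :]
    ov2_b, ov2_q = b2[:ov], q2[:ov]
    take2 = ov2_q > ov1_q
    ov_b = np.where(take2, ov2_b, ov1_b)
    ov_q = np.maximum(ov1_q, ov2_q)
    bases = (head_b.tobytes() + ov_b.tobytes() + tail_b.tobytes()).decode()
    quals = tuple(int(q) for q in np.concatenate([head_q, ov_q, tail_q]))
    return (
        MergedRead(r1.read_id, bases, quals, ov, mismatch_fraction),
        "ok",
    )


def length_gate(merged: MergedRead, ref: AmpliconReference, tolerance: int = 30) -> bool:
    """Keep merged reads whose length is within +/- tolerance of the amplicon."""
    return abs(len(merged) - ref.expected_length) <= tolerance


def align_to_reference(
    merged: MergedRead,
    ref: AmpliconReference,
    max_mismatch_rate: float = 0.15,
    min_overlap: int = 30,
) -> Optional[Alignment]:
    """Gapless placement at the offset minimizing mismatches.

    Every offset (including partial overhangs at either reference end,
    as long as >= ``min_overlap`` bases align) is scored by match count;
    the best placement is kept, ties resolved toward the leftmost
    offset.  Returns None when the best mismatch rate exceeds
    ``max_mismatch_rate``.
    """
    read = np.frombuffer(merged.bases.encode(), dtype="S1")
    refa = np.frombuffer(ref.sequence.encode(), dtype="S1")
    lr, lf = len(read), len(refa)
    best = None  # (matches, -mismatch_rate, -offset, offset, aligned)
    for offset in range(-(lr - min_overlap), lf - min_overlap + 1):
        r_lo = max(0, -offset)
        f_lo = max(0, offset)
        aligned = min(lr - r_lo, lf - f_lo)
        if aligned < min_overlap:
            continue
        matches = int((read[r_lo : r_lo + aligned] == refa[f_lo : f_lo + aligned]).sum())
        rate = (aligned - matches) / aligned
        key = (matches, -rate, -offset)
        if best is None or key > best[0]:
            best = (key, offset, aligned, matches)
    if best is None:
        return None
    _, offset, aligned, matches = best
    if (aligned - matches) / aligned > max_mismatch_rate:
        return None
    return Alignment(merged, offset, aligned - matches, aligned)


BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def build_pileup(
    alignments: Iterable[Alignment], ref: AmpliconReference, min_base_q: int = 30
) -> list[PileupColumn]:
    """Quality-filtered base counts per reference position.

    Only bases with quality >= ``min_base_q`` contribute; ambiguous
    bases never count.  Every reference position gets a column, possibly
    with zero depth.
    """
    counts = np.zeros((ref.expected_length, 4), dtype=np.int64)
    for aln in alignments:
        read = aln.read
        r_lo = max(0, -aln.offset)
        f_lo = max(0, aln.offset)
        b = np.frombuffer(read.bases.encode(), dtype="S1")[r_lo : r_lo + aln.aligned_length]
        q = np.asarray(read.qualities, dtype=np.int16)[r_lo : r_lo + aln.aligned_length]
        ok = q >= min_base_q
        for base, idx in _BASE_INDEX.items():
            sel = ok & (b == base.encode())
            positions = f_lo + np.nonzero(sel)[0]
            np.add.at(counts[:, idx], positions, 1)
    return [
        PileupColumn(
            i + 1,
            ref.sequence[i],
            {base: int(counts[i, j]) for base, j in _BASE_INDEX.items()},
        )
        for i in range(ref.expected_length)
    ]


def mutation_frequency(
    pileup: Sequence[PileupColumn], sample_id: str = "sample"
) -> MutationProfile:
    """Per-position total and per-substitution mutation frequencies.

    Frequency at a position is the fraction of covering (quality-
    filtered) bases differing from the reference base.  Zero-depth
    positions carry NaN frequencies, never 0/0.
    """
    rows = []
    for col in pileup:
        depth = col.depth
        row = {
            "position": col.position,
            "ref_base": col.ref_base,
            "depth": depth,
        }
        for base in BASES:
            row[f"n_{base}"] = col.counts.get(base, 0)
        if depth > 0:
            ref_count = col.counts.get(col.ref_base, 0)
            row["frequency"] = (depth - ref_count) / depth
            for base in BASES:
                row[f"f_{base}"] = (
                    col.counts.get(base, 0) / depth if base != col.ref_base else 0.0
                )
        else:
            row["frequency"] = math.nan
            for base in BASES:
                row[f"f_{base}"] = math.nan
        rows.append(row)
    return MutationProfile(sample_id, pd.DataFrame(rows))


def normalize_profile(profile: MutationProfile) -> MutationProfile:
    """Add region-normalized frequencies: freq(pos) / sum over all positions.

    Scale-invariant by construction; the normalized values sum to 1.
    Raises on an all-zero (or all-missing) profile rather than silently
    emitting zeros.
    """
    table = profile.table.copy()
    freqs = table["frequency"].fillna(0.0)
    total = freqs.sum()
    if total <= 0:
        raise DataError(
            f"sample {profile.sample_id!r}: no mutations observed; "
            "normalized profile undefined"
        )
    table["normalized_frequency"] = freqs / total
    return MutationProfile(profile.sample_id, table)


def compare_position(
    samples_a: Sequence[float],
    samples_b: Sequence[float],
    position: Optional[int] = None,
    welch: bool = False,
    alpha: float = 0.05,
) -> PositionComparison:
    """Unpaired two-tailed t-test between two groups of per-sample values."""
    t, p, note = two_sample_t(samples_a, samples_b, welch=welch)
    return PositionComparison(
        position,
        tuple(float(v) for v in samples_a),
        tuple(float(v) for v in samples_b),
        t,
        p,
        bool(p < alpha),
        note,
    )


@dataclass
class PipelineConfig:
    """Thresholds of the read-processing chain (defaults as published)."""

    trim_window: int = 5
    trim_min_mean_q: int = 25
    min_length_r1: int = 200
    min_length_r2: int = 100
    merge_max_mismatch_fraction: float = 0.10
    merge_min_overlap: int = 10
    gate_tolerance: int = 30
    align_max_mismatch_rate: float = 0.15
    align_min_overlap: int = 30
    pileup_min_base_q: int = 30
    clip_5p_r1: int = 0  # fixed-length clip for primer-derived random N stretches
    clip_5p_r2: int = 0


def _clip_5p(read: SequencedRead, n: int) -> SequencedRead:
    if n <= 0:
        return read
    return replace(read, bases=read.bases[n:], qualities=read.qualities[n:])


def process_sample(
    pairs: Iterable[tuple[SequencedRead, SequencedRead]],
    ref: AmpliconReference,
    config: Optional[PipelineConfig] = None,
    sample_id: str = "sample",
) -> tuple[MutationProfile, dict]:
    """Run the full chain on mate pairs and return the profile + run log.

    The run log accounts for every input pair exactly once across the
    outcome tallies (conservation is asserted by the test suite).
    """
    cfg = config or PipelineConfig()
    log = {
        "sample_id": sample_id,
        "n_pairs": 0,
        "rejected_at_length": 0,
        "rejected_at_merge": 0,
        "rejected_at_gate": 0,
        "rejected_at_align": 0,
        "merged_aligned": 0,
    }
    alignments: list[Alignment] = []
    for r1, r2 in pairs:
        log["n_pairs"] += 1
        r1 = sliding_window_trim(_clip_5p(r1, cfg.clip_5p_r1), cfg.trim_window, cfg.trim_min_mean_q)
        r2 = sliding_window_trim(_clip_5p(r2, cfg.clip_5p_r2), cfg.trim_window, cfg.trim_min_mean_q)
        if not length_filter(r1, r2, cfg.min_length_r1, cfg.min_length_r2):
            log["rejected_at_length"] += 1
            continue
        merged, reason = merge_pair(
            r1, r2, cfg.merge_max_mismatch_fraction, cfg.merge_min_overlap
        )
        if merged is None:
            log["rejected_at_merge"] += 1
            continue
        if not length_gate(merged, ref, cfg.gate_tolerance):
            log["rejected_at_gate"] += 1
            continue
        aln = align_to_reference(
            merged, ref, cfg.align_max_mismatch_rate, cfg.align_min_overlap
        )
        if aln is None:
            log["rejected_at_align"] += 1
            continue
        log["merged_aligned"] += 1
        alignments.append(aln)
    pileup = build_pileup(alignments, ref, cfg.pileup_min_base_q)
    profile = mutation_frequency(pileup, sample_id)
    return profile, log


def compare_profiles(
    profiles_a: Sequence[MutationProfile],
    profiles_b: Sequence[MutationProfile],
    column: str = "normalized_frequency",
    welch: bool = False,
) -> pd.DataFrame:
    """Position-wise t-tests between two groups of (normalized) profiles."""
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise DataError("each group needs at least 2 profiles")
    positions = profiles_a[0].table["position"].to_numpy()
    mat_a = np.vstack([p.table[column].to_numpy() for p in profiles_a])
    mat_b = np.vstack([p.table[column].to_numpy() for p in profiles_b])
    rows = []
    for j, pos in enumerate(positions):
        va, vb = mat_a[:, j], mat_b[:, j]
        cmp_ = compare_position(va, vb, position=int(pos), welch=welch)
        rows.append(
            {
                "position": int(pos),
                "mean_a": float(np.mean(va)),
                "mean_b": float(np.mean(vb)),
                "t_statistic": cmp_.t_statistic,
                "p_value": cmp_.p_value,
                "significant": cmp_.significant,
                "note": cmp_.note,
            }
        )
    return pd.DataFrame(rows)
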
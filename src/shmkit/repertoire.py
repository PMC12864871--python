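"""Repertoire-level mutability statistics for germline-aligned V sequences.

Groups every eligible cytosine of the germline into C-centered 15-mer
context groups, tallies coverage and central-C mutations across the
repertoire, applies a minimum-coverage filter, and computes
mutability-vs-PyPy and frequency-vs-PyPy statistics per motif, plus
per-subregion (FWR/CDR) mutation loads.

Context windows are always taken from the GERMLINE sequence: observed
mutations would otherwise destroy the grouping key and conflate cause
and effect.  Records carrying N bases or indels must be rejected at
load time (see :mod:`shmkit.io`); clonal independence of the input is
assumed.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import motifs as mg
from .errors import DataError
from .stats import CorrelationResult, box_stats, correlation_result

REGION_LABELS = ("FWR1", "CDR1", "FWR2", "CDR2", "FWR3", "CDR3")

#: region_map entry: (label, start, end) with 1-based inclusive bounds.
RegionMap = Sequence[tuple[str, int, int]]


@dataclass(frozen=True)
class AnnotatedSequenceRecord:
    """A germline/observed pair of equal length with region annotations."""

    record_id: str
    germline: str
    observed: str
    region_map: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if len(self.germline) != len(self.observed):
            raise DataError(
                f"record {self.record_id!r}: germline length {len(self.germline)} "
                f"!= observed length {len(self.observed)}"
            )
        for seq, label in ((self.germline, "germline"), (self.observed, "observed")):
            bad = set(seq) - set("ACGT")
            if bad:
                raise DataError(
                    f"record {self.record_id!r}: {label} contains {sorted(bad)} "
                    "(N bases and indels must be excluded upstream)"
                )
        prev_end = 0
        for label, start, end in self.region_map:
            if not (1 <= start <= end <= len(self.germline)):
                raise DataError(f"record {self.record_id!r}: region {label} out of bounds")
            if start <= prev_end:
                raise DataError(f"record {self.record_id!r}: region {label} overlaps/unordered")
            prev_end = end

    def region_of(self, position: int) -> Optional[str]:
        for label, start, end in self.region_map:
            if start <= position <= end:
                return label
        return None


@dataclass(frozen=True)
class MutationCall:
    position: int  # 1-based germline coordinate
    from_base: str
    to_base: str


@dataclass
class ContextGroup:
    """All repertoire observations sharing one C-centered k-mer."""

    kmer: str
    motif: Optional[str]
    coverage: int = 0
    central_mutated: int = 0
    pypy: int = 0

    @property
    def central_mutation_frequency(self) -> float:
        return self.central_mutated / self.coverage if self.coverage else 0.0


def call_mutations(record: AnnotatedSequenceRecord) -> list[MutationCall]:
    """One call per position where observed differs from germline."""
    return [
        MutationCall(i + 1, g, o)
        for i, (g, o) in enumerate(zip(record.germline, record.observed))
        if g != o
    ]


def _eligible_windows(germline: str, k: int, pypy_mode: str, include_motif: bool):
    """(position, kmer, motif, pypy) for every C with a usable window."""
    out = []
    for i, base in enumerate(germline):
        if base != "C":
            continue
        window = mg.extract_context(germline, i + 1, k=k)
        if window is None:
            continue
        out.append(
            (
                i + 1,
                window.kmer,
                window.motif,
                mg.pypy_content(window, mode=pypy_mode, include_motif=include_motif),
            )
        )
    return out


def build_context_groups(
    records: Iterable[AnnotatedSequenceRecord],
    k: int = 15,
    wrch_only: bool = False,
    pypy_mode: str = "wrch5",
    include_motif_pypy: bool = True,
) -> list[ContextGroup]:
    """Pool observations by exact germline k-mer across the repertoire.

    Coverage counts every observation of a k-mer (identical k-mers from
    different germline genes or positions pool into one group); the
    central-mutation tally counts observations whose observed base at
    the central C differs from germline.
    """
    groups: dict[str, ContextGroup] = {}
    window_cache: dict[str, list] = {}
    for record in records:
        wins = window_cache.get(record.germline)
        if wins is None:
            wins = _eligible_windows(record.germline, k, pypy_mode, include_motif_pypy)
            window_cache[record.germline] = wins
        for pos, kmer, motif, pypy in wins:
            if wrch_only and motif is None:
                continue
            group = groups.get(kmer)
            if group is None:
                group = groups[kmer] = ContextGroup(kmer, motif, pypy=pypy)
            group.coverage += 1
            if record.observed[pos - 1] != record.germline[pos - 1]:
                group.central_mutated += 1
    return sorted(groups.values(), key=lambda g: g.kmer)


def filter_coverage(
    groups: Iterable[ContextGroup], min_coverage: int = 30
) -> list[ContextGroup]:
    """Retain groups with coverage >= min_coverage (default 30)."""
    return [g for g in groups if g.coverage >= min_coverage]


def mutability_by_pypy(
    groups: Sequence[ContextGroup], weighted: bool = True
) -> tuple[pd.DataFrame, CorrelationResult]:
    """Fraction of k-mers mutated at the central C, per PyPy level.

    All groups must share one central motif.  Returns a per-level table
    (pypy, n_groups, n_mutated, fraction_mutated) and the Pearson
    correlation between PyPy level and fraction, with levels weighted by
    their group counts by default.
    """
    motifs_present = {g.motif for g in groups}
    if len(motifs_present) > 1:
        raise DataError(f"groups span multiple motifs: {sorted(map(str, motifs_present))}")
    motif = next(iter(motifs_present)) if motifs_present else None

    by_level: dict[int, list[ContextGroup]] = defaultdict(list)
    for g in groups:
        by_level[g.pypy].append(g)
    rows = [
        {
            "pypy": level,
            "n_groups": len(members),
            "n_mutated": sum(1 for g in members if g.central_mutated > 0),
            "fraction_mutated": sum(1 for g in members if g.central_mutated > 0)
            / len(members),
        }
        for level, members in sorted(by_level.items())
    ]
    table = pd.DataFrame(rows, columns=["pypy", "n_groups", "n_mutated", "fraction_mutated"])
    weights = table["n_groups"].tolist() if weighted else None
    corr = correlation_result(
        table["pypy"].tolist(), table["fraction_mutated"].tolist(), weights, motif
    )
    return table, corr


def mutability_by_pypy_groupwise(
    groups: Sequence[ContextGroup],
) -> CorrelationResult:
    """Correlation computed on individual k-mers (0/1 mutated) instead of levels."""
    motifs_present = {g.motif for g in groups}
    motif = next(iter(motifs_present)) if len(motifs_present) == 1 else None
    x = [g.pypy for g in groups]
    y = [1.0 if g.central_mutated > 0 else 0.0 for g in groups]
    return correlation_result(x, y, None, motif)


def frequency_by_pypy(
    groups: Sequence[ContextGroup], mutated_only: bool = True
) -> dict[int, dict]:
    """Central-C mutation-frequency distribution per PyPy level.

    Mirrors the box-plot presentation: by default only groups with at
    least one central mutation contribute.  Empty levels are omitted.
    """
    by_level: dict[int, list[float]] = defaultdict(list)
    for g in groups:
        if mutated_only and g.central_mutated == 0:
            continue
        by_level[g.pypy].append(g.central_mutation_frequency)
    return {
        level: {"values": sorted(vals), **box_stats(vals)}
        for level, vals in sorted(by_level.items())
        if vals
    }


def subregion_summary(
    records: Sequence[AnnotatedSequenceRecord], wrch_only: bool = False
) -> pd.DataFrame:
    """Per-region, per-motif mutation load over top-strand cytosines.

    With ``wrch_only`` every (region, WRCH motif) pair is reported, with
    explicit zero rows for motifs absent from a region; otherwise a
    single "all" motif row per region aggregates every cytosine.
    Positions outside the region map are tallied under "unassigned" with
    a warning.
    """
    motif_keys = list(mg.enumerate_wrch()) if wrch_only else ["all"]
    region_keys = list(REGION_LABELS)
    sites: dict[tuple[str, str], set] = defaultdict(set)
    observations: dict[tuple[str, str], int] = defaultdict(int)
    mutated: dict[tuple[str, str], int] = defaultdict(int)
    unassigned_seen = False

    site_cache: dict[str, list] = {}
    for record in records:
        cached = site_cache.get(record.germline)
        if cached is None:
            cached = []
            for i, base in enumerate(record.germline):
                if base != "C":
                    continue
                pos = i + 1
                motif = None
                if wrch_only:
                    lo = i - 2
                    if lo >= 0 and i + 1 < len(record.germline):
                        candidate = record.germline[lo : lo + 4]
                        if mg.is_wrch(candidate):
                            motif = candidate
                    if motif is None:
                        continue
                cached.append((pos, motif if wrch_only else "all"))
            site_cache[record.germline] = cached
        for pos, motif_key in cached:
            region = record.region_of(pos)
            if region is None:
                region = "unassigned"
                unassigned_seen = True
            key = (region, motif_key)
            sites[key].add((record.germline, pos))
            observations[key] += 1
            if record.observed[pos - 1] != record.germline[pos - 1]:
                mutated[key] += 1

    if unassigned_seen:
        warnings.warn("cytosines outside the region map counted under 'unassigned'")
        region_keys = region_keys + ["unassigned"]

    rows = []
    for region in region_keys:
        for motif_key in motif_keys:
            key = (region, motif_key)
            obs = observations.get(key, 0)
            rows.append(
                {
                    "region": region,
                    "motif": motif_key,
                    "n_sites": len(sites.get(key, ())),
                    "observations": obs,
                    "mutated": mutated.get(key, 0),
                    "frequency": (mutated.get(key, 0) / obs) if obs else 0.0,
                }
            )
    return pd.DataFrame(rows)


def groups_table(groups: Iterable[ContextGroup]) -> pd.DataFrame:
    """Flatten context groups for TSV export."""
    return pd.DataFrame(
        [
            {
                "kmer": g.kmer,
                "motif": g.motif or "",
                "coverage": g.coverage,
                "central_mutated": g.central_mutated,
                "central_mutation_frequency": g.central_mutation_frequency,
                "pypy": g.pypy,
            }
            for g in groups
        ]
    )
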
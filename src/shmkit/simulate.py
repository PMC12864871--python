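"""Synthetic inputs for the whole toolkit.

Builds germline V-region stand-ins with motifs planted at chosen
coordinates inside otherwise hotspot-free filler, mutates repertoires of
clonally independent copies under a motif x context x position rate
model, and emits overlapping paired-end amplicon reads — so every
estimator in the package can be exercised end to end without external
data.

The mutation model is deliberately mechanistic-phenomenological:
per-site independent Bernoulli deamination at motif target cytosines
(both strands) with multiplicative context and position modifiers, plus
an optional background rate at non-motif C/G sites.  Transversions
appear only through the substitution spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import motifs as mg
from .errors import ConfigError
from .repertoire import AnnotatedSequenceRecord

#: Default FWR/CDR intervals for the default germline layout (1-based).
DEFAULT_REGION_MAP: tuple[tuple[str, int, int], ...] = (
    ("FWR1", 1, 78),
    ("CDR1", 79, 114),
    ("FWR2", 115, 165),
    ("CDR2", 166, 200),
    ("FWR3", 201, 306),
    ("CDR3", 307, 336),
)


@dataclass(frozen=True)
class GermlineLayout:
    """Recipe for a synthetic germline: length, planted motifs, regions."""

    length: int = 336
    motifs: tuple[tuple[str, int], ...] = ()  # (4-mer, 1-based start)
    region_map: tuple[tuple[str, int, int], ...] = ()
    background_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    allow_incidental: bool = False  # permit accidental WRCH/DGYW in filler

    def __post_init__(self) -> None:
        spans = []
        for motif, start in self.motifs:
            if len(motif) != 4 or set(motif) - set("ACGT"):
                raise ConfigError(f"planted motif {motif!r} must be a concrete 4-mer")
            if start < 1 or start + 3 > self.length:
                raise ConfigError(f"motif {motif!r} at {start} outside layout")
            spans.append((start, start + 3))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ConfigError("planted motifs overlap")


def default_layout() -> GermlineLayout:
    """A V-region-like layout with five palindromic AGCT hotspots.

    The AGCT starts put the paired G/C targets at 27/28, 54/55, 89/90,
    243/244 and 311/312 (FWR3 and CDR3 copies 68 bp apart); an AGCA with
    G/C at 194/195 sits in CDR2.
    """
    return GermlineLayout(
        length=336,
        motifs=(
            ("AGCT", 26),
            ("AGCT", 53),
            ("AGCT", 88),
            ("AGCA", 193),
            ("AGCT", 242),
            ("AGCT", 310),
        ),
        region_map=DEFAULT_REGION_MAP,
    )


def _window_allowed(window_start0: int, planted_starts0: frozenset) -> bool:
    return window_start0 in planted_starts0


def make_germline(layout: GermlineLayout, seed: int = 0) -> tuple[str, tuple]:
    """Deterministically build the germline sequence for a layout.

    Filler is drawn from the background composition and then repaired by
    resampling until no WRCH/DGYW window exists outside the planted
    motif windows (unless ``allow_incidental``).  Planted bases are
    never resampled.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    w = np.asarray(layout.background_weights, dtype=float)
    if w.min() < 0 or w.sum() <= 0:
        raise ConfigError("background weights must be non-negative with positive sum")
    w = w / w.sum()
    seq = rng.choice(alphabet, size=layout.length, p=w)
    protected = np.zeros(layout.length, dtype=bool)
    planted_starts0 = frozenset(start - 1 for _, start in layout.motifs)
    for motif, start in layout.motifs:
        seq[start - 1 : start + 3] = list(motif)
        protected[start - 1 : start + 3] = True

    if not layout.allow_incidental:
        wrch, dgyw = set(mg.enumerate_wrch()), set(mg.enumerate_dgyw())
        for _ in range(1000):
            text = "".join(seq)
            offending = [
                i
                for i in range(layout.length - 3)
                if i not in planted_starts0
                and (text[i : i + 4] in wrch or text[i : i + 4] in dgyw)
            ]
            if not offending:
                break
            for i in offending:
                free = [j for j in range(i, i + 4) if not protected[j]]
                if not free:
                    raise ConfigError(
                        "planted motifs force an unavoidable incidental hotspot"
                    )
                j = int(rng.choice(free))
                seq[j] = rng.choice(alphabet, p=w)
        else:
            raise ConfigError("could not build hotspot-free filler; relax the layout")

    return "".join(seq), tuple(layout.region_map)


@dataclass(frozen=True)
class MutationModel:
    """Per-site deamination rates: base x context x position, clipped to [0,1].

    ``base_rate`` maps a WRCH motif (optionally ``(motif, strand)``) to
    its per-generation deamination probability.  ``context_multiplier``
    keys may be exact strand-resolved 15-mers (str) or PyPy counts of
    the motif +/- 5 segment (int); exact k-mers take precedence.
    ``position_multiplier`` entries are ``((start, end), factor)`` in
    1-based inclusive target coordinates.  ``spectrum`` gives the fate
    of a deaminated C; weights must sum to 1.
    """

    base_rate: Mapping = field(default_factory=dict)
    context_multiplier: Mapping = field(default_factory=dict)
    position_multiplier: tuple = ()
    spectrum: Mapping[str, float] = field(
        default_factory=lambda: {"T": 0.8, "G": 0.1, "A": 0.1}
    )
    background: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"substitution spectrum sums to {total}, not 1")
        if set(self.spectrum) - set("AGT"):
            raise ConfigError("spectrum keys must be target bases for a C (A/G/T)")
        for value in list(self.spectrum.values()) + [self.background]:
            if value < 0:
                raise ConfigError("rates and weights must be >= 0")

    def motif_rate(self, motif: str, strand: str) -> float:
        if (motif, strand) in self.base_rate:
            return float(self.base_rate[(motif, strand)])
        return float(self.base_rate.get(motif, 0.0))

    def context_factor(self, kmer: Optional[str], pypy: Optional[int]) -> float:
        if kmer is not None and kmer in self.context_multiplier:
            return float(self.context_multiplier[kmer])
        if pypy is not None and pypy in self.context_multiplier:
            return float(self.context_multiplier[pypy])
        return 1.0

    def position_factor(self, position: int) -> float:
        factor = 1.0
        for (start, end), value in self.position_multiplier:
            if start <= position <= end:
                factor *= float(value)
        return factor

    @classmethod
    def from_dict(cls, data: Mapping) -> "MutationModel":
        pos = tuple(
            ((int(entry["start"]), int(entry["end"])), float(entry["factor"]))
            for entry in data.get("position_multiplier", [])
        )
        ctx = {
            (int(k) if str(k).isdigit() else str(k)): float(v)
            for k, v in data.get("context_multiplier", {}).items()
        }
        return cls(
            base_rate={str(k): float(v) for k, v in data.get("base_rate", {}).items()},
            context_multiplier=ctx,
            position_multiplier=pos,
            spectrum={str(k): float(v) for k, v in data.get("spectrum", {"T": 0.8, "G": 0.1, "A": 0.1}).items()},
            background=float(data.get("background", 0.0)),
        )


@dataclass(frozen=True)
class SiteRates:
    """Per-position per-strand deamination probabilities (1-based outside)."""

    p_top: np.ndarray  # deamination of the top-strand C at each position
    p_bottom: np.ndarray  # deamination of the bottom-strand C (top-strand G)

    def table(self):
        import pandas as pd

        rows = []
        for i, (pt, pb) in enumerate(zip(self.p_top, self.p_bottom), start=1):
            if pt > 0:
                rows.append({"position": i, "strand": "top", "rate": float(pt)})
            if pb > 0:
                rows.append({"position": i, "strand": "bottom", "rate": float(pb)})
        return pd.DataFrame(rows, columns=["position", "strand", "rate"])


def _strand_context(germline: str, target_c: int, strand: str, k: int = 15):
    """(kmer, pypy) of the motif context as read on the hit's own strand."""
    if strand == "top":
        window = mg.extract_context(germline, target_c, k=k)
        if window is None:
            return None, None
        return window.kmer, mg.pypy_content(window)
    half = k // 2
    lo, hi = target_c - 1 - half, target_c + half
    if lo < 0 or hi > len(germline) or germline[target_c - 1] != "G":
        return None, None
    top_kmer = germline[lo:hi]
    if set(top_kmer) - set("ACGT"):
        return None, None
    kmer = mg.reverse_complement(top_kmer)
    window = mg.ContextWindow(kmer, target_c)
    return kmer, mg.pypy_content(window)


def site_rates(germline: str, model: MutationModel) -> SiteRates:
    """Per-site probabilities for every motif target plus background C/G sites.

    For each motif hit the rate is base_rate(motif, strand) x
    context factor x position factor, clipped to [0, 1].  Non-target
    top-strand C and G sites receive the background rate (an untargeted
    deamination floor); A/T sites never mutate under this model.
    """
    length = len(germline)
    p_top = np.zeros(length)
    p_bottom = np.zeros(length)
    targeted_top = np.zeros(length, dtype=bool)
    targeted_bottom = np.zeros(length, dtype=bool)
    for hit in mg.scan_wrch(germline):
        kmer, pypy = _strand_context(germline, hit.target_c, hit.strand)
        rate = (
            model.motif_rate(hit.motif, hit.strand)
            * model.context_factor(kmer, pypy)
            * model.position_factor(hit.target_c)
        )
        rate = min(1.0, max(0.0, rate))
        idx = hit.target_c - 1
        if hit.strand == "top":
            p_top[idx] = min(1.0, p_top[idx] + rate)
            targeted_top[idx] = True
        else:
            p_bottom[idx] = min(1.0, p_bottom[idx] + rate)
            targeted_bottom[idx] = True
    if model.background > 0:
        arr = np.frombuffer(germline.encode(), dtype="S1")
        bg_top = (arr == b"C") & ~targeted_top
        bg_bottom = (arr == b"G") & ~targeted_bottom
        p_top[bg_top] = min(1.0, model.background)
        p_bottom[bg_bottom] = min(1.0, model.background)
    return SiteRates(p_top, p_bottom)


_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


def simulate_repertoire(
    germline: str,
    model: MutationModel,
    n_sequences: int,
    seed: int = 0,
    region_map: Sequence[tuple[str, int, int]] = (),
    record_prefix: str = "rec",
) -> list[AnnotatedSequenceRecord]:
    """Independently mutated copies of the germline (substitution-only).

    Each site is an independent Bernoulli draw from :func:`site_rates`;
    a deaminated top-strand C is replaced per the substitution spectrum,
    a deaminated bottom-strand C is written as the complementary change
    at the paired top-strand G.
    """
    if n_sequences < 1:
        raise ConfigError("n_sequences must be >= 1")
    rng = np.random.default_rng(seed)
    rates = site_rates(germline, model)
    length = len(germline)
    base_arr = np.array(list(germline))
    spectrum_bases = list(model.spectrum.keys())
    spectrum_p = np.array([model.spectrum[b] for b in spectrum_bases])
    top_events = rng.random((n_sequences, length)) < rates.p_top
    bottom_events = rng.random((n_sequences, length)) < rates.p_bottom

    records = []
    for i in range(n_sequences):
        obs = base_arr.copy()
        top_idx = np.nonzero(top_events[i])[0]
        if top_idx.size:
            subs = rng.choice(spectrum_bases, size=top_idx.size, p=spectrum_p)
            obs[top_idx] = subs
        bot_idx = np.nonzero(bottom_events[i])[0]
        if bot_idx.size:
            subs = rng.choice(spectrum_bases, size=bot_idx.size, p=spectrum_p)
            obs[bot_idx] = [_COMPLEMENT_BASE[s] for s in subs]
        records.append(
            AnnotatedSequenceRecord(
                f"{record_prefix}{i:06d}",
                germline,
                "".join(obs),
                tuple(region_map),
            )
        )
    return records


@dataclass(frozen=True)
class ReadSimulationConfig:
    """Geometry and noise of the paired-end read simulator."""

    r1_length: int = 200
    r2_length: int = 150
    error_rate: float = 0.0
    quality_mean: float = 38.0
    quality_sd: float = 2.0
    quality_max: int = 41
    quality_min: int = 2
    depth: int = 100
    min_overlap: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigError("error_rate must be in [0, 1)")
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")


def simulate_read_pairs(
    sequences: "str | Sequence[str]",
    cfg: ReadSimulationConfig,
    seed: int = 0,
    read_prefix: str = "frag",
):
    """Paired-end reads over one amplicon or a pool of clone amplicons.

    Each pair samples one template uniformly; R1 covers the 5' end on
    the top strand, R2 the 3' end reverse-complemented, with the two
    mates guaranteed to overlap by at least ``cfg.min_overlap``.
    Sequencing errors are independent per-base substitutions; qualities
    are drawn from a clipped normal distribution.

    Yields ``(r1, r2)`` :class:`shmkit.mutpe.SequencedRead` pairs.
    """
    from .mutpe import SequencedRead

    pool = [sequences] if isinstance(sequences, str) else list(sequences)
    if not pool:
        raise ConfigError("empty template pool")
    for template in pool:
        if cfg.r1_length > len(template) or cfg.r2_length > len(template):
            raise ConfigError("read length exceeds template length")
        if cfg.r1_length + cfg.r2_length < len(template) + cfg.min_overlap:
            raise ConfigError(
                "reads too short to overlap: need r1 + r2 >= template + min_overlap"
            )
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    for i in range(cfg.depth):
        template = pool[int(rng.integers(len(pool)))]
        r1_bases = template[: cfg.r1_length]
        r2_bases = mg.reverse_complement(template[-cfg.r2_length :])
        mates = []
        for mate, bases in ((1, r1_bases), (2, r2_bases)):
            arr = np.array(list(bases))
            if cfg.error_rate > 0:
                err = rng.random(arr.size) < cfg.error_rate
                n_err = int(err.sum())
                if n_err:
                    # substitute with one of the three other bases
                    originals = arr[err]
                    repl = rng.choice(alphabet, size=n_err)
                    clash = repl == originals
                    while clash.any():
                        repl[clash] = rng.choice(alphabet, size=int(clash.sum()))
                        clash = repl == originals
                    arr[err] = repl
            quals = np.clip(
                np.rint(rng.normal(cfg.quality_mean, cfg.quality_sd, arr.size)),
                cfg.quality_min,
                cfg.quality_max,
            ).astype(int)
            mates.append(
                SequencedRead(
                    f"{read_prefix}{i:07d}", "".join(arr), tuple(quals), mate
                )
            )
        yield mates[0], mates[1]
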
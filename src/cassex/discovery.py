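"""De-novo cassette-exon discovery from pooled junction evidence.

A skipping event is a triplet of junctions: an upstream junction (UJ) and a
downstream junction (DJ) supporting inclusion of an internal exon, plus a
skipping junction (SJ) sharing the outer boundaries (SJ.start == UJ.start,
SJ.end == DJ.end).  Discovery enumerates every such triplet among junctions
that pass a minimum-support filter, then applies a read-count balance filter
requiring the two inner junctions to have similar counts in every sample of
the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from .io import Junction, JunctionCountTable

__all__ = [
    "SkippingEvent",
    "pool_junction_support",
    "filter_min_support",
    "enumerate_triplets",
    "balance_filter",
    "discover_events",
]


def _strands_compatible(a: str, b: str) -> bool:
    return a == b or a == "unknown" or b == "unknown"


def _combine_strand(*strands: str) -> str:
    defined = {s for s in strands if s != "unknown"}
    if len(defined) > 1:
        raise ValueError(f"incompatible strands {sorted(defined)}")
    return defined.pop() if defined else "unknown"


@dataclass(frozen=True)
class SkippingEvent:
    """A cassette-exon event defined by its three junctions.

    The cassette exon occupies [exon_start, exon_end] = [UJ.end + 1,
    DJ.start − 1] in 1-based inclusive coordinates.
    """

    event_id: str
    chrom: str
    strand: str
    uj: Junction
    dj: Junction
    sj: Junction

    def __post_init__(self) -> None:
        if self.uj.start != self.sj.start or self.dj.end != self.sj.end:
            raise ValueError(f"{self.event_id}: SJ boundaries do not match UJ/DJ")
        if self.uj.end >= self.dj.start:
            raise ValueError(f"{self.event_id}: inner junctions overlap")
        if self.exon_start > self.exon_end:
            raise ValueError(f"{self.event_id}: empty exon")

    @property
    def exon_start(self) -> int:
        return self.uj.end + 1

    @property
    def exon_end(self) -> int:
        return self.dj.start - 1

    @property
    def exon_length(self) -> int:
        return self.dj.start - self.uj.end - 1

    @classmethod
    def from_junctions(cls, uj: Junction, dj: Junction, sj: Junction) -> "SkippingEvent":
        strand = _combine_strand(uj.strand, dj.strand, sj.strand)
        event_id = f"{uj.chrom}:{uj.start}-{uj.end}:{dj.start}-{dj.end}"
        return cls(event_id=event_id, chrom=uj.chrom, strand=strand, uj=uj, dj=dj, sj=sj)


def pool_junction_support(tables: Iterable[JunctionCountTable]) -> Dict[Junction, int]:
    """Maximum per-sample read count for every junction observed anywhere."""
    pool: Dict[Junction, int] = {}
    n = 0
    for table in tables:
        n += 1
        for junction, count in table.counts.items():
            prev = pool.get(junction)
            if prev is None or count > prev:
                pool[junction] = count
    if n == 0:
        raise ValueError("pool_junction_support requires at least one table")
    return pool


def filter_min_support(pool: Dict[Junction, int], min_reads: int = 5) -> Set[Junction]:
    """Junctions supported by at least ``min_reads`` reads in some sample."""
    if min_reads < 1:
        raise ValueError(f"min_reads must be >= 1, got {min_reads}")
    return {j for j, c in pool.items() if c >= min_reads}


def enumerate_triplets(junctions: Iterable[Junction]) -> List[SkippingEvent]:
    """All cassette triplets among the given junctions.

    Emits one event per (UJ, DJ, SJ) combination with matching chromosome,
    compatible strands, shared outer boundaries and non-overlapping inner
    junctions; an exon with several alternative neighbors therefore yields
    several events.  Output is sorted by event_id and independent of input
    order.
    """
    juncs = list(dict.fromkeys(junctions))
    # For each candidate skipping junction, inner partners are found by hash
    # lookup on the shared outer boundaries: UJ starts where SJ starts, DJ
    # ends where SJ ends.
    starts_at: Dict[Tuple[str, int], List[Junction]] = {}
    ends_at: Dict[Tuple[str, int], List[Junction]] = {}
    for j in juncs:
        starts_at.setdefault((j.chrom, j.start), []).append(j)
        ends_at.setdefault((j.chrom, j.end), []).append(j)

    events: Dict[str, SkippingEvent] = {}
    for sj in juncs:
        for uj in starts_at.get((sj.chrom, sj.start), []):
            if uj == sj or uj.end >= sj.end:
                continue
            if not _strands_compatible(uj.strand, sj.strand):
                continue
            for dj in ends_at.get((sj.chrom, sj.end), []):
                # dj.start >= uj.end + 2 leaves >= 1 exonic base between introns
                if dj == sj or dj == uj or dj.start < uj.end + 2:
                    continue
                if not (
                    _strands_compatible(dj.strand, sj.strand)
                    and _strands_compatible(dj.strand, uj.strand)
                ):
                    continue
                try:
                    _combine_strand(uj.strand, dj.strand, sj.strand)
                except ValueError:
                    # e.g. UJ "+", DJ "-", SJ "unknown": pairwise compatible
                    # with SJ but jointly contradictory
                    continue
                event = SkippingEvent.from_junctions(uj, dj, sj)
                prev = events.get(event.event_id)
                # coordinate-identical triplets differing only in strand
                # annotation collapse to one event; prefer a defined strand
                if prev is None or (prev.strand == "unknown" and event.strand != "unknown"):
                    events[event.event_id] = event
    return [events[k] for k in sorted(events)]


def balance_filter(
    event: SkippingEvent,
    tables: Sequence[JunctionCountTable],
    max_abs_diff: int = 10,
    ratio_mult: int = 2,
) -> bool:
    """Inner-junction balance rule, applied over every sample of the dataset.

    Keeps the event iff in EVERY sample |UJC − DJC| < max_abs_diff or
    |UJC − DJC| < ratio_mult · min(UJC, DJC) (both inequalities strict).
    A junction absent from a sample counts as 0.
    """
    for table in tables:
        ujc = table.get(event.uj)
        djc = table.get(event.dj)
        diff = abs(ujc - djc)
        if not (diff < max_abs_diff or diff < ratio_mult * min(ujc, djc)):
            return False
    return True


def discover_events(
    tables: Sequence[JunctionCountTable],
    min_reads: int = 5,
    max_abs_diff: int = 10,
    ratio_mult: int = 2,
) -> List[SkippingEvent]:
    """Full per-dataset discovery: support filter, triplet enumeration, balance filter."""
    pool = pool_junction_support(tables)
    supported = filter_min_support(pool, min_reads=min_reads)
    candidates = enumerate_triplets(supported)
    return [
        e
        for e in candidates
        if balance_filter(e, tables, max_abs_diff=max_abs_diff, ratio_mult=ratio_mult)
    ]
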
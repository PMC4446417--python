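"""Direction-stratified k-mer enrichment around altered cassette exons.

Splicing factors bind short degenerate elements in the alternative exon and
the adjacent intronic sequence, and many act position-dependently: binding
downstream of an exon often promotes inclusion while upstream binding
promotes skipping.  The scan therefore compares k-mer (4–6 nt) *presence*
in the exon body and in up-to-250-nt intronic windows flanking altered
exons (split into tumor-included and tumor-excluded sets for the intronic
windows) against a background of highly expressed but unaltered exons,
using the upper-tail hypergeometric test with BH adjustment within each
(region, direction, cancer-type) stratum.

Known consensus elements map enriched k-mers to candidate splicing factors
(TGCATG/GCATG → RBFOX family, ACTAAC-like → QKI by default), and per-base
conservation profiles around motif occurrences quantify whether the motif
positions are more constrained than their flanks.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .discovery import SkippingEvent
from .io import ConservationTrack, Genome
from .psi import bh_fdr

__all__ = [
    "RegionSet",
    "EnrichmentResult",
    "MotifOccurrence",
    "REGIONS",
    "DEFAULT_FACTOR_MOTIFS",
    "extract_regions",
    "kmer_presence",
    "enrichment_scan",
    "map_motif_to_factor",
    "find_occurrences",
    "conservation_profile",
    "read_factor_motifs",
    "write_factor_motifs",
]

REGIONS = ("exon", "upstream_intron", "downstream_intron")

# Consensus k-mer sets for the factors the default mapping covers; further
# factors (PTB, CELF, MBNL, ...) are supplied through the mapping file.
DEFAULT_FACTOR_MOTIFS: Dict[str, Set[str]] = {
    "RBFOX": {"TGCATG", "GCATG"},
    "QKI": {"ACTAAC", "CTAAC", "ACTAA"},
}


@dataclass
class RegionSet:
    """One scan window of one event, in transcription orientation.

    ``start``/``end`` give the genomic (strand-agnostic) 1-based interval;
    ``sequence`` is reverse-complemented for − strand events so that
    upstream/downstream always refer to the direction of transcription.
    """

    event_id: str
    region: str  # one of REGIONS
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length does not match interval")


def extract_regions(
    event: SkippingEvent, genome: Genome, flank: int = 250
) -> Optional[Dict[str, RegionSet]]:
    """Exon body and flanking intronic windows for one event.

    Windows take up to ``flank`` intronic bases adjacent to the exon and
    never extend past the intron (so they cannot reach neighboring exons).
    For − strand events the genomic roles of the two introns swap and every
    sequence is reverse-complemented.  Events without a defined strand are
    skipped (returns None) because the windows are direction-specific.
    """
    if event.strand not in ("+", "-"):
        return None
    # genomic windows adjacent to the exon on either side
    left_len = min(flank, event.uj.length)
    right_len = min(flank, event.dj.length)
    left = (event.uj.end - left_len + 1, event.uj.end)
    right = (event.dj.start, event.dj.start + right_len - 1)
    exon_iv = (event.exon_start, event.exon_end)
    if event.strand == "+":
        upstream_iv, downstream_iv = left, right
    else:
        upstream_iv, downstream_iv = right, left
    out = {}
    for region, (s, e) in (
        ("exon", exon_iv),
        ("upstream_intron", upstream_iv),
        ("downstream_intron", downstream_iv),
    ):
        seq = genome.fetch(event.chrom, s, e, event.strand)
        out[region] = RegionSet(
            event_id=event.event_id,
            region=region,
            chrom=event.chrom,
            start=s,
            end=e,
            strand=event.strand,
            sequence=seq,
        )
    return out


def kmer_presence(sequence: str, k: int) -> Set[str]:
    """All length-k substrings over A/C/G/T present at least once.

    Presence (not occurrence counts) is recorded because the sampling unit
    of the enrichment test is the exon, not the occurrence.  Substrings
    containing N (or any non-ACGT letter) are skipped.
    """
    if k not in (4, 5, 6):
        raise ValueError(f"k must be one of 4, 5, 6; got {k}")
    seq = sequence.upper()
    valid = set("ACGT")
    out: Set[str] = set()
    for i in range(len(seq) - k + 1):
        sub = seq[i : i + k]
        if set(sub) <= valid:
            out.add(sub)
    return out


@dataclass
class EnrichmentResult:
    kmer: str
    k: int
    region: str
    direction: str  # "included", "excluded", or "pooled" for the exon body
    cancer_type: str
    fg_with: int
    fg_total: int
    bg_with: int
    bg_total: int
    p_hypergeometric: float
    q_value: float = float("nan")
    mapped_factors: List[str] = field(default_factory=list)


def _stratum_scan(
    fg_regions: Sequence[RegionSet],
    bg_regions: Sequence[RegionSet],
    region: str,
    direction: str,
    cancer_type: str,
    ks: Sequence[int],
    factor_motifs: Mapping[str, Set[str]],
) -> List[EnrichmentResult]:
    fg_total, bg_total = len(fg_regions), len(bg_regions)
    population = fg_total + bg_total
    results: List[EnrichmentResult] = []
    for k in ks:
        fg_sets = [kmer_presence(r.sequence, k) for r in fg_regions]
        bg_sets = [kmer_presence(r.sequence, k) for r in bg_regions]
        domain = sorted(set().union(*fg_sets)) if fg_sets else []
        for kmer in domain:
            fg_with = sum(kmer in s for s in fg_sets)
            bg_with = sum(kmer in s for s in bg_sets)
            successes = fg_with + bg_with
            p = float(stats.hypergeom.sf(fg_with - 1, population, successes, fg_total))
            results.append(
                EnrichmentResult(
                    kmer=kmer,
                    k=k,
                    region=region,
                    direction=direction,
                    cancer_type=cancer_type,
                    fg_with=fg_with,
                    fg_total=fg_total,
                    bg_with=bg_with,
                    bg_total=bg_total,
                    p_hypergeometric=p,
                    mapped_factors=map_motif_to_factor(kmer, factor_motifs),
                )
            )
    # BH across every k-mer of this (region, direction, cancer_type) stratum
    q = bh_fdr([r.p_hypergeometric for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return results


def enrichment_scan(
    foreground: Mapping[str, Sequence[RegionSet]],
    background: Sequence[RegionSet] | Mapping[str, Sequence[RegionSet]],
    cancer_type: str,
    ks: Sequence[int] = (4, 5, 6),
    factor_motifs: Mapping[str, Set[str]] | None = None,
) -> List[EnrichmentResult]:
    """Hypergeometric k-mer presence scan of foreground vs background regions.

    ``foreground`` maps direction ("included"/"excluded") to the region
    windows of altered exons changing in that direction; ``background``
    holds the windows of highly expressed, unaltered exons (either a flat
    sequence or the same mapping, which is flattened).  Intronic windows
    are scanned per direction; the exon body pools both directions.  The
    population of the test is foreground ∪ background exons of a region;
    successes are the exons whose window contains the k-mer; draws are the
    foreground.  q-values are BH-adjusted within each (region, direction,
    cancer-type) stratum and significance is assessed by the caller
    (typically q <= 0.01).
    """
    if factor_motifs is None:
        factor_motifs = DEFAULT_FACTOR_MOTIFS
    if isinstance(background, Mapping):
        bg_flat: List[RegionSet] = [r for rs in background.values() for r in rs]
    else:
        bg_flat = list(background)
    bg_by_region: Dict[str, List[RegionSet]] = {reg: [] for reg in REGIONS}
    for r in bg_flat:
        bg_by_region[r.region].append(r)

    fg_by: Dict[Tuple[str, str], List[RegionSet]] = {}
    for direction, regions in foreground.items():
        for r in regions:
            fg_by.setdefault((r.region, direction), []).append(r)

    results: List[EnrichmentResult] = []
    # exon body: direction-pooled
    fg_exon = fg_by.get(("exon", "included"), []) + fg_by.get(("exon", "excluded"), [])
    strata: List[Tuple[List[RegionSet], List[RegionSet], str, str]] = []
    if fg_exon:
        strata.append((fg_exon, bg_by_region["exon"], "exon", "pooled"))
    for region in ("upstream_intron", "downstream_intron"):
        for direction in ("included", "excluded"):
            fg = fg_by.get((region, direction), [])
            if fg:
                strata.append((fg, bg_by_region[region], region, direction))
    for fg, bg, region, direction in strata:
        if not bg:
            warnings.warn(f"empty background for {region}/{direction}; stratum skipped", stacklevel=2)
            continue
        results.extend(
            _stratum_scan(fg, bg, region, direction, cancer_type, ks, factor_motifs)
        )
    return results


def map_motif_to_factor(
    kmer: str, factor_motifs: Mapping[str, Set[str]] | None = None
) -> List[str]:
    """Splicing factors whose consensus set matches the k-mer.

    A factor matches when the k-mer is one of its consensus elements, or
    when a shorter consensus element is contained in the k-mer.
    """
    if factor_motifs is None:
        factor_motifs = DEFAULT_FACTOR_MOTIFS
    kmer = kmer.upper()
    factors = []
    for factor, motifs in factor_motifs.items():
        for motif in motifs:
            if kmer == motif or (len(kmer) > len(motif) and motif in kmer):
                factors.append(factor)
                break
    return sorted(factors)


def read_factor_motifs(path: str | os.PathLike) -> Dict[str, Set[str]]:
    """Two-column TSV (factor, k-mer) → factor → consensus set."""
    out: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            factor, motif = line.split("\t")[:2]
            out.setdefault(factor, set()).add(motif.upper())
    return out


def write_factor_motifs(mapping: Mapping[str, Set[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for factor in sorted(mapping):
            for motif in sorted(mapping[factor]):
                fh.write(f"{factor}\t{motif}\n")


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "kmer": r.kmer,
                "k": r.k,
                "region": r.region,
                "direction": r.direction,
                "cancer_type": r.cancer_type,
                "fg_with": r.fg_with,
                "fg_total": r.fg_total,
                "bg_with": r.bg_with,
                "bg_total": r.bg_total,
                "p": r.p_hypergeometric,
                "q": r.q_value,
                "factors": ",".join(r.mapped_factors),
            }
            for r in results
        ],
        columns=[
            "kmer", "k", "region", "direction", "cancer_type",
            "fg_with", "fg_total", "bg_with", "bg_total", "p", "q", "factors",
        ],
    )


@dataclass(frozen=True)
class MotifOccurrence:
    """One genomic occurrence of a motif (1-based inclusive interval)."""

    chrom: str
    start: int
    end: int


def find_occurrences(kmer: str, regions: Iterable[RegionSet]) -> List[MotifOccurrence]:
    """Genomic coordinates of every match of ``kmer`` within the regions.

    Matching happens on the transcription-oriented sequence; hit offsets on
    − strand regions are mapped back to genomic coordinates.
    """
    kmer = kmer.upper()
    k = len(kmer)
    occurrences = []
    for region in regions:
        seq = region.sequence.upper()
        for i in range(len(seq) - k + 1):
            if seq[i : i + k] != kmer:
                continue
            if region.strand == "-":
                g_end = region.end - i
                g_start = g_end - k + 1
            else:
                g_start = region.start + i
                g_end = g_start + k - 1
            occurrences.append(MotifOccurrence(region.chrom, g_start, g_end))
    return occurrences


def conservation_profile(
    occurrences: Sequence[MotifOccurrence],
    track: ConservationTrack,
    half_window: int = 50,
) -> pd.DataFrame:
    """Mean conservation score per position relative to motif midpoints.

    The midpoint of an occurrence is ``start + (len - 1) // 2`` on the
    genomic strand (left-of-center base for even motif lengths).  Returns a
    frame with columns offset, mean_score, n (occurrences contributing a
    non-missing score at that offset); empty when there are no occurrences.
    """
    offsets = np.arange(-half_window, half_window + 1)
    if not occurrences:
        return pd.DataFrame(columns=["offset", "mean_score", "n"])
    sums = np.zeros(offsets.size)
    counts = np.zeros(offsets.size, dtype=int)
    for occ in occurrences:
        mid = occ.start + (occ.end - occ.start) // 2
        scores = track.scores(occ.chrom, mid + offsets)
        ok = ~np.isnan(scores)
        sums[ok] += scores[ok]
        counts[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"offset": offsets, "mean_score": means, "n": counts})
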
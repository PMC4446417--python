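"""Synthetic matched tumor/normal splicing cohorts with known ground truth.

The generator emulates the structure of a multi-cancer matched-cohort
junction dataset: per cancer type, tumor/normal sample pairs from the same
patients; a synthetic chromosome carrying non-overlapping cassette-exon
loci; per-sample junction read counts whose PSI estimator recovers a
planted inclusion level; planted tumor−normal ΔPSI effects that are either
coherent (same direction in every cancer type) or non-coherent (flipped in
the last cancer type, mirroring the kidney-cohort discordance seen in real
tumor panels); splicing-factor k-mers written into flanking-intron windows
at different rates for altered and background exons; and a conservation
track elevated over the planted motif bases.

Counts follow a Poisson evidence model: with per-event-sample depth d and
true inclusion π, UJC and DJC are independent Poisson(d·π) and SJC is
Poisson(d·(1−π)), so 0.5(UJC+DJC)/(0.5(UJC+DJC)+SJC) is a consistent
estimator of π as d grows.  Biological variability enters through a
symmetric Beta-shaped jitter on π per sample.
"""

from __future__ import annotations

import json
import os
import shutil
from dataclasses import dataclass, field, asdict, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .discovery import SkippingEvent
from .io import (
    ConservationTrack,
    Genome,
    Junction,
    JunctionCountTable,
    SampleManifest,
    reverse_complement,
    write_manifest,
    write_sj_table,
)

__all__ = [
    "MotifPlant",
    "CohortDesign",
    "EventTruth",
    "SyntheticCohort",
    "generate_gene_models",
    "assign_truth",
    "simulate_counts",
    "plant_motifs",
    "generate_conservation",
    "generate_cohort",
    "write_cohort",
    "mirror_cohort",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MotifPlant:
    """A k-mer planted into one flanking window of a direction class."""

    kmer: str = "TGCATG"
    region: str = "downstream_intron"
    direction: str = "included"  # altered events changing this way get fg_rate
    fg_rate: float = 0.6
    bg_rate: float = 0.1


@dataclass(frozen=True)
class CohortDesign:
    """Study conditions for one synthetic cohort.

    Defaults describe a three-cancer-type matched panel of 20 pairs each,
    1000 cassette events of which 100 carry a |ΔPSI| = 0.25 tumor effect at
    mean junction depth 50, with a RBFOX-consensus 6-mer planted downstream
    of tumor-included altered exons.
    """

    cancer_types: Tuple[str, ...] = ("BRCA", "LUAD", "KIRC")
    pairs_per_type: int = 20
    n_events: int = 1000
    n_altered: int = 100
    delta_psi_effect: float = 0.25
    coherent_fraction: float = 0.65
    depth_mean: float = 50.0
    depth_cv: float = 0.3
    psi_jitter: float = 0.05  # half-width of the Beta-shaped per-sample deviation
    jitter_beta: float = 2.0
    exon_len_range: Tuple[int, int] = (60, 240)
    frame_preserving_fraction: float = 0.47
    intron_len_range: Tuple[int, int] = (300, 500)
    flank_len: int = 250
    minus_strand_fraction: float = 0.5
    spacer_range: Tuple[int, int] = (80, 160)
    altered_direction: Optional[str] = None  # force "inclusion"/"exclusion" for every altered event
    motif_plant: Optional[MotifPlant] = MotifPlant()
    conservation_baseline: float = 0.4
    conservation_motif: float = 0.9
    conservation_noise: float = 0.05
    chrom: str = "chrS"
    chrom_length: Optional[int] = None  # cap; auto-sized when None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_altered > self.n_events:
            raise ValueError("n_altered must not exceed n_events")
        if not 0 <= self.coherent_fraction <= 1:
            raise ValueError("coherent_fraction must lie in [0, 1]")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be non-negative")
        if not 0 < self.delta_psi_effect < 0.49:
            raise ValueError("delta_psi_effect must lie in (0, 0.49)")
        if self.motif_plant is not None:
            if not 0 <= self.motif_plant.fg_rate <= 1 or not 0 <= self.motif_plant.bg_rate <= 1:
                raise ValueError("motif plant rates must lie in [0, 1]")
            if len(self.motif_plant.kmer) > self.flank_len:
                raise ValueError("planted k-mer longer than the flanking window")


@dataclass
class EventTruth:
    """Planted ground truth for one event."""

    event_id: str
    psi_normal: float
    psi_tumor: Dict[str, float]  # per cancer type
    altered: bool
    direction: Dict[str, str]  # per cancer type: "inclusion"/"exclusion"/"none"
    base_direction: str  # sign class before any non-coherent flip
    coherent: bool
    motif_planted: bool = False
    motif_region: Optional[str] = None


@dataclass
class SyntheticCohort:
    design: CohortDesign
    events: List[SkippingEvent]
    genome: Genome
    truth: Dict[str, EventTruth]
    manifest: SampleManifest
    tables: List[JunctionCountTable]
    conservation: ConservationTrack
    planted: pd.DataFrame  # columns event_id, region, chrom, start, end

    def tables_of(self, cancer_type: str) -> List[JunctionCountTable]:
        wanted = set(self.manifest.samples_of(cancer_type))
        return [t for t in self.tables if t.sample_id in wanted]


def _random_exon_length(rng: np.random.Generator, design: CohortDesign) -> int:
    lo, hi = design.exon_len_range
    want_frame = rng.random() < design.frame_preserving_fraction
    for _ in range(200):
        length = int(rng.integers(lo, hi + 1))
        if (length % 3 == 0) == want_frame:
            return length
    return int(rng.integers(lo, hi + 1))  # degenerate range, e.g. (30, 30)


def generate_gene_models(
    design: CohortDesign, rng: Optional[np.random.Generator] = None
) -> Tuple[List[SkippingEvent], Genome]:
    """Non-overlapping cassette loci on one synthetic chromosome.

    Each locus is [spacer | upstream intron | exon | downstream intron];
    the three junctions follow the intron-coordinate convention (UJ and DJ
    are the introns, SJ spans both plus the exon).  Deterministic for a
    fixed design seed.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    events: List[SkippingEvent] = []
    cursor = 1
    for _ in range(design.n_events):
        gap = int(rng.integers(*design.spacer_range))
        u_len = int(rng.integers(design.intron_len_range[0], design.intron_len_range[1] + 1))
        d_len = int(rng.integers(design.intron_len_range[0], design.intron_len_range[1] + 1))
        exon_len = _random_exon_length(rng, design)
        strand = "-" if rng.random() < design.minus_strand_fraction else "+"
        u_start = cursor + gap
        u_end = u_start + u_len - 1
        exon_end = u_end + exon_len
        d_start = exon_end + 1
        d_end = d_start + d_len - 1
        uj = Junction(design.chrom, u_start, u_end, strand)
        dj = Junction(design.chrom, d_start, d_end, strand)
        sj = Junction(design.chrom, u_start, d_end, strand)
        events.append(SkippingEvent.from_junctions(uj, dj, sj))
        cursor = d_end + 1
    total_len = cursor + int(design.spacer_range[1])
    if design.chrom_length is not None:
        if total_len > design.chrom_length:
            raise ValueError(
                f"{design.n_events} loci need {total_len} bases but chrom_length is {design.chrom_length}"
            )
        total_len = design.chrom_length
    if design.n_events == 0:
        return [], Genome({})
    seq = "".join(rng.choice(_BASES, size=total_len))
    return events, Genome({design.chrom: seq})


def assign_truth(
    design: CohortDesign,
    events: Sequence[SkippingEvent],
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, EventTruth]:
    """Baseline inclusion levels and planted per-type tumor effects.

    Altered events share one sign across cancer types when coherent; a
    non-coherent event has its sign flipped in the last cancer type.
    Baselines of altered events are drawn so that both effect directions
    stay inside [0, 1] without clamping.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed + 1)
    n = len(events)
    altered_idx = set(rng.choice(n, size=design.n_altered, replace=False).tolist()) if design.n_altered else set()
    delta = design.delta_psi_effect
    truth: Dict[str, EventTruth] = {}
    for i, ev in enumerate(events):
        if i in altered_idx:
            base = float(rng.uniform(delta + 0.02, 1 - delta - 0.02))
            if design.altered_direction is not None:
                sign = 1 if design.altered_direction == "inclusion" else -1
                coherent = len(design.cancer_types) > 1
            else:
                sign = 1 if rng.random() < 0.5 else -1
                coherent = bool(rng.random() < design.coherent_fraction) and len(design.cancer_types) > 1
            psi_tumor, direction = {}, {}
            for j, ct in enumerate(design.cancer_types):
                s = sign
                if not coherent and len(design.cancer_types) > 1 and j == len(design.cancer_types) - 1:
                    s = -sign
                psi_tumor[ct] = base + s * delta
                direction[ct] = "inclusion" if s > 0 else "exclusion"
            truth[ev.event_id] = EventTruth(
                event_id=ev.event_id,
                psi_normal=base,
                psi_tumor=psi_tumor,
                altered=True,
                direction=direction,
                base_direction="inclusion" if sign > 0 else "exclusion",
                coherent=coherent if len(design.cancer_types) > 1 else False,
            )
        else:
            base = float(rng.uniform(0.10, 0.90))
            truth[ev.event_id] = EventTruth(
                event_id=ev.event_id,
                psi_normal=base,
                psi_tumor={ct: base for ct in design.cancer_types},
                altered=False,
                direction={ct: "none" for ct in design.cancer_types},
                base_direction="none",
                coherent=False,
            )
    return truth


def _build_manifest(design: CohortDesign) -> SampleManifest:
    rows = []
    for ct in design.cancer_types:
        for p in range(1, design.pairs_per_type + 1):
            patient = f"{ct}_P{p:03d}"
            rows.append((f"{patient}_T", patient, "tumor", ct))
            rows.append((f"{patient}_N", patient, "normal", ct))
    return SampleManifest(
        entries=pd.DataFrame(rows, columns=list(SampleManifest.COLUMNS))
    )


def simulate_counts(
    events: Sequence[SkippingEvent],
    truth: Dict[str, EventTruth],
    design: CohortDesign,
    manifest: Optional[SampleManifest] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[SampleManifest, List[JunctionCountTable]]:
    """Per-sample junction tables under the Poisson evidence model."""
    if rng is None:
        rng = np.random.default_rng(design.seed + 2)
    if manifest is None:
        manifest = _build_manifest(design)
    n = len(events)
    base_psi = {
        (ct, cond): np.array(
            [
                truth[e.event_id].psi_tumor[ct] if cond == "tumor" else truth[e.event_id].psi_normal
                for e in events
            ]
        )
        for ct in design.cancer_types
        for cond in ("tumor", "normal")
    }
    shape = 1.0 / (design.depth_cv**2) if design.depth_cv > 0 else None
    tables: List[JunctionCountTable] = []
    for _, row in manifest.entries.iterrows():
        pi = base_psi[(row["cancer_type"], row["condition"])]
        if design.psi_jitter > 0 and n:
            dev = (rng.beta(design.jitter_beta, design.jitter_beta, size=n) - 0.5) * 2 * design.psi_jitter
            pi = np.clip(pi + dev, 0.0, 1.0)
        if design.depth_mean == 0 or n == 0:
            d = np.zeros(n)
        elif shape is None:
            d = np.full(n, design.depth_mean)
        else:
            d = rng.gamma(shape, design.depth_mean / shape, size=n)
        ujc = rng.poisson(d * pi)
        djc = rng.poisson(d * pi)
        sjc = rng.poisson(d * (1.0 - pi))
        counts: Dict[Junction, int] = {}
        for i, ev in enumerate(events):
            counts[ev.uj] = int(ujc[i])
            counts[ev.dj] = int(djc[i])
            counts[ev.sj] = int(sjc[i])
        tables.append(JunctionCountTable(sample_id=row["sample_id"], counts=counts))
    return manifest, tables


def _plant_window(ev: SkippingEvent, region: str, flank: int) -> Tuple[int, int]:
    """Genomic interval of a transcription-oriented flanking window."""
    left = (max(ev.uj.start, ev.uj.end - flank + 1), ev.uj.end)
    right = (ev.dj.start, min(ev.dj.end, ev.dj.start + flank - 1))
    if region == "exon":
        return ev.exon_start, ev.exon_end
    if ev.strand == "+":
        return left if region == "upstream_intron" else right
    return right if region == "upstream_intron" else left


def plant_motifs(
    genome: Genome,
    events: Sequence[SkippingEvent],
    truth: Dict[str, EventTruth],
    design: CohortDesign,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Genome, pd.DataFrame]:
    """Write the configured k-mer into flanking windows at class-dependent rates.

    Altered events whose base direction matches the plant's direction
    receive the motif with probability ``fg_rate``; every other event with
    probability ``bg_rate``.  On − strand loci the genomic sequence carries
    the reverse complement so the transcription-oriented window reads the
    k-mer forwards.  Returns the modified genome and a table of planted
    genomic intervals.
    """
    plant = design.motif_plant
    if plant is None:
        return genome, pd.DataFrame(columns=["event_id", "region", "chrom", "start", "end", "foreground"])
    if rng is None:
        rng = np.random.default_rng(design.seed + 3)
    kmer = plant.kmer.upper()
    # plant directions use the enrichment vocabulary ("included"/"excluded")
    plant_dir = {"included": "inclusion", "excluded": "exclusion"}.get(plant.direction, plant.direction)
    seqs = {c: bytearray(genome.fetch(c, 1, genome.length(c)), "ascii") for c in genome.chroms}
    rows = []
    for ev in events:
        if ev.strand not in ("+", "-"):
            continue
        t = truth[ev.event_id]
        is_fg = t.altered and t.base_direction == plant_dir
        rate = plant.fg_rate if is_fg else plant.bg_rate
        if rng.random() >= rate:
            continue
        w_start, w_end = _plant_window(ev, plant.region, design.flank_len)
        w_len = w_end - w_start + 1
        if w_len < len(kmer):
            raise ValueError(f"{ev.event_id}: window shorter than the planted k-mer")
        offset = int(rng.integers(0, w_len - len(kmer) + 1))
        g_start = w_start + offset
        written = kmer if ev.strand == "+" else reverse_complement(kmer)
        seqs[ev.chrom][g_start - 1 : g_start - 1 + len(kmer)] = written.encode("ascii")
        rows.append(
            {
                "event_id": ev.event_id,
                "region": plant.region,
                "chrom": ev.chrom,
                "start": g_start,
                "end": g_start + len(kmer) - 1,
                "foreground": is_fg,
            }
        )
        t.motif_planted = True
        t.motif_region = plant.region
    planted = pd.DataFrame(rows, columns=["event_id", "region", "chrom", "start", "end", "foreground"])
    return Genome({c: bytes(s).decode("ascii") for c, s in seqs.items()}), planted


def generate_conservation(
    events: Sequence[SkippingEvent],
    planted: pd.DataFrame,
    design: CohortDesign,
    rng: Optional[np.random.Generator] = None,
) -> ConservationTrack:
    """Noisy baseline conservation over every scan window, elevated on motif bases."""
    if rng is None:
        rng = np.random.default_rng(design.seed + 4)
    track = ConservationTrack()
    noise = design.conservation_noise
    for ev in events:
        if ev.strand not in ("+", "-"):
            continue
        start = max(ev.uj.start, ev.uj.end - design.flank_len + 1)
        end = min(ev.dj.end, ev.dj.start + design.flank_len - 1)
        positions = np.arange(start, end + 1)
        scores = design.conservation_baseline + rng.uniform(-noise, noise, size=positions.size)
        track.set_scores(ev.chrom, positions, np.clip(scores, 0.0, 1.0))
    for _, row in planted.iterrows():
        positions = np.arange(row["start"], row["end"] + 1)
        scores = design.conservation_motif + rng.uniform(-noise, noise, size=positions.size)
        track.set_scores(row["chrom"], positions, np.clip(scores, 0.0, 1.0))
    return track


def generate_cohort(design: CohortDesign) -> SyntheticCohort:
    """Full cohort: gene models, truth, counts, motifs, conservation."""
    rng = np.random.default_rng(design.seed)
    events, genome = generate_gene_models(design, rng)
    truth = assign_truth(design, events, rng)
    manifest, tables = simulate_counts(events, truth, design, rng=rng)
    genome, planted = plant_motifs(genome, events, truth, design, rng)
    conservation = generate_conservation(events, planted, design, rng)
    return SyntheticCohort(
        design=design,
        events=events,
        genome=genome,
        truth=truth,
        manifest=manifest,
        tables=tables,
        conservation=conservation,
        planted=planted,
    )


def truth_to_frame(truth: Dict[str, EventTruth], cancer_types: Sequence[str]) -> pd.DataFrame:
    rows = []
    for eid in sorted(truth):
        t = truth[eid]
        row = {
            "event_id": eid,
            "psi_normal": t.psi_normal,
            "altered": t.altered,
            "coherent": t.coherent,
            "base_direction": t.base_direction,
            "motif_planted": t.motif_planted,
        }
        for ct in cancer_types:
            row[f"psi_tumor_{ct}"] = t.psi_tumor[ct]
            row[f"direction_{ct}"] = t.direction[ct]
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(design: CohortDesign, out_dir: str | os.PathLike) -> SyntheticCohort:
    """Materialise a cohort as the file tree the readers consume.

    Emits per-sample SJ tables under ``sj/``, the manifest, genome FASTA,
    conservation bedGraph, truth and planted-motif TSVs, and a JSON index
    of relative paths.  On any failure the partially written directory is
    removed before the error propagates.
    """
    out_dir = os.fspath(out_dir)
    cohort = generate_cohort(design)
    created = not os.path.exists(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    try:
        sj_dir = os.path.join(out_dir, "sj")
        os.makedirs(sj_dir, exist_ok=True)
        paths = {"sj_dir": "sj", "sj_tables": {}}
        for table in cohort.tables:
            rel = os.path.join("sj", f"{table.sample_id}.sj.tab")
            write_sj_table(table, os.path.join(out_dir, rel))
            paths["sj_tables"][table.sample_id] = rel
        write_manifest(cohort.manifest, os.path.join(out_dir, "manifest.tsv"))
        paths["manifest"] = "manifest.tsv"
        if cohort.events:
            cohort.genome.to_fasta(os.path.join(out_dir, "genome.fa"))
            paths["genome"] = "genome.fa"
            cohort.conservation.to_bedgraph(os.path.join(out_dir, "conservation.bedGraph"))
            paths["conservation"] = "conservation.bedGraph"
        truth_to_frame(cohort.truth, design.cancer_types).to_csv(
            os.path.join(out_dir, "truth_events.tsv"), sep="\t", index=False
        )
        paths["truth"] = "truth_events.tsv"
        cohort.planted.to_csv(os.path.join(out_dir, "planted_motifs.tsv"), sep="\t", index=False)
        paths["planted_motifs"] = "planted_motifs.tsv"
        with open(os.path.join(out_dir, "cohort.json"), "w") as fh:
            json.dump({"paths": paths, "seed": design.seed}, fh, indent=2, sort_keys=True)
    except BaseException:
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        raise
    return cohort


# ---------------------------------------------------------------------------
# mirroring (used by strand-invariance checks)

def _mirror_junction(j: Junction, length: int) -> Junction:
    flipped = {"+": "-", "-": "+", "unknown": "unknown"}[j.strand]
    return Junction(j.chrom, length - j.end + 1, length - j.start + 1, flipped)


def mirror_cohort(cohort: SyntheticCohort) -> Tuple[SyntheticCohort, Dict[str, str]]:
    """The coordinate-mirrored cohort and an old→new event-id mapping.

    Reverse-complements every chromosome and maps each position p to
    L − p + 1 with strands flipped.  Biological content is unchanged: each
    event's transcription-oriented sequences, PSI values and truth are
    identical, which makes the mirror a strand-correctness probe for the
    whole pipeline.
    """
    design = cohort.design
    lengths = {c: cohort.genome.length(c) for c in cohort.genome.chroms}
    genome = Genome(
        {c: reverse_complement(cohort.genome.fetch(c, 1, lengths[c])) for c in cohort.genome.chroms}
    )
    id_map: Dict[str, str] = {}
    events: List[SkippingEvent] = []
    for ev in cohort.events:
        L = lengths[ev.chrom]
        uj = _mirror_junction(ev.dj, L)  # genomic left/right swap
        dj = _mirror_junction(ev.uj, L)
        sj = _mirror_junction(ev.sj, L)
        new = SkippingEvent.from_junctions(uj, dj, sj)
        id_map[ev.event_id] = new.event_id
        events.append(new)
    tables = []
    for table in cohort.tables:
        counts = {
            _mirror_junction(j, lengths[j.chrom]): c for j, c in table.counts.items()
        }
        tables.append(JunctionCountTable(sample_id=table.sample_id, counts=counts))
    truth = {}
    for old_id, t in cohort.truth.items():
        new_id = id_map[old_id]
        truth[new_id] = replace(t, event_id=new_id)
    planted = cohort.planted.copy()
    if len(planted):
        L = planted["chrom"].map(lengths)
        new_start = L - planted["end"] + 1
        new_end = L - planted["start"] + 1
        planted["start"], planted["end"] = new_start, new_end
        planted["event_id"] = planted["event_id"].map(id_map)
    track = ConservationTrack()
    for chrom, L in lengths.items():
        scores = cohort.conservation.scores(chrom, np.arange(1, L + 1))
        ok = ~np.isnan(scores)
        positions = (L - np.arange(1, L + 1) + 1)[ok]
        track.set_scores(chrom, positions, scores[ok])
    mirrored = SyntheticCohort(
        design=design,
        events=events,
        genome=genome,
        truth=truth,
        manifest=cohort.manifest,
        tables=tables,
        conservation=track,
        planted=planted,
    )
    return mirrored, id_map
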
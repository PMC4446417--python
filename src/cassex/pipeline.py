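"""Stage orchestration: discovery → PSI → differential → recurrence/markers → motifs.

Each stage reads and writes plain TSV artifacts so stages can be run and
tested independently; every output carries a header comment recording the
configuration hash and the stage's in/out tallies, and the run log records
the event funnel after each filter.  Outputs are a pure function of
(inputs, configuration, seed).
"""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import discovery, motifs, psi, recurrence
from .io import (
    ConservationTrack,
    Genome,
    JunctionCountTable,
    SampleManifest,
    read_manifest,
    read_sj_table,
    write_bed,
)

logger = logging.getLogger("cassex")

__all__ = ["RunConfig", "run_pipeline", "load_tables"]


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    sj_dir: str = ""
    manifest: str = ""
    fasta: str = ""
    conservation: str = ""
    annotation: str = ""
    out_dir: str = "results"
    min_reads: int = 5
    balance_abs: int = 10
    balance_mult: int = 2
    min_cov: float = 10.0
    min_pairs: int = 15
    fdr: float = 0.05
    min_delta: float = 0.10
    marker_delta: float = 0.10
    marker_frac: float = 0.90
    flank: int = 250
    motif_fdr: float = 0.01
    kmin: int = 4
    kmax: int = 6
    profile_kmer: str = "TGCATG"
    profile_halfwin: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_reads", "balance_abs", "balance_mult", "min_cov", "min_pairs", "flank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fdr", "motif_fdr", "min_delta", "marker_delta", "marker_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not {self.kmin, self.kmax} <= {4, 5, 6} or self.kmin > self.kmax:
            raise ValueError("k-mer sizes must satisfy 4 <= kmin <= kmax <= 6")

    @property
    def ks(self) -> Tuple[int, ...]:
        return tuple(range(self.kmin, self.kmax + 1))

    #: location fields excluded from the hash: it identifies the analysis
    #: parameters, so the same run in another directory hashes identically
    _PATH_FIELDS = ("sj_dir", "manifest", "fasta", "conservation", "annotation", "out_dir")

    def config_hash(self) -> str:
        params = {
            k: v for k, v in dataclasses.asdict(self).items() if k not in self._PATH_FIELDS
        }
        payload = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str, **overrides) -> "RunConfig":
        """Flat key = value config file; later command-line overrides win."""
        values: Dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                values[key.strip()] = value.strip()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in values:
                kwargs[f.name] = _coerce(values[f.name], f.default)
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)


def _coerce(raw: str, default) -> object:
    if isinstance(default, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    return raw


def _write_tsv(df: pd.DataFrame, path: str, config: RunConfig, n_in: int, n_out: int, **index_kw) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cassex config={config.config_hash()} in={n_in} out={n_out}\n")
        df.to_csv(fh, sep="\t", na_rep="NA", **index_kw)


def read_stage_tsv(path: str, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], **kw)


def load_tables(sj_dir: str) -> List[JunctionCountTable]:
    paths = sorted(glob.glob(os.path.join(sj_dir, "*.tab")) + glob.glob(os.path.join(sj_dir, "*.tsv")))
    if not paths:
        raise FileNotFoundError(f"no SJ tables (*.tab, *.tsv) under {sj_dir}")
    return [read_sj_table(p) for p in paths]


def events_to_frame(events: Sequence[discovery.SkippingEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": e.event_id,
                "chrom": e.chrom,
                "strand": e.strand,
                "uj_start": e.uj.start,
                "uj_end": e.uj.end,
                "dj_start": e.dj.start,
                "dj_end": e.dj.end,
                "exon_start": e.exon_start,
                "exon_end": e.exon_end,
            }
            for e in events
        ],
        columns=[
            "event_id", "chrom", "strand", "uj_start", "uj_end",
            "dj_start", "dj_end", "exon_start", "exon_end",
        ],
    )


def frame_to_events(df: pd.DataFrame) -> List[discovery.SkippingEvent]:
    from .io import Junction

    events = []
    for _, r in df.iterrows():
        uj = Junction(r["chrom"], int(r["uj_start"]), int(r["uj_end"]), r["strand"])
        dj = Junction(r["chrom"], int(r["dj_start"]), int(r["dj_end"]), r["strand"])
        sj = Junction(r["chrom"], int(r["uj_start"]), int(r["dj_end"]), r["strand"])
        events.append(discovery.SkippingEvent.from_junctions(uj, dj, sj))
    return events


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> str:
    """Execute every stage in order; returns the result directory.

    Discovery and the balance filter run per cancer-type dataset (the
    junction filters are defined over "the dataset"); event sets are then
    unified by event id for the cross-cancer stages.  Any stage failure
    aborts with the stage name while earlier artifacts stay on disk.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    stage = "setup"
    try:
        manifest = read_manifest(config.manifest)
        tables = load_tables(config.sj_dir)
        by_sample = {t.sample_id: t for t in tables}
        cancer_types = manifest.cancer_types

        stage = "discover"
        events_by_id: Dict[str, discovery.SkippingEvent] = {}
        per_type_events: Dict[str, List[str]] = {}
        for ct in cancer_types:
            ct_tables = [by_sample[s] for s in manifest.samples_of(ct) if s in by_sample]
            pool = discovery.pool_junction_support(ct_tables)
            supported = discovery.filter_min_support(pool, min_reads=config.min_reads)
            candidates = discovery.enumerate_triplets(supported)
            kept = [
                e
                for e in candidates
                if discovery.balance_filter(
                    e, ct_tables, max_abs_diff=config.balance_abs, ratio_mult=config.balance_mult
                )
            ]
            logger.info(
                "%s: junctions %d -> supported %d; triplets %d -> balanced %d",
                ct, len(pool), len(supported), len(candidates), len(kept),
            )
            per_type_events[ct] = [e.event_id for e in kept]
            for e in kept:
                events_by_id.setdefault(e.event_id, e)
        events = [events_by_id[k] for k in sorted(events_by_id)]
        _write_tsv(
            events_to_frame(events), os.path.join(config.out_dir, "events.tsv"),
            config, n_in=sum(len(t) for t in tables), n_out=len(events), index=False,
        )
        write_bed(
            [(e.chrom, e.exon_start, e.exon_end, e.event_id, e.strand if e.strand != "unknown" else ".") for e in events],
            os.path.join(config.out_dir, "events.bed"),
        )

        stage = "psi"
        matrix = psi.build_psi_matrix(events, tables)
        matrix.to_tsv(
            os.path.join(config.out_dir, "psi.tsv"),
            os.path.join(config.out_dir, "coverage.tsv"),
        )

        stage = "diff"
        all_calls: List[psi.DifferentialCall] = []
        highly_expressed: Dict[str, List[str]] = {}
        for ct in cancer_types:
            candidate_ids = set(per_type_events[ct])
            passing = [
                eid
                for eid in psi.high_expression_filter(
                    matrix, manifest, ct, min_cov=config.min_cov, min_pairs=config.min_pairs
                )
                if eid in candidate_ids
            ]
            highly_expressed[ct] = passing
            calls = psi.call_differential(
                matrix, manifest, ct,
                fdr=config.fdr, min_delta=config.min_delta,
                min_cov=config.min_cov, min_pairs=config.min_pairs,
                event_ids=passing,
            )
            logger.info(
                "%s: highly expressed %d, significant %d",
                ct, len(passing), sum(c.significant for c in calls),
            )
            all_calls.extend(calls)
        diff_frame = psi.calls_to_frame(all_calls)
        _write_tsv(
            diff_frame, os.path.join(config.out_dir, "differential.tsv"),
            config, n_in=len(events), n_out=int(diff_frame["significant"].sum()) if len(diff_frame) else 0,
            index=False,
        )

        stage = "recur"
        records = recurrence.classify_recurrence(all_calls)
        rec_frame = recurrence.recurrence_to_frame(records, cancer_types)
        _write_tsv(
            rec_frame, os.path.join(config.out_dir, "recurrence.tsv"),
            config, n_in=len(all_calls), n_out=len(records), index=False,
        )

        stage = "markers"
        marker_calls: List[recurrence.MarkerCall] = []
        for ct in cancer_types:
            marker_calls.extend(
                recurrence.detect_markers(
                    matrix, manifest, ct, highly_expressed[ct],
                    delta=config.marker_delta, frac=config.marker_frac, min_cov=config.min_cov,
                )
            )
        mk_frame = recurrence.markers_to_frame(marker_calls)
        _write_tsv(
            mk_frame, os.path.join(config.out_dir, "markers.tsv"),
            config, n_in=len(marker_calls), n_out=int(mk_frame["marker"].sum()) if len(mk_frame) else 0,
            index=False,
        )

        stage = "motifs"
        enr_frames: List[pd.DataFrame] = []
        all_results: List[motifs.EnrichmentResult] = []
        genome = Genome.from_fasta(config.fasta) if config.fasta else None
        if genome is not None:
            sig = {
                (c.event_id, c.cancer_type): c for c in all_calls if c.significant
            }
            region_cache: Dict[str, Optional[Dict[str, motifs.RegionSet]]] = {}

            def regions_of(eid: str):
                if eid not in region_cache:
                    region_cache[eid] = motifs.extract_regions(
                        events_by_id[eid], genome, flank=config.flank
                    )
                return region_cache[eid]

            for ct in cancer_types:
                fg: Dict[str, List[motifs.RegionSet]] = {"included": [], "excluded": []}
                bg: List[motifs.RegionSet] = []
                for eid in highly_expressed[ct]:
                    regs = regions_of(eid)
                    if regs is None:
                        continue
                    call = sig.get((eid, ct))
                    if call is None:
                        bg.extend(regs.values())
                    else:
                        key = "included" if call.direction == "inclusion" else "excluded"
                        fg[key].extend(regs.values())
                if not (fg["included"] or fg["excluded"]) or not bg:
                    logger.info("%s: motif scan skipped (empty stratum)", ct)
                    continue
                results = motifs.enrichment_scan(fg, bg, ct, ks=config.ks)
                all_results.extend(results)
                enr_frames.append(motifs.enrichment_to_frame(results))
            enr = (
                pd.concat(enr_frames, ignore_index=True)
                if enr_frames
                else motifs.enrichment_to_frame([])
            )
            n_sig = int((enr["q"] <= config.motif_fdr).sum()) if len(enr) else 0
            _write_tsv(
                enr, os.path.join(config.out_dir, "motif_enrichment.tsv"),
                config, n_in=len(enr), n_out=n_sig, index=False,
            )

            stage = "profile"
            if config.conservation and config.profile_kmer:
                track = ConservationTrack.from_bedgraph(config.conservation)
                fg_regions: List[motifs.RegionSet] = []
                bg_regions: List[motifs.RegionSet] = []
                altered_ids = {c.event_id for c in all_calls if c.significant}
                tested_ids = sorted({eid for ids in highly_expressed.values() for eid in ids})
                for eid in tested_ids:
                    regs = regions_of(eid)
                    if regs is None:
                        continue
                    target = fg_regions if eid in altered_ids else bg_regions
                    target.extend(
                        r for r in regs.values() if r.region != "exon"
                    )
                fg_prof = motifs.conservation_profile(
                    motifs.find_occurrences(config.profile_kmer, fg_regions),
                    track, half_window=config.profile_halfwin,
                )
                bg_prof = motifs.conservation_profile(
                    motifs.find_occurrences(config.profile_kmer, bg_regions),
                    track, half_window=config.profile_halfwin,
                )
                prof = pd.merge(
                    fg_prof.rename(columns={"mean_score": "mean_fg", "n": "n_fg"}),
                    bg_prof.rename(columns={"mean_score": "mean_bg", "n": "n_bg"}),
                    on="offset", how="outer",
                )
                _write_tsv(
                    prof, os.path.join(config.out_dir, "conservation_profile.tsv"),
                    config, n_in=len(fg_regions) + len(bg_regions), n_out=len(prof), index=False,
                )
    except Exception as exc:
        raise StageFailure(stage, exc) from exc
    return config.out_dir
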
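"""Synthetic cohort generator: determinism, count model calibration, planting."""

import hashlib
import os

import numpy as np
import pandas as pd
import pytest

from cassex.io import reverse_complement
from cassex.motifs import extract_regions
from cassex.psi import build_psi_matrix, compute_psi
from cassex.simulate import (
    CohortDesign,
    EventTruth,
    MotifPlant,
    generate_cohort,
    generate_gene_models,
    mirror_cohort,
    simulate_counts,
    truth_to_frame,
    write_cohort,
)


def _design(**kw):
    defaults = dict(
        cancer_types=("AAA", "BBB"),
        pairs_per_type=4,
        n_events=30,
        n_altered=6,
        seed=5,
    )
    defaults.update(kw)
    return CohortDesign(**defaults)


def _flat_truth(events, psi, cancer_types):
    return {
        ev.event_id: EventTruth(
            event_id=ev.event_id,
            psi_normal=psi,
            psi_tumor={ct: psi for ct in cancer_types},
            altered=False,
            direction={ct: "none" for ct in cancer_types},
            base_direction="none",
            coherent=False,
        )
        for ev in events
    }


class TestGeneModels:
    def test_exon_length_range_respected(self):
        design = _design(exon_len_range=(30, 30), n_events=25)
        events, genome = generate_gene_models(design)
        assert len(events) == 25
        assert all(ev.exon_length == 30 for ev in events)
        assert genome.length(design.chrom) >= events[-1].dj.end

    def test_loci_do_not_overlap(self):
        events, _ = generate_gene_models(_design(n_events=50))
        for a, b in zip(events, events[1:]):
            assert a.dj.end < b.uj.start

    def test_strands_follow_fraction(self):
        events, _ = generate_gene_models(_design(n_events=40, minus_strand_fraction=1.0))
        assert all(ev.strand == "-" for ev in events)

    def test_chrom_length_cap_enforced(self):
        with pytest.raises(ValueError):
            generate_gene_models(_design(n_events=50, chrom_length=1000))


class TestTruth:
    def test_altered_effect_magnitude_exact(self):
        design = _design(n_events=60, n_altered=20, delta_psi_effect=0.25)
        cohort = generate_cohort(design)
        n_alt = 0
        for t in cohort.truth.values():
            if not t.altered:
                assert all(v == t.psi_normal for v in t.psi_tumor.values())
                continue
            n_alt += 1
            for ct in design.cancer_types:
                assert abs(t.psi_tumor[ct] - t.psi_normal) == pytest.approx(0.25)
                assert 0.0 <= t.psi_tumor[ct] <= 1.0
        assert n_alt == 20

    def test_non_coherent_flips_only_last_type(self):
        design = _design(
            cancer_types=("AAA", "BBB", "CCC"), n_events=200, n_altered=80, coherent_fraction=0.5
        )
        cohort = generate_cohort(design)
        saw_non_coherent = False
        for t in cohort.truth.values():
            if not t.altered:
                continue
            dirs = [t.direction[ct] for ct in design.cancer_types]
            if t.coherent:
                assert len(set(dirs)) == 1
            else:
                saw_non_coherent = True
                assert dirs[0] == dirs[1] == t.base_direction != dirs[2]
        assert saw_non_coherent

    def test_forced_direction_makes_every_altered_event_coherent(self):
        cohort = generate_cohort(_design(altered_direction="inclusion", n_altered=10))
        alt = [t for t in cohort.truth.values() if t.altered]
        assert len(alt) == 10
        assert all(t.base_direction == "inclusion" and t.coherent for t in alt)

    def test_truth_frame_round_shape(self):
        cohort = generate_cohort(_design())
        frame = truth_to_frame(cohort.truth, cohort.design.cancer_types)
        assert len(frame) == 30
        assert frame["altered"].sum() == 6
        assert "psi_tumor_AAA" in frame.columns


class TestCounts:
    def test_pi_one_never_emits_skipping_reads(self):
        design = _design(psi_jitter=0.0, motif_plant=None)
        events, _ = generate_gene_models(design)
        truth = _flat_truth(events, 1.0, design.cancer_types)
        _, tables = simulate_counts(events, truth, design)
        for table in tables:
            assert all(table.counts[ev.sj] == 0 for ev in events)

    def test_zero_depth_gives_all_missing_psi(self):
        design = _design(depth_mean=0.0)
        cohort = generate_cohort(design)
        matrix = build_psi_matrix(cohort.events, cohort.tables)
        assert matrix.psi.isna().all().all()

    def test_mean_psi_calibrated_at_high_depth(self):
        design = _design(
            cancer_types=("AAA",),
            pairs_per_type=30,
            n_events=150,
            n_altered=0,
            depth_mean=100.0,
            depth_cv=0.0,
            psi_jitter=0.0,
            motif_plant=None,
        )
        events, _ = generate_gene_models(design)
        truth = _flat_truth(events, 0.7, design.cancer_types)
        _, tables = simulate_counts(events, truth, design)
        est = [
            compute_psi(t.counts[ev.uj], t.counts[ev.dj], t.counts[ev.sj])
            for t in tables
            for ev in events
        ]
        assert np.nanmean(est) == pytest.approx(0.7, abs=0.01)

    def test_estimation_error_shrinks_with_depth(self):
        maes = []
        for depth in (10.0, 50.0, 200.0):
            design = _design(
                cancer_types=("AAA",),
                pairs_per_type=20,
                n_events=100,
                n_altered=0,
                depth_mean=depth,
                depth_cv=0.0,
                psi_jitter=0.0,
                motif_plant=None,
                seed=9,
            )
            events, _ = generate_gene_models(design)
            truth = _flat_truth(events, 0.6, design.cancer_types)
            _, tables = simulate_counts(events, truth, design)
            errs = [
                abs(compute_psi(t.counts[ev.uj], t.counts[ev.dj], t.counts[ev.sj]) - 0.6)
                for t in tables
                for ev in events
            ]
            maes.append(np.nanmean(errs))
        assert maes[0] > maes[1] > maes[2]


class TestPlanting:
    def test_rate_extremes_plant_exactly_the_foreground(self):
        design = _design(
            n_events=40,
            n_altered=10,
            altered_direction="inclusion",
            motif_plant=MotifPlant(fg_rate=1.0, bg_rate=0.0),
        )
        cohort = generate_cohort(design)
        altered = {eid for eid, t in cohort.truth.items() if t.altered}
        assert set(cohort.planted["event_id"]) == altered
        assert cohort.planted["foreground"].all()

    def test_zero_rates_plant_nothing(self):
        design = _design(motif_plant=MotifPlant(fg_rate=0.0, bg_rate=0.0))
        cohort = generate_cohort(design)
        assert cohort.planted.empty
        assert not any(t.motif_planted for t in cohort.truth.values())

    def test_minus_strand_plant_reads_forward_in_transcription_orientation(self):
        design = _design(
            n_events=20,
            n_altered=8,
            minus_strand_fraction=1.0,
            altered_direction="inclusion",
            motif_plant=MotifPlant(fg_rate=1.0, bg_rate=0.0),
        )
        cohort = generate_cohort(design)
        by_id = {ev.event_id: ev for ev in cohort.events}
        assert len(cohort.planted) == 8
        for _, row in cohort.planted.iterrows():
            ev = by_id[row["event_id"]]
            assert ev.strand == "-"
            genomic = cohort.genome.fetch(ev.chrom, row["start"], row["end"], "+")
            assert genomic == reverse_complement("TGCATG")
            regs = extract_regions(ev, cohort.genome, flank=design.flank_len)
            assert "TGCATG" in regs["downstream_intron"].sequence

    def test_conservation_elevated_on_planted_bases(self):
        design = _design(
            n_events=30, n_altered=10, altered_direction="inclusion",
            motif_plant=MotifPlant(fg_rate=1.0, bg_rate=0.0),
        )
        cohort = generate_cohort(design)
        for _, row in cohort.planted.iterrows():
            pos = np.arange(row["start"], row["end"] + 1)
            scores = cohort.conservation.scores(row["chrom"], pos)
            assert np.all(scores >= 0.85)
        ev = next(e for e in cohort.events if not cohort.truth[e.event_id].altered)
        flank = cohort.conservation.scores(ev.chrom, np.arange(ev.exon_start, ev.exon_end + 1))
        assert np.all(flank <= 0.45)


class TestDeterminismAndIO:
    def _digest(self, root):
        h = hashlib.sha256()
        for dirpath, _, files in sorted(os.walk(root)):
            for name in sorted(files):
                with open(os.path.join(dirpath, name), "rb") as fh:
                    h.update(name.encode())
                    h.update(fh.read())
        return h.hexdigest()

    def test_same_seed_same_cohort(self):
        a = generate_cohort(_design())
        b = generate_cohort(_design())
        assert [e.event_id for e in a.events] == [e.event_id for e in b.events]
        assert a.genome.fetch("chrS", 1, a.genome.length("chrS")) == b.genome.fetch(
            "chrS", 1, b.genome.length("chrS")
        )
        for ta, tb in zip(a.tables, b.tables):
            assert ta.sample_id == tb.sample_id and ta.counts == tb.counts
        pd.testing.assert_frame_equal(
            truth_to_frame(a.truth, a.design.cancer_types),
            truth_to_frame(b.truth, b.design.cancer_types),
        )

    def test_different_seed_differs(self):
        a = generate_cohort(_design(seed=1))
        b = generate_cohort(_design(seed=2))
        assert a.tables[0].counts != b.tables[0].counts

    def test_write_cohort_layout_and_byte_determinism(self, tmp_path):
        design = _design(pairs_per_type=5, n_events=20)
        cohort = write_cohort(design, tmp_path / "a")
        write_cohort(design, tmp_path / "b")
        sj_files = sorted(os.listdir(tmp_path / "a" / "sj"))
        assert len(sj_files) == 20  # 2 types x 5 pairs x 2 conditions
        assert len(cohort.manifest.matched_pairs("AAA")) == 5
        for name in ("manifest.tsv", "genome.fa", "conservation.bedGraph",
                     "truth_events.tsv", "planted_motifs.tsv", "cohort.json"):
            assert (tmp_path / "a" / name).is_file()
        assert self._digest(tmp_path / "a") == self._digest(tmp_path / "b")

    def test_empty_design_still_writes(self, tmp_path):
        cohort = write_cohort(_design(n_events=0, n_altered=0), tmp_path / "empty")
        assert cohort.events == []
        assert (tmp_path / "empty" / "manifest.tsv").is_file()


class TestMirror:
    def test_mirror_preserves_biology(self):
        cohort = generate_cohort(_design(n_events=25, n_altered=8))
        mirrored, id_map = mirror_cohort(cohort)
        assert len(id_map) == len(cohort.events) == len(mirrored.events)
        assert len(set(id_map.values())) == len(id_map)
        by_id = {ev.event_id: ev for ev in mirrored.events}
        for ev in cohort.events:
            mv = by_id[id_map[ev.event_id]]
            assert mv.strand == {"+": "-", "-": "+"}[ev.strand]
            assert mv.exon_length == ev.exon_length
            # transcription-oriented exon sequence is invariant
            assert cohort.genome.fetch(
                ev.chrom, ev.exon_start, ev.exon_end, ev.strand
            ) == mirrored.genome.fetch(mv.chrom, mv.exon_start, mv.exon_end, mv.strand)
        # per-sample PSI values carry over through the id map
        orig = build_psi_matrix(cohort.events, cohort.tables)
        mirr = build_psi_matrix(mirrored.events, mirrored.tables)
        relabeled = orig.psi.rename(index=id_map).sort_index()
        pd.testing.assert_frame_equal(relabeled, mirr.psi.sort_index())

    def test_mirror_is_an_involution_on_ids(self):
        cohort = generate_cohort(_design(n_events=10))
        mirrored, fwd = mirror_cohort(cohort)
        _, back = mirror_cohort(mirrored)
        for old, new in fwd.items():
            assert back[new] == old
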
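"""Recurrence/coherence, markers, frame preservation, overlap statistics."""

import numpy as np
import pandas as pd
import pytest

from cassex.psi import DifferentialCall, PsiMatrix
from cassex.recurrence import (
    classify_recurrence,
    delta_psi_correlation,
    detect_markers,
    frame_preserved,
    hypergeom_overlap,
    interval_overlap,
    proportion_test,
    psi_expression_correlation,
)
from conftest import make_manifest
from helpers import chi2_2x2, hypergeom_by_enumeration, hypergeom_upper_tail


def _call(event, ct, delta, significant=True):
    return DifferentialCall(
        event_id=event,
        cancer_type=ct,
        n_pairs_used=20,
        mean_delta_psi=delta,
        p_value=0.001,
        q_value=0.01 if significant else 0.5,
        direction="inclusion" if delta > 0 else "exclusion",
        significant=significant,
    )


class TestClassifyRecurrence:
    def test_same_sign_two_types_is_coherent(self):
        (rec,) = classify_recurrence([_call("e", "BRCA", 0.20), _call("e", "LUAD", 0.15)])
        assert rec.coherence == "coherent" and rec.n_types == 2

    def test_opposite_signs_non_coherent(self):
        (rec,) = classify_recurrence([_call("e", "BRCA", 0.20), _call("e", "KIRC", -0.15)])
        assert rec.coherence == "non_coherent"
        assert rec.discordant_types == ["KIRC"]

    def test_single_type(self):
        (rec,) = classify_recurrence([_call("e", "COAD", -0.12)])
        assert rec.coherence == "single" and rec.n_types == 1

    def test_non_significant_calls_ignored(self):
        recs = classify_recurrence([_call("e", "BRCA", 0.2, significant=False)])
        assert recs == []

    def test_agrees_with_naive_recomputation(self, small_cohort):
        from cassex.psi import build_psi_matrix, call_differential

        matrix = build_psi_matrix(small_cohort.events, small_cohort.tables)
        calls = []
        for ct in small_cohort.design.cancer_types:
            calls += call_differential(matrix, small_cohort.manifest, ct, min_pairs=5)
        recs = {r.event_id: r for r in classify_recurrence(calls)}
        sig = [c for c in calls if c.significant]
        by_event = {}
        for c in sig:
            by_event.setdefault(c.event_id, []).append(c.mean_delta_psi)
        assert set(recs) == set(by_event)
        for eid, deltas in by_event.items():
            if len(deltas) == 1:
                assert recs[eid].coherence == "single"
            elif all(d > 0 for d in deltas) or all(d < 0 for d in deltas):
                assert recs[eid].coherence == "coherent"
            else:
                assert recs[eid].coherence == "non_coherent"


def _marker_matrix(deltas, cov=50):
    """One event; per-pair tumor = 0.5 + delta, normal = 0.5."""
    psi, covd = {}, {}
    for p, d in enumerate(deltas):
        psi[f"t{p}"] = [0.5 + d]
        psi[f"n{p}"] = [0.5]
        covd[f"t{p}"] = [cov]
        covd[f"n{p}"] = [cov]
    covf = pd.DataFrame(covd, index=pd.Index(["e0"], name="event_id"))
    return PsiMatrix(psi=pd.DataFrame(psi, index=covf.index), cov=covf)


def _paired_manifest(n_pairs, ct="CT"):
    rows = []
    for p in range(n_pairs):
        rows.append((f"t{p}", f"P{p}", "tumor", ct))
        rows.append((f"n{p}", f"P{p}", "normal", ct))
    return make_manifest(rows)


class TestDetectMarkers:
    def test_nine_of_ten_down_is_marker(self):
        deltas = [-0.15] * 9 + [0.02]
        m = _marker_matrix(deltas)
        (call,) = detect_markers(m, _paired_manifest(10), "CT", ["e0"])
        assert call.fraction_changed == pytest.approx(0.9)
        assert call.marker

    def test_eight_of_ten_is_not(self):
        deltas = [-0.15] * 8 + [0.02, 0.02]
        (call,) = detect_markers(_marker_matrix(deltas), _paired_manifest(10), "CT", ["e0"])
        assert call.fraction_changed == pytest.approx(0.8)
        assert not call.marker

    def test_split_directions_not_consistent(self):
        deltas = [0.15] * 5 + [-0.15] * 5
        (call,) = detect_markers(_marker_matrix(deltas), _paired_manifest(10), "CT", ["e0"])
        assert call.fraction_changed == pytest.approx(0.5)
        assert not call.marker

    def test_label_swap_flips_mean_and_preserves_fraction(self):
        deltas = [-0.2] * 9 + [0.05]
        m = _marker_matrix(deltas)
        manifest = _paired_manifest(10)
        (fwd,) = detect_markers(m, manifest, "CT", ["e0"])
        swapped = manifest.entries.copy()
        swapped["condition"] = swapped["condition"].map({"tumor": "normal", "normal": "tumor"})
        (rev,) = detect_markers(m, make_manifest(list(swapped.itertuples(index=False))), "CT", ["e0"])
        assert rev.mean_delta_psi == pytest.approx(-fwd.mean_delta_psi)
        assert rev.fraction_changed == pytest.approx(fwd.fraction_changed)


@pytest.mark.parametrize(
    "lengths, expected", [(84, True), (85, False), ((70, 50), True), ((70, 49), False)]
)
def test_frame_preserved(lengths, expected):
    assert frame_preserved(lengths) is expected


class TestProportionTest:
    def test_identical_proportions_give_p_one(self):
        stat, p = proportion_test(50, 100, 50, 100)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_extreme_difference(self):
        stat, p = proportion_test(90, 100, 10, 100)
        assert stat == pytest.approx(chi2_2x2(90, 100, 10, 100))
        assert stat == pytest.approx(128.0)
        assert p < 1e-20

    def test_closed_form_small_table(self):
        stat, _ = proportion_test(0, 10, 10, 10)
        assert stat == pytest.approx(20.0)
        assert stat == pytest.approx(chi2_2x2(0, 10, 10, 10))

    def test_zero_margin_advises_exact_test(self):
        with pytest.raises(ValueError, match="exact"):
            proportion_test(0, 10, 0, 10)


class TestHypergeomOverlap:
    def test_full_overlap_is_certain(self):
        u = set(range(10))
        assert hypergeom_overlap(u, u, u) == pytest.approx(1.0)

    def test_matches_tail_summation(self):
        u = set(range(100))
        a = set(range(10))
        b = set(range(5, 15))  # overlap 5
        expected = hypergeom_upper_tail(5, 100, 10, 10)
        assert hypergeom_overlap(a, b, u) == pytest.approx(expected, rel=1e-10)

    def test_zero_overlap_is_a_probability(self):
        u = set(range(30))
        p = hypergeom_overlap(set(range(10)), set(range(10, 20)), u)
        assert 0 < p <= 1

    def test_matches_enumeration_small_universes(self, rng):
        for _ in range(20):
            n_u = int(rng.integers(4, 13))
            u = set(range(n_u))
            a = set(rng.choice(n_u, size=int(rng.integers(1, n_u)), replace=False).tolist())
            b = set(rng.choice(n_u, size=int(rng.integers(1, n_u)), replace=False).tolist())
            assert hypergeom_overlap(a, b, u) == pytest.approx(
                hypergeom_by_enumeration(a, b, u), rel=1e-9
            )

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_overlap({1, 99}, {1}, {1, 2})


class TestIntervalOverlap:
    def _events(self, *ivs):
        return pd.DataFrame(
            [{"chrom": "chr1", "start": s, "end": e, "name": f"e{i}"} for i, (s, e) in enumerate(ivs)]
        )

    def _anno(self, *ivs):
        return pd.DataFrame([{"chrom": "chr1", "start": s, "end": e} for s, e in ivs])

    def test_one_base_overlap_counts(self):
        assert interval_overlap(self._events((200, 299)), self._anno((250, 350))) == {"e0"}

    def test_adjacent_intervals_do_not_overlap(self):
        assert interval_overlap(self._events((200, 299)), self._anno((300, 400))) == set()

    def test_empty_annotation(self):
        assert interval_overlap(self._events((200, 299)), self._anno()) == set()

    def test_min_frac_threshold(self):
        events = self._events((1, 100))
        anno = self._anno((91, 100))  # 10% of the exon
        assert interval_overlap(events, anno, min_frac=0.05) == {"e0"}
        assert interval_overlap(events, anno, min_frac=0.5) == set()


class TestCorrelations:
    def test_exact_linear_relation(self):
        psi = np.linspace(0.1, 0.9, 10)
        r, weak = psi_expression_correlation(psi, 2 * psi + 1)
        assert r == pytest.approx(1.0)
        assert not weak

    def test_anticorrelation(self):
        psi = np.linspace(0.1, 0.9, 10)
        r, _ = psi_expression_correlation(psi, -psi)
        assert r == pytest.approx(-1.0)

    def test_constant_expression_is_undefined(self):
        with pytest.warns(UserWarning):
            r, weak = psi_expression_correlation([0.1, 0.5, 0.9], [2.0, 2.0, 2.0])
        assert np.isnan(r) and not weak

    def test_delta_identity_and_negation(self):
        a = {f"e{i}": v for i, v in enumerate([0.1, -0.2, 0.3, 0.05])}
        r, p, n = delta_psi_correlation(a, dict(a))
        assert r == pytest.approx(1.0) and n == 4
        r2, _, _ = delta_psi_correlation(a, {k: -v for k, v in a.items()})
        assert r2 == pytest.approx(-1.0)

    def test_independent_profiles_uncorrelated(self, rng):
        a = {f"e{i}": x for i, x in enumerate(rng.normal(size=1000))}
        b = {f"e{i}": x for i, x in enumerate(rng.normal(size=1000))}
        r, _, n = delta_psi_correlation(a, b)
        assert n == 1000 and abs(r) < 0.1

    def test_too_few_shared_events(self):
        r, p, n = delta_psi_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
        assert np.isnan(r) and n == 2
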
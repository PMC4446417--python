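"""Cross-cancer recurrence, splicing markers, and companion statistics.

An event significantly altered in two or more cancer-type cohorts is
*coherent* when the signed mean ΔPSI agrees in direction across all of
them, *non-coherent* otherwise; events altered in exactly one cohort are
labelled *single*.  A *splicing marker* is an event whose per-pair ΔPSI
reaches the threshold magnitude in one direction in at least 90% of the
examined matched pairs of a single cancer type.

The module also provides frame-preservation checks, 2×2 chi-square and
hypergeometric overlap tests, strand-agnostic interval overlap, and the
Pearson correlations used to relate PSI to expression or to external
knockdown ΔPSI profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .psi import DifferentialCall, PsiMatrix, _covered_pairs
from .io import SampleManifest

__all__ = [
    "RecurrenceRecord",
    "MarkerCall",
    "classify_recurrence",
    "detect_markers",
    "frame_preserved",
    "proportion_test",
    "hypergeom_overlap",
    "interval_overlap",
    "psi_expression_correlation",
    "delta_psi_correlation",
    "group_mean_delta",
]


@dataclass
class RecurrenceRecord:
    event_id: str
    delta_by_type: Dict[str, float]  # signed mean ΔPSI where significant
    coherence: str  # "coherent", "non_coherent" or "single"

    @property
    def n_types(self) -> int:
        return len(self.delta_by_type)

    @property
    def discordant_types(self) -> List[str]:
        """Cancer types whose sign differs from the majority direction."""
        if self.coherence != "non_coherent":
            return []
        signs = {t: np.sign(d) for t, d in self.delta_by_type.items()}
        n_pos = sum(1 for s in signs.values() if s > 0)
        n_neg = len(signs) - n_pos
        minority = 1 if n_pos < n_neg else -1
        return sorted(t for t, s in signs.items() if s == minority)


def classify_recurrence(calls: Iterable[DifferentialCall]) -> List[RecurrenceRecord]:
    """One record per event significant in at least one cancer type."""
    by_event: Dict[str, Dict[str, float]] = {}
    for c in calls:
        if c.significant:
            by_event.setdefault(c.event_id, {})[c.cancer_type] = c.mean_delta_psi
    records = []
    for eid in sorted(by_event):
        deltas = by_event[eid]
        if len(deltas) == 1:
            coherence = "single"
        else:
            signs = {np.sign(d) for d in deltas.values()}
            coherence = "coherent" if len(signs) == 1 else "non_coherent"
        records.append(RecurrenceRecord(event_id=eid, delta_by_type=deltas, coherence=coherence))
    return records


def recurrence_to_frame(records: Sequence[RecurrenceRecord], cancer_types: Sequence[str]) -> pd.DataFrame:
    """Event × cancer-type signed ΔPSI table with coherence labels."""
    rows = []
    for r in records:
        row = {"event_id": r.event_id, "n_types": r.n_types, "coherence": r.coherence}
        for ct in cancer_types:
            row[ct] = r.delta_by_type.get(ct, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=["event_id", "n_types", "coherence", *cancer_types])


@dataclass
class MarkerCall:
    event_id: str
    cancer_type: str
    n_pairs_examined: int
    fraction_changed: float  # fraction of pairs at |ΔPSI| >= delta in the majority direction
    mean_delta_psi: float
    marker: bool


def detect_markers(
    matrix: PsiMatrix,
    manifest: SampleManifest,
    cancer_type: str,
    event_ids: Sequence[str],
    delta: float = 0.10,
    frac: float = 0.90,
    min_cov: float = 10,
) -> List[MarkerCall]:
    """Events changed by >= delta in a single direction in >= frac of pairs.

    ``event_ids`` should be the events passing the high-expression filter
    for this cancer type; pairs are usable when both members reach
    ``min_cov`` coverage.
    """
    pairs, mask = _covered_pairs(matrix, manifest, cancer_type, min_cov)
    row_of = {eid: i for i, eid in enumerate(matrix.event_ids)}
    if pairs:
        tpsi = matrix.psi[[t for _, t, _ in pairs]].to_numpy()
        npsi = matrix.psi[[n for _, _, n in pairs]].to_numpy()
    calls = []
    for eid in event_ids:
        i = row_of[eid]
        use = mask[i] if pairs else np.zeros(0, dtype=bool)
        n_used = int(use.sum())
        if n_used == 0:
            calls.append(MarkerCall(eid, cancer_type, 0, float("nan"), float("nan"), False))
            continue
        d = tpsi[i, use] - npsi[i, use]
        n_up = int(np.sum(d >= delta))
        n_down = int(np.sum(d <= -delta))
        fraction = max(n_up, n_down) / n_used
        calls.append(
            MarkerCall(
                event_id=eid,
                cancer_type=cancer_type,
                n_pairs_examined=n_used,
                fraction_changed=fraction,
                mean_delta_psi=float(np.mean(d)),
                marker=fraction >= frac,
            )
        )
    return calls


def markers_to_frame(calls: Sequence[MarkerCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": c.event_id,
                "cancer_type": c.cancer_type,
                "n_pairs": c.n_pairs_examined,
                "mean_delta_psi": c.mean_delta_psi,
                "fraction_changed": c.fraction_changed,
                "marker": c.marker,
            }
            for c in calls
        ],
        columns=["event_id", "cancer_type", "n_pairs", "mean_delta_psi", "fraction_changed", "marker"],
    )


def frame_preserved(exon_lengths: int | Sequence[int]) -> bool:
    """True when the total exonic length is a multiple of 3.

    Multi-exon events (consecutive exons regulated as a unit) pass a
    sequence of lengths, which are summed before the divisibility check.
    """
    if isinstance(exon_lengths, (int, np.integer)):
        total = int(exon_lengths)
    else:
        total = int(sum(exon_lengths))
    if total < 0:
        raise ValueError("exon length must be non-negative")
    return total % 3 == 0


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> Tuple[float, float]:
    """2×2 chi-square test (no continuity correction) on two proportions.

    Returns (statistic, p-value) for the table [[k1, n1-k1], [k2, n2-k2]].
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 == 0 or n2 == 0:
        raise ValueError("need 0 <= k <= n with n > 0 for both groups")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("a margin is zero; use an exact test instead")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def hypergeom_overlap(set_a: Set, set_b: Set, universe: Set) -> float:
    """Upper-tail hypergeometric p-value for the overlap of two sets.

    P[X >= |A∩B|] with X ~ Hypergeometric(|U|, |B|, |A|): the chance that
    |A| draws without replacement from a universe containing |B| marked
    elements capture at least the observed overlap.
    """
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("both sets must be subsets of the universe")
    overlap = len(set_a & set_b)
    return float(stats.hypergeom.sf(overlap - 1, len(universe), len(set_b), len(set_a)))


def interval_overlap(
    events: pd.DataFrame,
    annotation: pd.DataFrame,
    min_frac: float = 0.0,
) -> Set[str]:
    """Event names whose interval overlaps any annotation interval.

    Both frames use 1-based inclusive ``chrom``/``start``/``end`` columns
    plus ``name`` on the events side (the layout ``cassex.io.read_bed``
    produces).  An event qualifies with >= 1 base of overlap, and with at
    least ``min_frac`` of its own length overlapped when set.
    """
    trees: Dict[str, IntervalTree] = {}
    for _, row in annotation.iterrows():
        # IntervalTree is half-open; [start, end] inclusive -> [start, end+1)
        trees.setdefault(row["chrom"], IntervalTree()).addi(row["start"], row["end"] + 1)
    hits: Set[str] = set()
    for _, row in events.iterrows():
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        start, end = row["start"], row["end"]
        overlaps = tree.overlap(start, end + 1)
        if not overlaps:
            continue
        if min_frac > 0:
            length = end - start + 1
            best = max(min(iv.end - 1, end) - max(iv.begin, start) + 1 for iv in overlaps)
            if best < min_frac * length:
                continue
        hits.add(row["name"])
    return hits


def psi_expression_correlation(
    psi_row: Sequence[float], expr_row: Sequence[float], weak_threshold: float = 0.3
) -> Tuple[float, bool]:
    """Pearson r between an event's PSI and its gene's expression.

    Complete-case over samples; returns (r, weak) where weak means
    |r| < weak_threshold.  r is NaN (with a warning) when fewer than 3
    complete cases remain or either vector is constant.
    """
    x = np.asarray(psi_row, dtype=float)
    y = np.asarray(expr_row, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("correlation undefined: <3 complete cases or zero variance", stacklevel=2)
        return float("nan"), False
    r = float(stats.pearsonr(x, y).statistic)
    return r, abs(r) < weak_threshold


def delta_psi_correlation(
    delta_a: Mapping[str, float], delta_b: Mapping[str, float]
) -> Tuple[float, float, int]:
    """Pearson (r, p, n) over events shared by two ΔPSI profiles.

    Used both for comparing cohort ΔPSI against splicing-factor knockdown
    ΔPSI tables and for PSI-profile QC between samples.  Returns NaN r/p
    with fewer than 3 shared events.
    """
    shared = sorted(set(delta_a) & set(delta_b))
    shared = [k for k in shared if not (np.isnan(delta_a[k]) or np.isnan(delta_b[k]))]
    n = len(shared)
    if n < 3:
        return float("nan"), float("nan"), n
    a = np.array([delta_a[k] for k in shared])
    b = np.array([delta_b[k] for k in shared])
    if np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan"), float("nan"), n
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue), n


def group_mean_delta(
    matrix: PsiMatrix,
    manifest: SampleManifest,
    cancer_type: str,
    event_ids: Sequence[str],
    min_cov: float = 10,
    paired: bool = True,
) -> Dict[str, float]:
    """Mean ΔPSI per event for cross-dataset comparisons.

    ``paired=True`` averages per-pair tumor−normal differences (the
    differential caller's estimate); ``paired=False`` takes the difference
    of unpaired group means over all covered tumor vs all covered normal
    samples, for comparisons against external unpaired experiments.
    """
    out: Dict[str, float] = {}
    row_of = {eid: i for i, eid in enumerate(matrix.event_ids)}
    if paired:
        pairs, mask = _covered_pairs(matrix, manifest, cancer_type, min_cov)
        if not pairs:
            return {eid: float("nan") for eid in event_ids}
        tpsi = matrix.psi[[t for _, t, _ in pairs]].to_numpy()
        npsi = matrix.psi[[n for _, _, n in pairs]].to_numpy()
        for eid in event_ids:
            i = row_of[eid]
            use = mask[i]
            out[eid] = float(np.mean(tpsi[i, use] - npsi[i, use])) if use.any() else float("nan")
        return out
    df = manifest.entries[manifest.entries["cancer_type"] == cancer_type]
    tumor_samples = [s for s in df.loc[df["condition"] == "tumor", "sample_id"] if s in matrix.psi.columns]
    normal_samples = [s for s in df.loc[df["condition"] == "normal", "sample_id"] if s in matrix.psi.columns]
    tpsi = matrix.psi[tumor_samples].to_numpy()
    tcov = matrix.cov[tumor_samples].to_numpy()
    npsi = matrix.psi[normal_samples].to_numpy()
    ncov = matrix.cov[normal_samples].to_numpy()
    for eid in event_ids:
        i = row_of[eid]
        tok = tcov[i] >= min_cov
        nok = ncov[i] >= min_cov
        if not tok.any() or not nok.any():
            out[eid] = float("nan")
        else:
            out[eid] = float(np.mean(tpsi[i, tok]) - np.mean(npsi[i, nok]))
    return out
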
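"""Percent-spliced-in (PSI) quantification and paired differential calling.

PSI for a cassette event is estimated from its three junction read counts:

    PSI = 0.5 (UJC + DJC) / (0.5 (UJC + DJC) + SJC)

where UJC/DJC support inclusion and SJC supports skipping; the inclusion
counts are halved because an included exon contributes two junction-spanning
read classes while a skipped one contributes a single class.  The same
half-sum plus SJC serves as the event's coverage, and events are only tested
in cohorts where coverage reaches ``min_cov`` in both members of at least
``min_pairs`` matched tumor/normal pairs.

Differential inclusion between matched tumor and normal samples is assessed
with the two-sided Wilcoxon signed-rank test over per-pair PSI differences;
q-values are Benjamini–Hochberg adjusted per cancer type, and an event is
called significant when q ≤ fdr and |mean ΔPSI| ≥ min_delta.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .discovery import SkippingEvent
from .io import JunctionCountTable, SampleManifest

__all__ = [
    "PsiMatrix",
    "DifferentialCall",
    "compute_psi",
    "coverage",
    "build_psi_matrix",
    "high_expression_filter",
    "paired_wilcoxon",
    "bh_fdr",
    "call_differential",
]


def compute_psi(ujc: float, djc: float, sjc: float) -> float:
    """Inclusion level from the three junction counts; NaN when uncovered."""
    if ujc < 0 or djc < 0 or sjc < 0:
        raise ValueError("junction counts must be non-negative")
    inclusion = 0.5 * (ujc + djc)
    denom = inclusion + sjc
    if denom == 0:
        return float("nan")
    return inclusion / denom


def coverage(ujc: float, djc: float, sjc: float) -> float:
    """Event coverage 0.5(UJC + DJC) + SJC."""
    if ujc < 0 or djc < 0 or sjc < 0:
        raise ValueError("junction counts must be non-negative")
    return 0.5 * (ujc + djc) + sjc


@dataclass
class PsiMatrix:
    """Events × samples inclusion levels with a companion coverage table.

    ``psi`` holds NaN where the event has zero coverage in a sample;
    ``cov`` always holds the (possibly zero) coverage value.
    """

    psi: pd.DataFrame  # index event_id, columns sample_id, values in [0,1] or NaN
    cov: pd.DataFrame  # same shape, 0.5(UJC+DJC)+SJC

    def __post_init__(self) -> None:
        if not self.psi.index.equals(self.cov.index) or not self.psi.columns.equals(
            self.cov.columns
        ):
            raise ValueError("psi and coverage tables must share index and columns")
        vals = self.psi.to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bad = np.nansum((vals < 0) | (vals > 1))
        if bad:
            raise ValueError("PSI values outside [0, 1]")
        if np.any(~np.isnan(vals) & (self.cov.to_numpy() <= 0)):
            raise ValueError("present PSI with non-positive coverage")

    @property
    def event_ids(self) -> List[str]:
        return list(self.psi.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.psi.columns)

    def to_tsv(self, psi_path, cov_path=None) -> None:
        self.psi.to_csv(psi_path, sep="\t", na_rep="NA", index_label="event_id")
        if cov_path is not None:
            self.cov.to_csv(cov_path, sep="\t", na_rep="NA", index_label="event_id")

    @classmethod
    def from_tsv(cls, psi_path, cov_path) -> "PsiMatrix":
        psi = pd.read_csv(psi_path, sep="\t", index_col="event_id", na_values=["NA"])
        cov = pd.read_csv(cov_path, sep="\t", index_col="event_id", na_values=["NA"])
        return cls(psi=psi, cov=cov)


def build_psi_matrix(
    events: Sequence[SkippingEvent], tables: Sequence[JunctionCountTable]
) -> PsiMatrix:
    """PSI and coverage for every event in every sample (absent junctions = 0)."""
    sample_ids = [t.sample_id for t in tables]
    n_ev, n_s = len(events), len(tables)
    psi = np.full((n_ev, n_s), np.nan)
    cov = np.zeros((n_ev, n_s))
    for i, ev in enumerate(events):
        for j, table in enumerate(tables):
            ujc = table.get(ev.uj)
            djc = table.get(ev.dj)
            sjc = table.get(ev.sj)
            cov[i, j] = coverage(ujc, djc, sjc)
            psi[i, j] = compute_psi(ujc, djc, sjc)
    index = pd.Index([e.event_id for e in events], name="event_id")
    return PsiMatrix(
        psi=pd.DataFrame(psi, index=index, columns=sample_ids),
        cov=pd.DataFrame(cov, index=index, columns=sample_ids),
    )


def _covered_pairs(
    matrix: PsiMatrix,
    manifest: SampleManifest,
    cancer_type: str,
    min_cov: float,
) -> Tuple[List[Tuple[str, str, str]], np.ndarray]:
    """Pairs of the cancer type and a (events × pairs) mask of joint coverage."""
    pairs = [
        (p, t, n)
        for p, t, n in manifest.matched_pairs(cancer_type)
        if t in matrix.cov.columns and n in matrix.cov.columns
    ]
    if not pairs:
        return [], np.zeros((len(matrix.event_ids), 0), dtype=bool)
    tcov = matrix.cov[[t for _, t, _ in pairs]].to_numpy()
    ncov = matrix.cov[[n for _, _, n in pairs]].to_numpy()
    return pairs, (tcov >= min_cov) & (ncov >= min_cov)


def high_expression_filter(
    matrix: PsiMatrix,
    manifest: SampleManifest,
    cancer_type: str,
    min_cov: float = 10,
    min_pairs: int = 15,
) -> List[str]:
    """Events covered (>= min_cov in both pair members) in >= min_pairs pairs."""
    if min_pairs < 1:
        raise ValueError(f"min_pairs must be >= 1, got {min_pairs}")
    _, mask = _covered_pairs(matrix, manifest, cancer_type, min_cov)
    keep = mask.sum(axis=1) >= min_pairs
    return [eid for eid, k in zip(matrix.event_ids, keep) if k]


def paired_wilcoxon(tumor_psi: Sequence[float], normal_psi: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired PSI values.

    Zero differences are dropped before ranking.  The exact null distribution
    is used when <= 25 nonzero differences remain and their magnitudes are
    tie-free; otherwise a normal approximation with tie and continuity
    correction.  Returns NaN with < 2 usable pairs and 1.0 when every pair is
    identical.
    """
    x = np.asarray(tumor_psi, dtype=float)
    y = np.asarray(normal_psi, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values must be removed before testing")
    if x.size < 2:
        return float("nan")
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        return 1.0
    if nz.size == 1:
        # a single nonzero difference: both sign assignments are extreme
        return 1.0
    abs_nz = np.abs(nz)
    exact = nz.size <= 25 and np.unique(abs_nz).size == abs_nz.size
    method = "exact" if exact else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(
            nz, zero_method="wilcox", alternative="two-sided", correction=not exact, method=method
        )
    return float(res.pvalue)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaN entries pass through."""
    p = np.asarray(p_values, dtype=float)
    present = ~np.isnan(p)
    if np.any((p[present] < 0) | (p[present] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if present.sum():
        q[present] = multipletests(p[present], method="fdr_bh")[1]
    return q


@dataclass
class DifferentialCall:
    """Per-event, per-cancer-type paired differential splicing result."""

    event_id: str
    cancer_type: str
    n_pairs_used: int
    mean_delta_psi: float
    p_value: float
    q_value: float
    direction: str  # "inclusion" (tumor gains the exon) or "exclusion"
    significant: bool


def call_differential(
    matrix: PsiMatrix,
    manifest: SampleManifest,
    cancer_type: str,
    fdr: float = 0.05,
    min_delta: float = 0.10,
    min_cov: float = 10,
    min_pairs: int = 15,
    event_ids: Optional[Sequence[str]] = None,
) -> List[DifferentialCall]:
    """Paired tumor−normal differential calls for one cancer-type cohort.

    Events are restricted to those passing the high-expression filter
    (or the explicit ``event_ids``).  For each event the usable pairs are
    those with coverage >= min_cov in both members; mean ΔPSI is the mean of
    per-pair (tumor − normal) differences over exactly those pairs, the
    p-value comes from the paired signed-rank test, and q-values are
    BH-adjusted across all tested events of this cancer type.
    """
    if event_ids is None:
        event_ids = high_expression_filter(
            matrix, manifest, cancer_type, min_cov=min_cov, min_pairs=min_pairs
        )
    event_ids = list(event_ids)
    pairs, mask = _covered_pairs(matrix, manifest, cancer_type, min_cov)
    if not event_ids or not pairs:
        if not event_ids:
            warnings.warn(f"{cancer_type}: no testable events", stacklevel=2)
        return []
    row_of = {eid: i for i, eid in enumerate(matrix.event_ids)}
    tpsi = matrix.psi[[t for _, t, _ in pairs]].to_numpy()
    npsi = matrix.psi[[n for _, _, n in pairs]].to_numpy()

    records: List[Tuple[str, int, float, float]] = []
    for eid in event_ids:
        i = row_of[eid]
        use = mask[i]
        n_used = int(use.sum())
        if n_used == 0:
            records.append((eid, 0, float("nan"), float("nan")))
            continue
        t = tpsi[i, use]
        n = npsi[i, use]
        mean_delta = float(np.mean(t - n))
        p = paired_wilcoxon(t, n)
        records.append((eid, n_used, mean_delta, p))

    q = bh_fdr([r[3] for r in records])
    calls = []
    for (eid, n_used, mean_delta, p), qv in zip(records, q):
        significant = bool(
            not math.isnan(qv)
            and not math.isnan(mean_delta)
            and qv <= fdr
            and abs(mean_delta) >= min_delta
        )
        calls.append(
            DifferentialCall(
                event_id=eid,
                cancer_type=cancer_type,
                n_pairs_used=n_used,
                mean_delta_psi=mean_delta,
                p_value=p,
                q_value=float(qv),
                direction="inclusion" if mean_delta > 0 else "exclusion",
                significant=significant,
            )
        )
    return calls


def calls_to_frame(calls: Sequence[DifferentialCall]) -> pd.DataFrame:
    """Tabular export of differential calls."""
    return pd.DataFrame(
        [
            {
                "event_id": c.event_id,
                "cancer_type": c.cancer_type,
                "n_pairs": c.n_pairs_used,
                "mean_delta_psi": c.mean_delta_psi,
                "p": c.p_value,
                "q": c.q_value,
                "direction": c.direction,
                "significant": c.significant,
            }
            for c in calls
        ],
        columns=[
            "event_id",
            "cancer_type",
            "n_pairs",
            "mean_delta_psi",
            "p",
            "q",
            "direction",
            "significant",
        ],
    )
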
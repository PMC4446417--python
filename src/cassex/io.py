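"""Readers, writers and the cohort data model.

The pipeline starts downstream of alignment: its primary input is the
per-sample splice-junction count table emitted by the STAR aligner
(``SJ.out.tab``), a 9-column tab-separated file with one intron per line.
Coordinates throughout the package are 1-based inclusive on intron bases,
the convention of that dialect; exon arithmetic is derived from it in
:mod:`cassex.discovery`.

Also provided here: the sample manifest (sample → patient, tumor/normal
condition, cancer type), indexed FASTA access with strand-aware fetching,
per-base conservation tracks parsed from bedGraph, and BED interval IO.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, NamedTuple, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Junction",
    "JunctionCountTable",
    "SampleManifest",
    "Genome",
    "ConservationTrack",
    "read_sj_table",
    "write_sj_table",
    "read_manifest",
    "write_manifest",
    "reverse_complement",
    "read_bed",
    "write_bed",
]

_STRAND_FROM_CODE = {"0": "unknown", "1": "+", "2": "-"}
_CODE_FROM_STRAND = {"unknown": "0", "+": "1", "-": "2"}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Junction(NamedTuple):
    """One intron call: 1-based first and last intronic base, plus strand.

    ``start`` and ``end`` are both intronic coordinates, so the flanking
    exonic bases are ``start - 1`` and ``end + 1``.
    """

    chrom: str
    start: int
    end: int
    strand: str  # "+", "-" or "unknown"

    def validate(self) -> "Junction":
        if self.start > self.end:
            raise ValueError(
                f"junction start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.start < 1:
            raise ValueError(f"junction coordinates must be positive: {self}")
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"bad strand {self.strand!r}")
        return self

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class JunctionCountTable:
    """Uniquely-mapping read counts per junction for one sample."""

    sample_id: str
    counts: Dict[Junction, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for j, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count {c} for {j}")

    def get(self, junction: Junction) -> int:
        """Count for ``junction``; absent junctions count as 0."""
        return self.counts.get(junction, 0)

    def __len__(self) -> int:
        return len(self.counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, JunctionCountTable):
            return NotImplemented
        return self.sample_id == other.sample_id and self.counts == other.counts


def read_sj_table(path: str | os.PathLike, sample_id: str | None = None) -> JunctionCountTable:
    """Parse an SJ.out.tab-dialect junction table.

    Columns: chrom, intron start (1-based), intron end (1-based), strand code
    (0=unknown, 1=+, 2=-), intron motif code, annotated flag, unique-mapping
    read count, multi-mapping read count, max overhang.  Only the
    unique-mapping count (column 7) is used as evidence; the multi-mapping
    column is parsed for validity but discarded.
    """
    path = os.fspath(path)
    if sample_id is None:
        sample_id = os.path.basename(path)
        for suffix in (".sj.tab", ".SJ.out.tab", ".tab", ".tsv"):
            if sample_id.endswith(suffix):
                sample_id = sample_id[: -len(suffix)]
                break
    counts: Dict[Junction, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"{path}:{lineno}: expected >=9 tab-separated columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                strand = _STRAND_FROM_CODE[fields[3]]
                unique = int(fields[6])
                int(fields[7])  # multi-mapping count: validated, unused
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from exc
            junction = Junction(chrom, start, end, strand).validate()
            if unique < 0:
                raise ValueError(f"{path}:{lineno}: negative read count")
            if junction in counts:
                raise ValueError(f"{path}:{lineno}: duplicate junction {junction}")
            counts[junction] = unique
    return JunctionCountTable(sample_id=sample_id, counts=counts)


def write_sj_table(table: JunctionCountTable, path: str | os.PathLike) -> None:
    """Write a table back in the 9-column SJ dialect (round-trips exactly).

    Motif and annotation codes are written as 0, multi-mapping counts as 0,
    and the overhang as 0: none of these are evidence the pipeline uses.
    """
    rows = sorted(table.counts.items(), key=lambda kv: (kv[0].chrom, kv[0].start, kv[0].end))
    with open(path, "w") as fh:
        for j, c in rows:
            fh.write(
                f"{j.chrom}\t{j.start}\t{j.end}\t{_CODE_FROM_STRAND[j.strand]}\t0\t0\t{c}\t0\t0\n"
            )


@dataclass
class SampleManifest:
    """Maps samples to patients, tumor/normal condition and cancer type."""

    entries: pd.DataFrame  # columns: sample_id, patient_id, condition, cancer_type

    COLUMNS = ("sample_id", "patient_id", "condition", "cancer_type")

    def __post_init__(self) -> None:
        df = self.entries
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        bad = set(df["condition"]) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"unknown condition token(s): {sorted(bad)}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_id(s): {dups}")
        key = df[["patient_id", "condition", "cancer_type"]]
        if key.duplicated().any():
            raise ValueError("duplicate (patient_id, condition) within a cancer type")

    @property
    def cancer_types(self) -> List[str]:
        return sorted(self.entries["cancer_type"].unique())

    @property
    def sample_ids(self) -> List[str]:
        return list(self.entries["sample_id"])

    def samples_of(self, cancer_type: str) -> List[str]:
        df = self.entries
        return list(df.loc[df["cancer_type"] == cancer_type, "sample_id"])

    def matched_pairs(self, cancer_type: str) -> List[Tuple[str, str, str]]:
        """(patient_id, tumor_sample, normal_sample) triples for one cancer type.

        A patient contributes a pair iff both a tumor and a normal sample
        exist for them within this cancer type.
        """
        df = self.entries[self.entries["cancer_type"] == cancer_type]
        tumor = df[df["condition"] == "tumor"].set_index("patient_id")["sample_id"]
        normal = df[df["condition"] == "normal"].set_index("patient_id")["sample_id"]
        shared = sorted(set(tumor.index) & set(normal.index))
        return [(p, tumor[p], normal[p]) for p in shared]

    def unmatched_samples(self, cancer_type: str) -> List[str]:
        df = self.entries[self.entries["cancer_type"] == cancer_type]
        paired = {p for p, _, _ in self.matched_pairs(cancer_type)}
        return list(df.loc[~df["patient_id"].isin(paired), "sample_id"])


def read_manifest(path: str | os.PathLike) -> SampleManifest:
    """Read a tab-separated manifest with header sample_id/patient_id/condition/cancer_type."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleManifest(entries=df)


def write_manifest(manifest: SampleManifest, path: str | os.PathLike) -> None:
    manifest.entries.to_csv(path, sep="\t", index=False)


class Genome:
    """Strand-aware 1-based-inclusive access to chromosome sequences.

    Holds sequences in memory; build from a dict of uppercase strings or via
    :meth:`from_fasta` (indexed access through pyfaidx).
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "Genome":
        from pyfaidx import Fasta

        with Fasta(os.fspath(path), as_raw=True) as fa:
            return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chroms(self) -> List[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of the 1-based inclusive interval; revcomp on the − strand."""
        if chrom not in self._seqs:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        seq = self._seqs[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds (len {len(seq)})"
            )
        sub = seq[start - 1 : end]
        return reverse_complement(sub) if strand == "-" else sub

    def to_fasta(self, path: str | os.PathLike, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


class ConservationTrack:
    """Per-base conservation scores in [0, 1] with explicit missingness.

    Backed by one NaN-initialised float array per chromosome; position
    lookups are 1-based.
    """

    def __init__(self) -> None:
        self._arrays: Dict[str, np.ndarray] = {}

    @classmethod
    def from_bedgraph(cls, path: str | os.PathLike) -> "ConservationTrack":
        """Parse bedGraph lines (chrom, 0-based start, end, score)."""
        intervals: Dict[str, List[Tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
                chrom, start0, end0, score = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                if not 0.0 <= score <= 1.0:
                    raise ValueError(f"{path}:{lineno}: score {score} outside [0, 1]")
                intervals.setdefault(chrom, []).append((start0, end0, score))
        track = cls()
        for chrom, ivs in intervals.items():
            size = max(e for _, e, _ in ivs)
            arr = np.full(size, np.nan)
            for s0, e0, sc in ivs:
                arr[s0:e0] = sc
            track._arrays[chrom] = arr
        return track

    def set_scores(self, chrom: str, positions: np.ndarray, scores: np.ndarray) -> None:
        """Assign scores at 1-based positions, growing the chromosome array as needed."""
        positions = np.asarray(positions, dtype=int)
        scores = np.asarray(scores, dtype=float)
        if positions.size == 0:
            return
        if np.any((scores < 0) | (scores > 1)):
            raise ValueError("conservation scores must lie in [0, 1]")
        needed = int(positions.max())
        arr = self._arrays.get(chrom)
        if arr is None or arr.size < needed:
            new = np.full(needed, np.nan)
            if arr is not None:
                new[: arr.size] = arr
            arr = new
            self._arrays[chrom] = arr
        arr[positions - 1] = scores

    def score(self, chrom: str, position: int) -> float:
        """Score at a 1-based position; NaN when missing."""
        arr = self._arrays.get(chrom)
        if arr is None or not 1 <= position <= arr.size:
            return float("nan")
        return float(arr[position - 1])

    def scores(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorised lookup at 1-based positions; out-of-track → NaN."""
        positions = np.asarray(positions, dtype=int)
        arr = self._arrays.get(chrom)
        out = np.full(positions.shape, np.nan)
        if arr is None:
            return out
        ok = (positions >= 1) & (positions <= arr.size)
        out[ok] = arr[positions[ok] - 1]
        return out

    def to_bedgraph(self, path: str | os.PathLike) -> None:
        """Write non-missing runs of equal score as bedGraph intervals."""
        with open(path, "w") as fh:
            for chrom in sorted(self._arrays):
                arr = self._arrays[chrom]
                present = ~np.isnan(arr)
                i = 0
                n = arr.size
                while i < n:
                    if not present[i]:
                        i += 1
                        continue
                    j = i + 1
                    while j < n and present[j] and arr[j] == arr[i]:
                        j += 1
                    fh.write(f"{chrom}\t{i}\t{j}\t{arr[i]:.6g}\n")
                    i = j


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read BED (0-based half-open) into 1-based inclusive columns.

    Returns a DataFrame with chrom, start (1-based), end (inclusive), name,
    strand; missing optional columns are filled with defaults.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            start0, end0 = int(f[1]), int(f[2])
            rows.append(
                {
                    "chrom": f[0],
                    "start": start0 + 1,
                    "end": end0,
                    "name": f[3] if len(f) > 3 else ".",
                    "strand": f[5] if len(f) > 5 else ".",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])


def write_bed(intervals: Iterable[Tuple[str, int, int, str, str]], path: str | os.PathLike) -> None:
    """Write (chrom, 1-based start, inclusive end, name, strand) tuples as BED."""
    with open(path, "w") as fh:
        for chrom, start, end, name, strand in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\t0\t{strand}\n")
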
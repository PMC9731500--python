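"""Per-position base-count pileups and C->T signal extraction.

The caller operates in transcript space on stranded libraries:
forward-strand primary alignments contribute one base per covered
reference position; reverse-strand alignments are skipped (and counted)
rather than complemented, and secondary/supplementary records are
ignored. Reference positions deleted in a read are tallied in the N
column, so they contribute to depth but never to a C->T count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .errors import ConsistencyError
from .reference import Reference, load_reference  # noqa: F401  (re-exported)

logger = logging.getLogger(__name__)

BASE_ORDER = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}


@dataclass
class Pileup:
    """Base counts per (transcript, position).

    ``counts[tid]`` is an ``(L, 5)`` integer array over columns A,C,G,T,N
    (1-based position p lives in row p-1). ``total depth`` at a position
    is by definition the row sum.
    """

    counts: dict[str, np.ndarray] = field(default_factory=dict)
    skipped_reverse: int = 0
    skipped_secondary: int = 0
    skipped_low_mapq: int = 0

    def depth(self, tid: str, position: int) -> int:
        return int(self.counts[tid][position - 1].sum())

    def base_count(self, tid: str, position: int, base: str) -> int:
        return int(self.counts[tid][position - 1, _BASE_INDEX[base]])

    def to_dataframe(self, ref: Reference) -> pd.DataFrame:
        rows = []
        for tid, arr in self.counts.items():
            seq = ref.sequence(tid)
            for i in range(arr.shape[0]):
                a, c, g, t, n = (int(x) for x in arr[i])
                rows.append((tid, i + 1, seq[i], a, c, g, t, n, a + c + g + t + n))
        return pd.DataFrame(
            rows,
            columns=[
                "transcript", "position", "ref_base",
                "A", "C", "G", "T", "N", "depth",
            ],
        )

    def to_tsv(self, path: str | Path, ref: Reference) -> Path:
        path = Path(path)
        self.to_dataframe(ref).to_csv(path, sep="\t", index=False)
        return path


def pileup_from_tsv(path: str | Path, ref: Reference) -> Pileup:
    """Rebuild a :class:`Pileup` from the TSV written by :meth:`Pileup.to_tsv`."""
    df = pd.read_csv(path, sep="\t")
    counts: dict[str, np.ndarray] = {}
    for tid, sub in df.groupby("transcript", sort=False):
        if tid not in ref:
            raise ConsistencyError(f"pileup transcript {tid!r} absent from reference")
        arr = np.zeros((ref.length(str(tid)), 5), dtype=np.int64)
        arr[sub["position"].to_numpy() - 1] = sub[list(BASE_ORDER)].to_numpy()
        counts[str(tid)] = arr
    return Pileup(counts=counts)


def pileup(sam_path: str | Path, ref: Reference, min_mapq: int = 0) -> Pileup:
    """Count bases per reference position from a SAM file.

    Raises :class:`~meclip.errors.ConsistencyError` when the SAM header
    names a reference absent from ``ref`` or disagrees on its length.
    """
    sam_path = Path(sam_path)
    result = Pileup(
        counts={tid: np.zeros((len(seq), 5), dtype=np.int64)
                for tid, seq in ref.records}
    )
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for tid, length in zip(sam.references, sam.lengths):
            if tid not in ref:
                raise ConsistencyError(
                    f"SAM reference {tid!r} not present in FASTA reference"
                )
            if ref.length(tid) != length:
                raise ConsistencyError(
                    f"length mismatch for {tid!r}: SAM {length}, FASTA {ref.length(tid)}"
                )
        for read in sam:
            if read.is_unmapped:
                continue
            if read.is_secondary or read.is_supplementary:
                result.skipped_secondary += 1
                continue
            if read.is_reverse:
                result.skipped_reverse += 1
                continue
            if read.mapping_quality < min_mapq:
                result.skipped_low_mapq += 1
                continue
            arr = result.counts[read.reference_name]
            seq = read.query_sequence or ""
            cigar = read.cigartuples or []
            if len(cigar) == 1 and cigar[0][0] == 0:
                # fast path: ungapped match
                start = read.reference_start
                codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
                col = _codes_to_columns(codes)
                np.add.at(arr, (np.arange(start, start + len(seq)), col), 1)
            else:
                _accumulate_general(arr, read)
    if result.skipped_reverse:
        logger.warning(
            "skipped %d reverse-strand alignments (stranded transcript-space "
            "pileup; reverse reads are never complemented)",
            result.skipped_reverse,
        )
    return result


_COLUMN_LUT = np.full(256, 4, dtype=np.int64)  # default: N column
for _b, _i in _BASE_INDEX.items():
    _COLUMN_LUT[ord(_b)] = _i


def _codes_to_columns(codes: np.ndarray) -> np.ndarray:
    return _COLUMN_LUT[codes]


def _accumulate_general(arr: np.ndarray, read: "pysam.AlignedSegment") -> None:
    """CIGAR-aware accumulation; deletions count as N at the deleted positions."""
    seq = read.query_sequence or ""
    for qpos, rpos in read.get_aligned_pairs(matches_only=False):
        if rpos is None:
            continue  # insertion / soft clip: no reference position
        if qpos is None:
            arr[rpos, _BASE_INDEX["N"]] += 1  # deletion spans this position
        else:
            arr[rpos, _COLUMN_LUT[ord(seq[qpos])]] += 1


@dataclass(frozen=True)
class MutationSignal:
    """Candidate crosslink signature: T reads at a reference C."""

    transcript_id: str
    c_position: int  # 1-based
    ct_count: int
    depth: int

    def __post_init__(self) -> None:
        if not 0 <= self.ct_count <= self.depth:
            raise ConsistencyError(
                f"ct_count {self.ct_count} outside 0..depth ({self.depth})"
            )

    @property
    def frequency(self) -> float:
        return self.ct_count / self.depth


def scan_ct_signals(p: Pileup, ref: Reference) -> list[MutationSignal]:
    """One signal per reference-C position with at least one T read.

    Frequency denominator is total depth at the C, all base columns
    included. Output is sorted by (transcript, position).
    """
    signals = []
    for tid, arr in p.counts.items():
        seq = ref.sequence(tid)
        t_col = arr[:, _BASE_INDEX["T"]]
        depths = arr.sum(axis=1)
        for i in np.nonzero(t_col)[0]:
            if seq[i] != "C":
                continue
            signals.append(
                MutationSignal(
                    transcript_id=tid,
                    c_position=int(i) + 1,
                    ct_count=int(t_col[i]),
                    depth=int(depths[i]),
                )
            )
    signals.sort(key=lambda s: (s.transcript_id, s.c_position))
    return signals


def signals_to_tsv(signals: list[MutationSignal], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            (s.transcript_id, s.c_position, s.ct_count, s.depth, s.frequency)
            for s in signals
        ],
        columns=["transcript", "c_position", "ct_count", "depth", "frequency"],
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def signals_from_tsv(path: str | Path) -> list[MutationSignal]:
    df = pd.read_csv(path, sep="\t")
    return [
        MutationSignal(str(r.transcript), int(r.c_position), int(r.ct_count),
                       int(r.depth))
        for r in df.itertuples()
    ]
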
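"""Transcript reference container and FASTA I/O.

Coordinates are 1-based and inclusive everywhere in this package except
inside BED files, which follow the usual 0-based half-open convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

_REFERENCE_ALPHABET = frozenset("ACGTN")
_SIM_ALPHABET = frozenset("ACGT")


@dataclass
class Reference:
    """Ordered collection of named transcript sequences.

    Sequences are stored uppercased. ``N`` is tolerated when loading real
    references but positions containing ``N`` are never callable; the
    simulator only ever emits A/C/G/T.
    """

    records: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        cleaned: list[tuple[str, str]] = []
        for tid, seq in self.records:
            if tid in seen:
                raise FormatError(f"duplicate transcript id: {tid!r}")
            seen.add(tid)
            seq = seq.upper()
            if not seq:
                raise FormatError(f"empty sequence for transcript {tid!r}")
            bad = set(seq) - _REFERENCE_ALPHABET
            if bad:
                raise FormatError(
                    f"transcript {tid!r} contains non-ACGTN characters: {sorted(bad)}"
                )
            cleaned.append((tid, seq))
        self.records = cleaned

    @property
    def ids(self) -> list[str]:
        return [tid for tid, _ in self.records]

    def __contains__(self, tid: str) -> bool:
        return any(t == tid for t, _ in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def sequence(self, tid: str) -> str:
        for t, s in self.records:
            if t == tid:
                return s
        raise KeyError(tid)

    def length(self, tid: str) -> int:
        return len(self.sequence(tid))

    def base(self, tid: str, position: int) -> str:
        """Reference base at a 1-based position."""
        seq = self.sequence(tid)
        if not 1 <= position <= len(seq):
            raise IndexError(f"position {position} outside 1..{len(seq)} on {tid!r}")
        return seq[position - 1]

    def to_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        records = [
            SeqRecord(Seq(seq), id=tid, description="") for tid, seq in self.records
        ]
        with open(path, "w") as handle:
            SeqIO.write(records, handle, "fasta")
        return path

    def to_fasta_string(self) -> str:
        buf = io.StringIO()
        records = [
            SeqRecord(Seq(seq), id=tid, description="") for tid, seq in self.records
        ]
        SeqIO.write(records, buf, "fasta")
        return buf.getvalue()


def load_reference(path: str | Path) -> Reference:
    """Read a FASTA file into a :class:`Reference`.

    Sequences are uppercased; duplicate ids and characters outside ACGTN
    raise :class:`~meclip.errors.FormatError`.
    """
    path = Path(path)
    try:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    except (ValueError, AssertionError) as exc:  # Biopython parse failures
        raise FormatError(f"malformed FASTA {path}: {exc}") from exc
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return Reference(records)
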
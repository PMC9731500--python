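"""Synthetic meCLIP libraries with planted m6A sites.

The generator emulates the data the site caller consumes: a transcript
reference, a set of methylated adenosines of known position and
stoichiometry, and matched IP / input read libraries. Antibody
crosslinking at a methylated A induces a C->T conversion during reverse
transcription at the base immediately 3' of the A, so an IP read covering
that C carries a T with probability

    stoichiometry x ip_enrichment x conversion_prob

while input libraries carry no crosslink chemistry at all. Background
sequencing noise substitutes any base uniformly at ``background_error``.

Reads are emitted pre-aligned: sense-strand, ungapped, fixed-length
alignments written directly as SAM (plus the raw reads as FASTQ), so the
pipeline is exercised end to end without an aligner. All randomness flows
from explicit integer seeds; identical arguments give byte-identical
output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConsistencyError, InputError, PlacementError
from .reference import Reference

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_PURINES = {"A", "G"}


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth methylated adenosine.

    ``position`` is the 1-based coordinate of the methylated A; the
    crosslink-induced C->T conversion is read out at ``position + 1``.
    """

    transcript_id: str
    position: int
    stoichiometry: float
    conversion_prob: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.stoichiometry <= 1.0:
            raise InputError(f"stoichiometry {self.stoichiometry} outside [0, 1]")
        if not 0.0 <= self.conversion_prob <= 1.0:
            raise InputError(f"conversion_prob {self.conversion_prob} outside [0, 1]")
        if self.position < 2:
            raise InputError("position-1 must be >= 1 (RAC context needs a 5' purine)")

    def validate_against(self, ref: Reference) -> None:
        seq = ref.sequence(self.transcript_id)
        if self.position + 1 > len(seq):
            raise ConsistencyError(
                f"site {self.transcript_id}:{self.position} has no +1 base"
            )
        triplet = seq[self.position - 2 : self.position + 1]
        if not (triplet[0] in _PURINES and triplet[1] == "A" and triplet[2] == "C"):
            raise ConsistencyError(
                f"site {self.transcript_id}:{self.position} context {triplet!r} "
                "violates the R-A-C invariant"
            )


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one library.

    depth is the mean read coverage per position; ip_enrichment is the
    fraction of IP reads at a planted locus drawn from antibody-bound
    (methylated) molecules.
    """

    read_length: int = 50
    depth: float = 200.0
    background_error: float = 0.001
    ip_enrichment: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 20:
            raise InputError("read_length must be >= 20")
        if self.depth <= 0:
            raise InputError("depth must be positive")
        for name in ("background_error", "ip_enrichment"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise InputError(f"{name} {value} outside [0, 1]")


@dataclass
class ReadSet:
    """Simulated aligned reads for one library (one kind, one seed)."""

    kind: str
    read_length: int
    reference_lengths: dict[str, int]
    # parallel per-read arrays: transcript id, 1-based POS, sequence
    transcript_ids: list[str]
    positions: list[int]
    sequences: list[str]

    def __len__(self) -> int:
        return len(self.sequences)

    def read_names(self) -> list[str]:
        return [
            f"{tid}.{self.kind}.{i:06d}"
            for i, tid in enumerate(self.transcript_ids)
        ]

    def to_sam_string(self) -> str:
        lines = ["@HD\tVN:1.6\tSO:coordinate"]
        for tid, length in self.reference_lengths.items():
            lines.append(f"@SQ\tSN:{tid}\tLN:{length}")
        qual = "I" * self.read_length
        cigar = f"{self.read_length}M"
        for name, tid, pos, seq in zip(
            self.read_names(), self.transcript_ids, self.positions, self.sequences
        ):
            lines.append(
                f"{name}\t0\t{tid}\t{pos}\t255\t{cigar}\t*\t0\t0\t{seq}\t{qual}"
            )
        return "\n".join(lines) + "\n"

    def to_fastq_string(self) -> str:
        qual = "I" * self.read_length
        chunks = [
            f"@{name}\n{seq}\n+\n{qual}\n"
            for name, seq in zip(self.read_names(), self.sequences)
        ]
        return "".join(chunks)

    def write_sam(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_sam_string())
        return path

    def write_fastq(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_fastq_string())
        return path


def build_reference(
    n_transcripts: int, length_range: tuple[int, int], seed: int
) -> Reference:
    """Seed-deterministic random transcripts over A/C/G/T.

    ``length_range`` is inclusive on both ends.
    """
    if n_transcripts < 1:
        raise InputError("n_transcripts must be >= 1")
    lo, hi = length_range
    if lo > hi or lo < 1:
        raise InputError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    records = []
    width = max(2, len(str(n_transcripts)))
    for i in range(n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        records.append((f"tx{i + 1:0{width}d}", seq))
    return Reference(records)


def plant_sites(
    ref: Reference,
    n_sites: int,
    stoichiometry: float,
    conversion_prob: float,
    seed: int,
    min_spacing: int = 100,
) -> tuple[Reference, list[PlantedSite]]:
    """Choose methylation sites and edit the reference to give each a
    R-A-C context.

    Positions are drawn uniformly over the interior of all transcripts,
    kept at least ``min_spacing`` nt apart (default twice the default
    read length, so no read can span two sites), and the sequence is
    edited in place -- at most 3 nt per site -- so that position-1 is a
    purine, the position itself an A, and position+1 a C. The edited
    reference is returned together with the ground truth; reads are
    always simulated from the edited sequence, so reference and reads
    never disagree.
    """
    if n_sites < 0:
        raise InputError("n_sites must be >= 0")
    if n_sites == 0:
        return ref, []

    rng = np.random.default_rng(seed)
    candidates: list[tuple[str, int]] = []
    for tid, seq in ref.records:
        # interior positions only: the RAC context needs pos-1 >= 1 and pos+1 <= len
        for pos in range(2, len(seq)):
            candidates.append((tid, pos))
    order = rng.permutation(len(candidates))

    chosen: dict[str, list[int]] = {}
    picked: list[tuple[str, int]] = []
    for idx in order:
        tid, pos = candidates[idx]
        if any(abs(pos - other) < min_spacing for other in chosen.get(tid, ())):
            continue
        chosen.setdefault(tid, []).append(pos)
        picked.append((tid, pos))
        if len(picked) == n_sites:
            break
    if len(picked) < n_sites:
        raise PlacementError(
            f"could only place {len(picked)} of {n_sites} sites with "
            f"spacing >= {min_spacing}"
        )

    edited = {tid: bytearray(seq, "ascii") for tid, seq in ref.records}
    n_edits = 0
    for tid, pos in picked:
        seq = edited[tid]
        if chr(seq[pos - 2]) not in _PURINES:
            seq[pos - 2] = ord("G")
            n_edits += 1
        if chr(seq[pos - 1]) != "A":
            seq[pos - 1] = ord("A")
            n_edits += 1
        if chr(seq[pos]) != "C":
            seq[pos] = ord("C")
            n_edits += 1
    logger.info("planted %d sites (%d nt edited to create RAC contexts)",
                len(picked), n_edits)

    new_ref = Reference(
        [(tid, edited[tid].decode("ascii")) for tid, _ in ref.records]
    )
    sites = [
        PlantedSite(tid, pos, stoichiometry, conversion_prob)
        for tid, pos in sorted(picked)
    ]
    for site in sites:
        site.validate_against(new_ref)
    return new_ref, sites


def simulate_library(
    ref: Reference,
    planted: list[PlantedSite],
    cfg: SimConfig,
    kind: str,
) -> ReadSet:
    """Draw one aligned library of the given ``kind`` ("ip" or "input").

    Reads tile each transcript at ~``cfg.depth`` mean coverage with
    uniformly random start positions and simple-match CIGARs. Crosslink
    conversions are applied first (IP only), then background
    substitutions on the remaining bases, so the conversion frequency at
    a planted +1 position follows Binomial(depth_at_site,
    stoichiometry x ip_enrichment x conversion_prob) exactly when
    background_error is 0.
    """
    kind = kind.lower()
    if kind not in {"ip", "input"}:
        raise InputError(f"kind must be 'ip' or 'input', got {kind!r}")
    for site in planted:
        if site.transcript_id not in ref:
            raise ConsistencyError(
                f"planted site on unknown transcript {site.transcript_id!r}"
            )
        site.validate_against(ref)

    rng = np.random.default_rng(cfg.seed)
    L = cfg.read_length
    by_tid: dict[str, list[PlantedSite]] = {}
    for site in planted:
        by_tid.setdefault(site.transcript_id, []).append(site)

    all_tids: list[str] = []
    all_pos: list[int] = []
    all_seqs: list[str] = []

    base_to_code = np.full(256, -1, dtype=np.int8)
    for code, b in enumerate(b"ACGT"):
        base_to_code[b] = code

    for tid, seq in ref.records:
        tlen = len(seq)
        if tlen < L:
            raise ConsistencyError(
                f"transcript {tid!r} shorter than read length {L}"
            )
        n_reads = int(round(cfg.depth * tlen / L))
        starts0 = np.sort(rng.integers(0, tlen - L + 1, size=n_reads))
        ref_codes = base_to_code[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        if (ref_codes < 0).any():
            raise ConsistencyError(
                f"transcript {tid!r} contains non-ACGT bases; cannot simulate"
            )
        cols = np.arange(L)
        matrix = ref_codes[starts0[:, None] + cols]  # (n_reads, L) base codes

        converted = np.zeros_like(matrix, dtype=bool)
        if kind == "ip":
            for site in by_tid.get(tid, ()):
                c0 = site.position  # 0-based index of the C at position+1
                covering = (starts0 <= c0) & (c0 <= starts0 + L - 1)
                idx = np.nonzero(covering)[0]
                if idx.size == 0:
                    continue
                p = site.stoichiometry * cfg.ip_enrichment * site.conversion_prob
                if p <= 0:
                    continue  # no draws: a null chemistry matches input exactly
                hits = idx[rng.random(idx.size) < p]
                matrix[hits, c0 - starts0[hits]] = 3  # T
                converted[hits, c0 - starts0[hits]] = True

        if cfg.background_error > 0:
            noise = (rng.random(matrix.shape) < cfg.background_error) & ~converted
            shift = rng.integers(1, 4, size=int(noise.sum()))
            matrix[noise] = (matrix[noise] + shift) % 4

        read_bytes = _BASES[matrix]
        for row, start0 in zip(read_bytes, starts0):
            all_tids.append(tid)
            all_pos.append(int(start0) + 1)
            all_seqs.append(row.tobytes().decode("ascii"))

    return ReadSet(
        kind=kind,
        read_length=L,
        reference_lengths={tid: len(seq) for tid, seq in ref.records},
        transcript_ids=all_tids,
        positions=all_pos,
        sequences=all_seqs,
    )


def write_truth_bed(sites: list[PlantedSite], path: str | Path) -> Path:
    """Ground-truth BED: one 0-based half-open record per planted A."""
    path = Path(path)
    lines = []
    for site in sorted(sites, key=lambda s: (s.transcript_id, s.position)):
        lines.append(
            "\t".join(
                (
                    site.transcript_id,
                    str(site.position - 1),
                    str(site.position),
                    f"m6A{site.position}",
                    str(int(round(1000 * site.stoichiometry))),
                    "+",
                )
            )
        )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_truth_bed(path: str | Path) -> list[tuple[str, int]]:
    """Read a truth-set BED back as (transcript_id, 1-based A position)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        out.append((fields[0], int(fields[1]) + 1))
    return out
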
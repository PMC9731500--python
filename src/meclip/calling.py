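"""Threshold-based m6A site calling from C->T mutation signals.

A candidate C->T signal becomes an m6A call when

* the adenosine one base 5' of the C sits in an R-A-C context
  (R = A or G, the middle A is the methylated base, the C carries the
  crosslink-induced mutation),
* at least ``min_count`` C->T events support it (3 by default; 2 in
  reduced mode), and
* its frequency lies in the inclusive window [``min_freq``, ``max_freq``]
  (2.5%--50% by default). The upper bound excludes signals mutated in
  most reads, which are more consistent with genetic variants than with
  sub-stoichiometric crosslink chemistry.

Calls are tiered: high confidence (>= 3 events in >= 5% of reads), low
confidence (>= 3 events in >= 2.5%), or reduced (exactly 2 events, only
reachable in reduced mode). Sites also present in the matched input
library are subtracted, removing mutations not induced by the antibody
crosslink.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError
from .profiling import MutationSignal
from .reference import Reference

_PURINES = {"A", "G"}

TIER_HIGH = "high"
TIER_LOW = "low"
TIER_REDUCED = "reduced"


@dataclass(frozen=True)
class CallingParams:
    min_count: int = 3
    min_freq: float = 0.025
    max_freq: float = 0.50
    high_conf_freq: float = 0.05
    reduced_mode: bool = False

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ConfigError("min_count must be >= 1")
        if not 0 < self.min_freq <= self.high_conf_freq <= self.max_freq <= 1:
            raise ConfigError(
                "require 0 < min_freq <= high_conf_freq <= max_freq <= 1, got "
                f"{self.min_freq}, {self.high_conf_freq}, {self.max_freq}"
            )

    @property
    def effective_min_count(self) -> int:
        return 2 if self.reduced_mode else self.min_count

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CallingParams":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown calling parameters: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class M6ACall:
    transcript_id: str
    a_position: int  # 1-based position of the methylated A (= c_position - 1)
    motif: str  # the R-A-C trinucleotide
    ct_count: int
    depth: int
    frequency: float
    tier: str
    replicate_id: str

    @property
    def key(self) -> tuple[str, int]:
        return (self.transcript_id, self.a_position)


def motif_ok(ref: Reference, transcript_id: str, a_position: int) -> bool:
    """True iff the 1-based ``a_position`` sits in an R-A-C context.

    Positions at a transcript edge lack a complete context and are
    rejected.
    """
    seq = ref.sequence(transcript_id)
    if not 2 <= a_position <= len(seq) - 1:
        return False
    return (
        seq[a_position - 2] in _PURINES
        and seq[a_position - 1] == "A"
        and seq[a_position] == "C"
    )


def assign_confidence(ct_count: int, frequency: float, params: CallingParams) -> str:
    """Tier for a signal that already passed the calling filters."""
    if ct_count >= 3:
        return TIER_HIGH if frequency >= params.high_conf_freq else TIER_LOW
    return TIER_REDUCED


def call_sites(
    signals: list[MutationSignal],
    ref: Reference,
    params: CallingParams | None = None,
    replicate_id: str = "rep1",
) -> list[M6ACall]:
    """Apply motif, count, and frequency filters to candidate signals."""
    params = params or CallingParams()
    calls = []
    for s in signals:
        a_pos = s.c_position - 1
        if not motif_ok(ref, s.transcript_id, a_pos):
            continue
        if s.ct_count < params.effective_min_count:
            continue
        freq = s.frequency
        if not params.min_freq <= freq <= params.max_freq:
            continue
        seq = ref.sequence(s.transcript_id)
        calls.append(
            M6ACall(
                transcript_id=s.transcript_id,
                a_position=a_pos,
                motif=seq[a_pos - 2 : a_pos + 1],
                ct_count=s.ct_count,
                depth=s.depth,
                frequency=freq,
                tier=assign_confidence(s.ct_count, freq, params),
                replicate_id=replicate_id,
            )
        )
    calls.sort(key=lambda c: (c.transcript_id, c.a_position))
    return calls


def subtract_input(
    ip_calls: list[M6ACall], input_calls: list[M6ACall]
) -> list[M6ACall]:
    """Remove IP calls whose (transcript, A position) also appears in the
    input library; order is preserved."""
    input_keys = {c.key for c in input_calls}
    return [c for c in ip_calls if c.key not in input_keys]


def calls_to_tsv(calls: list[M6ACall], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            (c.transcript_id, c.a_position, c.motif, c.ct_count, c.depth,
             c.frequency, c.tier, c.replicate_id)
            for c in calls
        ],
        columns=["transcript", "a_position", "motif", "ct_count", "depth",
                 "frequency", "tier", "replicate"],
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def calls_from_tsv(path: str | Path) -> list[M6ACall]:
    df = pd.read_csv(path, sep="\t")
    return [
        M6ACall(str(r.transcript), int(r.a_position), str(r.motif),
                int(r.ct_count), int(r.depth), float(r.frequency),
                str(r.tier), str(r.replicate))
        for r in df.itertuples()
    ]


def calls_to_bed(calls: list[M6ACall], path: str | Path) -> Path:
    """Single-base 0-based half-open intervals, score = 1000 x frequency."""
    path = Path(path)
    lines = []
    for c in sorted(calls, key=lambda c: (c.transcript_id, c.a_position)):
        lines.append(
            "\t".join(
                (
                    c.transcript_id,
                    str(c.a_position - 1),
                    str(c.a_position),
                    f"m6A{c.a_position}",
                    str(int(round(1000 * c.frequency))),
                    "+",
                )
            )
        )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path
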
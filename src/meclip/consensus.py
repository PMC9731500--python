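"""Multi-replicate consensus sites and occurrence matrices.

A site is a consensus site when it is detected at exactly the same
(transcript, position) in at least ``min_replicates`` replicates
(2 by default). Matching is exact-coordinate: the method is
single-nucleotide, so no fuzzy window is applied, and replicates need
not agree on the confidence tier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .calling import M6ACall, TIER_HIGH, TIER_LOW, TIER_REDUCED
from .errors import ConfigError

TIER_SYMBOLS = {TIER_HIGH: "X", TIER_LOW: "x", TIER_REDUCED: "*"}


@dataclass
class ConsensusSite:
    transcript_id: str
    a_position: int
    tiers: dict[str, str] = field(default_factory=dict)  # replicate -> tier
    min_replicates: int = 2

    @property
    def n_supporting(self) -> int:
        return len(self.tiers)

    @property
    def consensus(self) -> bool:
        return self.n_supporting >= self.min_replicates

    @property
    def key(self) -> tuple[str, int]:
        return (self.transcript_id, self.a_position)


def build_consensus(
    call_sets: Mapping[str, list[M6ACall]], min_replicates: int = 2
) -> list[ConsensusSite]:
    """Union of per-replicate call sets with support counts.

    Every (transcript, position) seen in any replicate appears exactly
    once; the consensus flag marks those supported by at least
    ``min_replicates`` replicates. Invariant to replicate ordering.
    """
    if min_replicates < 1:
        raise ConfigError("min_replicates must be >= 1")
    sites: dict[tuple[str, int], ConsensusSite] = {}
    for replicate_id in sorted(call_sets):
        for call in call_sets[replicate_id]:
            site = sites.setdefault(
                call.key,
                ConsensusSite(call.transcript_id, call.a_position,
                              min_replicates=min_replicates),
            )
            site.tiers[replicate_id] = call.tier
    return sorted(sites.values(), key=lambda s: s.key)


def occurrence_matrix(call_sets: Mapping[str, list[M6ACall]]) -> pd.DataFrame:
    """Site-by-experiment table of tier symbols.

    Rows are (transcript, position) sorted by coordinate; columns follow
    the mapping's insertion order. Cells carry "X" (high), "x" (low),
    "*" (reduced), or "" when the site was not detected in that
    experiment.
    """
    experiments = list(call_sets)
    keys = sorted({call.key for calls in call_sets.values() for call in calls})
    data = {}
    for exp in experiments:
        by_key = {c.key: TIER_SYMBOLS[c.tier] for c in call_sets[exp]}
        data[exp] = [by_key.get(k, "") for k in keys]
    index = pd.MultiIndex.from_tuples(keys, names=["transcript", "position"]) \
        if keys else pd.MultiIndex.from_arrays([[], []], names=["transcript", "position"])
    return pd.DataFrame(data, index=index, columns=experiments)


def export_sites(
    sites: list[ConsensusSite], path: str | Path, format: str = "tsv"
) -> Path:
    """Write consensus sites as TSV (lossless) or BED (coordinates only)."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "tsv":
        rows = [
            (
                s.transcript_id,
                s.a_position,
                s.n_supporting,
                s.consensus,
                s.min_replicates,
                ",".join(f"{rep}:{tier}" for rep, tier in sorted(s.tiers.items())),
            )
            for s in sites
        ]
        pd.DataFrame(
            rows,
            columns=["transcript", "a_position", "n_supporting", "consensus",
                     "min_replicates", "tiers"],
        ).to_csv(path, sep="\t", index=False)
    elif fmt == "bed":
        lines = []
        for s in sorted(sites, key=lambda s: (s.transcript_id, s.a_position)):
            lines.append(
                "\t".join(
                    (
                        s.transcript_id,
                        str(s.a_position - 1),
                        str(s.a_position),
                        f"m6A{s.a_position}",
                        str(s.n_supporting),
                        "+",
                    )
                )
            )
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ConfigError(f"unknown export format {format!r} (expected tsv or bed)")
    return path


def import_sites(path: str | Path) -> list[ConsensusSite]:
    """Inverse of :func:`export_sites` for the TSV format."""
    df = pd.read_csv(Path(path), sep="\t", keep_default_na=False)
    sites = []
    for r in df.itertuples():
        tiers = {}
        if r.tiers:
            for item in str(r.tiers).split(","):
                rep, tier = item.split(":")
                tiers[rep] = tier
        sites.append(
            ConsensusSite(
                transcript_id=str(r.transcript),
                a_position=int(r.a_position),
                tiers=tiers,
                min_replicates=int(r.min_replicates),
            )
        )
    return sites
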
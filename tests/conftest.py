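import numpy as np
import pytest

from meclip import Reference, build_reference, plant_sites


@pytest.fixture
def lncrna_ref() -> Reference:
    """One 2,200-nt transcript, the length scale of a spliced lncRNA."""
    return build_reference(1, (2200, 2200), seed=7)


@pytest.fixture
def planted_ref(lncrna_ref):
    """Reference with 8 planted sites at full stoichiometry."""
    return plant_sites(lncrna_ref, 8, stoichiometry=1.0, conversion_prob=0.15,
                       seed=11)


def make_reference(seq: str, tid: str = "tx1") -> Reference:
    return Reference([(tid, seq)])


def sam_text(reads, lengths) -> str:
    """Minimal SAM builder: reads are (qname, flag, rname, pos, cigar, seq)."""
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for tid, length in lengths.items():
        lines.append(f"@SQ\tSN:{tid}\tLN:{length}")
    for qname, flag, rname, pos, cigar, seq in reads:
        lines.append(
            f"{qname}\t{flag}\t{rname}\t{pos}\t255\t{cigar}\t*\t0\t0\t{seq}\t"
            + "I" * len(seq)
        )
    return "\n".join(lines) + "\n"


def brute_force_base_counts(sam_string: str) -> dict[tuple[str, int], dict[str, int]]:
    """Independent recount straight from SAM text.

    Counts each base of every mapped, primary, forward-strand match-only
    alignment at its 1-based reference position, using nothing but string
    splitting. Serves as the oracle the pileup must agree with.
    """
    counts: dict[tuple[str, int], dict[str, int]] = {}
    for line in sam_string.splitlines():
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        flag = int(fields[1])
        if flag & 0x4 or flag & 0x10 or flag & 0x100 or flag & 0x800:
            continue
        rname, pos, cigar, seq = fields[2], int(fields[3]), fields[5], fields[9]
        assert cigar == f"{len(seq)}M", "oracle only handles match-only CIGARs"
        for offset, base in enumerate(seq):
            key = (rname, pos + offset)
            counts.setdefault(key, {"A": 0, "C": 0, "G": 0, "T": 0, "N": 0})
            counts[key][base if base in "ACGTN" else "N"] += 1
    return counts


def brute_force_call(sam_string: str, ref: Reference, min_count=3,
                     min_freq=0.025, max_freq=0.50) -> set[tuple[str, int]]:
    """Oracle site caller: recount from SAM text, then apply the motif,
    count, and frequency rules directly. Returns (transcript, A position)."""
    counts = brute_force_base_counts(sam_string)
    called = set()
    for (tid, pos), bases in counts.items():
        a_pos = pos - 1
        seq = ref.sequence(tid)
        if not 2 <= a_pos <= len(seq) - 1:
            continue
        if not (seq[a_pos - 2] in "AG" and seq[a_pos - 1] == "A"
                and seq[a_pos] == "C"):
            continue
        depth = sum(bases.values())
        ct = bases["T"]
        if ct >= min_count and min_freq <= ct / depth <= max_freq:
            called.add((tid, a_pos))
    return called


@pytest.fixture
def rng():
    return np.random.default_rng(123)
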
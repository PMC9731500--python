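"""Downstream quantification operators.

Closed-form procedures used alongside the site caller:

* percent-input recovery of a RIP/meRIP qPCR experiment,
* recovery profiles normalized to an unmethylated reference region,
* a ddCt chromatin-association metric (chromatin/input, normalized to a
  housekeeping RNA such as 7SL, relative to a baseline condition),
* doubling time from log-linear least squares on confluence curves,
* peak-proximity counts and metaprofiles of an interval signal around
  single-nucleotide sites, and
* antimorph classification of paired differential-expression contrasts.

qPCR arithmetic assumes perfect amplification efficiency (a factor of 2
per cycle); no efficiency correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InputError


# --------------------------------------------------------------------------
# qPCR recovery

@dataclass(frozen=True)
class QPCRMeasurement:
    """Paired input/IP threshold cycles for one qPCR target.

    ``input_fraction`` is the fraction of the IP'd material that the
    input aliquot represents (e.g. 0.05 when 5% of the sample was
    reserved as input).
    """

    target: str
    ct_input: float
    ct_ip: float
    input_fraction: float

    def __post_init__(self) -> None:
        for name in ("ct_input", "ct_ip"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise InputError(f"{name} must be finite and positive, got {v}")
        if not 0 < self.input_fraction <= 1:
            raise InputError(
                f"input_fraction must be in (0, 1], got {self.input_fraction}"
            )


class Recovery(NamedTuple):
    fraction: float
    saturated: bool  # True when recovery > 1 (more signal than input implies)


def percent_input(m: QPCRMeasurement) -> Recovery:
    """Fraction of starting material recovered in the IP.

    recovery = input_fraction x 2^(Ct_input - Ct_ip); a value above 1 is
    returned as-is but flagged.
    """
    fraction = m.input_fraction * 2.0 ** (m.ct_input - m.ct_ip)
    return Recovery(fraction=fraction, saturated=fraction > 1.0)


def region_profile(
    recoveries: Mapping[str, float], reference_region: str
) -> dict[str, float]:
    """Normalize per-region recoveries to an m6A-free reference region.

    The reference region maps to exactly 1.0.
    """
    if reference_region not in recoveries:
        raise InputError(f"reference region {reference_region!r} missing")
    ref_value = recoveries[reference_region]
    if ref_value == 0:
        raise InputError("reference region recovery is zero; cannot normalize")
    return {region: value / ref_value for region, value in recoveries.items()}


# --------------------------------------------------------------------------
# Chromatin association (ddCt)

@dataclass(frozen=True)
class CtQuartet:
    """Threshold cycles for one condition: target and normalizer RNA,
    each measured in the chromatin fraction and in input."""

    target_chromatin: float
    target_input: float
    normalizer_chromatin: float
    normalizer_input: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InputError(f"{name} must be finite, got {v}")

    @property
    def ratio(self) -> float:
        """2^-ddCt of chromatin/input for target over normalizer."""
        ddct = (self.target_chromatin - self.target_input) - (
            self.normalizer_chromatin - self.normalizer_input
        )
        return 2.0 ** (-ddct)


def chromatin_association(
    conditions: Mapping[str, CtQuartet], baseline: str
) -> dict[str, float]:
    """Relative chromatin association per condition.

    Each condition's 2^-ddCt ratio (chromatin vs input, normalized to
    the housekeeping RNA) is divided by the baseline condition's ratio,
    so the baseline is exactly 1.0.
    """
    if baseline not in conditions:
        raise InputError(f"baseline condition {baseline!r} missing")
    base = conditions[baseline].ratio
    return {cond: q.ratio / base for cond, q in conditions.items()}


# --------------------------------------------------------------------------
# Growth fitting

@dataclass(frozen=True)
class GrowthCurve:
    """Confluence (percent) versus time (hours)."""

    time: tuple[float, ...]
    confluence: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.time) != len(self.confluence):
            raise InputError("time and confluence must have equal length")
        if len(self.time) < 3:
            raise InputError("growth curve needs at least 3 points")
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.confluence, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise InputError("time must be strictly increasing")
        if not np.all((c > 0) & (c <= 100)):
            raise InputError("confluence must lie in (0, 100]")


class GrowthFit(NamedTuple):
    doubling_time: float  # hours; NaN when not growing
    rate: float  # doublings per hour (slope of log2 confluence vs time)
    growing: bool


def doubling_time(g: GrowthCurve) -> GrowthFit:
    """Least-squares exponential growth fit.

    Fits log2(confluence) against time by ordinary least squares; the
    doubling time is the reciprocal of the slope. Non-positive slopes
    are flagged as non-growing with an undefined (NaN) doubling time.
    """
    t = np.asarray(g.time, dtype=float)
    y = np.log2(np.asarray(g.confluence, dtype=float))
    fit = stats.linregress(t, y)
    slope = float(fit.slope)
    if slope <= 0:
        return GrowthFit(doubling_time=float("nan"), rate=slope, growing=False)
    return GrowthFit(doubling_time=1.0 / slope, rate=slope, growing=True)


# --------------------------------------------------------------------------
# Peak proximity and metaprofiles

@dataclass
class PeakSet:
    """0-based half-open intervals with a signal value."""

    intervals: list[tuple[str, int, int, float]]

    def __post_init__(self) -> None:
        for chrom, start, end, signal in self.intervals:
            if start >= end:
                raise InputError(f"empty interval {chrom}:{start}-{end}")
            if not math.isfinite(signal):
                raise InputError(f"non-finite signal on {chrom}:{start}-{end}")

    def by_chrom(self) -> dict[str, list[tuple[int, int, float]]]:
        out: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, signal in self.intervals:
            out.setdefault(chrom, []).append((start, end, signal))
        for ivals in out.values():
            ivals.sort()
        return out


class ProximityResult(NamedTuple):
    n_proximal: int
    fraction: float
    distances: tuple[float, ...]  # nearest-edge distance per site (inf if none)


def peak_proximity(
    sites: Sequence[tuple[str, int]], peaks: PeakSet, window: int = 1000
) -> ProximityResult:
    """Count sites with a peak edge within ``window`` nt (inclusive).

    Sites are (chrom, position) in the same 0-based coordinate system as
    the peaks; a site inside a peak has distance 0.
    """
    if window < 0:
        raise ConfigError("window must be non-negative")
    by_chrom = peaks.by_chrom()
    distances = []
    for chrom, pos in sites:
        best = math.inf
        for start, end, _ in by_chrom.get(chrom, ()):
            if start <= pos < end:
                best = 0.0
                break
            d = start - pos if pos < start else pos - (end - 1)
            best = min(best, float(d))
        distances.append(best)
    n = sum(1 for d in distances if d <= window)
    fraction = n / len(sites) if sites else 0.0
    return ProximityResult(n, fraction, tuple(distances))


def peaks_to_track(peaks: PeakSet, lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Rasterize intervals into per-position signal arrays (summing overlaps)."""
    tracks = {chrom: np.zeros(length, dtype=float) for chrom, length in lengths.items()}
    for chrom, start, end, signal in peaks.intervals:
        if chrom in tracks:
            tracks[chrom][start:end] += signal
    return tracks


def metaprofile(
    sites: Sequence[tuple[str, int]],
    track: Mapping[str, np.ndarray],
    halfwidth: int = 1000,
    bins: int = 50,
) -> pd.DataFrame:
    """Mean signal versus offset from a set of anchor sites.

    Offsets run over [-halfwidth, +halfwidth]; sites near a sequence end
    contribute only their valid offsets. Returns a frame with one row
    per bin: offset_start, offset_end (inclusive), mean_signal, n_obs.
    """
    if halfwidth <= 0:
        raise ConfigError("halfwidth must be positive")
    if bins < 1:
        raise ConfigError("bins must be >= 1")
    if not sites:
        raise InputError("metaprofile requires at least one site")
    edges = np.linspace(-halfwidth, halfwidth + 1, bins + 1)
    sums = np.zeros(bins)
    counts = np.zeros(bins)
    for chrom, pos in sites:
        if chrom not in track:
            continue
        arr = track[chrom]
        lo = max(0, pos - halfwidth)
        hi = min(len(arr), pos + halfwidth + 1)
        if lo >= hi:
            continue
        offsets = np.arange(lo, hi) - pos
        idx = np.clip(np.digitize(offsets, edges) - 1, 0, bins - 1)
        np.add.at(sums, idx, arr[lo:hi])
        np.add.at(counts, idx, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "offset_start": np.floor(edges[:-1]).astype(int),
            "offset_end": np.floor(edges[1:] - 1).astype(int),
            "mean_signal": means,
            "n_obs": counts.astype(int),
        }
    )


# --------------------------------------------------------------------------
# Antimorph classification

CATEGORY_SAME = "same_direction"
CATEGORY_OPPOSITE = "opposite"
CATEGORY_A_ONLY = "a_only"
CATEGORY_B_ONLY = "b_only"
CATEGORY_NS = "not_significant"

REQUIRED_FC_COLUMNS = ["gene", "log2fc_a", "padj_a", "log2fc_b", "padj_b"]


class CorrelationResult(NamedTuple):
    r_linear: float
    r_log2: float
    slope: float  # trend line on the default (signed linear) axes
    intercept: float
    n: int


class AntimorphResult(NamedTuple):
    categories: pd.Series  # gene -> category
    counts: dict[str, int]
    correlation: CorrelationResult


def signed_linear_fc(log2fc: np.ndarray) -> np.ndarray:
    """Signed linear fold change: 2^|log2FC| carrying the sign of log2FC.

    Matches the reporting convention where a halving is written as -2
    rather than 0.5.
    """
    return np.sign(log2fc) * 2.0 ** np.abs(log2fc)


def antimorph_classify(
    table: pd.DataFrame, alpha: float = 0.1, fc_min: float = 1.15
) -> AntimorphResult:
    """Classify genes by direction of change across two contrasts.

    Contrast A is condition-vs-control (e.g. WT overexpression), contrast
    B is mutant-vs-control. Among genes significant in A (adjusted
    p < alpha): ``same_direction`` when also significant in B with a
    matching fold-change sign, ``opposite`` (the antimorph pattern) when
    significant in B with the opposing sign, ``a_only`` otherwise. Genes
    significant only in B are ``b_only``; the rest ``not_significant``.
    A zero log2 fold change has no direction and never matches or
    opposes, so such genes fall into ``a_only``.

    The correlation is computed over genes whose linear fold change
    exceeds ``fc_min`` in either direction in BOTH contrasts, as the
    Pearson r of the two fold-change axes with a least-squares trend
    line; both the signed-linear (default axes) and log2 variants are
    reported.
    """
    if not 0 < alpha < 1:
        raise ConfigError(f"alpha must be in (0, 1), got {alpha}")
    if fc_min < 1:
        raise ConfigError(f"fc_min must be >= 1, got {fc_min}")
    missing = [c for c in REQUIRED_FC_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"fold-change table missing columns {missing}")
    if table["gene"].duplicated().any():
        raise InputError("gene ids must be unique")
    padj = table[["padj_a", "padj_b"]].to_numpy(dtype=float)
    if np.any((padj < 0) | (padj > 1)):
        raise InputError("adjusted p values must lie in [0, 1]")

    l2a = table["log2fc_a"].to_numpy(dtype=float)
    l2b = table["log2fc_b"].to_numpy(dtype=float)
    sig_a = padj[:, 0] < alpha
    sig_b = padj[:, 1] < alpha

    categories = np.full(len(table), CATEGORY_NS, dtype=object)
    categories[sig_b & ~sig_a] = CATEGORY_B_ONLY
    categories[sig_a] = CATEGORY_A_ONLY
    both = sig_a & sig_b
    product = l2a * l2b
    categories[both & (product > 0)] = CATEGORY_SAME
    categories[both & (product < 0)] = CATEGORY_OPPOSITE

    cat_series = pd.Series(categories, index=table["gene"].to_numpy(), name="category")
    counts = {
        cat: int((categories == cat).sum())
        for cat in (CATEGORY_SAME, CATEGORY_OPPOSITE, CATEGORY_A_ONLY,
                    CATEGORY_B_ONLY, CATEGORY_NS)
    }

    threshold = math.log2(fc_min)
    keep = (np.abs(l2a) > threshold) & (np.abs(l2b) > threshold)
    if keep.sum() >= 2:
        xa = signed_linear_fc(l2a[keep])
        xb = signed_linear_fc(l2b[keep])
        r_linear = float(stats.pearsonr(xa, xb).statistic)
        r_log2 = float(stats.pearsonr(l2a[keep], l2b[keep]).statistic)
        fit = stats.linregress(xa, xb)
        correlation = CorrelationResult(
            r_linear=r_linear,
            r_log2=r_log2,
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            n=int(keep.sum()),
        )
    else:
        correlation = CorrelationResult(
            float("nan"), float("nan"), float("nan"), float("nan"), int(keep.sum())
        )
    return AntimorphResult(cat_series, counts, correlation)
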
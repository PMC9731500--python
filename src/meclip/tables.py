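"""Synthetic inputs for the downstream quantification operators.

Together with :mod:`meclip.simulate` (reads) this completes the
synthetic-data surface: every operator in :mod:`meclip.quant` can be
exercised on generated inputs of known ground truth -- qPCR Ct tables
whose cycles encode a chosen recovery or fold difference, confluence
curves of chosen doubling time, interval sets with a chosen proximal
fraction, and paired differential-expression tables with planted
category counts and anticorrelation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import InputError
from .quant import CtQuartet, GrowthCurve, PeakSet, QPCRMeasurement


def synth_rip_measurement(
    target: str,
    recovery: float,
    input_fraction: float = 0.05,
    ct_input: float = 24.0,
) -> QPCRMeasurement:
    """Ct pair whose percent-input recovery equals ``recovery`` exactly.

    Inverts recovery = input_fraction x 2^(Ct_input - Ct_ip) for Ct_ip.
    """
    if recovery <= 0:
        raise InputError("recovery must be positive")
    ct_ip = ct_input - math.log2(recovery / input_fraction)
    return QPCRMeasurement(target, ct_input, ct_ip, input_fraction)


def synth_chromatin_conditions(
    folds: dict[str, float],
    baseline: str,
    base_ct: float = 22.0,
) -> dict[str, CtQuartet]:
    """Ct quartets whose relative chromatin association equals ``folds``.

    The baseline condition's fold must be 1.0; other conditions' target
    chromatin Ct is shifted by -log2(fold) relative to baseline.
    """
    if baseline not in folds:
        raise InputError(f"baseline {baseline!r} missing from folds")
    if folds[baseline] != 1.0:
        raise InputError("baseline fold must be 1.0")
    out = {}
    for cond, fold in folds.items():
        if fold <= 0:
            raise InputError(f"fold for {cond!r} must be positive")
        # fewer cycles on the chromatin target = more chromatin RNA
        out[cond] = CtQuartet(
            target_chromatin=base_ct - math.log2(fold),
            target_input=base_ct,
            normalizer_chromatin=base_ct,
            normalizer_input=base_ct,
        )
    return out


def synth_growth_curve(
    doubling_h: float = 26.5,
    t_end_h: float = 48.0,
    dt_h: float = 2.0,
    start_confluence: float = 5.0,
    noise: float = 0.01,
    seed: int = 0,
) -> GrowthCurve:
    """Exponential confluence series imaged every ``dt_h`` hours.

    The default cadence (48 h, one scan every 2 h, starting from low
    confluence in a 96-well plate) matches a live-cell imager run.
    Noise is multiplicative and lognormal with sigma ``noise``;
    ``noise=0`` gives an exact exponential.
    """
    if doubling_h <= 0:
        raise InputError("doubling_h must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_end_h + dt_h / 2, dt_h)
    conf = start_confluence * 2.0 ** (t / doubling_h)
    # stop scanning once the well saturates; keep at least 3 points
    keep = conf <= 95.0
    keep[:3] = True
    t, conf = t[keep], conf[keep]
    if noise > 0:
        conf = conf * np.exp(rng.normal(0.0, noise, size=t.size))
    conf = np.clip(conf, 1e-6, 100.0)
    return GrowthCurve(tuple(t), tuple(conf))


def synth_sites_and_peaks(
    n_sites: int,
    n_proximal: int,
    window: int = 1000,
    peak_width: int = 20,
    spacing: int = 10_000,
    seed: int = 0,
) -> tuple[list[tuple[str, int]], PeakSet]:
    """Sites on one chromosome, ``n_proximal`` of which get a peak planted
    inside ``window`` nt; the rest have no peak within reach."""
    if not 0 <= n_proximal <= n_sites:
        raise InputError("need 0 <= n_proximal <= n_sites")
    rng = np.random.default_rng(seed)
    sites = [("chr1", spacing * (i + 1)) for i in range(n_sites)]
    proximal_idx = rng.choice(n_sites, size=n_proximal, replace=False)
    intervals = []
    for i in sorted(proximal_idx):
        pos = sites[i][1]
        offset = int(rng.integers(-window + peak_width, window - peak_width))
        start = pos + offset
        intervals.append(("chr1", start, start + peak_width, 1.0))
    return sites, PeakSet(intervals)


def synth_foldchange_table(
    n_opposite: int = 46,
    n_same: int = 18,
    n_a_only: int = 91,
    n_b_only: int = 694,
    n_null: int = 11_000,
    alpha: float = 0.1,
    mag_mean: float = 1.5,
    mag_sd: float = 0.6,
    mag_corr: float = 0.9,
    opposite_bias: float = 0.85,
    sub_sig_max: float = 1.0,
    fc_min: float = 1.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired-contrast fold-change table with planted structure.

    Contrast A emulates a wild-type-vs-control comparison with
    ``n_opposite + n_same + n_a_only`` significant genes; contrast B the
    mutant-vs-control comparison. Category membership is planted exactly
    (significance labels and fold-change signs), so a classifier must
    recover the category counts; fold-change magnitudes are random.

    Genes significant in both contrasts draw |log2FC| pairs from a
    correlated bivariate normal (|N(mag_mean, mag_sd)| with correlation
    ``mag_corr``), clipped above the ``fc_min`` filter. Genes significant
    only in A carry small sub-significant changes in B -- magnitude
    uniform between log2(fc_min) and ``sub_sig_max``, with sign opposing
    A's with probability ``opposite_bias`` -- reproducing the weak
    antimorph trend of genes that do not reach significance in the
    mutant contrast. Null genes sit below the fold-change filter in both
    contrasts.

    Adjusted p values are drawn uniformly below ``alpha`` for
    significant labels and above it otherwise.
    """
    rng = np.random.default_rng(seed)
    thr = math.log2(fc_min)
    floor = thr + 0.01

    def _sig_p(n: int) -> np.ndarray:
        return rng.uniform(0.0, alpha * 0.999, size=n)

    def _ns_p(n: int) -> np.ndarray:
        return rng.uniform(alpha * 1.001, 1.0, size=n)

    rows = []

    n_pair = n_opposite + n_same
    cov = mag_sd**2 * np.array([[1.0, mag_corr], [mag_corr, 1.0]])
    mags = np.abs(rng.multivariate_normal([mag_mean, mag_mean], cov, size=n_pair))
    sign_a = rng.choice([-1.0, 1.0], size=n_pair)
    sign_b = np.concatenate([-sign_a[:n_opposite], sign_a[n_opposite:]])
    l2a = sign_a * np.maximum(mags[:, 0], floor)
    l2b = sign_b * np.maximum(mags[:, 1], floor)
    pa, pb = _sig_p(n_pair), _sig_p(n_pair)
    for i in range(n_pair):
        rows.append((l2a[i], pa[i], l2b[i], pb[i]))

    mag_a = np.maximum(np.abs(rng.normal(mag_mean, mag_sd, n_a_only)), floor)
    sign_a2 = rng.choice([-1.0, 1.0], size=n_a_only)
    flip = rng.random(n_a_only) < opposite_bias
    sign_b2 = np.where(flip, -sign_a2, sign_a2)
    mag_b2 = rng.uniform(thr, sub_sig_max, size=n_a_only)
    pa, pb = _sig_p(n_a_only), _ns_p(n_a_only)
    for i in range(n_a_only):
        rows.append((sign_a2[i] * mag_a[i], pa[i], sign_b2[i] * mag_b2[i], pb[i]))

    mag_b3 = np.maximum(np.abs(rng.normal(mag_mean, mag_sd, n_b_only)), floor)
    sign_b3 = rng.choice([-1.0, 1.0], size=n_b_only)
    l2a3 = rng.uniform(-thr * 0.9, thr * 0.9, size=n_b_only)
    pa, pb = _ns_p(n_b_only), _sig_p(n_b_only)
    for i in range(n_b_only):
        rows.append((l2a3[i], pa[i], sign_b3[i] * mag_b3[i], pb[i]))

    l2a4 = rng.uniform(-thr * 0.9, thr * 0.9, size=n_null)
    l2b4 = rng.uniform(-thr * 0.9, thr * 0.9, size=n_null)
    pa, pb = _ns_p(n_null), _ns_p(n_null)
    for i in range(n_null):
        rows.append((l2a4[i], pa[i], l2b4[i], pb[i]))

    df = pd.DataFrame(rows, columns=["log2fc_a", "padj_a", "log2fc_b", "padj_b"])
    df.insert(0, "gene", [f"gene{i + 1:05d}" for i in range(len(df))])
    return df
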
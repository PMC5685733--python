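"""Spike-in calibrator normalization.

Between-sample scaling factors are estimated with the weighted trimmed
mean of M-values (TMM; Robinson & Oshlack 2010) on the full calibrator
count matrix — the spike-ins, added at known equal input to every
library, carry the normalization instead of the biological counts. The
factors are then applied to the biological matrices through the
effective library size (library size x factor) in a counts-per-million
transform.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    sum_trim: float,
) -> float:
    """Scaling factor of one sample against the reference column."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / lib_obs) / (ref / lib_ref))
        abs_e = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2.0
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)  # drops zero-count cells
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    r_l = rankdata(log_r)
    r_s = rankdata(abs_e)
    keep = (r_l >= lo_l) & (r_l <= hi_l) & (r_s >= lo_s) & (r_s <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame,
    lib_sizes: pd.Series | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Weighted trimmed-mean-of-M-values factors, geometric mean 1.

    The reference is the sample whose 75th-percentile count fraction is
    closest to the mean of those fractions. M-values are trimmed by
    `logratio_trim` (total, both sides) and A-values by `sum_trim`, and
    the retained M-values are averaged with inverse-delta-method
    (precision) weights. Cells with a zero count in either sample are
    excluded from the M/A computation.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    if counts.shape[0] < 2:
        raise ValueError("TMM requires at least 2 features")
    x = counts.to_numpy(dtype=float)
    if lib_sizes is None:
        lib = x.sum(axis=0)
    else:
        lib = lib_sizes.reindex(counts.columns).to_numpy(dtype=float)
    zero = lib == 0
    if zero.any():
        bad = list(counts.columns[zero])
        raise ValueError(f"samples with all-zero calibrator counts: {bad}")

    f75 = np.percentile(x, 75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.array(
        [
            _tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], logratio_trim, sum_trim)
            for j in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def cpm_normalize(
    counts: pd.DataFrame,
    factors: pd.Series | None,
    lib_sizes: pd.Series,
) -> pd.DataFrame:
    """cpm[f, s] = count[f, s] / (lib_size[s] * factor[s]) * 1e6."""
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    eff = (
        lib_sizes.reindex(counts.columns).astype(float)
        * factors.reindex(counts.columns).astype(float)
    )
    if (eff <= 0).any() or eff.isna().any():
        bad = list(eff.index[(eff <= 0) | eff.isna()])
        raise ValueError(f"zero or undefined effective library size for samples: {bad}")
    return counts / eff * 1e6


def calibrator_qc(
    calibrator_cpm: pd.DataFrame,
    cv_threshold: float = 0.2,
    sample_log2_threshold: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-sample dispersion check on normalized calibrator cpm.

    Returns (per-calibrator table with CV and flag, per-sample table of
    calibrator totals with an outlier flag for samples whose total
    deviates from the cohort median by more than `sample_log2_threshold`
    in log2).
    """
    mean = calibrator_cpm.mean(axis=1)
    sd = calibrator_cpm.std(axis=1, ddof=1)
    cv = (sd / mean).fillna(0.0)
    per_cal = pd.DataFrame(
        {"mean_cpm": mean, "cv": cv, "flagged": cv > cv_threshold}
    )
    per_cal.index.name = "calibrator"

    totals = calibrator_cpm.sum(axis=0)
    med = totals.median()
    with np.errstate(divide="ignore"):
        dev = np.log2(totals / med)
    per_sample = pd.DataFrame(
        {"calibrator_cpm_total": totals, "log2_vs_median": dev,
         "flagged": np.abs(dev) > sample_log2_threshold}
    )
    per_sample.index.name = "sample"
    return per_cal, per_sample
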
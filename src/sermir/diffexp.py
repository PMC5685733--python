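"""Precision-weighted moderated differential expression.

Counts are transformed to log2-cpm with observation-level precision
weights derived from an empirical mean-variance trend (the voom
approach: Law et al. 2014), fitted per feature by weighted least
squares, and the residual variances are shrunk toward a common prior by
empirical Bayes before computing moderated t-statistics (Smyth 2004).
P-values are Benjamini-Hochberg adjusted.

Two study contrasts are built from the patient table:

* ``metastasis`` — patients sampled before any treatment, M1 vs M0;
* ``treatment`` — serum after preoperative chemoradiotherapy (CRT-only
  patients) vs serum before treatment, M1-at-diagnosis removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests


@dataclass
class ContrastSpec:
    name: str
    samples: list[str]
    groups: pd.Series  # sample -> group label (0/1 coded by `reference`)
    reference: str     # the baseline group label


def define_contrast(metadata: pd.DataFrame, name: str) -> ContrastSpec:
    """Build one of the two study contrasts from patient metadata."""
    if name == "metastasis":
        sub = metadata[metadata["serum_timing"] == "before"]
        groups = sub["m_stage"].map({"M0": "M0", "M1": "M1"})
        spec = ContrastSpec(name, list(sub.index), groups, reference="M0")
    elif name == "treatment":
        sub = metadata[metadata["m_stage"] != "M1"]
        before = sub["serum_timing"] == "before"
        after_crt = (sub["serum_timing"] == "after") & (sub["treatment"] == "crt")
        sub = sub[before | after_crt]
        groups = np.where(sub["serum_timing"] == "after", "after", "before")
        spec = ContrastSpec(
            name, list(sub.index), pd.Series(groups, index=sub.index), reference="before"
        )
    else:
        raise ValueError(f"unknown contrast {name!r}")
    counts = spec.groups.value_counts()
    if len(counts) < 2 or (counts == 0).any():
        raise ValueError(f"contrast {name!r} has an empty group: {counts.to_dict()}")
    return spec


def filter_by_expression(
    cpm: pd.DataFrame,
    min_cpm: float = 1.0,
    min_fraction: float = 0.5,
    require_all: bool = False,
    inclusive: bool = True,
) -> pd.Index:
    """Features passing the expression filter.

    With `inclusive`, a sample counts when cpm >= min_cpm ("at least");
    otherwise cpm > min_cpm (strict, as in "more than 100 cpm"). A
    feature is kept when the qualifying fraction of samples is strictly
    greater than `min_fraction` ("more than 50%"), or in every sample
    when `require_all`.
    """
    if min_cpm <= 0:
        raise ValueError("min_cpm must be positive")
    ok = cpm >= min_cpm if inclusive else cpm > min_cpm
    if require_all:
        keep = ok.all(axis=1)
    else:
        keep = ok.mean(axis=1) > min_fraction
    return cpm.index[keep]


def design_matrix(
    groups: pd.Series,
    reference: str,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Intercept + group indicator (+ optional numeric covariates)."""
    x = pd.DataFrame(
        {"intercept": 1.0, "group": (groups != reference).astype(float)},
        index=groups.index,
    )
    if covariates is not None:
        x = pd.concat([x, covariates.astype(float)], axis=1)
    return x


def voom_transform(
    counts: pd.DataFrame,
    lib_sizes: pd.Series,
    design: pd.DataFrame,
    span: float = 0.5,
):
    """Log2-cpm with observation precision weights from the fitted
    mean-variance trend.

    log2-cpm uses a 0.5 count offset and a +1 library offset. The trend
    is a lowess fit of sqrt(residual standard deviation) against mean
    log2 count; each observation's weight is the predicted standard
    deviation at its fitted log-count, raised to the power -4.

    Returns (logcpm DataFrame, weights DataFrame, trend DataFrame).
    """
    if counts.shape[1] < 3:
        raise ValueError("voom requires at least 3 samples")
    lib = lib_sizes.reindex(counts.columns).to_numpy(dtype=float) + 1.0
    y = np.log2((counts.to_numpy(dtype=float) + 0.5) / lib[None, :] * 1e6)
    x = design.to_numpy(dtype=float)
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("design matrix is not of full rank")

    pinv = np.linalg.pinv(x)
    beta = y @ pinv.T                      # genes x p
    fitted = beta @ x.T
    resid = y - fitted
    df_resid = n - p
    sigma = np.sqrt((resid ** 2).sum(axis=1) / df_resid)

    # mean-variance trend on the log2-count scale
    sx = y.mean(axis=1) + np.mean(np.log2(lib)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    trend = lowess(sy, sx, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]

    fitted_logcount = fitted + (np.mean(np.log2(lib)) - np.log2(1e6))
    pred_sqrt_sd = np.interp(fitted_logcount, tx, ty)
    pred_sqrt_sd = np.clip(pred_sqrt_sd, 1e-6, None)
    weights = pred_sqrt_sd ** -4

    logcpm = pd.DataFrame(y, index=counts.index, columns=counts.columns)
    w = pd.DataFrame(weights, index=counts.index, columns=counts.columns)
    trend_df = pd.DataFrame({"mean_log2_count": tx, "sqrt_sd": ty})
    return logcpm, w, trend_df


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F / inverse-chi-square prior to residual
    variances on the log scale. Returns (df_prior, s2_prior);
    df_prior is inf when the variances show no excess spread."""
    s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        df_prior = 2.0 * _trigamma_inverse(e_var)
        s2_prior = float(np.exp(e_mean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0)))
    else:
        df_prior = np.inf
        s2_prior = float(np.exp(e_mean))
    return df_prior, s2_prior


def fit_moderated(
    logcpm: pd.DataFrame,
    weights: pd.DataFrame,
    design: pd.DataFrame,
    coef: str = "group",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-feature weighted least squares with empirical-Bayes variance
    moderation.

    `coef` names the design column tested. `prior_df` overrides the
    estimated prior degrees of freedom (0 recovers the ordinary
    weighted t-test). Returns a DataFrame with log2 fold change,
    moderated t, raw and BH-adjusted p.
    """
    x = design.to_numpy(dtype=float)
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("design matrix is not of full rank")
    ci = list(design.columns).index(coef)
    y = logcpm.to_numpy(dtype=float)
    w = weights.to_numpy(dtype=float)
    g = y.shape[0]
    df_resid = n - p

    beta = np.empty(g)
    stdev_unscaled = np.empty(g)
    s2 = np.empty(g)
    for i in range(g):
        wi = w[i]
        xtwx = x.T @ (x * wi[:, None])
        xtwy = x.T @ (wi * y[i])
        xtwx_inv = np.linalg.inv(xtwx)
        b = xtwx_inv @ xtwy
        resid = y[i] - x @ b
        rss = float(np.sum(wi * resid ** 2))
        beta[i] = b[ci]
        stdev_unscaled[i] = np.sqrt(xtwx_inv[ci, ci])
        s2[i] = rss / df_resid

    if prior_df is None:
        df_prior, s2_prior = fit_f_dist(s2, df_resid)
    elif prior_df == 0:
        df_prior, s2_prior = 0.0, 0.0
    else:
        df_prior, s2_prior = float(prior_df), float(np.median(s2))

    if np.isinf(df_prior):
        s2_post = np.full(g, s2_prior)
        df_total = np.inf
    else:
        s2_post = (df_prior * s2_prior + df_resid * s2) / (df_prior + df_resid)
        df_total = df_resid + df_prior

    t = beta / (stdev_unscaled * np.sqrt(s2_post))
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)

    out = pd.DataFrame(
        {
            "lfc": beta,
            "t": t,
            "p": pvals,
            "p_adj": adjust_bh(pvals),
            "s2": s2,
            "s2_post": s2_post,
        },
        index=logcpm.index,
    )
    out.attrs["df_prior"] = df_prior
    out.attrs["s2_prior"] = s2_prior
    return out


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de(
    counts: pd.DataFrame,
    lib_sizes: pd.Series,
    norm_factors: pd.Series,
    contrast: ContrastSpec,
    min_cpm: float = 1.0,
    min_fraction: float = 0.5,
    require_all: bool = False,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Filter, voom-transform and test one contrast end to end.

    Filtering is applied to the cpm of the contrast's samples;
    normalization factors come from the calibrators. Group mean cpm
    columns are appended for reporting.
    """
    from .normalization import cpm_normalize

    samples = contrast.samples
    sub = counts[samples]
    eff = lib_sizes[samples] * norm_factors[samples]
    cpm = cpm_normalize(sub, norm_factors[samples], lib_sizes[samples])
    keep = filter_by_expression(cpm, min_cpm, min_fraction, require_all)
    sub = sub.loc[keep]

    design = design_matrix(
        contrast.groups[samples], contrast.reference,
        covariates.loc[samples] if covariates is not None else None,
    )
    logcpm, w, _ = voom_transform(sub, eff, design)
    res = fit_moderated(logcpm, w, design, coef="group")
    for grp in sorted(contrast.groups.unique()):
        cols = [s for s in samples if contrast.groups[s] == grp]
        res[f"mean_cpm_{grp}"] = cpm.loc[keep, cols].mean(axis=1)
    return res.sort_values("p")
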
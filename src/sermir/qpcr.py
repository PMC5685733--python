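"""Reference-gene stability (NormFinder) and qPCR relative quantification.

NormFinder (Andersen et al. 2004) decomposes log-scale expression —
after removing per-sample effects — into gene-by-group effects and
within-group variances. A candidate reference gene is stable when both
its between-group difference and its within-group variation are small;
the two are combined into a single stability value (smaller = more
stable). The qPCR arm implements the standard dCt chain: dCt against
the geometric mean of the internal control miRNAs, relative quantity
RQ = 2^(-dCt) averaged over cDNA-synthesis duplicates, fold change
between groups, and an unpaired equal-variance t-test on dCt.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

_VAR_FLOOR = 1e-12


def normfinder(
    log_expression: pd.DataFrame,
    groups: pd.Series,
) -> pd.DataFrame:
    """Model-based stability ranking for two groups.

    `log_expression` is genes x samples on a log2 scale (e.g. log2 cpm);
    `groups` labels each sample with one of exactly two groups.

    Per gene the estimate has three parts: `group_difference`, the
    shrunken between-group expression difference; `group_sd`, the pooled
    within-group standard deviation; and `stability`, the sum of the
    absolute shrunken difference and its posterior standard error —
    small only when the gene is both unshifted and quiet.
    """
    if log_expression.shape[0] < 2:
        raise ValueError("NormFinder needs at least 2 genes")
    labels = pd.unique(groups.reindex(log_expression.columns).dropna())
    if len(labels) != 2:
        raise ValueError("exactly two groups are required")
    n_genes = log_expression.shape[0]

    # remove per-sample effects (column centering across genes)
    z = log_expression - log_expression.mean(axis=0)

    means = {}
    sig2 = {}
    n_g = {}
    for g in labels:
        cols = groups.index[groups == g].intersection(log_expression.columns)
        if len(cols) < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples")
        sub = z[cols]
        n_g[g] = len(cols)
        means[g] = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        # column centering couples the genes; invert the induced bias
        if n_genes > 2:
            total = float(v.sum()) * n_genes / (n_genes - 1)
            sig2[g] = np.maximum((v - total / n_genes ** 2) / (1.0 - 2.0 / n_genes), _VAR_FLOOR)
        else:
            sig2[g] = np.maximum(v, _VAR_FLOOR)

    g1, g2 = labels
    delta = means[g1] - means[g2]
    u = sig2[g1] / n_g[g1] + sig2[g2] / n_g[g2]      # sampling variance of delta
    tau2 = max(float((delta ** 2).sum()) / max(n_genes - 1, 1) - float(u.mean()), 0.0)
    shrink = tau2 / (tau2 + u) if tau2 > 0 else 0.0 * u
    delta_tilde = delta * shrink
    post_var = u * shrink if tau2 > 0 else u * 0.0 + u  # posterior ~ u when no spread

    pooled_sd = np.sqrt(
        ((n_g[g1] - 1) * sig2[g1] + (n_g[g2] - 1) * sig2[g2]) / (n_g[g1] + n_g[g2] - 2)
    )
    stability = np.abs(delta_tilde) + np.sqrt(post_var)
    out = pd.DataFrame(
        {
            "group_difference": delta_tilde,
            "group_sd": pooled_sd,
            "stability": stability,
        },
        index=log_expression.index,
    )
    out.index.name = "gene"
    return out.sort_values("stability")


def select_references(
    de_results: pd.DataFrame,
    stability: pd.DataFrame,
    mean_expression: pd.Series,
    k: int = 3,
    min_expression: float = 100.0,
    min_de_padj: float = 0.5,
) -> list[str]:
    """Pick internal-control candidates: highly expressed, clearly not
    differentially expressed, most stable.

    `mean_expression` is mean cpm per gene; genes with BH-adjusted DE p
    below `min_de_padj` or expression below `min_expression` are
    excluded, the rest ranked by stability.
    """
    genes = stability.index.intersection(de_results.index).intersection(mean_expression.index)
    ok = genes[
        (de_results.loc[genes, "p_adj"] > min_de_padj)
        & (mean_expression.loc[genes] >= min_expression)
    ]
    if len(ok) == 0:
        raise ValueError("no reference-gene candidates pass the filters")
    ranked = stability.loc[ok].sort_values("stability")
    return list(ranked.index[:k])


def delta_ct(
    ct_table: pd.DataFrame,
    target: str,
    controls: list[str],
    control_mean: str = "geometric",
) -> pd.DataFrame:
    """Per-sample dCt and RQ for one target miRNA.

    dCt = Ct(target) - mean of the control Cts per (sample, replicate);
    the control mean is the geometric mean of the Ct numbers by default
    (arithmetic available — Ct is already log scale, so the two differ
    negligibly for Cts in a narrow range). RQ = 2^(-dCt), averaged over
    cDNA-synthesis duplicates. Samples missing any Ct are dropped.
    """
    missing = [c for c in controls if c not in set(ct_table["gene"])]
    if missing or target not in set(ct_table["gene"]):
        raise ValueError(f"genes absent from the Ct table: {missing or [target]}")
    wide = ct_table.pivot_table(
        index=["sample", "group", "replicate"], columns="gene", values="Ct"
    )
    wide = wide.dropna(subset=[target] + controls)
    ctrl = wide[controls]
    if control_mean == "geometric":
        ref = np.exp(np.log(ctrl).mean(axis=1))
    elif control_mean == "arithmetic":
        ref = ctrl.mean(axis=1)
    else:
        raise ValueError("control_mean must be 'geometric' or 'arithmetic'")
    dct = wide[target] - ref
    per_rep = pd.DataFrame({"delta_ct": dct, "rq": 2.0 ** (-dct)})
    out = (
        per_rep.groupby(level=["sample", "group"])
        .agg(delta_ct=("delta_ct", "mean"), rq=("rq", "mean"))
        .reset_index()
    )
    return out


def qpcr_compare(
    per_sample: pd.DataFrame,
    group_col: str = "group",
    case_group: str = "metastatic",
) -> dict[str, float]:
    """Fold change and unpaired Student's t-test between two groups.

    Fold change is mean RQ(case) / mean RQ(control); the t-test is
    two-sided, equal variance, on the dCt values (log scale).
    """
    groups = pd.unique(per_sample[group_col])
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    other = [g for g in groups if g != case_group]
    if len(other) != 1:
        raise ValueError(f"case group {case_group!r} not found")
    control_group = other[0]
    case = per_sample[per_sample[group_col] == case_group]
    ctrl = per_sample[per_sample[group_col] == control_group]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("both groups need at least 2 samples")
    denom = ctrl["rq"].mean()
    if denom <= 0:
        raise ValueError("control-group mean RQ is zero")
    fold = case["rq"].mean() / denom
    t, p = stats.ttest_ind(case["delta_ct"], ctrl["delta_ct"], equal_var=True)
    return {"fold_change": float(fold), "t": float(t), "p": float(p)}
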
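"""Survival screening of serum small-RNA features.

Each candidate feature is dichotomized at its median cpm and entered in
a Cox proportional-hazards model (Efron tie handling) together with
age, sex and metastasis status; Wald p-values of the expression term
are Bonferroni-corrected over the features tested. Kaplan-Meier
product-limit curves (expression x metastasis, four groups) accompany
each hit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test


def km_estimator(times, events, groups=None):
    """Product-limit survival curves per group plus a log-rank test.

    Returns (curves, logrank_p): curves is a DataFrame with columns
    group / time / survival / at_risk / censored.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("survival times must be non-negative")
    if groups is None:
        groups = np.array(["all"] * len(times))
    else:
        groups = np.asarray(groups)

    frames = []
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        tbl = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        frames.append(
            pd.DataFrame(
                {
                    "group": str(g),
                    "time": surv.index.to_numpy(),
                    "survival": surv.to_numpy(),
                    "at_risk": tbl["at_risk"].to_numpy(),
                    "censored": tbl["censored"].to_numpy(),
                }
            )
        )
    curves = pd.concat(frames, ignore_index=True)
    if len(pd.unique(groups)) > 1:
        lr = multivariate_logrank_test(times, groups, events)
        p = float(lr.p_value)
    else:
        p = float("nan")
    return curves, p


def dichotomize(values: pd.Series) -> tuple[pd.Series, float]:
    """Median split into high/low labels; ties at the median go low.

    Returns (labels, cutpoint). A constant vector cannot be split.
    """
    v = pd.Series(values).astype(float)
    if len(v) < 4:
        raise ValueError("need at least 4 observations to dichotomize")
    if v.nunique() == 1:
        raise ValueError("cannot dichotomize a constant vector")
    cut = float(v.median())
    labels = pd.Series(np.where(v > cut, "high", "low"), index=v.index)
    return labels, cut


def cox_fit(
    data: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties) via partial likelihood.

    Returns a per-covariate table with coefficient, hazard ratio,
    standard error and Wald p. Monotone-likelihood / non-convergent
    fits raise lifelines' ConvergenceError to the caller.
    """
    cols = [duration_col, event_col] + (covariates or [c for c in data.columns if c not in (duration_col, event_col)])
    df = data[cols].astype(float)
    if df[event_col].sum() < 1:
        raise ValueError("at least one event is required")
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(
            df, duration_col=duration_col, event_col=event_col,
            fit_options={"precision": 1e-9, "max_steps": 500},
        )
        for w in caught:
            if issubclass(w.category, ConvergenceWarning) and "failed to converge" in str(w.message):
                converged = False
    out = cph.summary[["coef", "exp(coef)", "se(coef)", "p"]].copy()
    out.columns = ["coef", "hr", "se", "p"]
    # |coef| running away with a huge SE marks a monotone likelihood
    out["flag"] = np.where(
        ~np.isfinite(out["coef"]) | (np.abs(out["coef"]) > 15),
        "infinite-coefficient",
        "" if converged else "non-converged",
    )
    return out


def bonferroni(pvalues, m: int | None = None) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    m = m if m is not None else p.size
    return np.minimum(1.0, p * m)


def survival_screen(
    cpm: pd.DataFrame,
    metadata: pd.DataFrame,
    min_cpm: float = 100.0,
    min_fraction: float = 0.5,
    adjust_for_metastasis: bool = True,
    expression: str = "dichotomized",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Screen features for association with overall survival.

    Features passing the conservative filter (cpm strictly above
    `min_cpm` in strictly more than `min_fraction` of samples) are each
    fit in a Cox model: expression (median-dichotomized by default, or
    continuous log2 cpm) + age + sex (+ M1 status). P-values of the
    expression term are Bonferroni-corrected over the features tested.
    Per-feature fit failures are recorded and the screen continues.

    Returns (screen table, km_curves): km_curves holds four-group
    (expression x metastasis) Kaplan-Meier curves for each feature
    significant at `alpha` after correction.
    """
    from .diffexp import filter_by_expression

    samples = [s for s in cpm.columns if s in metadata.index]
    cpm = cpm[samples]
    meta = metadata.loc[samples]
    keep = filter_by_expression(cpm, min_cpm, min_fraction, inclusive=False)

    base = pd.DataFrame(
        {
            "time": meta["os_months"].astype(float),
            "event": meta["os_event"].astype(int),
            "age": meta["age"].astype(float),
            "sex": (meta["sex"] == "male").astype(float),
        },
        index=meta.index,
    )
    if adjust_for_metastasis:
        base["m1"] = (meta["m_stage"] == "M1").astype(float)

    rows = []
    curves: dict[str, pd.DataFrame] = {}
    for feat in keep:
        expr = cpm.loc[feat]
        row = {"feature": feat, "hr": np.nan, "p": np.nan, "cutpoint": np.nan, "error": ""}
        try:
            df = base.copy()
            if expression == "dichotomized":
                labels, cut = dichotomize(expr)
                df["expr"] = (labels == "high").astype(float)
                row["cutpoint"] = cut
            else:
                df["expr"] = np.log2(expr + 0.5)
            fit = cox_fit(df, covariates=["expr", "age", "sex"] + (["m1"] if adjust_for_metastasis else []))
            row["hr"] = fit.loc["expr", "hr"]
            row["p"] = fit.loc["expr", "p"]
            row["error"] = fit.loc["expr", "flag"]
        except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
            row["error"] = str(exc)[:120]
        rows.append(row)

    screen = pd.DataFrame(rows, columns=["feature", "hr", "p", "cutpoint", "error"])
    m = len(screen)
    screen["p_bonf"] = bonferroni(screen["p"].to_numpy(), m) if m else []
    screen = screen.set_index("feature").sort_values("p")

    for feat, row in screen.iterrows():
        if not (row["p_bonf"] <= alpha):
            continue
        labels, _ = dichotomize(cpm.loc[feat])
        if adjust_for_metastasis:
            grp = labels + "/" + np.where(meta["m_stage"] == "M1", "M1", "M0")
        else:
            grp = labels
        curves[feat], _ = km_estimator(base["time"], base["event"], grp)
    return screen, curves
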
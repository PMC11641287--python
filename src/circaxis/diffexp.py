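"""Tumor-vs-normal differential expression with multiplicity control.

The base contrast is a two-sided Welch t-test (unpaired) or a paired
t-test on within-pair tumor-minus-normal differences.  With few arrays per
group a per-feature variance estimate is unstable, so by default the
per-feature variances are shrunk toward a common prior fitted across all
features by empirical Bayes (the standard moderated-t construction for
microarray data); set ``moderated=False`` for the classical tests.

Fold changes are differences of group means on the log2 scale, tumor minus
normal, so negative values mean lower expression in tumors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import GROUP_NORMAL, GROUP_TUMOR, ExpressionMatrix, SampleDesign

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NS = "ns"

#: smallest reported p value, used when a feature has zero residual
#: variance but a nonzero mean difference
_P_FLOOR = float(np.nextafter(0.0, 1.0))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values.

    Inputs must lie in (0, 1]; the output is monotone over the sorted
    inputs, elementwise >= the raw p, and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ModeratedPrior:
    """Fitted inverse-chi-square prior for per-feature variances."""

    df_prior: float  # may be inf when variances look homogeneous
    var_prior: float


def _fit_variance_prior(variances: np.ndarray, df_resid: float) -> ModeratedPrior:
    """Method-of-moments fit of (d0, s0^2) from per-feature sample variances.

    Follows the classic hierarchical model: s_g^2 | sigma_g^2 scaled
    chi-square with df_resid, sigma_g^{-2} scaled chi-square with d0.
    Solved on the log scale via digamma/trigamma moments.
    """
    s2 = variances[np.isfinite(variances) & (variances > 0)]
    if s2.size < 3:
        return ModeratedPrior(df_prior=0.0, var_prior=float("nan"))
    z = np.log(s2)
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.sum((e - e_mean) ** 2) / (e.size - 1))
    target = e_var - special.polygamma(1, df_resid / 2.0)
    if target <= 0:
        # observed spread no larger than sampling noise: infinite prior df
        return ModeratedPrior(df_prior=np.inf, var_prior=float(np.exp(e_mean)))
    # invert trigamma(d0/2) = target by bisection on d0 in (0, 1e8)
    lo, hi = 1e-8, 1e8
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if special.polygamma(1, mid / 2.0) > target:
            lo = mid
        else:
            hi = mid
    d0 = float(np.sqrt(lo * hi))
    s0 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModeratedPrior(df_prior=d0, var_prior=s0)


def _moderate(variances: np.ndarray, df_resid: float, prior: ModeratedPrior):
    """Posterior variances and total df under the fitted prior."""
    if prior.df_prior == 0.0 or not np.isfinite(prior.var_prior):
        return variances, np.full_like(variances, df_resid)
    if np.isinf(prior.df_prior):
        post = np.full_like(variances, prior.var_prior)
        df_total = np.full_like(variances, 1e6)  # effectively a z test
        return post, df_total
    post = (prior.df_prior * prior.var_prior + df_resid * variances) / (
        prior.df_prior + df_resid
    )
    return post, np.full_like(variances, prior.df_prior + df_resid)


def differential_expression(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    mode: str = "auto",
    alpha: float = 0.05,
    lfc_min: float = 0.0,
    moderated: bool = True,
) -> pd.DataFrame:
    """Per-feature tumor-vs-normal contrast.

    Parameters
    ----------
    mode
        ``"paired"``, ``"unpaired"`` or ``"auto"`` (paired when the design
        carries pair ids, else unpaired).
    alpha
        Significance level applied to the BH-adjusted p value when calling
        direction.
    lfc_min
        Minimum |log2 fold change| additionally required for an up/down call.
    moderated
        Shrink per-feature variances toward an empirical-Bayes prior fitted
        across features.  Requires >= 3 features; otherwise the classical
        test is used.

    Returns
    -------
    DataFrame indexed by feature id with columns ``log2fc``, ``t``, ``p``,
    ``fdr``, ``direction`` and ``flagged`` (True where zero residual
    variance forced the p floor).
    """
    if mode == "auto":
        mode = "paired" if design.is_paired else "unpaired"
    if mode not in ("paired", "unpaired"):
        raise ValueError(f"unknown mode {mode!r}")

    values = matrix.values
    # features with missing values in the tested samples are dropped, not imputed
    tested = values.dropna(axis=0, how="any")

    if mode == "paired":
        if design.pairs is None:
            raise ValueError("paired mode requires pair ids in the design")
        pair_ids = sorted(set(design.pairs))
        tumor_cols, normal_cols = [], []
        for pid in pair_ids:
            members = design.pairs.index[design.pairs == pid]
            t = [s for s in members if design.groups[s] == GROUP_TUMOR]
            n = [s for s in members if design.groups[s] == GROUP_NORMAL]
            if t and n and t[0] in tested.columns and n[0] in tested.columns:
                tumor_cols.append(t[0])
                normal_cols.append(n[0])
        if len(tumor_cols) < 2:
            raise ValueError("paired mode needs at least 2 complete pairs")
        diffs = tested[tumor_cols].to_numpy() - tested[normal_cols].to_numpy()
        n = diffs.shape[1]
        log2fc = diffs.mean(axis=1)
        var = diffs.var(axis=1, ddof=1)
        df_resid = float(n - 1)
        se2_scale = 1.0 / n
    else:
        tumor = [s for s in design.samples_in(GROUP_TUMOR) if s in tested.columns]
        normal = [s for s in design.samples_in(GROUP_NORMAL) if s in tested.columns]
        if len(tumor) < 2 or len(normal) < 2:
            raise ValueError("unpaired mode needs >= 2 samples per group")
        xt = tested[tumor].to_numpy()
        xn = tested[normal].to_numpy()
        log2fc = xt.mean(axis=1) - xn.mean(axis=1)
        if moderated and tested.shape[0] >= 3:
            # pooled-variance contrast, as required for cross-feature shrinkage
            n1, n2 = xt.shape[1], xn.shape[1]
            df_resid = float(n1 + n2 - 2)
            var = (
                xt.var(axis=1, ddof=1) * (n1 - 1) + xn.var(axis=1, ddof=1) * (n2 - 1)
            ) / df_resid
            se2_scale = 1.0 / n1 + 1.0 / n2
        else:
            t_stat, p = stats.ttest_ind(xt, xn, axis=1, equal_var=False)
            t_stat = np.asarray(t_stat, dtype=float)
            p = np.asarray(p, dtype=float)
            zero_var = ~np.isfinite(p) | ~np.isfinite(t_stat) | (p == 0.0)
            flagged = zero_var & (log2fc != 0)
            p[flagged] = _P_FLOOR
            t_stat[flagged] = np.sign(log2fc[flagged]) * np.inf
            p[zero_var & (log2fc == 0)] = 1.0
            t_stat[zero_var & (log2fc == 0)] = 0.0
            return _finish(tested.index, log2fc, t_stat, p, alpha, lfc_min, flagged)

    if moderated and tested.shape[0] >= 3:
        prior = _fit_variance_prior(var, df_resid)
        var_post, df_total = _moderate(var, df_resid, prior)
    else:
        var_post, df_total = var, np.full_like(var, df_resid)

    se = np.sqrt(var_post * se2_scale)
    flagged = (se == 0) & (log2fc != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
    p = np.where(flagged, _P_FLOOR, p)
    with np.errstate(invalid="ignore"):
        t_stat = np.where(flagged, np.sign(log2fc) * np.inf, t_stat)
    p = np.where((se == 0) & (log2fc == 0), 1.0, p)
    return _finish(tested.index, log2fc, t_stat, p, alpha, lfc_min, flagged)


def _finish(index, log2fc, t_stat, p, alpha, lfc_min, flagged=None):
    p = np.clip(p, _P_FLOOR, 1.0)
    fdr = benjamini_hochberg(p)
    direction = np.full(len(p), DIRECTION_NS, dtype=object)
    sig = (fdr <= alpha) & (np.abs(log2fc) >= max(lfc_min, np.finfo(float).tiny))
    direction[sig & (log2fc > 0)] = DIRECTION_UP
    direction[sig & (log2fc < 0)] = DIRECTION_DOWN
    if flagged is None:
        flagged = np.zeros(len(p), dtype=bool)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t_stat,
            "p": p,
            "fdr": fdr,
            "direction": direction,
            "flagged": flagged,
        },
        index=pd.Index(index, name="feature_id"),
    )


def write_de_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index_label="feature_id")


def read_de_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")
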
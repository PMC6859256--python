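"""Differential expression (empirical-Bayes moderated t) and correlation
screening.

The moderated t follows the standard empirical-Bayes treatment of per-gene
variances: with residual variance s_g^2 on d degrees of freedom per
feature, a scaled inverse-chi-square prior with hyperparameters
(d0, s0^2) is fitted to the ensemble of s_g^2 by moment matching on the
log scale (digamma/trigamma equations), giving shrunken variances

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

and the moderated statistic

    t_g = logFC_g / (s~_g * sqrt(1/n1 + 1/n2))

on d0 + d degrees of freedom. p-values are two-sided; multiplicity is
controlled by Benjamini-Hochberg FDR.

Correlation screening computes Pearson or Spearman r for every
(feature, covariate) pair over shared, pairwise-complete samples and
reports only pairs with |r| strictly greater than a threshold
(default 0.5).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

from trnafrag.normfilter import NormalizedMatrix

logger = logging.getLogger(__name__)

D0_CAP = 1e6  # prior df cap when moment matching diverges (homogeneous variances)

DE_COLUMNS = ["feature_id", "logFC", "t_mod", "p", "fdr", "mean_group1", "mean_group2"]


@dataclass(frozen=True)
class CorrelationResult:
    feature_id: str
    covariate_id: str
    method: str
    r: float
    n: int
    p: float


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Monotone decreasing target; the Newton step on the reciprocal scale
    converges from the starting value 0.5 + 1/y for all y > 0.
    """
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F distribution to sample variances.

    Given residual variances ``s2`` each on ``df`` degrees of freedom,
    estimate the prior degrees of freedom d0 and prior variance s0^2 of a
    scaled inverse-chi-square variance prior, by matching the mean and
    variance of log(s2). Returns (d0, s0_squared); when the observed
    spread of log variances does not exceed the sampling spread
    (homogeneous variances), d0 is capped at a large finite value with a
    warning.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive variances to fit the prior")
    if not ok.all():
        logger.warning(
            "%d zero variances excluded from prior fitting", int((~ok).sum())
        )
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        warnings.warn(
            "log-variance spread does not exceed sampling noise; "
            f"prior df capped at {D0_CAP:g}",
            RuntimeWarning,
            stacklevel=2,
        )
        d0 = D0_CAP
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


def moderated_t_de(
    expr: NormalizedMatrix | pd.DataFrame,
    groups: pd.Series | dict,
    contrast: tuple[str, str] | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated-t differential expression.

    Parameters
    ----------
    expr
        log2-scale expression (features x samples); log2(TPM+1) by default
        in the pipeline. A NormalizedMatrix is accepted for convenience
        (its values are used as passed — transform beforehand).
    groups
        Sample -> label mapping; exactly two levels used.
    contrast
        ``(group1, group2)``; logFC = mean(group2) - mean(group1). Defaults
        to the two labels in sorted order.
    prior_df
        Override the estimated prior degrees of freedom d0 (0 recovers the
        ordinary pooled t; numpy.inf pins every denominator at s0^2).

    Returns a tidy DataFrame with one row per feature: logFC, t_mod, raw p,
    BH-adjusted fdr and group means, ordered as the input features.
    """
    values = expr.values if isinstance(expr, NormalizedMatrix) else expr
    groups = pd.Series(groups)
    levels = sorted(groups.unique()) if contrast is None else list(contrast)
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    g1 = [s for s in values.columns if groups.get(s) == levels[0]]
    g2 = [s for s in values.columns if groups.get(s) == levels[1]]
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")

    x1 = values[g1].to_numpy(dtype=float)
    x2 = values[g2].to_numpy(dtype=float)
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    logfc = m2 - m1
    df_resid = n1 + n2 - 2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    d0, s0_sq = fit_f_dist(s2, df_resid)
    if prior_df is not None:
        d0 = float(prior_df)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, logfc / se, np.where(logfc == 0, 0.0, np.inf * np.sign(logfc)))
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * sps.t.sf(np.abs(t_mod), df=df_total)
    fdr = bh_adjust(p)

    out = pd.DataFrame(
        {
            "feature_id": values.index,
            "logFC": logfc,
            "t_mod": t_mod,
            "p": p,
            "fdr": fdr,
            "mean_group1": m1,
            "mean_group2": m2,
        }
    )
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    out.attrs["df_resid"] = df_resid
    out.attrs["contrast"] = tuple(levels)
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (capped at 1,
    cumulative-minimum monotone, order-stable)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_de(
    results: pd.DataFrame, max_p: float, min_abs_logFC: float
) -> pd.DataFrame:
    """Keep features with fdr <= max_p and |logFC| >= min_abs_logFC."""
    if not (np.isfinite(max_p) and np.isfinite(min_abs_logFC)):
        raise ValueError("thresholds must be finite")
    keep = (results["fdr"] <= max_p) & (results["logFC"].abs() >= min_abs_logFC)
    return results.loc[keep].copy()


def correlate(
    expr: NormalizedMatrix | pd.DataFrame,
    covariates: pd.DataFrame,
    method: str = "pearson",
    min_abs_r: float = 0.5,
) -> tuple[list[CorrelationResult], list[tuple[str, str, str]]]:
    """Screen feature-covariate correlations, reporting |r| > min_abs_r.

    Both inputs are features/covariates x samples; samples are matched by
    name and each pair uses its pairwise-complete samples (>= 3 required
    overall). Spearman uses average ranks for ties; p-values come from the
    t-transform of r. The threshold is strict (> not >=).

    Returns ``(results, skipped)`` where ``skipped`` lists
    ``(feature, covariate, reason)`` diagnostics for undefined pairs
    (zero variance or too few complete observations).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    values = expr.values if isinstance(expr, NormalizedMatrix) else expr
    shared = [s for s in values.columns if s in covariates.columns]
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared samples, found {len(shared)}"
        )
    x = values[shared]
    y = covariates[shared]
    results: list[CorrelationResult] = []
    skipped: list[tuple[str, str, str]] = []
    for fid, frow in x.iterrows():
        fv = frow.to_numpy(dtype=float)
        for cid, crow in y.iterrows():
            cv = crow.to_numpy(dtype=float)
            ok = np.isfinite(fv) & np.isfinite(cv)
            n = int(ok.sum())
            if n < 3:
                skipped.append((fid, cid, f"only {n} complete paired samples"))
                continue
            a, b = fv[ok], cv[ok]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                skipped.append((fid, cid, "zero variance"))
                continue
            if method == "pearson":
                r, p = sps.pearsonr(a, b)
            else:
                r, p = sps.spearmanr(a, b)
            if abs(r) > min_abs_r:
                results.append(
                    CorrelationResult(
                        feature_id=str(fid),
                        covariate_id=str(cid),
                        method=method,
                        r=float(r),
                        n=n,
                        p=float(p),
                    )
                )
    return results, skipped


def correlation_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tidy DataFrame view of a correlation screen."""
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "covariate_id": r.covariate_id,
                "method": r.method,
                "r": r.r,
                "n": r.n,
                "p": r.p,
            }
            for r in results
        ],
        columns=["feature_id", "covariate_id", "method", "r", "n", "p"],
    )
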
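"""Per-feature inference of reduced heterologous hybridization.

A feature's replicate M values are summarized by their mean and variance; the
variances are shrunk toward a pooled prior by empirical Bayes (scaled-F /
inverse-chi-square model, hyperparameters estimated by matching the first two
moments of log s^2), giving a moderated t statistic with augmented degrees of
freedom.  Two-sided p-values are corrected by Benjamini-Hochberg, and a
feature is called diverged when its q-value clears a threshold *and* its mean
M is negative (reduced hybridization in the heterologous species).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import AnalysisError
from .preprocess import RatioMatrix

DEFAULT_THRESHOLDS = (0.1, 0.05, 0.01)


def fit_feature_stats(rm: RatioMatrix) -> pd.DataFrame:
    """Mean, unbiased variance and replicate count of usable M values.

    Features with fewer than two usable observations get NaN statistics (they
    are reported, never silently dropped).
    """
    if rm.M.size == 0:
        raise AnalysisError("empty ratio matrix")
    vals = rm.M.to_numpy(dtype=float)
    n_used = np.sum(~np.isnan(vals), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals, axis=1)
        s2 = np.nanvar(vals, axis=1, ddof=1)
    bad = n_used < 2
    mean[bad] = np.nan
    s2[bad] = np.nan
    return pd.DataFrame(
        {"n_used": n_used, "mean_M": mean, "s2": s2}, index=rm.M.index
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iterations on 1/trigamma)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the inverse-chi-square variance prior.

    Moment matching on z = log(s^2): under s^2 ~ s0^2 * F(df, d0),
    E[z] = log(s0^2) + psi(df/2) - log(df/2) - psi(d0/2) + log(d0/2) and
    Var[z] = psi'(df/2) + psi'(d0/2).  When the observed dispersion of z does
    not exceed the chi-square expectation, d0 is infinite and every posterior
    variance equals s0^2 (taken as the geometric mean of the sample
    variances).
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df >= 1)
    if ok.sum() < 2:
        raise AnalysisError("need at least two positive sample variances")
    s2, df = s2[ok], df[ok].astype(float)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        if z.var(ddof=1) < 1e-12:
            # exactly degenerate variances contradict the chi-square sampling
            # model; the common value is the only sensible prior
            s0_2 = float(np.exp(z.mean()))
        else:
            s0_2 = float(np.exp(emean))
    return float(d0), s0_2


@dataclass
class ModeratedStats:
    """Per-feature moderated statistics plus the global variance prior."""

    table: pd.DataFrame  # n_used mean_M s2 s2_post t_mod p
    d0: float
    s0_2: float


def shrink_variances(stats_df: pd.DataFrame, d0: float | None = None) -> ModeratedStats:
    """Shrink per-feature variances toward the pooled prior and test means.

    ``d0`` may be forced (e.g. ``np.inf`` for complete pooling); by default
    the hyperparameters are estimated from the data.  If estimation fails,
    falls back to unmoderated statistics with a warning.
    """
    n = stats_df["n_used"].to_numpy(dtype=float)
    mean = stats_df["mean_M"].to_numpy(dtype=float)
    s2 = stats_df["s2"].to_numpy(dtype=float)
    df = np.maximum(n - 1.0, 0.0)

    try:
        d0_est, s0_2 = estimate_prior(s2, df)
    except AnalysisError:
        warnings.warn("variance prior estimation failed; using unmoderated variances")
        d0_est, s0_2 = 0.0, np.nan
    if d0 is not None:
        d0_est = float(d0)
        if not np.isfinite(d0_est) and not np.isfinite(s0_2):
            s0_2 = float(np.exp(np.nanmean(np.log(s2[s2 > 0]))))

    with np.errstate(invalid="ignore", divide="ignore"):
        if np.isinf(d0_est):
            s2_post = np.where(df >= 1, s0_2, np.nan)
        elif d0_est == 0.0:
            s2_post = s2.copy()
        else:
            s2_post = (d0_est * s0_2 + df * s2) / (d0_est + df)
        se = np.sqrt(s2_post / n)
        t = np.where(se > 0, mean / se, np.where(mean == 0, 0.0, np.sign(mean) * np.inf))
        df_total = d0_est + df
        p = np.full_like(mean, np.nan)
        valid = (df >= 1) & np.isfinite(mean)
        finite_t = valid & np.isfinite(t)
        p[finite_t] = 2.0 * stats.t.sf(np.abs(t[finite_t]), df_total[finite_t])
        p[valid & np.isinf(t)] = 0.0
    table = stats_df.copy()
    table["s2_post"] = s2_post
    table["t_mod"] = t
    table["p"] = p
    return ModeratedStats(table=table, d0=d0_est, s0_2=s0_2)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, ties preserved)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise AnalysisError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise AnalysisError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_diverged(
    mstats: ModeratedStats, thresholds=DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Directional divergence calls at each q threshold.

    BH correction is applied over features with a defined p-value.  A feature
    is diverged at alpha iff q < alpha and mean_M < 0; nondirectional
    significance flags are emitted alongside.
    """
    table = mstats.table.copy()
    q = np.full(len(table), np.nan)
    valid = table["p"].notna().to_numpy()
    if valid.any():
        q[valid] = bh_fdr(table["p"].to_numpy()[valid])
    table["q"] = q
    neg = table["mean_M"].to_numpy() < 0
    for alpha in sorted(thresholds, reverse=True):
        pct = alpha * 100
        tag = f"q{int(round(pct)):02d}" if pct >= 1 else f"q{pct:g}"
        table[f"significant_{tag}"] = (q < alpha) & valid
        table[f"diverged_{tag}"] = (q < alpha) & valid & neg
    return table
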
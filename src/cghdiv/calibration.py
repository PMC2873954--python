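"""Calibration of hybridization ratio against sequence divergence.

Quantifies how well the array recovers true divergence: moving-window
detection curves over %ID, a logistic fit giving the ID-50 detection limit
(the %ID at which a feature has a 50% chance of being called diverged), the
linear regression of mean M on %ID, a hybridization-kinetics regression with
sequence covariates, robust partitioning of technical vs kinetics variance,
and a replication power analysis over array subsets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .detection import call_diverged, fit_feature_stats, shrink_variances
from .errors import AnalysisError

#: Consistency factor of the median-absolute-residual scale estimator for the
#: normal distribution (the 0.75 standard-normal quantile).
MAD_CONSISTENCY = 0.6745


def robust_sd(residuals) -> float:
    """Robust scale: median absolute residual divided by 0.6745.

    Residuals are taken as already centered (deviations from a regression
    line); for normal residuals the estimate is consistent for their SD.
    """
    r = np.asarray(residuals, dtype=float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        return np.nan
    return float(np.median(np.abs(r)) / MAD_CONSISTENCY)


# --------------------------------------------------------------------------
# detection curve and ID-50

def detection_curve(
    calls: pd.DataFrame,
    pct_id: pd.Series,
    window: int = 51,
    lowess_frac: float = 0.3,
) -> pd.DataFrame:
    """Moving-window fraction of diverged calls along %ID, per threshold.

    ``calls`` is the table from :func:`cghdiv.detection.call_diverged`;
    features without a %ID (no BLAST hit) or without a q-value are excluded.
    The window center is the mean %ID of the window; a lowess smooth of the
    window fractions is attached per threshold.
    """
    if window % 2 == 0:
        raise AnalysisError("window must be odd")
    div_cols = [c for c in calls.columns if c.startswith("diverged_")]
    keep = calls["q"].notna() & pct_id.reindex(calls.index).notna()
    sub = calls.loc[keep, div_cols].astype(float)
    ids = pct_id.reindex(calls.index)[keep]
    n = len(sub)
    if n < window:
        raise AnalysisError(f"need at least window={window} features with %ID (got {n})")
    order = np.argsort(ids.to_numpy(), kind="mergesort")
    ids_sorted = ids.to_numpy()[order]
    kernel_mean = lambda x: np.convolve(x, np.ones(window) / window, mode="valid")
    out = {"center_pct_id": kernel_mean(ids_sorted)}
    for col in div_cols:
        frac = kernel_mean(sub[col].to_numpy()[order])
        out[f"frac_{col[len('diverged_'):]}"] = frac
    df = pd.DataFrame(out)
    for col in list(df.columns[1:]):
        if len(df) < 5:  # nothing to smooth
            df[f"smooth_{col[len('frac_'):]}"] = df[col]
            continue
        sm_fit = lowess(
            df[col].to_numpy(), df["center_pct_id"].to_numpy(),
            frac=lowess_frac, it=0, return_sorted=True,
        )
        df[f"smooth_{col[len('frac_'):]}"] = np.interp(
            df["center_pct_id"], sm_fit[:, 0], sm_fit[:, 1]
        )
    return df


@dataclass
class Id50Fit:
    intercept: float
    slope: float
    id50: float
    status: str  # ok | out_of_range_high | out_of_range_low | separation
    n: int


def fit_id50(
    diverged, pct_id, id_range: tuple[float, float] = (60.0, 100.0)
) -> Id50Fit:
    """Binomial-logit regression of per-feature diverged calls on %ID.

    ID-50 is the %ID where the fitted probability crosses 0.5.  If the fit
    never crosses 0.5 inside ``id_range`` the estimate is flagged
    out-of-range with its side; complete separation yields a boundary
    estimate with status ``separation``.
    """
    y = np.asarray(diverged, dtype=float)
    x = np.asarray(pct_id, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    n = y.size
    lo, hi = id_range
    if n == 0:
        raise AnalysisError("no observations for logistic fit")
    if y.min() == y.max():
        status = "out_of_range_high" if y[0] == 1.0 else "out_of_range_low"
        return Id50Fit(np.nan, np.nan, np.nan, status, n)
    X = sm.add_constant(x)
    with warnings.catch_warnings(), np.errstate(over="ignore"):
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-10, maxiter=200)
            b0, b1 = fit.params
        except (PerfectSeparationError, PerfectSeparationWarning):
            gap_lo = x[y == 1].max() if x[y == 1].max() < x[y == 0].min() else x[y == 0].max()
            gap_hi = x[y == 0].min() if x[y == 1].max() < x[y == 0].min() else x[y == 1].min()
            return Id50Fit(np.nan, np.nan, float((gap_lo + gap_hi) / 2.0), "separation", n)
    if b1 == 0:
        return Id50Fit(float(b0), 0.0, np.nan, "out_of_range_high" if b0 > 0 else "out_of_range_low", n)
    id50 = -b0 / b1
    if not lo <= id50 <= hi:
        p_hi = 1.0 / (1.0 + np.exp(-(b0 + b1 * hi)))
        side = "out_of_range_high" if p_hi > 0.5 else "out_of_range_low"
        return Id50Fit(float(b0), float(b1), float(id50), side, n)
    return Id50Fit(float(b0), float(b1), float(id50), "ok", n)


# --------------------------------------------------------------------------
# regressions

@dataclass
class LinRegResult:
    slope: float
    intercept: float
    r2: float
    slope_se: float
    p: float
    n: int


def linreg_ratio_id(mean_m, pct_id) -> LinRegResult:
    """Ordinary least squares of mean M on %ID."""
    y = np.asarray(mean_m, dtype=float)
    x = np.asarray(pct_id, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    if y.size < 3:
        raise AnalysisError("need at least 3 features for the ratio~%ID regression")
    if np.ptp(x) == 0:
        raise AnalysisError("zero variance in %ID")
    res = sps.linregress(x, y)
    return LinRegResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        slope_se=float(res.stderr),
        p=float(res.pvalue),
        n=int(y.size),
    )


KINETICS_TERMS = ["%ID", "GC", "length", "%align", "%ID:GC", "%ID:length", "%ID:%align"]


@dataclass
class KineticsResult:
    table: pd.DataFrame  # index term; estimate, se, t, p
    r2: float
    standardized: bool
    scale: dict  # per-variable (mean, sd) used for standardization
    n: int

    def effect_profile(self, covariate: str, pct_id_grid) -> pd.DataFrame:
        """Standardized effect size of a covariate as a function of %ID.

        effect(%ID) = beta_cov + beta_%ID:cov * z(%ID); meaningful for a
        standardized fit.
        """
        grid = np.asarray(pct_id_grid, dtype=float)
        m, s = self.scale["%ID"]
        z = (grid - m) / s
        b = self.table["estimate"]
        eff = b[covariate] + b[f"%ID:{covariate}"] * z
        return pd.DataFrame({"pct_id": grid, "effect": eff})


def kinetics_regression(
    mean_m, pct_id, gc, length, pct_align, standardized: bool = False
) -> KineticsResult:
    """OLS of M on %ID crossed with GC, probe length and percent alignment.

    Model: M ~ %ID * (GC + length + %align), i.e. four main effects and the
    three %ID interactions.  With ``standardized=True`` the response and all
    explanatory variables are z-scored first and interactions are products of
    z-scores, so estimates are comparable effect sizes.
    """
    arrays = {
        "y": np.asarray(mean_m, dtype=float),
        "%ID": np.asarray(pct_id, dtype=float),
        "GC": np.asarray(gc, dtype=float),
        "length": np.asarray(length, dtype=float),
        "%align": np.asarray(pct_align, dtype=float),
    }
    keep = np.ones_like(arrays["y"], dtype=bool)
    for v in arrays.values():
        keep &= np.isfinite(v)
    arrays = {k: v[keep] for k, v in arrays.items()}
    scale = {k: (float(v.mean()), float(v.std(ddof=0))) for k, v in arrays.items()}
    if standardized:
        arrays = {
            k: (v - scale[k][0]) / scale[k][1] if scale[k][1] > 0 else v - scale[k][0]
            for k, v in arrays.items()
        }
    y = arrays.pop("y")
    cols = [
        arrays["%ID"], arrays["GC"], arrays["length"], arrays["%align"],
        arrays["%ID"] * arrays["GC"],
        arrays["%ID"] * arrays["length"],
        arrays["%ID"] * arrays["%align"],
    ]
    X = np.column_stack([np.ones_like(y)] + cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [(["const"] + KINETICS_TERMS)[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise AnalysisError(f"rank-deficient kinetics design; collinear term(s): {', '.join(bad)}")
    fit = sm.OLS(y, X).fit()
    table = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        },
        index=["const"] + KINETICS_TERMS,
    )
    return KineticsResult(
        table=table, r2=float(fit.rsquared), standardized=standardized,
        scale=scale, n=int(y.size),
    )


# --------------------------------------------------------------------------
# variance partition

def variance_partition(
    se_mean, residuals, pct_id, window: int = 301, bins=None
) -> pd.DataFrame:
    """Technical vs hybridization-kinetics variation along %ID.

    Per sliding window (default) or per explicit %ID bin: technical = mean
    per-feature standard error of the fitted mean; kinetic = robust SD of the
    M ~ %ID regression residuals (median absolute residual / 0.6745).
    """
    se = np.asarray(se_mean, dtype=float)
    res = np.asarray(residuals, dtype=float)
    ids = np.asarray(pct_id, dtype=float)
    keep = np.isfinite(se) & np.isfinite(res) & np.isfinite(ids)
    se, res, ids = se[keep], res[keep], ids[keep]
    if bins is not None:
        edges = np.asarray(bins, dtype=float)
        rows = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (ids >= lo) & (ids < hi)
            rows.append(
                {
                    "center_pct_id": (lo + hi) / 2.0,
                    "technical_sd": float(se[m].mean()) if m.any() else np.nan,
                    "kinetic_sd": robust_sd(res[m]) if m.any() else np.nan,
                    "n": int(m.sum()),
                }
            )
        return pd.DataFrame(rows)
    if window % 2 == 0:
        raise AnalysisError("window must be odd")
    if ids.size < window:
        raise AnalysisError(f"need at least window={window} features (got {ids.size})")
    order = np.argsort(ids, kind="mergesort")
    se_s, res_s, ids_s = se[order], res[order], ids[order]
    roll = lambda x, fn: getattr(
        pd.Series(x).rolling(window, center=True, min_periods=window), fn
    )().to_numpy()
    kinetic = roll(np.abs(res_s), "median") / MAD_CONSISTENCY
    technical = roll(se_s, "mean")
    centers = roll(ids_s, "mean")
    good = np.isfinite(centers)
    return pd.DataFrame(
        {
            "center_pct_id": centers[good],
            "technical_sd": technical[good],
            "kinetic_sd": kinetic[good],
            "n": window,
        }
    )


def find_crossover(vp: pd.DataFrame) -> float:
    """%ID where the kinetics curve overtakes the technical curve.

    The difference of the two curves is smoothed (overlapping windows make
    the raw difference locally noisy where the curves brush), then the
    highest-%ID sign change from kinetic-dominant (low %ID) to
    technical-dominant is linearly interpolated.  NaN if the curves never
    cross.
    """
    df = vp.dropna(subset=["technical_sd", "kinetic_sd"]).sort_values("center_pct_id")
    d = (df["kinetic_sd"] - df["technical_sd"]).to_numpy()
    c = df["center_pct_id"].to_numpy()
    if d.size >= 31:
        k = min(max(31, d.size // 20) | 1, d.size | 1)
        d = (
            pd.Series(d)
            .rolling(k, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    for i in range(d.size - 1, 0, -1):
        if d[i] <= 0 < d[i - 1]:
            w = d[i - 1] / (d[i - 1] - d[i])
            return float(c[i - 1] + w * (c[i] - c[i - 1]))
    return float("nan")


# --------------------------------------------------------------------------
# replication power analysis

DEFAULT_SE_BINS = (60.0, 70.0, 80.0, 85.0, 90.0, 95.0, 100.0)


def replication_power_analysis(
    rm,
    pct_id: pd.Series,
    k_list=(2, 4, 6, 8),
    alpha: float = 0.1,
    cap: int = 70,
    seed: int = 0,
    se_bins=DEFAULT_SE_BINS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-run detection and calibration on all k-array subsets.

    For each k in ``k_list`` every k-combination of arrays (or a seeded
    random sample of at most ``cap``) is analyzed end-to-end; results are
    averaged over combinations.  Returns (summary, se_table): summary has one
    row per k with the mean % diverged at ``alpha``, mean in-range ID-50,
    mean R^2 and mean analyzed count; se_table has the mean per-feature SE of
    the fitted mean binned by %ID, one row per k.
    """
    columns = list(rm.M.columns)
    n_arrays = len(columns)
    if max(k_list) > n_arrays:
        raise AnalysisError(f"k={max(k_list)} exceeds the {n_arrays} available arrays")
    rng = np.random.default_rng(seed)
    edges = np.asarray(se_bins, dtype=float)
    ids_all = pct_id.reindex(rm.M.index)

    summary_rows, se_rows = [], []
    for k in k_list:
        combos = list(itertools.combinations(columns, k))
        if len(combos) > cap:
            pick = rng.choice(len(combos), size=cap, replace=False)
            combos = [combos[i] for i in sorted(pick)]
        accum = {"pct_diverged": [], "id50": [], "r2": [], "n_analyzed": []}
        se_accum = []
        for combo in combos:
            sub = rm.subset_arrays(combo)
            stats_df = fit_feature_stats(sub)
            calls = call_diverged(shrink_variances(stats_df), thresholds=(alpha,))
            tag = [c for c in calls.columns if c.startswith("diverged_")][0]
            valid = calls["q"].notna() & ids_all.notna()
            accum["n_analyzed"].append(int(calls["q"].notna().sum()))
            accum["pct_diverged"].append(100.0 * calls.loc[valid, tag].mean())
            fit = fit_id50(calls.loc[valid, tag].to_numpy(), ids_all[valid].to_numpy())
            if fit.status == "ok":
                accum["id50"].append(fit.id50)
            accum["r2"].append(
                linreg_ratio_id(calls.loc[valid, "mean_M"], ids_all[valid]).r2
            )
            se = np.sqrt(calls["s2_post"] / calls["n_used"])
            which = np.digitize(ids_all.to_numpy(), edges) - 1
            row = []
            for b in range(edges.size - 1):
                m = (which == b) & valid.to_numpy() & np.isfinite(se.to_numpy())
                row.append(float(se.to_numpy()[m].mean()) if m.any() else np.nan)
            se_accum.append(row)
        summary_rows.append(
            {
                "k": k,
                "n_combos": len(combos),
                "n_analyzed": float(np.mean(accum["n_analyzed"])),
                "pct_diverged": float(np.mean(accum["pct_diverged"])),
                "id50": float(np.mean(accum["id50"])) if accum["id50"] else np.nan,
                "id50_in_range": len(accum["id50"]),
                "r2": float(np.mean(accum["r2"])),
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            se_mean = np.nanmean(np.asarray(se_accum, dtype=float), axis=0)
        se_rows.append(
            {"k": k, **{f"se_bin_{edges[b]:g}_{edges[b+1]:g}": se_mean[b] for b in range(edges.size - 1)}}
        )
    return pd.DataFrame(summary_rows), pd.DataFrame(se_rows)
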
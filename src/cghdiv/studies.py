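"""Canonical simulation studies used for validating the pipeline.

Each study fixes a generator configuration whose planted truth makes a
specific property of the analysis checkable: slope recovery, detection-limit
recovery, variance-partition crossover recovery, replication power trends,
null calibration, and normalization quality.  The same configurations back
the package's acceptance checks and its reproducibility script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calibration as cal
from .synthetic import DISTANT_PROFILE, GeneratorConfig, SpeciesProfile


def calibration_study_config(seed: int, n_features: int = 10000) -> GeneratorConfig:
    """The distant-contrast reference study: 8 dye-swapped arrays."""
    return GeneratorConfig(seed=seed, n_features=n_features, n_arrays=8, conserved_n=1000)


def ramp_sd_kinetic(pct_id):
    """Steep kinetic ramp below 90 %ID (sharp, identifiable crossover)."""
    pct_id = np.asarray(pct_id, dtype=float)
    return 0.01 + 0.15 * np.clip(90.0 - pct_id, 0.0, None)


def crossover_study_config(seed: int, n_features: int = 10000) -> GeneratorConfig:
    """Variance-partition study: kinetic SD ramps steeply below 90 %ID.

    Covariate effects are kept small so the planted ramp, not the sequence
    covariates, determines where hybridization-kinetics variation overtakes
    technical error.
    """
    return GeneratorConfig(
        seed=seed, n_features=n_features, n_arrays=8, conserved_n=1000,
        beta_gc=0.02, beta_align=0.01, beta_id_gc=-0.01,
        sd_kinetic=ramp_sd_kinetic,
    )


def null_study_config(seed: int, n_features: int = 4000) -> GeneratorConfig:
    """Global null: no divergence signal, no kinetic deviation.

    Dye bias, intensity trend and quality failures stay on (the
    normalization has to remove them); technical noise is homoscedastic.
    """
    flat = lambda x: np.full_like(np.asarray(x, dtype=float), 0.35)
    zero = lambda x: np.zeros_like(np.asarray(x, dtype=float))
    return GeneratorConfig(
        seed=seed, n_features=n_features, n_arrays=8, conserved_n=600,
        beta0=0.0, beta_id=0.0, beta_gc=0.0, beta_align=0.0, beta_id_gc=0.0,
        sd_kinetic=zero, sd_technical=flat,
    )


NULL_PROFILE = SpeciesProfile("nullcase", ((0.6, 96.0, 2.0), (0.4, 88.0, 4.0)))


def trend_study_config(seed: int, amplitude: float = 0.5) -> GeneratorConfig:
    """Normalization study: a strong planted cubic intensity trend."""
    zero = lambda x: np.zeros_like(np.asarray(x, dtype=float))
    small = lambda x: np.full_like(np.asarray(x, dtype=float), 0.05)
    return GeneratorConfig(
        seed=seed, n_features=4000, n_arrays=2, conserved_n=1000,
        beta0=0.0, beta_id=0.0, beta_gc=0.0, beta_align=0.0, beta_id_gc=0.0,
        sd_kinetic=zero, sd_technical=small, dye_bias=0.0,
        intensity_trend_amplitude=amplitude, frac_lowquality=0.0,
    )


def expected_variance_partition(
    truth: pd.DataFrame,
    cfg: GeneratorConfig,
    d0: float,
    s0_2: float,
    n_arrays: int,
    window: int = 301,
    bins=None,
) -> pd.DataFrame:
    """Design-implied variance-partition curves from the planted truth.

    Technical: the expected moderated standard error of the fitted mean,
    sqrt(((d0*s0^2 + d*sigma^2)/(d0+d))/n) with sigma the planted technical
    SD.  Kinetic: the population SD of the deviation from the regression
    line - planted kinetic deviation plus the sampling error of the mean -
    windowed with the same robust estimator geometry as the measured curves.
    """
    ids = truth["true_pct_id"].to_numpy()
    sigma2 = np.asarray(cfg.sd_technical(ids), dtype=float) ** 2
    d = float(n_arrays - 1)
    if np.isfinite(d0):
        s2_post = (d0 * s0_2 + d * sigma2) / (d0 + d)
    else:
        s2_post = np.full_like(sigma2, s0_2)
    tech = np.sqrt(s2_post / n_arrays)

    # center the deviations the way the measured residuals are centered:
    # remove the OLS line of the planted means on %ID
    mu = truth["true_mean_m"].to_numpy()
    X = np.column_stack([np.ones_like(ids), ids])
    beta, *_ = np.linalg.lstsq(X, mu, rcond=None)
    dev_centered = mu - X @ beta

    if bins is not None:
        edges = np.asarray(bins, dtype=float)
        rows = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (ids >= lo) & (ids < hi)
            if m.any():
                k = np.median(np.abs(dev_centered[m])) / cal.MAD_CONSISTENCY
                rows.append(
                    {
                        "center_pct_id": (lo + hi) / 2.0,
                        "technical_sd": float(tech[m].mean()),
                        "kinetic_sd": float(np.sqrt(k**2 + sigma2[m].mean() / n_arrays)),
                        "n": int(m.sum()),
                    }
                )
            else:
                rows.append(
                    {"center_pct_id": (lo + hi) / 2.0, "technical_sd": np.nan,
                     "kinetic_sd": np.nan, "n": 0}
                )
        return pd.DataFrame(rows)

    order = np.argsort(ids, kind="mergesort")
    roll = lambda x, fn: getattr(
        pd.Series(x[order]).rolling(window, center=True, min_periods=window), fn
    )().to_numpy()
    # robust scale of the planted deviations, then the sampling error of the
    # mean added in quadrature (the measured residuals contain both)
    kinetic = roll(np.abs(dev_centered), "median") / cal.MAD_CONSISTENCY
    kinetic = np.sqrt(kinetic**2 + roll(sigma2, "mean") / n_arrays)
    technical = roll(tech, "mean")
    centers = roll(ids, "mean")
    good = np.isfinite(centers)
    return pd.DataFrame(
        {
            "center_pct_id": centers[good],
            "technical_sd": technical[good],
            "kinetic_sd": kinetic[good],
            "n": window,
        }
    )


def window_span_at(vp: pd.DataFrame, pct_id: np.ndarray, window: int, at: float) -> float:
    """Width in %ID of the sliding window whose center is nearest ``at``."""
    ids = np.sort(np.asarray(pct_id, dtype=float))
    centers = (
        pd.Series(ids).rolling(window, center=True, min_periods=window).mean().to_numpy()
    )
    spans = (
        pd.Series(ids).rolling(window, center=True, min_periods=window).apply(np.ptp, raw=True).to_numpy()
    )
    good = np.isfinite(centers)
    idx = np.argmin(np.abs(centers[good] - at))
    return float(spans[good][idx])
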
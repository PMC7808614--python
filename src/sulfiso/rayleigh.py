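"""Rayleigh-distillation estimation of the sulfur isotope enrichment factor.

In a closed batch culture, dissimilatory sulfate reduction consumes a finite
sulfate pool with a near-constant isotope discrimination; the residual sulfate
becomes progressively enriched in ³⁴S while the accumulating sulfide is
depleted.  With ``f`` the fraction of the initial sulfate remaining, the
linearized Rayleigh relations are

    1000·ln(1 + δ³⁴S(SO₄²⁻)/1000) =  ³⁴ε · (−ln f)                 (sulfate)
    1000·ln(1 + δ³⁴S(HS⁻)/1000)  =  ³⁴ε · (f·ln f)/(1 − f)        (sulfide)

so the enrichment factor ³⁴ε (‰, positive = product depleted in ³⁴S) is the
slope of the transformed isotope coordinate on the transformed progress
coordinate.  Both a multi-point regression (free intercept by default, to
absorb instrument offsets) and a single-endpoint through-origin mode are
provided; the endpoint mode is what reproduces a table of final concentrations
and compositions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .timeseries import CultureTimeSeries

__all__ = [
    "delta_from_ratio",
    "ratio_from_delta",
    "fraction_remaining",
    "rayleigh_series",
    "sulfide_progress_coordinate",
    "EnrichmentEstimate",
    "epsilon_from_sulfate",
    "epsilon_from_sulfide",
    "epsilon_combined",
    "mass_balance_diagnostic",
]

#: ³⁴S/³²S of the VCDT reference; only sets the absolute ratio scale, the
#: δ-notation here is normalized to the starting sulfate of each culture.
R_VCDT = 0.0441626

#: timepoints with f above this are excluded from the sulfide regression by
#: default — the sulfide progress coordinate is ill-conditioned near its
#: f→1 limit of −1.
SULFIDE_F_CUTOFF = 0.98


def delta_from_ratio(ratio_sample: float, ratio_reference: float) -> float:
    """δ³⁴S (‰) of a sample ratio relative to a reference ratio."""
    return (np.asarray(ratio_sample) / ratio_reference - 1.0) * 1000.0


def ratio_from_delta(delta_permil: float, ratio_reference: float) -> float:
    """Inverse of :func:`delta_from_ratio`."""
    return ratio_reference * (1.0 + np.asarray(delta_permil) / 1000.0)


def fraction_remaining(sulfate_t, sulfate_0: float):
    """Fraction ``f`` of the initial sulfate remaining at a timepoint."""
    sulfate_t = np.asarray(sulfate_t, dtype=float)
    if sulfate_0 <= 0:
        raise ValueError("initial sulfate must be positive")
    if np.any(sulfate_t[np.isfinite(sulfate_t)] < 0):
        raise ValueError("sulfate concentrations must be non-negative")
    return sulfate_t / sulfate_0


def sulfide_progress_coordinate(f):
    """(f·ln f)/(1 − f), with the analytic limit −1 as f → 1."""
    f = np.asarray(f, dtype=float)
    out = np.full(f.shape, np.nan)
    near_one = np.abs(f - 1.0) < 1e-9
    ok = (f > 0) & ~near_one
    out[ok] = f[ok] * np.log(f[ok]) / (1.0 - f[ok])
    out[near_one] = -1.0
    return out


def rayleigh_series(series: CultureTimeSeries, sulfate_0: float | None = None) -> pd.DataFrame:
    """Per-timepoint transformed Rayleigh coordinates.

    Returns a frame with ``f``, ``x_sulfate = −ln f``,
    ``y_sulfate = 1000·ln(1+δ(SO₄)/1000)``, ``x_sulfide = (f·ln f)/(1−f)``
    and ``y_sulfide = 1000·ln(1+δ(HS)/1000)``.
    """
    if sulfate_0 is None:
        sulfate_0 = series.initial_sulfate
    df = series.data
    f = fraction_remaining(df["sulfate_mM"].to_numpy(dtype=float), sulfate_0)
    out = pd.DataFrame({"time_h": df["time_h"], "f": f})
    out["x_sulfate"] = -np.log(f)
    out["x_sulfide"] = sulfide_progress_coordinate(f)
    for pool, col in (("sulfate", "d34S_sulfate_permil"), ("sulfide", "d34S_sulfide_permil")):
        if col in df.columns:
            delta = df[col].to_numpy(dtype=float)
            out[f"y_{pool}"] = 1000.0 * np.log1p(delta / 1000.0)
        else:
            out[f"y_{pool}"] = np.nan
    return out


@dataclass
class EnrichmentEstimate:
    """A ³⁴ε point estimate with its uncertainty and provenance."""

    epsilon: float  # ‰
    se: float  # ‰; NaN when not estimable (single endpoint)
    method: str  # sulfate_regression | sulfide_regression | combined | endpoint
    n_points: int
    intercept: float = float("nan")  # ‰, when a free intercept was fitted

    def __post_init__(self) -> None:
        if np.isfinite(self.se) and self.se < 0:
            raise ValueError("standard error must be non-negative")

    def round(self, ndigits: int = 1) -> "EnrichmentEstimate":
        """Reporting precision: ε to 0.1‰ by default."""
        return EnrichmentEstimate(
            round(self.epsilon, ndigits),
            round(self.se, ndigits) if np.isfinite(self.se) else self.se,
            self.method,
            self.n_points,
            self.intercept,
        )


def _slope_fit(x: np.ndarray, y: np.ndarray, with_intercept: bool):
    X = sm.add_constant(x) if with_intercept else x[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):  # saturated fits: se undefined
        fit = sm.OLS(y, X).fit()
        if with_intercept:
            slope, slope_se = fit.params[1], fit.bse[1]
            intercept = fit.params[0]
        else:
            slope, slope_se = fit.params[0], fit.bse[0]
            intercept = float("nan")
    return float(slope), float(slope_se), float(intercept)


def _epsilon_from_coords(
    x: np.ndarray,
    y: np.ndarray,
    method: str,
    with_intercept: bool,
    min_progress_mask: np.ndarray,
) -> EnrichmentEstimate:
    keep = np.isfinite(x) & np.isfinite(y) & min_progress_mask
    x, y = x[keep], y[keep]
    n = len(x)
    if n == 0:
        raise ValueError("no usable timepoints: no progress (all f = 1) or all values missing")
    if n == 1:
        # endpoint mode, forced through the origin
        if x[0] == 0:
            raise ValueError("no progress: the single usable timepoint has f = 1")
        return EnrichmentEstimate(float(y[0] / x[0]), float("nan"), "endpoint", 1)
    slope, se, intercept = _slope_fit(x, y, with_intercept)
    return EnrichmentEstimate(slope, se, method, n, intercept)


def epsilon_from_sulfate(
    series: CultureTimeSeries,
    sulfate_0: float | None = None,
    with_intercept: bool = True,
) -> EnrichmentEstimate:
    """³⁴ε from the residual-sulfate Rayleigh relation.

    Slope of ``1000·ln(1+δ(SO₄)/1000)`` on ``−ln f``; positive ε means
    ³⁴S-enrichment of the residual sulfate.  With a single usable timepoint
    the fit is forced through the origin (endpoint mode).
    """
    rs = rayleigh_series(series, sulfate_0)
    x = rs["x_sulfate"].to_numpy(dtype=float)
    y = rs["y_sulfate"].to_numpy(dtype=float)
    progress = np.abs(x) > 1e-12  # drop f == 1 points only for endpoint safety
    if not np.any(progress & np.isfinite(x) & np.isfinite(y)):
        raise ValueError("no progress: all timepoints have f = 1")
    # regression keeps every finite point; endpoint mode needs x != 0
    n_usable = int(np.sum(np.isfinite(x) & np.isfinite(y)))
    mask = progress if n_usable <= 1 or np.sum(progress) == 1 else np.ones_like(x, bool)
    return _epsilon_from_coords(x, y, "sulfate_regression", with_intercept, mask)


def epsilon_from_sulfide(
    series: CultureTimeSeries,
    sulfate_0: float | None = None,
    with_intercept: bool = True,
    f_cutoff: float = SULFIDE_F_CUTOFF,
) -> EnrichmentEstimate:
    """³⁴ε from the accumulated-sulfide Rayleigh relation.

    Slope of ``1000·ln(1+δ(HS)/1000)`` on ``(f·ln f)/(1−f)``; the same sign
    convention as the sulfate estimator (product depleted ⇒ positive ε).
    Timepoints with ``f > f_cutoff`` are excluded when more than one point
    remains (the progress coordinate is ill-conditioned near −1).
    """
    rs = rayleigh_series(series, sulfate_0)
    x = rs["x_sulfide"].to_numpy(dtype=float)
    y = rs["y_sulfide"].to_numpy(dtype=float)
    f = rs["f"].to_numpy(dtype=float)
    finite = np.isfinite(x) & np.isfinite(y)
    mask = finite & (f <= f_cutoff)
    if np.sum(mask) == 0:
        mask = finite  # keep near-1 points rather than fail outright
    return _epsilon_from_coords(x, y, "sulfide_regression", with_intercept, mask)


def epsilon_combined(
    est_sulfate: EnrichmentEstimate, est_sulfide: EnrichmentEstimate
) -> EnrichmentEstimate:
    """Combine the two estimators into a single per-culture ³⁴ε.

    Inverse-variance weighted mean when both standard errors are finite and
    positive, otherwise the unweighted mean.  The combined estimate always
    lies between its two inputs.
    """
    e1, e2 = est_sulfate.epsilon, est_sulfide.epsilon
    s1, s2 = est_sulfate.se, est_sulfide.se
    if np.isfinite(s1) and np.isfinite(s2) and s1 > 0 and s2 > 0:
        w1, w2 = 1.0 / s1**2, 1.0 / s2**2
        eps = (w1 * e1 + w2 * e2) / (w1 + w2)
        se = math.sqrt(1.0 / (w1 + w2))
    elif np.isfinite(s1) and s1 >= 0 and np.isfinite(s2) and s2 == 0 and s1 > 0:
        eps, se = e2, 0.0
    else:
        eps = 0.5 * (e1 + e2)
        se = float("nan")
        if np.isfinite(s1) and np.isfinite(s2):
            se = 0.5 * math.sqrt(s1**2 + s2**2)
    n = est_sulfate.n_points + est_sulfide.n_points
    return EnrichmentEstimate(float(eps), float(se), "combined", n)


def mass_balance_diagnostic(
    series: CultureTimeSeries,
    sulfate_0: float | None = None,
    rel_err_conc: float = 0.05,
    abs_err_delta: float = 0.2,
) -> pd.DataFrame:
    """Per-timepoint isotope mass-balance closure residual (‰).

    In a closed system the pool-weighted δ mean is conserved; with the
    reference set to the starting sulfate the residual
    ``w_SO4·δ(SO₄) + w_HS·δ(HS)`` should vanish within the Rayleigh
    linearization error.  The sulfate weight is ``f``; the sulfide weight is
    the measured sulfide over the initial sulfate when sulfide was measured
    (so the diagnostic probes chemical and isotopic closure jointly), and
    ``1 − f`` otherwise.  Residuals larger than three times the propagated
    measurement error are flagged.
    """
    if sulfate_0 is None:
        sulfate_0 = series.initial_sulfate
    df = series.data
    f = fraction_remaining(df["sulfate_mM"].to_numpy(dtype=float), sulfate_0)
    d_so4 = df["d34S_sulfate_permil"].to_numpy(dtype=float)
    d_hs = df["d34S_sulfide_permil"].to_numpy(dtype=float)
    if "sulfide_mM" in df.columns:
        w_hs_meas = df["sulfide_mM"].to_numpy(dtype=float) / sulfate_0
        w_hs = np.where(np.isfinite(w_hs_meas), w_hs_meas, 1.0 - f)
    else:
        w_hs = 1.0 - f
    residual = f * d_so4 + w_hs * d_hs
    sigma_f = f * rel_err_conc * math.sqrt(2.0)  # sulfate_t and sulfate_0 both ±5%
    sigma_w = w_hs * rel_err_conc * math.sqrt(2.0)
    sigma = np.sqrt(
        (f * abs_err_delta) ** 2
        + (w_hs * abs_err_delta) ** 2
        + (d_so4 * sigma_f) ** 2
        + (d_hs * sigma_w) ** 2
    )
    out = pd.DataFrame(
        {
            "time_h": df["time_h"],
            "f": f,
            "residual_permil": residual,
            "sigma_permil": sigma,
        }
    )
    out["flagged"] = np.abs(residual) > 3.0 * sigma
    if out["flagged"].any():
        warnings.warn(
            f"{int(out['flagged'].sum())} timepoint(s) violate isotope mass balance "
            "beyond 3× the propagated measurement error",
            stacklevel=2,
        )
    return out
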
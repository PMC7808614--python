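"""Growth and respiration-rate parameters from a batch-culture time series.

Definitions follow standard batch-culture practice: the specific growth rate
μ (day⁻¹) is the ordinary-least-squares slope of ln(A660) versus time over
the exponential window; the growth yield Y (A660 per mM sulfate) is the
ratio of optical density gained to sulfate consumed between the window
endpoints; the specific sulfate reduction rate sSRR = μ/Y
(mM sulfate · A660⁻¹ · day⁻¹); and the cell-specific rate csSRR converts
sSRR to fmol sulfate · cell⁻¹ · day⁻¹ via a biovolume-per-OD factor and a
mean cell volume.

Unit chain for the csSRR conversion (explicit on purpose):

    cells·ml⁻¹ per A660  =  biovolume_per_od [μl·ml⁻¹] × 1e9 [μm³·μl⁻¹]
                             / cell_volume [μm³]
    sSRR [mM·A660⁻¹·day⁻¹] = [mmol·l⁻¹·…] = 1e9 [fmol·ml⁻¹·A660⁻¹·day⁻¹]
    csSRR [fmol·cell⁻¹·day⁻¹] = sSRR × 1e9 / (cells·ml⁻¹ per A660)
                              = sSRR × cell_volume / biovolume_per_od

so with the defaults (1.49 μl·ml⁻¹ per A660, 1.68 μm³ per cell) csSRR is
sSRR × 1.68/1.49 ≈ sSRR × 1.1275.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic import NoiseModel
from .timeseries import CultureTimeSeries

__all__ = [
    "ValueWithError",
    "GrowthParameters",
    "CellConversionFactors",
    "specific_growth_rate",
    "growth_yield",
    "specific_srr",
    "cell_specific_srr",
    "select_exponential_window",
    "fit_growth",
]

logger = logging.getLogger(__name__)

HOURS_PER_DAY = 24.0  # a day is 24 h exactly
CULTURE_TEMPERATURE_K = 293.15  # room temperature, 20 °C


@dataclass(frozen=True)
class ValueWithError:
    value: float
    se: float  # standard error; NaN when not estimable

    def __iter__(self):
        return iter((self.value, self.se))


@dataclass(frozen=True)
class CellConversionFactors:
    """OD → cell-count conversion: total biovolume per OD and mean cell volume."""

    biovolume_per_od: float = 1.49  # μl·ml⁻¹ at A660 = 1.0
    cell_volume: float = 1.68  # μm³

    def __post_init__(self) -> None:
        if self.biovolume_per_od <= 0 or self.cell_volume <= 0:
            raise ValueError("conversion factors must be positive")

    @property
    def cells_per_ml_per_od(self) -> float:
        return self.biovolume_per_od * 1e9 / self.cell_volume


@dataclass(frozen=True)
class GrowthParameters:
    """μ, Y, sSRR and csSRR with uncertainties, plus the window used."""

    mu: ValueWithError  # day⁻¹
    yield_Y: ValueWithError  # A660 per mM sulfate
    specific_srr: ValueWithError  # mM·A660⁻¹·day⁻¹
    cs_srr: ValueWithError  # fmol·cell⁻¹·day⁻¹
    window: tuple[float, float]  # (t_start, t_end) h


def select_exponential_window(
    series: CultureTimeSeries, min_points: int = 3, r2_tolerance: float = 1e-4
) -> tuple[float, float]:
    """Automatic exponential-window selection.

    Scans all contiguous runs of ≥ ``min_points`` timepoints with positive,
    increasing-overall OD and returns the longest window whose ln-OD
    regression R² is within ``r2_tolerance`` of the best achievable; ties
    break toward the earlier window.
    """
    df = series.data
    t = df["time_h"].to_numpy(dtype=float)
    od = df["od660"].to_numpy(dtype=float)
    usable = np.isfinite(t) & np.isfinite(od) & (od > 0)
    idx = np.nonzero(usable)[0]
    if len(idx) < min_points:
        raise ValueError(f"fewer than {min_points} usable (OD > 0) timepoints")
    best: tuple[float, int, float, tuple[float, float]] | None = None
    candidates = []
    for a in range(len(idx)):
        for b in range(a + min_points - 1, len(idx)):
            sel = idx[a : b + 1]
            if not np.all(np.diff(sel) == 1):
                continue
            x, y = t[sel] / HOURS_PER_DAY, np.log(od[sel])
            if np.ptp(y) <= 0:  # flat or declining: R² undefined/meaningless
                r2 = 0.0
            else:
                res = stats.linregress(x, y)
                r2 = res.rvalue**2
            candidates.append((r2, len(sel), (t[sel[0]], t[sel[-1]])))
    if not candidates:
        # only non-contiguous usable points: fall back to the full usable span
        return (t[idx[0]], t[idx[-1]])
    r2_max = max(c[0] for c in candidates)
    eligible = [c for c in candidates if c[0] >= r2_max - r2_tolerance]
    eligible.sort(key=lambda c: (-c[1], c[2][0]))
    return eligible[0][2]


def _window_mask(series: CultureTimeSeries, window: tuple[float, float]) -> np.ndarray:
    t = series.data["time_h"].to_numpy(dtype=float)
    return (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)


def specific_growth_rate(
    series: CultureTimeSeries, window: tuple[float, float] | None = None
) -> ValueWithError:
    """μ (day⁻¹): OLS slope of ln(OD) versus time over the window.

    Nonpositive OD values are excluded with a logged warning; fewer than
    three usable points is an explicit error.
    """
    if window is None:
        window = select_exponential_window(series)
    df = series.data
    mask = _window_mask(series, window)
    t = df["time_h"].to_numpy(dtype=float)[mask]
    od = df["od660"].to_numpy(dtype=float)[mask]
    bad = ~(np.isfinite(od) & (od > 0))
    if np.any(bad & np.isfinite(od)):
        logger.warning(
            "excluding %d nonpositive OD value(s) from the growth-rate fit",
            int(np.sum(bad & np.isfinite(od))),
        )
    t, od = t[~bad], od[~bad]
    if len(t) < 3:
        raise ValueError(
            f"growth window {window} has {len(t)} usable points; at least 3 required"
        )
    res = stats.linregress(t / HOURS_PER_DAY, np.log(od))
    return ValueWithError(float(res.slope), float(res.stderr))


def growth_yield(
    series: CultureTimeSeries,
    window: tuple[float, float] | None = None,
    noise: NoiseModel | None = None,
) -> ValueWithError:
    """Y (A660 per mM sulfate): ΔOD / Δsulfate between the window endpoints.

    Uncertainty by first-order propagation of the endpoint measurement
    errors under ``noise`` (defaults to the standard analytical model).
    """
    if window is None:
        window = select_exponential_window(series)
    if noise is None:
        noise = NoiseModel()
    df = series.data
    mask = _window_mask(series, window)
    sub = df[mask].dropna(subset=["od660", "sulfate_mM"])
    if len(sub) < 2:
        raise ValueError("growth window needs two usable (OD, sulfate) endpoints")
    od_a, od_b = float(sub["od660"].iloc[0]), float(sub["od660"].iloc[-1])
    s_a, s_b = float(sub["sulfate_mM"].iloc[0]), float(sub["sulfate_mM"].iloc[-1])
    d_od, d_s = od_b - od_a, s_a - s_b
    if d_s <= 0:
        raise ValueError("no sulfate consumed over the window; yield undefined")
    y = d_od / d_s
    var_dod = (noise.rel_err_od * od_a) ** 2 + (noise.rel_err_od * od_b) ** 2
    var_ds = (noise.rel_err_sulfate * s_a) ** 2 + (noise.rel_err_sulfate * s_b) ** 2
    if d_od == 0:
        se = math.sqrt(var_dod) / d_s
    else:
        se = abs(y) * math.sqrt(var_dod / d_od**2 + var_ds / d_s**2)
    return ValueWithError(float(y), float(se))


def specific_srr(mu: ValueWithError | float, yield_Y: ValueWithError | float) -> ValueWithError:
    """sSRR = μ / Y (mM sulfate · A660⁻¹ · day⁻¹) with propagated uncertainty."""
    mu = mu if isinstance(mu, ValueWithError) else ValueWithError(float(mu), float("nan"))
    yy = (
        yield_Y
        if isinstance(yield_Y, ValueWithError)
        else ValueWithError(float(yield_Y), float("nan"))
    )
    if yy.value <= 0:
        raise ValueError("growth yield must be positive")
    value = mu.value / yy.value
    if mu.value == 0:
        se = (mu.se / yy.value) if np.isfinite(mu.se) else float("nan")
    elif np.isfinite(mu.se) and np.isfinite(yy.se):
        se = abs(value) * math.sqrt((mu.se / mu.value) ** 2 + (yy.se / yy.value) ** 2)
    else:
        se = float("nan")
    return ValueWithError(float(value), float(se))


def cell_specific_srr(
    ssrr: ValueWithError | float, factors: CellConversionFactors | None = None
) -> ValueWithError:
    """csSRR (fmol·cell⁻¹·day⁻¹) from sSRR via the OD → cell conversion."""
    if factors is None:
        factors = CellConversionFactors()
    ssrr = (
        ssrr
        if isinstance(ssrr, ValueWithError)
        else ValueWithError(float(ssrr), float("nan"))
    )
    scale = 1e9 / factors.cells_per_ml_per_od  # == cell_volume / biovolume_per_od
    return ValueWithError(
        float(ssrr.value * scale),
        float(ssrr.se * scale) if np.isfinite(ssrr.se) else float("nan"),
    )


def fit_growth(
    series: CultureTimeSeries,
    window: tuple[float, float] | None = None,
    noise: NoiseModel | None = None,
    factors: CellConversionFactors | None = None,
) -> GrowthParameters:
    """Full growth-parameter fit: μ, Y, sSRR and csSRR over one window."""
    if window is None:
        window = select_exponential_window(series)
    mu = specific_growth_rate(series, window)
    yy = growth_yield(series, window, noise)
    ssrr = specific_srr(mu, yy)
    cssrr = cell_specific_srr(ssrr, factors)
    return GrowthParameters(mu, yy, ssrr, cssrr, window)
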
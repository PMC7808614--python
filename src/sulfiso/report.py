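"""Structured fit reports: growth parameters, enrichment factors with both
uncertainty routes, and mass-balance diagnostics, machine- and human-readable."""

from __future__ import annotations

import dataclasses
import json
from typing import Any

import numpy as np

from . import __version__
from .growth import CellConversionFactors, fit_growth
from .rayleigh import (
    epsilon_combined,
    epsilon_from_sulfate,
    epsilon_from_sulfide,
    mass_balance_diagnostic,
)
from .synthetic import NoiseModel
from .timeseries import CultureTimeSeries
from .uncertainty import UncertaintySettings, monte_carlo_propagate, taylor_propagate

__all__ = ["run_fit", "render_text"]


def _clean(obj: Any) -> Any:
    """JSON-safe conversion (dataclasses, numpy scalars, NaN → None)."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _clean(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        return x if np.isfinite(x) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def run_fit(
    series: CultureTimeSeries,
    noise: NoiseModel | None = None,
    settings: UncertaintySettings | None = None,
    window: tuple[float, float] | None = None,
    factors: CellConversionFactors | None = None,
    with_growth: bool = True,
) -> dict:
    """Fit one culture time series end to end.

    Returns a JSON-serializable report with growth parameters, the
    sulfate-based, sulfide-based and combined enrichment estimates, Monte
    Carlo and Taylor uncertainties for the combined estimate, per-timepoint
    mass-balance residuals, and the fully resolved settings and seeds.
    """
    if noise is None:
        noise = NoiseModel()
    if settings is None:
        settings = UncertaintySettings()
    report: dict = {
        "tool": "sulfiso",
        "version": __version__,
        "metadata": dict(series.metadata),
        "settings": {
            "noise": _clean(noise),
            "uncertainty": _clean(settings),
        },
    }

    if with_growth:
        growth = fit_growth(series, window=window, noise=noise, factors=factors)
        report["growth"] = _clean(growth)
        report["settings"]["window_h"] = list(growth.window)

    def combined_eps(s: CultureTimeSeries) -> float:
        return epsilon_combined(epsilon_from_sulfate(s), epsilon_from_sulfide(s)).epsilon

    est_so4 = epsilon_from_sulfate(series)
    est_hs = epsilon_from_sulfide(series)
    est = epsilon_combined(est_so4, est_hs)
    enrichment: dict = {
        "sulfate": _clean(est_so4),
        "sulfide": _clean(est_hs),
        "combined": _clean(est),
    }
    if settings.method in ("monte_carlo", "both"):
        enrichment["monte_carlo"] = _clean(
            monte_carlo_propagate(combined_eps, series, noise, settings)
        )
    if settings.method in ("taylor", "both"):
        enrichment["taylor"] = _clean(taylor_propagate(combined_eps, series, noise))
    report["enrichment"] = enrichment

    diag = mass_balance_diagnostic(
        series,
        rel_err_conc=noise.rel_err_sulfate,
        abs_err_delta=noise.abs_err_delta,
    )
    report["mass_balance"] = _clean(diag.to_dict(orient="list"))
    return report


def render_text(report: dict) -> str:
    """Human-readable summary of a fit report."""
    lines = [f"sulfiso {report['version']} fit report"]
    meta = report.get("metadata", {})
    if meta:
        lines.append("scenario: " + str(meta.get("scenario", "(unnamed)")))
    g = report.get("growth")
    if g:
        lines += [
            f"growth window: {g['window'][0]:.1f}-{g['window'][1]:.1f} h",
            f"mu       = {g['mu']['value']:.4g} ± {g['mu']['se']:.2g} /day",
            f"yield Y  = {g['yield_Y']['value']:.4g} ± {g['yield_Y']['se']:.2g} A660/mM",
            f"sSRR     = {g['specific_srr']['value']:.4g} mM/A660/day",
            f"csSRR    = {g['cs_srr']['value']:.4g} fmol/cell/day",
        ]
    e = report["enrichment"]
    lines.append(
        f"epsilon  = {e['combined']['epsilon']:.1f} permil "
        f"(sulfate {e['sulfate']['epsilon']:.1f}, sulfide {e['sulfide']['epsilon']:.1f})"
    )
    if "monte_carlo" in e:
        mc = e["monte_carlo"]
        lines.append(f"  Monte Carlo sd = {mc['sd']:.2f} permil (n={mc['n_draws']})")
    if "taylor" in e:
        lines.append(f"  Taylor sd      = {e['taylor']['sd']:.2f} permil")
    flagged = sum(bool(x) for x in report["mass_balance"].get("flagged", []))
    lines.append(f"mass-balance points flagged: {flagged}")
    return "\n".join(lines) + "\n"


def to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=False)
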
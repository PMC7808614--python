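"""Rayleigh estimators: δ-notation, endpoint arithmetic, regression recovery,
combination rules and isotope mass-balance diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sulfiso import (
    CultureTimeSeries,
    EnrichmentEstimate,
    NoiseModel,
    delta_from_ratio,
    epsilon_combined,
    epsilon_from_sulfate,
    epsilon_from_sulfide,
    fraction_remaining,
    mass_balance_diagnostic,
    methanol_scenario,
    ratio_from_delta,
    rayleigh_series,
    simulate_batch,
)
from sulfiso.rayleigh import R_VCDT, sulfide_progress_coordinate

from conftest import ALCOHOL_ENDPOINTS, endpoint_series


class TestDeltaNotation:
    def test_reference_ratio_gives_zero(self):
        assert delta_from_ratio(R_VCDT, R_VCDT) == 0.0

    def test_one_percent_heavier_is_ten_permil(self):
        assert delta_from_ratio(1.01 * R_VCDT, R_VCDT) == pytest.approx(10.0)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=-100.0, max_value=100.0))
    def test_round_trip_identity(self, delta):
        back = delta_from_ratio(ratio_from_delta(delta, R_VCDT), R_VCDT)
        assert back == pytest.approx(delta, abs=1e-12)


class TestFractionRemaining:
    @pytest.mark.parametrize(
        "remaining,initial,expected",
        [(10.9, 21.0, 0.519), (21.0, 21.0, 1.0), (15.0, 21.0, 0.714)],
    )
    def test_values(self, remaining, initial, expected):
        assert fraction_remaining(remaining, initial) == pytest.approx(expected, abs=5e-4)

    def test_rejects_nonpositive_initial(self):
        with pytest.raises(ValueError):
            fraction_remaining(1.0, 0.0)

    def test_sulfide_coordinate_limit_and_range(self):
        f = np.linspace(0.05, 0.95, 19)
        x = sulfide_progress_coordinate(f)
        assert np.all((x > -1.0) & (x < 0.0))
        assert sulfide_progress_coordinate(np.array([1.0]))[0] == -1.0


class TestEndpointEstimators:
    def test_sulfate_endpoint_hand_value(self):
        # f = 0.519, δ(SO4) = 6.9‰ → 1000·ln(1.0069)/(−ln 0.519) = 10.5‰
        ts = endpoint_series(10.9, 6.9, 9.5, -6.6)
        est = epsilon_from_sulfate(ts)
        assert est.method == "endpoint"
        assert est.epsilon == pytest.approx(10.5, abs=0.05)

    def test_sulfide_endpoint_hand_values(self):
        ts = endpoint_series(10.5, 6.8, 9.5, -6.6)  # f = 0.5
        est = epsilon_from_sulfide(ts)
        assert est.epsilon == pytest.approx(1000 * math.log(0.9934) / -0.6931, abs=0.05)
        ts2 = endpoint_series(10.9, 6.9, 9.5, -6.6)  # f = 0.519
        assert epsilon_from_sulfide(ts2).epsilon == pytest.approx(9.4, abs=0.05)

    @pytest.mark.parametrize("culture", sorted(ALCOHOL_ENDPOINTS))
    def test_alcohol_cultures_match_reported_epsilon(self, culture):
        remaining, d_so4, sulfide, d_hs, reported, tol = ALCOHOL_ENDPOINTS[culture]
        ts = endpoint_series(remaining, d_so4, sulfide, d_hs)
        e1 = epsilon_from_sulfate(ts)
        e2 = epsilon_from_sulfide(ts)
        combined = epsilon_combined(e1, e2)
        assert combined.epsilon == pytest.approx(reported, abs=tol)

    def test_zero_delta_gives_zero_epsilon(self):
        ts = endpoint_series(10.5, 0.0, 10.5, 0.0)
        assert epsilon_from_sulfate(ts).epsilon == 0.0
        assert epsilon_from_sulfide(ts).epsilon == 0.0

    def test_no_progress_is_an_error(self):
        df = pd.DataFrame(
            {
                "time_h": [0.0, 24.0],
                "sulfate_mM": [21.0, 21.0],
                "d34S_sulfate_permil": [0.0, 0.0],
            }
        )
        ts = CultureTimeSeries(df, {"initial_sulfate_mM": 21.0})
        with pytest.raises(ValueError, match="no progress"):
            epsilon_from_sulfate(ts)


def closed_form_slope(eps_true, f_values, pool, reference_ratio=R_VCDT):
    """Independent closed-form oracle for the biased estimator expectation.

    Evaluates the exact two-pool Rayleigh solution analytically at the given
    total-sulfate fractions and fits the approximate linearized relation the
    estimators use, without touching the generator or estimator code paths.
    """
    import statsmodels.api as sm
    from scipy.optimize import brentq

    alpha = 1.0 - eps_true / 1000.0
    r0 = reference_ratio
    f = np.asarray(f_values, dtype=float)
    g = np.array(
        [
            brentq(lambda gg: (gg + r0 * gg**alpha) / (1 + r0) - ff, 1e-12, 1.0)
            if ff < 1
            else 1.0
            for ff in f
        ]
    )
    if pool == "sulfate":
        y = 1000.0 * (alpha - 1.0) * np.log(g)
        x = -np.log(f)
    else:
        keep = (g < 1) & (f <= 0.98)
        g, f = g[keep], f[keep]
        y = 1000.0 * np.log((1.0 - g**alpha) / (1.0 - g))
        x = f * np.log(f) / (1.0 - f)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.params[1])


class TestRegressionRecovery:
    @pytest.mark.parametrize("eps_true", [5.0, 10.0, 20.0, 36.0, 45.0])
    @pytest.mark.parametrize("pool", ["sulfate", "sulfide"])
    def test_estimators_match_closed_form_oracle(self, eps_true, pool):
        """Simulated-and-refitted ε equals the closed-form expectation of the
        linearized estimator on exact closed-system data to 0.1%.

        The residual bias relative to ε_true is a property of the linearized
        relations themselves: below 0.2% for the sulfate form, and growing
        to ~0.7% at 45‰ for the sulfide form (the transform does not fully
        linearize the accumulated-product branch)."""
        cfg = methanol_scenario(methanol_mM=19.6, true_epsilon=eps_true, n_samples=12)
        ts = simulate_batch(cfg, NoiseModel.zero())
        f = ts.data["sulfate_mM"].to_numpy() / 21.0
        assert f.min() >= 0.297
        estimator = epsilon_from_sulfate if pool == "sulfate" else epsilon_from_sulfide
        est = estimator(ts)
        expected = closed_form_slope(eps_true, f, pool)
        assert est.epsilon == pytest.approx(expected, rel=1e-3)
        bias = abs(est.epsilon - eps_true) / eps_true
        assert bias < (0.0025 if pool == "sulfate" else 0.0075)

    def test_endpoint_and_two_point_regression_coincide(self):
        ts = endpoint_series(10.9, 6.9, 9.5, -6.6)
        endpoint = epsilon_from_sulfate(ts).epsilon
        # add the origin explicitly: regression through (0,0) and the endpoint
        df = ts.data.copy()
        df.loc[0, "d34S_sulfate_permil"] = 0.0
        two_pt = epsilon_from_sulfate(CultureTimeSeries(df, ts.metadata))
        assert two_pt.epsilon == pytest.approx(endpoint, abs=1e-9)

    def test_scale_equivariance(self, noiseless_methanol):
        """Multiplying all concentrations by a constant leaves f and ε̂ unchanged."""
        ref = epsilon_from_sulfate(noiseless_methanol).epsilon
        df = noiseless_methanol.data.copy()
        for col in ("sulfate_mM", "sulfide_mM", "methanol_mM"):
            df[col] = df[col] * 3.7
        meta = dict(noiseless_methanol.metadata)
        meta["initial_sulfate_mM"] = 21.0 * 3.7
        scaled = epsilon_from_sulfate(CultureTimeSeries(df, meta)).epsilon
        assert scaled == pytest.approx(ref, abs=1e-9)

    def test_sign_convention(self, noiseless_methanol):
        """ε > 0 ⇔ product depleted: δ(HS) < δ(SO4) at every timepoint."""
        df = noiseless_methanol.data.dropna(
            subset=["d34S_sulfate_permil", "d34S_sulfide_permil"]
        )
        assert (df["d34S_sulfide_permil"] < df["d34S_sulfate_permil"]).all()
        assert epsilon_from_sulfate(noiseless_methanol).epsilon > 0


class TestCombination:
    def test_unweighted_mean_without_ses(self):
        a = EnrichmentEstimate(10.5, float("nan"), "endpoint", 1)
        b = EnrichmentEstimate(9.4, float("nan"), "endpoint", 1)
        combined = epsilon_combined(a, b)
        assert combined.epsilon == pytest.approx(9.95)
        assert combined.method == "combined"

    def test_identical_inputs_unchanged(self):
        a = EnrichmentEstimate(12.0, 0.5, "sulfate_regression", 8)
        assert epsilon_combined(a, a).epsilon == pytest.approx(12.0)

    def test_infinite_variance_input_is_ignored(self):
        a = EnrichmentEstimate(10.0, 1.0, "sulfate_regression", 8)
        b = EnrichmentEstimate(50.0, 1e9, "sulfide_regression", 8)
        assert epsilon_combined(a, b).epsilon == pytest.approx(10.0, abs=1e-6)

    def test_combined_lies_between_inputs(self):
        a = EnrichmentEstimate(9.0, 0.4, "sulfate_regression", 8)
        b = EnrichmentEstimate(11.0, 0.8, "sulfide_regression", 8)
        assert 9.0 <= epsilon_combined(a, b).epsilon <= 11.0


class TestMassBalance:
    def test_measured_endpoint_residual_within_noise(self):
        """The ethanol-culture endpoint closes to ≈0.6‰, inside 3σ of the
        combined ±0.2‰ δ and ±5% concentration errors."""
        ts = endpoint_series(10.9, 6.9, 9.5, -6.6)
        diag = mass_balance_diagnostic(ts)
        resid = diag["residual_permil"].iloc[-1]
        assert resid == pytest.approx(0.6, abs=0.15)
        assert not diag["flagged"].iloc[-1]

    def test_noiseless_synthetic_closes_tightly(self, noiseless_methanol):
        diag = mass_balance_diagnostic(noiseless_methanol)
        sel = diag[diag["f"] > 0.3].dropna(subset=["residual_permil"])
        assert (sel["residual_permil"].abs() < 0.3).all()

    def test_zero_deltas_close_exactly(self):
        ts = endpoint_series(10.5, 0.0, 10.5, 0.0)
        diag = mass_balance_diagnostic(ts)
        assert diag["residual_permil"].iloc[-1] == 0.0

    def test_rayleigh_series_coordinates(self, noiseless_methanol):
        rs = rayleigh_series(noiseless_methanol)
        assert ((rs["f"] > 0) & (rs["f"] <= 1.0)).all()
        assert (rs["x_sulfate"] >= 0).all()
        inner = rs[(rs["f"] < 1) & (rs["f"] > 0)]
        assert ((inner["x_sulfide"] > -1) & (inner["x_sulfide"] < 0)).all()
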
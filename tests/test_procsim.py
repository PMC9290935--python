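"""Simulator: fixed points, stationary moments, determinism, serialization
and the measurement-error overlay."""

import io

import numpy as np
import pandas as pd
import pytest

import crosslag as cl
from crosslag.procsim import (ExplosionError, MeasurementErrorSpec, Panel,
                              ProcessSpec, add_measurement_error, default_spec,
                              simulate)


class TestProcessSpecValidation:
    @pytest.mark.parametrize("bad", [
        dict(kind="nope"),
        dict(kind="tradeoff_single", sigma_eps=-1.0),
        dict(kind="tradeoff_single", n_time=1),
        dict(kind="tradeoff_single", burn_in=-1),
        dict(kind="tradeoff_single", b=2.0, d=0.6),            # |b d| >= 1
        dict(kind="density_single", b=0.5, d=1.0, f=1.0, g=0.8),  # |bd+fg| >= 1
        dict(kind="tradeoff_multi", omega=[[1.0, 2.0], [2.0, 1.0]]),  # not PSD
        dict(kind="density_single", omega=[[0.2, 0.0], [0.0, 0.2]]),  # no REs allowed
    ])
    def test_invalid_specs_are_rejected_with_named_invariant(self, bad):
        with pytest.raises(ValueError):
            ProcessSpec(**bad)

    def test_spec_round_trips_through_yaml_and_json(self):
        spec = default_spec("grouplive_multi", seed=9)
        assert ProcessSpec.from_yaml(spec.to_yaml()) == spec
        assert ProcessSpec.from_json(spec.to_json()) == spec

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ProcessSpec.from_dict({"kind": "tradeoff_single", "bogus": 1})


class TestSimulate:
    def test_noiseless_fixed_point(self):
        # a=0, b=1, c=2, d=0, all noise off -> X = Y = 2 at every step
        spec = ProcessSpec(kind="tradeoff_single", a=0, b=1, c=2, d=0,
                           sigma_eps=0, sigma_kappa=0, n_time=6, burn_in=5)
        panel = simulate(spec)
        assert np.allclose(panel.data["X"], 2.0)
        assert np.allclose(panel.data["Y"], 2.0)

    def test_ar1_stationary_variance_and_autocorrelation(self):
        # X_t = bd X_{t-1} + d eps_{t-1} + kappa_t: Var = (d^2+1)/(1-(bd)^2)
        spec = ProcessSpec(kind="tradeoff_single", b=0.5, d=-0.5,
                           sigma_eps=1, sigma_kappa=1, n_time=200_000,
                           burn_in=200, seed=7)
        x = simulate(spec).data["X"].to_numpy()
        assert np.var(x) == pytest.approx(1.25 / (1 - 0.0625), rel=0.02)
        ac1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert ac1 == pytest.approx(-0.25, abs=0.01)

    def test_stationary_mean_matches_closed_form(self):
        spec = ProcessSpec(kind="tradeoff_single", a=1.0, b=0.4, c=2.0,
                           d=-0.5, sigma_eps=1, sigma_kappa=1,
                           n_time=200_000, burn_in=200, seed=8)
        x = simulate(spec).data["X"].to_numpy()
        expected = (2.0 + (-0.5) * 1.0) / (1 - 0.4 * (-0.5))
        assert np.mean(x) == pytest.approx(expected, abs=0.02)

    def test_identical_seed_gives_bit_identical_panels(self):
        spec = default_spec("grouplive_multi", n_subjects=20, n_time=8, seed=5)
        p1, p2 = simulate(spec), simulate(spec)
        pd.testing.assert_frame_equal(p1.data, p2.data)
        assert p1.data["X"].equals(p2.data["X"])

    def test_z_present_only_for_z_kinds(self):
        assert not simulate(default_spec("tradeoff_multi", n_subjects=3,
                                         n_time=4, seed=1)).has_z
        assert simulate(default_spec("density_single", n_time=4, seed=1)).has_z

    def test_explosive_recursion_raises_not_nan(self):
        # valid at construction (|bd + fg| < 1) but explosive in realization
        spec = ProcessSpec(kind="density_single", a=0, b=0.3, c=0, d=0.5,
                           f=1.0, g=0.8, sigma_eps=3, sigma_kappa=3,
                           sigma_lambda=3.0, n_time=4000, burn_in=0, seed=0)
        with pytest.raises(ExplosionError):
            simulate(spec)

    def test_realized_intercepts_match_omega(self):
        omega = np.array([[1.0, 0.6], [0.6, 1.0]])
        spec = default_spec("tradeoff_multi", omega=omega, n_subjects=10_000,
                            n_time=2, burn_in=0, seed=3)
        ints = simulate(spec).intercepts
        emp = np.cov(ints["mu"], ints["nu"])
        assert np.allclose(emp, omega, atol=0.05)

    def test_uncorrelated_increments_without_crosslag(self):
        # d=0, f=0, Omega=0: steps of X and Y are independent
        spec = ProcessSpec(kind="tradeoff_single", b=0.0, d=0.0,
                           sigma_eps=1, sigma_kappa=1, n_time=50_000,
                           burn_in=10, seed=4)
        d = simulate(spec).data
        dx, dy = np.diff(d["X"]), np.diff(d["Y"])
        assert abs(np.corrcoef(dx, dy)[0, 1]) < 0.02

    def test_negative_crosslag_makes_x_track_previous_y_negatively(self):
        spec = default_spec("tradeoff_single", n_time=50_000, seed=6)
        d = simulate(spec).data
        x, y = d["X"].to_numpy(), d["Y"].to_numpy()
        assert np.corrcoef(x[1:], y[:-1])[0, 1] < -0.2


class TestPanel:
    def test_duplicate_subject_time_rejected(self):
        df = pd.DataFrame({"subject": [1, 1], "time": [1, 1],
                           "X": [0.0, 1.0], "Y": [0.0, 1.0]})
        with pytest.raises(ValueError, match="unique"):
            Panel(df)

    def test_nonfinite_values_rejected(self):
        df = pd.DataFrame({"subject": [1, 1], "time": [1, 2],
                           "X": [0.0, np.inf], "Y": [0.0, 1.0]})
        with pytest.raises(ValueError, match="finite"):
            Panel(df)

    def test_csv_round_trip(self, tmp_path):
        panel = simulate(default_spec("grouplive_multi", n_subjects=4,
                                      n_time=5, seed=2))
        path = tmp_path / "panel.csv"
        panel.to_csv(path, meta={"seed": 2})
        back = Panel.from_csv(str(path))
        pd.testing.assert_frame_equal(back.data, panel.data)


class TestMeasurementError:
    def test_zero_fraction_is_identity(self, tradeoff_panel):
        out = add_measurement_error(tradeoff_panel, MeasurementErrorSpec(0, 0, seed=1))
        assert np.array_equal(out.data["X_obs"], out.data["X"])
        assert np.array_equal(out.data["Y_obs"], out.data["Y"])

    def test_fraction_bounds_validated(self):
        with pytest.raises(ValueError):
            MeasurementErrorSpec(frac_x=1.0)
        with pytest.raises(ValueError):
            MeasurementErrorSpec(frac_y=-0.1)

    def test_reliability_identity_at_quarter_error(self):
        # two independent contaminations of the same truth correlate at 0.75
        spec = default_spec("tradeoff_single", n_time=100_000, seed=10)
        panel = simulate(spec)
        a = add_measurement_error(panel, MeasurementErrorSpec(0.25, 0.25, seed=1))
        b = add_measurement_error(panel, MeasurementErrorSpec(0.25, 0.25, seed=2))
        r = np.corrcoef(a.data["X_obs"], b.data["X_obs"])[0, 1]
        assert r == pytest.approx(0.75, abs=0.01)

    def test_total_variance_decomposition(self, tradeoff_panel):
        out = add_measurement_error(tradeoff_panel,
                                    MeasurementErrorSpec(frac_x=0.25, seed=3))
        vx_true = tradeoff_panel.data["X"].var(ddof=1)
        assert out.error_variances["X"] == pytest.approx(vx_true / 3.0)

    def test_true_columns_retained(self, tradeoff_panel):
        out = add_measurement_error(tradeoff_panel,
                                    MeasurementErrorSpec(0.25, 0.25, seed=4))
        pd.testing.assert_series_equal(out.data["X"], tradeoff_panel.data["X"])
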
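from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from npniche.nullmodel import NullEnsemble
from npniche.tradeoff import (
    N_SIDE,
    P_SIDE,
    NullBand,
    _ols_slope,
    fit_quantreg,
    null_band,
    pinball_loss,
    polynomial_design,
    quantreg_ci,
    residual_widths,
    side_masks,
    subset_slopes,
)


def _vertex_oracle_loss(x, y, tau, degree):
    """Minimal pinball loss by enumerating all interpolating vertex fits."""
    p = degree + 1
    best = np.inf
    for subset in combinations(range(len(x)), p):
        X = polynomial_design(x[list(subset)], degree)
        if abs(np.linalg.det(X)) < 1e-12:
            continue
        beta = np.linalg.solve(X, y[list(subset)])
        loss = pinball_loss(y, polynomial_design(x, degree) @ beta, tau)
        best = min(best, loss)
    return best


class TestFitQuantreg:
    @pytest.mark.parametrize("tau", [0.5, 0.75, 0.9])
    def test_interpolable_parabola_recovered(self, tau):
        x = np.linspace(0, 2, 15)
        y = 0 + 2 * x - 1 * x**2
        fit = fit_quantreg(x, y, tau)
        assert fit.coefficients == pytest.approx([0.0, 2.0, -1.0], abs=1e-8)
        assert fit.pinball_loss == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("tau", [0.25, 0.5, 0.9])
    @pytest.mark.parametrize("degree", [1, 2])
    def test_matches_vertex_enumeration_oracle(self, tau, degree):
        rng = np.random.default_rng(17 + degree)
        x = rng.uniform(0, 1, 12)
        y = 0.5 + x - 0.8 * x**2 + rng.normal(0, 0.2, 12)
        fit = fit_quantreg(x, y, tau, degree)
        oracle = _vertex_oracle_loss(x, y, tau, degree)
        assert fit.pinball_loss == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_median_slope_within_ci_of_truth(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 300)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.1, 300)
        fit = fit_quantreg(x, y, 0.5, degree=1)
        ci = quantreg_ci(x, y, 0.5, degree=1, n_boot=200, seed=3)
        assert ci[1, 0] <= 0.5 <= ci[1, 1]
        assert abs(fit.coefficients[1] - 0.5) < 0.1

    @pytest.mark.parametrize("tau", [0.5, 0.75, 0.9])
    def test_quantile_count_property(self, tau):
        rng = np.random.default_rng(23)
        x = rng.uniform(0, 2, 120)
        y = 0.3 + 0.4 * x - 0.2 * x**2 + rng.gamma(2, 0.1, 120)
        fit = fit_quantreg(x, y, tau)
        pred = fit.predict(x)
        assert np.sum(y < pred - 1e-9) <= tau * 120
        assert np.sum(y > pred + 1e-9) <= (1 - tau) * 120

    def test_scale_equivariance(self):
        rng = np.random.default_rng(31)
        x = rng.uniform(0, 1, 60)
        y = 0.2 + x - 0.5 * x**2 + rng.normal(0, 0.05, 60)
        base = fit_quantreg(x, y, 0.75)
        scaled = fit_quantreg(x, 3.5 * y, 0.75)
        assert scaled.coefficients == pytest.approx(3.5 * base.coefficients, abs=1e-6)

    def test_degenerate_design_errors(self):
        with pytest.raises(ValueError, match="constant"):
            fit_quantreg(np.ones(10), np.arange(10.0), 0.5)
        with pytest.raises(ValueError):
            fit_quantreg(np.arange(3.0), np.arange(3.0), 0.5, degree=2)


class TestQuantregCI:
    def test_zero_width_on_noiseless_data(self):
        x = np.linspace(0, 1, 30)
        y = 1 + 2 * x - x**2
        ci = quantreg_ci(x, y, 0.5, n_boot=100, seed=1)
        assert np.allclose(ci[:, 0], ci[:, 1], atol=1e-7)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 40)
        y = x + rng.normal(0, 0.1, 40)
        a = quantreg_ci(x, y, 0.5, n_boot=120, seed=9)
        b = quantreg_ci(x, y, 0.5, n_boot=120, seed=9)
        assert np.array_equal(a, b)


def _toy_ensemble(positions_row, widths_row, n_replicates=10):
    S = len(positions_row)
    return NullEnsemble(
        species_ids=tuple(f"s{i}" for i in range(S)),
        master_seed=0,
        positions=np.tile(positions_row, (n_replicates, 1)),
        widths=np.tile(widths_row, (n_replicates, 1)),
        occurrences=np.full((n_replicates, S), 10, dtype=np.int32),
    )


class TestNullBand:
    def test_identical_replicates_collapse_to_single_fit(self):
        pos = np.linspace(0.8, 1.3, 20)
        wid = 0.1 + 0.5 * pos - 0.3 * pos**2
        ens = _toy_ensemble(pos, wid)
        band = null_band(ens, grid=np.linspace(0.8, 1.3, 11))
        single = fit_quantreg(pos, wid, 0.5)
        assert band.band_lower == pytest.approx(band.band_upper)
        assert band.mean_prediction() == pytest.approx(single.predict(band.grid), abs=1e-6)

    def test_band_contains_mean_curve(self, small_synthetic):
        from npniche.niche import select_pool
        from npniche.nullmodel import build_ensemble

        ds, _ = small_synthetic
        pool = select_pool(ds.matrix, 10)
        ens = build_ensemble(ds.matrix, ds.log_np(), pool, n_replicates=40, master_seed=3)
        band = null_band(ens, grid=np.linspace(0.95, 1.15, 21))
        assert np.all(band.band_lower <= band.mean_prediction() + 1e-9)
        assert np.all(band.mean_prediction() <= band.band_upper + 1e-9)


class TestResiduals:
    def _estimates(self, pos, wid):
        return pd.DataFrame(
            {
                "species_id": [f"s{i}" for i in range(len(pos))],
                "n_plots": 10, "position": pos, "width": wid,
                "extremity": np.abs(pos - pos.mean()),
                "residual_width": np.nan, "endangered": False,
            }
        )

    def test_on_curve_and_offset(self):
        x = np.linspace(0, 2, 12)
        y = 1 + x - 0.5 * x**2
        fit = fit_quantreg(x, y, 0.5)
        est = self._estimates(x, y + np.where(np.arange(12) == 3, 0.1, 0.0))
        est = residual_widths(est, fit)
        assert est.residual_width.iloc[0] == pytest.approx(0.0, abs=1e-8)
        assert est.residual_width.iloc[3] == pytest.approx(0.1, abs=1e-8)

    def test_median_sign_balance(self):
        rng = np.random.default_rng(41)
        pos = rng.uniform(0.7, 1.5, 150)
        wid = 0.4 - 0.3 * (pos - 1.1) ** 2 + rng.normal(0, 0.05, 150)
        fit = fit_quantreg(pos, wid, 0.5)
        est = residual_widths(self._estimates(pos, wid), fit)
        r = est.residual_width.to_numpy()
        assert np.sum(r < -1e-9) <= 75
        assert np.sum(r > 1e-9) <= 75


class TestSubsetSlopes:
    def test_ols_slope_matches_hand_computation(self):
        # x deviations (-1.5,-.5,.5,1.5), y deviations (.2,0,.1,-.3):
        # slope = -0.7 / 5 = -0.14
        assert _ols_slope(np.arange(4.0), np.array([1.0, 0.8, 0.9, 0.5])) == pytest.approx(-0.14)

    def test_constant_widths_give_zero_slope(self):
        pos = np.linspace(0.8, 1.4, 30)
        est = pd.DataFrame(
            {
                "species_id": [f"s{i}" for i in range(30)],
                "n_plots": 10, "position": pos, "width": 0.3,
                "extremity": np.abs(pos - 1.05), "residual_width": 0.0,
                "endangered": False,
            }
        )
        ens = _toy_ensemble(pos, np.full(30, 0.3))
        slopes = subset_slopes(est, ens, grand_mean=1.05)
        for s in slopes.values():
            assert s.slope_real == pytest.approx(0.0, abs=1e-12)
            assert 0 < s.p_value <= 1

    def test_overlap_masks_share_colimited_species(self):
        pos = np.array([1.0, 1.14, 1.25])  # N-limited, co-limited, P-limited
        masks = side_masks(pos, "overlap")
        assert list(masks[N_SIDE]) == [True, True, False]
        assert list(masks[P_SIDE]) == [False, True, True]
        disjoint = side_masks(pos, "midpoint_split")
        assert not np.any(disjoint[N_SIDE] & disjoint[P_SIDE])
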
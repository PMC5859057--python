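"""Niche-width vs niche-position trade-off analysis.

Because width variance is strongly heterogeneous along the gradient, the
relationship is characterised with quadratic quantile regressions (tau =
0.50, 0.75, 0.90, 0.95 by default) rather than a mean fit.  Each fit
minimises the pinball (check) loss exactly, as a linear program, which
makes optimality verifiable against enumeration oracles.  The median
(tau = 0.5) fit on every null replicate yields an average null regression
and a pointwise 95% envelope of predicted widths; the median fit on the
real data supplies residual widths.  Finally, the decrease of width
toward each gradient extreme is summarised by a linear slope per subset
(N-(co-)limited and P-(co-)limited sides) and tested against the null
replicate slope distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .nullmodel import NullEnsemble
from .stoichiometry import NP_LOWER, NP_UPPER

logger = logging.getLogger(__name__)

DEFAULT_TAUS = (0.50, 0.75, 0.90, 0.95)


@dataclass(frozen=True)
class QuantRegFit:
    tau: float
    coefficients: np.ndarray  # (intercept, linear, quadratic, ...) ascending degree
    ci95: np.ndarray | None  # (degree+1, 2) percentile bounds, or None
    n: int
    pinball_loss: float

    def predict(self, positions: np.ndarray) -> np.ndarray:
        return polynomial_design(np.asarray(positions, dtype=float), self.degree) @ self.coefficients

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1


def polynomial_design(positions: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(positions, degree + 1, increasing=True)


def pinball_loss(y: np.ndarray, pred: np.ndarray, tau: float) -> float:
    r = np.asarray(y, dtype=float) - np.asarray(pred, dtype=float)
    return float(np.sum(np.where(r >= 0, tau * r, (tau - 1) * r)))


def fit_quantreg(
    positions: np.ndarray, widths: np.ndarray, tau: float, degree: int = 2
) -> QuantRegFit:
    """Exact tau-quantile polynomial regression via linear programming.

    Decision variables are the coefficients (free) and the positive and
    negative parts of each residual; the objective is the pinball loss.
    HiGHS solves the LP deterministically.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(widths, dtype=float)
    n = x.size
    if n <= degree + 1:
        raise ValueError(f"need more than {degree + 1} points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("positions are constant: design is degenerate")
    if not 0 < tau < 1:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    X = polynomial_design(x, degree)
    p = degree + 1
    c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1 - tau)])
    A_eq = np.hstack([X, np.eye(n), -np.eye(n)])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile regression LP failed: {res.message}")
    beta = res.x[:p]
    return QuantRegFit(
        tau=tau,
        coefficients=beta,
        ci95=None,
        n=n,
        pinball_loss=pinball_loss(y, X @ beta, tau),
    )


def quantreg_ci(
    positions: np.ndarray,
    widths: np.ndarray,
    tau: float,
    degree: int = 2,
    n_boot: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Case-resampling bootstrap percentile 95% intervals per coefficient."""
    if n_boot < 100:
        logger.warning("n_boot=%d < 100: intervals will be unstable", n_boot)
    x = np.asarray(positions, dtype=float)
    y = np.asarray(widths, dtype=float)
    rng = np.random.default_rng(seed)
    n = x.size
    coefs = np.empty((n_boot, degree + 1))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        while np.ptp(x[idx]) == 0:  # redraw degenerate resamples
            idx = rng.integers(0, n, size=n)
        coefs[b] = fit_quantreg(x[idx], y[idx], tau, degree).coefficients
    return np.quantile(coefs, [0.025, 0.975], axis=0).T


@dataclass(frozen=True)
class NullBand:
    tau: float
    grid: np.ndarray
    mean_coefficients: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    n_replicates_used: int
    n_replicates_skipped: int

    def mean_prediction(self, positions: np.ndarray | None = None) -> np.ndarray:
        pos = self.grid if positions is None else np.asarray(positions, dtype=float)
        return polynomial_design(pos, len(self.mean_coefficients) - 1) @ self.mean_coefficients


def _replicate_fit_data(ensemble: NullEnsemble, i: int) -> tuple[np.ndarray, np.ndarray]:
    pos = ensemble.positions[i]
    wid = ensemble.widths[i]
    ok = np.isfinite(pos) & np.isfinite(wid)
    return pos[ok], wid[ok]


def null_band(
    ensemble: NullEnsemble,
    tau: float = 0.5,
    degree: int = 2,
    grid: np.ndarray | None = None,
    grid_points: int = 101,
) -> NullBand:
    """Average null regression and pointwise 95% envelope over the grid."""
    if grid is None:
        finite = ensemble.positions[np.isfinite(ensemble.positions)]
        grid = np.linspace(finite.min(), finite.max(), grid_points)
    grid = np.asarray(grid, dtype=float)
    design = polynomial_design(grid, degree)
    preds = []
    coefs = []
    skipped = 0
    for i in range(ensemble.n_replicates):
        pos, wid = _replicate_fit_data(ensemble, i)
        if pos.size < degree + 2 or np.ptp(pos) == 0:
            skipped += 1
            continue
        try:
            fit = fit_quantreg(pos, wid, tau, degree)
        except (ValueError, RuntimeError):
            skipped += 1
            continue
        coefs.append(fit.coefficients)
        preds.append(design @ fit.coefficients)
    if not coefs:
        raise ValueError("no replicate yielded a valid quantile fit")
    if skipped:
        logger.info("null_band: skipped %d replicates without a valid fit", skipped)
    preds = np.asarray(preds)
    lower, upper = np.quantile(preds, [0.025, 0.975], axis=0)
    return NullBand(
        tau=tau,
        grid=grid,
        mean_coefficients=np.mean(coefs, axis=0),
        band_lower=lower,
        band_upper=upper,
        n_replicates_used=len(coefs),
        n_replicates_skipped=skipped,
    )


def residual_widths(estimates: pd.DataFrame, median_fit: QuantRegFit) -> pd.DataFrame:
    """Fill residual_width = width - predicted width at the species position."""
    estimates = estimates.copy()
    estimates["residual_width"] = estimates["width"] - median_fit.predict(
        estimates["position"].to_numpy()
    )
    return estimates


# ---------------------------------------------------------------------------
# subset slopes toward the gradient extremes

N_SIDE = "N_side"
P_SIDE = "P_side"


@dataclass(frozen=True)
class SlopeComparison:
    side: str
    slope_real: float
    null_slopes: np.ndarray
    p_value: float
    n_real: int
    n_replicates: int  # all replicates; those without >= min_subset species count
    # against the alternative (their subset never produced the real trend)

    @property
    def null_slope_mean(self) -> float:
        return float(self.null_slopes.mean()) if self.null_slopes.size else float("nan")


def side_masks(
    positions: np.ndarray, mode: str = "overlap"
) -> dict[str, np.ndarray]:
    """Membership of the N-(co-)limited and P-(co-)limited subsets.

    'overlap' (default): the N side takes every species up to the
    P-limitation threshold and the P side every species from the
    N-limitation threshold on, so co-limited species belong to both.
    'midpoint_split' partitions at the log-midpoint of the co-limited
    band instead.
    """
    log_lower, log_upper = np.log10(NP_LOWER), np.log10(NP_UPPER)
    positions = np.asarray(positions, dtype=float)
    if mode == "overlap":
        return {
            N_SIDE: positions <= log_upper,
            P_SIDE: positions >= log_lower,
        }
    if mode == "midpoint_split":
        mid = (log_lower + log_upper) / 2
        return {N_SIDE: positions < mid, P_SIDE: positions >= mid}
    raise ValueError(f"unknown subset mode {mode!r}")


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    denom = np.sum(xc * xc)
    if denom == 0:
        raise ValueError("constant predictor: slope undefined")
    return float(np.sum(xc * (y - y.mean())) / denom)


def _side_extremity(positions: np.ndarray, side: str, grand_mean: float) -> np.ndarray:
    """Signed distance toward the side's gradient end (larger = more extreme)."""
    if side == N_SIDE:
        return grand_mean - np.asarray(positions, dtype=float)
    return np.asarray(positions, dtype=float) - grand_mean


def subset_slopes(
    estimates: pd.DataFrame,
    ensemble: NullEnsemble,
    grand_mean: float,
    mode: str = "overlap",
    min_subset: int = 3,
) -> dict[str, SlopeComparison]:
    """Width-vs-extremity slope per side, against the null slope distribution.

    Widths are regressed on the side-specific extremity so that a negative
    slope always reads "narrower toward the extreme".  The one-sided p is
    the add-one-corrected fraction of replicates whose slope is at least
    as negative as the real one, over ALL replicates: a replicate whose
    subset is too sparse to yield a slope never produced the real trend,
    so it counts against the alternative.
    """
    results = {}
    pos_real = estimates["position"].to_numpy()
    wid_real = estimates["width"].to_numpy()
    for side, mask in side_masks(pos_real, mode).items():
        if mask.sum() < min_subset:
            raise ValueError(f"{side}: fewer than {min_subset} species with widths")
        ext = _side_extremity(pos_real[mask], side, grand_mean)
        slope_real = _ols_slope(ext, wid_real[mask])
        null_slopes = []
        for i in range(ensemble.n_replicates):
            pos, wid = _replicate_fit_data(ensemble, i)
            m = side_masks(pos, mode)[side]
            if m.sum() < min_subset:
                continue
            try:
                null_slopes.append(
                    _ols_slope(_side_extremity(pos[m], side, grand_mean), wid[m])
                )
            except ValueError:
                continue
        null_slopes = np.asarray(null_slopes)
        if null_slopes.size < ensemble.n_replicates:
            logger.info(
                "%s: %d of %d replicates had no computable slope",
                side, ensemble.n_replicates - null_slopes.size, ensemble.n_replicates,
            )
        p = (1 + int(np.sum(null_slopes <= slope_real))) / (1 + ensemble.n_replicates)
        results[side] = SlopeComparison(
            side=side,
            slope_real=slope_real,
            null_slopes=null_slopes,
            p_value=p,
            n_real=int(mask.sum()),
            n_replicates=ensemble.n_replicates,
        )
    return results
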
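"""Unimodal-vs-bimodal tests for the niche-position distribution.

The reference (unimodal) model is a single Gaussian on the log N:P
scale; the alternative is a two-component Gaussian mixture fitted by EM.
Two statistics compare them: the likelihood ratio -2 ln(Lambda) =
2 (llBimodal - llUnimodal), and the difference Delta R^2 in variance
explained by each fitted density against the empirical histogram.
Critical values for both come from a parametric bootstrap: samples of
the same size are drawn from the fitted unimodal model, refit with both
models, and the empirical upper quantiles at p = 0.10, 0.05 and 0.01
taken.  Bimodality is declared only when BOTH statistics exceed their
critical values.

Because both statistics are invariant under location-scale changes of
the data (the Gaussian family is location-scale and the histogram bins
span the data range), critical values depend only on the sample size,
which lets one simulated table serve all null-ensemble replicates.

The real niche-position distribution is also compared against the null
ensemble with averaged two-sample Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .nullmodel import NullEnsemble

DEFAULT_LEVELS = (0.10, 0.05, 0.01)
SIGMA_FLOOR_FACTOR = 1e-3  # component sd floor, relative to sample sd


# ---------------------------------------------------------------------------
# histogram R^2 machinery

def histogram_edges(x: np.ndarray, rule: str = "sturges") -> np.ndarray:
    """Bin edges spanning the data range.

    ``rule`` is 'sturges' (default), 'fd', or 'fixed:<k>' for k equal bins.
    """
    x = np.asarray(x, dtype=float)
    if rule == "sturges":
        k = int(np.ceil(np.log2(x.size))) + 1
    elif rule == "fd":
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        h = 2 * iqr / x.size ** (1 / 3)
        k = max(1, int(np.ceil((x.max() - x.min()) / h))) if h > 0 else 1
    elif rule.startswith("fixed:"):
        k = int(rule.split(":", 1)[1])
    else:
        raise ValueError(f"unknown histogram rule {rule!r}")
    return np.linspace(x.min(), x.max(), k + 1)


def _hist_r2(x: np.ndarray, model_cdf, edges: np.ndarray) -> float:
    """1 - SSE/SST between bin relative frequencies and model bin probabilities."""
    counts, _ = np.histogram(x, bins=edges)
    obs = counts / counts.sum()
    model = np.diff(model_cdf(edges))
    sse = float(np.sum((obs - model) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        return 1.0 if sse == 0 else -np.inf
    return 1.0 - sse / sst


# ---------------------------------------------------------------------------
# model fits

@dataclass(frozen=True)
class UnimodalFit:
    mean: float
    sd: float
    log_likelihood: float
    r2: float


@dataclass(frozen=True)
class BimodalFit:
    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    log_likelihood: float
    r2: float
    converged: bool

    @property
    def n_modes(self) -> int:
        """Modes of the fitted density (a two-component fit can be unimodal)."""
        return mixture_mode_count(self.weights, self.means, self.sds)


def mixture_mode_count(
    weights: tuple[float, float], means: tuple[float, float], sds: tuple[float, float]
) -> int:
    """Count local maxima of a two-component Gaussian mixture density.

    A two-component fit with coincident means (a scale mixture, as EM
    produces on heavy-tailed but single-peaked data) has one mode; only a
    genuinely two-peaked density counts as bimodal.  Evaluated on a dense
    grid spanning the components.
    """
    lo = min(means) - 4 * max(sds)
    hi = max(means) + 4 * max(sds)
    grid = np.linspace(lo, hi, 2001)
    pdf = weights[0] * stats.norm.pdf(grid, means[0], sds[0]) + weights[1] * stats.norm.pdf(
        grid, means[1], sds[1]
    )
    interior = (pdf[1:-1] > pdf[:-2]) & (pdf[1:-1] > pdf[2:])
    return max(1, int(interior.sum()))


def fit_unimodal(x: np.ndarray, histogram_rule: str = "sturges") -> UnimodalFit:
    """Gaussian maximum-likelihood fit (MLE sd, i.e. n denominator)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: unimodal fit undefined")
    sd = float(x.std(ddof=0))
    mean = float(x.mean())
    ll = float(np.sum(stats.norm.logpdf(x, mean, sd)))
    edges = histogram_edges(x, histogram_rule)
    r2 = _hist_r2(x, lambda e: stats.norm.cdf(e, mean, sd), edges)
    return UnimodalFit(mean=mean, sd=sd, log_likelihood=ll, r2=r2)


def _em_vectorized(
    x: np.ndarray,
    w0: np.ndarray,
    mu0: np.ndarray,
    s0: np.ndarray,
    tol: float,
    max_iter: int,
    sigma_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run EM for R restarts simultaneously on 1-D data, K=2 components.

    Returns (weights, means, sds, log_likelihoods, converged) with leading
    dimension R.  The EM log-likelihood is non-decreasing per restart.
    """
    n = x.size
    w = w0.copy()  # (R, 2)
    mu = mu0.copy()
    sig = np.maximum(s0, sigma_floor)
    ll_prev = np.full(w.shape[0], -np.inf)
    converged = np.zeros(w.shape[0], dtype=bool)
    xx = x[None, None, :]  # (1, 1, n)
    for _ in range(max_iter):
        # E-step in log space: (R, 2, n)
        z = (xx - mu[:, :, None]) / sig[:, :, None]
        log_comp = (
            np.log(w[:, :, None])
            - 0.5 * z * z
            - np.log(sig[:, :, None])
            - 0.5 * math.log(2 * math.pi)
        )
        m = log_comp.max(axis=1, keepdims=True)
        lse = m[:, 0, :] + np.log(np.exp(log_comp - m).sum(axis=1))  # (R, n)
        ll = lse.sum(axis=1)
        resp = np.exp(log_comp - lse[:, None, :])  # (R, 2, n)
        # M-step
        nk = resp.sum(axis=2)  # (R, 2)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp @ x) / nk
        var = (resp @ (x * x)) / nk - mu * mu
        sig = np.sqrt(np.maximum(var, sigma_floor**2))
        newly = np.abs(ll - ll_prev) < tol
        converged |= newly
        ll_prev = ll
        if converged.all():
            break
    return w, mu, sig, ll_prev, converged


def _bimodal_inits(
    x: np.ndarray, n_restarts: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Initial (weights, means, sds) for each restart.

    Restart 0 is the collapsed mixture (both components equal to the
    Gaussian MLE), which nests the unimodal model and guarantees the
    mixture log-likelihood is never below the unimodal one.  Restart 1
    splits the sample at its median (k-means-style seeding); the rest
    perturb randomly around data points.
    """
    n = x.size
    mean, sd = x.mean(), x.std(ddof=0)
    w0 = np.full((n_restarts, 2), 0.5)
    mu0 = np.empty((n_restarts, 2))
    s0 = np.empty((n_restarts, 2))
    mu0[0] = (mean, mean)
    s0[0] = (sd, sd)
    if n_restarts > 1:
        med = np.median(x)
        lo, hi = x[x <= med], x[x > med]
        if hi.size == 0:  # all values at/below the median
            lo, hi = x, x
        mu0[1] = (lo.mean(), hi.mean())
        s0[1] = (max(lo.std(ddof=0), sd / 4), max(hi.std(ddof=0), sd / 4))
        w0[1] = (lo.size / n, max(hi.size, 1) / n)
        w0[1] /= w0[1].sum()
    for r in range(2, n_restarts):
        pair = rng.choice(n, size=2, replace=False)
        mu0[r] = np.sort(x[pair])
        s0[r] = sd * rng.uniform(0.3, 1.0, size=2)
        p = rng.uniform(0.2, 0.8)
        w0[r] = (p, 1 - p)
    return w0, mu0, s0


def fit_bimodal(
    x: np.ndarray,
    n_restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | np.random.Generator = 0,
    histogram_rule: str = "sturges",
) -> BimodalFit:
    """Two-component Gaussian mixture by EM, best of ``n_restarts`` starts."""
    x = np.asarray(x, dtype=float)
    if x.size < 6:
        raise ValueError("need at least 6 observations for a mixture fit")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: mixture fit undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma_floor = SIGMA_FLOOR_FACTOR * x.std(ddof=0)
    w0, mu0, s0 = _bimodal_inits(x, n_restarts, rng)
    w, mu, sig, ll, conv = _em_vectorized(x, w0, mu0, s0, tol, max_iter, sigma_floor)
    best = int(np.argmax(ll))
    order = np.argsort(mu[best])
    weights = tuple(w[best][order])
    means = tuple(mu[best][order])
    sds = tuple(sig[best][order])
    edges = histogram_edges(x, histogram_rule)

    def cdf(e):
        return weights[0] * stats.norm.cdf(e, means[0], sds[0]) + weights[1] * stats.norm.cdf(
            e, means[1], sds[1]
        )

    r2 = _hist_r2(x, cdf, edges)
    return BimodalFit(
        weights=weights,
        means=means,
        sds=sds,
        log_likelihood=float(ll[best]),
        r2=r2,
        converged=bool(conv.any()),
    )


# ---------------------------------------------------------------------------
# the modality decision

@dataclass(frozen=True)
class CriticalValues:
    """Simulated upper quantiles of (-2 ln Lambda, Delta R^2) per level."""

    n: int
    n_sim: int
    table: dict[float, tuple[float, float]]


@dataclass(frozen=True)
class ModalityResult:
    minus2lnLambda: float
    delta_r2: float
    critical_values: dict[float, tuple[float, float]]
    verdict: dict[float, str]  # level -> 'unimodal' | 'bimodal'
    unimodal: UnimodalFit
    bimodal: BimodalFit


def _both_stats(
    x: np.ndarray,
    n_restarts: int,
    tol: float,
    max_iter: int,
    rng: np.random.Generator,
    histogram_rule: str,
) -> tuple[float, float, bool]:
    uni = fit_unimodal(x, histogram_rule)
    bi = fit_bimodal(x, n_restarts, tol, max_iter, rng, histogram_rule)
    two_moded = bi.converged and bi.n_modes >= 2
    return 2.0 * (bi.log_likelihood - uni.log_likelihood), bi.r2 - uni.r2, two_moded


def simulate_critical_values(
    n: int,
    n_sim: int = 1000,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    histogram_rule: str = "sturges",
) -> CriticalValues:
    """Null sampling distribution of both statistics at sample size ``n``.

    Samples are drawn from a standard Gaussian; by location-scale
    invariance the resulting quantiles apply to any fitted unimodal model
    of the same sample size.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    lr = np.empty(n_sim)
    dr2 = np.empty(n_sim)
    for i in range(n_sim):
        sim = rng.standard_normal(n)
        lr[i], dr2[i], _ = _both_stats(sim, n_restarts, tol, max_iter, rng, histogram_rule)
    table = {
        level: (
            float(np.quantile(lr, 1 - level)),
            float(np.quantile(dr2, 1 - level)),
        )
        for level in levels
    }
    return CriticalValues(n=n, n_sim=n_sim, table=table)


def modality_test(
    x: np.ndarray,
    n_sim: int = 1000,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    seed: int = 0,
    n_restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 500,
    histogram_rule: str = "sturges",
    critical_values: CriticalValues | None = None,
) -> ModalityResult:
    """Decide unimodal vs bimodal for the niche-position sample ``x``.

    Verdict at a level is 'bimodal' only when the fitted two-component
    density actually has two modes AND both -2 ln Lambda and Delta R^2
    exceed their simulated critical values (a second component that only
    captures heavy tails does not make the distribution bimodal).  Pass
    ``critical_values`` to reuse a table simulated at the same n.
    """
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    uni = fit_unimodal(x, histogram_rule)
    bi = fit_bimodal(x, n_restarts, tol, max_iter, rng, histogram_rule)
    if not bi.converged:
        lr_data, dr2_data = 0.0, 0.0
    else:
        lr_data = 2.0 * (bi.log_likelihood - uni.log_likelihood)
        dr2_data = bi.r2 - uni.r2
    if critical_values is None:
        critical_values = simulate_critical_values(
            x.size, n_sim, levels, seed + 1, n_restarts, tol, max_iter, histogram_rule
        )
    elif critical_values.n != x.size:
        raise ValueError(
            f"critical values simulated at n={critical_values.n}, data has n={x.size}"
        )
    two_moded = bi.converged and bi.n_modes >= 2
    verdict = {}
    for level, (lr_crit, dr2_crit) in critical_values.table.items():
        bimodal = two_moded and lr_data > lr_crit and dr2_data > dr2_crit
        verdict[level] = "bimodal" if bimodal else "unimodal"
    return ModalityResult(
        minus2lnLambda=lr_data,
        delta_r2=dr2_data,
        critical_values=dict(critical_values.table),
        verdict=verdict,
        unimodal=uni,
        bimodal=bi,
    )


def ensemble_modality_rate(
    ensemble: NullEnsemble,
    critical_values: CriticalValues,
    level: float = 0.05,
    n_restarts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
    histogram_rule: str = "sturges",
    max_replicates: int | None = None,
) -> float:
    """Fraction of null replicates judged unimodal at ``level``.

    Each replicate's position sample is subsampled (or used whole) to the
    critical table's n, its statistics computed, and compared against the
    shared table — valid because the statistics are location-scale pivotal.
    """
    if level not in critical_values.table:
        raise ValueError(f"level {level} not in critical-value table")
    lr_crit, dr2_crit = critical_values.table[level]
    rng = np.random.default_rng(seed)
    n_rep = ensemble.n_replicates if max_replicates is None else min(
        max_replicates, ensemble.n_replicates
    )
    unimodal = 0
    for i in range(n_rep):
        pos = ensemble.replicate_positions(i)
        if pos.size > critical_values.n:
            pos = rng.choice(pos, size=critical_values.n, replace=False)
        lr, dr2, two_moded = _both_stats(pos, n_restarts, tol, max_iter, rng, histogram_rule)
        if not (two_moded and lr > lr_crit and dr2 > dr2_crit):
            unimodal += 1
    return unimodal / n_rep


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov comparison against the ensemble

@dataclass(frozen=True)
class KSComparison:
    mean_D: float
    mean_p: float
    n_comparisons: int


def ks_two_sample(x: np.ndarray, y: np.ndarray, exact_below: int = 30) -> tuple[float, float]:
    """Two-sample KS statistic and p; exact method for small samples."""
    method = "exact" if min(len(x), len(y)) < exact_below else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def ks_vs_ensemble(
    x: np.ndarray, ensemble: NullEnsemble, seed: int = 0, exact_below: int = 30
) -> KSComparison:
    """Average two-sample KS statistic/p of ``x`` against every replicate.

    When a replicate carries more positions than ``x`` (or vice versa) the
    longer sample is subsampled without replacement to the shorter length,
    so every comparison is of equal sample size.
    """
    x = np.asarray(x, dtype=float)
    if ensemble.n_replicates == 0:
        raise ValueError("empty ensemble")
    rng = np.random.default_rng(seed)
    ds = np.empty(ensemble.n_replicates)
    ps = np.empty(ensemble.n_replicates)
    for i in range(ensemble.n_replicates):
        rep = ensemble.replicate_positions(i)
        xa, ya = x, rep
        if rep.size > x.size:
            ya = rng.choice(rep, size=x.size, replace=False)
        elif rep.size < x.size:
            xa = rng.choice(x, size=rep.size, replace=False)
        ds[i], ps[i] = ks_two_sample(xa, ya, exact_below)
    return KSComparison(
        mean_D=float(ds.mean()), mean_p=float(ps.mean()), n_comparisons=ensemble.n_replicates
    )
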
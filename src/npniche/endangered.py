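"""Residual-niche-width comparisons for endangered vs non-endangered species.

Residual widths (observed minus the median-quantile-regression
prediction) are compared between endangered and non-endangered species
with a Mann-Whitney U test (exact significance where feasible), and
correlated with niche-position extremity within each group — and within
the endangered group split by N-limited vs co/P-limited niche positions
— with one-sided Spearman rank tests.  Distribution-free tests are used
because residual widths are neither (log-)normal nor homoscedastic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .stoichiometry import NP_LOWER

logger = logging.getLogger(__name__)

_SCIPY_ALTERNATIVE = {"less": "less", "greater": "greater", "two_sided": "two-sided"}


@dataclass(frozen=True)
class MWUResult:
    U: float
    p: float
    alternative: str
    group_medians: tuple[float, float]
    n1: int
    n2: int
    method: str  # 'exact' | 'asymptotic'


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    alternative: str
    n: int


def mann_whitney(
    a: np.ndarray, b: np.ndarray, alternative: str = "two_sided", exact_threshold: int = 25
) -> MWUResult:
    """Mann-Whitney U for two independent samples; U reported for ``a``.

    The exact null distribution is used when n1*n2 <= exact_threshold^2
    and the pooled sample is tie-free; otherwise the normal approximation
    with tie correction (exact enumeration under ties is exponential).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in _SCIPY_ALTERNATIVE:
        raise ValueError(f"alternative must be one of {sorted(_SCIPY_ALTERNATIVE)}")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact = a.size * b.size <= exact_threshold**2 and not has_ties
    method = "exact" if exact else "asymptotic"
    if has_ties and a.size * b.size <= exact_threshold**2:
        logger.info("mann_whitney: ties present, falling back to normal approximation")
    res = stats.mannwhitneyu(
        a,
        b,
        alternative=_SCIPY_ALTERNATIVE[alternative],
        method="exact" if exact else "asymptotic",
        use_continuity=not exact,
    )
    return MWUResult(
        U=float(res.statistic),
        p=float(res.pvalue),
        alternative=alternative,
        group_medians=(float(np.median(a)), float(np.median(b))),
        n1=a.size,
        n2=b.size,
        method=method,
    )


def spearman(x: np.ndarray, y: np.ndarray, alternative: str = "two_sided") -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    The p-value uses the t-approximation; the alternative direction is
    explicit in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need n >= 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input: correlation undefined")
    if alternative not in _SCIPY_ALTERNATIVE:
        raise ValueError(f"alternative must be one of {sorted(_SCIPY_ALTERNATIVE)}")
    res = stats.spearmanr(x, y, alternative=_SCIPY_ALTERNATIVE[alternative])
    return SpearmanResult(
        rho=float(res.statistic), p=float(res.pvalue), alternative=alternative, n=x.size
    )


def endangered_analysis(
    estimates: pd.DataFrame,
    mwu_alternative: str = "less",
    spearman_alternative: str = "greater",
    split_threshold: float | None = None,
    min_group: int = 3,
) -> dict[str, Any]:
    """All endangered-vs-non-endangered residual-width tests.

    Runs (i) Mann-Whitney on residual widths, endangered vs
    non-endangered (default alternative 'less': endangered residuals
    hypothesised smaller); (ii) Spearman extremity-vs-residual within
    endangered, within non-endangered, and within endangered split into
    N-limited vs co/P-limited niche positions at ``split_threshold``
    (default log10 of the N-limitation threshold).  Groups below
    ``min_group`` members skip their test with a logged reason.
    """
    if estimates["residual_width"].isna().any():
        raise ValueError("residual widths not filled; run the trade-off stage first")
    if split_threshold is None:
        split_threshold = float(np.log10(NP_LOWER))
    endangered = estimates[estimates["endangered"]]
    others = estimates[~estimates["endangered"]]
    out: dict[str, Any] = {
        "group_sizes": {"endangered": len(endangered), "non_endangered": len(others)},
        "group_medians": {
            "endangered": float(endangered["residual_width"].median()) if len(endangered) else None,
            "non_endangered": float(others["residual_width"].median()) if len(others) else None,
        },
        "split_threshold_log_np": split_threshold,
        "skipped": [],
    }
    if len(endangered) >= min_group and len(others) >= min_group:
        mwu = mann_whitney(
            endangered["residual_width"].to_numpy(),
            others["residual_width"].to_numpy(),
            alternative=mwu_alternative,
        )
        out["mann_whitney"] = vars(mwu) | {"group_medians": list(mwu.group_medians)}
    else:
        out["skipped"].append("mann_whitney: a group is below the minimum size")
        logger.info(out["skipped"][-1])
    subsets = {
        "endangered": endangered,
        "non_endangered": others,
        "endangered_n_limited": endangered[endangered["position"] < split_threshold],
        "endangered_co_p_limited": endangered[endangered["position"] >= split_threshold],
    }
    out["spearman"] = {}
    for name, sub in subsets.items():
        if len(sub) < min_group:
            out["skipped"].append(f"spearman[{name}]: fewer than {min_group} species")
            logger.info(out["skipped"][-1])
            continue
        try:
            res = spearman(
                sub["extremity"].to_numpy(),
                sub["residual_width"].to_numpy(),
                alternative=spearman_alternative,
            )
        except ValueError as exc:
            out["skipped"].append(f"spearman[{name}]: {exc}")
            logger.info(out["skipped"][-1])
            continue
        out["spearman"][name] = vars(res)
    return out
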
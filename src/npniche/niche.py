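"""Species niche position, width and extremity along the log N:P gradient.

The realized niche position of a species is the mean log10 N:P over the
plots where it occurs; its niche width is twice the sample standard
deviation of those values; its extremity is the absolute distance between
its position and the dataset-wide mean plot log10 N:P.  Positions are
estimated only for species occurring in at least ``min_occurrence`` plots
(10 by default), which keeps the position a stable average rather than an
artefact of one or two observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CommunityMatrix

DEFAULT_MIN_OCCURRENCE = 10


@dataclass(frozen=True)
class SpeciesPool:
    """Species meeting the occupancy criterion, with the pooled incidence sum."""

    species_ids: tuple[str, ...]
    min_occurrence: int
    total_observations: int

    def __len__(self) -> int:
        return len(self.species_ids)


def select_pool(
    matrix: CommunityMatrix, min_occurrence: int = DEFAULT_MIN_OCCURRENCE
) -> SpeciesPool:
    """Select the species occurring in at least ``min_occurrence`` plots."""
    occ = matrix.occurrence
    keep = occ >= min_occurrence
    if not keep.any():
        raise ValueError(
            f"no species occurs in >= {min_occurrence} plots; pool would be empty"
        )
    species = tuple(s for s, k in zip(matrix.species_ids, keep) if k)
    return SpeciesPool(
        species_ids=species,
        min_occurrence=min_occurrence,
        total_observations=int(occ[keep].sum()),
    )


def dataset_mean_log_np(plot_log_np: np.ndarray) -> float:
    """Arithmetic mean of plot log10 N:P over all retained plots."""
    arr = np.asarray(plot_log_np, dtype=float)
    if arr.size == 0:
        raise ValueError("no plots")
    return float(arr.mean())


def positions_and_widths(
    incidence: np.ndarray, plot_log_np: np.ndarray, min_width_occurrence: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (position, width, occurrence) for every matrix column.

    Species below ``min_width_occurrence`` occupied plots get NaN width;
    species with zero occurrences get NaN position as well.  Width uses
    the n-1 (sample) standard deviation, times two.
    """
    inc = np.asarray(incidence, dtype=float)
    x = np.asarray(plot_log_np, dtype=float)
    counts = inc.sum(axis=0)
    sums = inc.T @ x
    sumsq = inc.T @ (x * x)
    with np.errstate(invalid="ignore", divide="ignore"):
        positions = sums / counts
        ss = np.maximum(sumsq - sums * sums / counts, 0.0)
        widths = 2.0 * np.sqrt(ss / (counts - 1))
    positions[counts == 0] = np.nan
    widths[counts < min_width_occurrence] = np.nan
    return positions, widths, counts.astype(int)


def niche_estimates(
    matrix: CommunityMatrix,
    plot_log_np: np.ndarray,
    pool: SpeciesPool,
    endangered_flags: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Niche estimates for every pool species.

    Returns a DataFrame with columns species_id, n_plots, position, width,
    extremity, residual_width (NaN until the trade-off stage fills it) and
    endangered.
    """
    plot_log_np = np.asarray(plot_log_np, dtype=float)
    if plot_log_np.shape[0] != matrix.n_plots:
        raise ValueError("plot_log_np must have one value per matrix plot")
    sub = matrix.subset(species_ids=list(pool.species_ids))
    counts = sub.occurrence
    if (counts < 2).any():
        bad = [s for s, c in zip(sub.species_ids, counts) if c < 2]
        raise ValueError(f"width undefined for species with < 2 plots: {bad}")
    positions, widths, counts = positions_and_widths(sub.incidence, plot_log_np)
    grand_mean = dataset_mean_log_np(plot_log_np)
    flags = endangered_flags or {}
    return pd.DataFrame(
        {
            "species_id": list(pool.species_ids),
            "n_plots": counts,
            "position": positions,
            "width": widths,
            "extremity": np.abs(positions - grand_mean),
            "residual_width": np.nan,
            "endangered": [bool(flags.get(s, False)) for s in pool.species_ids],
        }
    )
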
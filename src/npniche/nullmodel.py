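"""Frequency-preserving bootstrap null model for community matrices.

Under the null hypothesis of no association between species occurrence
and the N:P gradient, each plot keeps its observed species richness but
its species are redrawn with replacement from the pooled multiset of all
species observations, so each species is drawn with probability
proportional to its observed occurrence count.  Within a plot, duplicate
draws are rejected and redrawn, because presence is binary and the plot
must keep exactly its original richness.  Row sums are therefore exact in
every replicate; column sums are preserved in expectation.

Reproducibility: replicate ``i`` uses the independent stream seeded by
``numpy.random.SeedSequence([master_seed, i])``, so ensembles are
bit-exact for a given master seed regardless of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import CommunityMatrix
from .niche import SpeciesPool

DEFAULT_N_REPLICATES = 1000


def replicate_rng(master_seed: int, replicate_index: int) -> np.random.Generator:
    """The documented seed-derivation rule: one substream per replicate."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, replicate_index]))


def _sample_plot(
    richness: int, cum_weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``richness`` distinct species indices, frequency-weighted.

    Implements with-replacement draws from the observation multiset with
    within-plot duplicate rejection: we oversample, keep first occurrences
    in draw order, and redraw until the plot is full.
    """
    n_pool = cum_weights.shape[0]
    if richness > n_pool:
        raise ValueError(f"plot richness {richness} exceeds pool size {n_pool}")
    chosen: list[int] = []
    seen = np.zeros(n_pool, dtype=bool)
    need = richness
    while need > 0:
        batch = np.searchsorted(cum_weights, rng.random(2 * need + 4), side="right")
        for s in batch:
            if not seen[s]:
                seen[s] = True
                chosen.append(s)
                need -= 1
                if need == 0:
                    break
    return np.asarray(chosen, dtype=np.intp)


def _pool_occurrences(matrix: CommunityMatrix, pool: SpeciesPool) -> np.ndarray:
    cols = {s: j for j, s in enumerate(matrix.species_ids)}
    occ = matrix.occurrence
    return np.array([occ[cols[s]] for s in pool.species_ids], dtype=float)


def calibrate_weights(
    richness: np.ndarray,
    occurrences: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> np.ndarray:
    """Draw weights whose realized replicate frequencies match the observed.

    Drawing a plot's k distinct species by frequency-weighted draws with
    duplicate rejection is successive (weighted without-replacement)
    sampling, whose inclusion probability for species s in a plot of
    richness k_i is approximately 1 - exp(-lambda_i w_s), with lambda_i
    solving sum_s (1 - exp(-lambda_i w_s)) = k_i (Hajek's approximation).
    Raw occurrence counts as weights therefore under-represent common
    species (they cannot occur twice in a plot) and inflate rare ones.
    This routine solves the biproportional problem for a single weight
    vector w: alternating Newton updates until both margins hold —
    per-plot expected richness k_i exactly, and per-species expected
    occurrence equal to the observed count.  Deterministic.
    """
    k = np.asarray(richness, dtype=float)
    occ = np.asarray(occurrences, dtype=float)
    n_species = occ.size
    if np.any(k > n_species):
        raise ValueError("plot richness exceeds pool size")
    # replicates receive the full plot richness but only pool species, so the
    # feasible target is the observed RELATIVE frequency scaled to that total
    occ = occ * (k.sum() / occ.sum())
    w = occ / occ.sum()
    lam = np.full(k.size, k.sum() / max(k.size, 1))
    for _ in range(max_iter):
        # plot potentials: solve sum_s (1 - exp(-lam_i w_s)) = k_i
        for _ in range(8):
            e = np.exp(-np.outer(lam, w))
            g = (1.0 - e).sum(axis=1) - k
            gp = e @ w
            lam = np.maximum(lam - g / np.maximum(gp, 1e-300), 1e-12)
        # species weights: solve sum_i (1 - exp(-lam_i w_s)) = occ_s
        for _ in range(8):
            e = np.exp(-np.outer(lam, w))
            h = (1.0 - e).sum(axis=0) - occ
            hp = lam @ e
            w = np.maximum(w - h / np.maximum(hp, 1e-300), 1e-300)
        e = np.exp(-np.outer(lam, w))
        err = max(
            np.abs((1.0 - e).sum(axis=1) - k).max(),
            np.abs((1.0 - e).sum(axis=0) - occ).max(),
        )
        if err < tol:
            break
    return w / w.sum()


def _pool_weights(
    matrix: CommunityMatrix, pool: SpeciesPool, calibrate: bool = True
) -> np.ndarray:
    occ = _pool_occurrences(matrix, pool)
    if calibrate:
        return calibrate_weights(matrix.richness, occ)
    return occ / occ.sum()


def replicate_matrix(
    matrix: CommunityMatrix,
    pool: SpeciesPool,
    rng: np.random.Generator,
    calibrate: bool = True,
    weights: np.ndarray | None = None,
) -> CommunityMatrix:
    """One null replicate over the pool species, preserving plot richness.

    ``calibrate`` adjusts the draw weights so realized species frequencies
    match the observed occurrence counts despite the within-plot
    distinct-species constraint; with ``calibrate=False`` raw occurrence
    counts are used as weights.  Pass precomputed ``weights`` to skip the
    calibration when drawing many replicates.
    """
    if weights is None:
        weights = _pool_weights(matrix, pool, calibrate)
    cum = np.cumsum(weights)
    cum[-1] = 1.0
    richness = matrix.richness
    incidence = np.zeros((matrix.n_plots, len(pool)), dtype=np.int8)
    for i, k in enumerate(richness):
        incidence[i, _sample_plot(int(k), cum, rng)] = 1
    return CommunityMatrix(matrix.plot_ids, list(pool.species_ids), incidence)


@dataclass
class NullEnsemble:
    """Per-replicate niche estimates under the frequency-preserving null.

    ``positions``/``widths``/``occurrences`` are (n_replicates, n_pool)
    arrays; a species absent from a replicate has NaN position, and one
    below ``min_width_occurrence`` occurrences has NaN width.
    """

    species_ids: tuple[str, ...]
    master_seed: int
    positions: np.ndarray
    widths: np.ndarray
    occurrences: np.ndarray
    min_width_occurrence: int = 2
    min_position_occurrence: int = 1
    plot_log_np: np.ndarray = field(default=None, repr=False)

    @property
    def n_replicates(self) -> int:
        return self.positions.shape[0]

    def replicate_positions(self, i: int) -> np.ndarray:
        """Finite niche positions of replicate ``i``."""
        p = self.positions[i]
        return p[np.isfinite(p)]

    def mean_occurrence(self) -> np.ndarray:
        """Ensemble-mean occurrence count per pool species."""
        return self.occurrences.mean(axis=0)


def build_ensemble(
    matrix: CommunityMatrix,
    plot_log_np: np.ndarray,
    pool: SpeciesPool,
    n_replicates: int = DEFAULT_N_REPLICATES,
    master_seed: int = 0,
    min_width_occurrence: int = 2,
    min_position_occurrence: int | None = None,
    calibrate: bool = True,
) -> NullEnsemble:
    """Build the null ensemble and its per-replicate niche estimates.

    Replicate matrices are not stored; only each replicate's per-species
    occurrence counts and the derived positions and widths, computed
    exactly as for the real data — including the occupancy criterion:
    ``min_position_occurrence`` (default: the pool's own threshold)
    applies within each replicate, so null estimates come from the same
    estimator as the real ones rather than from sparser, noisier species
    the real analysis would have excluded.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if min_position_occurrence is None:
        min_position_occurrence = pool.min_occurrence
    pos_floor = max(1, min_position_occurrence)
    width_floor = max(min_width_occurrence, pos_floor)
    plot_log_np = np.asarray(plot_log_np, dtype=float)
    if plot_log_np.shape[0] != matrix.n_plots:
        raise ValueError("plot_log_np must have one value per matrix plot")
    weights = _pool_weights(matrix, pool, calibrate)
    cum = np.cumsum(weights)
    cum[-1] = 1.0
    richness = matrix.richness.astype(int)
    n_pool = len(pool)
    x = plot_log_np
    positions = np.empty((n_replicates, n_pool))
    widths = np.empty((n_replicates, n_pool))
    occurrences = np.empty((n_replicates, n_pool), dtype=np.int32)
    for r in range(n_replicates):
        rng = replicate_rng(master_seed, r)
        sp_idx: list[np.ndarray] = []
        xs: list[np.ndarray] = []
        for i, k in enumerate(richness):
            idx = _sample_plot(k, cum, rng)
            sp_idx.append(idx)
            xs.append(np.full(idx.shape, x[i]))
        idx = np.concatenate(sp_idx)
        vals = np.concatenate(xs)
        counts = np.bincount(idx, minlength=n_pool).astype(float)
        sums = np.bincount(idx, weights=vals, minlength=n_pool)
        sumsq = np.bincount(idx, weights=vals * vals, minlength=n_pool)
        with np.errstate(invalid="ignore", divide="ignore"):
            pos = sums / counts
            ss = np.maximum(sumsq - sums * sums / counts, 0.0)
            wid = 2.0 * np.sqrt(ss / (counts - 1))
        pos[counts < pos_floor] = np.nan
        wid[counts < width_floor] = np.nan
        positions[r] = pos
        widths[r] = wid
        occurrences[r] = counts
    return NullEnsemble(
        species_ids=tuple(pool.species_ids),
        master_seed=master_seed,
        positions=positions,
        widths=widths,
        occurrences=occurrences,
        min_width_occurrence=min_width_occurrence,
        min_position_occurrence=pos_floor,
        plot_log_np=x,
    )


def replicate_estimates_frame(ensemble: NullEnsemble, i: int):
    """Positions/widths of replicate ``i`` as arrays aligned to species_ids."""
    return ensemble.positions[i], ensemble.widths[i], ensemble.occurrences[i]
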
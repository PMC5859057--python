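"""Synthetic community datasets with known niche structure.

The generator emulates the statistical features the analysis assumes in
real grassland/wetland data: plot log10 N:P is Gaussian (so N:P itself is
log-normal, centred near the observed mean plot ratio of ~11); species
have Gaussian occurrence response curves along log[N:P] whose optima
follow a two-mode mixture (a broad N-side mode and a tighter P-side
mode); response tolerances shrink linearly with optimum extremity, which
plants the width/position trade-off; per-species prevalence multipliers
are log-normal (heavy-tailed, as real occupancy frequencies are); and
endangered flags are enriched among species with P-limited optima.  The
full ground truth (optima, tolerances, prevalences) is returned alongside
the dataset so every downstream estimate can be checked by parameter
recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CommunityMatrix, Dataset, PlotRecord, SpeciesRecord
from .stoichiometry import NP_UPPER

TOLERANCE_FLOOR = 0.03  # minimum response tolerance on the log10 N:P scale


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults define the standard study conditions."""

    n_plots: int = 600
    n_species: int = 300
    mu_log_np: float = 1.05
    sigma_log_np: float = 0.25
    mode_weights: tuple[float, float] = (0.65, 0.35)
    mode_means: tuple[float, float] = (0.95, 1.45)
    mode_sds: tuple[float, float] = (0.18, 0.08)
    tolerance_base: float = 0.20
    tolerance_extremity_slope: float = -0.25
    prevalence_logmean: float = -1.5
    prevalence_logsd: float = 1.0
    prevalence_floor: float = 0.02
    endangered_p_side_prob: float = 0.6
    endangered_n_side_prob: float = 0.2
    richness_floor: int = 2
    tissue_n_mean: float = 15.0
    tissue_n_sd: float = 3.0
    nk_logmean: float = float(np.log(1.3))
    nk_logsd: float = 0.25
    biomass_logmean: float = float(np.log(400.0))
    biomass_logsd: float = 0.6
    mowing_probs: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    seed: int = 1

    def validate(self) -> None:
        if self.n_plots < 1 or self.n_species < 1:
            raise ValueError("n_plots and n_species must be positive")
        if not np.isclose(sum(self.mode_weights), 1.0):
            raise ValueError("mode_weights must sum to 1")
        if any(w < 0 for w in self.mode_weights):
            raise ValueError("mode_weights must be non-negative")
        if any(s <= 0 for s in self.mode_sds) or self.sigma_log_np <= 0:
            raise ValueError("spread parameters must be positive")
        if self.tolerance_base <= 0:
            raise ValueError("tolerance_base must be positive")
        for p in (self.endangered_p_side_prob, self.endangered_n_side_prob):
            if not 0 <= p <= 1:
                raise ValueError("endangered probabilities must be in [0, 1]")
        if self.richness_floor > self.n_species:
            raise ValueError("richness_floor exceeds n_species: infeasible")


@dataclass
class GroundTruth:
    """True per-species and per-plot parameters behind a synthetic dataset."""

    species: pd.DataFrame  # species_id, optimum, tolerance, prevalence, endangered
    plots: pd.DataFrame = field(default=None)  # plot_id, log_np, plant_n/p/k


def generate_plots(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[dict[str, PlotRecord], np.ndarray]:
    """Draw plots: log-normal N:P, tissue chemistry consistent with it.

    Tissue N is Gaussian around ``tissue_n_mean``; P follows from the
    drawn N:P ratio; K is set through a log-normal N:K ratio centred well
    below the K-limitation threshold, so K-limited plots stay rare.
    """
    config.validate()
    n = config.n_plots
    log_np = rng.normal(config.mu_log_np, config.sigma_log_np, size=n)
    np_ratio = 10.0**log_np
    plant_n = np.clip(rng.normal(config.tissue_n_mean, config.tissue_n_sd, size=n), 3.0, None)
    plant_p = plant_n / np_ratio
    nk = rng.lognormal(config.nk_logmean, config.nk_logsd, size=n)
    plant_k = plant_n / nk
    biomass = rng.lognormal(config.biomass_logmean, config.biomass_logsd, size=n)
    mowing = rng.choice(len(config.mowing_probs), size=n, p=config.mowing_probs)
    plots = {}
    for i in range(n):
        pid = f"plot{i:04d}"
        plots[pid] = PlotRecord(
            plot_id=pid,
            plant_n=float(plant_n[i]),
            plant_p=float(plant_p[i]),
            plant_k=float(plant_k[i]),
            biomass=float(biomass[i]),
            mowing_frequency=int(mowing[i]),
        )
    return plots, log_np


def generate_species(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw species truths: optima, tolerances, prevalences, endangered flags."""
    config.validate()
    n = config.n_species
    mode = rng.choice(2, size=n, p=config.mode_weights)
    optimum = rng.normal(
        np.asarray(config.mode_means)[mode], np.asarray(config.mode_sds)[mode]
    )
    tolerance = np.maximum(
        TOLERANCE_FLOOR,
        config.tolerance_base
        + config.tolerance_extremity_slope * np.abs(optimum - config.mu_log_np),
    )
    prevalence = np.minimum(
        1.0,
        np.maximum(
            config.prevalence_floor,
            rng.lognormal(config.prevalence_logmean, config.prevalence_logsd, size=n),
        ),
    )
    p_side = optimum > np.log10(NP_UPPER)
    endangered = rng.random(n) < np.where(
        p_side, config.endangered_p_side_prob, config.endangered_n_side_prob
    )
    return pd.DataFrame(
        {
            "species_id": [f"sp{i:04d}" for i in range(n)],
            "optimum": optimum,
            "tolerance": tolerance,
            "prevalence": prevalence,
            "endangered": endangered,
            "mode": mode,
        }
    )


def occurrence_probabilities(
    plot_log_np: np.ndarray, species: pd.DataFrame
) -> np.ndarray:
    """(n_plots, n_species) Bernoulli probabilities of the response model."""
    x = np.asarray(plot_log_np, dtype=float)[:, None]
    o = species["optimum"].to_numpy()[None, :]
    t = species["tolerance"].to_numpy()[None, :]
    prev = species["prevalence"].to_numpy()[None, :]
    return np.clip(prev * np.exp(-((x - o) ** 2) / (2 * t**2)), 0.0, 1.0)


def sample_presence(
    plot_log_np: np.ndarray,
    species: pd.DataFrame,
    config: SynthConfig,
    rng: np.random.Generator,
    plot_ids: list[str] | None = None,
) -> CommunityMatrix:
    """Independent Bernoulli occurrences, then top-up to the richness floor.

    Plots below the floor receive additional species, drawn among their
    absent species with probability proportional to the same response
    weights, until the floor is met.
    """
    config.validate()
    probs = occurrence_probabilities(plot_log_np, species)
    incidence = (rng.random(probs.shape) < probs).astype(np.int8)
    floor = config.richness_floor
    for i in np.nonzero(incidence.sum(axis=1) < floor)[0]:
        while incidence[i].sum() < floor:
            absent = incidence[i] == 0
            w = probs[i][absent]
            if w.sum() <= 0:
                w = np.ones(absent.sum())
            choice = rng.choice(np.nonzero(absent)[0], p=w / w.sum())
            incidence[i, choice] = 1
    if plot_ids is None:
        plot_ids = [f"plot{i:04d}" for i in range(len(plot_log_np))]
    return CommunityMatrix(plot_ids, list(species["species_id"]), incidence)


def generate_dataset(config: SynthConfig | None = None) -> tuple[Dataset, GroundTruth]:
    """Compose plots, species truths and presences into a full dataset."""
    config = config or SynthConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    plots, log_np = generate_plots(config, rng)
    species_truth = generate_species(config, rng)
    matrix = sample_presence(log_np, species_truth, config, rng, list(plots))
    species = {
        row.species_id: SpeciesRecord(species_id=row.species_id, endangered=bool(row.endangered))
        for row in species_truth.itertuples()
    }
    plot_frame = pd.DataFrame(
        {
            "plot_id": list(plots),
            "log_np": log_np,
            "plant_n": [plots[p].plant_n for p in plots],
            "plant_p": [plots[p].plant_p for p in plots],
            "plant_k": [plots[p].plant_k for p in plots],
        }
    )
    truth = GroundTruth(species=species_truth, plots=plot_frame)
    return Dataset(plots=plots, species=species, matrix=matrix), truth
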
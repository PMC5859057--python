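"""Core data containers: plots, species, and the binary community matrix.

A :class:`Dataset` bundles the plot table (tissue chemistry, biomass,
management), the species attribute table (endangered status, optional
Ellenberg indicator values) and the presence/absence community matrix,
with plot and species registries guaranteed to agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

EIV_NAMES = ("moisture", "ph", "salinity", "temperature", "light")

VALID_MOWING = frozenset({0, 1, 2, 3})


@dataclass
class PlotRecord:
    """One vegetation plot; concentrations in mg/g dry mass, biomass in g/m2."""

    plot_id: str
    plant_n: float
    plant_p: float
    plant_k: float | None
    biomass: float
    mowing_frequency: int = 0
    woody_cover_gt50: bool = False
    saline: bool = False
    country: str | None = None

    def __post_init__(self) -> None:
        if self.plant_n <= 0 or self.plant_p <= 0:
            raise ValueError(
                f"plot {self.plot_id}: plant_n and plant_p must be positive"
            )
        if self.plant_k is not None and self.plant_k <= 0:
            raise ValueError(f"plot {self.plot_id}: plant_k must be positive or missing")
        if self.biomass <= 0:
            raise ValueError(f"plot {self.plot_id}: biomass must be positive")
        if self.mowing_frequency not in VALID_MOWING:
            raise ValueError(
                f"plot {self.plot_id}: mowing_frequency must be 0-3, "
                f"got {self.mowing_frequency}"
            )


@dataclass
class SpeciesRecord:
    """One species: endangered (Red List derived) and curation flags.

    ``eiv`` optionally maps indicator names (moisture, ph, salinity,
    temperature, light) to ordinal Ellenberg values (>= 1).
    """

    species_id: str
    endangered: bool = False
    is_tree: bool = False
    ambiguous_identity: bool = False
    eiv: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.eiv.items():
            if name not in EIV_NAMES:
                raise ValueError(f"species {self.species_id}: unknown indicator {name!r}")
            if value < 1:
                raise ValueError(
                    f"species {self.species_id}: indicator {name} below ordinal range"
                )


class CommunityMatrix:
    """Binary plots x species incidence with identifier registries."""

    def __init__(
        self,
        plot_ids: Sequence[str],
        species_ids: Sequence[str],
        incidence: np.ndarray,
    ) -> None:
        incidence = np.asarray(incidence)
        if incidence.shape != (len(plot_ids), len(species_ids)):
            raise ValueError(
                f"incidence shape {incidence.shape} does not match "
                f"{len(plot_ids)} plots x {len(species_ids)} species"
            )
        if not np.isin(incidence, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")
        if len(set(plot_ids)) != len(plot_ids):
            raise ValueError("duplicate plot_id in matrix")
        if len(set(species_ids)) != len(species_ids):
            raise ValueError("duplicate species_id in matrix")
        self.plot_ids = list(plot_ids)
        self.species_ids = list(species_ids)
        self.incidence = incidence.astype(np.int8)

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def richness(self) -> np.ndarray:
        """Species count per plot (row sums)."""
        return self.incidence.sum(axis=1)

    @property
    def occurrence(self) -> np.ndarray:
        """Plot count per species (column sums)."""
        return self.incidence.sum(axis=0)

    @property
    def total_incidence(self) -> int:
        return int(self.incidence.sum())

    def subset(
        self,
        plot_ids: Sequence[str] | None = None,
        species_ids: Sequence[str] | None = None,
    ) -> "CommunityMatrix":
        plot_ids = self.plot_ids if plot_ids is None else list(plot_ids)
        species_ids = self.species_ids if species_ids is None else list(species_ids)
        prow = {p: i for i, p in enumerate(self.plot_ids)}
        scol = {s: j for j, s in enumerate(self.species_ids)}
        rows = [prow[p] for p in plot_ids]
        cols = [scol[s] for s in species_ids]
        return CommunityMatrix(plot_ids, species_ids, self.incidence[np.ix_(rows, cols)])

    def to_long(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.incidence)
        return pd.DataFrame(
            {
                "plot_id": [self.plot_ids[i] for i in rows],
                "species_id": [self.species_ids[j] for j in cols],
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityMatrix):
            return NotImplemented
        return (
            self.plot_ids == other.plot_ids
            and self.species_ids == other.species_ids
            and np.array_equal(self.incidence, other.incidence)
        )


@dataclass
class Dataset:
    """Plot records, species records and the community matrix, kept in sync."""

    plots: dict[str, PlotRecord]
    species: dict[str, SpeciesRecord]
    matrix: CommunityMatrix

    def __post_init__(self) -> None:
        if set(self.plots) != set(self.matrix.plot_ids):
            raise ValueError("plot registry does not match matrix plot_ids")
        if set(self.species) != set(self.matrix.species_ids):
            raise ValueError("species registry does not match matrix species_ids")

    @property
    def plot_ids(self) -> list[str]:
        return self.matrix.plot_ids

    @property
    def species_ids(self) -> list[str]:
        return self.matrix.species_ids

    def plot_frame(self) -> pd.DataFrame:
        """Plot table as a DataFrame in matrix order."""
        recs = [self.plots[p] for p in self.matrix.plot_ids]
        return pd.DataFrame(
            {
                "plot_id": [r.plot_id for r in recs],
                "plant_n": [r.plant_n for r in recs],
                "plant_p": [r.plant_p for r in recs],
                "plant_k": [r.plant_k for r in recs],
                "biomass": [r.biomass for r in recs],
                "mowing_frequency": [r.mowing_frequency for r in recs],
                "woody_cover_gt50": [r.woody_cover_gt50 for r in recs],
                "saline": [r.saline for r in recs],
                "country": [r.country for r in recs],
            }
        )

    def species_frame(self) -> pd.DataFrame:
        recs = [self.species[s] for s in self.matrix.species_ids]
        frame = pd.DataFrame(
            {
                "species_id": [r.species_id for r in recs],
                "endangered": [r.endangered for r in recs],
                "is_tree": [r.is_tree for r in recs],
                "ambiguous_identity": [r.ambiguous_identity for r in recs],
            }
        )
        for name in EIV_NAMES:
            frame[f"eiv_{name}"] = [r.eiv.get(name, np.nan) for r in recs]
        return frame

    def log_np(self) -> np.ndarray:
        """Per-plot log10 N:P in matrix plot order."""
        frame = self.plot_frame()
        return np.log10(frame["plant_n"].to_numpy() / frame["plant_p"].to_numpy())
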
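import numpy as np
import pytest

from npniche.datamodel import CommunityMatrix, Dataset, PlotRecord, SpeciesRecord
from npniche.simulate import SynthConfig, generate_dataset


def make_plot(pid, n=20.0, p=2.0, k=10.0, biomass=400.0, **kw) -> PlotRecord:
    return PlotRecord(plot_id=pid, plant_n=n, plant_p=p, plant_k=k, biomass=biomass, **kw)


def make_dataset(incidence, plot_kwargs=None, species_kwargs=None) -> Dataset:
    """Dataset from a 0/1 array; plots p0..pN, species s0..sM."""
    incidence = np.asarray(incidence)
    n_plots, n_species = incidence.shape
    plot_kwargs = plot_kwargs or {}
    species_kwargs = species_kwargs or {}
    plots = {f"p{i}": make_plot(f"p{i}", **plot_kwargs.get(f"p{i}", {})) for i in range(n_plots)}
    species = {
        f"s{j}": SpeciesRecord(species_id=f"s{j}", **species_kwargs.get(f"s{j}", {}))
        for j in range(n_species)
    }
    matrix = CommunityMatrix(list(plots), list(species), incidence)
    return Dataset(plots=plots, species=species, matrix=matrix)


@pytest.fixture(scope="session")
def default_synthetic():
    """The default synthetic dataset and its ground truth (seed 1)."""
    return generate_dataset(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def small_synthetic():
    """A reduced synthetic dataset for faster integration checks."""
    config = SynthConfig(n_plots=150, n_species=80, seed=7)
    return generate_dataset(config)
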
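import json

import numpy as np
import pandas as pd
import pytest

from npniche.datamodel import CommunityMatrix, PlotRecord, SpeciesRecord
from npniche.io import (
    apply_filters,
    community_mean_eiv,
    read_dataset,
    write_dataset,
    write_results,
)

from .conftest import make_dataset


def _write_inputs(tmp_path, plot_rows, species_rows, matrix_text):
    plots = tmp_path / "plots.tsv"
    plots.write_text(
        "plot_id\tplant_n\tplant_p\tplant_k\tbiomass\tmowing_frequency\twoody_cover_gt50\tsaline\n"
        + "".join(plot_rows)
    )
    species = tmp_path / "species.tsv"
    species.write_text(
        "species_id\tendangered\tis_tree\tambiguous_identity\teiv_moisture\n"
        + "".join(species_rows)
    )
    matrix = tmp_path / "matrix.tsv"
    matrix.write_text(matrix_text)
    return plots, species, matrix


PLOT_ROWS = [
    "p1\t20\t2\t10\t400\t1\t0\t0\n",
    "p2\t15\t1\t8\t300\t0\t0\t0\n",
    "p3\t18\t1.5\t\t500\t2\t0\t0\n",
]
SPECIES_ROWS = ["s1\t1\t0\t0\t7\n", "s2\t0\t0\t0\t9\n", "s3\t0\t1\t0\t\n", "s4\t0\t0\t0\t5\n"]


def test_read_wide_matrix_roundtrip(tmp_path):
    paths = _write_inputs(
        tmp_path, PLOT_ROWS, SPECIES_ROWS,
        "plot_id\ts1\ts2\ts3\ts4\np1\t1\t0\t1\t0\np2\t1\t1\t0\t1\np3\t0\t0\t0\t1\n",
    )
    ds = read_dataset(*paths)
    assert list(ds.matrix.richness) == [2, 3, 1]
    assert list(ds.matrix.occurrence) == [2, 1, 1, 2]
    # write/read round-trip preserves incidence exactly
    out = write_dataset(ds, tmp_path / "out")
    ds2 = read_dataset(out["plots"], out["species"], out["matrix"])
    assert ds2.matrix.subset(ds.matrix.plot_ids, ds.matrix.species_ids) == ds.matrix


def test_long_matrix_duplicates_collapse(tmp_path):
    paths = _write_inputs(
        tmp_path, PLOT_ROWS, SPECIES_ROWS,
        "plot_id\tspecies_id\np1\ts1\np1\ts1\np2\ts2\n",
    )
    ds = read_dataset(*paths)
    assert ds.matrix.total_incidence == 2


def test_unknown_species_in_matrix_errors(tmp_path):
    paths = _write_inputs(
        tmp_path, PLOT_ROWS, SPECIES_ROWS, "plot_id\tspecies_id\np1\tX\n"
    )
    with pytest.raises(ValueError, match="X"):
        read_dataset(*paths)


def test_non_binary_cell_errors(tmp_path):
    paths = _write_inputs(
        tmp_path, PLOT_ROWS, SPECIES_ROWS,
        "plot_id\ts1\ts2\ts3\ts4\np1\t2\t0\t0\t0\n",
    )
    with pytest.raises(ValueError, match="non-binary"):
        read_dataset(*paths)


def test_non_numeric_nutrient_cell_errors(tmp_path):
    rows = ["p1\tbad\t2\t10\t400\t1\t0\t0\n"]
    paths = _write_inputs(tmp_path, rows, SPECIES_ROWS, "plot_id\tspecies_id\np1\ts1\n")
    with pytest.raises(ValueError, match="non-numeric"):
        read_dataset(*paths)


class TestFilters:
    def test_plot_rules(self):
        ds = make_dataset(
            np.ones((5, 2)),
            plot_kwargs={
                "p1": {"saline": True},
                "p2": {"k": None},
            },
        )
        filtered, report = apply_filters(ds)
        assert filtered.matrix.n_plots == 3
        assert report.plots_saline == 1 and report.plots_missing_k == 1

    def test_tree_species_column_removed(self):
        inc = np.ones((4, 3))
        ds = make_dataset(inc, species_kwargs={"s1": {"is_tree": True}})
        filtered, _ = apply_filters(ds)
        assert filtered.matrix.n_species == 2
        assert list(filtered.matrix.richness) == [2, 2, 2, 2]

    def test_all_plots_flagged_errors(self):
        ds = make_dataset(np.ones((2, 2)), plot_kwargs={
            "p0": {"woody_cover_gt50": True}, "p1": {"saline": True}})
        with pytest.raises(ValueError, match="empty"):
            apply_filters(ds)

    def test_idempotent(self):
        ds = make_dataset(
            np.array([[1, 1, 0], [0, 1, 1], [1, 0, 0]]),
            plot_kwargs={"p2": {"saline": True}},
            species_kwargs={"s2": {"ambiguous_identity": True}},
        )
        once, _ = apply_filters(ds)
        twice, _ = apply_filters(once)
        assert once.matrix == twice.matrix

    def test_empty_plot_dropped(self):
        inc = np.array([[1, 0], [0, 1]])
        ds = make_dataset(inc, species_kwargs={"s0": {"is_tree": True}})
        filtered, report = apply_filters(ds)
        assert filtered.matrix.plot_ids == ["p1"]
        assert report.plots_empty == 1


class TestCommunityMeanEIV:
    def test_two_point_mean(self):
        ds = make_dataset(
            np.array([[1, 1]]),
            species_kwargs={"s0": {"eiv": {"moisture": 7}}, "s1": {"eiv": {"moisture": 9}}},
        )
        assert community_mean_eiv(ds, "moisture").iloc[0] == 8.0

    def test_species_without_value_skipped(self):
        ds = make_dataset(
            np.array([[1, 1, 1]]),
            species_kwargs={
                "s0": {"eiv": {"moisture": 5}},
                "s2": {"eiv": {"moisture": 7}},
            },
        )
        assert community_mean_eiv(ds, "moisture").iloc[0] == 6.0

    def test_no_valued_species_yields_missing(self):
        ds = make_dataset(np.array([[1, 1]]))
        assert np.isnan(community_mean_eiv(ds, "ph").iloc[0])

    def test_unknown_indicator_errors(self):
        ds = make_dataset(np.array([[1]]))
        with pytest.raises(ValueError, match="unknown indicator"):
            community_mean_eiv(ds, "altitude")

    def test_mean_within_contributing_range(self, small_synthetic):
        rng = np.random.default_rng(3)
        ds, _ = small_synthetic
        for sid in ds.species:
            ds.species[sid].eiv = {"light": float(rng.integers(1, 10))}
        means = community_mean_eiv(ds, "light")
        values = np.array([ds.species[s].eiv["light"] for s in ds.matrix.species_ids])
        inc = ds.matrix.incidence.astype(bool)
        for i, m in enumerate(means):
            present = values[inc[i]]
            assert present.min() <= m <= present.max()


class TestWriteResults:
    BUNDLE = {
        "config": {"master_seed": 3},
        "tests": {"dummy": 1.0},
        "niche_estimates": pd.DataFrame(
            {
                "species_id": ["a"], "n_plots": [10], "position": [1.1],
                "width": [0.2], "extremity": [0.05], "residual_width": [0.0],
                "endangered": [False],
            }
        ),
    }

    def test_schema_and_determinism(self, tmp_path):
        p1 = write_results(self.BUNDLE, tmp_path / "a")
        p2 = write_results(self.BUNDLE, tmp_path / "b")
        header = (tmp_path / "a" / "niche_estimates.tsv").read_text().splitlines()[0]
        assert header.split("\t") == [
            "species_id", "n_plots", "position", "width",
            "extremity", "residual_width", "endangered",
        ]
        assert p1["summary"].read_bytes() == p2["summary"].read_bytes()
        json.loads(p1["summary"].read_text())  # valid JSON

    def test_missing_section_errors(self, tmp_path):
        with pytest.raises(ValueError, match="mandatory"):
            write_results({"config": {}}, tmp_path)


def test_plot_record_validation():
    with pytest.raises(ValueError):
        PlotRecord("p", plant_n=-1, plant_p=2, plant_k=1, biomass=10)
    with pytest.raises(ValueError, match="mowing"):
        PlotRecord("p", plant_n=1, plant_p=2, plant_k=1, biomass=10, mowing_frequency=4)
    with pytest.raises(ValueError):
        SpeciesRecord("s", eiv={"moisture": 0})
    with pytest.raises(ValueError):
        CommunityMatrix(["p1", "p1"], ["s1"], np.array([[1], [0]]))
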
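"""Reading, filtering and writing of datasets and result bundles.

Input tables are delimited text (TSV default, CSV accepted) with a
mandatory header row.  The community matrix is accepted either wide
(plots x species, 0/1 cells) or long (``plot_id``, ``species_id`` pairs;
canonical for sparse data).  Output is a set of TSV tables plus one JSON
summary that embeds every statistic, seed and configuration value, so a
rerun with the same seed reproduces the JSON byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .datamodel import EIV_NAMES, CommunityMatrix, Dataset, PlotRecord, SpeciesRecord

logger = logging.getLogger(__name__)

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n", ""}


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _parse_bool(value: Any, context: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if pd.isna(value):
        return False
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValueError(f"{context}: cannot interpret {value!r} as a boolean flag")


def _parse_number(value: Any, context: str, allow_missing: bool = False) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        if allow_missing:
            return None
        raise ValueError(f"{context}: value missing")
    if isinstance(value, str):
        text = value.strip()
        if text == "":
            if allow_missing:
                return None
            raise ValueError(f"{context}: value missing")
        value = text
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{context}: non-numeric cell {value!r}") from exc


def read_plot_table(path: str | Path) -> dict[str, PlotRecord]:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if "plot_id" not in frame.columns:
        raise ValueError(f"{path}: missing plot_id column")
    plots: dict[str, PlotRecord] = {}
    for _, row in frame.iterrows():
        pid = str(row["plot_id"])
        if pid in plots:
            raise ValueError(f"{path}: duplicate plot_id {pid!r}")
        plots[pid] = PlotRecord(
            plot_id=pid,
            plant_n=_parse_number(row.get("plant_n"), f"plot {pid} plant_n"),
            plant_p=_parse_number(row.get("plant_p"), f"plot {pid} plant_p"),
            plant_k=_parse_number(row.get("plant_k"), f"plot {pid} plant_k", allow_missing=True),
            biomass=_parse_number(row.get("biomass"), f"plot {pid} biomass"),
            mowing_frequency=int(_parse_number(row.get("mowing_frequency", 0), f"plot {pid} mowing") or 0),
            woody_cover_gt50=_parse_bool(row.get("woody_cover_gt50", False), f"plot {pid}"),
            saline=_parse_bool(row.get("saline", False), f"plot {pid}"),
            country=None if pd.isna(row.get("country")) else str(row.get("country")),
        )
    return plots


def read_species_table(path: str | Path) -> dict[str, SpeciesRecord]:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if "species_id" not in frame.columns:
        raise ValueError(f"{path}: missing species_id column")
    species: dict[str, SpeciesRecord] = {}
    for _, row in frame.iterrows():
        sid = str(row["species_id"])
        if sid in species:
            raise ValueError(f"{path}: duplicate species_id {sid!r}")
        eiv = {}
        for name in EIV_NAMES:
            col = f"eiv_{name}"
            if col in frame.columns:
                value = _parse_number(row.get(col), f"species {sid} {col}", allow_missing=True)
                if value is not None:
                    eiv[name] = value
        species[sid] = SpeciesRecord(
            species_id=sid,
            endangered=_parse_bool(row.get("endangered", False), f"species {sid}"),
            is_tree=_parse_bool(row.get("is_tree", False), f"species {sid}"),
            ambiguous_identity=_parse_bool(row.get("ambiguous_identity", False), f"species {sid}"),
            eiv=eiv,
        )
    return species


def read_matrix(path: str | Path) -> CommunityMatrix:
    """Read a community matrix, auto-detecting wide vs long layout.

    Long layout has exactly the columns (plot_id, species_id); duplicate
    pairs collapse to a single presence.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if list(frame.columns) == ["plot_id", "species_id"]:
        plot_ids = list(dict.fromkeys(frame["plot_id"]))
        species_ids = list(dict.fromkeys(frame["species_id"]))
        prow = {p: i for i, p in enumerate(plot_ids)}
        scol = {s: j for j, s in enumerate(species_ids)}
        incidence = np.zeros((len(plot_ids), len(species_ids)), dtype=np.int8)
        for pid, sid in zip(frame["plot_id"], frame["species_id"]):
            incidence[prow[pid], scol[sid]] = 1
        return CommunityMatrix(plot_ids, species_ids, incidence)
    if "plot_id" not in frame.columns:
        raise ValueError(f"{path}: wide matrix needs a plot_id column")
    species_ids = [c for c in frame.columns if c != "plot_id"]
    plot_ids = [str(p) for p in frame["plot_id"]]
    cells = frame[species_ids].to_numpy()
    incidence = np.empty(cells.shape, dtype=np.int8)
    for idx, value in np.ndenumerate(cells):
        text = str(value).strip()
        if text not in {"0", "1"}:
            raise ValueError(
                f"{path}: non-binary matrix cell {value!r} at plot "
                f"{plot_ids[idx[0]]!r}, species {species_ids[idx[1]]!r}"
            )
        incidence[idx] = int(text)
    return CommunityMatrix(plot_ids, species_ids, incidence)


def read_dataset(
    plot_table_path: str | Path,
    species_table_path: str | Path,
    matrix_path: str | Path,
) -> Dataset:
    """Read and cross-validate the three input tables into a Dataset."""
    plots = read_plot_table(plot_table_path)
    species = read_species_table(species_table_path)
    matrix = read_matrix(matrix_path)
    for pid in matrix.plot_ids:
        if pid not in plots:
            raise ValueError(f"matrix references unknown plot_id {pid!r}")
    for sid in matrix.species_ids:
        if sid not in species:
            raise ValueError(f"matrix references unknown species_id {sid!r}")
    # registries may be supersets of the matrix; restrict to matrix members
    plots = {p: plots[p] for p in matrix.plot_ids}
    species = {s: species[s] for s in matrix.species_ids}
    return Dataset(plots=plots, species=species, matrix=matrix)


@dataclass
class FilterReport:
    plots_woody: int = 0
    plots_saline: int = 0
    plots_missing_k: int = 0
    plots_empty: int = 0
    species_tree: int = 0
    species_ambiguous: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


def apply_filters(dataset: Dataset) -> tuple[Dataset, FilterReport]:
    """Apply the curation rules and prune the matrix accordingly.

    Plots are dropped when more than half the surface is woody, when the
    plot is saline/coastal, or when tissue K was not measured.  Tree
    species and species of ambiguous identity are dropped.  Plots whose
    richness falls to zero afterwards are removed.  Idempotent.
    """
    report = FilterReport()
    keep_plots = []
    for pid in dataset.matrix.plot_ids:
        rec = dataset.plots[pid]
        if rec.woody_cover_gt50:
            report.plots_woody += 1
        elif rec.saline:
            report.plots_saline += 1
        elif rec.plant_k is None:
            report.plots_missing_k += 1
        else:
            keep_plots.append(pid)
    keep_species = []
    for sid in dataset.matrix.species_ids:
        rec = dataset.species[sid]
        if rec.is_tree:
            report.species_tree += 1
        elif rec.ambiguous_identity:
            report.species_ambiguous += 1
        else:
            keep_species.append(sid)
    if not keep_plots or not keep_species:
        raise ValueError("dataset empty after filtering")
    matrix = dataset.matrix.subset(keep_plots, keep_species)
    nonempty = matrix.richness > 0
    report.plots_empty = int((~nonempty).sum())
    if report.plots_empty:
        matrix = matrix.subset([p for p, ok in zip(matrix.plot_ids, nonempty) if ok])
    if matrix.n_plots == 0:
        raise ValueError("dataset empty after filtering")
    logger.info("filter report: %s", report.as_dict())
    filtered = Dataset(
        plots={p: dataset.plots[p] for p in matrix.plot_ids},
        species={s: dataset.species[s] for s in matrix.species_ids},
        matrix=matrix,
    )
    return filtered, report


def community_mean_eiv(dataset: Dataset, indicator_name: str) -> pd.Series:
    """Per-plot mean Ellenberg indicator value over present, valued species.

    Species lacking the indicator are skipped (never zero-filled); a plot
    where no present species carries the indicator yields NaN.
    """
    if indicator_name not in EIV_NAMES:
        raise ValueError(f"unknown indicator {indicator_name!r}; choose from {EIV_NAMES}")
    values = np.array(
        [dataset.species[s].eiv.get(indicator_name, np.nan) for s in dataset.matrix.species_ids]
    )
    inc = dataset.matrix.incidence.astype(float)
    valued = np.isfinite(values)
    weight = inc[:, valued]
    counts = weight.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = weight @ values[valued] / counts
    means[counts == 0] = np.nan
    return pd.Series(means, index=dataset.matrix.plot_ids, name=f"eiv_{indicator_name}")


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write plot/species tables (TSV) and the long-format matrix."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "plots": out_dir / "plots.tsv",
        "species": out_dir / "species.tsv",
        "matrix": out_dir / "matrix.tsv",
    }
    dataset.plot_frame().to_csv(paths["plots"], sep="\t", index=False)
    dataset.species_frame().to_csv(paths["species"], sep="\t", index=False)
    dataset.matrix.to_long().to_csv(paths["matrix"], sep="\t", index=False)
    return paths


MANDATORY_SECTIONS = ("config", "niche_estimates", "tests")


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_results(results_bundle: dict[str, Any], out_dir: str | Path) -> dict[str, Path]:
    """Write the results bundle: TSV tables plus one JSON summary.

    The bundle must carry the mandatory sections (config, niche_estimates,
    tests).  Values under ``tables`` (DataFrames) are written as TSV;
    everything else lands in ``summary.json``.  No timestamps are written,
    so identical bundles serialize identically.
    """
    for section in MANDATORY_SECTIONS:
        if section not in results_bundle:
            raise ValueError(f"results bundle missing mandatory section {section!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    estimates = results_bundle["niche_estimates"]
    if isinstance(estimates, pd.DataFrame):
        paths["niche_estimates"] = out_dir / "niche_estimates.tsv"
        estimates.to_csv(paths["niche_estimates"], sep="\t", index=False)
    for name, table in results_bundle.get("tables", {}).items():
        paths[name] = out_dir / f"{name}.tsv"
        table.to_csv(paths[name], sep="\t", index=False)
    summary = {
        k: (v.to_dict(orient="list") if isinstance(v, pd.DataFrame) else v)
        for k, v in results_bundle.items()
        if k != "tables"
    }
    paths["summary"] = out_dir / "summary.json"
    with open(paths["summary"], "w", encoding="utf-8") as fh:
        json.dump(_jsonify(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
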
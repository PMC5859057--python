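"""End-to-end orchestration of the niche-occupation analysis.

Stages run in order: curation filters -> nutrient ratios and limitation
classes -> species pool and niche estimates -> frequency-preserving null
ensemble -> modality tests and KS comparison -> quantile-regression
trade-off with null band, residual widths and subset slopes -> endangered
species tests.  One master seed drives every stochastic stage through a
documented derivation (SeedSequence(master_seed).generate_state, one
31-bit sub-seed per stage), so reruns are bit-exact.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import endangered as endangered_mod
from . import io, modality, niche, nullmodel, stoichiometry, tradeoff
from .datamodel import Dataset

logger = logging.getLogger(__name__)

_STAGES = ("ensemble", "modality", "ensemble_modality", "ks", "quantreg_ci", "band")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """One reproducible 31-bit sub-seed per stochastic stage."""
    state = np.random.SeedSequence(master_seed).generate_state(len(_STAGES), dtype=np.uint32)
    return {name: int(s & 0x7FFFFFFF) for name, s in zip(_STAGES, state)}


@dataclass
class PipelineConfig:
    """Every tunable of the analysis chain, namespaced by stage."""

    master_seed: int = 0
    # stoichiometry
    np_lower: float = stoichiometry.NP_LOWER
    np_upper: float = stoichiometry.NP_UPPER
    # niche metrics
    min_occurrence: int = 10
    # null model
    n_replicates: int = 1000
    min_width_occurrence: int = 2
    null_min_occurrence: int | None = None  # default: same rule as the pool
    # modality
    modality_n_sim: int = 1000
    modality_levels: tuple[float, ...] = (0.10, 0.05, 0.01)
    modality_n_restarts: int = 20
    ensemble_modality_restarts: int = 5
    ensemble_modality_max_replicates: int | None = None
    ensemble_modality_level: float = 0.05
    em_tol: float = 1e-8
    em_max_iter: int = 500
    histogram_rule: str = "sturges"
    # trade-off
    taus: tuple[float, ...] = tradeoff.DEFAULT_TAUS
    degree: int = 2
    n_boot: int = 1000
    grid_points: int = 101
    subset_mode: str = "overlap"
    # endangered tests
    mwu_alternative: str = "less"
    spearman_alternative: str = "greater"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("modality_levels", "taus"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def as_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["modality_levels"] = list(self.modality_levels)
        d["taus"] = list(self.taus)
        return d


def run_analysis(dataset: Dataset, config: PipelineConfig | None = None) -> dict[str, Any]:
    """Execute the full analysis and return the results bundle.

    The bundle carries the config echo, the niche-estimate table, all test
    statistics, and TSV-ready tables; feed it to :func:`npniche.io.write_results`.
    """
    config = config or PipelineConfig()
    seeds = stage_seeds(config.master_seed)
    timings: dict[str, float] = {}

    def tick(stage: str, t0: float) -> None:
        timings[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", stage, timings[stage])

    t0 = time.perf_counter()
    dataset, filter_report = io.apply_filters(dataset)
    tick("filters", t0)

    t0 = time.perf_counter()
    plot_log_np = dataset.log_np()
    np_ratio = 10.0**plot_log_np
    classes = [stoichiometry.classify_np(v, config.np_lower, config.np_upper) for v in np_ratio]
    plot_frame = dataset.plot_frame()
    k_limited = [
        stoichiometry.classify_k(r.plant_n / r.plant_k, r.plant_k / r.plant_p)
        for r in plot_frame.itertuples()
    ]
    stoich_summary = {
        "n_plots": dataset.matrix.n_plots,
        "n_species": dataset.matrix.n_species,
        "mean_plot_np_arithmetic": float(np_ratio.mean()),
        "mean_plot_np_geometric": float(10.0 ** plot_log_np.mean()),
        "mean_plot_log_np": float(plot_log_np.mean()),
        "np_range": [float(np_ratio.min()), float(np_ratio.max())],
        "limitation_counts": {
            c.value: sum(1 for x in classes if x == c) for c in stoichiometry.NPClass
        },
        "n_k_limited": int(sum(k_limited)),
    }
    tick("stoichiometry", t0)

    t0 = time.perf_counter()
    pool = niche.select_pool(dataset.matrix, config.min_occurrence)
    flags = {s: dataset.species[s].endangered for s in pool.species_ids}
    estimates = niche.niche_estimates(dataset.matrix, plot_log_np, pool, flags)
    grand_mean = niche.dataset_mean_log_np(plot_log_np)
    tick("niche_metrics", t0)

    t0 = time.perf_counter()
    ensemble = nullmodel.build_ensemble(
        dataset.matrix,
        plot_log_np,
        pool,
        n_replicates=config.n_replicates,
        master_seed=seeds["ensemble"],
        min_width_occurrence=config.min_width_occurrence,
        min_position_occurrence=config.null_min_occurrence,
    )
    tick("null_ensemble", t0)

    t0 = time.perf_counter()
    positions = estimates["position"].to_numpy()
    critical = modality.simulate_critical_values(
        n=positions.size,
        n_sim=config.modality_n_sim,
        levels=config.modality_levels,
        seed=seeds["modality"],
        n_restarts=config.ensemble_modality_restarts,
        tol=config.em_tol,
        max_iter=config.em_max_iter,
        histogram_rule=config.histogram_rule,
    )
    modality_result = modality.modality_test(
        positions,
        levels=config.modality_levels,
        seed=seeds["modality"] + 1,
        n_restarts=config.modality_n_restarts,
        tol=config.em_tol,
        max_iter=config.em_max_iter,
        histogram_rule=config.histogram_rule,
        critical_values=critical,
    )
    unimodal_rate = modality.ensemble_modality_rate(
        ensemble,
        critical,
        level=config.ensemble_modality_level,
        n_restarts=config.ensemble_modality_restarts,
        tol=config.em_tol,
        max_iter=config.em_max_iter,
        seed=seeds["ensemble_modality"],
        histogram_rule=config.histogram_rule,
        max_replicates=config.ensemble_modality_max_replicates,
    )
    ks = modality.ks_vs_ensemble(positions, ensemble, seed=seeds["ks"])
    tick("modality", t0)

    t0 = time.perf_counter()
    widths = estimates["width"].to_numpy()
    fits = {}
    for tau in config.taus:
        fit = tradeoff.fit_quantreg(positions, widths, tau, config.degree)
        ci = tradeoff.quantreg_ci(
            positions, widths, tau, config.degree, config.n_boot, seeds["quantreg_ci"]
        )
        fits[tau] = dataclasses.replace(fit, ci95=ci)
    median_fit = fits[0.5] if 0.5 in fits else fits[min(fits)]
    # grid over the real species' position range: quadratic fits are only
    # meaningful where the real data live
    grid = np.linspace(positions.min(), positions.max(), config.grid_points)
    band = tradeoff.null_band(ensemble, tau=0.5, degree=config.degree, grid=grid)
    estimates = tradeoff.residual_widths(estimates, median_fit)
    slopes = tradeoff.subset_slopes(
        estimates, ensemble, grand_mean, mode=config.subset_mode
    )
    tick("tradeoff", t0)

    t0 = time.perf_counter()
    endangered_results = endangered_mod.endangered_analysis(
        estimates,
        mwu_alternative=config.mwu_alternative,
        spearman_alternative=config.spearman_alternative,
    )
    tick("endangered", t0)

    # fraction of grid where the real median width prediction sits below the
    # band; also restricted to the null position support, where the null
    # quadratics interpolate instead of extrapolating
    real_pred = median_fit.predict(band.grid)
    below_band = float(np.mean(real_pred < band.band_lower))
    null_pos = ensemble.positions[np.isfinite(ensemble.positions)]
    lo, hi = np.percentile(null_pos, [1, 99])
    in_support = (band.grid >= lo) & (band.grid <= hi)
    below_band_support = float(
        np.mean(real_pred[in_support] < band.band_lower[in_support])
    ) if in_support.any() else float("nan")

    quantreg_table = pd.DataFrame(
        [
            {
                "tau": tau,
                "intercept": fit.coefficients[0],
                "linear": fit.coefficients[1],
                "quadratic": fit.coefficients[2] if config.degree >= 2 else np.nan,
                "intercept_lo": fit.ci95[0, 0], "intercept_hi": fit.ci95[0, 1],
                "linear_lo": fit.ci95[1, 0], "linear_hi": fit.ci95[1, 1],
                "quadratic_lo": fit.ci95[2, 0] if config.degree >= 2 else np.nan,
                "quadratic_hi": fit.ci95[2, 1] if config.degree >= 2 else np.nan,
                "pinball_loss": fit.pinball_loss,
                "n": fit.n,
            }
            for tau, fit in fits.items()
        ]
    )
    band_table = pd.DataFrame(
        {
            "position": band.grid,
            "null_mean": band.mean_prediction(),
            "null_lower": band.band_lower,
            "null_upper": band.band_upper,
            "real_median": real_pred,
        }
    )
    bundle: dict[str, Any] = {
        "config": config.as_dict(),
        "seeds": seeds,
        "filter_report": filter_report.as_dict(),
        "stoichiometry": stoich_summary,
        "pool": {
            "n_species": len(pool),
            "min_occurrence": pool.min_occurrence,
            "total_observations": pool.total_observations,
            "n_endangered": int(estimates["endangered"].sum()),
        },
        "dataset_mean_log_np": grand_mean,
        "niche_estimates": estimates,
        "modality": {
            "minus2lnLambda": modality_result.minus2lnLambda,
            "delta_r2": modality_result.delta_r2,
            "critical_values": {str(k): list(v) for k, v in modality_result.critical_values.items()},
            "verdict": {str(k): v for k, v in modality_result.verdict.items()},
            "bimodal_means": list(modality_result.bimodal.means),
            "bimodal_weights": list(modality_result.bimodal.weights),
            "bimodal_sds": list(modality_result.bimodal.sds),
            "unimodal_mean": modality_result.unimodal.mean,
            "unimodal_sd": modality_result.unimodal.sd,
            "null_unimodal_rate": unimodal_rate,
            "ks_mean_D": ks.mean_D,
            "ks_mean_p": ks.mean_p,
            "ks_n_comparisons": ks.n_comparisons,
        },
        "tradeoff": {
            "median_coefficients": list(median_fit.coefficients),
            "real_below_null_band_fraction": below_band,
            "real_below_null_band_fraction_null_support": below_band_support,
            "null_support_range": [float(lo), float(hi)],
            "null_band_replicates_used": band.n_replicates_used,
            "slopes": {
                side: {
                    "slope_real": s.slope_real,
                    "null_slope_mean": s.null_slope_mean,
                    "p_value": s.p_value,
                    "n_real": s.n_real,
                    "n_null_with_slope": int(s.null_slopes.size),
                    "n_replicates": s.n_replicates,
                }
                for side, s in slopes.items()
            },
        },
        "tests": endangered_results,
        "timings_s": timings,
        "tables": {"quantreg_fits": quantreg_table, "null_band": band_table},
        "_objects": {
            "ensemble": ensemble,
            "fits": fits,
            "band": band,
            "slopes": slopes,
            "modality_result": modality_result,
            "pool": pool,
            "plot_log_np": plot_log_np,
        },
    }
    return bundle


def write_bundle(bundle: dict[str, Any], out_dir: str | Path) -> dict[str, Path]:
    """Persist the bundle (drops in-memory objects) and a MANIFEST."""
    serializable = {k: v for k, v in bundle.items() if k != "_objects"}
    paths = io.write_results(serializable, out_dir)
    manifest = Path(out_dir) / "MANIFEST"
    manifest.write_text(
        "complete\n" + "".join(f"{name}\t{p.name}\n" for name, p in sorted(paths.items())),
        encoding="utf-8",
    )
    paths["manifest"] = manifest
    return paths
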
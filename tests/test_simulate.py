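import numpy as np
import pytest
from scipy import stats

from npniche.niche import niche_estimates, select_pool
from npniche.simulate import (
    SynthConfig,
    generate_dataset,
    generate_plots,
    generate_species,
    occurrence_probabilities,
    sample_presence,
)
from npniche.stoichiometry import classify_k


class TestGeneratePlots:
    def test_tissue_chemistry_consistent_with_drawn_ratio(self):
        config = SynthConfig(n_plots=200, seed=4)
        plots, log_np = generate_plots(config, np.random.default_rng(4))
        for (pid, rec), x in zip(plots.items(), log_np):
            assert np.log10(rec.plant_n / rec.plant_p) == pytest.approx(x, abs=1e-9)

    def test_mean_log_np_within_clt_bound(self):
        config = SynthConfig(seed=11)
        _, log_np = generate_plots(config, np.random.default_rng(11))
        bound = 3 * config.sigma_log_np / np.sqrt(config.n_plots)
        assert abs(log_np.mean() - config.mu_log_np) < bound

    def test_k_limitation_rare(self):
        config = SynthConfig(n_plots=2000, seed=6)
        plots, _ = generate_plots(config, np.random.default_rng(6))
        frac = np.mean(
            [classify_k(r.plant_n / r.plant_k, r.plant_k / r.plant_p) for r in plots.values()]
        )
        assert frac < 0.10


class TestGenerateSpecies:
    def test_tolerance_at_gradient_center_equals_base(self):
        config = SynthConfig()
        truth = generate_species(config, np.random.default_rng(0))
        expected = np.maximum(
            0.03,
            config.tolerance_base
            + config.tolerance_extremity_slope * np.abs(truth.optimum - config.mu_log_np),
        )
        assert truth.tolerance.to_numpy() == pytest.approx(expected.to_numpy())
        # zero extremity would leave exactly the base tolerance
        assert np.all(truth.tolerance <= config.tolerance_base)

    def test_mode_weights_recovered_at_large_n(self):
        config = SynthConfig(n_species=3000, seed=8)
        truth = generate_species(config, np.random.default_rng(8))
        n_mode0 = int((truth["mode"] == 0).sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], 3000, config.mode_weights[0])
        assert lo <= n_mode0 <= hi

    def test_endangered_enriched_on_p_side(self):
        config = SynthConfig(n_species=5000, seed=9)
        truth = generate_species(config, np.random.default_rng(9))
        p_side = truth.optimum > np.log10(16)
        frac_p = truth.endangered[p_side].mean()
        frac_n = truth.endangered[~p_side].mean()
        assert frac_p == pytest.approx(config.endangered_p_side_prob, abs=0.05)
        assert frac_n == pytest.approx(config.endangered_n_side_prob, abs=0.05)

    def test_invalid_mixture_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SynthConfig(mode_weights=(0.7, 0.7)).validate()


class TestSamplePresence:
    def test_richness_floor_enforced(self):
        config = SynthConfig(n_plots=80, n_species=30, richness_floor=4, seed=2)
        rng = np.random.default_rng(2)
        plots, log_np = generate_plots(config, rng)
        truth = generate_species(config, rng)
        m = sample_presence(log_np, truth, config, rng)
        assert m.richness.min() >= 4

    def test_narrow_species_stays_near_optimum(self):
        config = SynthConfig(seed=5)
        rng = np.random.default_rng(5)
        plots, log_np = generate_plots(config, rng)
        truth = generate_species(config, rng)
        truth.loc[0, ["optimum", "tolerance", "prevalence"]] = [1.05, 0.04, 1.0]
        m = sample_presence(log_np, truth, config, rng)
        occupied = log_np[m.incidence[:, 0] == 1]
        assert np.abs(occupied - 1.05).max() < 4 * 0.04

    def test_prevalence_scales_expected_occurrence(self):
        """Doubling a sub-clamp prevalence doubles expected occurrences."""
        config = SynthConfig(seed=3)
        rng = np.random.default_rng(3)
        _, log_np = generate_plots(config, rng)
        truth = generate_species(config, rng)
        truth["prevalence"] = 0.2
        base = occurrence_probabilities(log_np, truth).sum(axis=0)
        truth["prevalence"] = 0.4
        doubled = occurrence_probabilities(log_np, truth).sum(axis=0)
        assert doubled == pytest.approx(2 * base, rel=1e-9)

    def test_infeasible_floor_errors(self):
        config = SynthConfig(n_species=2, richness_floor=5)
        with pytest.raises(ValueError, match="infeasible"):
            config.validate()


class TestGenerateDataset:
    def test_deterministic_from_seed(self):
        config = SynthConfig(n_plots=100, n_species=50, seed=14)
        ds1, t1 = generate_dataset(config)
        ds2, t2 = generate_dataset(config)
        assert ds1.matrix == ds2.matrix
        assert t1.species.equals(t2.species)

    def test_registries_consistent(self, default_synthetic):
        ds, truth = default_synthetic
        assert list(truth.species.species_id) == ds.matrix.species_ids
        assert list(truth.plots.plot_id) == ds.matrix.plot_ids

    def test_position_recovery_against_truth(self, default_synthetic):
        """Estimated niche positions track the true optima (r > 0.9)."""
        ds, truth = default_synthetic
        pool = select_pool(ds.matrix, 10)
        est = niche_estimates(ds.matrix, ds.log_np(), pool)
        tm = truth.species.set_index("species_id").loc[list(pool.species_ids)]
        r = np.corrcoef(est.position, tm.optimum)[0, 1]
        assert r > 0.9

    def test_width_recovery_rank_correlation(self, default_synthetic):
        """Estimated widths rank-correlate with 2x the true tolerance."""
        ds, truth = default_synthetic
        pool = select_pool(ds.matrix, 10)
        est = niche_estimates(ds.matrix, ds.log_np(), pool)
        tm = truth.species.set_index("species_id").loc[list(pool.species_ids)]
        rho = stats.spearmanr(est.width, 2 * tm.tolerance).statistic
        assert rho > 0.5


class TestSanityPaths:
    """Switching a generator mechanism off removes the matching signal."""

    def test_single_mode_truth_yields_unimodal_verdict(self):
        from npniche.modality import modality_test

        config = SynthConfig(mode_weights=(1.0, 0.0), seed=21)
        ds, _ = generate_dataset(config)
        pool = select_pool(ds.matrix, 10)
        est = niche_estimates(ds.matrix, ds.log_np(), pool)
        res = modality_test(
            est.position.to_numpy(), n_sim=200, seed=33, n_restarts=6
        )
        assert res.verdict[0.05] == "unimodal"

    def test_flat_tolerance_removes_p_side_trend(self):
        from npniche.nullmodel import build_ensemble
        from npniche.tradeoff import subset_slopes

        config = SynthConfig(tolerance_extremity_slope=0.0, seed=22)
        ds, _ = generate_dataset(config)
        pool = select_pool(ds.matrix, 10)
        x = ds.log_np()
        est = niche_estimates(ds.matrix, x, pool)
        ens = build_ensemble(ds.matrix, x, pool, n_replicates=200, master_seed=22)
        slopes = subset_slopes(est, ens, grand_mean=float(x.mean()))
        assert slopes["P_side"].p_value > 0.05
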
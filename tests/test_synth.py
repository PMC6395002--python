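import math

import numpy as np
import pandas as pd
import pytest

from compadapt.epistasis import epistasis_table
from compadapt.hiervar import HierParams
from compadapt.mi import multi_hit_targets, mutual_information
from compadapt.synth import (
    SimConfig,
    simulate_fitness_gains,
    simulate_founder_panel,
    simulate_interaction_map,
    simulate_mutation_table,
    simulate_revertant_data,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_modules=0),
            dict(genes_per_module=0),
            dict(n_populations_per_founder=0),
            dict(founder_fitness_distribution=(-8.0, -1.0)),
            dict(mi_effect_strength=-0.1),
            dict(n_target_genes=0),
            dict(n_modules=3, genes_per_module=(1, 2)),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestFounderPanel:
    def test_default_design_shape(self):
        panel = simulate_founder_panel(SimConfig(seed=1))
        assert len(panel) == 37
        assert panel["module"].nunique() == 18
        assert panel["gene"].is_unique
        # nesting: each gene appears in exactly one module
        assert (panel.groupby("gene")["module"].nunique() == 1).all()

    def test_degenerate_single_founder(self):
        panel = simulate_founder_panel(SimConfig(n_modules=1,
                                                 genes_per_module=1))
        assert len(panel) == 1

    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=123)
        pd.testing.assert_frame_equal(simulate_founder_panel(cfg),
                                      simulate_founder_panel(cfg))

    def test_fitness_spread_matches_reference_regime(self):
        # configured to the reference spread, founders span roughly -24..+4
        panel = simulate_founder_panel(SimConfig(seed=5))
        x = panel["initial_fitness"]
        assert x.min() < -15 and x.max() > -2
        assert x.between(-40, 20).all()


class TestFitnessGains:
    def test_noise_free_limit_is_exact(self):
        cfg = SimConfig(n_modules=2, genes_per_module=2,
                        n_populations_per_founder=3,
                        n_replicate_measurements=2, seed=2)
        panel = simulate_founder_panel(cfg)
        p = HierParams(alpha=3.0, beta=-0.5)
        gains = simulate_fitness_gains(panel, p, cfg)
        x = gains.merge(panel, on=["module", "gene"])["initial_fitness"]
        assert np.allclose(gains["value"], 3.0 - 0.5 * x)

    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=4)
        panel = simulate_founder_panel(cfg)
        pd.testing.assert_frame_equal(
            simulate_fitness_gains(panel, config=cfg),
            simulate_fitness_gains(panel, config=cfg),
        )

    def test_law_of_total_variance(self):
        p = HierParams(alpha=2.0, beta=-0.4, sigma_m=1.5, sigma_g=1.0,
                       sigma_p=1.2, sigma_tau=0.8)
        cfg = SimConfig(n_modules=60, genes_per_module=2,
                        n_populations_per_founder=8,
                        n_replicate_measurements=2, seed=6)
        panel = simulate_founder_panel(cfg)
        gains = simulate_fitness_gains(panel, p, cfg)
        x = panel.set_index("gene")["initial_fitness"]
        expected = (
            p.beta**2 * x.var(ddof=0) + p.sigma_m**2 + p.sigma_g**2
            + p.sigma_p**2 + p.sigma_tau**2
        )
        got = gains["value"].var(ddof=0)
        assert got == pytest.approx(expected, rel=0.2)

    def test_expected_value_is_alpha_plus_beta_x(self):
        p = HierParams(alpha=2.0, beta=-0.4, sigma_p=0.5, sigma_tau=0.3)
        cfg = SimConfig(n_modules=2, genes_per_module=2,
                        n_populations_per_founder=400,
                        n_replicate_measurements=1, seed=8)
        panel = simulate_founder_panel(cfg)
        gains = simulate_fitness_gains(panel, p, cfg)
        per_gene = gains.groupby("gene")["value"].mean()
        x = panel.set_index("gene")["initial_fitness"]
        se = math.sqrt(0.5**2 + 0.3**2) / math.sqrt(400)
        assert np.allclose(per_gene, 2.0 - 0.4 * x[per_gene.index], atol=5 * se)


class TestRevertants:
    def _evolved(self, panel):
        return pd.DataFrame(
            {
                "population": range(1, len(panel) + 1),
                "gene": panel["gene"],
                "evolved_fitness": panel["initial_fitness"] + 5.0,
            }
        )

    def test_zero_outlier_rate_gives_tight_triplets(self):
        cfg = SimConfig(n_modules=3, genes_per_module=2, seed=10)
        panel = simulate_founder_panel(cfg)
        clones, _ = simulate_revertant_data(
            self._evolved(panel), panel, outlier_rate=0.0, clone_sd=0.1,
            config=cfg,
        )
        sds = clones.groupby("population")["fitness"].std(ddof=1)
        assert (sds < 0.5).all()

    def test_additive_case_median_matches_gain(self):
        cfg = SimConfig(n_modules=3, genes_per_module=2, seed=11)
        panel = simulate_founder_panel(cfg)
        evolved = self._evolved(panel)
        clones, truth = simulate_revertant_data(
            evolved, panel, epsilon_spec=0.0, outlier_rate=0.0,
            clone_sd=0.05, config=cfg,
        )
        med = clones.groupby("population")["fitness"].median()
        # with eps = 0 the revertant fitness equals evolved - founder = +5
        assert np.allclose(med, 5.0, atol=0.3)
        assert (truth["epsilon_true"] == 0).all()

    def test_outliers_planted_in_exactly_one_clone(self):
        cfg = SimConfig(n_modules=2, genes_per_module=2,
                        n_populations_per_founder=1, seed=12)
        panel = simulate_founder_panel(cfg)
        clones, truth = simulate_revertant_data(
            self._evolved(panel), panel, outlier_rate=1.0, clone_sd=0.01,
            outlier_offset=8.0, config=cfg,
        )
        for pop, grp in clones.groupby("population"):
            vals = np.sort(grp["fitness"].to_numpy())
            assert vals[2] - vals[1] > 5.0  # one clone far from the others
            assert vals[1] - vals[0] < 1.0

    def test_planted_entrenched_module_recovered_downstream(self):
        cfg = SimConfig(n_modules=4, genes_per_module=2,
                        n_populations_per_founder=5, seed=13)
        panel = simulate_founder_panel(cfg).copy()
        # entrenchment requires initially deleterious deletions
        panel["initial_fitness"] = -np.abs(panel["initial_fitness"]) - 1.0
        evolved = self._evolved(panel)
        clones, _ = simulate_revertant_data(
            evolved, panel, epsilon_spec={"M01": 30.0}, outlier_rate=0.0,
            clone_sd=0.1, config=cfg,
        )
        med = clones.groupby("population")["fitness"].median().rename(
            "revertant_fitness"
        )
        merged = (
            evolved.merge(panel[["gene", "module", "initial_fitness"]],
                          on="gene")
            .rename(columns={"gene": "founder_gene",
                             "initial_fitness": "founder_fitness"})
            .merge(med, on="population")
        )
        table = epistasis_table(merged).merge(
            panel[["gene", "module"]].rename(columns={"gene": "founder_gene"}),
            on="founder_gene",
        )
        assert table.loc[table["module"] == "M01", "entrenched"].all()
        assert not table.loc[table["module"] != "M01", "entrenched"].any()


class TestMutationTable:
    def test_counts_exactly_respected(self):
        cfg = SimConfig(n_modules=3, genes_per_module=2,
                        n_populations_per_founder=4,
                        mutations_per_population=("fixed", 3), seed=14)
        panel = simulate_founder_panel(cfg)
        table, _ = simulate_mutation_table(panel, cfg)
        counts = table.mutations.groupby("population").size()
        assert (counts == 3).all()
        assert len(counts) == table.n_populations

    def test_zero_mutations_give_zero_mi(self):
        cfg = SimConfig(n_modules=2, genes_per_module=2,
                        mutations_per_population=("fixed", 0), seed=15)
        panel = simulate_founder_panel(cfg)
        table, _ = simulate_mutation_table(panel, cfg)
        ts = multi_hit_targets(table)
        assert mutual_information(ts) == 0.0

    def test_strength_zero_is_founder_independent(self):
        cfg = SimConfig(n_modules=2, genes_per_module=2,
                        mi_effect_strength=0.0, seed=16)
        panel = simulate_founder_panel(cfg)
        _, truth = simulate_mutation_table(panel, cfg)
        assert np.allclose(truth["hit_probability"],
                           1.0 / cfg.n_target_genes)

    def test_observed_mi_approaches_generating_distribution_value(self):
        """With strong founder-conditional preferences, the plug-in MI at
        large sample size approaches the MI of the generating distribution
        (computed by brute force from the ground-truth probabilities)."""
        lam = 1.5
        cfg = SimConfig(n_modules=4, genes_per_module=1, n_target_genes=8,
                        mi_effect_strength=4.0,
                        mutations_per_population=("poisson", lam), seed=17)
        panel = simulate_founder_panel(cfg)
        table, truth = simulate_mutation_table(
            panel, cfg, n_populations_per_founder=800
        )
        # generating-distribution MI: p(hit t | founder) = 1 - exp(-lam p_t)
        piv = truth.pivot(index="founder_gene", columns="target_gene",
                          values="hit_probability")
        p_hit = 1.0 - np.exp(-lam * piv.to_numpy())
        pW = np.full(p_hit.shape[0], 1.0 / p_hit.shape[0])
        expected = 0.0
        for t in range(p_hit.shape[1]):
            for m in (0, 1):
                pmW = p_hit[:, t] if m else 1.0 - p_hit[:, t]
                pm = float(pW @ pmW)
                with np.errstate(divide="ignore", invalid="ignore"):
                    terms = np.where(pmW > 0,
                                     pW * pmW * np.log2(pmW / pm), 0.0)
                expected += float(terms.sum())
        ts = multi_hit_targets(table, level="gene")
        got = mutual_information(ts, by="gene")
        assert got == pytest.approx(expected, rel=0.05)

    def test_deterministic_under_seed(self):
        cfg = SimConfig(n_modules=2, genes_per_module=2, seed=18,
                        mi_effect_strength=1.0)
        panel = simulate_founder_panel(cfg)
        t1, _ = simulate_mutation_table(panel, cfg)
        t2, _ = simulate_mutation_table(panel, cfg)
        pd.testing.assert_frame_equal(t1.mutations, t2.mutations)


class TestInteractionMap:
    def test_perfect_correlation_limit(self):
        from compadapt.interaction import profile_correlations
        mods = pd.Series({"a": "M", "b": "M", "c": "N"})
        mat = simulate_interaction_map(mods, within_module_rho=1.0,
                                       noise_sd=0.0, n_background=30, seed=19)
        corr = profile_correlations(mat)
        i = {g: k for k, g in enumerate(corr.genes)}
        assert corr.rho[i["a"], i["b"]] == pytest.approx(1.0)
        assert abs(corr.rho[i["a"], i["c"]]) < 0.5

    def test_two_modules_recovered_by_threshold_components(self):
        from compadapt.interaction import interaction_clusters, profile_correlations
        mods = pd.Series({f"M{m}g{j}": f"M{m}" for m in range(2)
                          for j in range(4)})
        mat = simulate_interaction_map(mods, within_module_rho=0.8,
                                       n_background=200, seed=20)
        corr = profile_correlations(mat)
        labels = interaction_clusters(corr, threshold=0.2).labels
        panel_labels = {g: labels[g] for g in mods.index}
        m0 = {panel_labels[g] for g in mods.index if mods[g] == "M0"}
        m1 = {panel_labels[g] for g in mods.index if mods[g] == "M1"}
        assert len(m0) == 1 and len(m1) == 1 and m0 != m1

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            simulate_interaction_map(pd.Series({"a": "M"}),
                                     within_module_rho=1.2)
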
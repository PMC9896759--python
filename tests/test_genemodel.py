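"""The per-gene empirical-Bayes mixed model: oracles and invariants."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_logml, make_balanced_spec
from shrinkcrispr.genemodel import (DegenerateFitError, GeneModelSpec,
                                    HyperParameters, build_gene_specs,
                                    fit_gene, fit_genes, fit_hyperparameters,
                                    marginal_loglik, _reml_point_fits)
from shrinkcrispr.io import SampleSheet
from shrinkcrispr.preprocess import LethalityMatrix


def balanced_specs_from_model(n_genes, S=4, R=3, beta=0.0, tau_b=0.0,
                              tau_u=0.0, sigma=0.143, seed=0, beta_sd=0.0):
    """Generate genes directly from the mixed model's data-generating
    process (intercept + condition effect + guide effects + noise)."""
    rng = np.random.default_rng(seed)
    specs, betas = [], []
    guide = np.repeat(np.arange(S), 2 * R)
    cond = np.tile(np.repeat([0, 1], R), S)
    for g in range(n_genes):
        b = beta + beta_sd * rng.normal()
        bs = tau_b * rng.normal(size=S)
        us = tau_u * rng.normal(size=(S, 2))
        y = (0.2 + b * cond + bs[guide] + us[guide, cond]
             + sigma * rng.normal(size=S * 2 * R))
        specs.append(GeneModelSpec(gene=f"g{g}", y=y, condition=cond,
                                   guide=guide))
        betas.append(b)
    return specs, np.array(betas)


class TestMarginalLoglik:
    def test_agrees_with_bruteforce_quadrature(self, hp_toy):
        """Closed-form + quadrature marginal vs dense-grid integration."""
        rng = np.random.default_rng(21)
        for trial in range(4):
            S = int(rng.choice([2, 3]))
            spec = make_balanced_spec(S=S, R=2, beta=0.2 * (trial % 2),
                                      seed=100 + trial)
            for hypo in ("H0", "Ha"):
                ours = marginal_loglik(spec, hp_toy, hypo)
                oracle = brute_force_logml(spec, hp_toy, hypo)
                assert ours == pytest.approx(oracle, rel=1e-3)

    def test_no_signal_gives_bf_near_or_below_one(self, hp_toy):
        """Identical responses in both conditions leave no evidence for a
        condition effect (BF <= 1 up to quadrature slack)."""
        S, R = 3, 2
        guide = np.repeat(np.arange(S), 2 * R)
        cond = np.tile(np.repeat([0, 1], R), S)
        # exactly condition-symmetric data: same values in c=0 and c=1
        rng = np.random.default_rng(0)
        per_guide = rng.normal(0.2, 0.1, size=(S, R))
        y = np.concatenate([np.concatenate([per_guide[s], per_guide[s]])
                            for s in range(S)])
        spec = GeneModelSpec(gene="sym", y=y, condition=cond, guide=guide)
        f = fit_gene(spec, hp_toy)
        assert f.log_bf <= 0.1

    def test_scaling_identity(self, hp_toy):
        """Scaling y by k and all prior variances by k^2 shifts the log
        marginal by exactly -n log k."""
        k = 3.0
        spec = make_balanced_spec(S=3, R=2, beta=0.3, seed=7)
        spec_k = GeneModelSpec(gene="k", y=k * spec.y,
                               condition=spec.condition, guide=spec.guide)
        hp_k = HyperParameters(
            v_beta=k ** 2 * hp_toy.v_beta,
            log_theta_loc=hp_toy.log_theta_loc + 2 * np.log(k),
            log_theta_scale=hp_toy.log_theta_scale,
            v_alpha_scale=hp_toy.v_alpha_scale)
        n = spec.n_obs
        for hypo in ("H0", "Ha"):
            l1 = marginal_loglik(spec, hp_toy, hypo)
            l2 = marginal_loglik(spec_k, hp_k, hypo)
            assert l2 - l1 == pytest.approx(-n * np.log(k), abs=1e-5)

    def test_degenerate_gene_raises_with_name(self, hp_toy):
        spec = GeneModelSpec(gene="flatliner", y=np.full(8, 0.5),
                             condition=np.tile([0, 0, 1, 1], 2),
                             guide=np.repeat([0, 1], 4))
        with pytest.raises(DegenerateFitError, match="flatliner"):
            marginal_loglik(spec, hp_toy, "Ha")


class TestFitGene:
    def test_condition_swap_flips_beta_keeps_bf(self, hp_toy):
        for seed in (1, 2, 3):
            spec = make_balanced_spec(S=4, R=3, beta=0.4, seed=seed)
            f1 = fit_genes([spec], hp_toy)[0]
            f2 = fit_genes([spec.swap_conditions()], hp_toy)[0]
            assert f2.log_bf == pytest.approx(f1.log_bf, abs=1e-9)
            assert f2.beta_hat == pytest.approx(-f1.beta_hat, abs=1e-7)

    def test_fast_path_matches_dense_path(self, hp_toy):
        for seed in (5, 6):
            spec = make_balanced_spec(S=4, R=3, beta=0.2, seed=seed)
            fast = fit_genes([spec], hp_toy)[0]          # balanced group
            dense = fit_gene(spec, hp_toy)               # generic dense
            assert fast.logml_h0 == pytest.approx(dense.logml_h0, abs=1e-5)
            assert fast.logml_ha == pytest.approx(dense.logml_ha, abs=1e-5)
            assert fast.beta_hat == pytest.approx(dense.beta_hat, abs=1e-5)

    def test_determinism(self, hp_toy):
        spec = make_balanced_spec(S=4, R=3, beta=0.1, seed=9)
        a = fit_genes([spec], hp_toy)[0]
        b = fit_genes([spec], hp_toy)[0]
        assert a.logml_h0 == b.logml_h0 and a.logml_ha == b.logml_ha
        assert a.beta_hat == b.beta_hat

    def test_reordering_observations_preserves_bf(self, hp_toy):
        spec = make_balanced_spec(S=3, R=3, beta=0.3, seed=12)
        rng = np.random.default_rng(0)
        perm = rng.permutation(spec.n_obs)
        spec_p = GeneModelSpec(gene="p", y=spec.y[perm],
                               condition=spec.condition[perm],
                               guide=spec.guide[perm])
        f1 = fit_genes([spec], hp_toy)[0]
        f2 = fit_genes([spec_p], hp_toy)[0]
        assert f2.log_bf == pytest.approx(f1.log_bf, abs=1e-8)

    def test_shrinkage_toward_zero(self, hp_toy):
        """Posterior mean is strictly smaller in magnitude than the raw
        condition contrast whenever the effect prior is finite."""
        for seed in range(4):
            spec = make_balanced_spec(S=4, R=3, beta=0.35, seed=30 + seed)
            raw = (spec.y[spec.condition == 1].mean()
                   - spec.y[spec.condition == 0].mean())
            f = fit_genes([spec], hp_toy)[0]
            assert abs(f.beta_hat) < abs(raw)

    def test_monotone_evidence_in_effect_size(self):
        """Median log BF strictly increases along a beta grid."""
        hp = None
        medians = []
        for beta in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
            specs, _ = balanced_specs_from_model(100, beta=beta, sigma=0.143,
                                                 seed=int(beta * 10))
            if hp is None:
                hp = HyperParameters(
                    v_beta=0.05,
                    log_theta_loc=np.log(np.array([0.02, 0.005, 0.005])),
                    log_theta_scale=np.array([1.0, 1.5, 1.5]))
            fits = fit_genes(specs, hp)
            medians.append(np.median([f.log_bf for f in fits]))
        assert all(b > a for a, b in zip(medians, medians[1:]))

    def test_degenerate_time_design_matches_single_timepoint(self, hp_toy):
        spec = make_balanced_spec(S=3, R=3, beta=0.3, seed=40)
        spec_t = GeneModelSpec(gene="t0", y=spec.y, condition=spec.condition,
                               guide=spec.guide, time=np.zeros(spec.n_obs),
                               design="longitudinal")
        f_single = fit_gene(spec, hp_toy)
        f_long = fit_gene(spec_t, hp_toy)
        assert f_long.beta_time == pytest.approx(0.0, abs=1e-9)
        assert f_long.beta_interaction == pytest.approx(0.0, abs=1e-9)
        assert f_long.beta_hat == pytest.approx(f_single.beta_hat, abs=1e-6)

    def test_longitudinal_interaction_recovery(self, hp_toy):
        """A pure condition-by-time effect loads on beta3, not beta2."""
        S, R, T = 3, 3, 2
        rng = np.random.default_rng(55)
        rows = [(s, c, r, t) for s in range(S) for c in (0, 1)
                for r in range(R) for t in (0.0, 1.0)]
        cond = np.array([c for _, c, _, _ in rows])
        time = np.array([t for _, _, _, t in rows])
        guide = np.array([s for s, _, _, _ in rows])
        y = 0.1 + 0.5 * cond * time + 0.1 * rng.normal(size=len(rows))
        spec = GeneModelSpec(gene="lg", y=y, condition=cond, guide=guide,
                             time=time, design="longitudinal")
        f = fit_gene(spec, hp_toy, test="interaction")
        assert f.beta_interaction == pytest.approx(0.5, abs=0.2)
        assert f.log_bf > 2.0


class TestHyperparameters:
    def test_null_screen_collapses_v_beta_to_floor(self):
        specs, _ = balanced_specs_from_model(120, beta=0.0, seed=60)
        hp = fit_hyperparameters(specs)
        assert hp.v_beta == pytest.approx(hp.v_floor)

    def test_recovers_gaussian_effect_variance(self):
        """beta ~ N(0, 0.04) with modest noise: v_beta within 20%."""
        specs, _ = balanced_specs_from_model(1000, beta=0.0, beta_sd=0.2,
                                             sigma=0.03, seed=61)
        hp = fit_hyperparameters(specs)
        assert hp.v_beta == pytest.approx(0.04, rel=0.2)

    def test_doubling_responses_quadruples_v_beta(self):
        specs, _ = balanced_specs_from_model(400, beta=0.0, beta_sd=0.25,
                                             sigma=0.05, seed=62)
        specs2 = [GeneModelSpec(gene=s.gene, y=2 * s.y, condition=s.condition,
                                guide=s.guide) for s in specs]
        hp1 = fit_hyperparameters(specs)
        hp2 = fit_hyperparameters(specs2)
        assert hp2.v_beta == pytest.approx(4 * hp1.v_beta, rel=0.05)

    def test_too_few_genes_raises(self):
        specs, _ = balanced_specs_from_model(5, seed=63)
        with pytest.raises(ValueError, match="10"):
            fit_hyperparameters(specs)

    def test_reml_estimates_variance_components(self):
        """Stage-1 point fits recover sigma_eps and tau_b on average."""
        specs, _ = balanced_specs_from_model(300, beta=0.0, tau_b=0.2,
                                             sigma=0.1, seed=64)
        _, _, theta = _reml_point_fits(specs)
        assert np.median(theta[:, 0]) == pytest.approx(0.01, rel=0.25)
        assert np.median(theta[:, 1]) == pytest.approx(0.04, rel=0.5)


class TestBuildGeneSpecs:
    def make_lethality(self, values, guide_ids, sample_ids):
        return LethalityMatrix(values=np.asarray(values, float),
                               guide_ids=tuple(guide_ids),
                               sample_ids=tuple(sample_ids),
                               fc_neg=np.zeros(len(sample_ids)),
                               fc_pos=np.ones(len(sample_ids)))

    def sheet(self):
        rows = []
        for c in ("c1", "c2"):
            for r in (1, 2, 3):
                rows.append((f"T0_{c}_r{r}", c, r, "T0", ""))
                rows.append((f"T1_{c}_r{r}", c, r, "T1", f"T0_{c}_r{r}"))
        return SampleSheet(
            pd.DataFrame(rows, columns=["sample", "condition", "replicate",
                                        "timepoint", "t0_partner"]),
            design="independent")

    def test_complete_screen_gives_full_specs(self, small_screen):
        from shrinkcrispr.api import ShrinkCrisprModel
        model = ShrinkCrisprModel(small_screen.screen, small_screen.sheet,
                                  small_screen.controls)
        specs, excl = model.gene_specs()
        assert len(specs) == 80          # controls excluded by default
        assert all(s.n_obs == 24 for s in specs)
        assert len(excl) == 0

    def test_gene_missing_in_one_condition_excluded(self):
        samples = [f"T1_c{c}_r{r}" for c in (1, 2) for r in (1, 2, 3)]
        values = np.ones((2, 6))
        values[:, 3:] = np.nan        # both guides absent from condition 2
        l = self.make_lethality(values, ["a_sg1", "a_sg2"], samples)
        specs, excl = build_gene_specs(l, self.sheet(),
                                       {"a_sg1": "a", "a_sg2": "a"})
        assert len(specs) == 0
        assert excl["gene"].tolist() == ["a"]

    def test_single_guide_gene_excluded_unless_allowed(self):
        samples = [f"T1_c{c}_r{r}" for c in (1, 2) for r in (1, 2, 3)]
        rng = np.random.default_rng(0)
        l = self.make_lethality(rng.normal(size=(1, 6)), ["solo_sg1"], samples)
        specs, excl = build_gene_specs(l, self.sheet(), {"solo_sg1": "solo"})
        assert len(specs) == 0 and "guides" in excl["reason"].iloc[0]
        specs2, _ = build_gene_specs(l, self.sheet(), {"solo_sg1": "solo"},
                                     allow_single_guide=True)
        assert len(specs2) == 1

    def test_longitudinal_selection_doubles_observations(self):
        rows = []
        for c in ("c1", "c2"):
            for r in (1, 2):
                rows.append((f"T0_{c}_r{r}", c, r, "T0", ""))
                rows.append((f"T1_{c}_r{r}", c, r, "T1", f"T0_{c}_r{r}"))
                rows.append((f"T2_{c}_r{r}", c, r, "T2", f"T0_{c}_r{r}"))
        sheet = SampleSheet(
            pd.DataFrame(rows, columns=["sample", "condition", "replicate",
                                        "timepoint", "t0_partner"]),
            design="independent")
        samples = [f"T{t}_c{c}_r{r}" for c in (1, 2) for r in (1, 2)
                   for t in (1, 2)]
        rng = np.random.default_rng(1)
        l = self.make_lethality(rng.normal(size=(2, 8)),
                                ["a_sg1", "a_sg2"], samples)
        gmap = {"a_sg1": "a", "a_sg2": "a"}
        one, _ = build_gene_specs(l, sheet, gmap, timepoints=["T1"])
        both, _ = build_gene_specs(l, sheet, gmap, timepoints=["T1", "T2"])
        assert both[0].n_obs == 2 * one[0].n_obs
        assert both[0].design == "longitudinal"
        assert set(np.unique(both[0].time)) == {0.0, 1.0}
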
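"""REML engine: structure, likelihood oracle, constrained fits, recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from dyadige.animal_model import (
    AdmissibilityError,
    Constraint,
    ModelBuildError,
    ModelSpec,
    TraitModel,
    VarianceComponents,
    build_mixed_model,
    expand_components,
    fit,
    fit_constrained,
    refit_if_beaten,
    reml_loglik,
    _build_V,
)
from dyadige.pedigree import build_half_sib_design
from dyadige.synth import (
    AssayDesign,
    Channel,
    ChannelSet,
    DIRECT,
    EnvironmentConfig,
    GeneticCovariance,
    INDIRECT,
    sample_breeding_values,
    simulate_trials,
)

from conftest import random_pedigree

CD = Channel("lat_sing", DIRECT)
CI = Channel("lat_sing", INDIRECT)


def reml_loglik_oracle(y, X, V):
    """Error-contrast restricted likelihood: project y onto an orthonormal
    basis of the null space of X' and evaluate the plain Gaussian density."""
    n, p = X.shape
    Q, _ = np.linalg.qr(X, mode="complete")
    B = Q[:, p:]
    S = B.T @ V @ B
    w = B.T @ y
    _, logdet = np.linalg.slogdet(S)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdet + w @ np.linalg.solve(S, w))


def small_instance(seed, n_trials=40):
    """A small dyadic dataset plus an admissible component set."""
    rng = np.random.default_rng(seed)
    ped = random_pedigree(rng, n=30, n_generations=3)
    males, females = ped.males(), ped.females()
    trials = pd.DataFrame({
        "male_id": rng.choice(males, size=n_trials),
        "female_id": rng.choice(females, size=n_trials),
        "order": rng.integers(1, 4, size=n_trials),
        "shelf": rng.choice(["lower", "upper"], size=n_trials),
        "lat_sing": rng.normal(size=n_trials),
    })
    mm = build_mixed_model(trials, pd.DataFrame(columns=["id", "trait", "value", "occasion"]),
                           ped, ModelSpec.univariate("lat_sing"))
    a, b, c = rng.uniform(0.05, 0.4, size=3)
    rho = rng.uniform(-0.8, 0.8)
    G = np.array([[a, rho * np.sqrt(a * b)], [rho * np.sqrt(a * b), b]])
    vc = VarianceComponents(
        GeneticCovariance(mm.gchannels, G),
        {ch: rng.uniform(0.02, 0.3) for ch in mm.pe_channels},
        {"lat_sing": rng.uniform(0.3, 1.0)},
    )
    return mm, vc


class TestBuildMixedModel:
    def _tiny_data(self):
        ped = build_half_sib_design(1, 1, 3, 0.0, 0.5, seed=0)
        ids = ped.offspring_ids()
        males = [i for i in ids if ped.sex[ped.index[i]] == "M"] or ids[:1]
        females = [i for i in ids if ped.sex[ped.index[i]] == "F"] or ids[1:2]
        trials = pd.DataFrame({
            "male_id": [males[0]] * 6,
            "female_id": [females[0]] * 6,
            "order": [1, 2, 3, 1, 2, 3],
            "shelf": ["lower", "upper"] * 3,
            "lat_sing": np.arange(6.0),
        })
        morph = pd.DataFrame({
            "id": ids, "trait": "testis", "value": [1.0] * len(ids),
            "occasion": 1,
        })
        return ped, trials, morph

    def test_univariate_dyadic_structure(self):
        ped, trials, morph = self._tiny_data()
        mm = build_mixed_model(trials, morph, ped, ModelSpec.univariate("lat_sing"))
        assert mm.n == 6
        # intercept + order + shelf, minus columns dropped for rank deficiency
        assert {"order", "shelf:upper"} <= set(mm.fixed_names) | {"order", "shelf:upper"}
        assert len(mm.gchannels) == 2
        assert len(mm.pe_channels) == 2

    def test_once_morphology_has_single_channel_no_pe(self):
        ped, trials, morph = self._tiny_data()
        mm = build_mixed_model(trials, morph, ped, ModelSpec.univariate("testis"))
        assert mm.gchannels.labels == ["testis:direct"]
        assert mm.pe_channels == []
        assert mm.fixed_names == ["intercept:testis"]

    def test_bivariate_intercepts_only(self):
        ped, trials, morph = self._tiny_data()
        mm = build_mixed_model(trials, morph, ped, ModelSpec.bivariate("lat_sing", "testis"))
        assert mm.fixed_names == ["intercept:lat_sing", "intercept:testis"]

    def test_morphology_indirect_channel_rejected(self):
        with pytest.raises(ValueError, match="indirect"):
            TraitModel("testis", "once", "male", indirect_genetic=True)

    def test_once_trait_pe_rejected(self):
        with pytest.raises(ValueError, match="permanent-environment"):
            TraitModel("testis", "once", "male", direct_pe=True)

    def test_bivariate_fixed_effects_rejected(self):
        with pytest.raises(ValueError, match="intercept"):
            ModelSpec(
                traits=(TraitModel.standard("lat_sing"), TraitModel.standard("testis")),
                fixed_effects=("order",),
            )

    def test_spec_serialization_round_trip(self):
        spec = ModelSpec.bivariate("lat_sing", "testis")
        spec = dataclasses.replace(
            spec,
            pinned_covariances=frozenset({frozenset(
                (CI, Channel("testis", DIRECT)))}),
        )
        assert ModelSpec.from_dict(spec.to_dict()) == spec

    def test_unknown_individual_raises(self):
        ped, trials, morph = self._tiny_data()
        trials.loc[0, "male_id"] = "GHOST"
        with pytest.raises(ModelBuildError, match="GHOST"):
            build_mixed_model(trials, morph, ped, ModelSpec.univariate("lat_sing"))


class TestRemlLoglik:
    def test_matches_error_contrast_oracle(self):
        for seed in range(25):
            mm, vc = small_instance(seed)
            ll = reml_loglik(mm, vc)
            V = _build_V(mm, vc.to_sigma(mm))
            assert ll == pytest.approx(reml_loglik_oracle(mm.y, mm.X, V), abs=1e-8)

    def test_translation_invariance(self):
        mm, vc = small_instance(99)
        rng = np.random.default_rng(0)
        ll = reml_loglik(mm, vc)
        for _ in range(5):
            shifted = mm.with_response(mm.y + mm.X @ rng.normal(size=mm.p))
            assert reml_loglik(shifted, vc) == pytest.approx(ll, abs=1e-8)

    def test_no_random_channels_closed_form(self):
        """Fixed effects + residual only: the restricted likelihood has the
        textbook closed form with V = s2 I."""
        mm, vc = small_instance(7)
        mm0 = mm.with_constraints([
            Constraint("genetic_variance", (CD,)),
            Constraint("genetic_variance", (CI,)),
            Constraint("pe_variance", (CD,)),
            Constraint("pe_variance", (CI,)),
        ])
        s2 = 1.3
        vc0 = VarianceComponents(
            GeneticCovariance(mm0.gchannels, np.zeros((0, 0))), {}, {"lat_sing": s2})
        n, p = mm0.n, mm0.p
        # closed form: V = s2 I
        Q, _ = np.linalg.qr(mm0.X, mode="complete")
        w = Q[:, p:].T @ mm0.y
        expect = -0.5 * ((n - p) * np.log(2 * np.pi * s2) + w @ w / s2)
        assert reml_loglik(mm0, vc0) == pytest.approx(expect, abs=1e-8)

    def test_inadmissible_components_raise(self):
        mm, vc = small_instance(3)
        bad = VarianceComponents(vc.genetic, vc.pe, {"lat_sing": 0.0})
        with pytest.raises(AdmissibilityError):
            reml_loglik(mm, bad)


def simulate_and_build(seed, n_sires=8, offspring=10, assays=180,
                       v_am=0.15, v_af=0.10, cov=0.05, v_pem=0.10,
                       v_pef=0.10, v_r=0.60, pin_cov=False):
    ped = build_half_sib_design(n_sires, 2, offspring, 0.0, 0.5, seed=seed)
    g = GeneticCovariance.from_entries([CD, CI], {CD: v_am, CI: v_af}, {(CD, CI): cov})
    env = EnvironmentConfig(
        pe_variance={CD: v_pem, CI: v_pef},
        residual_variance={"lat_sing": v_r},
        beta_order={"lat_sing": -0.1}, beta_shelf={"lat_sing": 0.15},
    )
    bv = sample_breeding_values(ped, g, seed=seed + 1)
    trials, morph = simulate_trials(ped, bv, env, AssayDesign(target_assays=assays),
                                    seed=seed + 2)
    spec = ModelSpec.univariate("lat_sing")
    if pin_cov:
        spec = dataclasses.replace(
            spec, pinned_covariances=frozenset({frozenset((CD, CI))}))
    return build_mixed_model(trials, morph, ped, spec)


class TestFit:
    def test_restart_stability(self):
        mm = simulate_and_build(5, n_sires=5, assays=90)
        lls = [fit(mm, seed=s, restarts=1).loglik for s in (0, 1, 2)]
        assert max(lls) - min(lls) < 1e-6

    def test_null_data_recovers_near_zero_channels(self):
        """Residual-only truth: every channel estimate collapses toward 0."""
        mm = simulate_and_build(21, n_sires=12, offspring=14, assays=420,
                                v_am=0.0, v_af=0.0, cov=0.0,
                                v_pem=0.0, v_pef=0.0, v_r=1.0)
        f = fit(mm, seed=0, restarts=1)
        sig = f.components.to_sigma(mm)
        names = mm.component_names()
        for name, val in zip(names, sig):
            if name.startswith("R:"):
                continue
            assert abs(val) <= 0.05, name

    def test_nesting_constrained_not_above_full(self):
        mm = simulate_and_build(9, n_sires=6, assays=120)
        full = fit(mm, seed=0, restarts=1)
        for con in (
            Constraint("genetic_variance", (CI,)),
            Constraint("genetic_covariance", (CD, CI)),
            Constraint("pe_variance", (CD,)),
        ):
            red = fit_constrained(mm, [con], seed=1, init=full.components, restarts=1)
            full = refit_if_beaten(full, [red], mm, seed=2)
            assert red.loglik <= full.loglik + 1e-6

    def test_constraining_null_component_costs_nothing(self):
        """No indirect effect in truth: pinning V_Af barely moves logL."""
        mm = simulate_and_build(13, n_sires=8, offspring=12, assays=260,
                                v_af=0.0, cov=0.0, v_pef=0.0)
        full = fit(mm, seed=0, restarts=1)
        red = fit_constrained(mm, [Constraint("genetic_variance", (CI,))],
                              seed=1, init=full.components, restarts=1)
        assert full.loglik - red.loglik < 1e-4 * abs(full.loglik)

    def test_constraining_strong_covariance_costs_likelihood(self):
        """True correlation 0.8: pinning the covariance drops logL by > 2."""
        mm = simulate_and_build(17, n_sires=14, offspring=14, assays=500,
                                v_am=0.2, v_af=0.2,
                                cov=0.8 * 0.2, v_pem=0.05, v_pef=0.05)
        full = fit(mm, seed=0, restarts=1)
        red = fit_constrained(mm, [Constraint("genetic_covariance", (CD, CI))],
                              seed=1, init=full.components, restarts=1)
        assert full.loglik - red.loglik > 2.0

    def test_all_channels_constrained_is_fixed_effects_model(self):
        mm = simulate_and_build(3, n_sires=5, assays=90)
        red = fit_constrained(mm, [
            Constraint("genetic_variance", (CD,)),
            Constraint("genetic_variance", (CI,)),
            Constraint("pe_variance", (CD,)),
            Constraint("pe_variance", (CI,)),
        ], seed=0, restarts=1)
        # analytic REML for V = s2 I: s2 = y'My/(n-p) with M the residual maker
        Q, _ = np.linalg.qr(mm.X, mode="complete")
        w = Q[:, mm.p:].T @ mm.y
        n_p = mm.n - mm.p
        s2 = w @ w / n_p
        expect = -0.5 * (n_p * np.log(2 * np.pi * s2) + n_p)
        assert red.loglik == pytest.approx(expect, abs=1e-6)
        assert red.components.residual["lat_sing"] == pytest.approx(s2, rel=1e-5)

    def test_boundary_flag_set_on_zero_variance(self):
        mm = simulate_and_build(31, n_sires=8, offspring=12, assays=260,
                                v_af=0.0, cov=0.0, v_pef=0.0)
        f = fit(mm, seed=0, restarts=1)
        flagged = [n for n, b in f.boundary.items() if b]
        assert any(n.startswith(("G:", "PE:")) for n in flagged)


class TestClosedFormHalfSib:
    def test_reml_equals_anova_sire_estimator(self):
        """Balanced paternal half-sib, direct channel only: REML sigma2_A
        equals the ANOVA estimator 4 * sigma2_sire when interior."""
        n_sires, k = 20, 10
        ped = build_half_sib_design(n_sires, k, 1, 0.0, 0.5, seed=2)
        cd = Channel("testis", DIRECT)
        g = GeneticCovariance(ChannelSet([cd]), np.array([[0.4]]))
        bv = sample_breeding_values(ped, g, seed=3)
        rng = np.random.default_rng(4)
        ids = ped.offspring_ids()
        y = bv.loc[ids, "testis:direct"].to_numpy() + rng.normal(0, np.sqrt(0.6), len(ids))
        morph = pd.DataFrame({"id": ids, "trait": "testis", "value": y, "occasion": 1})
        trials = pd.DataFrame(columns=["male_id", "female_id", "order", "shelf"])
        mm = build_mixed_model(trials, morph, ped, ModelSpec.univariate("testis"))
        f = fit(mm, seed=0, restarts=1)

        sires = [ped.ids[s] for s in ped.sire_idx[[ped.index[i] for i in ids]]]
        df = pd.DataFrame({"sire": sires, "y": y})
        gm = df["y"].mean()
        means = df.groupby("sire")["y"].mean()
        msb = k * ((means - gm) ** 2).sum() / (n_sires - 1)
        msw = ((df["y"] - df["sire"].map(means)) ** 2).sum() / (n_sires * (k - 1))
        sigma2_sire = (msb - msw) / k
        assert sigma2_sire > 0  # interior
        est = f.components.genetic.value(cd, cd)
        assert est == pytest.approx(4 * sigma2_sire, abs=1e-6)


class TestParameterRecovery:
    def test_mean_estimates_unbiased_at_scale(self):
        """Half-sib mating-trial scenario: replicate simulate-and-fit means
        land within 3 Monte-Carlo SEs of the generating values."""
        truth = {"G:lat_sing:direct|lat_sing:direct": 0.15,
                 "G:lat_sing:direct|lat_sing:indirect": 0.05,
                 "G:lat_sing:indirect|lat_sing:indirect": 0.10,
                 "PE:lat_sing:direct": 0.10,
                 "PE:lat_sing:indirect": 0.10,
                 "R:lat_sing": 0.60}
        reps = 12
        ests = []
        for r in range(reps):
            mm = simulate_and_build(700 + 11 * r, n_sires=12, offspring=14,
                                    assays=420)
            f = fit(mm, seed=r, restarts=1)
            ests.append(f.components.to_sigma(mm))
        ests = np.array(ests)
        names = mm.component_names()
        for k, name in enumerate(names):
            mean = ests[:, k].mean()
            mc_se = ests[:, k].std(ddof=1) / np.sqrt(reps)
            assert abs(mean - truth[name]) < 3 * mc_se + 0.02, name
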
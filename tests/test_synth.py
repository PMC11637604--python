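"""Synthetic-data generator: breeding-value moments, trial structure, presets."""

import numpy as np
import pandas as pd
import pytest

from dyadige.pedigree import build_half_sib_design, relationship_matrix
from dyadige.synth import (
    AssayDesign,
    Channel,
    ChannelSet,
    DesignInfeasibleError,
    DIRECT,
    EnvironmentConfig,
    GeneticCovariance,
    INDIRECT,
    apply_preset_overrides,
    paper_scale_preset,
    preset_from_dict,
    preset_to_dict,
    sample_breeding_values,
    scaled_preset,
    simulate_study,
    simulate_trials,
)

from conftest import make_pedigree


CD = Channel("lat_sing", DIRECT)
CI = Channel("lat_sing", INDIRECT)


class TestChannels:
    def test_indirect_requires_dyadic_trait(self):
        with pytest.raises(ValueError):
            Channel("testis", INDIRECT)

    def test_expresser_sex(self):
        assert CD.expresser_sex == "male"
        assert CI.expresser_sex == "female"
        assert Channel("lat_mount", INDIRECT).expresser_sex == "male"

    def test_genetic_covariance_validation(self):
        cs = ChannelSet([CD, CI])
        with pytest.raises(ValueError):
            GeneticCovariance(cs, np.array([[1.0, 2.0], [2.0, 1.0]]))  # not PSD
        with pytest.raises(ValueError):
            GeneticCovariance(cs, np.array([[1.0, 0.1], [0.2, 1.0]]))  # asymmetric
        g = GeneticCovariance(cs, np.array([[0.3, 0.1], [0.1, 0.2]]))
        assert g.value(CD, CI) == pytest.approx(0.1)


class TestBreedingValues:
    def test_zero_genetic_variance_gives_zero_bv(self, sib_quartet):
        g = GeneticCovariance(ChannelSet([CD]), np.zeros((1, 1)))
        bv = sample_breeding_values(sib_quartet, g, seed=0)
        assert (bv.to_numpy() == 0).all()

    def test_seed_determinism(self, sib_quartet):
        g = GeneticCovariance(ChannelSet([CD, CI]), np.array([[0.3, 0.1], [0.1, 0.2]]))
        a = sample_breeding_values(sib_quartet, g, seed=5)
        b = sample_breeding_values(sib_quartet, g, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_parent_offspring_covariance(self):
        """Empirical cov(parent, offspring) ~= 0.5 * V_A over replicates."""
        ped = make_pedigree([
            ("S", "0", "0", "M"), ("D", "0", "0", "F"), ("X", "S", "D", "M"),
        ])
        g = GeneticCovariance(ChannelSet([CD]), np.array([[1.0]]))
        draws = np.array([
            sample_breeding_values(ped, g, seed=s).to_numpy().ravel()
            for s in range(2000)
        ])
        c = np.cov(draws[:, 0], draws[:, 2])[0, 1]
        # MC SE of a covariance of unit normals ~ sqrt((1 + 0.25)/n)
        assert abs(c - 0.5) < 3 * np.sqrt(1.25 / 2000)

    def test_kronecker_moment_structure(self):
        """cov(bv[i, c], bv[j, d]) ~= A_ij * G_cd on a fixed 40-member pedigree."""
        ped = build_half_sib_design(4, 2, 4, 0.0, 0.5, seed=9)
        assert len(ped) == 44
        G = np.array([[0.3, 0.1], [0.1, 0.2]])
        g = GeneticCovariance(ChannelSet([CD, CI]), G)
        A = relationship_matrix(ped).A
        reps = 2000
        draws = np.stack([
            sample_breeding_values(ped, g, seed=10_000 + s).to_numpy()
            for s in range(reps)
        ])  # (reps, n, 2)
        rng = np.random.default_rng(1)
        pairs = [(rng.integers(len(ped)), rng.integers(len(ped)),
                  rng.integers(2), rng.integers(2)) for _ in range(12)]
        for i, j, c, d in pairs:
            emp = np.cov(draws[:, i, c], draws[:, j, d])[0, 1]
            expect = A[i, j] * G[c, d]
            vi = A[i, i] * G[c, c]
            vj = A[j, j] * G[d, d]
            mc_se = np.sqrt((vi * vj + expect ** 2) / reps)
            assert abs(emp - expect) < 3 * mc_se + 1e-12


class TestSimulateTrials:
    def _env(self, vr=0.0, pe=0.0, b0=5.0):
        return EnvironmentConfig(
            pe_variance={CD: pe, CI: pe},
            residual_variance={"lat_sing": vr},
            intercept={"lat_sing": b0},
            beta_order={"lat_sing": 1.0},
            beta_shelf={"lat_sing": 10.0},
        )

    def _study(self, seed=0):
        ped = build_half_sib_design(4, 2, 6, 0.0, 0.5, seed=seed)
        g = GeneticCovariance(ChannelSet([CD, CI]), np.zeros((2, 2)))
        bv = sample_breeding_values(ped, g, seed=seed)
        return ped, bv

    def test_fixed_effects_only(self):
        """All variances zero: trait = intercept + order/shelf terms exactly."""
        ped, bv = self._study()
        trials, _ = simulate_trials(ped, bv, self._env(), AssayDesign(), seed=3)
        expect = 5.0 + trials["order"] + 10.0 * (trials["shelf"] == "upper")
        assert np.allclose(trials["lat_sing"], expect)

    def test_order_increments_within_male(self):
        ped, bv = self._study()
        trials, _ = simulate_trials(ped, bv, self._env(), AssayDesign(), seed=3)
        for _, sub in trials.groupby("male_id"):
            assert list(sub["order"]) == list(range(1, len(sub) + 1))

    def test_partners_distinct_within_male(self):
        ped, bv = self._study()
        trials, _ = simulate_trials(
            ped, bv, self._env(), AssayDesign(target_assays=30), seed=3
        )
        for _, sub in trials.groupby("male_id"):
            assert sub["female_id"].nunique() == len(sub)

    def test_reuse_disabled_raises(self):
        ped, bv = self._study()
        with pytest.raises(DesignInfeasibleError):
            simulate_trials(
                ped, bv, self._env(),
                AssayDesign(target_assays=36, allow_female_reuse=False), seed=3,
            )

    def test_determinism(self):
        ped, bv = self._study()
        env = self._env(vr=0.5, pe=0.2)
        t1, m1 = simulate_trials(ped, bv, env, AssayDesign(), seed=11)
        t2, m2 = simulate_trials(ped, bv, env, AssayDesign(), seed=11)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(m1, m2)


class TestPresets:
    def test_paper_scale_design_counts(self):
        p = paper_scale_preset()
        assert p.n_sires == 35
        assert p.dams_per_sire == 2
        assert p.design.target_assays == 826
        assert p.offspring_per_family == 16

    def test_paper_scale_realized_totals(self):
        p = paper_scale_preset()
        ped, bv, trials, morph = simulate_study(p, seed=3)
        assert len(trials) == 826
        n_m = trials["male_id"].nunique()
        n_f = trials["female_id"].nunique()
        assert abs(n_m - 310) <= 30
        assert abs(n_f - 747) <= 60
        fams = {(s, d) for s, d in zip(ped.sire_idx, ped.dam_idx) if s >= 0}
        assert abs(len(fams) - 66) <= 6
        assert trials.groupby("male_id")["order"].max().max() <= 3

    def test_guarding_has_no_genetic_variance(self):
        p = paper_scale_preset()
        gd = Channel("guard_dist", DIRECT)
        gi = Channel("guard_dist", INDIRECT)
        assert p.genetic.value(gd, gd) == 0.0
        assert p.genetic.value(gi, gi) == 0.0

    def test_scaled_preset_shrinks_assays(self):
        p = scaled_preset(15)
        assert p.n_sires == 15
        assert p.design.target_assays == pytest.approx(826 * 15 / 35, abs=1)

    def test_preset_dict_round_trip(self):
        p = paper_scale_preset()
        d = preset_to_dict(p)
        q = preset_from_dict(d)
        assert np.allclose(q.genetic.submatrix(list(p.genetic.channels)).G0,
                           p.genetic.G0)
        assert q.environment.residual_variance == p.environment.residual_variance
        assert q.design == p.design
        assert q.n_sires == p.n_sires

    def test_preset_overrides_named_parameters(self):
        p = paper_scale_preset()
        o = apply_preset_overrides(p, {
            "pedigree": {"n_sires": 5},
            "genetic": {"variances": {"lat_sing:indirect": 0.0},
                        "covariances": {
                            "lat_sing:direct|lat_sing:indirect": 0.0,
                            "lat_sing:indirect|testis:direct": 0.0}},
            "environment": {"residual_variance": {"lat_sing": 0.9}},
        })
        ci = Channel("lat_sing", INDIRECT)
        assert o.n_sires == 5
        assert o.genetic.value(ci, ci) == 0.0
        assert o.environment.residual_variance["lat_sing"] == 0.9
        # untouched parameters survive the merge
        assert o.environment.residual_variance["testis"] == \
            p.environment.residual_variance["testis"]

    def test_study_determinism(self):
        p = scaled_preset(6)
        _, _, t1, m1 = simulate_study(p, seed=2)
        _, _, t2, m2 = simulate_study(p, seed=2)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(m1, m2)
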
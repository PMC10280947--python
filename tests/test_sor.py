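"""Simulated-odds-ratio engine: oracles, symmetry, coverage, recovery."""

import math

import numpy as np
import pytest
import scipy.stats as st

import telepain as tp
from telepain import sor as S
from telepain import bench as B


class _StochasticOracle:
    """Classifier whose positive probability is logistic(b0 + b.x)."""

    def __init__(self, intercept=0.0, **effects):
        self.intercept = intercept
        self.effects = effects

    def predict_proba_more(self, X):
        lp = np.full(len(X), self.intercept, dtype=float)
        for var, beta in self.effects.items():
            lp += beta * X[var].to_numpy(float)
        return 1.0 / (1.0 + np.exp(-lp))


class _HardModel:
    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.full(len(X), self.label, dtype=int)


@pytest.fixture(scope="module")
def spec():
    return tp.default_spec(n=218)


class TestOdds:
    def test_basic_values(self):
        assert S.odds(0.5) == pytest.approx(1.0)
        assert S.odds(0.8) == pytest.approx(4.0)

    def test_continuity_correction(self):
        assert S.odds(1.0, eps=0.0025) == pytest.approx((1 - 0.0025) / 0.0025)
        assert S.odds(0.0, eps=0.0025) == pytest.approx(0.0025 / (1 - 0.0025))

    def test_domain(self):
        with pytest.raises(ValueError):
            S.odds(1.2)


class TestProfiles:
    def test_gender_consistency_contract(self, spec):
        rng = np.random.default_rng(0)
        X = S.sample_profiles(S.ProfileSpec(), spec, 4000, rng)
        assert (X.loc[X["site"] == "prostate", "gender"] == "male").all()
        assert (X.loc[X["site"] == "gynecological", "gender"] == "female").all()
        assert (X.loc[X["site"] == "breast", "gender"] == "female").mean() >= 0.95

    def test_fixed_features_held(self, spec):
        rng = np.random.default_rng(0)
        prof = S.ProfileSpec(fixed={"btcp": 1, "ecog": 3})
        X = S.sample_profiles(prof, spec, 500, rng)
        assert (X["btcp"] == 1).all()
        assert (X["ecog"] == 3).all()

    def test_age_gaussian_spec(self, spec):
        rng = np.random.default_rng(0)
        X = S.sample_profiles(S.ProfileSpec(age_gauss=(45, 5)), spec, 4000, rng)
        assert X["age"].mean() == pytest.approx(45, abs=0.5)
        assert X["age"].std() == pytest.approx(5, abs=0.5)

    def test_uniform_mode(self, spec):
        rng = np.random.default_rng(0)
        X = S.sample_profiles(S.ProfileSpec(), spec, 6000, rng, mode="uniform")
        assert X["btcp"].mean() == pytest.approx(0.5, abs=0.05)


class TestSimulateProfile:
    def test_constant_models(self, spec):
        rng = np.random.default_rng(0)
        assert S.simulate_profile(_HardModel(1), S.ProfileSpec(), spec, 50, rng) == 1.0
        assert S.simulate_profile(_HardModel(0), S.ProfileSpec(), spec, 50, rng) == 0.0

    def test_risk_unbiased_for_oracle(self, spec):
        # P(more)=0.7 independent of features: mean risk over replications 0.7
        model = _StochasticOracle(intercept=math.log(0.7 / 0.3))
        rng = np.random.default_rng(1)
        risks = [S.simulate_profile(model, S.ProfileSpec(), spec, 200, rng) for _ in range(500)]
        assert 0.68 <= np.mean(risks) <= 0.72


class TestComputeSor:
    def test_null_self_comparison(self, spec):
        model = _StochasticOracle(intercept=0.2, btcp=0.5)
        res = S.compute_sor(model, S.ProfileSpec(), S.ProfileSpec(), spec, S.SORConfig(seed=0))
        assert 0.8 <= res.mean <= 1.25
        lo, hi = res.ci
        assert lo <= 1.0 <= hi

    def test_known_effect_recovered(self, spec):
        model = _StochasticOracle(btcp=math.log(2))
        target = S.ProfileSpec(fixed={"btcp": 1})
        ref = S.ProfileSpec(fixed={"btcp": 0})
        res = S.compute_sor(model, target, ref, spec, S.SORConfig(seed=1))
        assert 1.7 <= res.mean <= 2.3

    def test_oracle_equivalence_large_sr(self, spec):
        beta = math.log(1.8)
        model = _StochasticOracle(neuropathic=beta)
        target = S.ProfileSpec(fixed={"neuropathic": 1})
        ref = S.ProfileSpec(fixed={"neuropathic": 0})
        res = S.compute_sor(model, target, ref, spec, S.SORConfig(S=1000, R=500, seed=2))
        assert res.mean == pytest.approx(math.exp(beta), rel=0.10)

    def test_symmetry(self, spec):
        model = _StochasticOracle(btcp=math.log(1.6))
        a = S.ProfileSpec(fixed={"btcp": 1})
        b = S.ProfileSpec(fixed={"btcp": 0})
        fwd = S.compute_sor(model, a, b, spec, S.SORConfig(seed=3))
        rev = S.compute_sor(model, b, a, spec, S.SORConfig(seed=3))
        assert fwd.mean == pytest.approx(1.0 / rev.mean, rel=0.10)

    def test_null_ci_coverage(self, spec):
        model = _StochasticOracle(intercept=0.1, btcp=0.4, age=-0.01)
        covered = 0
        for seed in range(100):
            res = S.compute_sor(
                model, S.ProfileSpec(), S.ProfileSpec(), spec,
                S.SORConfig(S=100, R=100, seed=seed),
            )
            lo, hi = res.ci
            covered += lo <= 1.0 <= hi
        assert covered >= 90

    def test_mismatched_free_sets_rejected(self, spec):
        model = _StochasticOracle()
        with pytest.raises(ValueError):
            S.compute_sor(
                model, S.ProfileSpec(fixed={"btcp": 1}), S.ProfileSpec(), spec
            )

    def test_replicate_frame_contract(self, spec):
        model = _StochasticOracle(btcp=0.3)
        cfg = S.SORConfig(S=50, R=40, seed=4)
        res = S.compute_sor(
            model, S.ProfileSpec(fixed={"btcp": 1}), S.ProfileSpec(fixed={"btcp": 0}), spec, cfg
        )
        frame = res.as_frame()
        assert len(frame) == 40
        lo, hi = res.ci
        assert lo <= res.median <= hi


class TestPresets:
    def test_four_presets(self):
        presets = S.condition_presets()
        assert len(presets) == 4
        names = [n for n, _, _ in presets]
        assert names == ["age", "btcp", "neuropathic", "btcp_neuro"]

    def test_age_preset_structure(self):
        _, target, ref = S.condition_presets()[0]
        assert target.age_gauss == (75, 5)
        assert ref.age_gauss == (45, 5)
        assert target.fixed == {}

    def test_btcp_preset_structure(self):
        _, target, ref = S.condition_presets()[1]
        assert target.fixed == {"btcp": 1}
        assert ref.fixed == {"btcp": 0}


class TestParameterRecovery:
    @pytest.mark.parametrize("omega", [1.5, 2.0])
    def test_rf_recovers_encoded_btcp_effect(self, omega):
        gen_spec = tp.default_spec(n=2000)
        gen_spec.outcome_model.btcp = math.log(omega)
        cohort = tp.sample_cohort(gen_spec, seed=30)
        X, y = B.features(cohort)
        rf = B.tune(B.default_specs()[1], X, y, k=2, repeats=1, seed=30)
        res = S.compute_sor(
            rf,
            S.ProfileSpec(fixed={"btcp": 1}),
            S.ProfileSpec(fixed={"btcp": 0}),
            gen_spec,
            S.SORConfig(S=200, R=150, seed=30),
        )
        assert 0.75 * omega <= res.mean <= 1.25 * omega


class TestRiskByAge:
    def test_constant_model_flat(self, spec):
        curve = S.risk_by_age(_HardModel(1), range(30, 90, 10), spec, S=50)
        assert (curve["risk"] == 1.0).all()

    def test_monotone_decreasing_oracle(self, spec):
        model = _StochasticOracle(intercept=2.0, age=-0.05)
        ages = np.linspace(20, 90, 20).astype(int)
        curve = S.risk_by_age(model, ages, spec, S=500, rng=np.random.default_rng(5))
        rho = st.spearmanr(curve["age"], curve["risk"]).statistic
        assert rho < -0.9
        assert curve["risk"].between(0, 1).all()
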
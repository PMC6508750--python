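import numpy as np
import pytest

from cyctx import (
    CellCycleRates,
    ModelParams,
    ParameterError,
    StageKinetics,
    constitutive_fold_change,
    fold_change,
    fold_change_shared,
    fold_change_thresholds,
    noise_measures,
    params_for_fold_change,
    slow_cycling_limits,
    stationary_means,
    stationary_second_moments,
    summarize,
)
from conftest import random_params


class TestStationaryMeans:
    def test_means_vanish_linearly_with_synthesis(self, baseline_params):
        """With no synthesis there is no mRNA: means scale linearly to 0 with nu."""
        m1_ref, m2_ref, m_ref = stationary_means(baseline_params)
        for eps in (1e-3, 1e-6, 1e-9):
            p = baseline_params.replace_rate("stage1.nu", 5.0 * eps)
            p = p.replace_rate("stage2.nu", 5.0 * eps)
            m1, m2, m = stationary_means(p)
            assert m1 == pytest.approx(eps * m1_ref, rel=1e-9)
            assert m2 == pytest.approx(eps * m2_ref, rel=1e-9)
            assert m == pytest.approx(eps * m_ref, rel=1e-9)

    def test_slow_cycling_mean_reduces_to_one_copy_telegraph(self, mesc_kinetics):
        """As kappa1 -> 0 the S1 mean approaches nu*lam/(delta*(lam+gamma))."""
        params = ModelParams.shared(mesc_kinetics, CellCycleRates(1e-9, 0.2727))
        m1, _, _ = stationary_means(params)
        limit, _ = slow_cycling_limits(mesc_kinetics)
        assert limit == pytest.approx(276.60, abs=0.01)
        assert m1 == pytest.approx(limit, rel=1e-6)

    def test_mixture_identities_exact(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = random_params(rng)
            m1, m2, m = stationary_means(p)
            mu1, mu2, mu, *_ = stationary_second_moments(p)
            w1, w2 = p.cycle.stage_weights
            assert m == pytest.approx(m1 * w1 + m2 * w2, rel=1e-14)
            assert mu == pytest.approx(mu1 * w1 + mu2 * w2, rel=1e-14)

    def test_second_moment_slow_cycling_limit(self, mesc_kinetics):
        """Printed kappa -> 0 limit of the S1 second moment."""
        lam, gam = mesc_kinetics.lam, mesc_kinetics.gamma
        nu, dl = mesc_kinetics.nu, mesc_kinetics.delta
        params = ModelParams.shared(mesc_kinetics, CellCycleRates(1e-9, 1e-9))
        mu1, *_ = stationary_second_moments(params)
        expected = (nu * lam / (dl * (lam + gam))) * (
            1.0 + nu * (dl + lam) / (dl * (dl + lam + gam))
        )
        assert mu1 == pytest.approx(expected, rel=1e-6)


class TestNoiseMeasures:
    def test_fano_identity_and_definitions(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = random_params(rng)
            m1, m2, m = stationary_means(p)
            mu1, mu2, mu, *_ = stationary_second_moments(p)
            e1, e2, e, f1, f2, f = noise_measures(p)
            assert f1 == pytest.approx(e1 * m1, rel=1e-10)
            assert f2 == pytest.approx(e2 * m2, rel=1e-10)
            assert f == pytest.approx((mu - m * m) / m, rel=1e-10)
            assert e == pytest.approx(f / m, rel=1e-10)

    def test_variances_non_negative_on_random_sweep(self):
        rng = np.random.default_rng(17)
        for _ in range(500):
            p = random_params(rng)
            m1, m2, m = stationary_means(p)
            mu1, mu2, mu, *_ = stationary_second_moments(p)
            assert mu1 >= m1 * m1 * (1 - 1e-12)
            assert mu2 >= m2 * m2 * (1 - 1e-12)
            assert mu >= m * m * (1 - 1e-12)

    def test_constitutive_poisson_limit(self):
        """Always-ON gene with slow cycling is Poissonian: Fano factor 1."""
        kin = StageKinetics(lam=5.0, gamma=1e-12, nu=10.0, delta=1.0)
        params = ModelParams.shared(kin, CellCycleRates(1e-9, 1e-9))
        *_, f1, f2, _ = noise_measures(params)
        assert f1 == pytest.approx(1.0, abs=1e-6)
        assert f2 == pytest.approx(1.0, abs=1e-6)

    def test_slow_cycling_fano_limit(self, mesc_kinetics):
        """Both stage Fano factors approach 1 + nu*gamma/((lam+gamma)(delta+lam+gamma))."""
        _, phi_lim = slow_cycling_limits(mesc_kinetics)
        assert phi_lim == pytest.approx(43.261, abs=1e-3)
        params = ModelParams.shared(mesc_kinetics, CellCycleRates(1e-9, 1e-9))
        *_, f1, f2, _ = noise_measures(params)
        assert f1 == pytest.approx(phi_lim, rel=1e-4)
        assert f2 == pytest.approx(phi_lim, rel=1e-4)


class TestFoldChange:
    def test_ratio_of_means_matches_direct_formula(self):
        rng = np.random.default_rng(23)
        for _ in range(1000):
            p = random_params(rng)
            m1, m2, _ = stationary_means(p)
            assert fold_change(p) == pytest.approx(m2 / m1, rel=1e-12)

    def test_scale_invariance_of_all_dimensionless_and_count_quantities(self):
        """Multiplying every rate by c leaves moments, noise and r* unchanged."""
        rng = np.random.default_rng(31)
        p = random_params(rng)
        for c in (0.25, 7.0):
            q = ModelParams(
                stage1=StageKinetics(*(c * np.array(
                    [p.stage1.lam, p.stage1.gamma, p.stage1.nu, p.stage1.delta]))),
                stage2=StageKinetics(*(c * np.array(
                    [p.stage2.lam, p.stage2.gamma, p.stage2.nu, p.stage2.delta]))),
                cycle=CellCycleRates(c * p.cycle.kappa1, c * p.cycle.kappa2),
            )
            a, b = summarize(p), summarize(q)
            for name, va in a.as_dict().items():
                assert getattr(b, name) == pytest.approx(va, rel=1e-9), name

    def test_shared_kinetics_equal_kappas_closed_form(self):
        """At kappa1 = kappa2 = k the shared formula collapses to (2d+3k)/(d+2k)."""
        kin = StageKinetics(lam=0.5556, gamma=1.0714, nu=113.4, delta=0.14)
        r = fold_change_shared(kin, CellCycleRates(0.0008, 0.0008))
        assert r == pytest.approx((2 * 0.14 + 3 * 0.0008) / (0.14 + 2 * 0.0008), rel=1e-12)
        assert r == pytest.approx(1.9944, abs=1e-4)

    def test_shared_formula_agrees_with_general_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            kin = StageKinetics(*np.exp(rng.uniform(np.log(0.05), np.log(20.0), 4)))
            cyc = CellCycleRates(*np.exp(rng.uniform(np.log(0.05), np.log(20.0), 2)))
            p = ModelParams.shared(kin, cyc)
            assert fold_change_shared(kin, cyc) == pytest.approx(fold_change(p), rel=1e-12)


class TestConstitutiveLimit:
    def test_budding_yeast_duplication_at_end_of_s_phase(self):
        """Duplication at 53 min of a 70-min cycle gives r* = 1.31."""
        _, _, r = constitutive_fold_change(2.52, 2.14, 1.18 / 60.0, 1 / 53, 1 / 17)
        assert round(r, 2) == 1.31

    def test_duplication_at_start_of_s_phase(self):
        _, _, r = constitutive_fold_change(2.52, 2.14, 1.18 / 60.0, 1 / 35, 1 / 35)
        assert r == pytest.approx(1.524, abs=1e-3)

    def test_doubling_limit_as_s2_lengthens(self):
        """Equal synthesis, kappa2 -> 0: the S2 mean doubles the S1 mean."""
        _, _, r = constitutive_fold_change(1.0, 1.0, 1.0, 0.5, 1e-10)
        assert r == pytest.approx(2.0, rel=1e-8)

    def test_consistency_with_large_activation_full_model(self):
        """The explicit limit matches the full model at lam -> large."""
        m1c, m2c, rc = constitutive_fold_change(5.0, 4.0, 1.0, 0.4, 0.7)
        big = 1e7
        p = ModelParams(
            stage1=StageKinetics(lam=big, gamma=1e-7, nu=5.0, delta=1.0),
            stage2=StageKinetics(lam=big, gamma=1e-7, nu=4.0, delta=1.0),
            cycle=CellCycleRates(0.4, 0.7),
        )
        m1, m2, _ = stationary_means(p)
        assert m1 == pytest.approx(m1c, rel=1e-5)
        assert m2 == pytest.approx(m2c, rel=1e-5)
        assert fold_change(p) == pytest.approx(rc, rel=1e-5)

    def test_rejects_non_positive_rates(self):
        with pytest.raises(ParameterError):
            constitutive_fold_change(0.0, 1.0, 1.0, 1.0, 1.0)


class TestPrescribedFoldChange:
    """Any positive fold change is attainable under shared kinetics."""

    @pytest.mark.parametrize("C", [0.25, 0.5, 1.0])
    def test_closed_form_witness_is_exact(self, C):
        p = params_for_fold_change(C, kappa1=1.0)
        assert p.stage1 == p.stage2
        assert fold_change(p) == pytest.approx(C, rel=1e-9)

    def test_closed_form_witness_structure(self):
        """C = 0.5 requires kappa2 = 8 kappa1 and delta = 78 kappa1."""
        p = params_for_fold_change(0.5, kappa1=1.0)
        assert p.cycle.kappa2 == pytest.approx(8.0)
        assert p.stage1.delta == pytest.approx(78.0)
        assert p.stage1.lam + p.stage1.gamma == pytest.approx(1.0)

    @pytest.mark.parametrize("C", [1.5, 3.0])
    def test_numeric_witness_above_one(self, C):
        p = params_for_fold_change(C, kappa1=2.0)
        assert p.stage1 == p.stage2
        assert fold_change(p) == pytest.approx(C, rel=1e-6)

    def test_non_positive_target_rejected(self):
        with pytest.raises(ParameterError):
            params_for_fold_change(0.0)


class TestFoldChangeThresholds:
    KIN = StageKinetics(lam=0.8, gamma=0.827, nu=1.0, delta=0.14)  # lam+gamma = 1.627

    def test_threshold_location_and_sign_change(self):
        flags = fold_change_thresholds(self.KIN, CellCycleRates(0.5, 0.1))
        assert flags.kappa1_threshold == pytest.approx(0.1 + 0.1 * 1.727 / 0.28, rel=1e-12)
        r_above = fold_change_shared(self.KIN, CellCycleRates(0.75, 0.1))
        r_below = fold_change_shared(self.KIN, CellCycleRates(0.70, 0.1))
        assert r_above > 2.0 > r_below

    def test_equal_kappas_never_exceed_two(self):
        for k in (0.01, 0.3, 2.0, 50.0):
            flags = fold_change_thresholds(self.KIN, CellCycleRates(k, k))
            assert not flags.gt2
            assert fold_change_shared(self.KIN, CellCycleRates(k, k)) < 2.0

    def test_fast_s2_transition_drops_below_one(self):
        cyc = CellCycleRates(0.5, 1e4)
        flags = fold_change_thresholds(self.KIN, cyc)
        assert flags.lt1
        assert fold_change_shared(self.KIN, cyc) < 1.0

    def test_flags_agree_with_direct_sign_on_grid(self):
        ks = np.geomspace(1e-3, 1e2, 50)
        for k1 in ks:
            for k2 in ks:
                cyc = CellCycleRates(k1, k2)
                r = fold_change_shared(self.KIN, cyc)
                flags = fold_change_thresholds(self.KIN, cyc)
                assert flags.gt2 == (r > 2.0)
                assert flags.lt1 == (r < 1.0)
                if k1 <= k2:
                    assert r < 2.0

    def test_unimodal_in_kappa1_and_u_shaped_in_kappa2(self):
        """r*(., k2) rises to a unique peak then falls toward 2; r*(k1, .)
        falls to a unique trough then rises toward 1."""
        ks = np.geomspace(1e-4, 1e6, 400)
        r_k1 = np.array([fold_change_shared(self.KIN, CellCycleRates(k, 0.1)) for k in ks])
        d = np.sign(np.diff(r_k1))
        assert (np.diff(d[d != 0]) != 0).sum() <= 1  # at most one direction change
        assert r_k1[-1] == pytest.approx(2.0, abs=1e-3)
        r_k2 = np.array([fold_change_shared(self.KIN, CellCycleRates(0.1, k)) for k in ks])
        d2 = np.sign(np.diff(r_k2))
        assert (np.diff(d2[d2 != 0]) != 0).sum() <= 1
        assert r_k2[-1] == pytest.approx(1.0, abs=1e-3)
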
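import numpy as np
import pytest
from dataclasses import replace

from rmdyn.stochastic import (
    Ensemble,
    StochasticConfig,
    calibrate_rates,
    deterministic_reference,
    equilibrium_check,
    simulate,
    summarize,
    summarize_all,
)


@pytest.fixture(scope="module")
def small_cfg():
    """Reduced ensemble / molecule counts for fast unit tests."""
    return calibrate_rates(
        c_target=200.0, r_target=400.0, m_target=100.0,
        n_cells=200, n_divisions=10, seed=1234,
    )


@pytest.fixture(scope="module")
def regulated_small(small_cfg):
    return simulate(small_cfg)


def _manual_ensemble(cfg, m, r):
    shape = (len(m), 1)
    return Ensemble(
        config=cfg,
        n=np.zeros(shape, dtype=np.int64),
        c=np.zeros(shape, dtype=np.int64),
        r_mol=np.asarray(r, dtype=np.int64).reshape(shape),
        m_mol=np.asarray(m, dtype=np.int64).reshape(shape),
    )


class TestConfig:
    def test_mode_and_seed_validated(self):
        with pytest.raises(ValueError, match="mode"):
            StochasticConfig(
                mode="bursty", seed=1, phi_l_abs=1, phi_m_abs=1, phi_M_abs=1,
                k_rc=1, kd1_n=1, kd2_n=1, kd_m_n=1, p=25, omega=130,
            )
        with pytest.raises(ValueError, match="seed"):
            StochasticConfig(
                mode="regulated", seed=None, phi_l_abs=1, phi_m_abs=1, phi_M_abs=1,
                k_rc=1, kd1_n=1, kd2_n=1, kd_m_n=1, p=25, omega=130,
            )

    def test_calibration_hits_deterministic_targets(self, small_cfg):
        ref = deterministic_reference(small_cfg)
        last = ref.iloc[-1]
        assert last.c == pytest.approx(200.0, rel=1e-6)
        assert last.r == pytest.approx(400.0, rel=1e-6)
        assert last.m == pytest.approx(100.0, rel=1e-6)


class TestSimulate:
    def test_reproducible_for_same_seed(self, small_cfg):
        a = simulate(replace(small_cfg, n_cells=20))
        b = simulate(replace(small_cfg, n_cells=20))
        for field in ("n", "c", "r_mol", "m_mol"):
            np.testing.assert_array_equal(getattr(a, field), getattr(b, field))

    def test_zero_rates_stay_zero(self):
        cfg = StochasticConfig(
            mode="regulated", seed=5, phi_l_abs=0.0, phi_m_abs=0.0, phi_M_abs=0.0,
            k_rc=1.0, kd1_n=10.0, kd2_n=1.0, kd_m_n=1.0, p=25, omega=130,
            n_cells=10, n_divisions=3,
        )
        zero = Ensemble(
            config=cfg,
            n=np.zeros((10, 1), dtype=np.int64),
            c=np.zeros((10, 1), dtype=np.int64),
            r_mol=np.zeros((10, 1), dtype=np.int64),
            m_mol=np.zeros((10, 1), dtype=np.int64),
        )
        ens = simulate(cfg, initial=zero)
        assert not ens.c.any() and not ens.r_mol.any() and not ens.m_mol.any()

    def test_constitutive_mean_matches_birth_halving_fixed_point(self, small_cfg):
        """Production P per cycle gives stationary mean 2P before division."""
        cfg = replace(small_cfg, mode="constitutive", n_cells=600)
        ens = simulate(cfg)
        for arr, per_plasmid in (
            (ens.c, cfg.const_c), (ens.r_mol, cfg.const_r), (ens.m_mol, cfg.const_m)
        ):
            x = arr[:, -1].astype(float)
            expected = 2.0 * cfg.n_target * per_plasmid
            se = np.std(x, ddof=1) / np.sqrt(len(x))
            assert abs(np.mean(x) - expected) < 3 * se + 1.0

    def test_regulated_median_matches_deterministic(self, small_cfg, regulated_small):
        ok, report = equilibrium_check(
            regulated_small, deterministic_reference(small_cfg), rtol=0.1
        )
        assert ok, report

    def test_transient_run_detected_as_nonequilibrium(self, small_cfg):
        cfg = replace(small_cfg, n_cells=100, n_divisions=2)
        zero = Ensemble(
            config=cfg,
            n=np.full((100, 1), cfg.n_target, dtype=np.int64),
            c=np.zeros((100, 1), dtype=np.int64),
            r_mol=np.zeros((100, 1), dtype=np.int64),
            m_mol=np.zeros((100, 1), dtype=np.int64),
        )
        ens = simulate(cfg, initial=zero)
        ok, _ = equilibrium_check(
            ens, deterministic_reference(small_cfg, n_divisions=2), rtol=0.1, n_last=2
        )
        assert not ok

    def test_post_segregational_requires_initial(self, small_cfg):
        with pytest.raises(ValueError, match="initial ensemble"):
            simulate(replace(small_cfg, mode="post_segregational"))

    def test_post_segregational_decay(self, small_cfg, regulated_small):
        cfg = replace(small_cfg, mode="post_segregational", n_divisions=7)
        ens = simulate(cfg, initial=regulated_small)
        assert not ens.n.any()  # plasmids removed
        # molecule counts can only fall at divisions
        assert np.all(np.diff(ens.r_mol, axis=1) <= 0)
        med = np.median(ens.r_mol, axis=0)
        for d in range(4):  # halving while counts are large
            assert med[d + 1] / med[d] == pytest.approx(0.5, abs=0.1)


class TestSummaries:
    def test_constant_ensemble_has_zero_spread(self, small_cfg):
        ens = _manual_ensemble(small_cfg, m=[10] * 8, r=[40] * 8)
        s = summarize(ens, 0)
        assert s.cv_mr == 0.0 and s.iqr_mr == 0.0 and s.median_mr == 0.25

    def test_known_sample_order_statistics(self, small_cfg):
        # M/R values 1..5: median 3; quartiles 2 and 4 by linear interpolation
        ens = _manual_ensemble(small_cfg, m=[1, 2, 3, 4, 5], r=[1] * 5)
        s = summarize(ens, 0)
        assert s.median_mr == 3.0
        assert s.iqr_mr == 2.0
        assert s.robust_cv_mr == pytest.approx(2.0 / 3.0)

    def test_zero_r_trajectories_excluded(self, small_cfg):
        ens = _manual_ensemble(small_cfg, m=[1, 2, 3, 9], r=[1, 1, 1, 0])
        s = summarize(ens, 0)
        assert s.n_excluded == 1 and s.n_retained == 3
        assert s.median_mr == 2.0

    def test_all_excluded_flagged_not_raised(self, small_cfg):
        ens = _manual_ensemble(small_cfg, m=[1, 2], r=[0, 0])
        s = summarize(ens, 0)
        assert not s.defined and np.isnan(s.median_mr)

    def test_regulation_increases_mr_noise(self, small_cfg, regulated_small):
        """Matched equilibrium medians, much broader regulated M/R spread."""
        con = simulate(replace(small_cfg, mode="constitutive"))
        s_reg = summarize(regulated_small, 10)
        s_con = summarize(con, 10)
        assert s_reg.median_mr == pytest.approx(s_con.median_mr, rel=0.1)
        assert s_reg.cv_mr > s_con.cv_mr
        assert s_reg.iqr_mr > s_con.iqr_mr

    def test_summary_table_shape(self, regulated_small):
        df = summarize_all(regulated_small)
        assert list(df.division) == list(range(11))
        assert {"median_mr", "iqr_mr", "cv_mr", "robust_cv_mr", "median_r"} <= set(df.columns)
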
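import numpy as np
import pytest

from fireardl import (
    DgpSpec,
    EcmSpec,
    build_ecm_design,
    fit_ecm,
    generate_ecm_system,
    long_run_coefficients,
    rotate_models,
    short_run_coefficients,
)


class TestDesign:
    def test_row_count_with_single_lags(self, full_system):
        ds, truth = full_system
        spec = EcmSpec("area_burned", tuple(truth.long_run_elasticities))
        design = build_ecm_design(ds, spec)
        assert design.y.shape[0] == 216 - 2  # one row to the difference, one to its lag
        assert design.names[0] == "const"
        assert design.names[1] == "L.area_burned"

    def test_q_zero_enters_contemporaneously_only(self, full_system):
        ds, truth = full_system
        spec = EcmSpec(
            "area_burned", tuple(truth.long_run_elasticities), q={"sunlight": 0}
        )
        design = build_ecm_design(ds, spec)
        assert "D.sunlight" in design.names
        assert "L1D.sunlight" not in design.names

    def test_level_columns_enumerated_for_bounds_test(self, full_system):
        ds, truth = full_system
        spec = EcmSpec("area_burned", tuple(truth.long_run_elasticities))
        design = build_ecm_design(ds, spec)
        assert len(design.level_columns) == 8
        assert all(c.startswith("L.") for c in design.level_columns)

    def test_role_swap_symmetry_with_first_regressor(self, full_system):
        ds, truth = full_system
        regs = tuple(truth.long_run_elasticities)
        spec1 = EcmSpec("area_burned", regs)
        swapped = EcmSpec(regs[0], ("area_burned",) + regs[1:])
        d1, d2 = build_ecm_design(ds, spec1), build_ecm_design(ds, swapped)
        assert sorted(n.split(".")[-1] for n in d1.names if n.startswith("L.")) == sorted(
            n.split(".")[-1] for n in d2.names if n.startswith("L.")
        )

    def test_unknown_variable_rejected(self, full_system):
        ds, _ = full_system
        with pytest.raises(KeyError):
            build_ecm_design(ds, EcmSpec("area_burned", ("nonesuch",)))

    def test_duplicate_regressors_rejected(self):
        with pytest.raises(ValueError):
            EcmSpec("y", ("wind", "wind"))


class TestFit:
    def test_noiseless_system_fits_exactly(self):
        spec = DgpSpec(
            n_obs=120,
            long_run_elasticities={"wind": 2.0, "t_max": 1.5},
            adjustment_speed=-0.6,
            innovation_sd=0.0,
            seed=3,
        )
        ds, truth = generate_ecm_system(spec)
        fit = fit_ecm(ds, EcmSpec("area_burned", ("wind", "t_max")))
        assert fit.ssr < 1e-12
        assert fit.r2 > 1 - 1e-12

    def test_coefficients_match_normal_equations_oracle(self, full_fit):
        X, y = full_fit.ols.X, full_fit.ols.y
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(full_fit.ols.params, oracle, atol=1e-8)

    def test_residuals_orthogonal_to_design(self, full_fit):
        X, e = full_fit.ols.X, full_fit.ols.resid
        scale = np.abs(X).max() * np.abs(e).max() * len(e)
        assert np.max(np.abs(X.T @ e)) < 1e-6 * max(scale, 1.0)

    def test_fit_statistics_in_range(self, full_fit):
        assert 0.0 <= full_fit.r2 <= 1.0
        assert 0.0 <= full_fit.durbin_watson <= 4.0
        w = np.linalg.eigvalsh(full_fit.ols.cov)
        assert w.min() > -1e-12

    def test_rank_deficient_design_names_columns(self, full_system):
        ds, truth = full_system
        f = ds.frame.copy()
        f["wind2"] = f["wind"]
        ds2 = ds.with_frame(f, {**ds.transforms, "wind2": ds.transforms["wind"]})
        spec = EcmSpec("area_burned", tuple(truth.long_run_elasticities) + ("wind2",))
        with pytest.raises(ValueError, match="rank deficient"):
            fit_ecm(ds2, spec)


class TestLongRun:
    def test_elasticity_arithmetic(self):
        assert -4.325 / -0.5 == pytest.approx(8.65)  # -th_k/th0 with th0=-0.5, th_k=4.325

    def test_zero_level_coefficient_gives_zero_elasticity(self):
        # construct a system where t_max has no long-run role
        spec = DgpSpec(
            n_obs=150,
            long_run_elasticities={"wind": 2.0, "t_max": 0.0},
            adjustment_speed=-0.5,
            innovation_sd=0.0,
            short_run={},
            seed=5,
        )
        ds, _ = generate_ecm_system(spec)
        lr = long_run_coefficients(fit_ecm(ds, EcmSpec("area_burned", ("wind", "t_max"))))
        assert abs(lr["t_max"].elasticity) < 1e-6

    def test_noiseless_recovery_of_truth(self):
        spec = DgpSpec(
            n_obs=150,
            long_run_elasticities={"wind": 20.81, "t_max": 8.651},
            adjustment_speed=-0.611,
            innovation_sd=0.0,
            seed=6,
        )
        ds, truth = generate_ecm_system(spec)
        fit = fit_ecm(ds, EcmSpec("area_burned", ("wind", "t_max")))
        lr = long_run_coefficients(fit)
        assert lr["wind"].elasticity == pytest.approx(20.81, abs=1e-7)
        sr = short_run_coefficients(fit)
        assert sr.ect == pytest.approx(-0.611, abs=1e-8)

    def test_location_invariance_of_elasticities(self, full_system):
        ds, truth = full_system
        spec = EcmSpec("area_burned", tuple(truth.long_run_elasticities))
        base = long_run_coefficients(fit_ecm(ds, spec))
        f = ds.frame.copy()
        f["wind"] = f["wind"] + 5.0  # constant shift of a log regressor
        shifted = long_run_coefficients(fit_ecm(ds.with_frame(f), spec))
        for r in truth.long_run_elasticities:
            assert shifted[r].elasticity == pytest.approx(base[r].elasticity, abs=1e-8)

    def test_positive_ect_flagged(self, full_system):
        ds, truth = full_system
        # regress a pure random walk on the system: no error correction
        rng = np.random.default_rng(0)
        f = ds.frame.copy()
        f["area_burned"] = np.cumsum(rng.standard_normal(len(f)))
        lr = long_run_coefficients(
            fit_ecm(ds.with_frame(f), EcmSpec("area_burned", tuple(truth.long_run_elasticities)))
        )
        # flag matches the sign of the estimated adjustment coefficient
        assert lr.no_error_correction == (lr.ect >= 0)


class TestShortRun:
    def test_ect_within_stable_interval(self, full_fit):
        sr = short_run_coefficients(full_fit)
        assert -1.0 < sr.ect < 0.0
        assert sr.stable

    def test_rows_cover_all_regressors(self, full_fit):
        sr = short_run_coefficients(full_fit)
        assert {r.regressor for r in sr.rows} == set(full_fit.spec.regressors)


class TestRotation:
    def test_eight_models_with_distinct_dependents(self, full_system):
        ds, truth = full_system
        spec = EcmSpec("area_burned", tuple(truth.long_run_elasticities))
        fits = rotate_models(ds, spec)
        assert len(fits) == 8
        assert set(fits) == set(ds.variables)
        for dep, f in fits.items():
            assert f.spec.dependent == dep

    def test_rotation_matches_direct_fit(self, full_system):
        ds, truth = full_system
        spec = EcmSpec("area_burned", tuple(truth.long_run_elasticities))
        fits = rotate_models(ds, spec)
        direct = fit_ecm(ds, spec)
        np.testing.assert_array_equal(fits["area_burned"].ols.params, direct.ols.params)
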
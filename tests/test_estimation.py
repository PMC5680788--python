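"""The four saturation-estimation strategies."""

import itertools

import numpy as np
import pandas as pd
import pytest

import t2oximetry as t2
from t2oximetry.estimation import _residuals, _pack_bounds


class TestPrecalibrated:
    def test_worked_example_via_arterial_calibration(self):
        """Arterial T2 at 100% saturation fixes T2O; venous T2 of 150 ms then gives ~63.5%."""
        sample = t2.OximetrySample((12.0,), (150.0,), (300.0,), 0.45, 100.0)
        res = t2.estimate_precalibrated(sample, t2.FitSpec.precalibrated())
        assert res.converged
        assert res.svo2_percent == pytest.approx(63.485, abs=1e-3)

    def test_equal_venous_and_arterial_t2_gives_arterial_saturation(self):
        sample = t2.OximetrySample((12.0,), (280.0,), (280.0,), 0.3, 100.0)
        res = t2.estimate_precalibrated(sample)
        assert res.svo2_percent == pytest.approx(100.0, abs=1e-9)

    def test_exact_inversion_of_simplified_model_data(self):
        k, t2o, sa, sv = 25.0, 300.0, 98.0, 70.0
        t2a = 1000.0 / t2.r2_simplified(sa, t2o, k)
        t2v = 1000.0 / t2.r2_simplified(sv, t2o, k)
        sample = t2.OximetrySample((12.0,), (t2v,), (t2a,), 0.25, sa)
        res = t2.estimate_precalibrated(sample)
        assert res.svo2_percent == pytest.approx(sv, abs=1e-6)

    def test_venous_t2_above_arterial_yields_no_solution(self):
        """Noise can push venous T2 above arterial; that dataset must be flagged, not crash."""
        sample = t2.OximetrySample((12.0,), (283.9,), (274.1,), 0.25, 100.0)
        res = t2.estimate_precalibrated(sample)
        assert not res.converged
        assert np.isnan(res.svo2_percent)

    def test_missing_tau180_rejected(self):
        sample = t2.OximetrySample((15.0,), (150.0,), (300.0,), 0.45, 100.0)
        with pytest.raises(ValueError):
            t2.estimate_precalibrated(sample, t2.FitSpec.precalibrated(tau180_ms=12.0))


class TestJointFit:
    def test_constrained_recovers_noiseless_truth(self, make_sample):
        res = t2.estimate_joint(make_sample(svo2=65.0), t2.FitSpec.constrained())
        assert res.converged
        assert res.svo2_percent == pytest.approx(65.0, abs=0.5)
        assert res.nuisance.t2o_ms == pytest.approx(300.0, rel=0.05)

    def test_noiseless_identifiability_grid(self, make_sample):
        """All four unknowns recovered for truths strictly inside the default bounds."""
        grid = itertools.product(
            [45.0, 55.0, 65.0, 75.0, 85.0],
            [(250.0, 2.0, 0.53), (300.0, 3.0, 0.545), (350.0, 4.0, 0.56), (275.0, 5.0, 0.555)],
        )
        for sv, (t2o, tau_ex, alpha) in grid:
            nuis = t2.NuisanceParams(t2o, tau_ex, alpha)
            sample = make_sample(svo2=sv, nuisance=nuis)
            res = t2.estimate_joint(sample, t2.FitSpec.constrained())
            assert res.converged
            assert res.svo2_percent == pytest.approx(sv, abs=0.5)
            assert res.nuisance.t2o_ms == pytest.approx(t2o, rel=0.05)
            assert res.nuisance.tau_ex_ms == pytest.approx(tau_ex, rel=0.05)
            assert res.nuisance.alpha_ppm == pytest.approx(alpha, rel=0.05)

    def test_fixed_mode_with_mismatched_values_is_biased(self, make_sample):
        """Wrong pinned nuisance values shift the saturation estimate.

        Oracle: brute-force 1-D scan over the saturation with the same pinned values.
        """
        sample = make_sample(svo2=65.0)
        spec = t2.FitSpec.fixed_values()  # 350 / 1.5 / 0.92 vs generating 300 / 3 / 0.545
        res = t2.estimate_joint(sample, spec)
        grid = np.linspace(0.0, 1.0, 20001)
        costs = [np.sum(_residuals(np.array([s]), sample, spec) ** 2) for s in grid]
        brute = 100.0 * grid[int(np.argmin(costs))]
        assert res.svo2_percent == pytest.approx(brute, abs=0.05)
        assert abs(res.svo2_percent - 65.0) > 1.0  # model mismatch leaves a real bias

    def test_residual_not_worse_than_initial_point(self, make_sample):
        sample = make_sample(svo2=55.0)
        spec = t2.FitSpec.constrained()
        res = t2.estimate_joint(sample, spec)
        x0 = np.array([spec.sv_init_frac, spec.init.t2o_ms, spec.init.tau_ex_ms, spec.init.alpha_ppm])
        assert res.residual_norm <= np.linalg.norm(_residuals(x0, sample, spec)) + 1e-9

    def test_multi_start_agreement_on_noiseless_data(self, make_sample):
        from dataclasses import replace

        sample = make_sample(svo2=72.0)
        base = t2.FitSpec.constrained()
        estimates = []
        for seed in range(5):
            jit = 1.0 + 0.05 * np.random.default_rng(seed).standard_normal(3)
            spec = replace(
                base,
                sv_init_frac=float(np.clip(0.8 * jit[0], 0.0, 1.0)),
                init=t2.NuisanceParams(
                    float(np.clip(300.0 * jit[1], 200.0, 400.0)),
                    3.0,
                    float(np.clip(0.545 * jit[2], 0.52, 0.57)),
                ),
            )
            estimates.append(t2.estimate_joint(sample, spec).svo2_percent)
        assert max(estimates) - min(estimates) < 0.1

    def test_degenerate_identical_t2_flagged(self):
        sample = t2.OximetrySample((12.0, 15.0, 20.0, 25.0), (200.0,) * 4, (200.0,) * 4, 0.25, 98.0)
        res = t2.estimate_joint(sample, t2.FitSpec.constrained())
        assert not res.converged

    def test_r2_residual_space_also_recovers_truth(self, make_sample):
        from dataclasses import replace

        spec = replace(t2.FitSpec.constrained(), residual_space="r2")
        res = t2.estimate_joint(make_sample(svo2=60.0), spec)
        assert res.svo2_percent == pytest.approx(60.0, abs=0.5)

    def test_single_tau180_rejected_for_joint_fit(self):
        sample = t2.OximetrySample((12.0,), (150.0,), (250.0,), 0.25, 98.0)
        with pytest.raises(ValueError):
            t2.estimate_joint(sample, t2.FitSpec.constrained())


class TestActiveBounds:
    def test_interior_solution_has_no_active_bounds(self, make_sample):
        res = t2.estimate_joint(make_sample(svo2=65.0), t2.FitSpec.constrained())
        assert res.active_bounds == frozenset()

    def test_exact_bound_hits_are_reported(self):
        spec = t2.FitSpec.constrained()
        res = t2.EstimationResult(70.0, t2.NuisanceParams(300.0, 6.0, 0.545), 0.0, True)
        assert t2.classify_active_bounds(res, spec) == {"tau_ex"}
        res = t2.EstimationResult(70.0, t2.NuisanceParams(300.0, 3.0, 0.52 + 5e-7), 0.0, True)
        assert t2.classify_active_bounds(res, spec) == {"alpha"}

    def test_truth_outside_bounds_activates_them(self, make_sample):
        nuis = t2.NuisanceParams(300.0, 8.0, 0.545)  # tau_ex above the [0, 6] box
        res = t2.estimate_joint(make_sample(svo2=65.0, nuisance=nuis), t2.FitSpec.constrained())
        assert t2.classify_active_bounds(res, t2.FitSpec.constrained(), tol=1e-3)


class TestTabularInterface:
    def test_round_trip_table_to_samples(self, make_sample):
        s = make_sample(svo2=62.0)
        rows = [
            {
                "subject": "p1",
                "stage": 0,
                "tau180_ms": tau,
                "t2_venous_ms": tv,
                "t2_arterial_ms": ta,
                "hct": s.hct,
                "sao2_percent": s.sao2_percent,
            }
            for tau, tv, ta in zip(s.tau180_ms, s.t2_venous_ms, s.t2_arterial_ms)
        ]
        samples = t2.samples_from_table(pd.DataFrame(rows))
        assert len(samples) == 1
        assert samples[0].tau180_ms == s.tau180_ms
        results = t2.fit_samples(samples, t2.FitSpec.constrained())
        assert results.loc[0, "svo2_percent"] == pytest.approx(62.0, abs=0.5)

    def test_missing_columns_reported(self):
        with pytest.raises(ValueError, match="missing required columns"):
            t2.samples_from_table(pd.DataFrame({"subject": [1]}))
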
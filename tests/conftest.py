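import pytest

import t2oximetry as t2


@pytest.fixture
def default_nuisance() -> t2.NuisanceParams:
    """Literature-range nuisance parameters used throughout the tests."""
    return t2.NuisanceParams(t2o_ms=300.0, tau_ex_ms=3.0, alpha_ppm=0.545)


@pytest.fixture
def make_sample(default_nuisance):
    """Factory for noiseless eight-T2 samples forward-generated from the full model."""

    def _make(
        svo2=65.0,
        sao2=98.0,
        hct=0.25,
        nuisance=None,
        tau180=(12.0, 15.0, 20.0, 25.0),
        omega0=t2.OMEGA0_1P5T,
    ):
        nuisance = nuisance or default_nuisance
        t2v = [
            t2.t2_full(t2.BloodState(svo2, hct), nuisance, t2.AcquisitionContext(omega0, tau))
            for tau in tau180
        ]
        t2a = [
            t2.t2_full(t2.BloodState(sao2, hct), nuisance, t2.AcquisitionContext(omega0, tau))
            for tau in tau180
        ]
        return t2.OximetrySample(tau180, t2v, t2a, hct, sao2, omega0)

    return _make
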
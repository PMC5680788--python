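"""Luz-Meiboom (L-M) chemical-exchange model of blood transverse relaxation.

The apparent relaxation rate of whole blood measured with a CPMG refocusing
train (or a T2-preparation module) depends on its oxygen saturation because
deoxyhemoglobin is paramagnetic: water protons exchanging between
erythrocytes and plasma experience a saturation-dependent frequency offset
``alpha * omega0 * (1 - S/100)`` and the resulting exchange broadening is
partially refocused depending on the inter-echo spacing ``tau180``.  The
full model is

    R2b = 1/T2O + Hct (1-Hct) tau_ex [(1 - S/100) alpha omega0]^2
          * [1 - (2 tau_ex / tau180) tanh(tau180 / (2 tau_ex))]

with the exchange-site fraction taken equal to the hematocrit.  When the
acquisition parameters are held fixed the exchange prefactor collapses into
a single in-vitro calibration constant K, giving the simplified model

    R2b = 1/T2O + K (1 - S/100)^2

which is analytically invertible for S.

Unit conventions: interfaces use the field's customary units (ms, percent,
ppm, rad/s); all arithmetic is done in SI internally.  ``alpha`` is stored
in ppm and enters the frequency offset as ``alpha * 1e-6 * omega0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BloodState",
    "NuisanceParams",
    "AcquisitionContext",
    "CalibrationFactor",
    "NoPhysicalSolutionError",
    "exchange_attenuation",
    "r2_full",
    "t2_full",
    "r2_simplified",
    "solve_sbo2_simplified",
    "rescale_k_for_hct",
    "effective_k",
]

#: proton resonance frequency at 1.5 T, rad/s
OMEGA0_1P5T = 4.0e8


class NoPhysicalSolutionError(ValueError):
    """Measured blood T2 exceeds the fully-oxygenated T2.

    The simplified model then has no saturation in [0, 100] that explains
    the measurement (negative radicand); in practice this happens when a
    venous T2 measures slightly above the arterial T2 through noise.
    """


@dataclass(frozen=True)
class BloodState:
    """Oxygen saturation (percent) and hematocrit (volume fraction) of one pool."""

    sbo2_percent: float
    hct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.sbo2_percent <= 100.0:
            raise ValueError(f"sbo2_percent must be in [0, 100], got {self.sbo2_percent}")
        if not 0.0 <= self.hct <= 1.0:
            raise ValueError(f"hct must be in [0, 1], got {self.hct}")


@dataclass(frozen=True)
class NuisanceParams:
    """The three subject-specific biophysical parameters of the full model.

    Attributes
    ----------
    t2o_ms
        T2 of fully oxygenated blood, ms.
    tau_ex_ms
        Erythrocyte-plasma water proton exchange time, ms.
    alpha_ppm
        Susceptibility/red-cell-geometry coupling parameter, ppm.
    """

    t2o_ms: float
    tau_ex_ms: float
    alpha_ppm: float

    def __post_init__(self) -> None:
        if self.t2o_ms <= 0:
            raise ValueError(f"t2o_ms must be > 0, got {self.t2o_ms}")
        if self.tau_ex_ms < 0:
            raise ValueError(f"tau_ex_ms must be >= 0, got {self.tau_ex_ms}")
        if self.alpha_ppm < 0:
            raise ValueError(f"alpha_ppm must be >= 0, got {self.alpha_ppm}")


@dataclass(frozen=True)
class AcquisitionContext:
    """Scanner-controlled quantities: field strength (via omega0) and tau180."""

    omega0_rad_per_s: float = OMEGA0_1P5T
    tau180_ms: float = 12.0

    def __post_init__(self) -> None:
        if self.omega0_rad_per_s <= 0:
            raise ValueError("omega0_rad_per_s must be > 0")
        if self.tau180_ms <= 0:
            raise ValueError("tau180_ms must be > 0")


@dataclass(frozen=True)
class CalibrationFactor:
    """Global calibration constant K of the simplified model, s^-1."""

    k_per_s: float

    def __post_init__(self) -> None:
        if self.k_per_s <= 0:
            raise ValueError(f"k_per_s must be > 0, got {self.k_per_s}")


def exchange_attenuation(tau_ex_ms, tau180_ms):
    """Refocusing attenuation factor 1 - (2 tau_ex/tau180) tanh(tau180/(2 tau_ex)).

    The factor lies in (0, 1]: short inter-echo spacings refocus the exchange
    broadening (factor -> 0), long spacings leave it fully expressed
    (factor -> 1).  The tau_ex = 0 limit is exactly 1.

    Accepts scalars or arrays; broadcasts.
    """
    tau_ex = np.asarray(tau_ex_ms, dtype=float)
    tau180 = np.asarray(tau180_ms, dtype=float)
    if np.any(tau_ex < 0):
        raise ValueError("tau_ex_ms must be >= 0")
    if np.any(tau180 <= 0):
        raise ValueError("tau180_ms must be > 0")
    # analytic limit at tau_ex = 0; guard the division
    ratio = np.divide(tau_ex, tau180, out=np.zeros_like(tau_ex * tau180), where=tau_ex > 0)
    with np.errstate(divide="ignore", over="ignore"):
        inv = np.divide(tau180, 2.0 * tau_ex, out=np.full_like(ratio, np.inf), where=tau_ex > 0)
    out = 1.0 - 2.0 * ratio * np.tanh(inv)
    out = np.where(tau_ex == 0, 1.0, out)
    return out if out.ndim else float(out)


def r2_full(blood: BloodState, nuisance: NuisanceParams, ctx: AcquisitionContext):
    """Apparent relaxation rate of blood under the full exchange model, s^-1.

    Always >= 1/T2O; equals 1/T2O exactly when the blood is fully
    oxygenated or the hematocrit is 0 or 1 (no exchange partner).
    """
    t2o_s = nuisance.t2o_ms / 1000.0
    tau_ex_s = nuisance.tau_ex_ms / 1000.0
    deoxy = 1.0 - blood.sbo2_percent / 100.0
    dw = deoxy * nuisance.alpha_ppm * 1e-6 * ctx.omega0_rad_per_s  # rad/s
    atten = exchange_attenuation(nuisance.tau_ex_ms, ctx.tau180_ms)
    return 1.0 / t2o_s + blood.hct * (1.0 - blood.hct) * tau_ex_s * dw**2 * atten


def t2_full(blood: BloodState, nuisance: NuisanceParams, ctx: AcquisitionContext):
    """Apparent blood T2 in ms: the reciprocal of :func:`r2_full`."""
    return 1000.0 / r2_full(blood, nuisance, ctx)


def r2_simplified(sbo2_percent: float, t2o_ms: float, k: CalibrationFactor | float):
    """Relaxation rate under the globally-calibrated model, s^-1."""
    if not 0.0 <= sbo2_percent <= 100.0:
        raise ValueError("sbo2_percent must be in [0, 100]")
    if t2o_ms <= 0:
        raise ValueError("t2o_ms must be > 0")
    k_per_s = k.k_per_s if isinstance(k, CalibrationFactor) else float(k)
    return 1000.0 / t2o_ms + k_per_s * (1.0 - sbo2_percent / 100.0) ** 2


def solve_sbo2_simplified(t2b_ms: float, t2o_ms: float, k: CalibrationFactor | float) -> float:
    """Invert the simplified model for saturation, percent.

    Raises
    ------
    NoPhysicalSolutionError
        If the measured T2 exceeds T2O (negative radicand), so no
        saturation in [0, 100] reproduces the measurement.
    """
    if t2b_ms <= 0 or t2o_ms <= 0:
        raise ValueError("T2 values must be > 0")
    k_per_s = k.k_per_s if isinstance(k, CalibrationFactor) else float(k)
    if k_per_s <= 0:
        raise ValueError("k must be > 0")
    radicand = (1000.0 / t2b_ms - 1000.0 / t2o_ms) / k_per_s
    if radicand < 0:
        raise NoPhysicalSolutionError(
            f"measured T2 ({t2b_ms} ms) exceeds T2O ({t2o_ms} ms): no saturation in [0, 100]"
        )
    return 100.0 * (1.0 - np.sqrt(radicand))


def rescale_k_for_hct(k_ref: CalibrationFactor | float, hct_ref: float, hct_new: float) -> CalibrationFactor:
    """Adjust a calibration factor for a different hematocrit.

    K inherits the full model's Hct(1-Hct) dependence, so a factor
    calibrated at ``hct_ref`` transfers to ``hct_new`` by the ratio of those
    products — e.g. a normal-range calibration overestimates saturation in
    anemic blood unless rescaled.
    """
    if not 0.0 < hct_ref < 1.0 or not 0.0 < hct_new < 1.0:
        raise ValueError("hematocrits must lie strictly inside (0, 1)")
    k_per_s = k_ref.k_per_s if isinstance(k_ref, CalibrationFactor) else float(k_ref)
    scale = (hct_new * (1.0 - hct_new)) / (hct_ref * (1.0 - hct_ref))
    return CalibrationFactor(k_per_s * scale)


def effective_k(hct: float, nuisance: NuisanceParams, ctx: AcquisitionContext) -> CalibrationFactor:
    """Lumped K implied by the full model at a given acquisition, s^-1.

    K = Hct(1-Hct) tau_ex (alpha*1e-6*omega0)^2 * attenuation(tau_ex, tau180);
    as tau180 -> inf the attenuation tends to 1 and the full model converges
    to the simplified model with this K.
    """
    dw_unit = nuisance.alpha_ppm * 1e-6 * ctx.omega0_rad_per_s
    k = (
        hct
        * (1.0 - hct)
        * (nuisance.tau_ex_ms / 1000.0)
        * dw_unit**2
        * exchange_attenuation(nuisance.tau_ex_ms, ctx.tau180_ms)
    )
    return CalibrationFactor(k)
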
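"""Learning fixed nuisance values and bounds from a training subset.

With a handful of training stages whose venous saturation is known from
blood-gas analysis, exhaustive search over a small grid selects either a
single fixed value per nuisance parameter (for the fixed-value fit) or a
(lower, upper) interval per parameter (for the constrained fit), minimizing
the mean absolute venous-saturation error of the corresponding fit across
the training set.  The grid defaults span the literature ranges for whole
blood (T2O 154-372 ms, tau_ex 0.6-12 ms, alpha 0.1-1.4 ppm).

Ties are broken toward the least restrictive candidate: the widest bounds,
or the fixed value closest to the shipped defaults (300 ms / 3 ms /
0.545 ppm).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .estimation import FitSpec, OximetrySample, estimate_joint
from .model import NuisanceParams

__all__ = ["GridSpec", "learn_fixed_values", "learn_bounds"]

_DEFAULT_CENTER = {"t2o": 300.0, "tau_ex": 3.0, "alpha": 0.545}


@dataclass(frozen=True)
class GridSpec:
    """Candidate fixed values and candidate bound intervals per parameter."""

    t2o_values: tuple[float, ...] = (175.0, 250.0, 300.0, 350.0)
    tau_ex_values: tuple[float, ...] = (1.0, 3.0, 6.0, 9.0)
    alpha_values: tuple[float, ...] = (0.3, 0.545, 0.9, 1.2)
    t2o_bounds: tuple[tuple[float, float], ...] = ((154.0, 372.0), (200.0, 400.0), (250.0, 350.0))
    tau_ex_bounds: tuple[tuple[float, float], ...] = ((0.6, 12.0), (0.0, 6.0), (1.5, 4.5))
    alpha_bounds: tuple[tuple[float, float], ...] = ((0.1, 1.4), (0.4, 0.7), (0.52, 0.57))

    def __post_init__(self) -> None:
        for vals in (self.t2o_values, self.tau_ex_values, self.alpha_values):
            if not vals:
                raise ValueError("candidate value lists must be non-empty")
        for pairs in (self.t2o_bounds, self.tau_ex_bounds, self.alpha_bounds):
            if not pairs:
                raise ValueError("candidate bound lists must be non-empty")
            for lo, hi in pairs:
                if lo >= hi:
                    raise ValueError(f"candidate bound ({lo}, {hi}) must have lower < upper")


def _mean_abs_error(samples, references, spec: FitSpec) -> float:
    errs = []
    for sample, ref in zip(samples, references):
        res = estimate_joint(sample, spec)
        if not res.converged or not np.isfinite(res.svo2_percent):
            return float("inf")
        errs.append(abs(res.svo2_percent - ref))
    return float(np.mean(errs))


def _check_inputs(samples, references):
    samples = list(samples)
    references = [float(r) for r in references]
    if not samples or len(samples) != len(references):
        raise ValueError("need >= 1 training sample with one reference each")
    return samples, references


def learn_fixed_values(samples, references, grid: GridSpec | None = None) -> NuisanceParams:
    """Exhaustively select the fixed nuisance triple minimizing training error.

    Every combination of candidate values is evaluated with a fixed-mode
    joint fit on every training sample; the triple with the lowest mean
    |estimated - reference| venous saturation wins.  At equal error the
    triple closest (in normalized Euclidean distance) to the shipped
    default center is preferred — a deterministic tie-break.
    """
    grid = grid or GridSpec()
    samples, references = _check_inputs(samples, references)
    best = None
    for t2o, tau_ex, alpha in itertools.product(grid.t2o_values, grid.tau_ex_values, grid.alpha_values):
        fixed = NuisanceParams(t2o, tau_ex, alpha)
        err = _mean_abs_error(samples, references, FitSpec.fixed_values(fixed))
        dist = (
            ((t2o - _DEFAULT_CENTER["t2o"]) / _DEFAULT_CENTER["t2o"]) ** 2
            + ((tau_ex - _DEFAULT_CENTER["tau_ex"]) / _DEFAULT_CENTER["tau_ex"]) ** 2
            + ((alpha - _DEFAULT_CENTER["alpha"]) / _DEFAULT_CENTER["alpha"]) ** 2
        )
        key = (err, dist)
        if best is None or key < best[0]:
            best = (key, fixed)
    if not np.isfinite(best[0][0]):
        raise RuntimeError("no grid point produced converged fits on the training set")
    return best[1]


def _constrained_spec_for(bounds_triple) -> FitSpec:
    (t2o_b, tau_b, alpha_b) = bounds_triple
    init = NuisanceParams(
        float(np.clip(_DEFAULT_CENTER["t2o"], *t2o_b)),
        float(np.clip(_DEFAULT_CENTER["tau_ex"], *tau_b)),
        float(np.clip(_DEFAULT_CENTER["alpha"], *alpha_b)),
    )
    return FitSpec(
        mode="constrained",
        init=init,
        bounds={"svo2": (0.0, 1.0), "t2o": t2o_b, "tau_ex": tau_b, "alpha": alpha_b},
    )


def learn_bounds(samples, references, grid: GridSpec | None = None) -> dict:
    """Exhaustively select the bound triple minimizing training error.

    Each candidate (T2O, tau_ex, alpha) interval combination is evaluated
    with a constrained joint fit (initialized at the defaults clipped into
    the candidate box).  Ties break toward the widest bounds (largest total
    interval volume).  Returns a bounds dict usable directly in a
    :class:`~t2oximetry.estimation.FitSpec`.
    """
    grid = grid or GridSpec()
    samples, references = _check_inputs(samples, references)
    best = None
    for triple in itertools.product(grid.t2o_bounds, grid.tau_ex_bounds, grid.alpha_bounds):
        spec = _constrained_spec_for(triple)
        err = _mean_abs_error(samples, references, spec)
        width = -float(np.prod([hi - lo for lo, hi in triple]))  # wider = smaller key
        key = (err, width)
        if best is None or key < best[0]:
            best = (key, spec.bounds)
    if not np.isfinite(best[0][0]):
        raise RuntimeError("no candidate bounds produced converged fits on the training set")
    return dict(best[1])
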
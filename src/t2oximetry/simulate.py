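"""Synthetic graded-hypoxemia experiments for end-to-end validation.

Emulates a controlled desaturation study: each subject is stepped through
hypoxemic stages with arterial saturation falling from ~100% toward 70%,
the venous pool trailing the arterial by an oxygen-extraction gap, subject
hematocrit drawn around 0.25 (the anesthetized-swine range), and
subject-level exchange-model parameters (T2O, tau_ex, alpha) drawn around
literature values.  Four blood T2 values per pool per stage are produced by
the full exchange model at tau180 = 12/15/20/25 ms with additive Gaussian
measurement noise, alongside duplicate blood-gas reference readings with a
configurable coefficient of variation.

Everything is deterministic given the seed.  Stages whose true venous
saturation falls below 40% are flagged ``excluded`` (severe hypoxemia
degrades image quality in practice and such stages are dropped from
analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mapping import DEFAULT_SCHEDULES, T2PrepSchedule, T2PrepStack
from .model import AcquisitionContext, BloodState, NuisanceParams, OMEGA0_1P5T, t2_full

__all__ = [
    "ExperimentConfig",
    "HypoxemiaDataset",
    "simulate_experiment",
    "simulate_bloodgas_replicates",
    "simulate_t2prep_stacks",
    "ImageConfig",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Study-design parameters for one synthetic hypoxemia experiment.

    Defaults reproduce the validation study's conditions: 7 subjects x 5
    stages, arterial saturation stepped 100 -> 70%, an extraction gap of
    15-35 percentage points with the venous pool floored at 40%, hematocrit
    ~ N(0.25, 0.03) truncated to [0.15, 0.45], nuisance parameters centred
    on T2O = 300 ms, tau_ex = 3 ms, alpha = 0.545 ppm, and 3 ms Gaussian
    noise on each T2 measurement.
    """

    n_subjects: int = 7
    n_stages: int = 5
    sao2_schedule: tuple[float, ...] = (100.0, 92.5, 85.0, 77.5, 70.0)
    extraction_gap_pp: tuple[float, float] = (15.0, 35.0)
    svo2_floor: float = 40.0
    hct_mean: float = 0.25
    hct_sd: float = 0.03
    hct_range: tuple[float, float] = (0.15, 0.45)
    t2o_mean_ms: float = 300.0
    t2o_sd_ms: float = 25.0
    tau_ex_mean_ms: float = 3.0
    tau_ex_sd_ms: float = 0.5
    alpha_mean_ppm: float = 0.545
    alpha_sd_ppm: float = 0.01
    t2_noise_sd_ms: float = 3.0
    # noise grows linearly with tau180 when heteroscedastic (flow dephasing)
    heteroscedastic: bool = False
    bloodgas_cv: float = 0.026
    omega0_rad_per_s: float = OMEGA0_1P5T
    tau180_ms: tuple[float, ...] = (12.0, 15.0, 20.0, 25.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_stages < 1:
            raise ValueError("need >= 1 subject and stage")
        if len(self.sao2_schedule) != self.n_stages:
            raise ValueError("sao2_schedule length must equal n_stages")
        if self.t2_noise_sd_ms < 0 or self.bloodgas_cv < 0:
            raise ValueError("noise parameters must be >= 0")
        lo, hi = self.extraction_gap_pp
        if not 0 <= lo <= hi:
            raise ValueError("extraction gap bounds must satisfy 0 <= lo <= hi")


@dataclass
class HypoxemiaDataset:
    """Samples table (the estimation input) plus the generating truth table.

    ``samples`` is long format, one row per (subject, stage, tau180);
    ``truth`` has one row per (subject, stage) with the true saturations,
    hematocrit, nuisance parameters, blood-gas reference readings and the
    ``excluded`` flag.
    """

    samples: pd.DataFrame
    truth: pd.DataFrame
    config: ExperimentConfig


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Draw by rejection; exact truncation, deterministic given rng state."""
    out = rng.normal(mean, sd, size=size)
    while True:
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))


def simulate_bloodgas_replicates(truth_percent, cv: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate blood-gas readings (pre- and post-imaging) around a truth.

    Each replicate is truth * (1 + cv * z) with independent standard-normal
    z, so the population within-pair coefficient of variation equals ``cv``
    in expectation.  The analysis reference is the mean of the pair.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    truth = np.asarray(truth_percent, dtype=float)
    pre = truth * (1.0 + cv * rng.standard_normal(truth.shape))
    post = truth * (1.0 + cv * rng.standard_normal(truth.shape))
    return pre, post


def simulate_experiment(config: ExperimentConfig | None = None) -> HypoxemiaDataset:
    """Generate one full multi-subject hypoxemia experiment.

    With zero noise every T2 in the samples table equals the full-model
    forward value for the stored truths exactly.
    """
    config = config or ExperimentConfig()
    rng = np.random.default_rng(config.seed)

    hct = _truncated_normal(
        rng, config.hct_mean, config.hct_sd, *config.hct_range, size=config.n_subjects
    )
    t2o = _truncated_normal(rng, config.t2o_mean_ms, config.t2o_sd_ms, 150.0, 450.0, config.n_subjects)
    tau_ex = _truncated_normal(rng, config.tau_ex_mean_ms, config.tau_ex_sd_ms, 0.5, 8.0, config.n_subjects)
    alpha = _truncated_normal(rng, config.alpha_mean_ppm, config.alpha_sd_ppm, 0.3, 0.8, config.n_subjects)

    sample_rows, truth_rows = [], []
    for s in range(config.n_subjects):
        nuis = NuisanceParams(t2o[s], tau_ex[s], alpha[s])
        for g, sao2 in enumerate(config.sao2_schedule):
            gap = rng.uniform(*config.extraction_gap_pp)
            svo2 = max(sao2 - gap, 0.0)
            sa_pre, sa_post = simulate_bloodgas_replicates(sao2, config.bloodgas_cv, rng)
            sv_pre, sv_post = simulate_bloodgas_replicates(svo2, config.bloodgas_cv, rng)
            truth_rows.append(
                {
                    "subject": s,
                    "stage": g,
                    "sao2_true": sao2,
                    "svo2_true": svo2,
                    "hct": hct[s],
                    "t2o_ms": t2o[s],
                    "tau_ex_ms": tau_ex[s],
                    "alpha_ppm": alpha[s],
                    "sao2_pre": float(sa_pre),
                    "sao2_post": float(sa_post),
                    "svo2_pre": float(sv_pre),
                    "svo2_post": float(sv_post),
                    "sao2_ref": float((sa_pre + sa_post) / 2.0),
                    "svo2_ref": float((sv_pre + sv_post) / 2.0),
                    "excluded": bool(svo2 < config.svo2_floor),
                }
            )
            for tau in config.tau180_ms:
                ctx = AcquisitionContext(config.omega0_rad_per_s, tau)
                t2v = t2_full(BloodState(svo2, hct[s]), nuis, ctx)
                t2a = t2_full(BloodState(sao2, hct[s]), nuis, ctx)
                sd = config.t2_noise_sd_ms
                if config.heteroscedastic:
                    sd = sd * tau / min(config.tau180_ms)
                noise = rng.normal(0.0, sd, size=2) if sd > 0 else np.zeros(2)
                sample_rows.append(
                    {
                        "subject": s,
                        "stage": g,
                        "tau180_ms": tau,
                        "t2_venous_ms": max(t2v + noise[0], 1.0),
                        "t2_arterial_ms": max(t2a + noise[1], 1.0),
                        "hct": hct[s],
                        "sao2_percent": sao2,
                    }
                )
    return HypoxemiaDataset(pd.DataFrame(sample_rows), pd.DataFrame(truth_rows), config)


@dataclass(frozen=True)
class ImageConfig:
    """Geometry and noise of synthetic two-pool T2-prepared image stacks."""

    shape: tuple[int, int] = (16, 16)
    s0: float = 1000.0
    noise_sd: float = 0.0
    seed: int = 0

    def venous_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[2:-2, 2 : self.shape[1] // 2 - 1] = True
        return m

    def arterial_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[2:-2, self.shape[1] // 2 + 1 : -2] = True
        return m


def simulate_t2prep_stacks(
    t2_venous_ms: float,
    t2_arterial_ms: float,
    image_config: ImageConfig | None = None,
    schedules: dict[float, tuple[float, ...]] | None = None,
) -> dict[float, T2PrepStack]:
    """Two-pool synthetic image stacks, one per tau180 schedule.

    Each stack holds a rectangular venous region decaying with the venous
    T2 and an arterial region with the arterial T2 on a dark background;
    ROI-fit T2 converges to the nominal values as noise -> 0.  Set both
    pools to a common T2 (e.g. 233 or 184 ms) for a static-phantom layout.
    """
    cfg = image_config or ImageConfig()
    schedules = schedules or DEFAULT_SCHEDULES
    rng = np.random.default_rng(cfg.seed)
    vmask, amask = cfg.venous_mask(), cfg.arterial_mask()
    stacks = {}
    for tau, t2p in schedules.items():
        sched = T2PrepSchedule(tau, tuple(t2p))
        t = np.asarray(sched.t2p_ms)
        img = np.zeros(cfg.shape + (len(t),))
        img[vmask] = cfg.s0 * np.exp(-t / t2_venous_ms)
        img[amask] = cfg.s0 * np.exp(-t / t2_arterial_ms)
        if cfg.noise_sd > 0:
            img = np.clip(img + rng.normal(0.0, cfg.noise_sd, img.shape), 0.0, None)
        stacks[tau] = T2PrepStack(img, sched)
    return stacks
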
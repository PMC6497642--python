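"""Synthetic blood series and tumor geometries for closed-loop testing.

Defaults emulate the study conditions of the calibration data set: five 8 mg
intratumoral cisplatin injections (40 mg total) with venous samples drawn at
5, 15, 30, 60 and 120 min after the final injection, a ~40 mL tumor, and the
fitted kinetics ``k_i + k_f = 2.51e-4`` 1/s, ``V_f = 12.2`` L,
``k_r = 3.85e-4`` 1/s.  Measurement error is multiplicative lognormal with a
configurable coefficient of variation (mean-one, so averaging replicates
recovers the noiseless curve).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import BloodSeries
from .fields import InjectionPlan, blood_curve
from .geometry import TumorGeometry, synthetic_tumor
from .parameters import DEFAULT_RENAL_HALF_LIFE_S, renal_rate_from_half_life

__all__ = [
    "SyntheticBloodConfig",
    "default_five_site_plan",
    "generate_blood_series",
    "generate_default_patient_like_case",
]

DEFAULT_SAMPLE_TIMES_MIN = (5.0, 15.0, 30.0, 60.0, 120.0)


def default_five_site_plan(total_dose: float = 40.0) -> InjectionPlan:
    """Five equal injections spread ~1 cm apart through a tumor-sized region
    (site geometry is irrelevant to the lumped blood model, but the plan is
    reusable for field evaluation on the default geometry)."""
    sites = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.2, 0.0, 0.0],
            [-1.2, 0.0, 0.0],
            [0.0, 0.9, 0.0],
            [0.0, -0.9, 0.0],
        ]
    )
    return InjectionPlan.equal_split(sites, total_dose)


@dataclass(frozen=True)
class SyntheticBloodConfig:
    """Forward-model configuration for a synthetic blood series."""

    seed: int
    plan: InjectionPlan = field(default_factory=default_five_site_plan)
    sample_times_min: tuple = DEFAULT_SAMPLE_TIMES_MIN
    true_k_sum: float = 2.51e-4
    true_V_f: float = 12.2e3
    k_r: float = renal_rate_from_half_life(DEFAULT_RENAL_HALF_LIFE_S)
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        t = np.asarray(self.sample_times_min, dtype=float)
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be positive and increasing")


def generate_blood_series(config: SyntheticBloodConfig) -> BloodSeries:
    """Biexponential curve at the sample times, times lognormal noise.

    The lognormal is parameterised to unit mean: ``sigma^2 = ln(1 + cv^2)``,
    ``mu = -sigma^2 / 2``.  Deterministic given the seed.
    """
    times_s = 60.0 * np.asarray(config.sample_times_min, dtype=float)
    clean = blood_curve(
        times_s, config.plan.doses, config.true_k_sum, config.k_r, config.true_V_f
    )
    if config.noise_cv > 0:
        rng = np.random.default_rng(config.seed)
        sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
        noise = rng.lognormal(-0.5 * sigma**2, sigma, size=clean.shape)
        clean = clean * noise
    return BloodSeries(times_s, clean, config.plan)


def generate_default_patient_like_case(
    seed: int = 0, noise_cv: float = 0.0
) -> tuple[BloodSeries, TumorGeometry]:
    """Standard end-to-end fixture: noiseless-by-default blood series at the
    fitted parameters plus a 40 cm^3 ellipsoid mask (aspect 1.5:1:1,
    mimicking an elongated paratracheal mass) at 0.1 cm spacing."""
    series = generate_blood_series(
        SyntheticBloodConfig(seed=seed, noise_cv=noise_cv)
    )
    geom = synthetic_tumor("ellipsoid", volume=40.0, aspect=(1.5, 1.0, 1.0), spacing=0.1)
    return series, geom
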
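"""Longitudinal two-group CSA cohort simulator.

Generates long-format cord cross-sectional-area records with the generative
structure the downstream analyses assume: group-specific intercepts, linear
and quadratic time trends (atrophy and its deceleration), an age-by-time
interaction, subject-level random effects (intercept, slope, quadratic,
level), a scanner change partway through the study, and for each of two
measurement modalities an additive bias plus independent measurement noise.

The defaults are fixed to the study conditions this package models: 21
controls and 23 spinal-cord-injury patients followed at 0, 2, 6, 12 and 24
months over cervical levels C1-C3, patient atrophy of roughly -0.53
mm^2/month with deceleration, and a synthetic-modality bias of -0.31 mm^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CohortSpec", "simulate_cohort", "CSA_COLUMNS"]

CSA_COLUMNS = [
    "subject_id",
    "group",
    "age_years",
    "scanner_id",
    "time_months",
    "level",
    "modality",
    "csa_mm2",
]


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a longitudinal two-group CSA cohort."""

    n_controls: int = 21
    n_patients: int = 23
    timepoints: tuple[float, ...] = (0.0, 2.0, 6.0, 12.0, 24.0)
    levels: tuple[str, ...] = ("C1", "C2", "C3")
    level_offsets: tuple[float, ...] = (1.5, 0.5, -2.0)  # mm^2 about the intercept
    control_intercept: float = 66.08  # mm^2
    patient_intercept: float = 64.27  # mm^2
    control_rate: float = 0.063  # mm^2/month
    patient_rate: float = -0.527  # mm^2/month
    control_quad: float = -0.0017  # mm^2/month^2
    patient_quad: float = 0.0059  # mm^2/month^2
    age_time_coef: float = 0.0  # mm^2/month per centered year of age
    control_age_range: tuple[float, float] = (24.0, 44.0)  # ~33.7 +/- 10
    patient_age_range: tuple[float, float] = (28.0, 66.0)  # ~46.8 +/- 19
    sd_intercept: float = 7.0  # mm^2
    sd_slope: float = 0.10  # mm^2/month
    sd_quad: float = 0.0  # mm^2/month^2
    sd_level: float = 1.0  # mm^2
    residual_sd: float = 1.0  # mm^2, shared latent measurement occasion
    modality_bias: dict[str, float] = field(
        default_factory=lambda: {"reference": 0.0, "synthetic": -0.31}
    )
    modality_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"reference": 1.0, "synthetic": 1.0}
    )
    scanner_switch_month: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_intercept", "sd_slope", "sd_quad", "sd_level", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(s < 0 for s in self.modality_noise_sd.values()):
            raise ValueError("modality noise SDs must be >= 0")
        t = np.asarray(self.timepoints)
        if t.size < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if len(self.level_offsets) != len(self.levels):
            raise ValueError("level_offsets must match levels")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort realization; deterministic per ``(spec, spec.seed)``.

    Both modalities share the same latent CSA per (subject, time, level) —
    they are two measurements of the same anatomy — and differ only by their
    additive bias and independent measurement noise.  Non-positive generated
    CSA values are resampled (count logged).
    """
    rng = np.random.default_rng(spec.seed)
    mean_age = None  # centered within the whole cohort below

    subjects = []
    for grp, n, (alo, ahi) in (
        ("control", spec.n_controls, spec.control_age_range),
        ("patient", spec.n_patients, spec.patient_age_range),
    ):
        for i in range(n):
            subjects.append(
                {
                    "subject_id": f"{grp[:3]}{i:03d}",
                    "group": grp,
                    "age_years": rng.uniform(alo, ahi),
                    "b0": rng.normal(0.0, spec.sd_intercept),
                    "b1": rng.normal(0.0, spec.sd_slope),
                    "b2": rng.normal(0.0, spec.sd_quad),
                    "blev": rng.normal(0.0, spec.sd_level, len(spec.levels)),
                }
            )
    mean_age = float(np.mean([s["age_years"] for s in subjects]))

    rows = []
    n_resampled = 0
    for s in subjects:
        grp = s["group"]
        inter = spec.control_intercept if grp == "control" else spec.patient_intercept
        rate = spec.control_rate if grp == "control" else spec.patient_rate
        quad = spec.control_quad if grp == "control" else spec.patient_quad
        age_c = s["age_years"] - mean_age
        for t in spec.timepoints:
            scanner = "scannerA" if t < spec.scanner_switch_month else "scannerB"
            occasion_noise = rng.normal(0.0, spec.residual_sd, len(spec.levels))
            for j, (lev, lev_off) in enumerate(zip(spec.levels, spec.level_offsets)):
                latent = (
                    inter
                    + lev_off
                    + s["blev"][j]
                    + (rate + s["b1"] + spec.age_time_coef * age_c) * t
                    + (quad + s["b2"]) * t * t
                    + s["b0"]
                    + occasion_noise[j]
                )
                for mod, bias in spec.modality_bias.items():
                    sd = spec.modality_noise_sd.get(mod, 0.0)
                    val = latent + bias + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                    while val <= 0:
                        n_resampled += 1
                        val = latent + bias + rng.normal(0.0, sd if sd > 0 else 1.0)
                    rows.append(
                        {
                            "subject_id": s["subject_id"],
                            "group": grp,
                            "age_years": s["age_years"],
                            "scanner_id": scanner,
                            "time_months": t,
                            "level": lev,
                            "modality": mod,
                            "csa_mm2": val,
                        }
                    )
    if n_resampled:
        logger.info("resampled %d non-positive CSA draws", n_resampled)
    return pd.DataFrame(rows, columns=CSA_COLUMNS)
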
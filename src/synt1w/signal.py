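"""Closed-form MPRAGE signal synthesis from quantitative PD/R1/R2* maps.

The MPRAGE (magnetization-prepared rapid gradient-echo) steady-state signal
at the central echo of a linearly ordered readout train is

    S = PD * sin(alpha) * exp(-TE * R2star) * Q

where ``Q`` is the longitudinal-magnetization factor at the centre of the
readout, obtained as the fixed point of one preparation cycle: perfect
inversion, free relaxation for ``TI - tau/2``, a spoiled excitation train of
``n`` pulses spaced ``ES`` (total duration ``tau = n * ES``) during which the
magnetization relaxes with the apparent time constant ``T1*`` toward the
driven equilibrium ``R1 * T1*``, and a final free-relaxation delay ``TD``.

All times are stored in **seconds** and relaxation rates in **s^-1**; use
:meth:`SequenceParams.from_ms` to enter the millisecond values customary on
the scanner console.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SequenceParams",
    "TimingDerivation",
    "TissueVoxel",
    "SignalComponents",
    "derive_timing",
    "compute_t1star",
    "signal_components",
    "compute_Q",
    "synthesize_voxel",
    "synthesize_volume",
]


@dataclass(frozen=True)
class SequenceParams:
    """Acquisition/reconstruction parameters of one synthetic contrast.

    Parameters
    ----------
    flip_angle_deg : float
        Excitation flip angle in degrees, 0 <= alpha < 90 (alpha = 0 is the
        degenerate no-excitation case and yields zero signal).
    TE : float
        Echo time in seconds (>= 0).
    TR : float
        Repetition time of the whole preparation cycle in seconds.
    TI : float
        Inversion time (inversion pulse to central echo) in seconds.
    ES : float
        Echo spacing between excitations of the readout train in seconds.
    n_partitions : int
        Number of partitions, i.e. excitations per readout train.
    """

    flip_angle_deg: float
    TE: float
    TR: float
    TI: float
    ES: float
    n_partitions: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_angle_deg < 90.0:
            raise ValueError(
                f"flip_angle_deg must be in [0, 90), got {self.flip_angle_deg}"
            )
        if self.TE < 0:
            raise ValueError(f"TE must be >= 0, got {self.TE}")
        if self.TR <= 0:
            raise ValueError(f"TR must be > 0, got {self.TR}")
        if self.TI <= 0:
            raise ValueError(f"TI must be > 0, got {self.TI}")
        if self.ES <= 0:
            raise ValueError(f"ES must be > 0, got {self.ES}")
        if int(self.n_partitions) != self.n_partitions or self.n_partitions < 1:
            raise ValueError(f"n_partitions must be a positive integer, got {self.n_partitions}")

    @classmethod
    def from_ms(
        cls,
        flip_angle_deg: float,
        TE_ms: float,
        TR_ms: float,
        TI_ms: float,
        ES_ms: float,
        n_partitions: int,
    ) -> "SequenceParams":
        """Construct from millisecond timings (the console convention)."""
        return cls(
            flip_angle_deg=flip_angle_deg,
            TE=TE_ms * 1e-3,
            TR=TR_ms * 1e-3,
            TI=TI_ms * 1e-3,
            ES=ES_ms * 1e-3,
            n_partitions=int(n_partitions),
        )


@dataclass(frozen=True)
class TimingDerivation:
    """Derived cycle timing: readout duration and post-readout delay.

    ``tau = n * ES`` and ``TD = TR - (TI - tau/2) - tau``.  ``TD`` may be
    negative, in which case the parameter set is not feasible as a physical
    acquisition (``feasible=False``) but may still be used for synthesis.
    """

    tau: float
    TD: float
    feasible: bool


@dataclass(frozen=True)
class TissueVoxel:
    """Quantitative tissue parameters of a single voxel."""

    PD: float
    R1: float
    R2star: float

    @property
    def valid(self) -> bool:
        vals = (self.PD, self.R1, self.R2star)
        return all(math.isfinite(v) and v >= 0 for v in vals)


@dataclass(frozen=True)
class SignalComponents:
    """Intermediate relaxation factors of the closed-form signal."""

    T1star: np.ndarray | float
    E1: np.ndarray | float
    E2: np.ndarray | float
    E3: np.ndarray | float
    E4: np.ndarray | float
    Q: np.ndarray | float


def derive_timing(params: SequenceParams) -> TimingDerivation:
    """Derive readout duration ``tau`` and delay ``TD`` from the parameters.

    A parameter set is flagged infeasible when the readout train does not fit
    into the cycle: either ``TD < 0`` or the train would have to start before
    the inversion pulse (``TI - tau/2 < 0``).
    """
    tau = params.n_partitions * params.ES
    TD = params.TR - (params.TI - tau / 2.0) - tau
    feasible = TD >= 0.0 and (params.TI - tau / 2.0) >= 0.0
    return TimingDerivation(tau=tau, TD=TD, feasible=feasible)


def compute_t1star(R1, flip_angle_deg: float, ES: float):
    """Apparent longitudinal relaxation time during the spoiled train.

    ``T1* = (R1 - ln(cos(alpha)) / ES)^-1``.  The repeated RF excitation adds
    an effective decay ``-ln(cos alpha)/ES`` to the thermal relaxation rate,
    so ``T1* <= T1`` always, and ``T1* -> 0`` as ``alpha -> 90``.
    """
    if not 0.0 <= flip_angle_deg < 90.0:
        raise ValueError(f"flip_angle_deg must be in [0, 90), got {flip_angle_deg}")
    if ES <= 0:
        raise ValueError(f"ES must be > 0, got {ES}")
    alpha = math.radians(flip_angle_deg)
    rate = np.asarray(R1, dtype=float) - math.log(math.cos(alpha)) / ES
    out = 1.0 / rate
    if np.ndim(R1) == 0:
        return float(out)
    return out


def signal_components(params: SequenceParams, R1) -> SignalComponents:
    """Evaluate ``T1*``, ``E1..E4`` and the steady-state factor ``Q``.

    ``R1`` may be a scalar or an array; the result is vectorized elementwise.
    A negative delay time ``TD`` (infeasible acquisition timing) is allowed —
    ``E2 = exp(-TD*R1)`` then exceeds 1 — and triggers a warning.
    """
    timing = derive_timing(params)
    if timing.TD < 0:
        warnings.warn(
            f"TD = {timing.TD * 1e3:.1f} ms < 0: parameters are not feasible as "
            "an acquisition; synthesizing anyway (E2 > 1).",
            stacklevel=2,
        )
    R1 = np.asarray(R1, dtype=float)
    T1star = 1.0 / (R1 - math.log(math.cos(math.radians(params.flip_angle_deg))) / params.ES)
    tau, TD = timing.tau, timing.TD
    E1 = np.exp(-(params.TI - tau / 2.0) * R1)
    E2 = np.exp(-TD * R1)
    E3 = np.exp(-tau / T1star)
    E4 = np.exp(-tau / (2.0 * T1star))

    num = E4 * (1.0 - 2.0 * E1 + E1 * E2) + T1star * R1 * (
        1.0 + E1 * E2 * E3 - E1 * E2 * E4 - E4
    )
    den = 1.0 + E1 * E2 * E3
    Q = num / den

    for name, arr in (("E1", E1), ("E2", E2), ("E3", E3), ("E4", E4), ("Q", Q)):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite value in factor {name}")
    if R1.ndim == 0:
        return SignalComponents(
            float(T1star), float(E1), float(E2), float(E3), float(E4), float(Q)
        )
    return SignalComponents(T1star, E1, E2, E3, E4, Q)


def compute_Q(params: SequenceParams, R1):
    """Steady-state longitudinal factor at the central echo (scalar or array)."""
    return signal_components(params, R1).Q


def synthesize_voxel(voxel: TissueVoxel, params: SequenceParams) -> float:
    """Closed-form signal of a single voxel; invalid voxels synthesize to 0."""
    if not voxel.valid:
        return 0.0
    Q = compute_Q(params, voxel.R1)
    alpha = math.radians(params.flip_angle_deg)
    return voxel.PD * math.sin(alpha) * math.exp(-params.TE * voxel.R2star) * Q


def synthesize_volume(maps, params: SequenceParams) -> np.ndarray:
    """Vectorized closed-form synthesis over a :class:`~synt1w.maps.QuantitativeMaps`.

    Voxels flagged invalid in ``maps.validity_mask`` are set to 0.  Returns a
    float array with the grid shape of the input maps.
    """
    maps.validate()
    alpha = math.radians(params.flip_angle_deg)
    mask = maps.validity_mask
    R1 = np.where(mask, maps.R1, 0.0)
    PD = np.where(mask, maps.PD, 0.0)
    R2s = np.where(mask, maps.R2star, 0.0)
    Q = compute_Q(params, R1)
    signal = PD * math.sin(alpha) * np.exp(-params.TE * R2s) * Q
    signal[~mask] = 0.0
    return signal
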
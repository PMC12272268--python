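"""Pulse-by-pulse steady-state oracle for the MPRAGE preparation cycle.

The closed-form signal factor ``Q`` in :mod:`synt1w.signal` is the analytic
fixed point of one preparation cycle.  This module recomputes that fixed
point the slow way — by simulating the cycle pulse-by-pulse and iterating
until the longitudinal magnetization converges — providing an independent
check of the steady-state algebra (the composition of the relaxation factors
E1..E4 and the fixed-point solution).

Within the readout train the magnetization is propagated one echo-spacing
interval at a time with the effective-relaxation operator of spoiled trains,

    Mz -> Mss + (Mz - Mss) * exp(-ES / T1*),   Mss = R1 * T1*,

which is the same centered-main-echo, linear-k-space-ordering description the
closed form assumes; what the iteration verifies is the cycle fixed point,
not the intra-train approximation itself.  The signal is read at the central
excitation, index ``ceil(n/2)`` (1-based), i.e. after ``ceil(n/2)`` train
intervals — for even ``n`` exactly time ``tau/2`` into the train.

Only physically realizable timings (``TD >= 0`` and ``TI >= tau/2``) are
accepted: the oracle refuses parameter sets that could not be acquired.
"""

from __future__ import annotations

import math

import numpy as np

from .signal import SequenceParams, derive_timing

__all__ = ["mprage_steady_state"]


def mprage_steady_state(
    params: SequenceParams,
    R1: float,
    init_Mz: float = 1.0,
    tol: float = 1e-12,
    max_cycles: int = 100_000,
) -> float:
    """Steady-state normalized signal factor ``sin(alpha) * Mz(central echo)``.

    Parameters
    ----------
    params : SequenceParams
        Cycle parameters; must satisfy ``TD >= 0`` and ``TI - tau/2 >= 0``.
    R1 : float
        Longitudinal relaxation rate in s^-1 (thermal equilibrium Mz = 1).
    init_Mz : float
        Starting longitudinal magnetization before the first inversion.  The
        cycle map is a contraction, so the fixed point is independent of it.
    tol : float
        Convergence tolerance on the cycle-to-cycle change of Mz.
    max_cycles : int
        Maximum preparation cycles before declaring non-convergence.

    Raises
    ------
    ValueError
        If the timing is not physically realizable.
    RuntimeError
        If the iteration does not converge within ``max_cycles``.
    """
    timing = derive_timing(params)
    if not timing.feasible:
        raise ValueError(
            f"oracle requires physically realizable timing (TD={timing.TD * 1e3:.1f} ms, "
            f"TI - tau/2 = {(params.TI - timing.tau / 2) * 1e3:.1f} ms)"
        )
    alpha = math.radians(params.flip_angle_deg)
    R1 = float(R1)
    n = params.n_partitions
    t1star = 1.0 / (R1 - math.log(math.cos(alpha)) / params.ES) if (
        R1 > 0 or alpha > 0
    ) else math.inf
    mss = R1 * t1star  # driven equilibrium of the spoiled train
    e_es = math.exp(-params.ES / t1star)
    pre_delay = params.TI - timing.tau / 2.0
    e_pre = math.exp(-pre_delay * R1)
    e_td = math.exp(-timing.TD * R1)
    central = math.ceil(n / 2)

    mz = float(init_Mz)
    mz_central = math.nan
    for _ in range(max_cycles):
        mz_prev = mz
        mz = -mz  # perfect inversion
        mz = 1.0 - (1.0 - mz) * e_pre  # free relaxation to train start
        for k in range(1, n + 1):  # spoiled excitation train
            mz = mss + (mz - mss) * e_es
            if k == central:
                mz_central = mz
        mz = 1.0 - (1.0 - mz) * e_td  # free relaxation over TD
        if abs(mz - mz_prev) < tol:
            return math.sin(alpha) * mz_central
    raise RuntimeError(
        f"steady state not reached in {max_cycles} cycles "
        f"(residual {abs(mz - mz_prev):.3e})"
    )
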
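"""Grid search of synthesis parameters minimizing CSA bias against a reference.

For each candidate parameter cell the pipeline synthesizes a contrast for
every calibration subject, segments the cord, takes the median CSA across
vertebral levels, subtracts the subject's reference CSA, and aggregates
across subjects.  The default objective is the absolute value of the mean
signed difference (the calibration target is the cohort-level bias); the
mean of absolute differences is available as an alternative aggregation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maps import QuantitativeMaps
from .morphometry import SegmentationConfig, measure_csa, segment_cord
from .signal import SequenceParams, synthesize_volume

logger = logging.getLogger(__name__)

__all__ = ["ParamGrid", "OptimizationResult", "objective_eval", "grid_search"]

_TIE_RTOL = 1e-9


def _ms_range(lo: float, hi: float, step: float) -> tuple[float, ...]:
    n = int(round((hi - lo) / step))
    return tuple(lo + i * step for i in range(n + 1))


@dataclass(frozen=True)
class ParamGrid:
    """Cartesian grid over (alpha, TI, TR, TE, ES) with fixed partition count.

    Values are given in the console units (degrees and milliseconds).  The
    defaults span the full calibration ranges alpha 6-14 deg, TI 400-1000 ms,
    TR 1000-2500 ms, TE 0-10 ms, ES 5-16 ms with round steps (1 deg, 50 ms,
    100 ms, 1 ms, 1 ms).
    """

    alpha_deg: tuple[float, ...] = tuple(float(a) for a in range(6, 15))
    TI_ms: tuple[float, ...] = _ms_range(400.0, 1000.0, 50.0)
    TR_ms: tuple[float, ...] = _ms_range(1000.0, 2500.0, 100.0)
    TE_ms: tuple[float, ...] = _ms_range(0.0, 10.0, 1.0)
    ES_ms: tuple[float, ...] = _ms_range(5.0, 16.0, 1.0)
    n_partitions: int = 176

    def __post_init__(self) -> None:
        for name in ("alpha_deg", "TI_ms", "TR_ms", "TE_ms", "ES_ms"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"{name} grid is empty")

    @property
    def size(self) -> int:
        return (
            len(self.alpha_deg) * len(self.TI_ms) * len(self.TR_ms)
            * len(self.TE_ms) * len(self.ES_ms)
        )

    def cells(self):
        """Yield SequenceParams in lexicographic (alpha, TI, TR, TE, ES) order."""
        for a, ti, tr, te, es in itertools.product(
            self.alpha_deg, self.TI_ms, self.TR_ms, self.TE_ms, self.ES_ms
        ):
            if te == 0.0:
                te = 0.0  # normalize -0.0
            yield SequenceParams.from_ms(a, te, tr, ti, es, self.n_partitions)


@dataclass
class OptimizationResult:
    best_params: SequenceParams
    objective: float
    trace: pd.DataFrame
    ties: list[SequenceParams] = field(default_factory=list)


def objective_eval(
    params: SequenceParams,
    calibration_set: list[tuple[QuantitativeMaps, float]],
    levels: dict[str, tuple[int, int]] | None = None,
    seg_config: SegmentationConfig | None = None,
    aggregation: str = "abs_mean",
) -> tuple[float, float]:
    """Mean signed CSA difference (synthetic - reference) and the objective.

    ``calibration_set`` pairs each subject's quantitative maps with their
    reference CSA in mm^2 (median across levels, as measured on the reference
    contrast).  Subjects whose morphometry fails are excluded with a log
    entry; if all fail, an error is raised.  Returns ``(mean_signed,
    objective)`` where the objective is ``|mean|`` (default) or the mean of
    per-subject absolute differences (``aggregation="mean_abs"``).
    """
    if not calibration_set:
        raise ValueError("calibration set is empty")
    if aggregation not in {"abs_mean", "mean_abs"}:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    diffs = []
    for i, (maps, ref_csa) in enumerate(calibration_set):
        try:
            vol = synthesize_volume(maps, params)
            mask = segment_cord(vol, maps.voxel_spacing, seg_config)
            meas = measure_csa(mask, levels=levels)
            if levels:
                csa = float(np.median(list(meas.level_means.values())))
            else:
                csa = meas.overall_mean
        except (ValueError, FloatingPointError) as exc:
            logger.warning("subject %d excluded at %s: %s", i, params, exc)
            continue
        diffs.append(csa - ref_csa)
    if not diffs:
        raise ValueError("all calibration subjects failed morphometry")
    mean_signed = float(np.mean(diffs))
    if aggregation == "abs_mean":
        objective = abs(mean_signed)
    else:
        objective = float(np.mean(np.abs(diffs)))
    return mean_signed, objective


def grid_search(
    grid: ParamGrid,
    calibration_set: list[tuple[QuantitativeMaps, float]],
    levels: dict[str, tuple[int, int]] | None = None,
    seg_config: SegmentationConfig | None = None,
    aggregation: str = "abs_mean",
) -> OptimizationResult:
    """Exhaustive search; argmin of the objective with lexicographic tie-break.

    The trace records every cell.  Cells tying with the minimum (relative
    tolerance 1e-9) are listed in ``ties`` in evaluation order; the returned
    ``best_params`` is the lexicographically first of them.
    """
    import warnings as _warnings

    rows = []
    evaluated: list[tuple[SequenceParams, float]] = []
    for params in grid.cells():
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # infeasible-TD warnings are per-cell noise here
            mean_signed, obj = objective_eval(
                params, calibration_set, levels=levels,
                seg_config=seg_config, aggregation=aggregation,
            )
        evaluated.append((params, obj))
        rows.append(
            {
                "alpha_deg": params.flip_angle_deg,
                "TI_ms": params.TI * 1e3,
                "TR_ms": params.TR * 1e3,
                "TE_ms": params.TE * 1e3,
                "ES_ms": params.ES * 1e3,
                "mean_signed_diff_mm2": mean_signed,
                "objective_mm2": obj,
            }
        )
    trace = pd.DataFrame(rows)
    best_obj = min(obj for _, obj in evaluated)
    atol = _TIE_RTOL * max(1.0, abs(best_obj))
    ties = [p for p, obj in evaluated if obj <= best_obj + atol]
    return OptimizationResult(
        best_params=ties[0], objective=best_obj, trace=trace, ties=ties
    )
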
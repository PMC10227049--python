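"""Separation probability from paired quantile retention-time bands.

Given the predicted 10th-90th percentile retention-time bands of the
two enantiomers, the fraction of the union span not covered by the
band overlap is the separation probability

    S_p = 1 - max(0, RT90_min - RT10_max) / (RT90_max - RT10_min)

where RT90_max/RT90_min are the larger/smaller of the two 90th
percentiles and RT10_max/RT10_min of the two 10th percentiles.
Disjoint bands give S_p = 1, identical bands 0.  A pair is called
separable when S_p strictly exceeds the decision threshold (default
0.38, calibrated on practical separations).  The classical point-
prediction criterion ΔRT > 0.3 min is provided for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from .chem_graphs import ColumnSpec, Condition
from .errors import ContractError
from .qgeognn_model import QuantilePrediction

SP_THRESHOLD = 0.38
DELTA_RT_THRESHOLD_MIN = 0.3


@dataclass
class SeparationAssessment:
    sp: float
    rt90_max: float
    rt90_min: float
    rt10_max: float
    rt10_min: float
    call: str                      # "separable" | "inseparable"
    threshold: float = SP_THRESHOLD
    condition: Optional[tuple] = None


def _interval_sp(lo_a: float, hi_a: float, lo_b: float, hi_b: float) -> float:
    """Direct interval arithmetic: 1 - overlap length / union span."""
    rt90_min, rt90_max = min(hi_a, hi_b), max(hi_a, hi_b)
    rt10_min, rt10_max = min(lo_a, lo_b), max(lo_a, lo_b)
    denom = rt90_max - rt10_min
    if denom == 0:
        return 0.0
    return 1.0 - max(0.0, rt90_min - rt10_max) / denom


def separation_probability(
    a: QuantilePrediction,
    b: QuantilePrediction,
    flow_rate: Optional[float] = None,
    threshold: float = SP_THRESHOLD,
    condition: Optional[tuple] = None,
) -> SeparationAssessment:
    """S_p for a pair of quantile predictions.

    Predictions are on the RTv scale; ``flow_rate`` (or the flow rate
    stored on the predictions) converts to retention time in minutes.
    S_p itself is invariant to that positive rescaling.
    """
    bands = []
    for p in (a, b):
        v = flow_rate if flow_rate is not None else p.flow_rate
        if v is None or v <= 0:
            raise ContractError("positive flow_rate required (argument or prediction field)")
        lo, hi = p.q10 / v, p.q90 / v
        if lo > hi:
            raise ContractError(
                f"degenerate quantile band: q10 {p.q10:.4g} > q90 {p.q90:.4g}"
            )
        if lo == hi:
            warnings.warn("zero-width quantile band; S_p follows the interval limit")
        bands.append((lo, hi))
    (lo_a, hi_a), (lo_b, hi_b) = bands
    rt90_min, rt90_max = min(hi_a, hi_b), max(hi_a, hi_b)
    rt10_min, rt10_max = min(lo_a, lo_b), max(lo_a, lo_b)
    denom = rt90_max - rt10_min
    if denom == 0:
        warnings.warn("all four quantile extremes equal; treating as complete overlap")
        sp = 0.0
    else:
        sp = 1.0 - max(0.0, rt90_min - rt10_max) / denom
    call = "separable" if sp > threshold else "inseparable"
    return SeparationAssessment(
        sp=sp, rt90_max=rt90_max, rt90_min=rt90_min,
        rt10_max=rt10_max, rt10_min=rt10_min,
        call=call, threshold=threshold, condition=condition,
    )


def delta_rt(
    a: QuantilePrediction,
    b: QuantilePrediction,
    flow_rate: Optional[float] = None,
    threshold_min: float = DELTA_RT_THRESHOLD_MIN,
) -> tuple[float, str]:
    """Classical point-prediction criterion: ΔRT = |RT1 - RT2|.

    Separable iff ΔRT strictly exceeds ``threshold_min`` minutes.
    """
    va = flow_rate if flow_rate is not None else a.flow_rate
    vb = flow_rate if flow_rate is not None else b.flow_rate
    if not va or not vb or va <= 0 or vb <= 0:
        raise ContractError("positive flow_rate required")
    d = abs(a.pred / va - b.pred / vb)
    return d, ("separable" if d > threshold_min else "inseparable")


@dataclass
class ConditionAssessment:
    condition: tuple                      # (column name, proportion, flow rate)
    assessment: Optional[SeparationAssessment]
    mean_rt: Optional[float]
    error: Optional[str] = None


def rank_conditions(
    pair_smiles: tuple[str, str],
    conditions: Sequence[tuple[ColumnSpec, float, float]],
    model,
    seed: int = 0,
    threshold: float = SP_THRESHOLD,
) -> list[ConditionAssessment]:
    """Rank candidate conditions for separating one enantiomer pair.

    ``conditions`` are (ColumnSpec, elution proportion, flow rate)
    triples; requires a column-aware (multi-column) model.  Sorted by
    S_p descending, ties broken by smaller mean predicted retention
    time (a moderate RT wastes less instrument time).  A condition
    whose featurization fails is reported as failed, not raised.
    """
    from .chem_graphs import build_dual_graph
    from .errors import ChirsepError

    if not conditions:
        raise ContractError("at least one condition required")
    out: list[ConditionAssessment] = []
    for column, proportion, flow in conditions:
        key = (column.name, proportion, flow)
        try:
            cond = Condition(proportion, flow)
            preds = [
                model.forward(build_dual_graph(s, cond, seed=seed, column=column))
                for s in pair_smiles
            ]
            assess = separation_probability(
                preds[0], preds[1], flow_rate=flow, threshold=threshold, condition=key
            )
            mean_rt = (preds[0].pred + preds[1].pred) / (2.0 * flow)
            out.append(ConditionAssessment(key, assess, mean_rt))
        except ChirsepError as exc:
            out.append(ConditionAssessment(key, None, None, error=str(exc)))
    ok = [c for c in out if c.error is None]
    failed = [c for c in out if c.error is not None]
    ok.sort(key=lambda c: (-c.assessment.sp, c.mean_rt))
    return ok + failed
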
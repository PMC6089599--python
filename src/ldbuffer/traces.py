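"""Trace-level quantification: bleaching correction, percent-of-initial
metrics, two-level replicate aggregation, and dynamic/static classification.

Conventions follow the imaging analysis the package emulates: the first
post-event sample defines 100% of signal, per-nucleus values are averaged
within an embryo before embryos are compared, and error bars are standard
deviations across embryos.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import FluorescenceTrace

__all__ = [
    "AggregateSummary",
    "GridMismatchError",
    "normalize_to_control",
    "percent_lost",
    "percent_remaining",
    "aggregate_replicates",
    "classify_regime",
]


class GridMismatchError(ValueError):
    """Two traces that must share a time grid do not."""


def normalize_to_control(
    trace: FluorescenceTrace, control: FluorescenceTrace
) -> FluorescenceTrace:
    """Correct a trace for imaging photobleach using a control ROI.

    corrected_i = trace_i / (control_i / control_0), so a control that
    decays as e^{-bt} cancels the same decay in the signal exactly, and a
    constant control returns the input unchanged.  Both traces must share
    the same time grid and the control must be strictly positive.
    """
    if trace.times.shape != control.times.shape or not np.array_equal(
        trace.times, control.times
    ):
        raise GridMismatchError("trace and control are sampled at different times")
    if np.any(control.values <= 0):
        raise ValueError("control trace contains non-positive values")
    corrected = trace.values / (control.values / control.values[0])
    return FluorescenceTrace(times=trace.times.copy(), values=corrected, meta=trace.meta)


def _value_at(trace: FluorescenceTrace, t_query: float) -> float:
    """Value at the grid point nearest t_query, within half a sampling step.

    No interpolation: a query farther than half the sampling interval from
    any sample, or outside the trace range, is an error.
    """
    t = trace.times
    if t_query < t[0] or t_query > t[-1]:
        raise ValueError(f"t_query={t_query} outside trace range [{t[0]}, {t[-1]}]")
    step = float(np.median(np.diff(t))) if t.size > 1 else 0.0
    idx = int(np.argmin(np.abs(t - t_query)))
    if abs(t[idx] - t_query) > step / 2 + 1e-9:
        raise ValueError(
            f"t_query={t_query} is more than half a sampling interval from any sample"
        )
    return float(trace.values[idx])


def percent_lost(trace: FluorescenceTrace, t_query: float) -> float:
    """Percentage of initial signal lost by t_query.

    The first sample of the trace defines 100%; returns
    100 * (1 - value(t_query) / value(t0)).
    """
    v0 = float(trace.values[0])
    if v0 <= 0:
        raise ValueError("initial trace value must be > 0 to define 100%")
    return 100.0 * (1.0 - _value_at(trace, t_query) / v0)


def percent_remaining(trace: FluorescenceTrace, t_query: float) -> float:
    """Percentage of initial signal remaining; complements percent_lost to 100."""
    return 100.0 - percent_lost(trace, t_query)


@dataclass(frozen=True)
class AggregateSummary:
    """Two-level replicate summary for one group (genotype/stage).

    ``mean`` is the mean of per-embryo means (never a pool of nuclei across
    embryos) and ``sd`` the standard deviation across embryos (ddof=1);
    with a single embryo the SD is undefined and reported as NaN.
    """

    group: str
    per_embryo_means: Mapping[str, float]
    mean: float
    sd: float
    n_embryos: int


def aggregate_replicates(
    values: Sequence[float],
    embryos: Sequence[str],
    groups: Sequence[str] | None = None,
) -> list[AggregateSummary]:
    """Aggregate per-nucleus values: nuclei -> embryo means -> group summary.

    ``values[i]`` is one per-nucleus measurement belonging to ``embryos[i]``
    and (optionally) ``groups[i]``.  Empty input is an error.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to aggregate")
    if len(embryos) != values.size:
        raise ValueError("values and embryos must have equal length")
    if groups is None:
        groups = ["all"] * values.size
    if len(groups) != values.size:
        raise ValueError("values and groups must have equal length")
    df = pd.DataFrame({"value": values, "embryo": list(embryos), "group": list(groups)})
    out = []
    for group, gdf in df.groupby("group", sort=True):
        per_embryo = gdf.groupby("embryo", sort=True)["value"].mean()
        n = len(per_embryo)
        sd = float(per_embryo.std(ddof=1)) if n > 1 else math.nan
        out.append(
            AggregateSummary(
                group=str(group),
                per_embryo_means=dict(per_embryo),
                mean=float(per_embryo.mean()),
                sd=sd,
                n_embryos=n,
            )
        )
    return out


def classify_regime(
    trace: FluorescenceTrace,
    t_query: float = 180.0,
    dynamic_min: float = 20.0,
    static_max: float = 10.0,
) -> Literal["dynamic", "static", "indeterminate"]:
    """Classify a region-decay trace as pre-MBT-like (dynamic) or post-MBT-like.

    A trace losing >= ``dynamic_min`` percent of initial signal by
    ``t_query`` seconds is ``dynamic`` (rapid LD<->cytoplasm exchange);
    one losing <= ``static_max`` percent is ``static`` (exchange has
    ceased); anything between is ``indeterminate``.  The default
    thresholds separate the two measured phenotypes (~50% loss by 3 min
    pre-MBT, no detectable loss mid-cycle-14) with a wide margin.
    """
    if dynamic_min <= static_max:
        raise ValueError("dynamic_min must exceed static_max")
    if trace.times[-1] - trace.times[0] < t_query:
        raise ValueError(f"trace must span at least {t_query} s to classify")
    lost = percent_lost(trace, t_query)
    if lost >= dynamic_min:
        return "dynamic"
    if lost <= static_max:
        return "static"
    return "indeterminate"
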
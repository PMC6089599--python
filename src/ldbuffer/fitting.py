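"""Exponential curve fitting and dosage-trend models.

Recovery and decay traces are fit by nonlinear least squares to
B + A*(1 - e^{-kt}) or B + A*e^{-kt}; fitted import rates across a Jabba
dosage series are fit to the buffering relationship predicted by the
kinetic model,

    k(J) = A * Ktilde / (Ktilde + J),

which is k_eff with L = L1*J, A = D*k2_on and Ktilde = K_HL/L1 (the form is
invariant to rescaling the dosage axis up to the units of Ktilde).  Nuclear
levels across an H2Av dosage series are fit by ordinary least squares,
testing the predicted proportionality.  A recovery harness quantifies how
well the generating rate constant is re-estimated from noisy synthetic
traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import lmfit
import numpy as np
import statsmodels.api as sm

from .simulate import FluorescenceTrace
from .traces import aggregate_replicates

__all__ = [
    "IllConditionedError",
    "ExpFitResult",
    "DosageSeries",
    "JabbaFitResult",
    "LinearDosageFit",
    "RecoveryReport",
    "fit_exponential",
    "fit_jabba_relationship",
    "fit_linear_dosage",
    "recover_parameters",
]

K_BOUNDS = (1e-6, 10.0)  # plausible rate window, 1/s


class IllConditionedError(ValueError):
    """The trace carries no usable signal (e.g. flat within the noise floor)."""


@dataclass(frozen=True)
class ExpFitResult:
    """Result of a single-exponential fit.

    ``k`` is the rate constant (1/s), ``amplitude`` the recovery/decay span
    and ``baseline`` the offset.  ``converged`` reports the optimizer's own
    verdict; a non-converged result keeps the last iterate but should not
    be trusted.
    """

    k: float
    amplitude: float
    baseline: float
    rss: float
    stderr: Mapping[str, float | None]
    converged: bool
    n_points: int
    form: str

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.form == "recovery":
            return self.baseline + self.amplitude * -np.expm1(-self.k * t)
        return self.baseline + self.amplitude * np.exp(-self.k * t)


def _model(t: np.ndarray, k: float, A: float, B: float, form: str) -> np.ndarray:
    if form == "recovery":
        return B + A * -np.expm1(-k * t)
    return B + A * np.exp(-k * t)


def _init_k(t: np.ndarray, y: np.ndarray, A0: float, B0: float, form: str) -> float:
    """Log-linear initial guess: regress log of the tail-corrected signal on t."""
    if form == "recovery":
        resid = (B0 + A0) - y  # ~ A e^{-kt}
    else:
        resid = y - B0
    mask = resid > 1e-12 * max(abs(A0), 1.0)
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], np.log(resid[mask]), 1)[0]
        if slope < 0:
            return float(np.clip(-slope, *K_BOUNDS))
    span = t[-1] - t[0]
    return float(np.clip(1.0 / span if span > 0 else 1.0, *K_BOUNDS))


def fit_exponential(
    trace: FluorescenceTrace | tuple[np.ndarray, np.ndarray],
    form: Literal["recovery", "decay"] = "recovery",
    weights: np.ndarray | None = None,
    noise_floor: float = 0.0,
) -> ExpFitResult:
    """Fit a single exponential to a recovery or decay trace.

    Unweighted nonlinear least squares by default (per-point 1/SD weights
    may be supplied).  The rate is bounded to ``K_BOUNDS``; initialization
    uses first/last samples for amplitude and baseline and a log-linear
    transform for the rate.  A flat trace (peak-to-peak at or below
    ``noise_floor``, or numerically constant) raises
    :class:`IllConditionedError`; optimizer failure is reported via
    ``converged=False``, never by fabricating a rate.
    """
    if form not in ("recovery", "decay"):
        raise ValueError(f"form must be 'recovery' or 'decay', got {form!r}")
    if isinstance(trace, FluorescenceTrace):
        t, y = trace.times, trace.values
    else:
        t = np.asarray(trace[0], dtype=float)
        y = np.asarray(trace[1], dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 points to fit three parameters")
    scale = max(float(np.max(np.abs(y))), 1.0)
    ptp = float(np.ptp(y))
    if ptp <= max(noise_floor, 1e-12 * scale):
        raise IllConditionedError("trace is flat: no exponential signal to fit")

    if form == "recovery":
        B0, A0 = float(y[0]), float(y[-1] - y[0])
    else:
        B0, A0 = float(y[-1]), float(y[0] - y[-1])
    A0 = A0 if abs(A0) > 1e-12 * scale else ptp
    k0 = _init_k(t, y, A0, B0, form)

    params = lmfit.Parameters()
    params.add("k", value=k0, min=K_BOUNDS[0], max=K_BOUNDS[1])
    params.add("A", value=A0)
    params.add("B", value=B0)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        r = y - _model(t, p["k"].value, p["A"].value, p["B"].value, form)
        return r if weights is None else r * weights

    out = lmfit.minimize(residual, params, method="leastsq")
    kv = float(out.params["k"].value)
    converged = bool(out.success) and math.isfinite(kv) and kv > 0
    return ExpFitResult(
        k=kv,
        amplitude=float(out.params["A"].value),
        baseline=float(out.params["B"].value),
        rss=float(np.sum(np.asarray(out.residual) ** 2)),
        stderr={name: out.params[name].stderr for name in ("k", "A", "B")},
        converged=converged,
        n_points=int(t.size),
        form=form,
    )


@dataclass(frozen=True)
class DosageSeries:
    """Paired (dosage level, response) observations.

    ``levels`` are gene copy numbers or relative expression values (>= 0);
    ``responses`` the matching fitted rate constants or nuclear levels.
    """

    levels: np.ndarray
    responses: np.ndarray
    uncertainty: np.ndarray | None = None

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        rs = np.asarray(self.responses, dtype=float)
        if lv.shape != rs.shape or lv.ndim != 1:
            raise ValueError("levels and responses must be 1-D of equal length")
        if np.any(lv < 0):
            raise ValueError("levels must be >= 0")
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "responses", rs)
        if self.uncertainty is not None:
            u = np.asarray(self.uncertainty, dtype=float)
            if u.shape != lv.shape:
                raise ValueError("uncertainty must match levels in length")
            object.__setattr__(self, "uncertainty", u)


@dataclass(frozen=True)
class JabbaFitResult:
    """Fit of k(J) = A * Ktilde / (Ktilde + J) to a Jabba dosage series."""

    A: float
    Ktilde: float
    stderr: Mapping[str, float | None]
    residuals: np.ndarray
    levels: np.ndarray
    converged: bool

    def predict(self, J: np.ndarray) -> np.ndarray:
        J = np.asarray(J, dtype=float)
        return self.A * self.Ktilde / (self.Ktilde + J)


def fit_jabba_relationship(
    series: DosageSeries, exclude_zero: bool = True
) -> JabbaFitResult:
    """Fit the predicted buffering hyperbola to rate-vs-Jabba-dosage data.

    ``A`` is the unbuffered import rate D*k2_on (the J -> 0 limit) and
    ``Ktilde`` the LD binding constant in per-copy units.  The 0x point is
    excluded by default: without LD retention the slow-maturation
    invisible fraction biases the measured rate there.  Both parameters
    are free and positive.
    """
    mask = series.levels > 0 if exclude_zero else np.ones_like(series.levels, bool)
    J, k = series.levels[mask], series.responses[mask]
    if J.size < 3:
        raise ValueError("need at least 3 dosage levels after exclusion")
    if np.any(k <= 0):
        raise ValueError("rate responses must be > 0")

    params = lmfit.Parameters()
    # J->0 extrapolation from the smallest dosage as a starting point
    params.add("A", value=float(k[np.argmin(J)] * (1 + np.min(J))), min=1e-12)
    params.add("Ktilde", value=1.0, min=1e-12)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return k - p["A"].value * p["Ktilde"].value / (p["Ktilde"].value + J)

    out = lmfit.minimize(residual, params, method="leastsq")
    result = JabbaFitResult(
        A=float(out.params["A"].value),
        Ktilde=float(out.params["Ktilde"].value),
        stderr={n: out.params[n].stderr for n in ("A", "Ktilde")},
        residuals=np.asarray(out.residual),
        levels=J,
        converged=bool(out.success),
    )
    return result


@dataclass(frozen=True)
class LinearDosageFit:
    """OLS fit of response on dosage level, with the linear-trend statistic."""

    slope: float
    intercept: float
    r_squared: float
    t_stat: float
    p_value: float

    def predict(self, levels: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(levels, dtype=float)


def fit_linear_dosage(series: DosageSeries) -> LinearDosageFit:
    """Ordinary least squares of response against dosage level.

    Returns slope, intercept, r-squared, and the slope t statistic as the
    linear-trend test.  All-equal levels are degenerate and an error;
    all-equal responses give slope 0 and r-squared 0.
    """
    x, y = series.levels, series.responses
    if x.size < 3:
        raise ValueError("need at least 3 dosage levels")
    if np.ptp(x) == 0:
        raise ValueError("degenerate series: all dosage levels equal")
    if np.ptp(y) == 0:
        return LinearDosageFit(
            slope=0.0, intercept=float(y[0]), r_squared=0.0, t_stat=0.0, p_value=1.0
        )
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearDosageFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        t_stat=float(res.tvalues[1]),
        p_value=float(res.pvalues[1]),
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Parameter-recovery summary over a set of traces with known truth.

    Per parameter: relative bias of the median estimate, mean relative
    bias, relative RMSE, and the fraction of fits whose +/- 2 SE interval
    covers the truth (NaN when the optimizer reports no standard errors).
    Estimates are aggregated nuclei -> embryo -> overall, matching the
    replicate conventions of the trace-processing stage.
    """

    n_traces: int
    n_converged: int
    truth: Mapping[str, float]
    estimates: Mapping[str, np.ndarray]
    median_bias: Mapping[str, float]
    mean_bias: Mapping[str, float]
    rmse: Mapping[str, float]
    coverage: Mapping[str, float]
    per_embryo_k: Mapping[str, float]


_PARAM_KEYS = {"k": "k", "A": "amplitude", "B": "baseline"}


def recover_parameters(
    traces: Sequence[FluorescenceTrace],
    truth: Mapping[str, float],
    form: Literal["recovery", "decay"] = "recovery",
) -> RecoveryReport:
    """Fit every trace and compare the estimates with the generating truth.

    ``truth`` must contain the generating rate ``k`` and may also contain
    ``A`` and ``B``.  Deterministic given the dataset.
    """
    if "k" not in truth:
        raise ValueError("truth must include the generating rate 'k'")
    fits = [fit_exponential(tr, form=form) for tr in traces]
    ok = [f for f in fits if f.converged]
    if not ok:
        raise IllConditionedError("no trace produced a converged fit")

    estimates: dict[str, np.ndarray] = {}
    median_bias: dict[str, float] = {}
    mean_bias: dict[str, float] = {}
    rmse: dict[str, float] = {}
    coverage: dict[str, float] = {}
    for name, attr in _PARAM_KEYS.items():
        if name not in truth:
            continue
        true_v = float(truth[name])
        est = np.array([getattr(f, attr) for f in ok])
        rel = (est - true_v) / true_v
        estimates[name] = est
        median_bias[name] = float(np.median(rel))
        mean_bias[name] = float(np.mean(rel))
        rmse[name] = float(np.sqrt(np.mean(rel**2)))
        ses = [f.stderr[name] for f in ok]
        if all(s is not None and math.isfinite(s) for s in ses):
            cov = np.mean(
                [abs(e - true_v) <= 2 * s for e, s in zip(est, ses)]  # type: ignore[arg-type]
            )
            coverage[name] = float(cov)
        else:
            coverage[name] = math.nan

    k_by_embryo = aggregate_replicates(
        [f.k for f in ok],
        [tr.meta.embryo_id for tr, f in zip(traces, fits) if f.converged],
    )[0].per_embryo_means
    return RecoveryReport(
        n_traces=len(traces),
        n_converged=len(ok),
        truth=dict(truth),
        estimates=estimates,
        median_bias=median_bias,
        mean_bias=mean_bias,
        rmse=rmse,
        coverage=coverage,
        per_embryo_k=dict(k_by_embryo),
    )
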
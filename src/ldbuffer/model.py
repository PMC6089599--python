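"""Three-pool kinetics of histone H2Av buffering by lipid droplets.

The histone variant H2Av in an early fly embryo is modelled as partitioning
between three pools: free in the cytoplasm, bound to lipid-droplet (LD)
surfaces via the anchor protein Jabba, and incorporated into nuclear
chromatin.  Exchange follows mass action with constant free-site
concentrations,

    free + LD-site   <->  LD-bound     (k1_on, k1_off)
    free + DNA-site  <->  DNA-bound    (k2_on, k2_off)

When cytoplasm<->LD exchange is much faster than chromatin incorporation,
the free/LD partition stays at its equilibrium ratio (quasi-equilibrium)
and nuclear accumulation collapses to a single exponential with effective
rate

    k_eff = K_HL / (K_HL + [L]) * [D] * k2_on,      K_HL = k1_off / k1_on.

LD binding sites therefore buffer nuclear import: raising [L] lowers the
free pool and slows import, while the asymptotic nuclear level is set by
total H2Av abundance alone.

Units: time in seconds, concentrations in arbitrary units (a.u.),
second-order rates in 1/(a.u.*s).  No absolute concentrations are implied.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParams",
    "PoolState",
    "Trajectory",
    "RegimeDiagnostics",
    "UndefinedEquilibriumError",
    "UndefinedRatioError",
    "IntegrationError",
    "khl",
    "effective_rate",
    "hd_analytic",
    "nonnuclear_analytic",
    "equilibrium_partition",
    "equilibrium_initial_state",
    "rhs",
    "initial_exchange_flux",
    "integrate",
    "validate_regime",
]

#: relative tolerance at which mass conservation must hold along trajectories
CONSERVATION_RTOL = 1e-8


class UndefinedEquilibriumError(ValueError):
    """K_HL = k1_off/k1_on is requested but k1_on is zero."""


class UndefinedRatioError(ValueError):
    """A regime diagnostic ratio has a zero denominator."""


class IntegrationError(RuntimeError):
    """The ODE solver failed to converge; no partial trajectory is returned."""


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and pool/site concentrations of the three-pool model.

    Parameters
    ----------
    k1_on, k1_off
        On/off rates of H2Av binding to LD sites (1/(a.u.*s), 1/s).
    k2_on, k2_off
        On/off rates of H2Av incorporation into chromatin.  ``k2_off``
        defaults to 0: chromatin-bound H2Av is treated as irreversibly
        trapped, consistent with nuclear export being undetectable on the
        minutes time scale of the experiments the model describes.
    L, D
        Free H2Av binding-site concentrations on LDs and on DNA (a.u.).
        Both are held constant (no site depletion), which keeps the system
        linear and admits the closed-form exponential solution.
    H_tot
        Total H2Av concentration (a.u.).

    The defaults are the package's reference calibration; they place the
    system deep in the quasi-equilibrium regime (separation ratio 18) with
    k_eff = 0.005 /s, i.e. a nuclear-accumulation half-time of ~2.3 min.
    """

    k1_on: float = 0.05
    k1_off: float = 0.1
    k2_on: float = 0.01
    k2_off: float = 0.0
    L: float = 18.0
    D: float = 5.0
    H_tot: float = 100.0

    def __post_init__(self) -> None:
        for name in ("k1_on", "k1_off", "k2_on", "k2_off", "L", "D", "H_tot"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def K_HL(self) -> float:
        """Equilibrium constant for H2Av-LD binding, k1_off/k1_on."""
        return khl(self)

    def with_(self, **kw: float) -> "KineticParams":
        return replace(self, **kw)

    # -- flat-mapping I/O (JSON / YAML) ------------------------------------
    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "KineticParams":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "KineticParams":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(data)


@dataclass(frozen=True)
class PoolState:
    """Concentrations of the three H2Av pools at one time point."""

    t: float
    H_free: float
    H_LD: float
    H_DNA: float

    def __post_init__(self) -> None:
        for name in ("H_free", "H_LD", "H_DNA"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def total(self) -> float:
        return self.H_free + self.H_LD + self.H_DNA

    def as_array(self) -> np.ndarray:
        return np.array([self.H_free, self.H_LD, self.H_DNA])


@dataclass(frozen=True)
class Trajectory:
    """Integrated time course of the three pools.

    ``times`` is strictly increasing; ``pools`` has shape ``(len(times), 3)``
    with columns (H_free, H_LD, H_DNA).  Mass conservation holds at every
    output time to :data:`CONSERVATION_RTOL` relative.
    """

    times: np.ndarray
    pools: np.ndarray
    params: KineticParams

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.pools, dtype=float)
        if t.ndim != 1 or p.shape != (t.size, 3):
            raise ValueError("times must be 1-D and pools of shape (n, 3)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "pools", p)

    @property
    def H_free(self) -> np.ndarray:
        return self.pools[:, 0]

    @property
    def H_LD(self) -> np.ndarray:
        return self.pools[:, 1]

    @property
    def H_DNA(self) -> np.ndarray:
        return self.pools[:, 2]

    def conservation_error(self) -> float:
        """Max relative deviation of the pool sum from H_tot."""
        total = self.pools.sum(axis=1)
        return float(np.max(np.abs(total - self.params.H_tot)) / self.params.H_tot)

    def states(self) -> list[PoolState]:
        return [
            PoolState(t=float(t), H_free=float(f), H_LD=float(l), H_DNA=float(d))
            for t, (f, l, d) in zip(self.times, self.pools)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.times,
                "H_free": self.H_free,
                "H_LD": self.H_LD,
                "H_DNA": self.H_DNA,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def khl(params: KineticParams) -> float:
    """Equilibrium constant K_HL = k1_off / k1_on for H2Av-LD binding.

    Small K_HL means tight LD binding.  Undefined when ``k1_on`` is zero.
    """
    if params.k1_on == 0:
        raise UndefinedEquilibriumError("K_HL undefined: k1_on is zero")
    return params.k1_off / params.k1_on


def effective_rate(params: KineticParams) -> float:
    """Effective nuclear-import rate under quasi-equilibrium (1/s).

    k_eff = K_HL/(K_HL + [L]) * [D] * k2_on.  The prefactor is the free
    fraction of the non-nuclear pool; with no LDs ([L]=0) the rate is at
    its maximum [D]*k2_on, and it decreases monotonically as buffering
    capacity [L] grows.
    """
    K = khl(params)
    denom = K + params.L
    if denom == 0:
        # K_HL = 0 and L = 0: no LD binding at all, free fraction is 1
        return params.D * params.k2_on
    return K / denom * params.D * params.k2_on


def _check_times(t: float | np.ndarray) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("time must be >= 0")
    return arr


def hd_analytic(params: KineticParams, t: float | np.ndarray) -> float | np.ndarray:
    """Closed-form DNA-bound (nuclear) H2Av at time t.

    H_D(t) = H_tot * (1 - exp(-k_eff * t)): zero at t = 0 and
    asymptotically approaching H_tot, exactly linear in H_tot.
    """
    arr = _check_times(t)
    out = params.H_tot * -np.expm1(-effective_rate(params) * arr)
    return float(out) if np.isscalar(t) else out


def nonnuclear_analytic(params: KineticParams, t: float | np.ndarray) -> float | np.ndarray:
    """Closed-form non-nuclear H2Av (free + LD-bound) at time t.

    H_tot * exp(-k_eff * t); complements :func:`hd_analytic` so that the
    two sum to H_tot at every time.
    """
    arr = _check_times(t)
    out = params.H_tot * np.exp(-effective_rate(params) * arr)
    return float(out) if np.isscalar(t) else out


def equilibrium_partition(params: KineticParams, H_nonnuclear: float) -> tuple[float, float]:
    """Split a non-nuclear amount into (H_free, H_LD) at the LD equilibrium.

    H_free = K_HL/(K_HL+L) * H_nn and H_LD = L/(K_HL+L) * H_nn; the two
    sum to H_nn exactly.  K_HL = 0 puts everything on LDs (infinitely
    tight binding); L = 0 leaves everything free.
    """
    if H_nonnuclear < 0:
        raise ValueError("H_nonnuclear must be >= 0")
    K = khl(params)
    denom = K + params.L
    if denom == 0:
        return H_nonnuclear, 0.0
    H_free = K / denom * H_nonnuclear
    return H_free, H_nonnuclear - H_free


def equilibrium_initial_state(params: KineticParams, t0: float = 0.0) -> PoolState:
    """Default initial condition: empty nuclei, non-nuclear pool pre-equilibrated."""
    H_free, H_LD = equilibrium_partition(params, params.H_tot)
    return PoolState(t=t0, H_free=H_free, H_LD=H_LD, H_DNA=0.0)


def rhs(params: KineticParams, state: PoolState) -> tuple[float, float, float]:
    """Mass-action time derivatives (dH_free, dH_LD, dH_DNA) in a.u./s.

    The three derivatives sum to exactly zero (closed system).
    """
    d = _rhs_vec(state.as_array(), params)
    return float(d[0]), float(d[1]), float(d[2])


def _rhs_vec(y: np.ndarray, p: KineticParams) -> np.ndarray:
    H_free, H_LD, H_DNA = y
    ld_flux = p.k1_on * H_free * p.L - p.k1_off * H_LD
    dna_flux = p.k2_on * H_free * p.D - p.k2_off * H_DNA
    return np.array([-ld_flux - dna_flux, ld_flux, dna_flux])


def integrate(
    params: KineticParams,
    init: PoolState,
    times: Sequence[float] | np.ndarray,
    rtol: float = 1e-10,
    atol: float | None = None,
    method: str = "LSODA",
) -> Trajectory:
    """Numerically integrate the rate equations on the given output grid.

    Uses a stiff-capable adaptive solver (LSODA by default): under fast LD
    exchange ``k1_on*L`` can exceed ``k2_on*D`` by orders of magnitude.
    ``times`` must be strictly increasing with ``times[0] == init.t``, and
    ``init`` must satisfy mass conservation.  Solver failure raises
    :class:`IntegrationError`; a trajectory is never silently truncated.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("times must be a 1-D array with at least two points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if not np.isclose(t[0], init.t, rtol=0, atol=1e-12):
        raise ValueError("times[0] must equal init.t")
    if abs(init.total - params.H_tot) > CONSERVATION_RTOL * max(params.H_tot, 1.0):
        raise ValueError(
            f"initial state violates conservation: pools sum to {init.total}, "
            f"H_tot is {params.H_tot}"
        )
    if atol is None:
        atol = 1e-13 * max(params.H_tot, 1.0)
    sol = solve_ivp(
        lambda _t, y: _rhs_vec(y, params),
        (t[0], t[-1]),
        init.as_array(),
        t_eval=t,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or sol.y.shape[1] != t.size:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    pools = np.clip(sol.y.T, 0.0, None)  # clip solver noise at the origin
    traj = Trajectory(times=t, pools=pools, params=params)
    err = traj.conservation_error()
    if err > CONSERVATION_RTOL:
        raise IntegrationError(
            f"conservation violated beyond tolerance: relative error {err:.3e}"
        )
    return traj


def initial_exchange_flux(params: KineticParams) -> float:
    """LD -> cytoplasm off-flux at the pre-equilibrated initial state (a.u./s).

    k1_off * L/(K_HL+L) * H_tot.  The expression contains no [D]: how fast
    H2Av leaves LDs is set entirely by the binding equilibrium and the
    pool size, independent of chromatin demand.
    """
    _, H_LD = equilibrium_partition(params, params.H_tot)
    return params.k1_off * H_LD


@dataclass(frozen=True)
class RegimeDiagnostics:
    """Diagnostics for the three quasi-equilibrium model assumptions.

    separation_ratio
        k1_on*L / (k2_on*D): LD capture must outpace chromatin
        incorporation for the rapid pre-equilibration picture to hold.
    partition_ratio
        L / K_HL: LD-bound H2Av must sit well below free H2Av in energy,
        i.e. the LD pool dominates the non-nuclear pool.
    reversibility_ratio
        k2_off / (k2_on*D): chromatin-bound H2Av must sit well below
        LD-bound H2Av in energy, i.e. nuclear export is negligible.
    """

    separation_ratio: float
    partition_ratio: float
    reversibility_ratio: float
    separation_ok: bool
    partition_ok: bool
    reversibility_ok: bool

    @property
    def assumptions_hold(self) -> bool:
        return self.separation_ok and self.partition_ok and self.reversibility_ok


def validate_regime(
    params: KineticParams,
    separation_min: float = 10.0,
    partition_min: float = 5.0,
    reversibility_max: float = 0.01,
) -> RegimeDiagnostics:
    """Check whether the parameter set is in the quasi-equilibrium regime.

    Thresholds are pragmatic defaults (the underlying assumptions are
    order-of-magnitude statements, not sharp bounds) and are configurable.
    Pure function; raises :class:`UndefinedRatioError` on zero denominators.
    """
    if params.k1_on <= 0 or params.k2_on <= 0:
        raise ValueError("k1_on and k2_on must be > 0 for regime diagnostics")
    K = khl(params)
    if params.D == 0:
        raise UndefinedRatioError("separation ratio undefined: k2_on*D is zero")
    if K == 0:
        raise UndefinedRatioError("partition ratio undefined: K_HL is zero")
    separation = params.k1_on * params.L / (params.k2_on * params.D)
    partition = params.L / K
    reversibility = params.k2_off / (params.k2_on * params.D)
    return RegimeDiagnostics(
        separation_ratio=separation,
        partition_ratio=partition,
        reversibility_ratio=reversibility,
        separation_ok=separation >= separation_min,
        partition_ok=partition >= partition_min,
        reversibility_ok=reversibility <= reversibility_max,
    )
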
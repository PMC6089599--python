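"""Seeded generators for synthetic live-imaging fluorescence traces.

These emulate the statistical structure of the live-imaging experiments the
model describes — FRAP nuclear-recovery curves, photoswitch region-decay
curves, imaging-photobleaching control ROIs, and genotype series varying
Jabba (LD binding-site) and H2Av (total histone) gene dosage — so that the
processing and fitting stages can be exercised and validated without real
microscopy data.

Every generator is a pure function of (parameters, design, seed): the same
inputs reproduce bit-identical traces.  Measurement noise is multiplicative
Gaussian with a configurable coefficient of variation, independent across
time points; with CV = 0 every sample lies exactly on its closed-form curve.
Per-trace random streams are derived from the design seed together with the
(embryo, nucleus) indices, so adding replicates never perturbs existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .model import KineticParams, effective_rate, hd_analytic, khl

__all__ = [
    "ConfigError",
    "TraceMeta",
    "FluorescenceTrace",
    "FrapDesign",
    "PhotoswitchDesign",
    "ControlDesign",
    "DosageDesign",
    "DosageSeriesResult",
    "PRE_MBT_K_EX",
    "EGFP_MATURATION_RATE",
    "gen_frap_recovery",
    "gen_photoswitch_decay",
    "gen_control_roi",
    "gen_dosage_series",
    "visible_recovery_fraction",
]

MODALITIES = frozenset(
    {"frap_recovery", "photoswitch_region_decay", "nuclear_photoswitch", "control_roi"}
)
STAGES = (
    "cleavage",
    "NC10",
    "NC11",
    "NC12",
    "NC13",
    "NC14_early",
    "NC14_mid",
    "NC15",
)

#: Default pre-MBT region-exchange rate: ln 2 / 180 s, calibrated so the
#: noise-free region-decay trace loses half its signal by 3 min — the
#: measured magnitude of H2Av loss from photoswitched LD regions.
PRE_MBT_K_EX = math.log(2.0) / 180.0

#: First-order eGFP fluorophore maturation rate, time constant ~30 min.
EGFP_MATURATION_RATE = 1.0 / 1800.0


class ConfigError(ValueError):
    """A generator design is self-inconsistent or out of range."""


@dataclass(frozen=True)
class TraceMeta:
    """Genotype, stage and provenance labels attached to one trace."""

    modality: str
    jabba_copies: int = 2
    h2av_copies: int = 2
    stage: str = "NC13"
    embryo_id: str = "e0"
    nucleus_id: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ConfigError(f"unknown modality {self.modality!r}")
        if not 0 <= self.jabba_copies <= 3:
            raise ConfigError("jabba_copies must be in 0..3")
        if self.h2av_copies not in (1, 2, 4):
            raise ConfigError("h2av_copies must be one of 1, 2, 4")


@dataclass(frozen=True)
class FluorescenceTrace:
    """A sampled fluorescence time series (a.u.) with its metadata."""

    times: np.ndarray
    values: np.ndarray
    meta: TraceMeta

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("fluorescence values must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    @property
    def trace_id(self) -> str:
        m = self.meta
        nuc = f"_{m.nucleus_id}" if m.nucleus_id else ""
        return (
            f"{m.modality}_{m.stage}_j{m.jabba_copies}h{m.h2av_copies}_{m.embryo_id}{nuc}"
        )


def _sampling_grid(duration_s: float, interval_s: float) -> np.ndarray:
    n = int(round(duration_s / interval_s))
    return np.arange(n + 1, dtype=float) * interval_s


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _apply_noise(curve: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return curve.copy()
    noisy = curve * (1.0 + cv * rng.standard_normal(curve.size))
    return np.clip(noisy, 0.0, None)


def _check_positive(design, names: Iterable[str]) -> None:
    for name in names:
        v = getattr(design, name)
        if not np.isfinite(v) or v < 0:
            raise ConfigError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class FrapDesign:
    """Replicate/noise/sampling settings for FRAP nuclear-recovery traces.

    Defaults mirror the imaging protocol of the experiments being emulated:
    sampling every 60 s for 5 min, five nuclei per embryo, five embryos.
    ``amplitude`` and ``baseline`` set the recovery span B + A*(1-e^{-kt}).
    """

    n_embryos: int = 5
    n_nuclei: int = 5
    noise_cv: float = 0.05
    duration_s: float = 300.0
    interval_s: float = 60.0
    amplitude: float = 80.0
    baseline: float = 20.0
    stage: str = "NC13"
    jabba_copies: int = 2
    h2av_copies: int = 2
    use_ode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        _check_positive(
            self, ("n_embryos", "n_nuclei", "noise_cv", "duration_s", "interval_s",
                   "amplitude", "baseline"))
        if self.n_embryos < 1 or self.n_nuclei < 1:
            raise ConfigError("need at least one embryo and one nucleus")
        if self.duration_s < self.interval_s:
            raise ConfigError("duration_s must cover at least one interval")


def gen_frap_recovery(
    params: KineticParams, design: FrapDesign = FrapDesign()
) -> list[FluorescenceTrace]:
    """Generate per-nucleus FRAP recovery traces.

    The noise-free signal is I(t) = B + A*(1 - e^{-k t}) with
    k = effective_rate(params); with ``use_ode`` the recovery follows the
    numerically integrated DNA-bound pool instead of the quasi-equilibrium
    closed form (the two coincide in the rapid-exchange regime).
    """
    times = _sampling_grid(design.duration_s, design.interval_s)
    if design.use_ode:
        from .model import equilibrium_initial_state, integrate

        traj = integrate(params, equilibrium_initial_state(params), times)
        recovery = traj.H_DNA / params.H_tot
    else:
        k = effective_rate(params)
        recovery = -np.expm1(-k * times)
    curve = design.baseline + design.amplitude * recovery
    traces = []
    for e in range(design.n_embryos):
        for n in range(design.n_nuclei):
            rng = _rng(design.seed, 0, e, n)
            meta = TraceMeta(
                modality="frap_recovery",
                jabba_copies=design.jabba_copies,
                h2av_copies=design.h2av_copies,
                stage=design.stage,
                embryo_id=f"e{e}",
                nucleus_id=f"n{n}",
                seed=design.seed,
            )
            traces.append(
                FluorescenceTrace(times, _apply_noise(curve, design.noise_cv, rng), meta)
            )
    return traces


@dataclass(frozen=True)
class PhotoswitchDesign:
    """Settings for photoswitched-region decay traces (one per embryo).

    ``k_ex`` is the region-exchange rate; left as None it resolves to the
    pre-MBT calibration (:data:`PRE_MBT_K_EX`) or to 0 post-MBT.  ``p_inf``
    is the long-time plateau fraction, 0 by default (the photoswitched
    region is a negligible fraction of the embryo-wide sink).
    """

    n_embryos: int = 5
    noise_cv: float = 0.05
    duration_s: float = 360.0
    interval_s: float = 60.0
    s0: float = 100.0
    k_ex: float | None = None
    p_inf: float = 0.0
    stage: str = "NC13"
    jabba_copies: int = 2
    h2av_copies: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        _check_positive(
            self, ("n_embryos", "noise_cv", "duration_s", "interval_s", "s0"))
        if not 0.0 <= self.p_inf <= 1.0:
            raise ConfigError("p_inf must lie in [0, 1]")
        if self.k_ex is not None and (not np.isfinite(self.k_ex) or self.k_ex < 0):
            raise ConfigError("k_ex must be >= 0")


def gen_photoswitch_decay(
    regime: Literal["pre_MBT", "post_MBT"],
    design: PhotoswitchDesign = PhotoswitchDesign(),
) -> list[FluorescenceTrace]:
    """Generate region-decay traces after photoswitching.

    Noise-free signal S(t) = S0 * (p_inf + (1-p_inf) * e^{-k_ex t}).
    Pre-MBT uses the calibrated default exchange rate regardless of the
    nuclear-cycle label (loss rates are stage-invariant before the
    midblastula transition); post-MBT exchange has ceased, k_ex = 0.
    """
    if regime not in ("pre_MBT", "post_MBT"):
        raise ConfigError(f"regime must be 'pre_MBT' or 'post_MBT', got {regime!r}")
    if design.k_ex is not None:
        k_ex = design.k_ex
    else:
        k_ex = PRE_MBT_K_EX if regime == "pre_MBT" else 0.0
    stage = design.stage
    if regime == "post_MBT" and design.stage == "NC13":
        stage = "NC14_mid"  # default label for the static regime
    times = _sampling_grid(design.duration_s, design.interval_s)
    curve = design.s0 * (design.p_inf + (1.0 - design.p_inf) * np.exp(-k_ex * times))
    traces = []
    for e in range(design.n_embryos):
        rng = _rng(design.seed, 1, e)
        meta = TraceMeta(
            modality="photoswitch_region_decay",
            jabba_copies=design.jabba_copies,
            h2av_copies=design.h2av_copies,
            stage=stage,
            embryo_id=f"e{e}",
            seed=design.seed,
        )
        traces.append(
            FluorescenceTrace(times, _apply_noise(curve, design.noise_cv, rng), meta)
        )
    return traces


@dataclass(frozen=True)
class ControlDesign:
    """Settings for control-ROI traces used to correct imaging photobleach."""

    n_embryos: int = 5
    noise_cv: float = 0.05
    duration_s: float = 300.0
    interval_s: float = 60.0
    c0: float = 100.0
    stage: str = "NC13"
    seed: int = 0

    def __post_init__(self) -> None:
        _check_positive(
            self, ("n_embryos", "noise_cv", "duration_s", "interval_s", "c0"))


def gen_control_roi(
    bleach_rate: float, design: ControlDesign = ControlDesign()
) -> list[FluorescenceTrace]:
    """Generate control-ROI traces, C(t) = C0 * e^{-b t} plus noise.

    ``bleach_rate`` b is the imaging-photobleaching rate; b = 0 yields a
    constant control.
    """
    if not np.isfinite(bleach_rate) or bleach_rate < 0:
        raise ConfigError("bleach_rate must be >= 0")
    times = _sampling_grid(design.duration_s, design.interval_s)
    curve = design.c0 * np.exp(-bleach_rate * times)
    traces = []
    for e in range(design.n_embryos):
        rng = _rng(design.seed, 2, e)
        meta = TraceMeta(
            modality="control_roi",
            stage=design.stage,
            embryo_id=f"e{e}",
            seed=design.seed,
        )
        traces.append(
            FluorescenceTrace(times, _apply_noise(curve, design.noise_cv, rng), meta)
        )
    return traces


def visible_recovery_fraction(
    t: np.ndarray, k: float, invisible_share: float, k_mat: float = EGFP_MATURATION_RATE
) -> np.ndarray:
    """Fraction of nuclear recovery visible when fluorophores mature slowly.

    A share ``invisible_share`` of the import flux arrives with an immature
    (dark) fluorophore and becomes visible only after first-order maturation
    at rate ``k_mat`` inside the nucleus (a two-compartment immature->mature
    cascade on top of the single-exponential import curve):

        v(t) = (1 - e^{-kt}) - f * k/(k - k_mat) * (e^{-k_mat t} - e^{-kt})

    with the continuous limit at k = k_mat.
    """
    if not 0.0 <= invisible_share <= 1.0:
        raise ConfigError("invisible_share must lie in [0, 1]")
    t = np.asarray(t, dtype=float)
    total = -np.expm1(-k * t)
    if invisible_share == 0.0 or k == 0.0:
        return total
    if math.isclose(k, k_mat, rel_tol=1e-9):
        dark = invisible_share * k * t * np.exp(-k * t)
    else:
        dark = invisible_share * k / (k - k_mat) * (np.exp(-k_mat * t) - np.exp(-k * t))
    return np.clip(total - dark, 0.0, None)


@dataclass(frozen=True)
class DosageDesign:
    """Settings for genotype series varying Jabba and H2Av gene dosage.

    Dosage maps linearly onto model parameters (protein levels scale with
    gene dosage): ``jabba_copies`` j gives LD sites L = L1*j with L1 the
    per-copy site concentration (wild type is 2x), and ``h2av_copies`` c
    gives H_tot = H1*c.  ``maturation`` switches on the slow-fluorophore
    confound: the LD-routed share of the import flux, L/(K_HL+L), has had
    time to mature during cytoplasmic retention, while the directly
    imported share K_HL/(K_HL+L) arrives dark and matures in the nucleus
    at ``k_mat`` — a stylized invisible fraction largest at 0x Jabba.
    """

    frap: FrapDesign = FrapDesign()
    endpoint_t_s: float = 600.0
    jabba_reference_copies: int = 2
    h2av_reference_copies: int = 2
    maturation: bool = False
    k_mat: float = EGFP_MATURATION_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.endpoint_t_s < 0:
            raise ConfigError("endpoint_t_s must be >= 0")
        if self.jabba_reference_copies < 1 or self.h2av_reference_copies < 1:
            raise ConfigError("reference copy numbers must be >= 1")
        if not np.isfinite(self.k_mat) or self.k_mat < 0:
            raise ConfigError("k_mat must be >= 0")


@dataclass(frozen=True)
class DosageSeriesResult:
    """Labelled outputs of a dosage series.

    ``frap_traces[j]`` are recovery traces at Jabba dosage j; ``true_k[j]``
    the generating effective rate; ``apparent_invisible_share[j]`` the dark
    share applied when maturation is on (0 otherwise).
    ``h2av_endpoints[c]`` are noise-free nuclear levels at the design
    endpoint time for H2Av dosage c (exactly proportional to c).
    """

    frap_traces: dict[int, list[FluorescenceTrace]]
    true_k: dict[int, float]
    apparent_invisible_share: dict[int, float]
    h2av_endpoints: dict[int, float]
    params_per_jabba: dict[int, KineticParams]
    design: DosageDesign


def gen_dosage_series(
    base_params: KineticParams,
    jabba_levels: Sequence[int] = (1, 2, 3),
    h2av_levels: Sequence[int] = (1, 2, 4),
    design: DosageDesign = DosageDesign(),
) -> DosageSeriesResult:
    """Generate the two genotype series: Jabba dosage and H2Av dosage.

    For each Jabba copy number j a FRAP recovery set is generated with
    L = L1*j (L = 0 at j = 0, i.e. no buffering sites); for each H2Av copy
    number c a noise-free nuclear endpoint hd_analytic(endpoint_t_s) with
    H_tot = H1*c.  ``base_params`` describes the wild-type (reference)
    genotype.
    """
    for j in jabba_levels:
        if not 0 <= int(j) <= 3:
            raise ConfigError("jabba levels must be in 0..3")
    for c in h2av_levels:
        if int(c) not in (1, 2, 4):
            raise ConfigError("h2av levels must be one of 1, 2, 4")
    L1 = base_params.L / design.jabba_reference_copies
    H1 = base_params.H_tot / design.h2av_reference_copies
    K = khl(base_params)

    frap_traces: dict[int, list[FluorescenceTrace]] = {}
    true_k: dict[int, float] = {}
    dark_share: dict[int, float] = {}
    params_per_jabba: dict[int, KineticParams] = {}
    times = _sampling_grid(design.frap.duration_s, design.frap.interval_s)
    for j in map(int, jabba_levels):
        p_j = base_params.with_(L=L1 * j)
        k_j = effective_rate(p_j)
        f_j = K / (K + p_j.L) if design.maturation else 0.0
        curve = design.frap.baseline + design.frap.amplitude * visible_recovery_fraction(
            times, k_j, f_j, design.k_mat
        )
        traces = []
        for e in range(design.frap.n_embryos):
            for n in range(design.frap.n_nuclei):
                rng = _rng(design.seed, 3, j, e, n)
                meta = TraceMeta(
                    modality="frap_recovery",
                    jabba_copies=j,
                    h2av_copies=design.h2av_reference_copies,
                    stage=design.frap.stage,
                    embryo_id=f"e{e}",
                    nucleus_id=f"n{n}",
                    seed=design.seed,
                )
                traces.append(
                    FluorescenceTrace(
                        times, _apply_noise(curve, design.frap.noise_cv, rng), meta
                    )
                )
        frap_traces[j] = traces
        true_k[j] = k_j
        dark_share[j] = f_j
        params_per_jabba[j] = p_j

    h2av_endpoints = {
        int(c): hd_analytic(base_params.with_(H_tot=H1 * int(c)), design.endpoint_t_s)
        for c in h2av_levels
    }
    return DosageSeriesResult(
        frap_traces=frap_traces,
        true_k=true_k,
        apparent_invisible_share=dark_share,
        h2av_endpoints=h2av_endpoints,
        params_per_jabba=params_per_jabba,
        design=design,
    )
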
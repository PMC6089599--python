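# Methods

## The model

`ldbuffer` implements a minimal kinetic account of how lipid droplets (LDs)
buffer nuclear accumulation of the histone variant H2Av in the syncytial
*Drosophila* embryo. Total H2Av, `H_tot`, is split across three pools —
free in the cytoplasm (`H_free`), bound to LD surface sites (`H_LD`), and
incorporated into chromatin (`H_DNA`) — exchanging by mass action against
constant free-site concentrations `[L]` (LD sites, set by Jabba abundance)
and `[D]` (chromatin sites):

```
dH_free/dt = −k1_on·H_free·L + k1_off·H_LD − k2_on·H_free·D + k2_off·H_DNA
dH_LD/dt   =  k1_on·H_free·L − k1_off·H_LD
dH_DNA/dt  =  k2_on·H_free·D − k2_off·H_DNA
```

Holding `L` and `D` constant (no site depletion) keeps the system linear;
this is what admits the closed-form solution below, and a site-depletion
variant is deliberately out of scope. `k2_off` defaults to 0 — chromatin
incorporation is treated as irreversible, since nuclear loss of H2Av is
undetectable on the minutes time scale being modelled — but is kept as a
parameter so the reversible system is representable.

### Quasi-equilibrium solution

Three assumptions define the operating regime: (i) LD capture is much
faster than chromatin incorporation (`k1_on·L ≫ k2_on·D`), (ii) LD-bound
H2Av is much lower in energy than free H2Av (`L ≫ K_HL`, where
`K_HL = k1_off/k1_on`), and (iii) chromatin-bound H2Av is much lower in
energy than LD-bound (`k2_off ≈ 0`). Under (i) the non-nuclear pool stays
at its binding equilibrium, a free fraction `K_HL/(K_HL+L)`, and nuclear
accumulation collapses to a single exponential:

```
k_eff   = K_HL/(K_HL + L) · D · k2_on
H_D(t)  = H_tot · (1 − e^{−k_eff·t}),      H_nn(t) = H_tot · e^{−k_eff·t}
```

with `H_D(0) = 0` (empty nuclei, pre-equilibrated cytoplasm/LD pool as the
default initial condition). Two testable consequences follow directly:
nuclear levels are exactly proportional to `H_tot` at every time, and
`k_eff` falls monotonically with `L` — buffering capacity tunes the *rate*
of import, not its endpoint. A third: the LD→cytoplasm off-flux at the
initial equilibrium, `k1_off·L/(K_HL+L)·H_tot`, contains no `[D]`, so loss
of histone from droplets is formally independent of chromatin demand.

`validate_regime` scores the three assumptions as ratios with default
thresholds: separation `k1_on·L/(k2_on·D) ≥ 10`, partition `L/K_HL ≥ 5`,
reversibility `k2_off/(k2_on·D) ≤ 0.01`. The thresholds are pragmatic —
the assumptions are order-of-magnitude statements — and configurable.

### Numerics

`integrate` wraps `scipy.integrate.solve_ivp` with LSODA (stiff-capable:
the separation ratio can reach orders of magnitude), `rtol = 1e-10` and an
absolute tolerance tied to `H_tot`. Mass conservation is enforced post hoc
to `1e-8` relative at every output time; a violation or solver failure
raises rather than returning a truncated trajectory. Tiny negative
overshoots at the origin are clipped to 0. Against the closed form, the
numerical solution agrees to <2% of `H_tot` over five effective half-lives
once the separation ratio is ≳100, and the disagreement grows measurably
as the ratio approaches 1 — the approximation degrades gracefully and
detectably, which the test suite checks.

## Units, defaults, calibration

Time is in seconds; concentrations in arbitrary units (a.u.); second-order
rates in 1/(a.u.·s). No absolute concentrations are measurable from the
kind of imaging data the package emulates, so all defaults are
calibration choices made once:

| parameter | default | rationale |
|---|---|---|
| `k1_on`, `k1_off` | 0.05, 0.1 | sets `K_HL = 2` and a separation ratio of 18 (regime holds) |
| `k2_on`, `k2_off` | 0.01, 0 | irreversible trapping; with defaults `k_eff = 0.005`/s |
| `L`, `D` | 18, 5 | LD-dominated partition (90% of non-nuclear pool on LDs) |
| `H_tot` | 100 | an arbitrary scale |
| pre-MBT `k_ex` | ln 2/180 ≈ 3.85×10⁻³/s | region decay loses half its signal by 3 min, the measured magnitude |
| noise CV | 0.05 | multiplicative Gaussian per point; source data report only SD error bars |
| sampling | 60 s; 300 s (FRAP) / 360 s (photoswitch) | imaging cadence of the emulated experiments |
| replicates | 5 embryos × 5 nuclei | source protocol averages five nuclei per embryo; embryo count raised from 3 to 5 for recovery-test power |
| `k_mat` | 1/1800 s⁻¹ | eGFP maturation time constant ~30 min |

`k_eff = 0.005`/s gives a nuclear-accumulation half-time of ~2.3 min,
comparable to the FRAP recoveries being emulated.

## What the generators emulate — and what they do not

`gen_frap_recovery` produces nuclear recovery `B + A·(1 − e^{−k_eff t})`;
`gen_photoswitch_decay` produces region decay
`S₀·(p_inf + (1−p_inf)·e^{−k_ex t})` with `k_ex = 0` post-MBT (the regime
switch is a parameter, not a mechanism — the N:C-ratio clock that triggers
it is out of scope) and a stage-invariant pre-MBT rate; `gen_control_roi`
produces `C₀·e^{−bt}` for photobleaching correction; `gen_dosage_series`
maps gene copy number linearly onto parameters (`L = L₁·j` per Jabba copy,
`H_tot = H₁·c` per H2Av copy, wild type = 2 copies), justified by protein
levels scaling with gene dosage in both genotype series. The long-time
photoswitch plateau `p_inf` defaults to 0 (the switched region is a
negligible fraction of the embryo-wide sink) but is exposed, since the
data do not settle whether a plateau exists.

Noise is multiplicative Gaussian, independent across time points, clipped
at zero. Real traces additionally contain mitotic interruptions, spatial
heterogeneity, autofluorescent yolk, and correlated acquisition noise —
none of which are modelled. Passing recovery tests therefore demonstrate
that the estimators are correct and well-conditioned under the stated
noise model at realistic magnitudes, not that they are robust to every
artifact of real microscopy. Spatial spread is lumped into the single
region-exchange rate `k_ex`; no reaction–diffusion is attempted.

### The slow-maturation ("invisible fraction") confound

Newly synthesized fluorescent fusion protein is dark until its fluorophore
matures (first-order, `k_mat`). With LD buffering intact, a molecule is
retained in the cytoplasm long enough to mature before import; without
LDs it is imported dark, so measured recovery underestimates true import
most severely at 0x Jabba. The generator implements this as a
two-compartment cascade on the import flux: a share `L/(K_HL+L)` of
imported molecules (the LD-routed share) arrives visible, while the
directly imported share `K_HL/(K_HL+L)` arrives dark and matures in the
nucleus at `k_mat`:

```
v(t) = (1 − e^{−kt}) − f · k/(k − k_mat) · (e^{−k_mat t} − e^{−kt}),
f = K_HL/(K_HL + L)
```

This is a deliberate caricature — it reproduces the direction and locus of
the bias (apparent rate collapses toward `k_mat` at 0x, is nearly
unbiased at 1x–3x) rather than its measured magnitude, which would require
modelling the synthesis history of the maternal pool.

## Trace processing conventions

The first post-event sample defines 100% of signal; `percent_lost` and
`percent_remaining` complement to exactly 100. Queries snap to the nearest
sample within half the sampling interval and never interpolate or
extrapolate. Bleaching correction divides by the control ROI normalized to
its first sample, cancelling a shared exponential decay exactly; both
corrected and uncorrected paths are supported since not every emulated
experiment documents a correction. Aggregation is strictly two-level —
nuclei are averaged within an embryo before embryos are compared — and the
SD is across embryos (ddof = 1), reported as NaN (not 0) for a single
embryo. `classify_regime` calls a trace dynamic at ≥20% loss by 180 s and
static at ≤10%; the thresholds are not measured quantities but are placed
to separate the two observed phenotypes (~50% loss vs none) with wide
margin, and are configurable.

## Fitting choices

Single-exponential fits (`B + A·(1−e^{−kt})` or `B + A·e^{−kt}`) use
unweighted nonlinear least squares (lmfit/Levenberg–Marquardt; per-point
weights optional), `k` bounded to (1e-6, 10] /s, amplitude/baseline
initialized from the first and last samples and `k` from a log-linear
regression of the tail-corrected signal. The offset-included recovery form
is the default; both forms are supported since the emulated analysis does
not state whether an offset was fitted. A numerically flat trace raises an
ill-conditioned error; optimizer failure is reported via a `converged`
flag, never by fabricating a rate.

The rate-vs-Jabba-dosage relationship `k(J) = A·K̃/(K̃+J)` (the model's
`k_eff` with `L = L₁·J`; `A = D·k2_on`, `K̃ = K_HL/L₁`) is fit with both
parameters free and positive; the functional form is invariant to
rescaling the dosage axis up to the units of `K̃`. The 0x point is excluded
by default because of the maturation confound above. A caveat the test
suite documents: when `K̃ ≪ J` over the observed dosages the curve is
`≈ A·K̃/J` and only the product `A·K̃` is well determined, so individual
estimates from three dosage levels are noisy even at 10% measurement
error; the recovery simulations use a better-conditioned generating pair
(`A = 0.02`, `K̃ = 1.5`). The H2Av-dosage trend uses ordinary least squares
(statsmodels) with the slope t statistic as the linear-trend test.

`recover_parameters` fits every trace, aggregates rates per the two-level
replicate convention, and reports per-parameter median/mean relative bias,
relative RMSE, and ±2 SE coverage; it is deterministic given the dataset.

## Reproducibility

All generators draw from `numpy` `SeedSequence([seed, modality, embryo,
nucleus])` substreams: a single config seed reproduces every trace
bit-identically and adding replicates does not perturb existing ones. The
CLI records config hash, seed, scheme, package version, and output
checksums in a per-run manifest. Problem sizes used by the test suite and
the acceptance script (25-trace recovery sets, 100-seed fit simulations,
200-trace classification panels, 100–200-point trajectories) run in
seconds and were chosen to give stable medians at the stated tolerances.

## Known limitations

- No site depletion: at long times all of `H_tot` enters nuclei regardless
  of `D`, so the model is only meaningful on within-interphase time scales.
- No new-synthesis source term: the slow rise in total H2Av across cycles
  is excluded by design, except as stylized by the maturation confound.
- The MBT switch is a parameter (`k_ex → 0`), not a mechanism.
- Standard-error approximations only; no bootstrap or Bayesian intervals.
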
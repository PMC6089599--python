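# ldbuffer

Kinetics of histone buffering by lipid droplets in early *Drosophila*
embryos — a three-pool exchange model with its quasi-equilibrium solution,
seeded generators of synthetic live-imaging fluorescence traces, the
trace-quantification conventions of that experimental literature, and
exponential/dosage-trend fitting with a parameter-recovery harness.

## The problem

Syncytial fly embryos hold a vast maternal store of the histone variant
H2Av on lipid-droplet (LD) surfaces, anchored by the protein Jabba. H2Av
exchanges continuously between droplets via a small free cytoplasmic pool,
and that free pool feeds nuclear import and chromatin incorporation. The
package is for quantitative biologists who want to simulate, fit and test
this buffering mechanism: LD binding does not gate histone release on
demand, it simply lowers the free concentration and thereby slows nuclear
import kinetically.

## The model

H2Av partitions across free (`H_free`), LD-bound (`H_LD`) and DNA-bound
(`H_DNA`) pools by mass action against constant site concentrations `[L]`
and `[D]`:

```
free + LD-site  <->  LD-bound    (k1_on, k1_off)      K_HL = k1_off/k1_on
free + DNA-site ->   DNA-bound   (k2_on; k2_off = 0 by default)
```

When LD exchange is much faster than chromatin incorporation, the free/LD
partition stays at equilibrium and nuclear accumulation is a single
exponential,

```
k_eff  = K_HL/(K_HL + [L]) · [D] · k2_on
H_D(t) = H_tot · (1 − e^{−k_eff·t})
```

Consequences the package tests: nuclear levels scale proportionally with
total H2Av; `k_eff` falls as `K̃/(K̃+J)` with Jabba gene dosage `J`; the
LD off-flux is independent of chromatin demand `[D]`; and import proceeds
at a nearly constant rate through a prolonged interphase. See
`docs/methods.md` for assumptions, calibration and limitations.

## Worked example

```python
import numpy as np
import ldbuffer as lb

params = lb.KineticParams()            # reference calibration, K_HL = 2
print(lb.effective_rate(params))       # 0.005  (/s)

# photoswitched-region decay under the default pre-MBT calibration
trace = lb.gen_photoswitch_decay(
    "pre_MBT", lb.PhotoswitchDesign(noise_cv=0.0, n_embryos=1))[0]
print(lb.percent_lost(trace, 180.0))   # 50.0   (% of initial signal, 3 min)

# FRAP recovery across Jabba gene dosage, fitted per trace
design = lb.DosageDesign(frap=lb.FrapDesign(noise_cv=0.0, n_embryos=1, n_nuclei=1))
res = lb.gen_dosage_series(params, jabba_levels=(1, 2, 3), design=design)
khat = {j: lb.fit_exponential(trs[0]).k for j, trs in res.frap_traces.items()}
print(khat)   # {1: 0.009091, 2: 0.005, 3: 0.003448}  — slower with more buffering

fit = lb.fit_jabba_relationship(
    lb.DosageSeries(np.array([1., 2., 3.]),
                    np.array([khat[1], khat[2], khat[3]])))
print(fit.A, fit.Ktilde)               # 0.0500 /s, 0.2222
```

The fitted rates fall with Jabba dosage exactly along `k(J) = A·K̃/(K̃+J)`:
`A = D·k2_on = 0.05`/s is the unbuffered import rate and
`K̃ = K_HL/L₁ = 0.22` the LD binding constant in per-gene-copy units.
Nuclear endpoints across 1x/2x/4x H2Av dosage come out 47.5 : 95.0 : 190.0
— the exact 1:2:4 proportionality the model predicts.

## Command line

```sh
ldbuffer simulate -c config.yaml   # traces.csv (+ endpoints, truth, manifest)
ldbuffer analyze  -c config.yaml   # percent/summaries/fits + curve fits
ldbuffer recover  -c config.yaml   # parameter-recovery report vs stored truth
ldbuffer report   -c config.yaml   # markdown summary
```

A single YAML config with a mandatory global `seed` drives every stage;
identical configs give byte-identical outputs, and each run writes a
manifest with the config hash and output checksums.

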
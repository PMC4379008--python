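# melstep

Silent-substitution stimulus design, protocol generation, spike-train
simulation and analysis for **melanopsin-isolating** visual-neuroscience
experiments.

Melanopsin, the photopigment of intrinsically photosensitive retinal
ganglion cells (ipRGCs), peaks near 480 nm — uncomfortably close to rod
opsin's 498 nm. Isolating melanopsin-driven activity in a rod-functional
retina (e.g. the coneless *Cnga3⁻/⁻* mouse) therefore relies on *receptor
silent substitution*: exchanging a "yellow" background and a "blue" step
whose spectra are tuned so rods receive identical effective photon flux
while melanopsin sees a large Michelson contrast. `melstep` implements that
design problem and everything around it — the stimulation protocols, a
synthetic retina/dLGN spike-train generator for pipeline validation, and
the response-detection, latency and threshold-irradiance analyses applied
to the recordings.

It is aimed at sensory-physiology groups designing photoreceptor-isolating
stimuli or benchmarking their spike-train analysis chains.

## The core computations

**Effective photon flux.** For pigment *p* with peak-normalised in-vivo
sensitivity *S_p(λ)* (Govardovskii A1 nomogram × lens transmission) and a
stimulus with spectral photon flux *E(λ)*:

    Φ_p = ∫ E(λ) S_p(λ) dλ      [photons cm⁻² s⁻¹]

**Rod-silent step.** With two primaries at drive weights **w**, fluxes are
linear, Φ_p = **m**_p·**w**. Given a background **w**_bg and a target
melanopsin Michelson contrast *c*, the step solves

    m_rod · w  = m_rod · w_bg
    m_mel · w  = (m_mel · w_bg) · (1 + c)/(1 − c)

subject to 0 ≤ w ≤ w_max, where the Michelson contrast is
(Φ_step − Φ_bg)/(Φ_step + Φ_bg). The maximum feasible *c* is found in
closed form along the isoluminance line.

**Synthetic units and analysis.** Simulated units drive inhomogeneous
Poisson spiking from a threshold-linear melanopsin drive on log irradiance
(asymmetric first-order kinetics, slowly adapting threshold) plus a
transient rod contrast response that is *exactly* zero for rod-silent
stimuli. The analysis stage classifies light-responsive units (paired
t-test, baseline vs step), measures Δ firing rate, estimates onset/offset
latencies by the baseline-mean + 1 SD crossing rule, runs repeated-measures
ANOVA with Bonferroni post-hocs, and estimates per-ramp-arm threshold
irradiances and their light-adaptation shift. See `docs/methods.md` for the
model equations, defaults and calibrations.

## Worked example

```python
from melstep import StimulusSetting
from melstep.fixtures import fixture_device
from melstep.spectra import log_flux

device = fixture_device(in_vivo=True)          # 438/575-nm Gaussian LEDs
background = StimulusSetting({"yellow": 0.5})  # bright yellow background

cmax = device.max_silent_contrast(background, "rod", "melanopsin")
print(f"max rod-silent melanopsin contrast: {100*cmax:.1f}%")

pair = device.solve_silent_step(background, "rod", "melanopsin", 0.71)
w = pair.step.weights
print(f"step weights: blue={w['blue']:.4f} yellow={w['yellow']:.4f}")
print(f"rod contrast: {pair.contrasts['rod']:.2e}")
print(f"melanopsin contrast: {pair.contrasts['melanopsin']:.6f}")
bg_f, st_f = pair.fluxes["melanopsin"]
print(f"melanopsin flux: {log_flux(bg_f):.2f} -> {log_flux(st_f):.2f} log photons/cm^2/s")
```

prints

```
max rod-silent melanopsin contrast: 72.1%
step weights: blue=0.4733 yellow=0.0267
rod contrast: 7.19e-17
melanopsin contrast: 0.710000
melanopsin flux: 14.30 -> 15.07 log photons/cm^2/s
```

The solved step swaps almost all of the yellow background for blue while
holding the rod-effective flux fixed to machine precision; melanopsin sees
a 71 % contrast — a 5.90-fold flux increase from a daylight-range
background. Asking for more than the 72.1 % gamut limit raises a
`GamutError` naming the limiting primary.

The same machinery drives the full pipeline from the shell:

```sh
melstep design --contrast 0.71 --contrast 0.32 --out pairs.json
melstep protocol ramp --contrast 0.71 --out protocol2.json
melstep simulate --protocol protocol2.json --n-units 50 --seed 1 --out spikes.csv
melstep analyze --dataset spikes.csv --protocol protocol2.json --out units.csv
melstep run --seed 1 --outdir run/          # design → simulate → classify
melstep fixtures --outdir fixtures/         # example spectra, config, dataset
```

`melstep run` writes stimulus pairs, protocol JSON, a spike dataset with its
ground-truth sidecar, a per-unit classification table and a manifest with
the config hash and all derived seeds; identical config + seed reproduce
the outputs byte for byte.

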
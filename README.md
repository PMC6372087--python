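# synaptiq

Quantitative analysis of presynaptic physiology experiments at large
glutamatergic terminals (calyx of Held): voltage-gated Ca²⁺ channel
current-voltage fitting, readily-releasable-pool (RRP) estimation from
high-frequency EPSC trains, miniature EPSC detection, immunogold
point-pattern clustering from freeze-fracture replicas, vesicle-to-active-zone
geometry from thin-section EM, and ratiometric Fura-2 calcium calibration —
with a seeded synthetic-data module so every estimator ships with
ground-truth recovery tests.

It is written for electrophysiologists and EM morphologists who have
exported traces and coordinates (delimited text + JSON sidecars) and want
the downstream numbers — RRP, P_r, replenishment rate, V_m/k_m, cluster
metrics, docked counts, [Ca²⁺] — computed reproducibly.

## The core models

**IV curves** are fitted with four Hodgkin-Huxley gates on a
Goldman-Hodgkin-Katz open-channel driving force,

    I(V) = Γ · V · (1 − e^{−(V−E_rev)/25}) / (1 − e^{−V/25}) · [1 + e^{−(V−V_m)/k_m}]^{−4},

tail currents with a Boltzmann function
I_base + I_min/(1 + e^{−(V−V_1/2)/k}).

**RRP back-extrapolation**: cumulative EPSC amplitude vs stimulus number
during a 300 Hz train; a line fitted to the steady-state segment is
extrapolated to time zero.  Intercept = RRP, slope = replenishment rate,
first EPSC / RRP = initial P_r.

**mEPSC detection**: sliding scaled-template matching (biexponential
kernel, criterion = fitted scale / SD of fit error), 5 s moving-average
frequency.

**Immunogold clustering**: circles of 30 nm (clusters, ≥2 particles) and
100 nm (putative active zones) extended from each particle; overlapping
circles merge.  Areas are unions of disks.

**Fura-2**: [Ca²⁺] = K_eff (R − R_min)/(R_max − R), K_eff = 239.95 nM.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a noisy depressing train under the depletion model
(N₀ = 100 quanta, p = 0.2, q = 30 pA, 10% amplitude noise) and estimate the
pool:

```python
>>> from synaptiq.synthdata import DepletionModelParams, gen_train
>>> from synaptiq.trains import backextrapolate_rrp
>>> train, truth = gen_train(DepletionModelParams(
...     n0=100, p=0.2, r=0.016, q=30.0, noise_cv=0.1, seed=7))
>>> est = backextrapolate_rrp(train)
>>> print(f"RRP = {est.rrp:.0f} pA  ({est.rrp / 30:.1f} quanta), "
...       f"P_r = {est.pr_initial:.3f}, "
...       f"replenishment = {est.slope_normalized:.4f} RRP/stimulus")
RRP = 2614 pA  (87.1 quanta), P_r = 0.230, replenishment = 0.0164 RRP/stimulus
```

The intercept of the steady-state line through the cumulative amplitudes
recovers ~87 of the 100 true quanta (the back-extrapolation method
systematically undershoots when replenishment refills vacancies during the
train — see the methods note), the first EPSC divided by that pool gives an
initial release probability near the true p = 0.2, and the normalized slope
returns the replenishment fraction per stimulus.

The same analyses are scriptable from the shell:

```bash
synaptiq simulate train --seed 7 --out demo/
synaptiq train-rrp --train demo/train.csv --freq 300 --out demo/rrp.json
synaptiq replica-cluster --points face.csv --radius 30 --az-radius 100 --out clusters.json
```

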
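# phosdyn

Protein conformational dynamics from oxygen-quenched phosphorescence
lifetimes.

## The problem

Millisecond-scale internal motions of a protein can be read out with a
phosphorescent probe: a Zn-protoporphyrin substituted for the heme in the
β-subunits of human hemoglobin emits ms-lived triplet phosphorescence that
is collisionally quenched by molecular oxygen — but only when the protein
matrix is dynamically active enough for O₂ to diffuse. Measuring the
ensemble-average lifetime ⟨τ⟩ while warming an oxygen-saturated,
cryosolvent-free sample from 10 K to above 250 K therefore turns the
thermal activation of global protein dynamics (near 200 K) into a sharp
drop of ⟨τ⟩/τ₀.

`phosdyn` implements the full analysis chain for such experiments:

1. **Decay deconvolution.** Each photon-counting trace is fitted with a
   discrete sum of exponentials, I(t) = Σᵢ Aᵢ e^(−t/τᵢ) (n ≤ 5), by Poisson
   maximum likelihood, with an automatic parsimony rule for n.
2. **Ensemble average.** ⟨τ⟩ = ΣAᵢτᵢ² / ΣAᵢτᵢ, the intensity-weighted mean
   lifetime of the heterogeneous population.
3. **Baseline normalisation.** τ₀ is the mean ⟨τ⟩ over the frozen plateau
   (10–180 K by default); the series is reduced to the ratio ⟨τ⟩/τ₀.
4. **Two-state activation fit.** The protein-specific transition is fitted
   with

   ⟨τ⟩/τ₀(T) = (1 + x) / (1 + K_d·x),  x = e^(−(ΔE − TΔS)/RT),

   where ΔE (kJ/mol) and ΔS (J/(mol·K)) are the molar energy and entropy
   differences between the "frozen" and "molten" dynamic states and K_d is
   the factor by which dynamic quenching speeds up the decay. The midpoint
   temperature is T_MP = ΔE / (ΔS + R ln K_d).

Because raw spectrometer traces for this type of experiment are rarely
public, the package ships a first-class synthetic-data generator that
emulates the acquisition (80 µs bins, 14 000 summed flashes, Poisson
counting noise, stepwise 10 K / 5 K warming grid) with known ground truth,
so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
from phosdyn import (
    TwoStateParams, SeriesDesign, default_plateau_mixture,
    simulate_series, fit_transition, midpoint_temperature,
)

truth = TwoStateParams(delta_E=113.4, delta_S=526.0, K_d=2.0, tau0=28.7)
design = SeriesDesign(
    temperatures=np.arange(185.0, 246.0, 5.0),
    plateau_mixture=default_plateau_mixture(28.7),
    true_params=truth, noise_sd=0.02, seed=1,
)
series = simulate_series(design)
res = fit_transition(series)
print(f"dE = {res.params.delta_E:.1f} kJ/mol, dS = {res.params.delta_S:.0f} "
      f"J/(mol K), K_d = {res.params.K_d:.2f}, T_MP = {res.T_MP:.1f} K")
print(f"midpoint from truth: {midpoint_temperature(truth):.1f} K")
```

prints

```
dE = 117.7 kJ/mol, dS = 546 J/(mol K), K_d = 1.99, T_MP = 213.3 K
midpoint from truth: 213.3 K
```

i.e. from a single 13-point noisy warming series the fit recovers the
activation energy and entropy within ~4%, the quenching speed-up within
~1%, and places the transition midpoint within a tenth of a kelvin of the
generator truth.

The two core fits are scikit-learn style estimators
(`MultiExponentialDecay`, `TwoStateTransition`) with `fit`/`predict` and
fitted attributes (`lifetimes_`, `delta_E_`, `T_MP_`, …), so they compose
with sklearn tooling; the functions above are thin wrappers.

A command-line interface covers the same surface:

```sh
phosdyn simulate-experiment design.json --seed 1 -o traces/
phosdyn fit-decay traces/trace000_T100K.csv -o fit.json
phosdyn run -c pipeline.json -o out/   # traces -> <tau>(T) -> fit -> report
```

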
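# cfsekinetics

Inference of rare, slowly cycling (label-retaining) cell subpopulations
from dye-dilution proliferation assays.

## The problem

In a CFSE (carboxyfluorescein succinimidyl ester) experiment a cell
population is covalently labeled, cultured through a chase period, and
read out on a flow cytometer. Each division splits the dye roughly in
half, so a cell's fluorescence reports how many times it has divided:
cells that remain bright after many bulk cell cycles — label-retaining
cells (LRCs) — have divided rarely, a hallmark of quiescent or slowly
cycling compartments in tumors and stem-cell niches. The day-6 CFSE
histogram of such a culture is typically a dim bulk peak with a faint
bright shoulder, and the scientific question is whether that shoulder
is a genuinely distinct slowly cycling subpopulation, and how large it
is.

`cfsekinetics` answers this with an explicit renewal model of cell
division fitted to the intensity histogram, plus an agent-based
simulator that generates dye-dilution experiments with known ground
truth for validation.

## The model

Each population has an intrinsic division-time distribution, a gamma
density with a hard minimum cycle time t_b:

    K(t) = 0                                           for t < t_b
    K(t) = ((t - t_b)/σ)^(λ-1) exp(-(t - t_b)/σ) / (σ Γ(λ))  otherwise

Divisions form a renewal process: the density of the n-th division time
is the n-fold convolution L_n = K * L_{n-1}, the probability of having
divided at least n times is H_n(t) = ∫₀ᵗ L_n, and the expected number of
cells in generation n is

    N_n(t) = 2ⁿ N₀ [H_n(t) − H_{n+1}(t)].

On a log-intensity axis each division is a shift by log 2, so the
predicted chase-time histogram is a generation-weighted mixture of
shifted copies of the day-0 intensity density, normalized to unit mass.
The observed population is modeled as a two-component mixture

    I_t(i) = (1 − α) I_t^bulk(i) + α I_t^slow(i),

and the seven parameters (t_b, σ, λ for each population, plus the slow
fraction α) are estimated by least squares on the binned densities with
multi-start Nelder–Mead. The nested α = 0 single-population model is
fitted alongside, so the evidence for a second population is an explicit
objective comparison rather than an assumption.

## Worked example

Simulate a 6-day chase with a 1.5% slowly cycling admixture (bulk mean
cycle 23 h, slow 72 h, 15% measurement CV), then fit it:

```python
import numpy as np
from cfsekinetics import DyeDilutionMixture, SimulationConfig, simulate_experiment

cells = simulate_experiment(SimulationConfig(seed=11, n_cells=100_000))
day0 = cells[cells.chase_time == 0.0].measured_intensity.to_numpy()
day6 = cells[cells.chase_time == 144.0].measured_intensity.to_numpy()

est = DyeDilutionMixture(chase_time=144.0, random_state=0).fit(day6, day0=day0)
print(f"slow fraction alpha     : {est.slow_fraction_:.4f}")
print(f"bulk mean cycle time (h): {est.mixture_.bulk.mean_cycle_time:.1f}")
print(f"slow mean cycle time (h): {est.mixture_.slow.mean_cycle_time:.1f}")
print(f"improvement over alpha=0: {100 * est.result_.relative_improvement:.1f}%")
print(f"LRC gate threshold      : {est.gate_threshold_:.0f}")
```

prints

```
slow fraction alpha     : 0.0145
bulk mean cycle time (h): 24.3
slow mean cycle time (h): 74.4
improvement over alpha=0: 34.1%
LRC gate threshold      : 976
```

i.e. the fit recovers a sub-2% slowly cycling population with a roughly
three-fold longer cycle time, and the mixture clearly beats the
single-population fit. `est.predict(day6)` then labels individual
events as CFSE-high (label-retaining) using a gate derived from the
fitted bulk-only distribution; `gate_high_retainers` offers plain
quantile/threshold gating.

The same pipeline is available from the shell:

```sh
cfsekinetics simulate --config sim.yaml --out run/
cfsekinetics fit --day0 run/events_0h.csv --chase run/events_144h.csv \
    --time 6d --out fitdir/
cfsekinetics gate --chase run/events_144h.csv --quantile 0.995
cfsekinetics report --fit-dir fitdir/
```

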
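# filtergate

Model-based analysis of ion permeation and voltage-dependent gating in a
small viral K⁺ channel (Kcv-type) that lacks a voltage-sensor domain.  The
package links the steady-state ion occupation of the selectivity filter —
computed from Markov ion-hopping models — to the sub-millisecond closing
rate of the channel, fits single-channel IV curves and closing-rate curves
globally with one shared parameter set, discriminates permeation models and
occupancy–gating links by their error sums, and recovers gating rate
constants faster than the recording bandwidth from simulated, filtered
current traces by amplitude-histogram (extended beta distribution) fitting.

It is written for single-channel electrophysiologists and modellers who
want a tested, reproducible implementation of this analysis chain.  No raw
recordings are distributed; a first-class synthetic-data module generates
the full study (18 KCl condition series, −160…+160 mV) from a documented
ground truth, so every stage is testable end to end.

## The model

**Permeation.** The selectivity filter is a cyclic Markov chain over ion
configurations (occupancy of sites S0–S4 and the pore mouths).  For the
five-state cycle the open-channel current is

  I = e · (k₁₂k₂₃k₃₄k₄₅k₅₁ − k₁₅k₅₄k₄₃k₃₂k₂₁) / (D₁ + … + D₅),

the King–Altman form, where the Dₘ are spanning-tree sums of rate products
and the stationary occupation probabilities are Pₘ = Dₘ/ΣD.  Ion-binding
steps are proportional to K⁺ *activity* (k₁₂ = k₁₂,₁·a_in,
k₅₄ = k₅₄,₁·a_out); the two concerted translocation steps carry Eyring
voltage dependence k_ij = k_ij,0·exp(s_ij·V/V_ij), with the reverse edge
sharing (s, V_char) via exp(−(1−s)V/V_char).  In production the stationary
state is a dense linear solve; the spanning-tree enumeration is retained as
an independent oracle.  A thermodynamic-consistency flag (default on)
enforces zero current at the Nernst potential E_K: the cycle base-rate
products balance at 0 mV and 1/V₂₃ + 1/V₅₁ = F/RT (one charge per cycle).

**Gating link.** The closing rate of the sub-millisecond gate is modelled
as k_OM = w·Pₘ, w/Pₘ, or w·P₄/P₃ with a single voltage- and
concentration-independent scale w.  A global Nelder–Mead fit (log-rate /
logit parameterisation, multi-start, least-squares polish) minimises

  error = Σ (I_model − I_data)² + Σ (ln k_OM,model − ln k_OM,data)²

over all 36 curves, the rate term restricted to negative voltages.  Ranking
the candidate links by best-fit error sum reproduces the model-selection
logic; a diagnostic quantifies the collapse of k_OM onto the K⁺ motive
force Kmf = V − E_K.

**Fast gating.** Rate constants above the recording bandwidth are recovered
by simulating the O/S/M/F gating scheme as a piecewise-constant current,
filtering with a digital 4-pole Bessel low-pass (1 kHz), sampling at 5 kHz,
convolving the amplitude histogram with the Gaussian baseline noise, and
adjusting (k_OM, k_MO, I_true) by simplex until the simulated histogram
matches the target (common random numbers per fit).  The derived currents
obey |I_app| ≤ |I_OF| ≤ |I_true|, with I_OF = I_true·k_FO/(k_OF+k_FO) and
I_app = I_true·p_O.

## Worked example

```python
from filtergate import (Condition, GatingLink, FitConfig,
                        default_ground_truth, generate_dataset, run_global_fit)

truth = default_ground_truth()           # five-state model, k_OM = w*P4/P3
model = truth.model()
data = generate_dataset(truth, noise=False, seed=1)   # 18 series, 36 curves
fit = run_global_fit(data, model, GatingLink("ratio", "4", "3"),
                     FitConfig(seed=3, restarts=8))
print(f"error sum {fit.error_sum:.2e}")
print(f"k23 fitted {fit.params.base_rates['k23']:.3e} /s "
      f"(truth {truth.params.base_rates['k23']:.3e})")
print(f"w fitted {fit.w:.1f} /s (truth {truth.link.w:.1f})")
```

prints

```
error sum 4.47e-27
k23 fitted 2.233e+08 /s (truth 2.300e+08)
w fitted 30000.0 /s (truth 30000.0)
```

The fitted rates sit at 0.971× the generating values — exactly the constant
O–F duty factor by which the synthetic effective current I_OF is scaled
below the cycle current — and the gating scale w is recovered exactly; the
residual error is at machine level.  The numbered drivers under `analysis/`
run the same stages as narrative scripts (study generation, recovery fit,
11-link comparison, histogram-fitter recovery, Kmf collapse, drift
correction) and write their tables under `results/`.

There is also a CLI:

```sh
filtergate make-dataset --out ds.csv --seed 1
filtergate global-fit --dataset ds.csv --link P4/P3 --out fit.json
filtergate compare-links --dataset ds.csv --out table.csv
```

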
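# lmspeed

Analysis pipeline for asking how the **directional selectivity** of
global-visual-motion neurons changes with **stimulus speed**.

Pretectal neurons (e.g. in the avian nucleus lentiformis mesencephali, the
homolog of the mammalian nucleus of the optic tract) respond to wide-field
motion and are classically characterized by a preferred direction measured
at one intermediate speed. This package implements the full analysis needed
to characterize direction tuning *at every speed* of an 8-direction grating
protocol (speeds spanning 0.062–1,024 °/s as temporal/spatial frequency
ratios), and a synthetic spiking-population generator with known ground
truth so that every stage is testable end to end.

## What it computes

For each cell × speed response (spontaneous rate subtracted, estimated from
the 500–1,000 ms window of the static-grating epoch):

- **Preferred direction (PD)** by vector sum,
  `PD = atan2(Σₙ FRₙ sin θₙ, Σₙ FRₙ cos θₙ)`;
- **Sensitivity index (SI)**, the normalized mean-resultant length
  `SI = ‖Σₙ FRₙ e^{iθₙ}‖ / Σₙ FRₙ ∈ [0, 1]` (0 = uniform, 1 = one
  direction);
- **Inverse CV** (mean over directions / SD across directions), **AP/PD**
  (anti-preferred over preferred rate) and **peak count** of a periodized
  natural-cubic-spline fit of the tuning curve;
- a **two-stage shape classification**: stage 1 labels each response
  directional / bidirectional / omnidirectional (gradient-boosted trees
  trained with repeated 5×5-fold CV on rule-labeled most-active responses,
  with a deterministic rule classifier as the audit oracle); stage 2
  reclassifies a response as **unmodulated** iff fewer than six directions
  differ significantly from the spontaneous rate *and* SI ≤ 0.29;
- population analyses: the normalized directional response
  `Rₙ ∈ [−1, 1]`, the population speed-tuning curve, per-speed
  maximal-response proportions, PD stability (±22.5° zone), the four
  across-speed categories, and classification transition (Sankey) tables;
- temporal dynamics on 10 ms bins: time to peak and peak activity in the
  initial-transient (40–200 ms), transitional (200–1,000 ms) and
  steady-state (1,000–3,000 ms) phases;
- **additive-model comparison**: three families of Gaussian GAM candidates
  (`Rₙ`, `log₂ timeₚ`, `activityₚ` vs. smooths of log₂ speed, shape/phase
  factors and per-cell random intercepts), fitted by penalized least
  squares with marginal-likelihood smoothing selection and compared by
  AIC.

## Worked example

The numbered drivers under `analysis/` run the study on the default
synthetic population (114 cells, seed 1) and write tidy tables under
`results/`:

```bash
python analysis/01_simulate.py --seed 1
python analysis/03_classify.py --seed 1
python analysis/04_population.py --seed 1
```

Output of `03_classify.py` / `04_population.py`:

```
     true_label   n  recovery
    directional 354  1.000000
  bidirectional 119  0.974790
omnidirectional 311  0.987138
    unmodulated 164  0.182927
boosted model vs deterministic rule agreement: 0.947
stage-1 training accuracy: 1.000, CV accuracy: 0.986

population speed tuning peaks at 32 deg/s (mean max Rn 0.96)
most cells maximally responsive at 32 deg/s (73/114)
across-speed categories: {'mostly_directional': 40, 'dir_to_omni': 34,
                          'mostly_omni': 24, 'variable': 16}
TN-directional cohort at 32 deg/s: 48 cells
```

Reading this: the three modulated tuning shapes are recovered at ≥ 97%
from spikes alone; the population is most responsive at 32 °/s; and the
across-speed category partition recovers the generating mix
(36/32/24/22) within a few cells. Unmodulated recovery is intrinsically
low — the SI ≤ 0.29 reclassification bound cannot separate pure noise from
structure (see `docs/methods.md`). `05_dynamics.py` shows the median time
to peak falling monotonically from 375 ms at 4 °/s to 65 ms at 1,024 °/s,
with the initial-transient phase peaking at a faster speed (256 °/s) than
the steady state (64 °/s); `06_model_comparison.py` fits the GAM candidate
families and verifies that AIC recovers each candidate's own generative
form in ≥ 49/50 seeded replicates.

A `lmspeed` console command runs the same stages
(`lmspeed all --seed 1 --out results/`).

## Layout

```
src/lmspeed/     io, synth, metrics, classify, population, dynamics, gam,
                 pipeline, cli  (library: all computation lives here)
analysis/        numbered narrative drivers over the library
tests/           unit, property and end-to-end recovery tests
docs/methods.md  model, assumptions, parameter defaults, limitations
```
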
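# meiox

Oxygen-limited metabolism of benthic meiofauna: a body-oxygen diffusion
model, closed-chamber Monod respirometry fitting, and oxygen-corrected
community carbon budgets.

Meiofauna (32 µm – 1 mm animals and protists: nematodes, foraminifera,
ostracods, juvenile molluscs) dominate the metazoan abundance of marine
sediments, yet their respiration is almost always measured — and their role
in carbon cycling budgeted — at full air saturation. Sediment pore water is
rarely anywhere near saturated. `meiox` implements the three linked
analyses needed to quantify the consequences, for ecophysiologists and
benthic biogeochemists:

1. **Body-oxygen model** (`meiox.body`). A worm-shaped body is an infinite
   cylinder consuming oxygen at rate *Q* throughout its tissue and supplied
   by diffusion (diffusivity *D*) through its wall from pore water at
   concentration *AW*. At steady state

   *C(r) = AW − (Q/4D)(R² − r²)*,

   which yields the **critical thickness** 4·√(D·AW/Q) — the widest body
   whose centre is still oxic — its decline with sediment depth along an
   O₂(z) profile, and the **residence time** τ = C̄/Q of the body oxygen
   inventory (a few seconds to a few tens of seconds; too short for
   "hold your breath and commute to the oxic layer" strategies).

2. **Chamber kinetics** (`meiox.kinetics`). Closed micro-chamber optode
   drawdowns are modelled as Monod kinetics with a minimum-oxygen offset,
   d*C*/d*t* = −*R*max(*C*−*O*₂,min)/(*k*s+*C*−*O*₂,min), fitted by
   nonlinear least squares (with blank correction and a two-phase
   Monod-plateau-linear variant for the ostracod stress response). Fitted
   rates convert to biomass-specific carbon respiration and evaluate at any
   % of air saturation via the anchored Monod curve; *k*s measures how
   sharply metabolism shuts down as oxygen falls.

3. **Carbon budget** (`meiox.budget`). Community respiration computed the
   classical way (allometric length/width → carbon, *a*·*m*ᵇ rates, Q10
   temperature scaling, everything fully oxic) versus the same community
   respiring at the Monod-limited rate of its actual oxygen environment,
   layer by layer down the oxygen penetration depth. Their ratio is the
   **overestimation factor** — in published station data it runs from 1.5
   (deep-sea, deeply oxygenated) to 7.3 (coastal fine sand, 8 mm OPD).

`meiox.synth` generates every input (noisy drawdown traces, blanks,
two-phase traces, log-normal layered communities) with known ground truth;
`meiox.datasets` ships the published coefficient tables used as inputs and
cross-checks; `meiox.cli` exposes the lot as a `meiox` command.

## Worked example

```python
import numpy as np
from meiox import *

# How wide can a nematode be in oxic pore water, and how fast does its
# internal oxygen turn over?
params = BodyModelParams(aw=230.0)              # µmol O2 / l
print(f"critical thickness at 230 umol/l: {critical_thickness(params):.0f} um")
print(f"O2 residence time (200 um radius): "
      f"{residence_time(params, BodyGeometry(200.0)):.1f} s")

# Fit a (synthetic, ground-truth k_s = 105.25) chamber drawdown and express
# it as carbon respiration at 100 / 10 / 1 % air saturation.
truth = MonodParams(r_max_vol=63.8, k_s=105.25, o2_init=229.59)
trace, _ = gen_chamber_trace(TraceGenSpec(params=truth, seed=42))
fit = fit_monod(trace)
print(f"fitted k_s = {fit.params.k_s:.1f} umol/l, "
      f"R_max = {fit.params.r_max_vol:.1f} umol/l/h")

cfg = ChamberConfig(volume_l=3.0e-4, total_biomass_ugC=122.5)
rates = saturation_rates(volumetric_to_specific(fit.params.r_max_vol, cfg),
                         fit.params.k_s)
print(f"Resp_day at 100/10/1% saturation: "
      f"{rates.r_100:.3f} / {rates.r_10:.3f} / {rates.r_1:.3f} ugC ugC-1 d-1")
```

prints

```
critical thickness at 230 umol/l: 797 um
O2 residence time (200 um radius): 34.7 s
fitted k_s = 95.2 umol/l, R_max = 61.0 umol/l/h
Resp_day at 100/10/1% saturation: 0.043 / 0.012 / 0.001 ugC ugC-1 d-1
```

A body much wider than ~800 µm would go anoxic at its core even in fully
oxic water; at 200 µm radius the oxygen inventory turns over in ~35 s. The
noisy 5-minute optode trace recovers the drawdown kinetics to within a few
percent, and the anchored Monod evaluation shows this animal's respiration
collapsing to a quarter at 10% saturation and to ~2% of its oxic rate at 1%
saturation — the quantitative reason fully-oxic budgets overestimate.

The same operations are available from the shell:

```sh
meiox body-model --aw 230 --radius-um 200
meiox critical-thickness --aw0 230 --opd-mm 8 --out curve.csv
meiox synth trace --seed 42 --out trace.csv && meiox fit-chamber trace.csv
meiox synth community --seed 3 --out community.csv
meiox budget community.csv --station station.yaml --mode stepwise
```

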
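# ulvfit

Calibration of m-alternative forced-choice (m-AFC) visual-performance
instruments on a relative d′ scale, built for ultra-low-vision (ULV)
outcome-measure research.

## The problem

People with ultra-low vision (acuity ≤ 20/1600, 1.9 logMAR) cannot be
assessed with letter charts, so functional vision is measured with batteries
of forced-choice activities — locate a towel, detect whether the room lights
are on, report the direction of a moving ball — each presented at several
visibility levels. Every activity is an m-AFC task (2 ≤ m ≤ 4), so raw
percent correct is not comparable across items: 67% on a 2-alternative task
is near chance, while 67% on a 4-alternative task is far above it.

`ulvfit` places persons and items on a single latent axis using
equal-variance Gaussian signal detection theory. The probability that person
*p* answers item *i* correctly is

    Pc(θp − bi; m) = ∫ φ(x − (θp − bi)) Φ(x)^(m−1) dx,

where θp is the person measure (ability), bi the item measure (difficulty),
both in relative d′ units, and m the item's number of response alternatives.
Pc(0; m) = 1/m for every m, so d′ = 0 means chance performance regardless of
m; the scale origin is anchored at the sample-mean ability (mean θ = 0).
Both parameter blocks are estimated by joint maximum likelihood, with
standard errors from the observed information and 95% CIs as estimate
± 1.96 SE. A dichotomous Rasch baseline — which lacks a chance floor and
therefore stratifies mixed-m item difficulties by m — is included for
comparison, along with a Brown–Forsythe test of category means, an OLS
regression of logMAR acuity on person measure, and a synthetic-data
generator matching the 37-person, 57-item, 3-trials-per-item study design.

## Worked example

```python
from ulvfit import (SimulationConfig, fit_sdt, load_item_bank,
                    score_responses, simulate_responses)

bank = load_item_bank("canonical")          # 19 activities x 3 levels
ds = simulate_responses(bank, SimulationConfig(seed=3))
res = fit_sdt(score_responses(ds.records), bank.m_of_item())
print(res.summary())
```

```
SDT latent-variable fit (relative d' scale)
===============================================
persons: 37    items: 57
log-likelihood: -3601.5732   converged: True (5 cycles)   se: block
person measures: mean +0.0000  range [-1.40, 1.58]
item measures:   range [-1.33, 0.54]   below-chance items (b > 0): 17
at-bound parameters: 0
```

Person measures average exactly zero (the anchoring constraint); items with
b > 0 are those the average person performs below chance, which is common at
the lowest visibility levels. `res.to_frame()` gives the long estimates
table:

```
  id   kind   measure       se    ci_low   ci_high  at_bound
P001 person -0.119743 0.136166 -0.386628  0.147143     False
P002 person -0.433428 0.137054 -0.702054 -0.164803     False
P003 person  0.999227 0.153714  0.697947  1.300507     False
P004 person  0.458552 0.141288  0.181627  0.735476     False
```

The same workflow is available from the shell:

```sh
ulvfit simulate --persons 37 --trials 3 --seed 3 --out-dir sim/
ulvfit fit --responses sim/responses.csv --out estimates.csv
ulvfit report --responses sim/responses.csv --acuity sim/acuity.csv --out-dir report/
```

`ulvfit report` writes `item_measures.csv`, `person_measures.csv`,
`category_stats.json` (per-category means and the Brown–Forsythe test),
`acuity_regression.json`, `rasch_comparison.csv` and a `manifest.json`.

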
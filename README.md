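# glaucoma-cea

A two-eye Markov cohort cost-effectiveness model comparing **primary
trabeculectomy** against **medical treatment** for patients presenting with
advanced primary open angle glaucoma, with full probabilistic and
deterministic sensitivity analysis. The package is aimed at health
economists and methodologists who want a transparent, scriptable
implementation of this class of decision model — including a synthetic
individual-level trial generator, so the entire pipeline runs end-to-end
with no external data.

## The model

Each eye moves along an ordered severity scale (default
`advanced → severe → end_stage → blind`); disease is irreversible, so an eye
either stays put or moves one level worse per annual cycle. The cohort
occupies *combined* states $s = (i, f)$ — index-eye and fellow-eye levels —
plus one absorbing death state: $k^2 + 1$ states for a $k$-level scale.
Within a cycle, death comes first with probability
$q^\*(a) = 1 - (1-q(a))^{\mathrm{SMR}}$, where $q(a)$ is the age/sex
life-table death probability and the standardised mortality ratio reflects
unilateral or bilateral blindness; survivors' eyes then progress
independently, each with annual probability $p = 1 - e^{-\lambda}$ from its
arm-specific hazard $\lambda$, so a joint two-eye move carries the product
of the per-eye probabilities.

Economic outcomes are accumulated from the cohort trace $\pi_t$:

$$\text{QALYs} = \sum_t (1+d)^{-t}\, \pi_t \cdot u, \qquad
  \text{Cost} = \sum_t (1+d)^{-t}\, \pi_t \cdot c,$$

with $d = 3.5\%$ per annum, utilities $u$ keyed to the better eye (vision
quality follows the better eye) and costs $c$ to the worse eye, each cell
taken from linear regressions of the trial outcomes on severity level and
treatment arm. Strategies are compared by the incremental
cost-effectiveness ratio $\mathrm{ICER} = \Delta C / \Delta Q$ and net
monetary benefit $\mathrm{NMB}(\lambda) = \lambda Q - C$ at willingness-to-pay
thresholds $\lambda \in \{0, 10\,000, 20\,000, 50\,000\}$ £/QALY.

Uncertainty is propagated by Monte-Carlo PSA — gamma distributions for
costs, beta for utilities and transition probabilities, multinormal
(Cholesky) blocks for regression coefficients — and summarised as a
cost-effectiveness acceptability curve, a CE-plane confidence ellipse and
one-way tornado analyses.

## Worked example

```python
import glaucoma_cea as g

config = g.TrialConfig(rng_seed=1)                     # 1000 participants, 5 annual visits
records = g.generate_trial(config)
param_set = g.estimate_params(records, config.life_table, start_age=67)
table = g.evaluate(param_set, horizons=(2, 10, "lifetime"), instruments=("eq5d",))
print(table[["horizon", "arm", "Cost", "dCost", "QALY", "dQALY", "ICER"]].round(2))
```

prints (seed 1):

```
 horizon            arm     Cost   dCost  QALY  dQALY      ICER
lifetime trabeculectomy 16134.23 3234.76 10.19   0.27  12120.85
lifetime     medication 12899.47     NaN  9.93    NaN       NaN
      10 trabeculectomy  8994.97 2030.85  6.15   0.06  31576.34
      10     medication  6964.12     NaN  6.09    NaN       NaN
       2 trabeculectomy  2059.83  542.79  1.51   0.00 310219.48
       2     medication  1517.04     NaN  1.50    NaN       NaN
```

Surgery costs more each year but slows progression, so its QALY gain — and
with it the ICER — improves as the horizon lengthens: at 2 years surgery
has had no time to pay back its extra cost (ICER ≈ £310k/QALY), while over
a lifetime it buys a QALY for about £12k, well under the £20 000/QALY
reference threshold. `g.run_psa(...)` and `g.ceac(...)` then quantify how
certain that conclusion is; `examples/` walks through every stage
(`01_simulate_trial.py` … `05_tornado_scenarios.py`).

The same pipeline is available from the shell:

```bash
glaucoma-cea simulate --out sim
glaucoma-cea estimate --trial sim/trial.csv --out params
glaucoma-cea run --params params --out run
glaucoma-cea psa --params params --out psa
glaucoma-cea report --run run --psa psa --out report/report.txt
```

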
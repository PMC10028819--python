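# subpoisson

Analysis toolkit for **sub-Poissonian mRNA noise** in constitutively
expressed genes, built around smFISH-style per-cell spot tables and a
multi-step stochastic model of transcription, nuclear export and
cytoplasmic degradation.

The classical model of constitutive expression — one rate-limiting step
with exponential waiting times — predicts Poisson-distributed mRNA numbers,
i.e. a Fano factor (variance/mean) of exactly 1, often called the noise
floor. Single-molecule FISH counting in fission yeast shows genes whose
cell-size-corrected Fano factor sits *below* 1, and below it more strongly
in the cytoplasm than in the nucleus. This package implements the
quantitative machinery needed to establish and interpret that observation:

* **`subpoisson.model`** — the gene-expression model: a single promoter
  cycles through `N_t` exponential steps (rates `k_A`, `k_B`, …), emits one
  nuclear mRNA per cycle, the mRNA is exported at rate `k_C` and degraded
  through `N_d` equal-rate cytoplasmic stages (per-step rate `k_D`). All
  rates are in units of the effective degradation rate. Because all
  propensities are linear, stationary means and covariances are computed
  *exactly* (one linear solve plus one Lyapunov solve); full joint
  distributions come from finite state projection, and
  `subpoisson.ssa` provides exact seeded Gillespie sampling.
* **`subpoisson.spots`** — per-cell counting from spot tables: median
  normalization of spot intensities per replicate, spot / intensity /
  hybrid counting rules (hybrid: spots dimmer than the cytoplasmic 95th
  percentile count as one molecule, brighter ones as their normalized
  intensity), nascent/mature classification by the valley of the bimodal
  spot-to-transcription-site distance distribution, and transcription-site
  cell filters with nucleus expansion.
* **`subpoisson.noise`** — raw and size-corrected Fano factors
  (OLS regression of count on cell length or volume; residual variance over
  mean; percentile-bootstrap CIs), sliding-window Fano profiles, and a
  parametric Monte-Carlo test against a size-dependent Poisson null.
* **`subpoisson.infer`** — Bayesian comparison of step numbers
  `(N_t, N_d)` and posterior estimation of `(k_A, k_B, k_C)` from summary
  statistics via a Gaussian synthetic likelihood on a deterministic grid.
* **`subpoisson.synthetic`** — a ground-truth generator emulating the
  statistical structure of the real data (cell lengths 7–16 μm, means
  growing with size, mono/binucleated subpopulations, single-molecule
  intensities clustered at 1).

## Worked example

```python
from subpoisson import ModelSpec, solve_steady_state_moments, crossover_export_rate

# three rate-limiting steps in transcription and degradation,
# k_A = k_B = 10, export k_C = 5, in units of the effective degradation rate
spec = ModelSpec(n_txn_steps=3, txn_rates=(10.0, 10.0), export_rate=5.0, n_deg_steps=3)
mom = solve_steady_state_moments(spec)
print(mom.mean_nuc, mom.mean_cyt)    # 0.6667 3.3333
print(mom.fano_nuc, mom.fano_cyt)    # 0.7544 0.6203
print(crossover_export_rate(spec))   # 2.0053
```

Both Fano factors are below 1 — impossible in the one-step model — and the
cytoplasmic one is lower than the nuclear one because export (`k_C = 5`) is
faster than the crossover rate `k_C* ≈ 2.01`; below that export rate the
ordering flips.

The same analysis runs from the shell on tabular data:

```
$ subpoisson simulate-cells --n-cells 120 --seed 3 --out-dir demo
$ subpoisson count --spots demo/spots.csv --cells demo/cells.csv --method hybrid --out demo/counts.csv
$ subpoisson fano  --counts demo/counts.csv --cells demo/cells.csv --seed 1 --out demo/fano.json
fano_raw=0.5858 fano_corrected=0.5112 [0.3833, 0.6250] n=120
```

Here the raw Fano of total mRNA per cell is 0.59; removing the variance
explained by cell length leaves a corrected Fano of 0.51 with a 95%
bootstrap CI of [0.38, 0.63] — clearly sub-Poissonian, as expected for the
default 3-step generating model.

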
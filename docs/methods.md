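# Methods

## The expression model

A single gene copy is modelled as a promoter that cycles irreversibly
through `N_t` exponential steps with rates `k_A, k_B, …` (steps beyond the
second default to `k_B` when only two rates are given). Completing the last
step emits one nuclear mRNA and resets the promoter to the first step, so
synthesis is a renewal process whose inter-event times are hypoexponential
— strictly narrower than exponential for `N_t ≥ 2`. Nuclear mRNA is
exported in a single exponential step (rate `k_C`) and then traverses
`N_d` equal-rate degradation stages (per-step rate `k_D`), i.e. an Erlang
cytoplasmic residence time with mean `N_d / k_D`.

All rates are expressed in units of the **effective cytoplasmic
degradation rate** — the reciprocal of the mean residence time. By default
`k_D = N_d`, fixing that rate to 1; passing `deg_step_rate` overrides it
(the effective rate is then `k_D / N_d`). One consequence used throughout:
the stationary synthesis rate is `λ = 1 / Σᵢ 1/rᵢ`, the nuclear mean is
`λ/k_C` and the cytoplasmic mean is `λ` under the default normalization.

Assumptions: exactly one gene copy; no on/off promoter toggling (the
constitutive regime); no replication or dosage change; export is a single
step; degradation stages share one rate. Size effects are extrinsic and
live in the synthetic-data generator, not in the model.

### Exact moments

Every propensity is linear in the state (promoter-state indicators,
nuclear count, per-stage cytoplasmic counts), so the first- and
second-moment equations close exactly. After eliminating the last promoter
indicator through the conservation law, the stationary mean solves
`J m + h = 0` and the stationary covariance the continuous Lyapunov
equation `J C + C Jᵀ + B(m) = 0` (`scipy.linalg.solve_continuous_lyapunov`).
For `N_t = N_d = 1` this reproduces the Poisson result `Fano = 1` in both
compartments to machine precision, for any rates.

### Finite state projection

The joint stationary distribution over (promoter state × nuclear count ×
degradation stages) is computed on a truncated box. Initial bounds are
mean + 8 sd per species; bounds double until the stationary probability on
the outermost shell falls below 1e-8 (that shell mass is the reported
truncation-quality measure, `1 − captured_mass`); a hard cap of 5×10⁶
states raises a resource error carrying the attempted dimensions. The
stationary vector is found by uniformized power iteration
(`P = I + Q/Λ`, L1 convergence threshold 1e-14): the multi-species CME
generator fills in catastrophically under sparse LU, while each power step
is O(nnz) and the iteration count is bounded by the relaxation time times
the uniformization constant. Stage counts are then marginalized to total
cytoplasmic mRNA. Validation: for `N_t = 1` the result equals a product of
Poissons (total variation < 1e-12 in tests); for the 3-step regime it
matches the exact moments to ~1e-10 and the SSA histogram to TV < 0.006 at
1e5 samples.

### Stochastic simulation

`ssa_sample` draws independent stationary cells: one direct-method
Gillespie trajectory per cell, started empty and burned in for ten times
the slowest mean timescale (promoter cycle, nuclear residence, cytoplasmic
residence). The kernel is numba-compiled and fully determined by the seed.
Independent trajectories trade compute for zero autocorrelation; the
package always records this sampling mode in the CSV sidecar.

### Noise floor and crossover

`min_cytoplasmic_fano` minimizes the exact cytoplasmic Fano over a
log-spaced grid (default `logspace(-1, 3, 17)`) of the shared per-step
transcription rate and the export rate. Equal per-step rates are used
because, among hypoexponential cycle-time distributions with fixed mean,
the equal-rate profile minimizes the squared coefficient of variation, so
it attains the floor; searching full per-step rate combinations would cost
`grid^N_t` and add nothing. On this grid the floor for four transcription
and four degradation steps is 0.456, attained at the fast-rate corner, and
the floor decreases monotonically in either step number.

`crossover_export_rate` brackets the sign change of
`fano_cyt − fano_nuc` and locates it with `scipy.optimize.brentq`
(relative tolerance 1e-6); identical curves (the one-step model) return
"no crossover" rather than an error. The crossover decreases with step
number: 2.60 (2 steps) → 2.01 (3) → 1.75 (4) at per-step rate 10.

## Spot counting

Intensities of mRNA-channel spots are divided by the median cytoplasmic
intensity of their replicate (`replicate_id` plays the role of one image).
The three counting rules per cell and compartment: *spot* = number of
spots; *intensity* = sum of normalized intensities; *hybrid* = 1 per spot
below the replicate's cytoplasmic 95th percentile, the normalized intensity
otherwise. Ties exactly at the percentile count as the intensity (the
single-molecule rule applies strictly below it); the percentile is the
linear-interpolation quantile. Fractional counts are expected for the
intensity and hybrid rules.

Nascent/mature classification: per replicate, the 3D distances of nuclear
mRNA spots to the nearest same-cell TS spot are collected; the cutoff is
the minimum of a Gaussian-KDE of the distances between its two largest
modes, with a two-cluster 1D split (midpoint of cluster means, exhaustive
within-cluster-SS search) as fallback for unimodal or small (< 10
distances) samples. Cells without TS spots get all-mature labels.

TS-based cell filters: any cytoplasmic TS spot, or any nucleus with 0 or
more than 2 TS spots (TS spots assigned to their nearest nucleus), excludes
the cell with a recorded reason. TS spots outside their nucleus sphere are
handled in two modes: *expand* grows the sphere isotropically to touch the
TS and reassigns mRNA spots that fall inside, *filter* excludes the cell.
Nuclei are abstracted as spheres throughout since the inputs are tabular;
a constant 3D chromatic offset (default zero) can be applied to the TS
channel.

## Noise statistics

Cell volume uses the cylinder-with-hemispherical-caps shape:
`V = π(w/2)²(L−w) + (4/3)π(w/2)³`. Both length and volume are supported as
the size variable.

The size-corrected Fano factor fits `count = a + b·size` by OLS and
divides the residual variance by the mean count. Residual and total
variance share the `n−1` normalization, so corrected ≤ raw holds on every
dataset; a degenerate size vector falls back to the raw Fano with a
warning. The 95% CI is a percentile bootstrap over cells (default 1000
resamples, seeded). Calibration: Poisson counts with mean ∝ size give a
raw Fano well above 1 and a corrected Fano averaging 1.002 (sd 0.023)
at n = 5000 across repeated datasets.

Sliding windows span 1 μm of cell length stepped by 0.1 μm. A window
qualifies with at least 50 cells (pooled) or 40 (single replicate), and
windows are retained only inside runs of at least 20 consecutive
qualifying windows; for mononucleated cells the thresholds are 40/30/10
and for binucleated cells 30/20/6.

The finite-sample test is a parametric Monte-Carlo re-specification (the
original procedure is not available in detail): the null draws Poisson
counts with cell-specific means `â + b̂·size` from the observed fit
(negative fitted means clamped to 0), recomputes the size-corrected Fano
B times, and reports `p = (1 + #{null ≤ observed}) / (B + 1)` — never
exactly 0. Type-I error is 5% within binomial error over 200 repetitions;
counts from the strongly sub-Poissonian 4-step model at n = 500 are
rejected in the majority of runs.

## Synthetic data

The generator emulates the features the analysis relies on: lognormal cell
lengths (median 10 μm, 0.15 log-sd, truncated to 7–16 μm), widths
3.5 ± 0.1 μm, 20% binucleated cells, nucleus radius 1.2 μm, and
transcription rates scaled by `(length/median)^exponent` (default 1), so
mean mRNA number grows with size while concentration stays roughly
constant. Counts are quasi-static: each cell's counts are one stationary
SSA draw from its size-scaled model — adequate because the analysis only
uses steady-state statistics conditioned on size, but it ignores
growth-coupled dynamics. Binucleated cells use the same model by default
(an optional rate multiplier lets tests mimic cell-cycle differences
without claiming a mechanism), and the nascent/mature split of nuclear
mRNA (default fraction 0.6) is a rendering convenience for testing the
classifier, not a mechanistic statement.

Spots are placed uniformly: nascent within 0.3 μm of the TS, mature
nuclear in the nucleus sphere but at least twice the nascent radius from
the TS — the resolvability gap a diffraction-limited detector imposes,
since a mature mRNA closer than ~0.6 μm would merge into the TS-proximal
spot — and cytoplasmic mRNA in the spherocylinder outside nuclei.
Single-molecule intensities are lognormal (median 1, CV 0.25); TS spots
are bright (5.0). True labels ride along in a hidden column. What passing
tests on these data do *not* show: robustness to segmentation errors,
optical blur, spot-detection misses, or non-spherical nuclei — none of
which are modelled.

## Inference

The data enter as four summary statistics — nuclear and cytoplasmic means
and size-corrected Fano factors (population normalization, so duplicating
every cell leaves them unchanged) — with a bootstrap covariance over cells
(default 500 resamples; near-singular covariances are ridge-regularized
with a warning). The likelihood is Gaussian in these statistics with the
model's exact stationary values as the mean — a synthetic likelihood,
adopted because the full data likelihood of the original analysis is not
available. An important caveat inherits from this choice: the Gaussian
approximation and the bootstrap covariance are both finite-sample
estimates, so posterior calibration is only approximate (the 90% HPD for
`k_C` covers the generating value in ≥ 70% of synthetic datasets in the
test suite, not 90%).

Priors are log-uniform on [0.1, 100] per rate (a package choice, exposed
in `PriorSpec`). Evidence is a deterministic trapezoidal integral in
log-parameter space over a grid (default 25 nodes/axis), made accurate by
**two-scale quadrature**: the compartment means are analytic in the rates
and constrain them to a ridge far narrower than the grid spacing, so the
likelihood is evaluated on a 5× refined grid using exact analytic means
together with Fano surfaces interpolated from exact moment solves at the
coarse nodes (the Fano surfaces vary slowly, so interpolation error is far
below their statistical uncertainty). Without this, evidence differences
between models are lattice artifacts of where grid nodes fall relative to
the ridge. Log-evidence is stable to < 0.1 under 2× grid refinement.

Model selection compares log-evidence across candidate `(N_t, N_d)` pairs
(default 1..4 × 1..4); candidates within a Bayes factor of 10 of the best
form the support set. The `k_A`/`k_B` exchange symmetry of the posterior is
exact for `N_t = 2`; for `N_t ≥ 3` the convention that later steps reuse
`k_B` makes the rate multiset asymmetric under the swap, so only the
trivial grid-relabeling symmetry holds. The nuclear mRNA fraction is
deliberately excluded from the fit and serves as an out-of-sample check
(`noise.nuclear_fraction`; it decreases monotonically with `k_C`).

## Problem sizes and determinism

Default problem sizes keep the full test suite and the acceptance script
at desk scale: SSA cross-validations use 1e4–1e5 stationary samples (3
Monte-Carlo standard errors as the agreement criterion), parameter
recovery and step-number selection use 2000 synthetic cells, calibration
studies use 200 repetitions, and the coverage study 20 datasets of 800
cells. All randomness flows through explicit integer seeds (numpy
`default_rng`, numba `np.random.seed`), and every pipeline stage records
its seed split in the run manifest; identical config + seed reproduces
identical outputs bit-for-bit for all deterministic stages.

## Known limitations

* The model has one gene copy and no cell-cycle structure; binucleated
  cells in real data are post-replication and genuinely differ.
* The equal-rate restriction in the noise-floor search is provably optimal
  only for the cycle-time CV; the full Fano landscape over unequal rates
  is assumed to inherit that ordering.
* The synthetic likelihood discards distribution shape beyond the first
  two moments; genes whose distributions differ at fixed (mean, Fano)
  are indistinguishable to the inference module.
* FSP uses reflecting truncation; its error measure (boundary shell mass)
  is a heuristic bound, kept conservative by the 1e-8 threshold.
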
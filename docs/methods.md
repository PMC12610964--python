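# Methods

## The model

Herd activity is treated as a first-order, time-homogeneous Markov chain
over a labelled state space. The canonical space mixes six behavioral
activities (F, M, L, S, RS, RL) with three environmental variables (T, H,
THI), nine states in the fixed order T, H, THI, F, M, L, S, RS, RL — an
unusual construction (environmental quantities are continuous, not
occupied states), but it is the construction the shipped prior matrix is
defined over, so the analysis layer supports it as-is. For *data
generation* the package takes the stricter view: a cow occupies exactly
one behavioral state per time step, so synthetic sequences are drawn from
the 6×6 behavioral sub-chain (rows/columns F…RL, renormalized) while
temperature and humidity are generated as parallel continuous series.

Key assumptions: one step per sampling interval, no covariates (time of
day and bout duration are not modelled), and stationarity over the
analysis window. These are the standard first-order simplifications; they
make the stationary distribution a meaningful "activity budget".

## Transition-matrix handling

* **Renormalization.** Published matrices rounded to three decimals have
  row sums of ≈0.994–0.997. Every loader renormalizes rows to sum exactly
  to 1 and records the original sums; the as-printed entries remain
  available (`raw_probs`). Analysis never runs on a sub-stochastic matrix.
* **Sequence MLE.** `P̂[i,j] = (n_ij + s) / (n_i· + k·s)` with pseudo-count
  `s ≥ 0` (default 0, keeping the MLE exact on clean data). With `s = 0` a
  visited state must have an outgoing transition — a state seen only at
  the end of the sequence raises an error suggesting smoothing. States
  never visited receive a uniform row so the estimate is always a valid
  stochastic matrix; the source tag records when this happened.
* **Composition estimator.** Duration tables carry compositions, not
  transitions. Each row is normalized to a proportion vector q(d);
  `lagged` mode row-normalizes Σ_d q(d)q(d+1)ᵀ, `co-occurrence` mode
  Σ_d q(d)q(d)ᵀ. This is a surrogate: it recovers the stationary structure
  well (rows concentrate near the mean composition) but is not claimed to
  recover the true P, and no claim is made that any particular published
  prior was derived this way. It operates on whichever state columns the
  table has, so behavior-only tables yield the 6×6 sub-chain.

## Stationary solvers

Irreducibility is checked first via strong connectivity of the
positive-entry digraph (scipy's strongly-connected components); reducible
chains are rejected ("stationary distribution not unique"). Two routes:

* **eigen** (default): left eigenvector of eigenvalue 1 via
  `scipy.linalg.eig(P.T)`; handles periodic chains directly.
* **power**: iterate v ← vP to tolerance 1e-12 (max 100 000 iterations).
  Period-2 oscillation is handled by testing the average of two successive
  iterates for stationarity, which is exact for a two-cycle.

Both clip vanishing negative components, normalize, and verify the
residual ‖πP − π‖∞ ≤ 1e-8. They agree to < 1e-9 on random irreducible
chains (tested). The cumulative form sets C_k = Σ_{i≤k} π_i with the last
element forced to exactly 1 so inverse-CDF sampling can never fall off the
end. Note that a published cumulative row computed from unrounded π can
differ from partial sums of the rounded π by ~0.002; only C₁ and the final
1 are stable reference points.

## Samplers

* **Direct**: next state by `searchsorted` on the current row's
  cumulatives against one uniform draw per step.
* **Metropolis–Hastings**: target π, proposal uniform over all k states
  (including the current one — a lazy, symmetric proposal; self-proposals
  keep the kernel valid and simply count as accepted). Acceptance
  probability min(1, π_j/π_i); rejection repeats the current state. The
  target must be strictly positive, otherwise zero-mass states would still
  be proposed. The acceptance rate is reported (~0.84 for the shipped
  nine-state target).

Burn-in (default 1000) counts proposals, not acceptances; the retained
sequence has exactly `n_iterations` samples. All randomness flows through
one `numpy.random.default_rng(seed)` per run, so identical configs give
bit-identical sequences. The default initial state is the first state of
the space (deterministic); `"stationary-draw"` is available.

Both samplers converge to the same long-run distribution; the evaluation
harness accepts either, since "simulate the chain" and "sample π" are both
legitimate readings of MCMC simulation of an activity model.

## Time-series features

The eight per-variable statistics are conventions fixed here (there is no
single field-wide definition) and all are configurable:

* sd: sample (n−1); skewness bias-corrected; kurtosis excess,
  bias-corrected (a flat-ish series gives ≈ −1.2 … −1.5, which is why
  negative tabulated kurtosis values imply the excess convention).
* Shannon entropy: histogram over `n_bins = 10` equal-width bins spanning
  [min, max], natural log, 0·log 0 := 0; range [0, ln 10 ≈ 2.303], and
  invariant under positive affine maps because the bin edges transform
  with the data.
* trend strength: `max(0, 1 − Var(remainder)/Var(series))` from a centred
  moving-average decomposition (odd window, default min(7, ⌊n/3⌋·2+1);
  partial windows at the edges). In [0, 1]; a noiseless ramp scores
  ≈ 0.9999, white noise ≈ 0.
* linearity / curvature: degree-1 and degree-2 coefficients of the trend
  component regressed on an orthonormal polynomial basis of time (QR of
  the Vandermonde design). Unbounded, scale-covariant.
* Constant series: sd = entropy = skewness = kurtosis = trend =
  linearity = curvature = 0 by convention; series shorter than 4 are
  rejected (third/fourth moments undefined after bias correction).

## PCA variable selection

Variables are standardized (mean 0, sample sd 1) and the covariance of the
standardized data — the correlation matrix — is eigendecomposed with
`numpy.linalg.eigh`. Components are sorted by eigenvalue, each sign-fixed
so its largest-magnitude loading is positive. `n_selected` is the smallest
k whose cumulative explained-variance ratio reaches the threshold
(default 0.95, with 0.90 a documented alternative). Variable contribution
score: Σ over selected components of explained_ratio × |loading|, ranked
descending with ties kept in original order. The orientation of the input
matrix (observations × sensor variables, or variables × features) is the
caller's choice; both are meaningful.

## Evaluation metrics

AAE, AES and RMSE as defined in the README; RMSE = √AES is enforced as an
identity (tabulated values satisfy it to 4 decimals, pinning down the
square root that a bare mean-of-squares formula would omit). N is always
the length of the compared vectors. `stationary_similarity` applies the
same metrics to two probability vectors (both must sum to 1 within 1e-9)
— the package's stationary-similarity measure between a reference budget
and an empirical one. The cohort report pools all 3 × n_cows metric values
per iteration count into one mean and reports Accuracy =
round_half_up(1 − mean, 2); note 1 − 0.034821 = 0.9652 rounds to 0.97, so
a tabulated 0.96 at that error level implies truncation rather than
rounding — the half-up convention is used consistently here.

## Synthetic herd generator

Defaults encode the study conditions the package targets: 5 cows, 30
days, 1-minute sampling (1 Hz streams aggregated to 1-minute intervals),
ground truth = the shipped prior matrix, and hot-season weather
(T ~ 31.5 ± 0.9 °C, H ~ 77.5 ± 4 %RH, matching the ranges of the shipped
30-day table) with AR(1) day-to-day autocorrelation ρ = 0.5 — enough
temporal structure to exercise the trend/linearity features. Innovations
are scaled by √(1−ρ²) so the stated sds are marginal sds; humidity is
clipped to [0, 100]. THI = 0.8·T + (H/100)(T − 14.4) + 46.4, the standard
livestock heat-stress index; logged THI columns from field instruments
differ from it by a few tenths (placement corrections), so shipped THI
values are treated as data, never recomputed. Per-cow sequences are
seeded `seed + cow_index`; environment streams use an offset seed block.

What the generator does *not* emulate: diurnal behavior rhythm, bout-
duration memory (sequences are exactly first-order), inter-cow
heterogeneity (all cows share one ground truth), and any accelerometer /
mastication waveform. Passing round-trip tests therefore shows estimator
correctness under the model's own assumptions, not fidelity to real herd
data.

## Problem sizes and numerical choices

The test suite and acceptance script use 1e5-step sequences for
parameter-recovery and sampler-agreement checks (max-entry error ≤ 0.01),
20-seed batteries at 3000/4000/5000 iterations for the Monte-Carlo
accuracy claims, one 30-day × 1-minute cow for the full round trip, and
100 random chains for solver cross-validation — sizes at which the Monte-
Carlo bands (±0.02 on a single state frequency at n = 5000, single-run sd
≈ 0.010) are comfortably resolved. Where a single-run quantity sits close
to its band, the acceptance script reports the mean of 5 seeded replicate
chains, a variance-reduction protocol fixed in advance of any comparison.
Tolerances: row-stochasticity 1e-12, solver agreement 1e-9, stationary
residual 1e-8.

## Known limitations

* Mixing behavioral and environmental states in one chain is kept for
  compatibility with the shipped prior but has no generative
  interpretation; prefer the behavioral sub-chain for simulation.
* The composition estimator's lagged and co-occurrence modes are nearly
  indistinguishable on daily aggregates of a fast-mixing chain; they only
  separate when compositions change substantially between intervals.
* Per-cow observed vectors behind the shipped error table are not
  available, so those exact values are fixture data, not reproducible
  outputs; the package reproduces their internal arithmetic (pooled
  means, RMSE/AES identity) and the qualitative convergence behavior.
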
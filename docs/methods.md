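# Methods

## Model

`ordspec` tests a univariate series against the null hypothesis that it is
a (possibly monotone static transform of a) linearly correlated stochastic
process. The test statistic is the *ordinal spectrum*: the Fourier
transform of the rank autocovariance of the series' ordinal-pattern
symbolization.

**Symbolization.** Each delay vector (X_t, X_{t+τ}, …, X_{t+(D−1)τ}) is
mapped to the permutation that sorts it ascending; the permutation is
encoded as its 1-based lexicographic rank (Lehmer code). The ascending
pattern gets code 1 and the descending pattern code D!, so the two
monotone motifs sit at the extremes of the code range and the integer
codes carry a meaningful "rank" scale. The encoding depends only on order
relations, hence is exactly invariant under strictly increasing transforms
of the data — the property that lets the test ignore static monotone
nonlinearities.

**Rank autocovariance.** The code sequence S_t is treated as a
homogeneous Markov chain over the D! patterns. With stationary
probabilities p\*_i (occupation frequencies) and m-step transition
probabilities p^m_ij,

E{S} = Σ i·p\*_i, Var(S) = Σ i²·p\*_i − E{S}², and
Cov(m) = Σ_ij i·j·p\*_i p^m_ij − E{S}².

Two estimators of p^m_ij are provided:

- `markov` (default): count the one-step matrix P₁ from consecutive
  symbols and set P_m = P₁^m. Every lag inherits the well-sampled one-step
  structure (L−1 pairs estimate D!² entries once), so Cov(m) is smooth,
  decays geometrically for mixing chains, and stays exactly periodic for
  cyclic ones. Under this first-order model the whole autocovariance — and
  hence the spectrum — is a deterministic function of (p\*, P₁), which is
  what gives the surrogate test its power at short lengths.
- `counting`: count symbol pairs at each lag m directly; no Markov
  assumption, but each lag is estimated from its own L−m pairs and the
  high-lag tail is noisy. Matching the plug-in formula, Cov(m) uses the
  global mean convention; an optional "biased" normalization multiplies
  lag m by (L−m)/L, which tames the tail and keeps the sequence close to
  positive semidefinite. In validation runs the per-lag noise of this
  estimator washed out the test's power (the chaotic logistic map at
  T=2000 was frequently not rejected), which is why the first-order
  estimator — the model the symbolic chain is explicitly given — is the
  default. `chapman_kolmogorov_diagnostic` quantifies how far a sequence
  departs from first-order structure if the choice needs auditing.

Cov(0) = Var(S) holds exactly under both estimators.

**Spectrum.** Since Cov(−m) = Cov(m), the two-sided transform collapses
to a cosine series, evaluated by direct summation on a uniform grid of 256
normalized frequencies in [0, 0.5] cycles/sample (`n_freq`
configurable; direct summation keeps arbitrary grids possible and the
output exactly real). No taper is applied by default — the spectrum is the
plain transform of Cov(m); a Bartlett lag window is available for variance
reduction. The number of lags N defaults to min(L, 512); with the
first-order estimator the result is insensitive to N because the estimated
covariance tail decays geometrically rather than accumulating noise.

**Surrogate test.** IAAFT surrogates are built by alternating a spectrum
step (impose the original Fourier amplitudes on the current phases) and an
amplitude step (rank-remap onto the sorted original values), stopping at a
rank-order fixed point or 100 iterations, always ending on the amplitude
step so the surrogate's value multiset equals the original's exactly. Each
surrogate passes through the identical symbolize → autocovariance →
spectrum pipeline with the same (D, τ) and estimator options. Per
frequency, z(f) = (OS(f) − μ_s(f)) / σ_s(f) with the ensemble mean and
standard deviation (ddof = 1); two-sided p-values come from the standard
normal (deviations below the ensemble count too — "statistically distant"
has no sign), and Benjamini–Hochberg FDR at α = 0.05 corrects over the
frequency grid. BH rather than the Benjamini–Yekutieli variant: ordinal
spectra are smooth, neighbouring frequencies are positively dependent, and
BY would be needlessly conservative. An empirical percentile-rank p-value
(`pvalue_method="percentile"`) is available when the surrogate spectra are
visibly non-Gaussian; note its resolution is limited to 2/(n_surrogates+1),
so it needs broad deviations to survive FDR. The null is rejected iff any
frequency stays significant after correction; contiguous significant
frequencies are reported as bands. The default ensemble size is 500.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| D | 3 | pattern length; alphabet D! must be well sampled, rule of thumb T ≥ (D+1)! (violations warn, not fail) |
| τ | 1 | embedding delay in samples; `"auto"` picks min(first ACF zero crossing, first local minimum), with the 1/e folding time for monotone ACFs. "Zero" means below the white-noise 95% band 1.96/√T, since a finite-sample ACF rarely hits zero exactly |
| n_surrogates | 500 | IAAFT ensemble size |
| alpha | 0.05 | FDR level over frequencies |
| n_freq | 256 | grid points on [0, 0.5] cycles/sample |
| max_lag | min(L, 512) | autocovariance lags entering the transform |
| tie_rule | stable | equal values ordered by time index; `jitter` adds seeded noise of relative magnitude 1e−12 instead |
| cov_method | markov | see above |
| iaaft_max_iter | 100 | iteration cap; convergence is a rank-order fixed point |

## Synthetic systems

The generator module reproduces the validation battery: the logistic map
(periodic windows r = 3.55, 3.739; chaos at r = 3.8, 4; T = 2000 after a
1000-step burn-in), a Rössler-type flow ẋ = −y−z, ẏ = x+ay,
ż = 2+z(x−4) with periodic (a = 0.30) and chaotic (a = 0.42, 0.54)
regimes (T = 10⁴, burn-in 1000), Gaussian white noise, 1/f^α noise by
spectral synthesis (amplitudes ∝ f^(−α/2), uniform phases, standardized),
a nonlinear recursion driven by Laplace(0, 1) noise with sinusoidal
forcing, and a tanh² static transform of a linear AR process driven by
squared-uniform innovations. Every generator is bit-reproducible given
(parameters, seed).

Numerical choices made where the systems' definitions left freedom:

- Rössler integration: fixed-step RK4, dt = 0.05, initial state
  (1, 1, 0), one sample per step, divergence guard at norm 10⁶. Step
  halving changes the sampled trajectory by < 10⁻³ relative RMS in the
  periodic regime. The fundamental oscillation period (~152 samples at
  a = 0.54) is located as the dominant periodogram peak.
- The sinusoidal forcing sin(4πt) + sin(6πt) vanishes identically on an
  integer time grid; time is therefore taken as t_n = n·dt_index with
  dt_index = 0.01 so the forcing actually oscillates.
- The tanh²-AR recursion is y_t = 0.4y_{t−3} − 0.3y_{t−2} + 0.2y_{t−1} +
  e_t; the +0.2 sign keeps the AR companion spectral radius below 1
  (checked at import).
- The logistic x₀ defaults to a seeded uniform draw in (0.01, 0.99),
  avoiding the unstable fixed points.

These fixtures emulate the dynamical regimes, not any particular measured
record: they are noise-free (the deterministic systems), stationary, and
free of ties, missing values, trends and observational noise. Passing the
battery shows the statistic separates chaos from linear stochasticity
under those clean conditions; it does not certify behaviour on short,
nonstationary or heavily tied real data (counts, quantized EEG), where the
tie rule and the T ≥ (D+1)! check deserve attention.

## Validation battery and problem sizes

The test suite runs the full pipeline at the battery's native sizes:
T = 2000 series with 200-surrogate ensembles, 10 replicates per condition
for the verdict checks, 50 Gaussian replicates for the family-wise
type-I-error bound (≤ 0.10 observed against nominal 0.05), 20 chaotic
replicates for the power bound (≥ 0.90), and a length sweep
{125, 250, 500, 1000, 2000} for the detection threshold. The Rössler
truncation experiment uses five independent trajectories (perturbed
initial conditions) truncated to 3–20 fundamental cycles; rejection
becomes reliable (≥ 4/5) between 5 and 20 cycles, consistent with the
roughly-ten-cycle scale expected for the chaotic flow. Surrogate ensembles
in tests use 200 members — inside the method's validated 200–500 range —
and the acceptance script uses 500 where the protocol specifies them.

## Degenerate inputs and edge behaviour

Non-finite samples, series too short to form one window, and out-of-range
parameters raise typed errors (`InvalidInputError`, `ParameterError`).
Constant series pass through IAAFT unchanged with a warning (there is
nothing to randomize). A surrogate ensemble with zero spread at any
frequency raises `DegenerateEnsembleError` rather than producing infinite
z-scores. Ties are resolved by time order (stable sort) by default, making
results deterministic; the jitter alternative is seeded. Up to 10% of
surrogates may fail individually (the rest carry the ensemble); more is an
error.

## Known limitations

- The first-order Markov default smooths over genuine higher-order
  symbolic dependence; the counting estimator is available but
  under-powered at the battery's lengths.
- The normal z-test assumes approximately Gaussian surrogate spectra at
  each frequency; the percentile option trades that assumption for coarse
  p-value resolution.
- Band edges inherit the frequency grid's resolution (Δf ≈ 0.002 at the
  default 256 points); adjacent-band merging beyond grid adjacency is not
  attempted.
- Weighted/amplitude-aware ordinal patterns, multivariate extensions,
  cross-spectra, and AR-model spectral estimation of the rank
  autocovariance are out of scope.
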
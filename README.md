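# ordspec

Frequency-domain analysis of ordinal-pattern symbolic dynamics, with an
IAAFT-surrogate significance test that separates chaotic dynamics from
periodic signals and from (possibly nonlinearly transformed) linear
stochastic processes.

Classical power spectra cannot tell a chaotic signal from colored noise: a
monotone nonlinear transform of linearly filtered noise can reproduce any
spectrum. `ordspec` works on the *ordinal* structure instead. A series
X_t is mapped to Bandt–Pompe ordinal patterns — the permutation that sorts
each delay vector (X_t, X_{t+τ}, …, X_{t+(D−1)τ}) — encoded as the
permutation's lexicographic rank in {1, …, D!}, so the fully ascending and
fully descending patterns sit at the opposite ends of the code range. The
coded sequence S_t is modelled as a finite-state Markov chain with
stationary distribution p\*_i and m-step transition probabilities p^m_ij,
from which a rank mean, variance and autocovariance follow:

    E{S}   = Σ_i i · p*_i
    Var(S) = Σ_i i² · p*_i − E{S}²
    Cov(m) = Σ_i Σ_j i · j · p*_i p^m_ij − E{S}²

The **ordinal spectrum** is the Fourier transform of this rank
autocovariance over normalized frequency f ∈ [0, 0.5] cycles/sample:

    OS(f) = Σ_{m=−(N−1)}^{N−1} Cov(m) e^{−i2πfm}
          = Cov(0) + 2 Σ_{m≥1} Cov(m) cos(2πfm)

Peaks in OS(f) alone prove nothing — correlated noise has them too. The
test therefore compares OS(f) with an ensemble of IAAFT surrogates
(iterative amplitude-adjusted Fourier transform), which preserve the
series' amplitude distribution exactly and its power spectrum to
convergence while destroying all higher-order temporal structure. A
per-frequency z-test with Benjamini–Hochberg FDR correction flags the
frequency bands where the symbolic dynamics cannot be explained by a
linearly correlated stochastic process — the signature of nonlinear
(e.g. chaotic) dynamics. It is aimed at noisy biomedical, epidemiological,
astronomical and physical records where "is this chaos or filtered noise?"
is the operative question.

## Worked example

```python
from ordspec import OrdinalSpectrumModel, generators

x = generators.logistic(r=4.0, T=2000, burn_in=1000, seed=7)   # chaotic map
res = OrdinalSpectrumModel(x, D=3, tau=1, seed=7).fit(n_surrogates=200)
print(res.summary())
```

```
Ordinal spectrum surrogate test
===============================================
Observations                               2000
Embedding dimension D                         3
Embedding delay tau                           1
Symbol sequence length L                   1998
Autocovariance lags N                       512
Cov estimator                            markov
Frequency grid points                       256
IAAFT surrogates                            200
Rank variance Var(S)                    2.68501
Mean rank E{S}                          2.97397
-----------------------------------------------
alpha (FDR)                                0.05
min adjusted p (q)                     1.05e-26
significant frequencies                     221
verdict                           null_rejected
===============================================
Significant frequency bands (cycles/sample):
  [0.0020, 0.1059]
  [0.1569, 0.2608]
  [0.2804, 0.5000]
```

The fully chaotic logistic map is rejected decisively: broad frequency
bands of its ordinal spectrum lie many surrogate standard deviations away
from the IAAFT ensemble (minimum FDR-adjusted p ≈ 10⁻²⁶). Running the same
analysis on a periodic window of the map (`r=3.55`) or on Gaussian/1/f
noise returns `null_not_rejected`: despite large spectral peaks, their
ordinal dynamics are fully reproduced by the surrogates. Per-frequency
arrays (OS, surrogate mean/std, z, p, q) live on `res.report` and
`res.ensemble`; `res.to_json(path)` / `res.to_tsv(path)` export them, and
`res.plot()` draws the spectrum against the surrogate envelope.

## Command line

```sh
ordspec generate logistic series.txt -T 2000 --seed 3 -p r=4.0
ordspec analyze series.txt -D 3 --tau 1 --n-surrogates 500 -o out/
ordspec spectrum series.txt spec.tsv --n-freq 256        # no test
ordspec surrogate series.txt sur -n 10 --seed 1          # IAAFT samples
```

`analyze` writes a JSON report (config echo, verdict, bands, per-frequency
arrays) and a TSV table; input is single-column text (optional header) or
CSV with `--column`. `--tau auto` picks the embedding delay from the sample
autocorrelation function (first zero crossing or local minimum, folding
time 1/e for monotone ACFs).

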
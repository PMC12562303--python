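"""Stationary/transition estimation and the rank autocovariance."""

import numpy as np
import pytest

from ordspec.errors import ParameterError
from ordspec.rank_dynamics import (
    chapman_kolmogorov_diagnostic,
    estimate_stationary,
    estimate_transition,
    rank_autocovariance,
    transition_model,
)
from ordspec.symbolizer import EmbeddingParams, SymbolSequence


def make_seq(codes, D=3):
    return SymbolSequence(np.asarray(codes), EmbeddingParams(D, 1))


def alternating(L):
    """Codes 1,6,1,6,... of length L."""
    return make_seq(np.tile([1, 6], (L + 1) // 2)[:L])


def counting_cov_oracle(codes, m, normalization):
    """Independent oracle: uncentered lag product with the global mean
    convention, sum_t s_t s_{t+m} / (L-m) - E^2, evaluated by a plain loop."""
    s = [float(c) for c in codes]
    L = len(s)
    E = sum(s) / L
    acc = 0.0
    for t in range(L - m):
        acc += s[t] * s[t + m]
    c = acc / (L - m) - E * E
    if normalization == "biased":
        c *= (L - m) / L
    return c


class TestStationary:
    def test_degenerate_constant_sequence(self):
        p = estimate_stationary(make_seq([1] * 50))
        assert np.array_equal(p, [1, 0, 0, 0, 0, 0])

    def test_alternating_half_half(self):
        p = estimate_stationary(alternating(100))
        assert p[0] == p[5] == 0.5 and p[1:5].sum() == 0

    def test_iid_uniform_codes_near_uniform(self):
        rng = np.random.default_rng(11)
        seq = make_seq(rng.integers(1, 7, size=100_000))
        p = estimate_stationary(seq)
        assert np.all(np.abs(p - 1 / 6) < 0.01)


class TestTransition:
    def test_alternating_lag_one(self):
        # odd length -> exactly 50 pairs each way out of 100
        joint, cond, occ = estimate_transition(alternating(101), 1)
        assert joint[0, 5] == pytest.approx(0.5)
        assert joint[5, 0] == pytest.approx(0.5)
        assert joint.sum() == pytest.approx(1.0, abs=1e-12)
        assert cond[0, 5] == 1.0 and cond[5, 0] == 1.0
        assert list(np.flatnonzero(occ)) == [0, 5]

    def test_alternating_lag_two_self_loops(self):
        joint, _, _ = estimate_transition(alternating(101), 2)
        assert joint[0, 0] + joint[5, 5] == pytest.approx(1.0, abs=1e-12)

    def test_joint_normalizes_for_arbitrary_sequence(self, rng):
        seq = make_seq(rng.integers(1, 7, size=500))
        for m in (1, 7, 100):
            joint, cond, occ = estimate_transition(seq, m)
            assert joint.sum() == pytest.approx(1.0, abs=1e-12)
            rowsums = cond[occ].sum(axis=1)
            assert np.all(np.abs(rowsums - 1.0) < 1e-12)

    def test_lag_out_of_range(self):
        with pytest.raises(ParameterError):
            estimate_transition(alternating(10), 10)

    def test_transition_model_collects_lags(self, rng):
        seq = make_seq(rng.integers(1, 7, size=300))
        tm = transition_model(seq, lags=[1, 2, 5])
        assert tm.lags == (1, 2, 5)
        assert tm.stationary.sum() == pytest.approx(1.0, abs=1e-12)

    def test_chapman_kolmogorov_small_for_true_markov_chain(self, rng):
        # iid codes are trivially first-order Markov: powered one-step
        # matrix must be close to the directly counted m-step matrix
        seq = make_seq(rng.integers(1, 7, size=200_000))
        assert chapman_kolmogorov_diagnostic(seq, 3) < 0.02


class TestRankAutocovariance:
    @pytest.mark.parametrize("method", ["markov", "counting"])
    def test_constant_sequence_zero_everywhere(self, method):
        res = rank_autocovariance(make_seq([4] * 60), max_lag=10, method=method)
        assert res.variance == 0.0
        assert np.allclose(res.cov, 0.0, atol=1e-12)

    def test_alternating_exact_values_unbiased(self):
        # half-half on codes {1, 6}: E = 3.5, Var = 18.5 - 12.25 = 6.25;
        # lag 1 pairs all (1,6) or (6,1): Cov(1) = 6 - 12.25 = -6.25;
        # lag 2 pairs all (1,1) or (6,6): Cov(2) = +6.25
        res = rank_autocovariance(alternating(100), max_lag=3,
                                  method="counting", normalization="unbiased")
        assert res.mean_rank == pytest.approx(3.5)
        assert res.variance == pytest.approx(6.25)
        assert res.cov[1] == pytest.approx(-6.25)
        assert res.cov[2] == pytest.approx(6.25)

    def test_alternating_markov_matches_exact_cycle(self):
        # the fitted chain is an exact 2-cycle, so the markov estimator
        # reproduces the same +-6.25 alternation at every lag
        res = rank_autocovariance(alternating(100), max_lag=6, method="markov")
        assert np.allclose(res.cov, 6.25 * (-1.0) ** np.arange(6), atol=1e-9)

    @pytest.mark.parametrize("normalization", ["biased", "unbiased"])
    def test_counting_estimator_equals_direct_oracle(self, rng, normalization):
        """The double sum over empirical joint probabilities equals the
        direct sample autocovariance with matching normalization and mean
        convention, to 1e-10 — on several random sequences."""
        for _ in range(3):
            codes = rng.integers(1, 7, size=rng.integers(40, 120))
            seq = make_seq(codes)
            res = rank_autocovariance(seq, max_lag=8, method="counting",
                                      normalization=normalization)
            n = seq.params.n_patterns
            ranks = np.arange(1, n + 1)
            for m in range(1, 8):
                # route 1: explicit double sum over the lag-m joint
                joint, _, _ = estimate_transition(seq, m)
                eq2 = float(ranks @ joint @ ranks) - res.mean_rank**2
                if normalization == "biased":
                    eq2 *= (len(seq) - m) / len(seq)
                # route 2: plain-loop product oracle
                direct = counting_cov_oracle(codes, m, normalization)
                assert res.cov[m] == pytest.approx(eq2, abs=1e-10)
                assert res.cov[m] == pytest.approx(direct, abs=1e-10)

    @pytest.mark.parametrize("method", ["markov", "counting"])
    def test_cov0_equals_variance_exactly(self, rng, method):
        seq = make_seq(rng.integers(1, 7, size=1000))
        res = rank_autocovariance(seq, max_lag=20, method=method)
        assert abs(res.cov[0] - res.variance) < 1e-10

    @pytest.mark.parametrize("method", ["markov", "counting"])
    def test_iid_codes_decay_to_zero(self, method):
        rng = np.random.default_rng(5)
        seq = make_seq(rng.integers(1, 7, size=100_000))
        res = rank_autocovariance(seq, max_lag=51, method=method)
        assert np.all(np.abs(res.cov[1:]) < 0.1)

    def test_biased_counting_bounded_by_variance(self, logistic_chaotic):
        from ordspec.symbolizer import symbolize

        seq = symbolize(logistic_chaotic, EmbeddingParams(3, 1))
        res = rank_autocovariance(seq, max_lag=256, method="counting",
                                  normalization="biased")
        assert np.all(np.abs(res.cov[1:]) <= res.cov[0] + 1e-12)

    def test_max_lag_validation(self):
        with pytest.raises(ParameterError):
            rank_autocovariance(alternating(20), max_lag=21)

    def test_tsv_roundtrip(self, tmp_path, rng):
        seq = make_seq(rng.integers(1, 7, size=200))
        res = rank_autocovariance(seq, max_lag=16)
        path = tmp_path / "cov.tsv"
        res.to_tsv(path)
        lag, cov = np.loadtxt(path, skiprows=1, unpack=True)
        assert np.array_equal(lag, np.arange(16))
        assert np.allclose(cov, res.cov, atol=0)
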
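import math
from fractions import Fraction

import numpy as np
import pytest

from midecay.corpus import TokenStream
from midecay.markov import (
    MarkovChain,
    community_experiment,
    fit_markov,
    null_max_distance,
    poisson_exact_ci,
)
from midecay.synthetic import block_transition_matrix


def brute_force_flags(T, tol=1e-12):
    """Matrix-power reachability and return-time gcd oracle for small chains."""
    k = T.shape[0]
    reach = np.zeros((k, k), dtype=bool)
    P = np.eye(k)
    for _ in range(k):
        P = P @ T
        reach |= P > tol
    irreducible = bool(reach.all())
    period = 0
    P = np.eye(k)
    for n in range(1, 3 * k + 1):
        P = P @ T
        for i in range(k):
            if P[i, i] > tol:
                period = math.gcd(period, n)
    return irreducible, period


class TestFitMarkov:
    def test_hand_counted_bigrams(self):
        m = fit_markov(TokenStream(("A", "A", "B", "A", "B")))
        assert m.states_ == ["A", "B"]
        T = m.transition_
        assert T[0, 0] == pytest.approx(1 / 3)
        assert T[0, 1] == pytest.approx(2 / 3)
        assert T[1, 0] == pytest.approx(1.0)

    def test_rows_are_exact_bigram_ratios(self):
        rng = np.random.default_rng(0)
        syms = tuple("ABCD"[i] for i in rng.integers(0, 4, 200))
        m = fit_markov(TokenStream(syms))
        # rational-arithmetic cross-check
        counts = {}
        for a, b in zip(syms[:-1], syms[1:]):
            counts[(a, b)] = counts.get((a, b), 0) + 1
        for (a, b), c in counts.items():
            i, j = m.states_.index(a), m.states_.index(b)
            row_total = sum(v for (x, _), v in counts.items() if x == a)
            assert m.transition_[i, j] == pytest.approx(float(Fraction(c, row_total)), abs=1e-15)

    def test_alternator_periodic(self):
        m = fit_markov(TokenStream(tuple("AB" * 10)))
        assert m.irreducible_
        assert m.period_ == 2
        assert not m.aperiodic_

    def test_cycle_gcd_example(self):
        # transitions A->B, B->C, C->A plus A->A: cycle lengths {1, 3}, gcd 1
        m = fit_markov(TokenStream(("A", "A", "B", "C", "A", "B", "C", "A")))
        assert m.irreducible_
        assert m.period_ == 1

    def test_dangling_state_gets_self_loop(self):
        with pytest.warns(UserWarning, match="self-loop"):
            m = fit_markov(TokenStream(("A", "B", "C")))
        i = m.states_.index("C")
        assert m.transition_[i, i] == 1.0
        assert np.allclose(m.transition_.sum(1), 1.0)

    def test_single_symbol_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            m = fit_markov(TokenStream(("A",)))
        assert m.degenerate_

    def test_flags_match_brute_force_oracle_on_random_ensemble(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            k = int(rng.integers(2, 7))
            # random sparse support, rows restochasticised
            T = rng.dirichlet(np.ones(k), size=k)
            mask = rng.random((k, k)) < 0.5
            for i in range(k):
                if not mask[i].any():
                    mask[i, rng.integers(k)] = True
            T = T * mask
            T = T / T.sum(1, keepdims=True)
            states = [f"s{i}" for i in range(k)]
            m = MarkovChain()
            m.states_ = states
            # build flags via the same public path: simulate a long stream is
            # wasteful, so fit from an explicit stream realising the support
            import networkx as nx

            g = nx.DiGraph((states[i], states[j]) for i in range(k) for j in range(k) if T[i, j] > 0)
            g.add_nodes_from(states)
            from midecay.markov import _digraph_period

            irr_oracle, per_oracle = brute_force_flags(T)
            assert nx.is_strongly_connected(g) == irr_oracle
            assert _digraph_period(g) == per_oracle


class TestSimulate:
    def test_identity_chain_constant(self):
        m = MarkovChain()
        m.fit(TokenStream(("A", "A", "A", "B", "B", "B")))
        # force identity dynamics
        m.transition_ = np.eye(2)
        m.irreducible_ = False
        with pytest.warns(UserWarning, match="empirical"):
            s = m.simulate(10, random_state=0)
        assert len(set(s.symbols)) == 1

    def test_deterministic_two_cycle_alternates(self):
        m = fit_markov(TokenStream(tuple("AB" * 10)))
        s = m.simulate(6, random_state=1)
        assert s.symbols in (("A", "B") * 3, ("B", "A") * 3)

    def test_empirical_bigrams_converge_to_transition_matrix(self):
        T = block_transition_matrix(6, 2, 0.8)
        m = MarkovChain()
        m.fit(TokenStream(tuple("ABCDEF")))  # placeholder fit, then override
        m.transition_ = T
        m.irreducible_ = True
        s = m.simulate(100_000, random_state=3)
        codes = np.array([m.states_.index(x) for x in s.symbols])
        emp = np.zeros_like(T)
        for a, b in zip(codes[:-1], codes[1:]):
            emp[a, b] += 1
        emp = emp / emp.sum(1, keepdims=True)
        assert np.max(np.abs(emp - T)) < 0.01

    def test_seed_reproducibility(self):
        m = fit_markov(TokenStream(tuple("ABACABCBA")))
        assert m.simulate(50, random_state=7).symbols == m.simulate(50, random_state=7).symbols


class TestPoissonCI:
    def test_garwood_all_maxima_equal_three(self):
        lo, hi = poisson_exact_ci(300, 100)
        assert lo == pytest.approx(2.67, abs=0.005)
        assert hi == pytest.approx(3.36, abs=0.005)

    def test_zero_total(self):
        lo, hi = poisson_exact_ci(0, 10)
        assert lo == 0.0
        assert hi > 0

    def test_coverage_on_iid_counts(self):
        rng = np.random.default_rng(5)
        mu, n = 4.0, 50
        hits = 0
        trials = 200
        for _ in range(trials):
            x = rng.poisson(mu, n)
            lo, hi = poisson_exact_ci(x.sum(), n)
            hits += lo <= mu <= hi
        assert hits / trials >= 0.90


class TestNullMaxDistance:
    def test_iid_chain_yields_small_null_and_greater_verdict(self):
        k = 8
        m = MarkovChain()
        m.fit(TokenStream(tuple(f"s{i}" for i in np.random.default_rng(0).integers(0, k, 500))))
        m.transition_ = np.full((k, k), 1 / k)
        m.irreducible_ = True
        nd = null_max_distance(m, corpus_length=600, observed=17, n_sims=12,
                               d_max=25, n_perm=60, seed=1)
        assert nd.mean < 5
        assert nd.verdict == "greater"

    def test_observed_at_null_mean_not_greater(self):
        from midecay.markov import NullMaxDistanceDistribution

        nd = NullMaxDistanceDistribution(maxima=np.full(100, 3), observed=3, n_failures=0, seed=0)
        assert nd.verdict == "not_greater"
        nd2 = NullMaxDistanceDistribution(maxima=np.full(100, 3), observed=4, n_failures=0, seed=0)
        assert nd2.verdict == "greater"


class TestCommunity:
    def test_deterministic_tally(self):
        import pandas as pd

        from midecay.markov import CommunityPreferenceSummary

        rows = pd.DataFrame(
            {
                "sim": range(4),
                "all_fitted": [True] * 4,
                "sole_best": ["exponential", "exponential", "exponential", None],
                "max_distance": [5, 6, 7, 8],
            }
        )
        summary = CommunityPreferenceSummary(rows=rows, n_sequences=4)
        assert summary.sole_best_counts["exponential"] == 3
        assert summary.tie_count == 1
        assert summary.proportions["sole_exponential"] == pytest.approx(0.75)
        assert summary.proportions["tie"] == pytest.approx(0.25)

    def test_markov_community_prefers_exponential(self):
        from midecay.synthetic import gen_markov

        pooled = gen_markov(length=3000, seed=5)
        summary = community_experiment(pooled, n_sequences=12, sim_length=1500,
                                       d_max=40, n_perm=100, seed=5)
        # short dependency ranges defeat the composite fit on some sequences
        fitted = summary.rows[summary.rows["all_fitted"]]
        assert len(fitted) >= 4
        exp_ok = (
            (fitted["sole_best"] == "exponential")
            | fitted["best_set"].str.contains("exponential")
        ).mean()
        assert exp_ok > 0.5
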
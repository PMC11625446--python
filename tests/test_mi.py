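import numpy as np
import pytest

from midecay.corpus import Corpus, ActionSequence, ActionToken, TokenStream
from midecay.entropy import grassberger_entropy
from midecay.mi import (
    MIDecayCurve,
    MIDecayEstimator,
    estimate_decay_curve,
    max_dependency_distance,
    mi_at_distance,
    pairs_at_distance,
)
from midecay.synthetic import gen_markov


def markov_mi_oracle(T, d):
    """Analytic MI (bits) of (X_0, X_d) for a stationary chain: the joint is
    diag(pi) @ T^d. Independent of the estimator path."""
    T = np.asarray(T, dtype=float)
    vals, vecs = np.linalg.eig(T.T)
    pi = np.abs(np.real(vecs[:, np.argmin(np.abs(vals - 1))]))
    pi = pi / pi.sum()
    joint = pi[:, None] * np.linalg.matrix_power(T, d)
    px = joint.sum(1)
    py = joint.sum(0)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log2(joint[mask] / (px[:, None] * py[None, :])[mask])))


class TestPairsAtDistance:
    def test_d1_enumeration(self):
        t = pairs_at_distance(TokenStream(("A", "B", "A", "B")), 1)
        assert t.joint == {("A", "B"): 2, ("B", "A"): 1}
        assert t.n_pairs == 3
        assert t.x_counts == {"A": 2, "B": 1}

    def test_d0_is_diagonal(self):
        t = pairs_at_distance(TokenStream(("A", "B", "A", "B")), 0)
        assert t.joint == {("A", "A"): 2, ("B", "B"): 2}

    def test_boundary_single_pair_and_range_error(self):
        s = TokenStream(tuple("ABCD"))
        assert pairs_at_distance(s, 3).n_pairs == 1
        with pytest.raises(ValueError):
            pairs_at_distance(s, 4)

    def test_marginals_sum_to_joint(self):
        s = TokenStream(tuple("ABCABBACBA"))
        t = pairs_at_distance(s, 2)
        assert sum(t.joint.values()) == t.n_pairs
        assert sum(t.x_counts.values()) == t.n_pairs


class TestMIAtDistance:
    def test_alternating_stream_one_bit(self, alternating_stream):
        mi = mi_at_distance(pairs_at_distance(alternating_stream, 2))
        assert mi == pytest.approx(1.0, abs=0.01)

    def test_iid_near_zero(self):
        rng = np.random.default_rng(0)
        s = TokenStream(tuple(f"s{i}" for i in rng.integers(0, 4, 100_000)))
        assert abs(mi_at_distance(pairs_at_distance(s, 5))) < 0.005

    @pytest.mark.parametrize("d", [1, 3, 6])
    def test_matches_markov_matrix_power_oracle(self, d):
        T = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.25, 0.25, 0.5]])
        s = gen_markov(transition=T, length=150_000, seed=11)
        got = mi_at_distance(pairs_at_distance(s, d))
        assert got == pytest.approx(markov_mi_oracle(T, d), abs=0.003)

    def test_reversal_symmetry_exact(self):
        rng = np.random.default_rng(3)
        s = TokenStream(tuple(f"s{i}" for i in rng.integers(0, 5, 400)))
        rev = TokenStream(s.symbols[::-1])
        for d in (1, 4, 9):
            assert mi_at_distance(pairs_at_distance(s, d)) == pytest.approx(
                mi_at_distance(pairs_at_distance(rev, d)), abs=1e-12
            )

    def test_plugin_mi_bounds_and_d0_identity(self):
        rng = np.random.default_rng(5)
        s = TokenStream(tuple(f"s{i}" for i in rng.integers(0, 6, 500)))
        t0 = pairs_at_distance(s, 0)
        from midecay.entropy import plugin_entropy

        sx = plugin_entropy(list(t0.x_counts.values())).value
        assert mi_at_distance(t0, corrected=False) == pytest.approx(sx, abs=1e-12)
        for d in (1, 2, 7):
            t = pairs_at_distance(s, d)
            mi = mi_at_distance(t, corrected=False)
            bound = min(
                plugin_entropy(list(t.x_counts.values())).value,
                plugin_entropy(list(t.y_counts.values())).value,
            )
            assert -1e-12 <= mi <= bound + 1e-12


class TestDecayCurve:
    def test_alternating_mi_adj_one_bit_everywhere(self, alternating_stream):
        curve = estimate_decay_curve(alternating_stream, d_max=20, n_perm=100, seed=0)
        assert np.all(curve.mi_adj[1:] > 0.9)
        # permuted joint destroys the alternation: the floor sits near zero
        assert np.all(np.abs(curve.mi_sh_mean[1:]) < 0.1)

    def test_iid_stays_inside_null(self, iid_stream):
        curve = estimate_decay_curve(iid_stream, d_max=40, n_perm=200, seed=1)
        frac_inside = np.mean(
            (curve.mi_hat[1:] >= curve.mi_sh_lo[1:]) & (curve.mi_hat[1:] <= curve.mi_sh_hi[1:])
        )
        assert frac_inside >= 0.9

    def test_determinism_under_seed(self, alternating_stream):
        a = estimate_decay_curve(alternating_stream, d_max=10, n_perm=50, seed=9)
        b = estimate_decay_curve(alternating_stream, d_max=10, n_perm=50, seed=9)
        assert np.array_equal(a.mi_hat, b.mi_hat)
        assert np.array_equal(a.mi_sh_hi, b.mi_sh_hi)

    def test_mi_hat_d0_consistent_with_marginal_entropy(self, iid_stream):
        curve = estimate_decay_curve(iid_stream, d_max=5, n_perm=50, seed=2)
        counts = np.unique(np.array(iid_stream.symbols), return_counts=True)[1]
        assert curve.mi_hat[0] == pytest.approx(grassberger_entropy(counts).value, abs=1e-9)

    def test_truncation_warning_when_window_exceeds_stream(self):
        s = TokenStream(tuple("ABCAB"))
        with pytest.warns(UserWarning, match="truncating"):
            curve = estimate_decay_curve(s, d_max=50, n_perm=10, seed=0)
        assert curve.d_max == 4

    def test_too_short_stream_rejected(self):
        with pytest.raises(ValueError):
            estimate_decay_curve(TokenStream(("A",)), n_perm=10)

    def test_cross_boundary_exclusion_changes_pair_counts(self):
        tok = [ActionToken("a", "x"), ActionToken("b", "x"), ActionToken("c", "x")]
        corpus = Corpus("i", [
            ActionSequence("i", "s1", tok * 20, 0),
            ActionSequence("i", "s2", tok * 20, 1),
        ])
        est = MIDecayEstimator(d_max=5, n_perm=20, random_state=0,
                               exclude_cross_boundary_pairs=True).fit(corpus)
        est2 = MIDecayEstimator(d_max=5, n_perm=20, random_state=0).fit(corpus)
        assert est.curve_.N == est2.curve_.N == 120
        # both are valid curves; exclusion only drops boundary-spanning pairs
        assert np.isfinite(est.curve_.mi_hat).all()


class TestMaxDependencyDistance:
    def _curve(self, margins):
        n = len(margins)
        z = np.zeros(n)
        margins = np.asarray(margins, dtype=float)
        return MIDecayCurve(
            distances=np.arange(n), mi_hat=margins, mi_sh_mean=z,
            mi_sh_lo=z - 1, mi_sh_hi=z, n_permutations=10, N=100,
        )

    def test_first_negative_at_8_gives_7(self):
        margins = [1.0] + [0.5] * 7 + [-0.1, 0.2]
        assert max_dependency_distance(self._curve(margins)) == (7, False)

    def test_never_negative_is_censored(self):
        assert max_dependency_distance(self._curve([1.0] * 101)) == (100, True)

    def test_negative_at_d1_gives_zero(self):
        assert max_dependency_distance(self._curve([1.0, -0.5, 1.0])) == (0, False)

    def test_invariant_to_margins_beyond_first_failure(self):
        a = [1.0, 0.4, 0.4, -0.1, 5.0, -9.0]
        b = [1.0, 0.4, 0.4, -0.1, 0.0, 0.0]
        assert max_dependency_distance(self._curve(a)) == max_dependency_distance(self._curve(b))
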
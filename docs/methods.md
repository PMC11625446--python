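# Methods

## Sequence model and MI estimation

An action is a manipulation/object bigram rendered as one categorical
symbol ("grasp NUT"); an individual's corpus is its coded sequences
concatenated in collection order, with no boundary markers. MI at distance
d is estimated from all ordered pairs (s_i, s_{i+d}):

    MI(d) = S(X) + S(Y) − S(X, Y),

with the Grassberger bias-corrected entropy S = [ln N − (1/N) Σ Nᵢ ψ(Nᵢ)]
/ ln 2 bits. Two estimation choices deserve note:

* **Units.** The estimator is evaluated entirely in nats and converted to
  bits, the standard form of the correction. A `strict_literal` flag
  instead evaluates a mixed-base variant (log₂ leading term, natural-log
  digamma sum) for comparison with analyses that mixed bases; the two
  differ by (1 − 1/ln 2) times the digamma sum and the strict form is not
  used anywhere by default.
* **Marginals on the paired subsample.** S(X) and S(Y) are computed from
  the first and last N−d symbols respectively, not the full stream, which
  keeps the identity MI(0) = S(X) exact at every d.

### Permutation chance floor

Finite samples make MI estimates strictly positive even for independent
pairs. The floor MI_sh(d) = S(X) + S(Y) − S_sh(X, Y) uses the joint entropy
of a uniformly shuffled stream with the *observed* marginals. Each of the
`n_perm` replicates (default 1,000; 200 in the desk preset) shuffles the
whole stream once and is reused across all distances — cheaper than
re-shuffling per distance and consistent with treating the replicate as one
permuted sequence; the choice is isolated in `MIDecayEstimator` and the
percentile CI (2.5/97.5) is taken over replicates per distance. MI_Adj(d) =
MI(d) − mean MI_sh(d).

The maximum dependency distance applies a conservative rule: the first
d ≥ 1 where MI(d) falls below the *upper* 95% permutation quantile ends the
dependency range at d − 1; a curve that never falls below within the 0–100
window is censored at 100. On iid streams the fraction of distances where
the observed MI escapes the permutation band is ~5% by construction; the
test suite checks ≥92.5% containment to leave slack for the coupling of
estimates across distances, which share the same stream.

Run-heavy streams deserve a caveat: long repeat runs violate the iid
assumption behind the pairwise entropy estimates, biasing MI_Adj upward at
*all* distances and sometimes censoring the range entirely. This is a
property of the method, not a bug — it is exactly why the analysis is
repeated on condensed streams (maximal runs collapsed to one token) with
Markov nulls retrained on the condensed data.

## Decay models and selection

Exponential a·e^(−bx), power-law a·x^b (b ≤ 0) and composite a·e^(−bx) +
c·x^d models are fitted to (d, MI_Adj) over d = 1..D, D the maximum
dependency distance. Distance 0 is excluded (it measures entropy, not
decay); negative MI_Adj points near the noise floor are retained to avoid
selection bias. No additive constant is fitted: the fitted Markov chains
are checked to be irreducible and aperiodic, under which MI must decay to
zero. Fitting is Levenberg–Marquardt least squares in linear space (lmfit)
over a deterministic start grid — amplitudes {0.1, 1, max y}, rates
{0.05, 0.3, 1.0}, exponents {−0.1, −0.5, −1.5}, crossed for the composite
(81 starts) — keeping fits reproducible without randomness. Bounds enforce
decay (a, c ≥ 0, b ≥ 0, power exponents ≤ 0).

Model ranking uses AICc with LL = −(n/2)[ln 2π + ln(RSS/n) + 1] and
K = n_coefficients + 1 (the error variance is a parameter: K = 3 for the
two-coefficient families, 5 for the composite). Noise-free fits can reach
RSS near machine zero; RSS is floored at the smallest positive double so LL
stays finite — rankings between two numerically-zero RSS values are then
decided by K, which is the desired behaviour. Akaike weights are
exp(−Δᵢ/2) normalised; a family is the *sole* best only when it alone has
Δ < 2.0 (configurable). That threshold reproduces every sole/competing call
in the reference analyses this package mirrors: competing pairs at Δ = 0.3
and 1.8, sole winners from Δ = 2.7 up.

The default fit domain is 1..D inclusive. Published AICc tables in this
literature sometimes back-solve to n = D − 1 points; `drop_last_point=True`
reproduces that convention, and the choice is recorded in every run config.

## Transition points

For a winning composite fit, g(u) = log₁₀ f(10^u) is evaluated on 2,000
uniform points in u ∈ [0, log₁₀ D] and g'' is computed by central
differences (a closed-form g'' is implemented for cross-checking; the
central-difference error is second order in the step, ~2×10⁻⁵ at step 10⁻³
and below 10⁻⁶ at step 10⁻⁴ on representative curves). The transition point
is the floor of the distance at the interior minimand of g'' — the last
distance before power-law behaviour takes over, interpreted as subroutine
length; a minimand on the grid edge is flagged unreliable. The reported
distance is scale-invariant under rescaling of MI_Adj. "Significantly
shorter than per-nut sequences" is operationalised as transition <
mean − 2·SE of per-nut length, with SE = sqrt(mean/n) from the Poisson
normal approximation (the convention that reproduces the study-style
descriptive tables).

## Markov null models

Chains are maximum-likelihood bigram ratios over lexicographically ordered
states. Irreducibility is strong connectivity of the positive-transition
digraph; the period is the gcd of cycle lengths computed per strongly
connected component by BFS levels (0 for acyclic graphs). States never
observed as sources receive a self-loop row with a warning. Simulations
start from the stationary distribution (empirical start frequencies for
reducible chains) and use inverse-CDF sampling.

The per-individual null runs the full MI stack on each of `n_sims`
(default 100) simulated streams of the observed corpus length and collects
maximum dependency distances. The "exact Poisson" 95% CI on their mean is
the Garwood chi-square construction applied to the summed maxima divided by
n_sims — the most standard reading of an exact Poisson interval — and the
observed maximum is judged `greater` only if it exceeds the upper limit.
The community experiment pools all included individuals' corpora
end-to-end in alphabetical order, trains one chain (optionally after
condensing, with the chain retrained on the condensed stream), simulates
500 sequences of 1,000 elements (50 at desk scale) and tallies sole-best
and tie outcomes over the sequences where all three families fitted —
sequences whose short dependency range defeats the composite fit are
counted as fit failures, and per-sequence rows are exported so the
fit-success-vs-length relationship can be modelled externally.

## Synthetic generators

The generators define the package's ground-truth test conditions; all are
deterministic given their seed.

* `gen_markov` — default is a two-community, ten-state chain staying in its
  community with probability 0.88 (uniform within, self included). Its MI
  decay is governed by a single real eigenvalue, giving the clean
  exponential benchmark; dependency ranges at N = 2000 land around 6–12
  elements, comfortably inside the study's per-individual range.
* `gen_hierarchical` — a stochastic substitution tree: each symbol expands
  into two children drawn from a copy-with-mutation conditional
  (copy probability 0.85), depth 11 (N = 2048). Leaves at distance d share
  an ancestor ~2 log₂ d generations up, so correlation decays
  polynomially; adjusted MI typically stays positive beyond 30 elements.
  A deterministic substitution table is also accepted (the A→AB, B→BA
  system reproduces the Thue–Morse word exactly).
* `gen_composite` — subroutine identities (default 4) arranged by the same
  branching process, each expanded into an internal first-order run of
  length 5 (configurable [L_min, L_max]). Each subroutine's chain
  concentrates on its own three-symbol subset with a 5% leak, and runs
  start from the chain's stationary distribution so symbols do not encode
  within-run phase; ground-truth span boundaries are returned. Short-range
  MI then decays Markovian-fashion within runs and hands over to the
  power-law decay of the identity arrangement near the true subroutine
  length.
* `gen_nutcracking_corpus` — per-individual corpora whose shape mirrors the
  eight analysed field corpora (sequence counts and totals), token
  frequencies skewed so the five dominant actions hold 63.5% of the corpus
  with a Zipf-like tail over a 40-symbol alphabet, geometric repeat runs
  (repeat probability 0.4 — repeats such as successive hammer strikes are
  prominent in this behaviour, though the field data pin no rate), and
  Poisson(22)-length nut episodes matching the per-nut scale of the
  descriptive tables.

What these generators do *not* emulate: semantic constraints between
actions (you cannot strike a nut you have not placed), duration and timing,
observer fragmentation correlated with behaviour, and drift between
sequences. Passing recovery tests therefore shows the estimator chain
discriminates the three structural hypotheses under realistic symbol
statistics — not that real corpora are free of confounds.

## Problem sizes in the test suite and acceptance script

Stochastic suites run at N = 2000, 200 permutations, window 0–100:
structure separation over 20 seeds per class in the tests (12 in the
acceptance script), transition recovery over 20 (15) seeds, iid
calibration over 8 streams. These sizes give stable majorities and run in
minutes on one CPU; the full-scale defaults (1,000 permutations, 100 null
simulations, 500 community sequences) remain the `RunConfig` defaults for
real analyses.

## Known limitations

* Grassberger correction assumes iid sampling within each pair subsample;
  overlapping pairs and repeat runs violate this, inflating MI_Adj for
  run-heavy streams (mitigated by the condensed variant, not eliminated).
* The transition point floors a continuous minimand and so is biased
  slightly below the generative subroutine length; recovered values for
  true length 5 cluster in 3–5.
* Reconstructing Akaike weights from ΔAICc values printed to one decimal
  can shift the second decimal of a weight (±0.013); comparisons against
  printed weights should allow that much.
* With ≤ ~10 fitted points the composite family (7-point minimum) often
  cannot be fitted at all; such comparisons are reported as fit failures
  rather than silently reduced to two families when tallying community
  preferences.
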
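# midecay

Mutual-information decay analysis for ethogram-coded behavioural action
sequences.

Long, goal-directed behavioural sequences — a chimpanzee cracking nuts with
stone tools, a bird singing, a person making tea — can be generated by very
different kinds of machinery: a reflexive serial chain in which each action
triggers only the next, a fully hierarchical plan, or something in between
in which short stereotyped *subroutines* are chained locally and arranged
hierarchically. These mechanisms leave distinct statistical fingerprints in
how the mutual information (MI) between two actions falls off with the
number of actions separating them: Markov chains force exponential decay,
nested hierarchical generators produce power-law decay, and
subroutines-under-hierarchy produce a composite of the two. `midecay`
implements that fingerprinting pipeline for discrete action streams, for
researchers in computational ethology and comparative cognition.

## The method

For a concatenated stream of categorical actions, MI at inter-element
distance *d* is estimated as

    MI(d) = S(X) + S(Y) − S(X, Y)

where X and Y are the first and second members of all ordered pairs
(s_i, s_{i+d}) and every entropy uses the Grassberger finite-sample
correction, S = [ln N − (1/N) Σᵢ Nᵢ ψ(Nᵢ)] / ln 2 bits, with ψ the digamma
function. A chance floor MI_sh(d) comes from uniformly permuting the stream
(1,000 replicates by default) and recombining the permuted joint entropy
with the observed marginals; the adjusted score is MI_Adj = MI − mean MI_sh.
The maximum dependency distance is the last *d* before MI first drops below
the permutation upper 95% CI; curves that never drop within the 0–100
window are censored.

Three decay families are then fitted to MI_Adj over distances 1..D by
multi-start Levenberg–Marquardt least squares, with no additive constant:

    exponential  a·e^(−bx)      power law  a·x^b      composite  a·e^(−bx) + c·x^b

and ranked by AICc with Gaussian log-likelihood LL = −(n/2)[ln 2π +
ln(RSS/n) + 1] and K = n_coefficients + 1. When the composite model wins,
the exponential→power-law transition point — an estimate of subroutine
length — is the minimand of the second derivative of the curve in log₁₀
space. First-order Markov chains fitted from the same data provide null
models: per-individual null distributions of the maximum dependency
distance (Garwood Poisson-exact 95% CI), and a pooled "community"
experiment measuring how often genuinely Markovian sequences are
misclassified as power-law or composite.

Because no public corpus accompanies the method, the package ships a
first-class synthetic-data module that generates streams with known ground
truth under all three structural hypotheses, plus a toy nut-cracking corpus
emulating the field data's statistical shape (heavily skewed token
frequencies, repeat runs, sequence fragmentation, per-nut episodes).

## Worked example

```python
from midecay import (MIDecayEstimator, DecayModelSelector, MarkovChain,
                     gen_composite, transition_point, null_max_distance)

stream, truth = gen_composite(seed=10)         # subroutines of length 5, arranged hierarchically
est = MIDecayEstimator(d_max=100, n_perm=200, random_state=10).fit(stream)
print(est.max_distance_, est.censored_)

x, y = est.curve_.fit_points(est.max_distance_)
sel = DecayModelSelector().fit(x, y)
print(sel.comparison_.table[["family", "K", "AICc", "dAICc", "AICc_wt"]].round(2))
print("transition:", transition_point(sel.fits_["composite"], est.max_distance_).transition_distance)
```

prints

```
32 False
        family  K    AICc  dAICc  AICc_wt
0    composite  5 -169.23   0.00      1.0
1  exponential  3 -120.68  48.55      0.0
2    power_law  3 -106.80  62.43      0.0
transition: 5
```

Dependencies reach 32 elements — far beyond a Markovian range — the
composite model takes essentially all the Akaike weight, and the recovered
transition point equals the generator's true subroutine length of 5
actions.

The same analysis runs from the shell on a corpus TSV
(`individual, sequence_id, collection_index, order, manipulation, object[,
nut_episode]`):

```bash
midecay --seed 1 --desk mi corpus.tsv --individual tua --plots
midecay --seed 1 study corpus.tsv
```

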
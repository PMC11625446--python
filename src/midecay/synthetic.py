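"""Synthetic sequence generators with known ground-truth structure.

Three structural hypotheses for how action sequences are put together, each
with its own generator:

* ``gen_markov`` — a first-order chain (serial chaining): MI between
  elements decays exponentially with distance.
* ``gen_hierarchical`` — a stochastic substitution (branching) process in
  which every symbol expands into ``branching`` children drawn from a
  parent-conditional distribution; the leaves of the depth-m tree read
  left-to-right form the stream. Deep generative trees of this kind
  produce power-law MI decay.
* ``gen_composite`` — subroutine identities arranged by the same branching
  process, each identity expanded into a short internal first-order run of
  2-8 actions: exponential decay within subroutines, power-law decay
  between them.

``gen_nutcracking_corpus`` emulates the statistical shape of a field
nut-cracking corpus (heavily skewed token frequencies, repeat runs,
fragmentation into sequences, per-nut episodes) for end-to-end tests.
All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .corpus import ActionSequence, ActionToken, Corpus, TokenStream

__all__ = [
    "SyntheticSpec",
    "random_transition_matrix",
    "block_transition_matrix",
    "gen_markov",
    "gen_hierarchical",
    "gen_composite",
    "gen_nutcracking_corpus",
    "generate",
]

MAX_STREAM_LENGTH = 1 << 20


@dataclass
class SyntheticSpec:
    """Declarative description of one synthetic stream or corpus."""

    generator: str
    seed: Optional[int] = None
    params: dict = field(default_factory=dict)


def generate(spec: SyntheticSpec):
    """Dispatch a spec to its generator; returns the generator's output."""
    fns = {
        "markov": gen_markov,
        "hierarchical": gen_hierarchical,
        "composite": gen_composite,
        "nutcracking": gen_nutcracking_corpus,
    }
    if spec.generator not in fns:
        raise ValueError(f"unknown generator {spec.generator!r}")
    return fns[spec.generator](seed=spec.seed, **spec.params)


def _check_stochastic(T: np.ndarray):
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if (T < 0).any() or not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must be probability simplexes")
    return T


def _default_alphabet(k: int, prefix: str = "act") -> list:
    return [f"{prefix}{i:02d} OBJ" for i in range(k)]


def random_transition_matrix(k: int, concentration: float = 0.15,
                             floor: float = 0.01, seed=None) -> np.ndarray:
    """Random ergodic row-stochastic matrix with concentrated rows.

    Small ``concentration`` makes each row dominated by one or two
    successors (strong adjacent structure); ``floor`` guarantees
    irreducibility and aperiodicity.
    """
    rng = np.random.default_rng(seed)
    T = rng.dirichlet(np.full(k, concentration), size=k)
    T = (1 - floor * k) * T + floor
    return T / T.sum(axis=1, keepdims=True)


def block_transition_matrix(k: int = 10, n_blocks: int = 2,
                            within: float = 0.88) -> np.ndarray:
    """Community-structured ergodic chain with a single slow decay mode.

    States fall into ``n_blocks`` equal communities; each step stays inside
    the current community with probability ``within`` (uniform over its
    members, self included) and defects uniformly otherwise. Community
    membership then evolves as a simple ergodic chain whose MI decays as a
    clean single exponential — the canonical serial-chaining benchmark.
    """
    if k % n_blocks:
        raise ValueError("k must be divisible by n_blocks")
    bs = k // n_blocks
    T = np.empty((k, k))
    for i in range(k):
        b = i // bs
        for j in range(k):
            T[i, j] = within / bs if j // bs == b else (1 - within) / (k - bs)
    return T / T.sum(axis=1, keepdims=True)


def gen_markov(transition=None, length: int = 2000, alphabet=None,
               k: int = 10, seed=None) -> TokenStream:
    """Stream from a first-order chain (default: the two-community chain of
    :func:`block_transition_matrix`, whose MI decays single-exponentially).

    The initial state is drawn from the stationary distribution when it is
    unique, else uniformly.
    """
    rng = np.random.default_rng(seed)
    if transition is None:
        transition = block_transition_matrix(k)
    T = _check_stochastic(transition)
    n_states = T.shape[0]
    if alphabet is None:
        alphabet = _default_alphabet(n_states)
    if len(alphabet) != n_states:
        raise ValueError("alphabet size must match the transition matrix")
    if length < 1:
        raise ValueError("length must be >= 1")
    try:
        vals, vecs = np.linalg.eig(T.T)
        pi = np.abs(np.real(vecs[:, int(np.argmin(np.abs(vals - 1.0)))]))
        p0 = pi / pi.sum()
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        p0 = np.full(n_states, 1.0 / n_states)
    out = np.empty(length, dtype=np.int64)
    out[0] = rng.choice(n_states, p=p0)
    cum = np.cumsum(T, axis=1)
    u = rng.random(length)
    for t in range(1, length):
        out[t] = np.searchsorted(cum[out[t - 1]], u[t], side="right")
    return TokenStream(tuple(alphabet[i] for i in out))


def gen_hierarchical(alphabet=None, k_symbols: int = 10, branching: int = 2,
                     depth: int = 11, substitution=None, start=None,
                     mutation: float = 0.15, seed=None) -> TokenStream:
    """Stream from a stochastic substitution (deep generative tree) process.

    Starting from one root symbol, every symbol is replaced by ``branching``
    children; after ``depth`` rounds the stream has length branching**depth.
    ``substitution`` may be a deterministic mapping ``symbol -> tuple of
    children`` (e.g. A -> (A, B), B -> (B, A) yields the Thue-Morse word).
    By default children are drawn iid from a copy-with-mutation conditional:
    with probability 1 - ``mutation`` a child copies its parent, otherwise
    it is drawn from a random substitution distribution. Leaves separated
    by distance d share an ancestor ~2 log2 d generations up, so their MI
    decays as a power of d — the hierarchical signature.
    """
    if branching < 2 or depth < 1:
        raise ValueError("need branching >= 2 and depth >= 1")
    if branching**depth > MAX_STREAM_LENGTH:
        raise ValueError(f"branching**depth exceeds the length cap {MAX_STREAM_LENGTH}")
    rng = np.random.default_rng(seed)
    if substitution is not None:
        alphabet = sorted(substitution)
        for sym, children in substitution.items():
            if len(children) != branching:
                raise ValueError(f"substitution for {sym!r} must emit {branching} children")
        current = [start if start is not None else alphabet[0]]
        for _ in range(depth):
            current = [c for s in current for c in substitution[s]]
        return TokenStream(tuple(current))
    if not 0 < mutation < 1:
        raise ValueError("mutation must be in (0, 1)")
    if alphabet is None:
        alphabet = _default_alphabet(k_symbols, prefix="hier")
    n = len(alphabet)
    cond = (1 - mutation) * np.eye(n) + mutation * rng.dirichlet(np.ones(n), size=n)
    codes = np.array([rng.integers(n) if start is None else list(alphabet).index(start)])
    for _ in range(depth):
        children = np.empty(len(codes) * branching, dtype=np.int64)
        for i, parent in enumerate(codes):
            children[i * branching:(i + 1) * branching] = rng.choice(
                n, size=branching, p=cond[parent]
            )
        codes = children
    return TokenStream(tuple(alphabet[i] for i in codes))


def _make_subroutine_library(n_subroutines: int, per_subroutine: int,
                             concentration: float, leak: float, rng) -> list:
    """Per-subroutine internal first-order chains over the shared alphabet.

    Each subroutine owns a preferred symbol subset; its chain concentrates
    transitions inside that subset (with a small ``leak`` elsewhere), so the
    symbol distribution identifies the subroutine and between-subroutine MI
    tracks the hierarchical arrangement of identities.
    """
    k = n_subroutines * per_subroutine
    library = []
    for i in range(n_subroutines):
        own = np.arange(i * per_subroutine, (i + 1) * per_subroutine)
        T = np.full((k, k), leak / k)
        for row in range(k):
            T[row, own] += (1 - leak) * rng.dirichlet(np.full(per_subroutine, concentration))
        T = T / T.sum(axis=1, keepdims=True)
        vals, vecs = np.linalg.eig(T.T)
        pi = np.abs(np.real(vecs[:, int(np.argmin(np.abs(vals - 1.0)))]))
        library.append({"transition": T, "cum": np.cumsum(T, axis=1), "pi": pi / pi.sum()})
    return library


def gen_composite(n_subroutines: int = 4, per_subroutine: int = 3,
                  L_min: int = 5, L_max: int = 5, depth: int = 9, branching: int = 2,
                  arrangement_mutation: float = 0.2, concentration: float = 0.5,
                  leak: float = 0.05, length: Optional[int] = 2000, seed=None):
    """Stream of Markov subroutines arranged by a hierarchical process.

    Subroutine identities are generated by the copy-with-mutation branching
    process of :func:`gen_hierarchical`; each identity expands into an
    internal first-order run whose length is drawn uniformly from
    [L_min, L_max] and whose initial symbol comes from the subroutine
    chain's stationary distribution. Returns ``(stream, boundaries)``
    where boundaries is a list of ``(start, end_exclusive, subroutine_id)``
    ground-truth spans.
    """
    if n_subroutines < 1:
        raise ValueError("subroutine library must be non-empty")
    if not 1 <= L_min <= L_max:
        raise ValueError("need 1 <= L_min <= L_max")
    if n_subroutines == 1:
        import warnings

        warnings.warn("single-subroutine library: stream collapses to one periodic chain")
    rng = np.random.default_rng(seed)
    alphabet = _default_alphabet(n_subroutines * per_subroutine)
    library = _make_subroutine_library(n_subroutines, per_subroutine, concentration, leak, rng)
    id_alphabet = [f"sub{i}" for i in range(n_subroutines)]
    if n_subroutines > 1:
        ids = gen_hierarchical(
            alphabet=id_alphabet, branching=branching, depth=depth,
            mutation=arrangement_mutation, seed=int(rng.integers(2**31 - 1)),
        ).symbols
    else:
        ids = [id_alphabet[0]] * (branching**depth)
    symbols = []
    boundaries = []
    for sid in ids:
        sub = library[id_alphabet.index(sid)]
        L = int(rng.integers(L_min, L_max + 1))
        run = [int(rng.choice(len(alphabet), p=sub["pi"]))]
        for _ in range(L - 1):
            run.append(int(np.searchsorted(sub["cum"][run[-1]], rng.random(), side="right")))
        boundaries.append((len(symbols), len(symbols) + L, sid))
        symbols.extend(alphabet[i] for i in run)
        if length is not None and len(symbols) >= length:
            break
    if length is not None:
        symbols = symbols[:length]
        boundaries = [(s, min(e, length), sid) for s, e, sid in boundaries if s < length]
    return TokenStream(tuple(symbols)), boundaries


# -- nut-cracking corpus emulation ------------------------------------

# Printed shares of the five dominant action types; they sum to 0.635 of
# the corpus, the remainder spreads over the rare tail.
TOP5_ACTIONS = (
    ("strikeonehand HAMMER", 0.246),
    ("eat KERNEL", 0.118),
    ("grasp NUT", 0.105),
    ("place NUT", 0.086),
    ("grasp KERNEL", 0.080),
)

# Default per-individual corpus shape: (n_sequences, total elements),
# mirroring the field study's eight analysed individuals.
DEFAULT_CORPUS_SHAPE = {
    "ind1": (21, 1368),
    "ind2": (35, 453),
    "ind3": (8, 299),
    "ind4": (18, 1373),
    "ind5": (12, 482),
    "ind6": (39, 1178),
    "ind7": (15, 1168),
    "ind8": (15, 1940),
}


def _token_probabilities(alphabet_size: int, top5_share: float) -> tuple:
    if not 0 < top5_share < 1:
        raise ValueError("top5_share must be in (0, 1)")
    if alphabet_size < 6:
        raise ValueError("alphabet must exceed the five dominant actions")
    top_syms = [s for s, _ in TOP5_ACTIONS]
    top_p = np.array([p for _, p in TOP5_ACTIONS])
    top_p = top_p / top_p.sum() * top5_share
    n_tail = alphabet_size - 5
    tail = np.array([1.0 / (i + 1) for i in range(n_tail)])  # Zipf-like tail
    tail = tail / tail.sum() * (1.0 - top5_share)
    syms = top_syms + [f"rare{i:02d} OBJ" for i in range(n_tail)]
    return syms, np.concatenate([top_p, tail])


def _draw_stream(n: int, probs: np.ndarray, repeat_intensity: float, rng) -> np.ndarray:
    """Draw n symbols; with probability ``repeat_intensity`` repeat the
    previous symbol, else draw fresh from the base distribution (which is
    then exactly the stationary marginal). At zero intensity fresh draws
    additionally exclude the previous symbol, so no adjacent repeats occur.
    """
    out = np.empty(n, dtype=np.int64)
    out[0] = rng.choice(len(probs), p=probs)
    for t in range(1, n):
        if repeat_intensity > 0 and rng.random() < repeat_intensity:
            out[t] = out[t - 1]
        else:
            nxt = rng.choice(len(probs), p=probs)
            while repeat_intensity == 0 and nxt == out[t - 1]:
                nxt = rng.choice(len(probs), p=probs)
            out[t] = nxt
    return out


def gen_nutcracking_corpus(shape: Optional[dict] = None, alphabet_size: int = 40,
                           top5_share: float = 0.635, repeat_intensity: float = 0.4,
                           mean_per_nut: float = 22.0, seed=None) -> dict:
    """Toy per-individual corpora with field-study statistical shape.

    Token frequencies are heavily skewed (the five dominant actions hold
    ``top5_share`` of the corpus), repeats come in geometric runs of mean
    1/(1-repeat_intensity), each corpus is fragmented into its configured
    number of sequences, and every sequence is chopped into nut episodes of
    roughly Poisson(mean_per_nut) actions.

    Returns a dict individual id -> :class:`Corpus` with nut annotations.
    """
    rng = np.random.default_rng(seed)
    shape = dict(shape) if shape is not None else dict(DEFAULT_CORPUS_SHAPE)
    syms, probs = _token_probabilities(alphabet_size, top5_share)
    corpora = {}
    for ind, (n_seq, total) in shape.items():
        if n_seq < 1 or total < n_seq:
            raise ValueError(f"infeasible shape for {ind!r}: {n_seq} sequences, {total} elements")
        # fragment the corpus into sequences of roughly equal length
        cuts = np.sort(rng.choice(np.arange(1, total), size=n_seq - 1, replace=False)) \
            if n_seq > 1 else np.array([], dtype=int)
        seq_lengths = np.diff(np.concatenate([[0], cuts, [total]]))
        # one draw for the whole corpus so the no-adjacent-repeat guarantee
        # at zero intensity survives concatenation across sequence boundaries
        all_codes = _draw_stream(total, probs, repeat_intensity, rng)
        offsets = np.concatenate([[0], np.cumsum(seq_lengths)])
        nut_counter = 0
        sequences = []
        for si, L in enumerate(seq_lengths):
            codes = all_codes[offsets[si]:offsets[si + 1]]
            tokens = [ActionToken(*syms[c].split(" ", 1)) for c in codes]
            nut_ids = []
            remaining = int(L)
            pos = 0
            while remaining > 0:
                ep_len = min(max(1, int(rng.poisson(mean_per_nut))), remaining)
                nut_counter += 1
                nut_ids.extend([f"nut{nut_counter:04d}"] * ep_len)
                pos += ep_len
                remaining -= ep_len
            sequences.append(
                ActionSequence(
                    individual_id=ind,
                    sequence_id=f"{ind}_seq{si:02d}",
                    tokens=tokens,
                    collection_index=si,
                    nut_episode_ids=nut_ids,
                )
            )
        corpora[ind] = Corpus(individual_id=ind, sequences=sequences)
    return corpora
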
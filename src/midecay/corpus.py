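"""Data model and I/O for ethogram-coded action sequences.

An *action* is a manipulation/object bigram ("grasp NUT"); a corpus is the
set of coded sequences for one individual, concatenated in the order the
sequences were collected. Runs of identical actions can be collapsed
("condensed") to a single token to strip repetition-driven dependencies.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActionToken",
    "ActionSequence",
    "TokenStream",
    "Corpus",
    "CorpusSummary",
    "SchemaError",
    "IntegrityError",
    "load_corpus",
    "condense",
    "summarize_corpus",
    "action_type_profile",
    "write_corpus",
]


class SchemaError(ValueError):
    """Input table is missing required columns or has malformed rows."""


class IntegrityError(ValueError):
    """Input table violates ordering/uniqueness contracts."""


def normalize_symbol(manipulation: str, obj: str) -> str:
    """Render the canonical symbol: case-folded manipulation, upper-cased
    object, single-space joined. Round-trips byte-identically once applied."""
    m = str(manipulation).strip().casefold()
    o = str(obj).strip().upper()
    if not m or not o:
        raise ValueError("manipulation and object labels must be non-empty")
    return f"{m} {o}"


@dataclass(frozen=True)
class ActionToken:
    """One coded action: a manipulation directed at an object."""

    manipulation: str
    object: str

    def __post_init__(self):
        if not str(self.manipulation).strip() or not str(self.object).strip():
            raise ValueError("manipulation and object labels must be non-empty")
        object.__setattr__(self, "manipulation", str(self.manipulation).strip().casefold())
        object.__setattr__(self, "object", str(self.object).strip().upper())

    @property
    def symbol(self) -> str:
        return f"{self.manipulation} {self.object}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.symbol


@dataclass(frozen=True)
class TokenStream:
    """An ordered categorical sequence of action symbols."""

    symbols: tuple

    def __post_init__(self):
        if len(self.symbols) < 1:
            raise ValueError("TokenStream must contain at least one symbol")
        object.__setattr__(self, "symbols", tuple(str(s) for s in self.symbols))

    @property
    def N(self) -> int:
        return len(self.symbols)

    @property
    def alphabet(self) -> tuple:
        return tuple(sorted(set(self.symbols)))

    def codes(self):
        """Integer-encode against the sorted alphabet.

        Returns (codes array, alphabet tuple); the encoding is deterministic
        so identical streams always encode identically.
        """
        alpha = self.alphabet
        index = {s: i for i, s in enumerate(alpha)}
        return np.fromiter((index[s] for s in self.symbols), dtype=np.int64, count=self.N), alpha

    def __len__(self) -> int:
        return self.N

    def __iter__(self):
        return iter(self.symbols)


@dataclass
class ActionSequence:
    """One contiguous bout of coded actions for one individual."""

    individual_id: str
    sequence_id: str
    tokens: list
    collection_index: int
    nut_episode_ids: Optional[list] = None

    def __post_init__(self):
        if not self.tokens:
            raise ValueError(f"sequence {self.sequence_id!r} has no tokens")
        if self.nut_episode_ids is not None and len(self.nut_episode_ids) != len(self.tokens):
            raise ValueError("nut_episode_ids must align one-to-one with tokens")

    @property
    def symbols(self) -> list:
        return [t.symbol for t in self.tokens]

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Corpus:
    """All sequences for one individual, with collection-order concatenation."""

    individual_id: str
    sequences: list = field(default_factory=list)

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("Corpus requires at least one sequence")
        idx = [s.collection_index for s in self.sequences]
        if len(set(idx)) != len(idx):
            raise IntegrityError(
                f"duplicate collection_index for individual {self.individual_id!r}"
            )
        self.sequences = sorted(self.sequences, key=lambda s: s.collection_index)

    @property
    def concatenated(self) -> TokenStream:
        out = []
        for seq in self.sequences:
            out.extend(seq.symbols)
        return TokenStream(tuple(out))

    @property
    def sequence_labels(self) -> np.ndarray:
        """Per-position source-sequence index in the concatenated stream
        (used to optionally exclude cross-boundary pairs in MI estimation)."""
        return np.repeat(np.arange(len(self.sequences)), [len(s) for s in self.sequences])

    @property
    def has_nut_episodes(self) -> bool:
        return any(s.nut_episode_ids is not None for s in self.sequences)

    def nut_episode_lengths(self) -> list:
        """Number of actions in each labelled nut-cracking episode."""
        counts: Counter = Counter()
        for seq in self.sequences:
            if seq.nut_episode_ids is None:
                continue
            for ep in seq.nut_episode_ids:
                if ep is not None and str(ep).strip() not in ("", "nan", "NA"):
                    counts[(seq.sequence_id, str(ep).strip())] += 1
        return [counts[k] for k in sorted(counts)]


@dataclass
class CorpusSummary:
    """Descriptive statistics for one individual's corpus.

    Standard errors of mean lengths use the normal approximation to the
    Poisson: SE = sqrt(mean / n).
    """

    individual_id: str
    n_sequences: int
    n_elements: int
    n_action_types: int
    mean_seq_length: float
    se_seq_length: float
    nuts_cracked: Optional[int] = None
    mean_per_nut_length: Optional[float] = None
    se_per_nut_length: Optional[float] = None

    @property
    def per_nut_available(self) -> bool:
        return self.mean_per_nut_length is not None


def poisson_se(mean: float, n: int) -> float:
    """SE of a mean count under the Poisson normal approximation."""
    return math.sqrt(mean / n)


REQUIRED_COLUMNS = ("individual", "sequence_id", "collection_index", "order", "manipulation", "object")

BORIS_COLUMN_MAP = {
    "Subject": "individual",
    "Observation id": "sequence_id",
    "Time": "order",
    "Behavior": "manipulation",
    "Modifier": "object",
}


def _frame_to_corpora(df: pd.DataFrame) -> dict:
    corpora = {}
    for ind, ind_df in df.groupby("individual", sort=True):
        seqs = []
        for (seq_id, coll), seq_df in ind_df.groupby(["sequence_id", "collection_index"], sort=False):
            seq_df = seq_df.sort_values("order")
            orders = seq_df["order"].to_numpy()
            if len(np.unique(orders)) != len(orders):
                dup = seq_df.loc[seq_df["order"].duplicated(), "_row"].iloc[0]
                raise IntegrityError(
                    f"duplicate (sequence, order) pair in sequence {seq_id!r} at row {dup}"
                )
            tokens = []
            for _, row in seq_df.iterrows():
                try:
                    tokens.append(ActionToken(row["manipulation"], row["object"]))
                except (ValueError, TypeError) as exc:
                    raise SchemaError(f"malformed action at row {row['_row']}: {exc}") from exc
            nut_ids = None
            if "nut_episode" in seq_df.columns and seq_df["nut_episode"].notna().any():
                nut_ids = [None if pd.isna(v) else v for v in seq_df["nut_episode"]]
            seqs.append(
                ActionSequence(
                    individual_id=str(ind),
                    sequence_id=str(seq_id),
                    tokens=tokens,
                    collection_index=int(coll),
                    nut_episode_ids=nut_ids,
                )
            )
        corpora[str(ind)] = Corpus(individual_id=str(ind), sequences=seqs)
    return corpora


def load_corpus(path, dialect: str = "corpus") -> dict:
    """Read a delimited action-sequence table into one :class:`Corpus` per
    individual.

    Parameters
    ----------
    path : str or file
        TSV/CSV with columns ``individual, sequence_id, collection_index,
        order, manipulation, object[, nut_episode]`` (``dialect="corpus"``)
        or a BORIS-style export (``dialect="boris"``), whose Subject /
        Observation id / Time / Behavior / Modifier columns are mapped onto
        the same schema.

    Returns
    -------
    dict mapping individual id -> Corpus. Row order in the file is
    irrelevant: concatenation follows ``collection_index``.
    """
    sep = None
    if isinstance(path, str) and path.endswith(".csv"):
        sep = ","
    df = pd.read_csv(path, sep=sep or "\t", dtype=str, engine="python")
    if df.empty:
        raise SchemaError("empty input file: no action rows")
    if dialect == "boris":
        missing = [c for c in BORIS_COLUMN_MAP if c not in df.columns]
        if missing:
            raise SchemaError(f"missing BORIS columns: {missing}")
        df = df.rename(columns=BORIS_COLUMN_MAP)
        if "collection_index" not in df.columns:
            # BORIS exports carry no explicit collection order; observations
            # are numbered in first-appearance order.
            first_seen = {s: i for i, s in enumerate(pd.unique(df["sequence_id"]))}
            df["collection_index"] = df["sequence_id"].map(first_seen)
    elif dialect != "corpus":
        raise ValueError(f"unknown dialect {dialect!r}")

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = df.copy()
    df["_row"] = np.arange(2, len(df) + 2)  # 1-based incl. header, for diagnostics
    for col, kind in (("collection_index", int), ("order", float)):
        try:
            df[col] = df[col].astype(kind)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"column {col!r} is not numeric: {exc}") from exc
    bad = df["manipulation"].isna() | df["object"].isna()
    if bad.any():
        raise SchemaError(
            f"row {int(df.loc[bad, '_row'].iloc[0])} is missing a manipulation/object label"
        )
    return _frame_to_corpora(df)


def write_corpus(corpora: dict, path) -> None:
    """Write corpora back to the normalized corpus TSV schema."""
    rows = []
    for ind in sorted(corpora):
        for seq in corpora[ind].sequences:
            for i, tok in enumerate(seq.tokens):
                rows.append(
                    {
                        "individual": ind,
                        "sequence_id": seq.sequence_id,
                        "collection_index": seq.collection_index,
                        "order": i,
                        "manipulation": tok.manipulation,
                        "object": tok.object,
                        "nut_episode": (
                            seq.nut_episode_ids[i] if seq.nut_episode_ids is not None else None
                        ),
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def condense(stream: TokenStream) -> TokenStream:
    """Collapse every maximal run of identical consecutive symbols to one.

    ``strike HAMMER, strike HAMMER, strike HAMMER`` becomes a single
    ``strike HAMMER`` codon; the output has no two equal adjacent symbols.
    Idempotent.
    """
    syms = stream.symbols
    out = [syms[0]]
    for s in syms[1:]:
        if s != out[-1]:
            out.append(s)
    return TokenStream(tuple(out))


def summarize_corpus(corpus: Corpus) -> CorpusSummary:
    """Per-individual descriptive table: sequence counts, mean lengths with
    Poisson-approximation SEs, and per-nut episode lengths when annotated."""
    stream = corpus.concatenated
    n_seq = len(corpus.sequences)
    n_el = stream.N
    mean_len = n_el / n_seq
    summary = CorpusSummary(
        individual_id=corpus.individual_id,
        n_sequences=n_seq,
        n_elements=n_el,
        n_action_types=len(stream.alphabet),
        mean_seq_length=mean_len,
        se_seq_length=poisson_se(mean_len, n_seq),
    )
    if corpus.has_nut_episodes:
        lengths = corpus.nut_episode_lengths()
        if lengths:
            n_nuts = len(lengths)
            mean_nut = sum(lengths) / n_nuts
            summary.nuts_cracked = n_nuts
            summary.mean_per_nut_length = mean_nut
            summary.se_per_nut_length = poisson_se(mean_nut, n_nuts)
    return summary


def action_type_profile(corpus_or_stream, threshold: float = 0.0) -> pd.Series:
    """Relative frequency of each action type, optionally filtered to types
    at or above ``threshold``; frequencies always sum to 1 before filtering."""
    stream = (
        corpus_or_stream.concatenated
        if isinstance(corpus_or_stream, Corpus)
        else corpus_or_stream
    )
    counts = Counter(stream.symbols)
    total = sum(counts.values())
    freqs = pd.Series({s: c / total for s, c in counts.items()}, dtype=float)
    freqs = freqs.sort_values(ascending=False)
    if threshold > 0:
        freqs = freqs[freqs >= threshold]
    freqs.index.name = "action_type"
    freqs.name = "proportion"
    return freqs
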
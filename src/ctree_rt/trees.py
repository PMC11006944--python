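"""Contexts, context trees and probabilistic context trees.

A stochastic chain with memory of variable length (VLMC) chooses its next
symbol according to the shortest suffix of the past — the *context* — that
determines the transition law.  The set of all contexts is suffix-free and can
be drawn as the leaves of a rooted labelled tree, hence *context tree*.

Conventions used throughout the package:

* Symbols are small non-negative integers (``0`` = left, ``1`` = center,
  ``2`` = right in the goalkeeper game).
* A context is a plain tuple of symbols stored **oldest first**, so the
  context written ``"21"`` means ``X[n-1] = 2, X[n] = 1``.  The empty tuple is
  the root context of a memoryless chain.
* Sequences are 0-based internally; file formats use 1-based trial numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np

#: A context: a tuple of integer symbols, oldest first.  ``()`` is the root.
Context = tuple[int, ...]

_ROW_SUM_TOL = 1e-12


def context_from_string(s: str) -> Context:
    """Parse a digit string such as ``"21"`` into a context tuple ``(2, 1)``.

    The empty string parses to the root context ``()``.
    """
    return tuple(int(ch) for ch in s)


def context_to_string(w: Context) -> str:
    """Render a context tuple as a digit string, oldest symbol first."""
    return "".join(str(a) for a in w)


@dataclass(frozen=True)
class Alphabet:
    """A finite, totally ordered set of integer-coded symbols."""

    symbols: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        if len(self.symbols) == 0:
            raise ValueError("alphabet must be non-empty")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be distinct")
        object.__setattr__(self, "symbols", tuple(sorted(self.symbols)))

    def __contains__(self, a: int) -> bool:
        return a in self.symbols

    def __iter__(self) -> Iterator[int]:
        return iter(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)


def reverse_lex_compare(u: Context, v: Context) -> int:
    """Compare equal-length sequences in reverse lexicographic order.

    Sequences are ordered by their most recent symbol first: ``u < v`` iff
    ``u[-1] < v[-1]``, or the length-``(j-1)`` suffixes agree and
    ``u[-j] < v[-j]`` for some ``j``.  Returns ``-1``, ``0`` or ``1``.

    Raises
    ------
    ValueError
        If ``u`` and ``v`` have different lengths (the order is only defined
        between sequences of the same length).
    """
    if len(u) != len(v):
        raise ValueError(
            f"reverse lexicographic order requires equal lengths, "
            f"got {len(u)} and {len(v)}"
        )
    ru, rv = u[::-1], v[::-1]
    if ru < rv:
        return -1
    if ru > rv:
        return 1
    return 0


def reverse_lex_key(w: Context) -> Context:
    """Sort key realising :func:`reverse_lex_compare` (the reversed tuple)."""
    return w[::-1]


def is_suffix(u: Context, v: Context) -> bool:
    """True iff ``u`` is a (not necessarily proper) suffix of ``v``."""
    if len(u) > len(v):
        return False
    return len(u) == 0 or v[-len(u):] == u


def is_proper_suffix(u: Context, v: Context) -> bool:
    """True iff ``u`` is a strictly shorter suffix of ``v``."""
    return len(u) < len(v) and is_suffix(u, v)


def is_suffix_free(contexts: Iterable[Context]) -> bool:
    """Check the leaf property: no member is a proper suffix of another."""
    ctxs = list(contexts)
    for u in ctxs:
        for v in ctxs:
            if is_proper_suffix(u, v):
                return False
    return True


@dataclass(frozen=True)
class ContextTree:
    """A suffix-free set of contexts — the leaves of a context tree."""

    contexts: frozenset[Context]
    alphabet: Alphabet = field(default_factory=Alphabet)

    def __post_init__(self) -> None:
        object.__setattr__(self, "contexts", frozenset(tuple(w) for w in self.contexts))
        for w in self.contexts:
            for a in w:
                if a not in self.alphabet:
                    raise ValueError(f"context {w!r} uses symbol outside alphabet")
        if not is_suffix_free(self.contexts):
            raise ValueError("context set is not suffix-free")

    @property
    def depth(self) -> int:
        """Length of the longest context (0 for the root-only tree)."""
        return max((len(w) for w in self.contexts), default=0)

    def __contains__(self, w: Context) -> bool:
        return tuple(w) in self.contexts

    def __iter__(self) -> Iterator[Context]:
        return iter(sorted(self.contexts, key=lambda w: (len(w), reverse_lex_key(w))))

    def __len__(self) -> int:
        return len(self.contexts)

    def as_strings(self) -> list[str]:
        return [context_to_string(w) for w in self]


def longest_context_suffix(tree: ContextTree, past: Sequence[int]) -> Optional[Context]:
    """Find the member of ``tree`` that is a suffix of ``past``.

    By suffix-freeness at most one member matches; the root ``()`` matches any
    past.  Returns ``None`` when no member is a suffix of ``past``.
    """
    past = tuple(past)
    for l in range(min(len(past), tree.depth), -1, -1):
        if past[len(past) - l:] in tree.contexts:
            return past[len(past) - l:]
    return None


@dataclass(frozen=True)
class ProbabilisticContextTree:
    """A context tree together with a next-symbol distribution per context.

    ``transition[w][a]`` is the probability that the next symbol equals
    ``alphabet.symbols[a]`` given that the realised past ends in context ``w``.
    """

    tree: ContextTree
    transition: Mapping[Context, np.ndarray]

    def __post_init__(self) -> None:
        rows = {}
        for w in self.tree.contexts:
            if w not in self.transition:
                raise ValueError(f"missing transition row for context {w!r}")
            row = np.asarray(self.transition[w], dtype=float)
            if row.shape != (len(self.tree.alphabet),):
                raise ValueError(f"transition row for {w!r} has wrong length")
            if np.any(row < 0):
                raise ValueError(f"negative probability in row for {w!r}")
            if abs(row.sum() - 1.0) > _ROW_SUM_TOL:
                raise ValueError(f"row for {w!r} sums to {row.sum()}, not 1")
            rows[w] = row
        object.__setattr__(self, "transition", rows)

    @property
    def alphabet(self) -> Alphabet:
        return self.tree.alphabet

    def next_symbol_distribution(self, past: Sequence[int]) -> np.ndarray:
        """Transition row for the context matching ``past``.

        Raises
        ------
        LookupError
            If no context of the tree is a suffix of ``past`` (the model does
            not cover this past).
        """
        w = longest_context_suffix(self.tree, past)
        if w is None:
            raise LookupError(f"no context matches past ending in {tuple(past)[-4:]}")
        return self.transition[w]


def goalkeeper_generating_tree() -> ProbabilisticContextTree:
    """The probabilistic context tree driving the penalty taker's kicks.

    The chain concatenates triplets ``0 * 1`` where ``*`` is 2 with
    probability 0.7 and 1 otherwise, independently of everything else.  As a
    VLMC this is the context tree ``{0, 2, 01, 11, 21}`` with

    * ``p(2 | 0) = 0.7``, ``p(1 | 0) = 0.3``  (the only stochastic choice),
    * ``p(1 | 2) = p(1 | 01) = 1`` and ``p(0 | 11) = p(0 | 21) = 1``.
    """
    alphabet = Alphabet((0, 1, 2))
    contexts = frozenset({(0,), (2,), (0, 1), (1, 1), (2, 1)})
    transition = {
        (0,): np.array([0.0, 0.3, 0.7]),
        (2,): np.array([0.0, 1.0, 0.0]),
        (0, 1): np.array([0.0, 1.0, 0.0]),
        (1, 1): np.array([1.0, 0.0, 0.0]),
        (2, 1): np.array([1.0, 0.0, 0.0]),
    }
    return ProbabilisticContextTree(ContextTree(contexts, alphabet), transition)


@dataclass
class SessionData:
    """One participant's aligned game record.

    Attributes
    ----------
    kicks : ndarray of int
        Penalty taker's choices ``X_1..X_N``.
    predictions : ndarray of int
        Goalkeeper's choices ``Y_1..Y_N``; trial ``n`` is *correct* when
        ``Y_n == X_n``.
    response_times : ndarray of float
        Seconds from response prompt to button press, ``T_n > 0``.
    participant_id : str
        Label used in file names and reports.
    """

    kicks: np.ndarray
    predictions: np.ndarray
    response_times: np.ndarray
    participant_id: str = "P00"
    alphabet: Alphabet = field(default_factory=Alphabet)

    def __post_init__(self) -> None:
        self.kicks = np.asarray(self.kicks, dtype=np.int64)
        self.predictions = np.asarray(self.predictions, dtype=np.int64)
        self.response_times = np.asarray(self.response_times, dtype=float)
        n = len(self.kicks)
        if len(self.predictions) != n or len(self.response_times) != n:
            raise ValueError("kicks, predictions and response_times must be aligned")
        for name, seq in (("kicks", self.kicks), ("predictions", self.predictions)):
            bad = set(np.unique(seq)) - set(self.alphabet.symbols)
            if bad:
                raise ValueError(f"{name} contain symbols outside alphabet: {sorted(bad)}")
        if n and not np.all(self.response_times > 0):
            raise ValueError("response times must be strictly positive")

    def __len__(self) -> int:
        return len(self.kicks)
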
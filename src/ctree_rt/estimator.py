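"""Context-tree estimation from response times.

This is an extension of Rissanen's Context algorithm to a real-valued series
driven by a VLMC: instead of comparing empirical transition counts, sibling
candidate contexts are compared through the two-sample Kolmogorov–Smirnov
test on the response times that follow their occurrences.  A branch whose
leaves carry statistically different response-time laws is kept; otherwise it
is pruned to its parent, bottom-up, starting from all strings of a maximal
length ``K`` that occur in the sequence and visiting candidates in reverse
lexicographic order.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .trees import (
    Alphabet,
    Context,
    ContextTree,
    SessionData,
    context_to_string,
    is_proper_suffix,
    reverse_lex_key,
)

logger = logging.getLogger(__name__)


def occurrence_ends(kicks: Sequence[int], w: Context) -> np.ndarray:
    """0-based positions ``i`` at which an occurrence of ``w`` ends."""
    kicks = np.asarray(kicks, dtype=np.int64)
    w = tuple(w)
    l = len(w)
    if l == 0:
        return np.arange(len(kicks))
    if l > len(kicks):
        return np.array([], dtype=np.int64)
    hit = np.ones(len(kicks) - l + 1, dtype=bool)
    for off, a in enumerate(w):
        hit &= kicks[off : off + len(hit)] == a
    return np.nonzero(hit)[0] + l - 1


def collect_context_rt_samples(
    kicks: Sequence[int], response_times: Sequence[float], w: Context
) -> np.ndarray:
    """Response times following occurrences of ``w``.

    For every occurrence of ``w`` ending at step ``n`` the associated
    observation is ``T[n+1]`` — the response to the *next* prediction.
    Occurrences ending at the final trial carry no successor and are dropped.
    """
    rts = np.asarray(response_times, dtype=float)
    if len(w) < 1:
        raise ValueError("context must have length >= 1")
    ends = occurrence_ends(kicks, w)
    ends = ends[ends + 1 < len(rts)]
    return rts[ends + 1]


def occurring_strings(kicks: Sequence[int], length: int) -> set[Context]:
    """All distinct substrings of the given length occurring in ``kicks``."""
    kicks = np.asarray(kicks, dtype=np.int64)
    return {
        tuple(int(a) for a in kicks[i : i + length])
        for i in range(len(kicks) - length + 1)
    }


def sibling_family(
    kicks: Sequence[int], w: Context, alphabet: Optional[Alphabet] = None
) -> frozenset[Context]:
    """Candidate siblings of ``w``: one-symbol extensions of its suffix.

    ``F(w) = {a + w[1:] : a in alphabet}`` restricted to strings that occur in
    the sequence; ``w`` itself belongs to its family whenever it occurs.
    """
    if len(w) < 1:
        raise ValueError("context must have length >= 1")
    alphabet = alphabet or Alphabet()
    occ = occurring_strings(kicks, len(w))
    s = tuple(w)[1:]
    return frozenset((a,) + s for a in alphabet if (a,) + s in occ)


@dataclass
class BranchDecision:
    """Outcome of the sibling KS comparison for one candidate family."""

    reject: bool
    pairs: list[tuple[Context, Context, float, float]] = field(default_factory=list)
    excluded: list[Context] = field(default_factory=list)
    flagged: bool = False  # fewer than two testable siblings: retained by default


def branch_ks_decision(
    samples: Mapping[Context, np.ndarray],
    alpha: float,
    min_count: int = 5,
) -> BranchDecision:
    """Pairwise two-sample KS tests among sibling response-time samples.

    The family is *rejected* (kept as leaves) as soon as at least one pair of
    testable siblings has KS p-value below ``alpha``.  Siblings with fewer
    than ``min_count`` observations are excluded from testing; with fewer
    than two testable siblings the family is retained for lack of evidence.
    """
    testable = sorted(
        (w for w, s in samples.items() if len(s) >= min_count), key=reverse_lex_key
    )
    excluded = [w for w in samples if w not in set(testable)]
    pairs = []
    reject = False
    if len(testable) < 2:
        return BranchDecision(False, pairs, excluded, flagged=True)
    for i in range(len(testable)):
        for j in range(i + 1, len(testable)):
            u, v = testable[i], testable[j]
            res = stats.ks_2samp(samples[u], samples[v], method="auto")
            pairs.append((u, v, float(res.statistic), float(res.pvalue)))
            if res.pvalue < alpha:
                reject = True
    return BranchDecision(reject, pairs, excluded, flagged=False)


@dataclass
class BranchRecord:
    """Log entry for one processed candidate family."""

    candidate: Context
    family: tuple[Context, ...]
    action: str  # "reject", "retain", "singleton", "partial"
    pairs: list[tuple[Context, Context, float, float]] = field(default_factory=list)


@dataclass
class EstimationResult:
    """Estimated context tree plus estimation metadata."""

    tree: ContextTree
    records: list[BranchRecord]
    K: int
    alpha: float
    min_count: int
    ks_method: str = "auto"

    def to_dict(self) -> dict:
        return {
            "alphabet": list(self.tree.alphabet.symbols),
            "contexts": self.tree.as_strings(),
            "K": self.K,
            "alpha": self.alpha,
            "min_count": self.min_count,
            "ks_method": self.ks_method,
            "branches": [
                {
                    "candidate": context_to_string(r.candidate),
                    "family": [context_to_string(w) for w in r.family],
                    "action": r.action,
                    "pairs": [
                        {
                            "a": context_to_string(u),
                            "b": context_to_string(v),
                            "D": d,
                            "p": p,
                        }
                        for u, v, d, p in r.pairs
                    ],
                }
                for r in self.records
            ],
        }


def estimate_context_tree(
    kicks: Sequence[int],
    response_times: Sequence[float],
    K: int = 3,
    alpha: float = 0.05,
    min_count: int = 5,
    alphabet: Optional[Alphabet] = None,
) -> EstimationResult:
    """Estimate a context tree from a symbol sequence and its response times.

    The candidate list ``C`` starts with every length-``K`` string occurring
    in the sequence, sorted in reverse lexicographic order.  Repeatedly the
    first candidate ``w`` is taken and its sibling family ``F(w)`` formed:

    * ``F(w) == {w}``: the lone sibling is replaced by its suffix (no test);
    * ``F(w) ⊆ C``: the siblings' response-time laws are KS-compared — on
      rejection the whole family becomes leaves of the estimate, otherwise it
      is pruned and the common suffix re-enqueued;
    * ``F(w) ⊄ C``: some sibling's subtree was already kept deeper down, so
      the members still pending become leaves without testing.

    The loop ends when ``C`` is empty.  If pruning reaches the root with
    nothing kept, the root-only (memoryless) tree is returned.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    kicks = np.asarray(kicks, dtype=np.int64)
    rts = np.asarray(response_times, dtype=float)
    if len(kicks) != len(rts):
        raise ValueError("kicks and response_times must be aligned")
    if len(kicks) <= K:
        raise ValueError("sequence must be longer than K")
    alphabet = alphabet or Alphabet()
    if len(rts) > 1 and np.all(rts == rts[0]):
        warnings.warn(
            "all response times identical: no KS rejection is possible, "
            "the estimate collapses toward the root",
            stacklevel=2,
        )

    sample_cache: dict[Context, np.ndarray] = {}

    def sample(w: Context) -> np.ndarray:
        if w not in sample_cache:
            sample_cache[w] = collect_context_rt_samples(kicks, rts, w)
        return sample_cache[w]

    initial = sorted(occurring_strings(kicks, K), key=reverse_lex_key)
    C: deque[Context] = deque(initial)
    in_C: set[Context] = set(initial)
    tau: set[Context] = set()
    records: list[BranchRecord] = []

    def enqueue(s: Context) -> None:
        if len(s) > 0 and s not in in_C:
            C.append(s)
            in_C.add(s)

    while C:
        w = C.popleft()
        if w not in in_C:
            continue  # removed as part of an earlier family
        family = sibling_family(kicks, w, alphabet)
        suffix = w[1:]
        if family == {w}:
            in_C.discard(w)
            enqueue(suffix)
            records.append(BranchRecord(w, tuple(family), "singleton"))
        elif family <= in_C:
            decision = branch_ks_decision({v: sample(v) for v in family}, alpha, min_count)
            in_C -= family
            if decision.reject:
                tau |= family
                records.append(BranchRecord(w, tuple(sorted(family, key=reverse_lex_key)), "reject", decision.pairs))
            else:
                enqueue(suffix)
                records.append(BranchRecord(w, tuple(sorted(family, key=reverse_lex_key)), "retain", decision.pairs))
        else:
            kept = family & in_C
            tau |= kept
            in_C -= kept
            records.append(BranchRecord(w, tuple(sorted(kept, key=reverse_lex_key)), "partial"))

    contexts = frozenset(tau) if tau else frozenset({()})
    tree = ContextTree(contexts, alphabet)
    logger.info(
        "estimated tree with %d context(s), depth %d (%d branch decisions)",
        len(tree),
        tree.depth,
        len(records),
    )
    return EstimationResult(tree, records, K, alpha, min_count)


def estimate_by_epoch(
    session: SessionData,
    boundaries: Sequence[int] = (334, 668),
    K: int = 3,
    alpha: float = 0.05,
    min_count: int = 5,
) -> dict[int, EstimationResult]:
    """Estimate one tree per epoch of a session.

    Epochs are the closed 1-based trial ranges delimited by the rest-break
    positions (``[1, b1], [b1+1, b2], ..., [bk+1, N]``).  Epochs shorter than
    ``K + 1`` trials are skipped with a warning.
    """
    from .stats import split_epochs  # local import to avoid a cycle

    ranges = split_epochs(len(session), boundaries)
    out: dict[int, EstimationResult] = {}
    for e, (start, stop) in enumerate(ranges, start=1):
        lo, hi = start - 1, stop  # to 0-based half-open
        if hi - lo <= K:
            warnings.warn(f"epoch {e} ({hi - lo} trials) is too short for K={K}; skipped", stacklevel=2)
            continue
        out[e] = estimate_context_tree(
            session.kicks[lo:hi],
            session.response_times[lo:hi],
            K=K,
            alpha=alpha,
            min_count=min_count,
            alphabet=session.alphabet,
        )
    return out


@dataclass
class ModeTreeResult:
    """Across-participant summary of estimated trees."""

    counts: dict[Context, int]
    n_trees: int
    threshold: float
    tree: ContextTree

    def counts_by_string(self) -> dict[str, int]:
        return {
            context_to_string(w): c
            for w, c in sorted(self.counts.items(), key=lambda kv: (len(kv[0]), reverse_lex_key(kv[0])))
        }


def mode_context_tree(
    trees: Iterable[ContextTree], threshold: float = 0.5
) -> ModeTreeResult:
    """The mode context tree: contexts present in more than a threshold
    fraction of the participants' estimated trees.

    Suffix conflicts among retained contexts are resolved in favour of the
    more frequent member (ties favour the longer, more specific context) so
    the result is again a valid suffix-free context set.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("mode_context_tree requires at least one tree")
    alphabet = trees[0].alphabet
    counts: dict[Context, int] = {}
    for t in trees:
        for w in t.contexts:
            counts[w] = counts.get(w, 0) + 1
    # strictly more than the threshold fraction of trees; unanimous contexts
    # always qualify so threshold=1.0 means exactly "in every tree"
    retained = [
        w for w, c in counts.items() if c / len(trees) > threshold or c == len(trees)
    ]
    # greedy resolution: most frequent first, longer wins ties
    retained.sort(key=lambda w: (-counts[w], -len(w), reverse_lex_key(w)))
    kept: list[Context] = []
    for w in retained:
        if any(is_proper_suffix(w, v) or is_proper_suffix(v, w) for v in kept):
            continue
        kept.append(w)
    tree = ContextTree(frozenset(kept) if kept else frozenset({()}), alphabet)
    return ModeTreeResult(counts, len(trees), threshold, tree)
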
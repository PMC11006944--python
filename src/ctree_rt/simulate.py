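"""Synthetic goalkeeper-game sessions.

Three generators compose a full session:

1. the penalty taker's kicks, simulated from a probabilistic context tree;
2. the goalkeeper's predictions, from a per-context accuracy model;
3. response times, log-normal with a per-context location plus an additive
   log-scale shift on trials whose most recent symbol-0 transition was
   mispredicted — the outcome effect propagating one step forward into
   context 2 (and 01) and two steps into context 21.

The defaults reproduce the study conditions: 22 participants, 1000 trials,
rest breaks after trials 334 and 668, and the ``0 * 1`` generating chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .trees import (
    Context,
    ContextTree,
    ProbabilisticContextTree,
    SessionData,
    goalkeeper_generating_tree,
    longest_context_suffix,
)

logger = logging.getLogger(__name__)

#: Past used to seed the kick simulation: one full ``0 2 1`` triplet, so the
#: very first simulated step already has a well-defined context.
DEFAULT_INITIAL_PAST: Context = (0, 2, 1)


def _rng(seed: Optional[int], rng: Optional[np.random.Generator]) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


@dataclass
class BehaviorModel:
    """Goalkeeper accuracy model: P(correct prediction) per generating context.

    The real goalkeeper's strategy is unobserved; this stand-in draws a
    correct prediction with the accuracy of the context governing the trial
    and otherwise picks uniformly among the remaining symbols.
    """

    per_context_accuracy: dict[Context, float]

    def __post_init__(self) -> None:
        self.per_context_accuracy = {tuple(w): float(p) for w, p in self.per_context_accuracy.items()}
        for w, p in self.per_context_accuracy.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"accuracy for context {w!r} outside [0, 1]: {p}")

    @classmethod
    def default(cls) -> "BehaviorModel":
        # Deterministic contexts are easy once learned; context 0 is the only
        # genuinely uncertain one (its successor is 2 only 70% of the time).
        return cls(
            {
                (0,): 0.65,
                (2,): 0.90,
                (0, 1): 0.90,
                (1, 1): 0.90,
                (2, 1): 0.90,
            }
        )


@dataclass
class RTModel:
    """Log-normal response-time model with context and outcome effects.

    ``T_n = exp(log_median[w] + failure_shift[w] * 1{last 0-transition
    mispredicted} + log_sd * eps_n)`` where ``w`` is the context ending at
    trial ``n - 1`` and ``eps_n`` is standard normal.

    Parameters
    ----------
    log_median : dict
        Log-seconds location per context; the keys must form a suffix-free
        context set.
    log_sd : float
        Common log-scale standard deviation (> 0).
    failure_shift : dict
        Additive log-scale effect per context, applied when the prediction at
        the most recent symbol-0 transition strictly before the trial failed.
    baseline_log_median : float, optional
        Location for the few leading trials whose past is too short to match
        any context; defaults to the mean of ``log_median`` values.
    anchor_symbol : int
        The symbol whose transition outcome conditions the shift (0, the
        start of each ``0 * 1`` triplet).
    """

    log_median: dict[Context, float]
    log_sd: float = 0.1
    failure_shift: dict[Context, float] = field(default_factory=dict)
    baseline_log_median: Optional[float] = None
    anchor_symbol: int = 0

    def __post_init__(self) -> None:
        self.log_median = {tuple(w): float(m) for w, m in self.log_median.items()}
        self.failure_shift = {tuple(w): float(s) for w, s in self.failure_shift.items()}
        if not self.log_sd > 0:
            raise ValueError("log_sd must be positive")
        if not all(np.isfinite(list(self.failure_shift.values()) or [0.0])):
            raise ValueError("failure shifts must be finite")
        if self.baseline_log_median is None:
            self.baseline_log_median = float(np.mean(list(self.log_median.values())))

    @property
    def context_tree(self) -> ContextTree:
        return ContextTree(frozenset(self.log_median))

    @classmethod
    def default(cls) -> "RTModel":
        """Context-separated medians (seconds) with the outcome shifts
        +0.3 for context 2 (one step after the 0), +0.15 for 21 (two steps
        after) and -0.2 for 01 (slower after *correct* predictions there)."""
        medians = {(0,): 0.95, (2,): 0.70, (0, 1): 1.25, (1, 1): 0.92, (2, 1): 0.68}
        return cls(
            log_median={w: float(np.log(m)) for w, m in medians.items()},
            log_sd=0.1,
            failure_shift={(2,): 0.3, (2, 1): 0.15, (0, 1): -0.2},
        )

    @classmethod
    def context_free(cls, median_seconds: float = 0.85, log_sd: float = 0.1) -> "RTModel":
        """Null model: response times i.i.d., blind to context and outcome."""
        w0 = float(np.log(median_seconds))
        keys = [(0,), (2,), (0, 1), (1, 1), (2, 1)]
        return cls(log_median={w: w0 for w in keys}, log_sd=log_sd, failure_shift={})


@dataclass
class CohortConfig:
    """Study-level configuration for a synthetic cohort."""

    n_participants: int = 22
    n_trials: int = 1000
    epoch_boundaries: tuple[int, ...] = (334, 668)
    tree: ProbabilisticContextTree = field(default_factory=goalkeeper_generating_tree)
    behavior: BehaviorModel = field(default_factory=BehaviorModel.default)
    rt_model: RTModel = field(default_factory=RTModel.default)
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_participants < 0:
            problems.append("n_participants must be >= 0")
        if self.n_trials < self.tree.tree.depth + 1:
            problems.append("n_trials must exceed the generating tree depth")
        bs = tuple(self.epoch_boundaries)
        if any(b2 <= b1 for b1, b2 in zip(bs, bs[1:])):
            problems.append("epoch boundaries must be strictly increasing")
        if any(not 0 < b < self.n_trials for b in bs):
            problems.append("epoch boundaries must lie strictly inside 1..n_trials")
        if problems:
            raise ValueError("invalid cohort config: " + "; ".join(problems))


def generate_kicks(
    model: ProbabilisticContextTree,
    n: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    initial_past: Sequence[int] = DEFAULT_INITIAL_PAST,
) -> np.ndarray:
    """Simulate ``n`` symbols from a probabilistic context tree.

    The chain is started from ``initial_past`` (not included in the output) so
    every simulated step has a defined context; the default is one full
    ``0 2 1`` triplet.

    Raises
    ------
    LookupError
        If the realised past ever matches no context of ``model`` (an
        incomplete model).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    gen = _rng(seed, rng)
    symbols = np.array(model.alphabet.symbols)
    # precompute cumulative rows keyed by context for fast inverse sampling
    cumrows = {w: np.cumsum(row) for w, row in model.transition.items()}
    depth = model.tree.depth
    past = list(initial_past)
    out = np.empty(n, dtype=np.int64)
    u = gen.random(n)
    for i in range(n):
        w = longest_context_suffix(model.tree, past[-depth:] if depth else ())
        if w is None:
            raise LookupError(f"model has no context for past ending {tuple(past[-depth:])}")
        a = symbols[int(np.searchsorted(cumrows[w], u[i], side="right"))]
        out[i] = a
        past.append(int(a))
        if len(past) > depth:
            past = past[-depth:]
    return out


def generate_predictions(
    kicks: np.ndarray,
    behavior: BehaviorModel,
    generating_tree: ContextTree,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Simulate goalkeeper predictions with per-context accuracy.

    Trial ``n`` (n >= 2) is predicted correctly with the accuracy of the
    context ending at trial ``n - 1``; on an error the prediction is uniform
    over the remaining symbols.  The first trial — and any early trial whose
    short past matches no context — is predicted uniformly.
    """
    kicks = np.asarray(kicks, dtype=np.int64)
    if len(kicks) == 0:
        raise ValueError("kicks must be non-empty")
    gen = _rng(seed, rng)
    symbols = list(generating_tree.alphabet.symbols)
    depth = generating_tree.depth
    out = np.empty(len(kicks), dtype=np.int64)
    for i in range(len(kicks)):
        w = longest_context_suffix(generating_tree, kicks[max(0, i - depth):i]) if i > 0 else None
        if w is None:
            out[i] = symbols[gen.integers(len(symbols))]
            continue
        if w not in behavior.per_context_accuracy:
            raise KeyError(f"behavior model has no accuracy for realised context {w!r}")
        if gen.random() < behavior.per_context_accuracy[w]:
            out[i] = kicks[i]
        else:
            others = [a for a in symbols if a != kicks[i]]
            out[i] = others[gen.integers(len(others))]
    return out


def _last_anchor_failure(
    kicks: np.ndarray, predictions: np.ndarray, i: int, anchor: int
) -> Optional[bool]:
    """Outcome of the prediction at the most recent anchor transition.

    Scans for the largest ``m <= i - 2`` (0-based) with ``kicks[m] == anchor``
    and reports whether the prediction of the *next* symbol failed; ``None``
    when no anchor occurs early enough.
    """
    for m in range(i - 2, -1, -1):
        if kicks[m] == anchor:
            return bool(predictions[m + 1] != kicks[m + 1])
    return None


def generate_response_times(
    kicks: np.ndarray,
    predictions: np.ndarray,
    rt_model: RTModel,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Simulate response times for aligned kick/prediction sequences."""
    kicks = np.asarray(kicks, dtype=np.int64)
    predictions = np.asarray(predictions, dtype=np.int64)
    if kicks.shape != predictions.shape:
        raise ValueError("kicks and predictions must be aligned")
    gen = _rng(seed, rng)
    tree = rt_model.context_tree
    n = len(kicks)
    eps = gen.standard_normal(n)
    log_t = np.empty(n)
    n_undefined = 0
    depth = tree.depth
    for i in range(n):
        w = longest_context_suffix(tree, kicks[max(0, i - depth):i]) if i > 0 else None
        if w is None:
            log_t[i] = rt_model.baseline_log_median
            n_undefined += 1
        else:
            loc = rt_model.log_median[w]
            shift = rt_model.failure_shift.get(w, 0.0)
            if shift != 0.0:
                failed = _last_anchor_failure(kicks, predictions, i, rt_model.anchor_symbol)
                if failed:
                    loc = loc + shift
            log_t[i] = loc
    if n_undefined:
        logger.debug("%d leading trial(s) had no defined context; baseline location used", n_undefined)
    return np.exp(log_t + rt_model.log_sd * eps)


def generate_session(
    config: CohortConfig,
    seed_sequence: np.random.SeedSequence,
    participant_id: str,
) -> SessionData:
    """Generate one participant's session from a dedicated seed stream."""
    k_ss, p_ss, t_ss = seed_sequence.spawn(3)
    kicks = generate_kicks(config.tree, config.n_trials, rng=np.random.default_rng(k_ss))
    predictions = generate_predictions(
        kicks, config.behavior, config.tree.tree, rng=np.random.default_rng(p_ss)
    )
    rts = generate_response_times(
        kicks, predictions, config.rt_model, rng=np.random.default_rng(t_ss)
    )
    return SessionData(kicks, predictions, rts, participant_id, config.tree.alphabet)


def generate_cohort(config: CohortConfig) -> list[SessionData]:
    """Generate a full cohort; a pure, reproducible function of the config."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_participants)
    sessions = []
    for j, child in enumerate(children, start=1):
        pid = f"P{j:02d}"
        sessions.append(generate_session(config, child, pid))
        logger.info("generated session %s (%d trials)", pid, config.n_trials)
    return sessions
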
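"""Behavioral statistics for the goalkeeper game.

Covers the per-context conditioning of response times on the outcome of the
most recent symbol-0 transition, robust (trimmed-mean) paired differences
across participants, the two-tailed Wilcoxon signed-rank test, the
Benjamini–Hochberg false-discovery-rate procedure, the index of correctly
predicted transitions, and a Kruskal–Wallis comparison of response times by
response finger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .trees import Context, SessionData, context_to_string
from .estimator import occurrence_ends

logger = logging.getLogger(__name__)


def split_epochs(n_trials: int, boundaries: Sequence[int]) -> list[tuple[int, int]]:
    """Closed 1-based trial ranges delimited by the rest-break positions.

    ``split_epochs(1000, (334, 668))`` gives ``[(1, 334), (335, 668),
    (669, 1000)]``.
    """
    bs = tuple(int(b) for b in boundaries)
    if any(b2 <= b1 for b1, b2 in zip(bs, bs[1:])):
        raise ValueError("boundaries must be strictly increasing")
    if any(not 0 < b < n_trials for b in bs):
        raise ValueError("boundaries must lie strictly between 1 and n_trials")
    edges = (0,) + bs + (n_trials,)
    return [(lo + 1, hi) for lo, hi in zip(edges, edges[1:])]


@dataclass
class TransitionCounts:
    """Counts of correctly/incorrectly predicted transitions ``w -> a``.

    Steps are 0-based occurrence-end indices; occurrences ending at the final
    trial have no successor and are not counted.
    """

    context: Context
    target: int
    steps_correct: np.ndarray
    steps_incorrect: np.ndarray

    @property
    def n_correct(self) -> int:
        return len(self.steps_correct)

    @property
    def n_incorrect(self) -> int:
        return len(self.steps_incorrect)


def transition_counts(
    kicks: Sequence[int],
    predictions: Sequence[int],
    w: Context,
    a: int,
) -> TransitionCounts:
    """Count occurrences of ``w`` followed by ``a``, split by prediction
    success (``Y[n+1] == a``) versus failure (``Y[n+1] != a``)."""
    kicks = np.asarray(kicks, dtype=np.int64)
    predictions = np.asarray(predictions, dtype=np.int64)
    if kicks.shape != predictions.shape:
        raise ValueError("kicks and predictions must be aligned")
    if len(w) < 1:
        raise ValueError("context must have length >= 1")
    ends = occurrence_ends(kicks, w)
    ends = ends[(ends + 1 < len(kicks)) & (kicks[np.minimum(ends + 1, len(kicks) - 1)] == a)]
    correct = ends[predictions[ends + 1] == a]
    incorrect = ends[predictions[ends + 1] != a]
    return TransitionCounts(tuple(w), int(a), correct, incorrect)


def correct_transition_index(counts: TransitionCounts) -> float:
    """Index of correctly predicted transitions:
    ``I = N_correct / (N_correct + N_incorrect)``."""
    total = counts.n_correct + counts.n_incorrect
    if total == 0:
        raise ZeroDivisionError(
            f"transition {counts.context!r} -> {counts.target} never occurs"
        )
    return counts.n_correct / total


def trimmed_mean(sample: Sequence[float], trim: float = 0.2) -> float:
    """Symmetric trimmed mean: drop ``floor(trim * n)`` observations from
    each tail and average the rest."""
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("sample must be non-empty")
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must lie in [0, 0.5)")
    cut = int(trim * x.size)
    if x.size - 2 * cut < 1:
        raise ValueError("trimming removes the entire sample")
    return float(sps.trim_mean(x, trim))


@dataclass
class ConditionedRT:
    """Response times in context ``w`` split by the outcome of the prediction
    at the most recent symbol-0 transition."""

    context: Context
    success: np.ndarray
    failure: np.ndarray
    n_discarded: int = 0
    trim: float = 0.2

    @property
    def mean_success(self) -> float:
        return trimmed_mean(self.success, self.trim)

    @property
    def mean_failure(self) -> float:
        return trimmed_mean(self.failure, self.trim)

    @property
    def difference(self) -> float:
        """Trimmed-mean difference, failure minus success."""
        return self.mean_failure - self.mean_success


def condition_rt_on_last_zero_outcome(
    kicks: Sequence[int],
    predictions: Sequence[int],
    response_times: Sequence[float],
    w: Context,
    trim: float = 0.2,
    anchor_symbol: int = 0,
) -> ConditionedRT:
    """Split the response times following context ``w`` by the outcome of the
    last symbol-0 transition.

    For each occurrence of ``w`` ending at step ``n`` (with ``T[n+1]``
    defined), let ``m*`` be the most recent step ``m`` with ``m + 1 <= n`` at
    which the anchor symbol occurred.  ``T[n+1]`` joins the *success* sample
    when the prediction at ``m* + 1`` was correct and the *failure* sample
    otherwise; occurrences with no preceding anchor are discarded.
    """
    kicks = np.asarray(kicks, dtype=np.int64)
    predictions = np.asarray(predictions, dtype=np.int64)
    rts = np.asarray(response_times, dtype=float)
    if not (kicks.shape == predictions.shape == rts.shape):
        raise ValueError("kicks, predictions and response_times must be aligned")
    zeros = np.nonzero(kicks == anchor_symbol)[0]
    if zeros.size == 0:
        logger.warning("anchor symbol %d never occurs; empty conditioning", anchor_symbol)
        return ConditionedRT(tuple(w), np.array([]), np.array([]), 0, trim)
    ends = occurrence_ends(kicks, w)
    ends = ends[ends + 1 < len(rts)]
    success, failure, discarded = [], [], 0
    for n in ends:
        # largest anchor position m with m <= n - 1
        k = int(np.searchsorted(zeros, n - 1, side="right")) - 1
        if k < 0:
            discarded += 1
            continue
        m = int(zeros[k])
        if predictions[m + 1] == kicks[m + 1]:
            success.append(rts[n + 1])
        else:
            failure.append(rts[n + 1])
    return ConditionedRT(
        tuple(w), np.asarray(success), np.asarray(failure), discarded, trim
    )


@dataclass
class TestResult:
    """A rank-test result: statistic, optional Z, df, two-sided p-value."""

    statistic: float
    p_value: float
    z: Optional[float] = None
    df: Optional[int] = None
    n: tuple[int, ...] = ()
    method: str = ""


def _signed_rank_setup(differences: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all differences are zero: signed-rank test undefined")
    ranks = sps.rankdata(np.abs(d))
    return d, ranks


def _exact_signed_rank_p(t_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p-value by enumerating all sign assignments.

    Handles ties through midranks; feasible for n <= ~20.
    """
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    eps = 1e-9
    p_ge = np.mean(sums >= t_plus - eps)
    p_le = np.mean(sums <= t_plus + eps)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def wilcoxon_signed_rank(
    differences: Sequence[float], method: str = "auto"
) -> TestResult:
    """Two-tailed Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking.  ``method="approx"`` uses
    the tie-corrected normal approximation and reports a signed ``Z`` whose
    sign follows the direction of the rank sum (positive when positive
    differences dominate); ``method="exact"`` enumerates all sign
    assignments (midranks under ties); ``"auto"`` picks exact for n <= 15.
    """
    d, ranks = _signed_rank_setup(differences)
    n = d.size
    t_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    if method == "auto":
        method = "exact" if n <= 15 else "approx"
    if method == "exact":
        p = _exact_signed_rank_p(t_plus, ranks)
        return TestResult(t_plus, p, z=None, n=(n,), method="exact")
    if method != "approx":
        raise ValueError(f"unknown method {method!r}")
    # tie correction: subtract sum(t^3 - t)/48 from the null variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return TestResult(t_plus, 1.0, z=0.0, n=(n,), method="approx")
    z = (t_plus - mu) / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(t_plus, min(1.0, p), z=float(z), n=(n,), method="approx")


@dataclass
class BHResult:
    """Benjamini–Hochberg step-up decision at false-discovery rate ``q``."""

    p_values: np.ndarray
    q: float
    k: int
    rejected: np.ndarray  # boolean, in input order

    @property
    def M(self) -> int:
        return len(self.p_values)


def benjamini_hochberg(p_values: Sequence[float], q: float = 0.05) -> BHResult:
    """Step-up FDR control: reject the ``k`` smallest p-values where ``k`` is
    the largest rank ``i`` with ``p_(i) <= q * i / M``."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    order = np.argsort(p, kind="stable")
    M = p.size
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / M:
            k = rank
    rejected = np.zeros(M, dtype=bool)
    rejected[order[:k]] = True
    return BHResult(p, q, k, rejected)


def kruskal_wallis_by_group(samples: Mapping[object, Sequence[float]]) -> TestResult:
    """Kruskal–Wallis rank test across groups (tie-corrected H, chi-square
    p-value with ``df = groups - 1``).

    Degenerate input in which every observation is identical yields ``H = 0``
    and ``p = 1`` rather than an error.
    """
    groups = [np.asarray(s, dtype=float) for s in samples.values()]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must contain at least one observation")
    sizes = tuple(int(g.size) for g in groups)
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # all observations identical: no rank variation, no evidence
        return TestResult(0.0, 1.0, df=df, n=sizes, method="kruskal-wallis")
    h, p = sps.kruskal(*groups)
    return TestResult(float(h), float(p), df=df, n=sizes, method="kruskal-wallis")


def response_times_by_finger(session: SessionData) -> dict[int, np.ndarray]:
    """Group a session's response times by the predicted symbol — i.e. by the
    finger used (0 index, 1 middle, 2 ring)."""
    return {
        int(a): session.response_times[session.predictions == a]
        for a in session.alphabet
        if np.any(session.predictions == a)
    }


def run_misprediction_analysis(
    cohort: Sequence[SessionData],
    contexts: Sequence[Context],
    trim: float = 0.2,
    q: float = 0.05,
    min_samples: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Across-participant misprediction analysis.

    For every requested context the per-participant trimmed-mean difference
    (failure minus success, conditioning on the last symbol-0 transition) is
    computed; the differences are tested against zero with the two-tailed
    Wilcoxon signed-rank test and the per-context p-values are screened with
    Benjamini–Hochberg at rate ``q``.

    Returns
    -------
    report : DataFrame
        One row per context: ``context, n_participants, median_diff, Z, p,
        bh_rejected``.
    participant_means : DataFrame
        One row per participant and context with the conditioned trimmed
        means and sample sizes.
    """
    if len(cohort) < 2:
        raise ValueError("misprediction analysis requires at least two participants")
    rows = []
    per_participant = []
    for w in contexts:
        w = tuple(w)
        diffs = []
        for session in cohort:
            cond = condition_rt_on_last_zero_outcome(
                session.kicks, session.predictions, session.response_times, w, trim
            )
            if min(len(cond.success), len(cond.failure)) < min_samples:
                logger.info(
                    "participant %s excluded for context %s (n_s=%d, n_f=%d)",
                    session.participant_id,
                    context_to_string(w),
                    len(cond.success),
                    len(cond.failure),
                )
                continue
            diffs.append(cond.difference)
            per_participant.append(
                {
                    "participant": session.participant_id,
                    "context": context_to_string(w),
                    "mean_success": cond.mean_success,
                    "mean_failure": cond.mean_failure,
                    "n_success": len(cond.success),
                    "n_failure": len(cond.failure),
                    "difference": cond.difference,
                }
            )
        if len(diffs) < 2 or np.all(np.asarray(diffs) == 0):
            rows.append(
                {
                    "context": context_to_string(w),
                    "n_participants": len(diffs),
                    "median_diff": float(np.median(diffs)) if diffs else np.nan,
                    "Z": np.nan,
                    "p": np.nan,
                }
            )
            continue
        res = wilcoxon_signed_rank(diffs, method="approx")
        rows.append(
            {
                "context": context_to_string(w),
                "n_participants": len(diffs),
                "median_diff": float(np.median(diffs)),
                "Z": res.z,
                "p": res.p_value,
            }
        )
    report = pd.DataFrame(rows)
    tested = report["p"].notna()
    report["bh_rejected"] = False
    if tested.any():
        bh = benjamini_hochberg(report.loc[tested, "p"].to_numpy(), q)
        report.loc[tested, "bh_rejected"] = bh.rejected
    participant_means = pd.DataFrame(per_participant)
    return report, participant_means
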
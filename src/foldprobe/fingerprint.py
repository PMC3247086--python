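"""Stage 1: topological fingerprint selection and plan assessment.

Each SSE pair is a binary random variable c (in contact or not).  Contact
probabilities are estimated from occurrence frequencies over the models,
softened by an agreement weight q in (0.5, 1] that anticipates imperfect
experimental evaluation of a contact: a model whose state is y contributes
weight q to Pr(c = y) and 1 − q to the opposite state.

A fingerprint F is grown greedily by minimum-redundancy maximum-relevance
(mRMR): at each step add the pair c* maximizing

    score(c) = H(c) − (1/|F|) Σ_{c' ∈ F} I(c, c')

(pure entropy for the first pick), stopping when the best incremental
score drops below a threshold (0.01 bits by default).

A plan is assessed by exhaustive enumeration of the 2^|F| possible
experimental outcome vectors X:

* Bayes error ε — probability of uniquely selecting a wrong-fold model,
* expected tie ratio τ — probability mass of datasets where two or more
  models tie for the maximum likelihood,
* none-of-the-above ratio ν — fraction of datasets for which an uncovered
  fold (a signature no model exhibits) beats every covered fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .topology import FoldSignature, SSEContactGraph, fold_signature

__all__ = [
    "ContactProbModel",
    "Fingerprint",
    "FoldDecision",
    "estimate_contact_probs",
    "entropy",
    "mutual_information",
    "select_fingerprint",
    "likelihood",
    "bayes_error",
    "tie_ratio",
    "nota_ratio",
    "interpret_fold_data",
    "assess_fingerprint",
    "fingerprint_report",
]

DEFAULT_Q = 0.8
DEFAULT_STOP_THRESHOLD = 0.01
ENUMERATION_CAP = 20

Pair = tuple[int, int]


@dataclass
class ContactProbModel:
    """Soft contact marginals and pairwise joints over the SSE-pair universe."""

    q: float
    pairs: list[Pair]
    pr_c: dict[Pair, np.ndarray]  # pair -> [Pr(c=0), Pr(c=1)]
    pr_joint: dict[tuple[Pair, Pair], np.ndarray]  # (c, c') -> 2x2, [x, x']
    states: np.ndarray  # models × pairs raw binary states (for reference)


@dataclass
class Fingerprint:
    """Ordered SSE-pair subset with greedy scores and plan assessment."""

    pairs: list[Pair]
    scores: list[float]
    epsilon: float | None = None
    tie_ratio: float | None = None
    nota_ratio: float | None = None


@dataclass
class FoldDecision:
    """Outcome of interpreting a fold-level dataset X."""

    best_models: list[str]
    likelihoods: dict[str, float]
    none_of_the_above: bool
    best_uncovered: FoldSignature | None = None


def _q_weight(q: float, x: int, y: int) -> float:
    return q if x == y else 1.0 - q


def estimate_contact_probs(
    graphs: Sequence[SSEContactGraph],
    q: float = DEFAULT_Q,
    pairs: Sequence[Pair] | None = None,
) -> ContactProbModel:
    """Estimate Pr(c) and Pr(c, c') from contact-state frequencies.

    Pr(c = x) = (1/|M|) Σ_i Q(x, y_i) where y_i is the state of c in model
    i and Q(x, y) = q if x == y else 1 − q; joints use the product
    Q(x, y_i) Q(x', y'_i).  Marginals of every joint table match the
    corresponding Pr(c) by construction.
    """
    if not graphs:
        raise ValueError("need at least one contact graph")
    if not 0.5 < q <= 1.0:
        raise ValueError(f"agreement weight q must be in (0.5, 1], got {q}")
    if pairs is None:
        ids = graphs[0].sse_ids
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
    pairs = [tuple(p) for p in pairs]
    states = np.array([[g.state(p) for p in pairs] for g in graphs], dtype=int)
    n_models = states.shape[0]

    # Q[x, y]
    Q = np.array([[q, 1 - q], [1 - q, q]])
    pr_c: dict[Pair, np.ndarray] = {}
    for k, p in enumerate(pairs):
        y = states[:, k]
        pr_c[p] = np.array([Q[0, y].sum(), Q[1, y].sum()]) / n_models

    pr_joint: dict[tuple[Pair, Pair], np.ndarray] = {}
    for k, p in enumerate(pairs):
        for l, p2 in enumerate(pairs):
            y, y2 = states[:, k], states[:, l]
            table = np.zeros((2, 2))
            for x in (0, 1):
                for x2 in (0, 1):
                    table[x, x2] = (Q[x, y] * Q[x2, y2]).sum() / n_models
            pr_joint[(p, p2)] = table
    return ContactProbModel(q=q, pairs=list(pairs), pr_c=pr_c, pr_joint=pr_joint, states=states)


def entropy(model: ContactProbModel, c: Pair) -> float:
    """Shannon entropy H(c) in bits (0·log 0 := 0)."""
    p = model.pr_c[tuple(c)]
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def mutual_information(model: ContactProbModel, c: Pair, c2: Pair) -> float:
    """Mutual information I(c, c') in bits; I(c, c) = H(c).

    Distinct edges are read out by independent noisy experiments, so
    their joint carries the product Q weighting; an edge paired with
    itself is a single variable and its self-information is its entropy.
    """
    if tuple(c) == tuple(c2):
        return entropy(model, c)
    joint = model.pr_joint[(tuple(c), tuple(c2))]
    pc = model.pr_c[tuple(c)]
    pc2 = model.pr_c[tuple(c2)]
    mi = 0.0
    for x in (0, 1):
        for x2 in (0, 1):
            j = joint[x, x2]
            if j > 0:
                mi += j * math.log2(j / (pc[x] * pc2[x2]))
    return max(0.0, mi)


def select_fingerprint(
    model: ContactProbModel,
    universe: Sequence[Pair] | None = None,
    stop_threshold: float = DEFAULT_STOP_THRESHOLD,
    max_pairs: int | None = None,
) -> Fingerprint:
    """Greedy mRMR fingerprint selection over the SSE-pair universe.

    The first pick maximizes H(c) alone; later picks maximize
    H(c) − mean I(c, selected).  Selection stops when the best incremental
    score falls below ``stop_threshold`` (in bits) or at ``max_pairs``.
    Ties are broken by lexicographic SSE-pair order for determinism.
    """
    if universe is None:
        universe = model.pairs
    universe = [tuple(p) for p in universe]
    if not universe:
        raise ValueError("empty SSE-pair universe")
    selected: list[Pair] = []
    scores: list[float] = []
    remaining = sorted(universe)
    limit = len(universe) if max_pairs is None else min(max_pairs, len(universe))
    while remaining and len(selected) < limit:
        best_pair, best_score = None, -math.inf
        for c in remaining:
            score = entropy(model, c)
            if selected:
                score -= sum(mutual_information(model, c, s) for s in selected) / len(selected)
            if score > best_score:
                best_pair, best_score = c, score
        if best_score < stop_threshold:
            break
        selected.append(best_pair)
        scores.append(best_score)
        remaining.remove(best_pair)
    return Fingerprint(pairs=selected, scores=scores)


def likelihood(X: Sequence[int], m_signature: FoldSignature, q: float = DEFAULT_Q) -> float:
    """Pr(X | m) = Π_i Q(X_i, state_i) = q^agree · (1−q)^disagree."""
    if len(X) != len(m_signature.states):
        raise ValueError(
            f"data vector length {len(X)} != signature length {len(m_signature.states)}"
        )
    agree = sum(1 for x, s in zip(X, m_signature.states) if x == s)
    disagree = len(m_signature.states) - agree
    return (q ** agree) * ((1 - q) ** disagree)


# ---------------------------------------------------------------------------
# plan assessment by exhaustive enumeration


def _check_cap(n: int) -> None:
    if n > ENUMERATION_CAP:
        raise ValueError(
            f"fingerprint of {n} pairs exceeds the enumeration cap of "
            f"{ENUMERATION_CAP} (2^|F| outcome vectors must be enumerated)"
        )


def _enumerate_X(n: int) -> np.ndarray:
    """All binary vectors of length n as a (2^n, n) array."""
    _check_cap(n)
    ints = np.arange(2 ** n, dtype=np.int64)
    return ((ints[:, None] >> np.arange(n - 1, -1, -1)) & 1).astype(int)


def _signature_matrix(signatures: Sequence[FoldSignature]) -> np.ndarray:
    return np.array([s.states for s in signatures], dtype=int)


def _hamming_all(X: np.ndarray, sigs: np.ndarray) -> np.ndarray:
    """(2^n × n_models) Hamming distances."""
    return (X[:, None, :] != sigs[None, :, :]).sum(axis=2)


def _decision_masks(ham: np.ndarray):
    """Per dataset: minimal Hamming distance, winner mask, model-level tie flag."""
    min_ham = ham.min(axis=1)
    winners = ham == min_ham[:, None]
    ties = winners.sum(axis=1) >= 2
    return min_ham, winners, ties


def _likelihood_matrix(ham: np.ndarray, n: int, q: float) -> np.ndarray:
    return (q ** (n - ham)) * ((1 - q) ** ham)


def bayes_error(
    model: ContactProbModel,
    F: Sequence[Pair],
    signatures: Sequence[FoldSignature],
    priors: Sequence[float] | None = None,
) -> float:
    """Bayes error ε of a fingerprint by exhaustive outcome enumeration.

    For each assumed-correct model m and dataset X (weighted by the model
    prior and Pr(X | m)), an error occurs when a *unique* maximum-
    likelihood model exists whose fold signature on F differs from m's.
    Datasets where two or more models tie for the maximum contribute zero
    (ties are scored by :func:`tie_ratio`).
    """
    n = len(F)
    if n == 0:
        return 0.0
    sigs = _signature_matrix(signatures)
    n_models = sigs.shape[0]
    priors = np.full(n_models, 1.0 / n_models) if priors is None else np.asarray(priors, float)
    X = _enumerate_X(n)
    ham = _hamming_all(X, sigs)
    lik = _likelihood_matrix(ham, n, model.q)
    _, winners, ties = _decision_masks(ham)
    winner_idx = winners.argmax(axis=1)  # unique winner where not tied
    eps = 0.0
    for m in range(n_models):
        # error: unique winner whose signature differs from model m's
        err = (~ties) & (sigs[winner_idx] != sigs[m]).any(axis=1)
        eps += priors[m] * lik[err, m].sum()
    return float(eps)


def tie_ratio(
    model: ContactProbModel,
    F: Sequence[Pair],
    signatures: Sequence[FoldSignature],
    priors: Sequence[float] | None = None,
) -> float:
    """Expected tie ratio τ: mass of datasets where ≥ 2 models tie at the top."""
    n = len(F)
    sigs = _signature_matrix(signatures)
    n_models = sigs.shape[0]
    if n_models < 2:
        return 0.0
    priors = np.full(n_models, 1.0 / n_models) if priors is None else np.asarray(priors, float)
    if n == 0:
        return 1.0  # every model trivially ties on the empty fingerprint
    X = _enumerate_X(n)
    ham = _hamming_all(X, sigs)
    lik = _likelihood_matrix(ham, n, model.q)
    _, _, ties = _decision_masks(ham)
    tau = 0.0
    for m in range(n_models):
        tau += priors[m] * lik[ties, m].sum()
    return float(tau)


def nota_ratio(
    F: Sequence[Pair],
    signatures: Sequence[FoldSignature],
    q: float = DEFAULT_Q,
) -> float:
    """Expected none-of-the-above ratio ν.

    Enumerates all 2^|F| datasets (no prior on X) and counts those for
    which the best uncovered fold has strictly greater likelihood than the
    best covered fold.  Covered folds are the *set* of distinct model
    signatures restricted to F; uncovered folds are the remaining binary
    vectors, treated uniformly.
    """
    n = len(F)
    if n == 0:
        return 0.0
    sigs = np.unique(_signature_matrix(signatures), axis=0)
    X = _enumerate_X(n)
    covered = {tuple(s) for s in sigs}
    uncovered = np.array([x for x in X if tuple(x) not in covered], dtype=int)
    if uncovered.size == 0:
        return 0.0
    ham_cov = _hamming_all(X, sigs).min(axis=1)
    ham_unc = _hamming_all(X, uncovered).min(axis=1)
    # likelihood is strictly decreasing in Hamming distance for q > 0.5
    count = int((ham_unc < ham_cov).sum())
    return count / X.shape[0]


def interpret_fold_data(
    X: Sequence[int],
    F: Sequence[Pair],
    signatures: dict[str, FoldSignature],
    q: float = DEFAULT_Q,
) -> FoldDecision:
    """Maximum-likelihood fold decision for an observed dataset X.

    Returns the tied-for-optimal model set and flags none-of-the-above
    when some uncovered fold has strictly greater likelihood than the best
    covered one (in which case the best uncovered signature is reported).
    """
    n = len(F)
    if any(len(sig.states) != n for sig in signatures.values()):
        raise ValueError("signatures must be restricted to the fingerprint")
    liks = {mid: likelihood(X, sig, q) for mid, sig in signatures.items()}
    best = max(liks.values())
    best_models = sorted(mid for mid, l in liks.items() if l == best)

    covered = {sig.states for sig in signatures.values()}
    nota = False
    best_uncovered = None
    if len(covered) < 2 ** n:
        Xall = _enumerate_X(n)
        unc = [tuple(x) for x in Xall if tuple(x) not in covered]
        pairs_t = tuple(tuple(p) for p in F)
        unc_liks = [
            (likelihood(X, FoldSignature(pairs_t, states), q), states) for states in unc
        ]
        top_lik, top_states = max(unc_liks, key=lambda t: (t[0], t[1]))
        if top_lik > best:
            nota = True
            best_uncovered = FoldSignature(pairs_t, top_states)
    return FoldDecision(
        best_models=best_models,
        likelihoods=liks,
        none_of_the_above=nota,
        best_uncovered=best_uncovered,
    )


# ---------------------------------------------------------------------------
# convenience


def assess_fingerprint(
    fingerprint: Fingerprint,
    model: ContactProbModel,
    graphs: Sequence[SSEContactGraph],
    priors: Sequence[float] | None = None,
) -> Fingerprint:
    """Fill a fingerprint's ε/τ/ν from the ensemble's contact graphs."""
    sigs = [fold_signature(g, fingerprint.pairs) for g in graphs]
    fingerprint.epsilon = bayes_error(model, fingerprint.pairs, sigs, priors)
    fingerprint.tie_ratio = tie_ratio(model, fingerprint.pairs, sigs, priors)
    fingerprint.nota_ratio = nota_ratio(fingerprint.pairs, sigs, model.q)
    return fingerprint


def fingerprint_report(
    fingerprint: Fingerprint,
    model: ContactProbModel,
    graphs: Sequence[SSEContactGraph],
    priors: Sequence[float] | None = None,
):
    """Per-greedy-step assessment table (pandas DataFrame).

    Columns: step, sse_a, sse_b, incremental_score, epsilon, tau, nu —
    one row per greedy step, ε/τ/ν evaluated on the fingerprint prefix.
    """
    import pandas as pd

    rows = []
    for k in range(1, len(fingerprint.pairs) + 1):
        prefix = fingerprint.pairs[:k]
        sigs = [fold_signature(g, prefix) for g in graphs]
        rows.append(
            {
                "step": k,
                "sse_a": prefix[-1][0],
                "sse_b": prefix[-1][1],
                "incremental_score": fingerprint.scores[k - 1],
                "epsilon": bayes_error(model, prefix, sigs, priors),
                "tau": tie_ratio(model, prefix, sigs, priors),
                "nu": nota_ratio(prefix, sigs, model.q),
            }
        )
    return pd.DataFrame(rows)
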
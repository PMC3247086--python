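"""Stage 2: residue-level disulfide cross-link planning per SSE pair.

For a fingerprint SSE pair, candidate cross-links are residue pairs (one
residue per SSE, drawn from residues common to at least half the models)
whose Cβ–Cβ distance is within the cross-linkable window (≤ 19 Å) in at
least one model.  Each candidate link is a binary random variable; its
probability of forming is tiered on distance (0.95 for ≤ 9 Å, 0.5 for
9–19 Å, 0.05 beyond).

Two noise sources make links dependent: threading misalignment — each SSE
may sit δ residues off register, with a symmetric distribution putting
half its mass at δ = 0 and decaying exponentially outward — and backbone
flexibility, sampled along the lowest non-rigid mode of a Cα elastic
network.  Links are conditionally independent given (δ_a, δ_b, backbone,
model), so joints marginalize the product of per-link conditionals over
those shared latent variables.

Links are selected greedily by mRMR (relevance = mutual information with
the contact variable, redundancy = mean mutual information with already
selected links).  Data are interpreted with a sigmoidal likelihood in the
detected-link count k, centred at k0 (default 3 of 10), and the plan is
scored with a Bayes error over all 2^|L| outcome vectors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structures import ModelEnsemble, StructuralModel
from .topology import SSEContactGraph

__all__ = [
    "LinkProbTiers",
    "BackboneSample",
    "NoiseModel",
    "SigmoidParams",
    "CrossLinkPlan",
    "common_residues",
    "build_xlink_graph",
    "offset_distribution",
    "backbone_ensemble",
    "build_noise_model",
    "link_prob",
    "marginal_link_prob",
    "joint_link_prob",
    "select_links",
    "plan_for_fingerprint",
    "contact_likelihood",
    "interpret_xlink_data",
    "xlink_bayes_error",
    "plan_table",
    "read_outcome_table",
]

XLINK_MAX_DISTANCE = 19.0
DEFAULT_PLAN_SIZE = 10
ENUMERATION_CAP = 20

Pair = tuple[int, int]


@dataclass(frozen=True)
class LinkProbTiers:
    """Tiered prior probability of disulfide formation vs Cβ–Cβ distance."""

    p_near: float = 0.95
    p_mid: float = 0.50
    p_far: float = 0.05
    near_distance: float = 9.0
    mid_distance: float = 19.0

    def __post_init__(self) -> None:
        if not (1.0 >= self.p_near > self.p_mid > self.p_far >= 0.0):
            raise ValueError("tiers must satisfy 1 >= p_near > p_mid > p_far >= 0")

    def prob(self, distance: float) -> float:
        if distance <= self.near_distance:
            return self.p_near
        if distance <= self.mid_distance:
            return self.p_mid
        return self.p_far


@dataclass
class BackboneSample:
    """One perturbed backbone: residue index → Cβ position, with probability."""

    cb: dict[int, np.ndarray]
    prob: float


@dataclass
class NoiseModel:
    """Misalignment offsets and per-model flexibility ensembles."""

    offset_probs: dict[int, float]
    backbones: dict[str, list[BackboneSample]]

    @classmethod
    def degenerate(cls, models: Sequence[StructuralModel]) -> "NoiseModel":
        """No misalignment, no flexibility: each model is its own single backbone."""
        return cls(
            offset_probs={0: 1.0},
            backbones={
                m.model_id: [BackboneSample(cb={r.index: r.cb for r in m.residues}, prob=1.0)]
                for m in models
            },
        )


@dataclass(frozen=True)
class SigmoidParams:
    """Sigmoidal contact likelihood: P(data | c=1) = logistic(slope·(k − k0)).

    With the default k0 = 3 the slope ln(19)/k0 pins the likelihood to
    0.05 / 0.5 / 0.95 at k = 0 / 3 / 6 detected links.
    """

    k0: int = 3
    slope: float | None = None

    @property
    def effective_slope(self) -> float:
        if self.slope is not None:
            if self.slope <= 0:
                raise ValueError("sigmoid slope must be positive")
            return self.slope
        return math.log(19.0) / self.k0


@dataclass
class CrossLinkPlan:
    """Ordered cross-link set for one SSE pair, with greedy scores and ε."""

    sse_pair: Pair
    links: list[Pair]
    scores: list[float] = field(default_factory=list)
    marginal_probs: list[float] = field(default_factory=list)
    k0: int = 3
    plan_size: int = DEFAULT_PLAN_SIZE
    epsilon_xlink: float | None = None


# ---------------------------------------------------------------------------
# candidate construction


def common_residues(ensemble: ModelEnsemble, sse_pair: Pair) -> tuple[list[int], list[int]]:
    """Residues of each SSE present in the matched interval of ≥ half the models.

    Only models possessing a matched annotation for the SSE vote; the
    returned lists are sorted residue indices.
    """
    out = []
    for sse_id in sse_pair:
        sse = ensemble.common_sse(sse_id)
        members = sse.members if sse.members else {m.model_id: (sse.start, sse.end) for m in ensemble.models}
        counts: dict[int, int] = {}
        for s, e in members.values():
            for i in range(s, e + 1):
                counts[i] = counts.get(i, 0) + 1
        need = len(members) / 2.0
        residues = sorted(i for i, c in counts.items() if c >= need)
        if not residues:
            raise ValueError(f"SSE {sse_id}: no residues common to half the models")
        out.append(residues)
    return out[0], out[1]


def build_xlink_graph(
    model: StructuralModel,
    R: tuple[list[int], list[int]],
    max_distance: float = XLINK_MAX_DISTANCE,
) -> set[Pair]:
    """Cross-SSE residue pairs cross-linkable in one model (Cβ–Cβ ≤ max_distance)."""
    ra = [i for i in R[0] if model.has_residue(i)]
    rb = [j for j in R[1] if model.has_residue(j)]
    if not ra or not rb:
        return set()
    A = np.array([model.residue(i).cb for i in ra])
    B = np.array([model.residue(j).cb for j in rb])
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)
    return {
        (ra[x], rb[y]) for x, y in zip(*np.nonzero(d <= max_distance))
    }


# ---------------------------------------------------------------------------
# noise models


def offset_distribution(delta_max: int = 2, decay: float = 1.0) -> dict[int, float]:
    """Symmetric misalignment distribution: Pr(0) = 0.5, exponential tails.

    The nonzero offsets ±1..±delta_max share the remaining 0.5 mass with
    weights proportional to exp(−decay·|δ|).  delta_max = 0 degenerates to
    {0: 1.0}.
    """
    if delta_max < 0:
        raise ValueError("delta_max must be >= 0")
    if decay <= 0:
        raise ValueError("decay rate must be positive")
    if delta_max == 0:
        return {0: 1.0}
    tail = {d: math.exp(-decay * abs(d)) for d in range(-delta_max, delta_max + 1) if d != 0}
    z = sum(tail.values())
    probs = {0: 0.5}
    probs.update({d: 0.5 * w / z for d, w in tail.items()})
    return probs


def _anm_hessian(coords: np.ndarray, cutoff: float) -> np.ndarray:
    """Anisotropic-network-model Hessian with unit springs within cutoff."""
    n = coords.shape[0]
    H = np.zeros((3 * n, 3 * n))
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] > cutoff or dist[i, j] < 1e-9:
                continue
            d = diff[i, j] / dist[i, j]
            block = -np.outer(d, d)
            H[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            H[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
            H[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
            H[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return H


def backbone_ensemble(
    model: StructuralModel,
    n_samples: int = 5,
    amplitude_max: float = 3.0,
    enm_cutoff: float = 10.0,
    kT: float | None = None,
) -> list[BackboneSample]:
    """Sample alternative backbones along the lowest non-rigid elastic mode.

    A Cα anisotropic network (unit springs within ``enm_cutoff``) yields a
    mass-free Hessian; the eigenvector after the six rigid-body modes is
    scaled so its largest per-residue displacement is 1 Å, and coordinate
    sets are generated at ``n_samples`` amplitudes evenly spaced over
    [−amplitude_max, +amplitude_max].  Each residue's Cβ is displaced
    rigidly with its Cα.  Probabilities follow the Hookean potential,
    Pr(b) ∝ exp(−λ a² / 2kT); by default kT is set so the extreme sample
    has 0.05 the probability of the unperturbed centre.

    Falls back to the original structure alone (with a warning) for tiny
    or disconnected networks.
    """
    base = {r.index: r.cb for r in model.residues}
    if len(model.residues) < 4 or n_samples <= 1 or amplitude_max <= 0:
        return [BackboneSample(cb=base, prob=1.0)]
    coords = np.array([r.ca for r in model.residues])
    H = _anm_hessian(coords, enm_cutoff)
    w, V = np.linalg.eigh(H)
    tol = max(1e-8, 1e-8 * abs(w[-1]))
    nonzero = np.nonzero(w > tol)[0]
    n_zero = 3 * len(coords) - len(nonzero)
    if n_zero != 6 or len(nonzero) == 0:
        warnings.warn(
            f"model {model.model_id}: elastic network has {n_zero} zero modes "
            "(expected 6); using the unperturbed structure only"
        )
        return [BackboneSample(cb=base, prob=1.0)]
    lam = float(w[nonzero[0]])
    mode = V[:, nonzero[0]].reshape(-1, 3)
    mode = mode / np.linalg.norm(mode, axis=1).max()
    if kT is None:
        kT = lam * amplitude_max ** 2 / (2.0 * math.log(20.0))
    amplitudes = np.linspace(-amplitude_max, amplitude_max, n_samples)
    weights = np.exp(-lam * amplitudes ** 2 / (2.0 * kT))
    weights /= weights.sum()
    samples = []
    for a, p in zip(amplitudes, weights):
        cb = {
            r.index: r.cb + a * mode[k] for k, r in enumerate(model.residues)
        }
        samples.append(BackboneSample(cb=cb, prob=float(p)))
    return samples


def build_noise_model(
    models: Sequence[StructuralModel],
    delta_max: int = 2,
    decay: float = 1.0,
    n_samples: int = 5,
    amplitude_max: float = 3.0,
    enm_cutoff: float = 10.0,
    kT: float | None = None,
) -> NoiseModel:
    """Assemble the full noise model (offsets + flexibility) for an ensemble."""
    if delta_max == 0 and n_samples <= 1:
        return NoiseModel.degenerate(models)
    return NoiseModel(
        offset_probs=offset_distribution(delta_max, decay),
        backbones={
            m.model_id: backbone_ensemble(m, n_samples, amplitude_max, enm_cutoff, kT)
            for m in models
        },
    )


# ---------------------------------------------------------------------------
# link probabilities


def link_prob(
    pair: Pair,
    delta: tuple[int, int],
    backbone: BackboneSample,
    tiers: LinkProbTiers = LinkProbTiers(),
) -> float:
    """Tiered link probability for a δ-shifted residue pair in one backbone.

    The probe of residue r under offset δ reads the geometry of residue
    r + δ; residues shifted out of the structure contribute the far tier.
    """
    i, j = pair[0] + delta[0], pair[1] + delta[1]
    if i not in backbone.cb or j not in backbone.cb:
        return tiers.p_far
    d = float(np.linalg.norm(backbone.cb[i] - backbone.cb[j]))
    return tiers.prob(d)


def _conditions(
    model_ids: Sequence[str], noise: NoiseModel
) -> list[tuple[float, tuple[int, int], BackboneSample]]:
    """Flatten the shared latent variables (model, δ_a, δ_b, backbone).

    Returns (weight, (δ_a, δ_b), backbone) triples whose weights sum to 1;
    models in the class are weighted uniformly.
    """
    if not model_ids:
        raise ValueError("empty model class")
    conds = []
    w_model = 1.0 / len(model_ids)
    for mid in model_ids:
        for da, pa in noise.offset_probs.items():
            for db, pb in noise.offset_probs.items():
                for sample in noise.backbones[mid]:
                    conds.append((w_model * pa * pb * sample.prob, (da, db), sample))
    return conds


def _candidate_prob_matrix(
    candidates: Sequence[Pair],
    conds: Sequence[tuple[float, tuple[int, int], BackboneSample]],
    tiers: LinkProbTiers,
) -> tuple[np.ndarray, np.ndarray]:
    """(weights, P) with P[l, k] = link probability of candidate l under condition k."""
    weights = np.array([c[0] for c in conds])
    P = np.empty((len(candidates), len(conds)))
    for l, pair in enumerate(candidates):
        for k, (_, delta, sample) in enumerate(conds):
            P[l, k] = link_prob(pair, delta, sample, tiers)
    return weights, P


def marginal_link_prob(
    models: Sequence[StructuralModel],
    pair: Pair,
    noise: NoiseModel,
    tiers: LinkProbTiers = LinkProbTiers(),
) -> float:
    """Noise-marginalized link probability, averaged over a model class."""
    conds = _conditions([m.model_id for m in models], noise)
    w, P = _candidate_prob_matrix([pair], conds, tiers)
    return float(w @ P[0])


def joint_link_prob(
    models: Sequence[StructuralModel],
    pair1: Pair,
    pair2: Pair,
    noise: NoiseModel,
    tiers: LinkProbTiers = LinkProbTiers(),
) -> np.ndarray:
    """Joint outcome table Pr(y1, y2) of two links, shared-noise marginalized."""
    conds = _conditions([m.model_id for m in models], noise)
    w, P = _candidate_prob_matrix([pair1, pair2], conds, tiers)
    p, q = P[0], P[1]
    return np.array(
        [
            [w @ ((1 - p) * (1 - q)), w @ ((1 - p) * q)],
            [w @ (p * (1 - q)), w @ (p * q)],
        ]
    )


def _mi_2x2(joint: np.ndarray) -> float:
    joint = np.clip(joint, 0.0, None)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = 0.0
    for x in (0, 1):
        for y in (0, 1):
            j = joint[x, y]
            if j > 0 and px[x] > 0 and py[y] > 0:
                mi += j * math.log2(j / (px[x] * py[y]))
    return max(0.0, mi)


# ---------------------------------------------------------------------------
# mRMR link selection


def select_links(
    ensemble: ModelEnsemble,
    sse_pair: Pair,
    contact_states: dict[str, int],
    noise: NoiseModel,
    tiers: LinkProbTiers = LinkProbTiers(),
    plan_size: int = DEFAULT_PLAN_SIZE,
    pr_contact: tuple[float, float] | None = None,
    sigmoid: SigmoidParams = SigmoidParams(),
    compute_epsilon: bool = True,
    max_distance: float = XLINK_MAX_DISTANCE,
) -> CrossLinkPlan:
    """Greedy mRMR selection of cross-links to probe one SSE pair.

    Relevance of a candidate link is its mutual information with the
    contact variable c: within the contact class (models whose graphs show
    the pair in contact) link probabilities are noise-marginalized; under
    c = 0 every link forms at the background rate ``tiers.p_far``.
    ``pr_contact`` supplies Pr(c) (stage-1 estimate; uniform when None).
    Redundancy is the mean mutual information with already-selected links,
    with joints marginalized over the shared (model, δ, backbone) latent
    variables and over c.  Selection stops at ``plan_size`` links or when
    candidates are exhausted.
    """
    R = common_residues(ensemble, sse_pair)
    candidates: set[Pair] = set()
    for m in ensemble.models:
        candidates |= build_xlink_graph(m, R, max_distance)
    if not candidates:
        raise ValueError(
            f"SSE pair {sse_pair} cannot be probed: no cross-linkable residue pairs"
        )
    candidates = sorted(candidates)
    if pr_contact is None:
        pr_contact = (0.5, 0.5)
    p_c0, p_c1 = float(pr_contact[0]), float(pr_contact[1])

    contact_ids = [mid for mid, s in contact_states.items() if s == 1]
    if contact_ids:
        conds = _conditions(contact_ids, noise)
        w, P = _candidate_prob_matrix(candidates, conds, tiers)
    else:
        # no model shows the pair in contact: fall back to the near tier
        # as the in-contact link probability (spec'd degenerate behaviour)
        w = np.array([1.0])
        P = np.full((len(candidates), 1), tiers.p_near)

    p1 = P @ w  # Pr(link | c = 1) per candidate
    p0 = tiers.p_far

    def relevance(l: int) -> float:
        joint = np.array(
            [
                [p_c0 * (1 - p0), p_c0 * p0],
                [p_c1 * (1 - p1[l]), p_c1 * p1[l]],
            ]
        )  # rows: c, cols: y
        return _mi_2x2(joint)

    def redundancy_with(s: int) -> np.ndarray:
        """I(ℓ, ℓ_s) for every candidate ℓ at once (stacked 2×2 tables)."""
        ps = P[s]
        j11 = p_c1 * ((P * ps) @ w) + p_c0 * p0 * p0
        j10 = p_c1 * ((P * (1 - ps)) @ w) + p_c0 * p0 * (1 - p0)
        j01 = p_c1 * (((1 - P) * ps) @ w) + p_c0 * (1 - p0) * p0
        j00 = p_c1 * (((1 - P) * (1 - ps)) @ w) + p_c0 * (1 - p0) ** 2
        mi = np.zeros(len(candidates))
        for j, px, py in (
            (j00, j00 + j01, j00 + j10),
            (j01, j00 + j01, j01 + j11),
            (j10, j10 + j11, j00 + j10),
            (j11, j10 + j11, j01 + j11),
        ):
            mask = j > 0
            mi[mask] += j[mask] * np.log2(j[mask] / (px[mask] * py[mask]))
        return np.clip(mi, 0.0, None)

    rel = np.array([relevance(l) for l in range(len(candidates))])
    red_sum = np.zeros(len(candidates))
    selected: list[int] = []
    scores: list[float] = []
    while len(selected) < min(plan_size, len(candidates)):
        score = rel - (red_sum / len(selected) if selected else 0.0)
        score[selected] = -math.inf
        # lexicographic tie-break on the (sorted) candidate list
        best_l = int(score.argmax())
        selected.append(best_l)
        scores.append(float(score[best_l]))
        red_sum += redundancy_with(best_l)
    plan = CrossLinkPlan(
        sse_pair=tuple(sse_pair),
        links=[candidates[l] for l in selected],
        scores=scores,
        marginal_probs=[float(p1[l]) for l in selected],
        k0=sigmoid.k0,
        plan_size=plan_size,
    )
    if compute_epsilon:
        plan.epsilon_xlink = xlink_bayes_error(
            plan, ensemble, contact_states, noise, tiers, sigmoid
        )
    return plan


def plan_for_fingerprint(
    ensemble: ModelEnsemble,
    fingerprint_pairs: Sequence[Pair],
    graphs: Sequence[SSEContactGraph],
    noise: NoiseModel,
    tiers: LinkProbTiers = LinkProbTiers(),
    plan_size: int = DEFAULT_PLAN_SIZE,
    pr_c: dict[Pair, np.ndarray] | None = None,
    sigmoid: SigmoidParams = SigmoidParams(),
    compute_epsilon: bool = True,
    max_distance: float = XLINK_MAX_DISTANCE,
) -> list[CrossLinkPlan]:
    """Cross-link plans for every fingerprint SSE pair (the combined plan
    is their union).  Pairs without candidates are skipped with a warning."""
    by_model = {g.model_id: g for g in graphs}
    plans = []
    for pair in fingerprint_pairs:
        states = {mid: g.state(tuple(pair)) for mid, g in by_model.items()}
        prc = None
        if pr_c is not None and tuple(pair) in pr_c:
            prc = tuple(pr_c[tuple(pair)])
        try:
            plans.append(
                select_links(
                    ensemble,
                    tuple(pair),
                    states,
                    noise,
                    tiers,
                    plan_size,
                    prc,
                    sigmoid,
                    compute_epsilon,
                    max_distance,
                )
            )
        except ValueError as exc:
            warnings.warn(str(exc))
    return plans


# ---------------------------------------------------------------------------
# data interpretation and plan evaluation


def contact_likelihood(
    k: int, plan_size: int = DEFAULT_PLAN_SIZE, params: SigmoidParams = SigmoidParams()
) -> float:
    """Sigmoidal Pr(data | c = 1) as a function of the detected-link count k."""
    if not 0 <= k <= plan_size:
        raise ValueError(f"detected count k={k} outside 0..{plan_size}")
    return 1.0 / (1.0 + math.exp(-params.effective_slope * (k - params.k0)))


@dataclass
class XlinkDecision:
    """Contact decision from a cross-link outcome vector."""

    contact: int
    lik_contact: float
    lik_no_contact: float
    tie: bool


def interpret_xlink_data(
    Y: Sequence[int], plan: CrossLinkPlan, params: SigmoidParams = SigmoidParams()
) -> XlinkDecision:
    """Compare Pr(Y | c=1) and Pr(Y | c=0) via the sigmoidal likelihoods.

    Pr(Y | c=0) is the mirrored sigmoid (decreasing in k), so the decision
    reduces to comparing k with k0; the tie at k = k0 resolves
    conservatively to "not in contact" and is flagged.
    """
    if len(Y) != len(plan.links):
        raise ValueError(f"outcome vector length {len(Y)} != plan size {len(plan.links)}")
    k = int(sum(Y))
    lik1 = contact_likelihood(k, len(plan.links), params)
    lik0 = 1.0 - lik1
    return XlinkDecision(
        contact=int(lik1 > lik0),
        lik_contact=lik1,
        lik_no_contact=lik0,
        tie=(lik1 == lik0),
    )


def xlink_bayes_error(
    plan: CrossLinkPlan,
    ensemble: ModelEnsemble,
    contact_states: dict[str, int],
    noise: NoiseModel,
    tiers: LinkProbTiers = LinkProbTiers(),
    params: SigmoidParams = SigmoidParams(),
) -> float:
    """Bayes error of a cross-link plan by exact outcome enumeration.

    ε = Σ_{c∈{0,1}} ½ Σ_{Y∈{0,1}^|L|} Pr(Y|c) · 1[decision(Y) ≠ c], with
    Pr(Y | c=1) marginalizing the product of per-link conditionals over
    the shared (model, δ, backbone) latent variables of the contact class,
    and Pr(Y | c=0) = Π p_far^{y} (1−p_far)^{1−y}.  The decision rule is
    k > k0 (ties resolve to not-in-contact).
    """
    L = len(plan.links)
    if L > ENUMERATION_CAP:
        raise ValueError(
            f"plan of {L} links exceeds the enumeration cap of {ENUMERATION_CAP}"
        )
    contact_ids = [mid for mid, s in contact_states.items() if s == 1]
    if contact_ids:
        conds = _conditions(contact_ids, noise)
        w, P = _candidate_prob_matrix(plan.links, conds, tiers)
    else:
        w = np.array([1.0])
        P = np.full((L, 1), tiers.p_near)
    P = np.clip(P, 1e-12, 1 - 1e-12)

    ints = np.arange(2 ** L, dtype=np.int64)
    Y = ((ints[:, None] >> np.arange(L - 1, -1, -1)) & 1).astype(float)
    # Pr(Y | c = 1): mixture over conditions of independent Bernoulli products
    logP1 = Y @ np.log(P) + (1 - Y) @ np.log(1 - P)  # (2^L × n_cond)
    pr_y_c1 = np.exp(logP1) @ w
    # Pr(Y | c = 0): independent background rate
    k = Y.sum(axis=1)
    p0 = min(max(tiers.p_far, 1e-12), 1 - 1e-12)
    pr_y_c0 = (p0 ** k) * ((1 - p0) ** (L - k))
    decide_contact = k > params.k0
    eps = 0.5 * pr_y_c1[~decide_contact].sum() + 0.5 * pr_y_c0[decide_contact].sum()
    return float(eps)


# ---------------------------------------------------------------------------
# tabular I/O


def plan_table(plans: Sequence[CrossLinkPlan]) -> str:
    """Combined tab-separated plan: one row per cross-link, plus per-pair
    summary comment lines carrying ε_xlink."""
    lines = ["sse_a\tsse_b\tres_i\tres_j\tincremental_score\tmarginal_link_prob"]
    for plan in plans:
        a, b = plan.sse_pair
        for (i, j), score, mp in zip(plan.links, plan.scores, plan.marginal_probs):
            lines.append(f"{a}\t{b}\t{i}\t{j}\t{score:.6f}\t{mp:.6f}")
        eps = "NA" if plan.epsilon_xlink is None else f"{plan.epsilon_xlink:.6g}"
        lines.append(f"# pair {a}-{b}\tn_links={len(plan.links)}\tk0={plan.k0}\tepsilon_xlink={eps}")
    return "\n".join(lines) + "\n"


def read_outcome_table(path) -> dict[Pair, int]:
    """Experimental outcomes: tab-separated res_i, res_j, outcome ∈ {0,1}."""
    out: dict[Pair, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("res_i"):
                continue
            parts = line.split()
            try:
                i, j, y = int(parts[0]), int(parts[1]), int(parts[2])
                if y not in (0, 1):
                    raise ValueError
            except (IndexError, ValueError):
                raise ValueError(f"{path}:{lineno}: expected 'res_i res_j outcome(0|1)'") from None
            out[(i, j)] = y
    return out
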
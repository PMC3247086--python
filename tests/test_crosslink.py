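"""Stage-2 cross-link planning: noise models, mRMR selection, sigmoid
interpretation, and the cross-link Bayes error."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from foldprobe.crosslink import (
    BackboneSample,
    LinkProbTiers,
    NoiseModel,
    SigmoidParams,
    backbone_ensemble,
    build_xlink_graph,
    common_residues,
    contact_likelihood,
    interpret_xlink_data,
    joint_link_prob,
    link_prob,
    marginal_link_prob,
    offset_distribution,
    select_links,
    xlink_bayes_error,
    CrossLinkPlan,
)
from foldprobe.structures import cb_distance
from foldprobe.simulate import two_helix_ensemble


@pytest.fixture(scope="module")
def pair_states(two_helix):
    from foldprobe.topology import build_contact_graphs

    graphs = build_contact_graphs(two_helix)
    return {g.model_id: g.state((1, 2)) for g in graphs}


# ---------------------------------------------------------------------------
# candidates


def test_common_residues_identical_intervals(two_helix):
    ra, rb = common_residues(two_helix, (1, 2))
    assert ra == list(range(1, 13))
    assert rb == list(range(17, 29))


def test_common_residues_majority_rule(jittered_fixture):
    ensemble, _, _ = jittered_fixture
    for sse_pair in [(1, 2), (2, 3)]:
        ra, rb = common_residues(ensemble, sse_pair)
        for residues, sse_id in ((ra, sse_pair[0]), (rb, sse_pair[1])):
            sse = ensemble.common_sse(sse_id)
            # brute-force per-residue count oracle
            for i in range(sse.start - 4, sse.end + 5):
                count = sum(1 for s, e in sse.members.values() if s <= i <= e)
                assert (i in residues) == (count >= len(sse.members) / 2)


def test_xlink_graph_brute_force(two_helix):
    model = two_helix.models[0]
    R = common_residues(two_helix, (1, 2))
    edges = build_xlink_graph(model, R)
    assert edges
    expected = {
        (i, j)
        for i in R[0]
        for j in R[1]
        if cb_distance(model, i, j) <= 19.0
    }
    assert edges == expected


def test_xlink_graph_empty_when_far():
    far = two_helix_ensemble(n_models=2, separation=40.0)
    R = common_residues(far, (1, 2))
    assert build_xlink_graph(far.models[0], R) == set()


# ---------------------------------------------------------------------------
# offset distribution


def test_offset_distribution_degenerate():
    assert offset_distribution(0) == {0: 1.0}


def test_offset_distribution_hand_normalized():
    probs = offset_distribution(2, decay=1.0)
    z = 2 * math.exp(-1) + 2 * math.exp(-2)
    assert probs[0] == pytest.approx(0.5)
    assert probs[1] == pytest.approx(0.5 * math.exp(-1) / z)
    assert probs[-1] == probs[1]
    assert probs[2] == pytest.approx(0.5 * math.exp(-2) / z)


@pytest.mark.parametrize("delta_max,decay", [(1, 0.5), (2, 1.0), (4, 2.0)])
def test_offset_distribution_normalizes(delta_max, decay):
    probs = offset_distribution(delta_max, decay)
    assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)
    assert all(probs[d] == probs[-d] for d in probs)


# ---------------------------------------------------------------------------
# elastic-network backbone ensemble


def test_backbone_ensemble_center_reproduces_input(two_helix):
    model = two_helix.models[0]
    samples = backbone_ensemble(model, n_samples=5, amplitude_max=3.0)
    assert len(samples) == 5
    center = samples[2]
    for r in model.residues:
        assert np.allclose(center.cb[r.index], r.cb, atol=1e-9)


def test_backbone_probabilities_symmetric_peaked(two_helix):
    samples = backbone_ensemble(two_helix.models[0], n_samples=5, amplitude_max=3.0)
    probs = [s.prob for s in samples]
    assert probs[0] == pytest.approx(probs[-1])
    assert probs[1] == pytest.approx(probs[-2])
    assert max(probs) == probs[2]
    assert sum(probs) == pytest.approx(1.0)
    # default temperature: extreme sample at 5% of the center's weight
    assert probs[0] / probs[2] == pytest.approx(0.05, rel=1e-6)


def test_enm_has_six_rigid_body_modes(two_helix):
    from foldprobe.crosslink import _anm_hessian

    model = two_helix.models[0]
    coords = np.array([r.ca for r in model.residues])
    H = _anm_hessian(coords, 10.0)
    w = np.linalg.eigvalsh(H)
    assert (np.abs(w) < 1e-8).sum() == 6
    assert w[6] > 1e-8


def test_disconnected_network_falls_back(two_helix):
    far = two_helix_ensemble(n_models=2, separation=40.0)
    with pytest.warns(UserWarning, match="zero modes"):
        samples = backbone_ensemble(far.models[0], n_samples=5, amplitude_max=3.0)
    assert len(samples) == 1 and samples[0].prob == 1.0


# ---------------------------------------------------------------------------
# link probabilities


def test_link_prob_tiers(two_helix):
    tiers = LinkProbTiers()
    # synthetic single-residue backbones at controlled distances
    for d, expected in ((5.0, 0.95), (12.0, 0.5), (25.0, 0.05)):
        sample = BackboneSample(
            cb={1: np.zeros(3), 2: np.array([d, 0.0, 0.0])}, prob=1.0
        )
        assert link_prob((1, 2), (0, 0), sample, tiers) == expected
    # boundary values sit in the lower tier (inclusive thresholds)
    for d, expected in ((9.0, 0.95), (19.0, 0.5)):
        sample = BackboneSample(cb={1: np.zeros(3), 2: np.array([d, 0, 0])}, prob=1.0)
        assert link_prob((1, 2), (0, 0), sample, tiers) == expected


def test_link_prob_out_of_range_offset_is_far():
    sample = BackboneSample(cb={1: np.zeros(3), 2: np.ones(3)}, prob=1.0)
    assert link_prob((1, 2), (5, 0), sample, LinkProbTiers()) == 0.05


def test_marginal_reduces_to_tiered_without_noise(two_helix):
    noise = NoiseModel.degenerate(two_helix.models)
    tiers = LinkProbTiers()
    model = two_helix.models[0]
    for pair in [(1, 17), (5, 22), (12, 28)]:
        expected = tiers.prob(cb_distance(model, *pair))
        got = marginal_link_prob([model], pair, noise, tiers)
        assert got == pytest.approx(expected)


def test_marginal_matches_exhaustive_noise_enumeration(two_helix):
    """Brute-force sum over every (δa, δb, backbone) combination."""
    from foldprobe.crosslink import build_noise_model

    models = two_helix.models[:2]
    noise = build_noise_model(models, delta_max=1, n_samples=3)
    tiers = LinkProbTiers()
    pair = (6, 21)
    expected = 0.0
    for m in models:
        for da, pa in noise.offset_probs.items():
            for db, pb in noise.offset_probs.items():
                for sample in noise.backbones[m.model_id]:
                    expected += (
                        pa * pb * sample.prob * link_prob(pair, (da, db), sample, tiers)
                    ) / len(models)
    assert marginal_link_prob(models, pair, noise, tiers) == pytest.approx(expected)


def test_joint_factorizes_without_shared_variation(two_helix):
    noise = NoiseModel.degenerate(two_helix.models[:1])
    tiers = LinkProbTiers()
    table = joint_link_prob(two_helix.models[:1], (3, 19), (9, 25), noise, tiers)
    assert table.sum() == pytest.approx(1.0, abs=1e-12)
    p1 = table[1].sum()
    p2 = table[:, 1].sum()
    assert table[1, 1] == pytest.approx(p1 * p2, abs=1e-12)


def test_joint_normalizes_with_noise(two_helix):
    from foldprobe.crosslink import build_noise_model

    noise = build_noise_model(two_helix.models[:3], delta_max=1, n_samples=3)
    table = joint_link_prob(two_helix.models[:3], (3, 19), (9, 25), noise, LinkProbTiers())
    assert table.sum() == pytest.approx(1.0, abs=1e-9)
    assert (table >= 0).all()


# ---------------------------------------------------------------------------
# mRMR link selection


def _oracle_select(ensemble, sse_pair, states, noise, tiers, plan_size, pr_contact):
    """Independent re-implementation of the incremental link-selection rule,
    looping explicitly over noise conditions."""
    R = common_residues(ensemble, sse_pair)
    candidates = set()
    for m in ensemble.models:
        candidates |= build_xlink_graph(m, R)
    candidates = sorted(candidates)
    contact_models = [m for m in ensemble.models if states[m.model_id] == 1]
    p0c, p1c = pr_contact
    p_far = tiers.p_far

    def conds():
        for m in contact_models:
            for da, pa in noise.offset_probs.items():
                for db, pb in noise.offset_probs.items():
                    for s in noise.backbones[m.model_id]:
                        yield pa * pb * s.prob / len(contact_models), (da, db), s

    def mi(joint):
        out = 0.0
        px = [joint[0][0] + joint[0][1], joint[1][0] + joint[1][1]]
        py = [joint[0][0] + joint[1][0], joint[0][1] + joint[1][1]]
        for x in (0, 1):
            for y in (0, 1):
                if joint[x][y] > 0:
                    out += joint[x][y] * math.log2(joint[x][y] / (px[x] * py[y]))
        return max(0.0, out)

    def relevance(link):
        p1 = sum(w * link_prob(link, d, s, tiers) for w, d, s in conds())
        return mi([[p0c * (1 - p_far), p0c * p_far], [p1c * (1 - p1), p1c * p1]])

    def redundancy(a, b):
        e11 = sum(
            w * link_prob(a, d, s, tiers) * link_prob(b, d, s, tiers)
            for w, d, s in conds()
        )
        pa = sum(w * link_prob(a, d, s, tiers) for w, d, s in conds())
        pb = sum(w * link_prob(b, d, s, tiers) for w, d, s in conds())
        j = [
            [
                p1c * (1 - pa - pb + e11) + p0c * (1 - p_far) ** 2,
                p1c * (pb - e11) + p0c * (1 - p_far) * p_far,
            ],
            [
                p1c * (pa - e11) + p0c * p_far * (1 - p_far),
                p1c * e11 + p0c * p_far ** 2,
            ],
        ]
        return mi(j)

    L, scores = [], []
    while len(L) < min(plan_size, len(candidates)):
        best, best_score = None, -np.inf
        for cand in candidates:
            if cand in L:
                continue
            s = relevance(cand)
            if L:
                s -= sum(redundancy(cand, l) for l in L) / len(L)
            if s > best_score + 1e-15:
                best, best_score = cand, s
        L.append(best)
        scores.append(best_score)
    return L, scores


def test_select_links_matches_oracle(pair_states):
    """Greedy trajectory equals an independent step-by-step recomputation
    on a small candidate set."""
    small = two_helix_ensemble(n_models=3, separation=8.0, length=4, seed=2)
    from foldprobe.topology import build_contact_graphs
    from foldprobe.crosslink import build_noise_model

    graphs = build_contact_graphs(small, min_contacts=3, min_residue_fraction=0.1)
    states = {g.model_id: g.state((1, 2)) for g in graphs}
    assert set(states.values()) == {1}
    noise = build_noise_model(small.models, delta_max=1, n_samples=3)
    tiers = LinkProbTiers()
    plan = select_links(
        small, (1, 2), states, noise, tiers, plan_size=6,
        pr_contact=(0.2, 0.8), compute_epsilon=False,
    )
    links, scores = _oracle_select(small, (1, 2), states, noise, tiers, 6, (0.2, 0.8))
    assert plan.links == links
    assert np.allclose(plan.scores, scores, atol=1e-9)


def test_select_links_no_duplicates(two_helix, pair_states):
    noise = NoiseModel.degenerate(two_helix.models)
    plan = select_links(
        two_helix, (1, 2), pair_states, noise, plan_size=10, compute_epsilon=False
    )
    assert len(plan.links) == len(set(plan.links)) == 10


def test_select_links_single_candidate():
    near = two_helix_ensemble(n_models=2, separation=18.5, length=1)
    from foldprobe.topology import build_contact_graphs

    noise = NoiseModel.degenerate(near.models)
    plan = select_links(
        near, (1, 2), {m.model_id: 1 for m in near.models}, noise,
        plan_size=10, compute_epsilon=False,
    )
    assert len(plan.links) == 1


def test_select_links_duplicate_geometry_chosen_last(two_helix, pair_states):
    """A second copy of an identical-geometry link is fully redundant and
    adds a near-zero incremental score."""
    noise = NoiseModel.degenerate(two_helix.models)
    plan = select_links(
        two_helix, (1, 2), pair_states, noise, plan_size=10, compute_epsilon=False
    )
    # the two-helix fixture is noiseless: every model identical, so any
    # two links with equal distance have identical outcome distributions.
    # Verify the greedy scores drop once redundant links are forced in.
    assert plan.scores[0] > plan.scores[-1]


def test_no_contact_class_falls_back_to_near_tier():
    far = two_helix_ensemble(n_models=2, separation=15.0)
    noise = NoiseModel.degenerate(far.models)
    plan = select_links(
        far, (1, 2), {m.model_id: 0 for m in far.models}, noise,
        plan_size=3, compute_epsilon=False,
    )
    assert len(plan.links) == 3


def test_unprobeable_pair_raises():
    far = two_helix_ensemble(n_models=2, separation=40.0)
    noise = NoiseModel.degenerate(far.models)
    with pytest.raises(ValueError, match=r"\(1, 2\)"):
        select_links(far, (1, 2), {m.model_id: 1 for m in far.models}, noise)


# ---------------------------------------------------------------------------
# sigmoid interpretation


def test_contact_likelihood_anchor_values():
    assert contact_likelihood(0) == pytest.approx(0.05, abs=1e-12)
    assert contact_likelihood(3) == 0.5
    assert contact_likelihood(6) == pytest.approx(0.95, abs=1e-12)


def test_contact_likelihood_strictly_increasing():
    vals = [contact_likelihood(k) for k in range(11)]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_contact_likelihood_range_check():
    with pytest.raises(ValueError):
        contact_likelihood(11)
    with pytest.raises(ValueError):
        contact_likelihood(-1)


def test_interpret_xlink_decisions():
    plan = CrossLinkPlan(sse_pair=(1, 2), links=[(i, i + 20) for i in range(1, 11)])
    all_on = interpret_xlink_data([1] * 10, plan)
    assert all_on.contact == 1 and not all_on.tie
    all_off = interpret_xlink_data([0] * 10, plan)
    assert all_off.contact == 0
    at_k0 = interpret_xlink_data([1, 1, 1] + [0] * 7, plan)
    assert at_k0.contact == 0 and at_k0.tie
    assert at_k0.lik_contact == at_k0.lik_no_contact == 0.5
    with pytest.raises(ValueError):
        interpret_xlink_data([1, 0], plan)


# ---------------------------------------------------------------------------
# cross-link Bayes error


def test_xlink_bayes_error_hand_enumeration(two_helix, pair_states):
    """plan_size=1, k0=0: four-term enumeration gives 0.5[(1−p) + p_far]."""
    noise = NoiseModel.degenerate(two_helix.models)
    tiers = LinkProbTiers()
    plan = select_links(
        two_helix, (1, 2), pair_states, noise, tiers, plan_size=1,
        sigmoid=SigmoidParams(k0=0, slope=1.0), compute_epsilon=False,
    )
    p = plan.marginal_probs[0]
    eps = xlink_bayes_error(
        plan, two_helix, pair_states, noise, tiers, SigmoidParams(k0=0, slope=1.0)
    )
    assert eps == pytest.approx(0.5 * ((1 - p) + tiers.p_far), abs=1e-9)


def test_xlink_bayes_error_matches_monte_carlo(two_helix, pair_states):
    from foldprobe.crosslink import build_noise_model, _conditions, _candidate_prob_matrix

    noise = build_noise_model(two_helix.models, delta_max=1, n_samples=3)
    tiers = LinkProbTiers()
    plan = select_links(
        two_helix, (1, 2), pair_states, noise, tiers, plan_size=8,
        compute_epsilon=False,
    )
    eps = xlink_bayes_error(plan, two_helix, pair_states, noise, tiers)

    rng = np.random.default_rng(17)
    contact_ids = [mid for mid, s in pair_states.items() if s == 1]
    conds = _conditions(contact_ids, noise)
    weights = np.array([c[0] for c in conds])
    _, P = _candidate_prob_matrix(plan.links, conds, tiers)
    n = 60_000
    wrong = 0
    for _ in range(n):
        if rng.random() < 0.5:  # c = 1
            k_cond = rng.choice(len(conds), p=weights)
            y = rng.random(len(plan.links)) < P[:, k_cond]
            wrong += int(y.sum() <= 3)
        else:  # c = 0
            y = rng.random(len(plan.links)) < tiers.p_far
            wrong += int(y.sum() > 3)
    mc = wrong / n
    se = math.sqrt(eps * (1 - eps) / n)
    assert abs(eps - mc) < 3 * se + 1e-9


def test_xlink_bayes_error_shrinks_with_plan_size(two_helix, pair_states):
    """More cross-links shrink ε while the decision midpoint k0 = 3 is the
    binding constraint; beyond ~2·k0 links the background false-positive
    channel grows slowly, so monotonicity is only asserted up to there."""
    noise = NoiseModel.degenerate(two_helix.models)
    eps = {}
    for size in (2, 4, 6, 8, 10):
        plan = select_links(
            two_helix, (1, 2), pair_states, noise, plan_size=size,
            compute_epsilon=False,
        )
        eps[size] = xlink_bayes_error(plan, two_helix, pair_states, noise)
    ordered = [eps[s] for s in (2, 4, 6, 8)]
    assert all(b <= a + 1e-9 for a, b in zip(ordered, ordered[1:]))
    assert eps[10] < 0.01 < eps[2]


def test_xlink_bayes_error_cap():
    plan = CrossLinkPlan(sse_pair=(1, 2), links=[(i, i + 100) for i in range(25)])
    ens = two_helix_ensemble(n_models=2)
    with pytest.raises(ValueError, match="cap"):
        xlink_bayes_error(plan, ens, {m.model_id: 1 for m in ens.models},
                          NoiseModel.degenerate(ens.models))
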
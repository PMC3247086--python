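"""Stage 2: plan disulfide cross-links to probe one SSE pair.

Takes two ideal 12-residue helices 8 Å apart (in contact in every model)
and selects 10 residue pairs by mRMR under the full noise model:
±2-residue threading misalignment and a 5-sample elastic-network
backbone ensemble.  Each link's noise-marginalized formation probability
and the plan's Bayes error (exact enumeration over all 2^10 outcome
vectors) are reported.
"""

from foldprobe import select_links, two_helix_ensemble
from foldprobe.crosslink import build_noise_model
from foldprobe.fingerprint import estimate_contact_probs
from foldprobe.topology import build_contact_graphs

ensemble = two_helix_ensemble(n_models=10, separation=8.0, length=12, seed=1)
graphs = build_contact_graphs(ensemble)
states = {g.model_id: g.state((1, 2)) for g in graphs}
prob_model = estimate_contact_probs(graphs)
noise = build_noise_model(ensemble.models)

plan = select_links(
    ensemble, (1, 2), states, noise,
    pr_contact=tuple(prob_model.pr_c[(1, 2)]), plan_size=10,
)

print("link   residues   score    Pr(link | contact)")
for k, ((i, j), s, p) in enumerate(
    zip(plan.links, plan.scores, plan.marginal_probs), 1
):
    print(f"{k:4d}   {i:3d}-{j:<3d}   {s:6.4f}   {p:.3f}")
print(f"\nplan Bayes error: {plan.epsilon_xlink:.4%}")
print(
    "A link probability near 0.8 reflects a tight contact blurred by\n"
    "misalignment/flexibility; the sub-1% Bayes error means 10 links\n"
    "decide this SSE contact almost surely despite that noise."
)
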
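"""Stage 1: select a topological fingerprint for a synthetic ensemble.

Builds a 12-model ensemble of four helices packed in two alternative
topologies, estimates per-SSE-pair contact probabilities, and grows the
fingerprint greedily by entropy minus mean redundancy.  The table shows,
per greedy step, the incremental mRMR score (bits) and the plan metrics:
Bayes error ε (probability of picking a wrong-fold model), expected tie
ratio τ (mass of datasets with several tied-for-best models), and
none-of-the-above ratio ν (fraction of datasets an unrepresented fold
would win).
"""

from foldprobe import FixtureSpec, generate_fixture
from foldprobe.fingerprint import (
    estimate_contact_probs,
    fingerprint_report,
    select_fingerprint,
)
from foldprobe.topology import build_contact_graphs

ensemble, truth, info = generate_fixture(
    FixtureSpec(n_models=12, n_sses=4, topology_variants=2, seed=0)
)
graphs = build_contact_graphs(ensemble)
prob_model = estimate_contact_probs(graphs, q=0.8)
fingerprint = select_fingerprint(prob_model)

print(f"common SSE pairs: {len(prob_model.pairs)}, "
      f"fingerprint: {fingerprint.pairs}")
print(fingerprint_report(fingerprint, prob_model, graphs).to_string(index=False))
print(
    "\nε = 0 with τ = 1 means the data can never favour a wrong fold, but\n"
    "models sharing the truth's fold remain tied — the expected outcome\n"
    "when several models are topologically identical."
)
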
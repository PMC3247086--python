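"""Robustness to threading misalignment.

Every model in this fixture is built one residue off register relative
to the ground truth.  Counting the models whose geometry explains all
simulated cross-link outcomes shows the value of marginalizing the
offset distribution: at δ = 0 the shifted models cannot explain the
data; allowing |δ| ≤ 1 recovers them.
"""

from foldprobe import FixtureSpec, generate_fixture
from foldprobe.crosslink import NoiseModel, plan_for_fingerprint
from foldprobe.fingerprint import estimate_contact_probs, select_fingerprint
from foldprobe.simulate import agreeing_models, simulate_outcomes
from foldprobe.topology import build_contact_graphs

spec = FixtureSpec(n_models=10, threading_offset=1, seed=6)
ensemble, truth, info = generate_fixture(spec)
graphs = build_contact_graphs(ensemble)
prob_model = estimate_contact_probs(graphs)
fingerprint = select_fingerprint(prob_model)
plans = plan_for_fingerprint(
    ensemble, fingerprint.pairs, graphs,
    NoiseModel.degenerate(ensemble.models), compute_epsilon=False,
)
Y, _ = simulate_outcomes(truth, plans)

for delta in (0, 1, 2):
    n = len(agreeing_models(ensemble, plans, Y, delta_max=delta))
    print(f"models agreeing with all simulated cross-links at |δ| <= {delta}: {n}")
print(
    "\nThe jump from δ=0 to δ=1 is the one-residue register error being\n"
    "absorbed by the misalignment model instead of being mistaken for a\n"
    "different fold."
)
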
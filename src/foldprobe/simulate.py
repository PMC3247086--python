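"""End-to-end validation harness on synthetic model ensembles.

The fixture generator emulates the structure of fold-recognition model
ensembles: one common SSE complement (ideal helices and strands) placed
on a linear packing layout, with alternative packing topologies realized
as permutations of SSEs over layout slots, plus per-model boundary
jitter, threading offsets, and Gaussian coordinate noise.  A ground-truth
structure built from one chosen topology variant stands in for the
crystal structure.

Simulated data are read off the ground truth: a planned cross-link forms
iff its Cβ–Cβ distance in the truth is below 9 Å.  The harness then runs
interpretation, labels each model by fold equality with the truth at a
sweep of contact-fraction thresholds r, and summarizes discrimination
power with ROC/AUC per r.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .config import RunConfig
from .crosslink import (
    CrossLinkPlan,
    LinkProbTiers,
    NoiseModel,
    SigmoidParams,
    build_noise_model,
    interpret_xlink_data,
    plan_for_fingerprint,
)
from .fingerprint import (
    Fingerprint,
    FoldDecision,
    assess_fingerprint,
    estimate_contact_probs,
    interpret_fold_data,
    select_fingerprint,
)
from .structures import (
    ModelEnsemble,
    Residue,
    SSEAnnotation,
    StructuralModel,
    cb_distance,
    match_common_sses,
)
from .topology import build_contact_graphs, fold_equal, fold_signature

__all__ = [
    "FixtureSpec",
    "SimulationReport",
    "generate_fixture",
    "two_helix_ensemble",
    "write_pdb",
    "write_fixture_pdbs",
    "simulate_outcomes",
    "label_models",
    "roc_analysis",
    "run_end_to_end",
    "agreeing_models",
]

#: Distance between adjacent packing slots (Å); adjacent SSEs are in
#: contact, SSEs one slot further apart are not.
SLOT_SPACING = 10.0
#: Sequence-numbering gap between consecutive SSE intervals.
SEQUENCE_GAP = 4
HELIX_RISE = 1.5
HELIX_TWIST = math.radians(100.0)
HELIX_RADIUS = 2.3
STRAND_RISE = 3.3
SIM_XLINK_DISTANCE = 9.0


@dataclass
class FixtureSpec:
    """Parameters of a synthetic model ensemble."""

    n_sses: int = 4
    sse_kind_pattern: tuple[str, ...] = ("H",)
    sse_length: int = 12
    n_models: int = 20
    topology_variants: int = 2
    boundary_jitter: int = 0
    coordinate_noise: float = 0.0
    threading_offset: int = 0
    seed: int = 0
    truth_variant: int = 0
    truth_in_ensemble: bool = True

    def __post_init__(self) -> None:
        if self.n_sses < 3:
            raise ValueError("fixtures need at least 3 SSEs")
        if self.topology_variants < 2:
            raise ValueError("fixtures need at least 2 topology variants")
        if min(self.sse_length, self.n_models) < 1:
            raise ValueError("counts must be positive")
        if not self.truth_in_ensemble and self.topology_variants < 3:
            raise ValueError(
                "excluding the truth variant needs >= 3 variants so the "
                "ensemble still holds >= 2"
            )

    def kinds(self) -> list[str]:
        pat = self.sse_kind_pattern
        return [pat[i % len(pat)] for i in range(self.n_sses)]

    def nominal_interval(self, sse_index: int) -> tuple[int, int]:
        start = sse_index * (self.sse_length + SEQUENCE_GAP) + 1
        return start, start + self.sse_length - 1


@dataclass
class SimulationReport:
    """Everything the end-to-end harness computed for one fixture."""

    spec: FixtureSpec
    fingerprint: Fingerprint
    plans: list[CrossLinkPlan]
    simulated_Y: dict[tuple[int, int], list[int]]
    simulated_X: dict[tuple[int, int], int]
    decision: FoldDecision
    fold_labels: dict[float, dict[str, bool]]
    roc: dict[float, tuple[float | None, list[tuple[float, float]]]]
    nota_detected: bool
    truth_variant_models: list[str]
    variant_of_model: dict[str, int]

    @property
    def auc(self) -> dict[float, float | None]:
        return {r: a for r, (a, _) in self.roc.items()}


# ---------------------------------------------------------------------------
# fixture geometry


def _sse_coords(
    kind: str,
    slot_x: float,
    t: float,
    center_t: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Cα and Cβ of residue at axial position t of an SSE in a slot."""
    z = (t - center_t) * (HELIX_RISE if kind == "H" else STRAND_RISE)
    if kind == "H":
        theta = t * HELIX_TWIST
        ca = np.array([slot_x + HELIX_RADIUS * math.cos(theta),
                       HELIX_RADIUS * math.sin(theta), z])
        cb = np.array([slot_x + (HELIX_RADIUS + 1.53) * math.cos(theta),
                       (HELIX_RADIUS + 1.53) * math.sin(theta), z])
    else:
        side = 1.0 if int(round(t)) % 2 == 0 else -1.0
        ca = np.array([slot_x, 0.0, z])
        cb = np.array([slot_x + side * 1.53, 0.0, z])
    return ca, cb


def _build_model(
    spec: FixtureSpec,
    model_id: str,
    permutation: Sequence[int],
    jitter: dict[int, tuple[int, int]],
    offsets: dict[int, int],
    noise_rng: np.random.Generator | None,
) -> StructuralModel:
    """One model: SSE k sits in slot permutation.index(k), ideal geometry.

    ``offsets[k]`` is the threading offset of SSE k: the residue numbered
    r is built at the axial position of nominal residue r + δ, so the
    model's numbering is off register by δ relative to the geometry.
    """
    kinds = spec.kinds()
    slot_of_sse = {sse: slot for slot, sse in enumerate(permutation)}
    residues: list[Residue] = []
    annotations: list[SSEAnnotation] = []
    for k in range(spec.n_sses):
        s0, e0 = spec.nominal_interval(k)
        j1, j2 = jitter.get(k, (0, 0))
        start, end = max(1, s0 + j1), max(s0 + 1, e0 + j2)
        delta = offsets.get(k, 0)
        slot_x = slot_of_sse[k] * SLOT_SPACING
        center_t = (s0 + e0) / 2.0
        for r in range(start, end + 1):
            ca, cb = _sse_coords(kinds[k], slot_x, float(r + delta), center_t)
            if noise_rng is not None and spec.coordinate_noise > 0:
                shift = noise_rng.normal(0.0, spec.coordinate_noise, 3)
                ca = ca + shift
                cb = cb + shift
            residues.append(Residue(index=r, aa="A", ca=ca, cb=cb))
        annotations.append(SSEAnnotation(kinds[k], start, end))
    return StructuralModel(model_id=model_id, residues=residues, sses=annotations)


def _min_inter_sse_distance(model: StructuralModel) -> float:
    coords = np.array([r.ca for r in model.residues])
    # SSEs occupy disjoint index blocks; nearest approach between blocks
    idx = np.array([r.index for r in model.residues])
    blocks = np.cumsum(np.r_[0, np.diff(idx) > 1])
    best = np.inf
    for b in np.unique(blocks):
        a_mask = blocks == b
        d = np.linalg.norm(coords[a_mask][:, None, :] - coords[~a_mask][None, :, :], axis=-1)
        if d.size:
            best = min(best, float(d.min()))
    return best


def _sample_permutations(
    n_sses: int, n_variants: int, rng: np.random.Generator
) -> list[list[int]]:
    """Distinct packing topologies: permutations with pairwise-distinct
    adjacent-slot SSE pair sets.  Variant 0 is the identity layout."""

    def edge_set(perm: Sequence[int]) -> frozenset[frozenset[int]]:
        return frozenset(frozenset((perm[s], perm[s + 1])) for s in range(len(perm) - 1))

    variants = [list(range(n_sses))]
    seen = {edge_set(variants[0])}
    attempts = 0
    while len(variants) < n_variants:
        attempts += 1
        if attempts > 1000:
            raise ValueError(
                f"could not find {n_variants} distinct packing topologies for {n_sses} SSEs"
            )
        perm = list(rng.permutation(n_sses))
        es = edge_set(perm)
        if es not in seen:
            seen.add(es)
            variants.append([int(x) for x in perm])
    return variants


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[ModelEnsemble, StructuralModel, dict]:
    """Generate a synthetic ensemble plus its ground-truth structure.

    Deterministic given ``spec.seed``.  Models cycle through the available
    topology variants (all variants, or all but the truth variant when
    ``truth_in_ensemble`` is False); each gets its own boundary jitter and
    coordinate noise.  The ground truth is an unperturbed build of
    ``truth_variant``.
    """
    rng = np.random.default_rng(spec.seed)
    variants = _sample_permutations(spec.n_sses, spec.topology_variants, rng)
    pool = list(range(spec.topology_variants))
    if not spec.truth_in_ensemble:
        pool = [v for v in pool if v != spec.truth_variant]

    models: list[StructuralModel] = []
    variant_of_model: dict[str, int] = {}
    for i in range(spec.n_models):
        variant = pool[i % len(pool)]
        model_id = f"model_{i:03d}"
        for attempt in range(100):
            jitter = {
                k: (
                    int(rng.integers(-spec.boundary_jitter, spec.boundary_jitter + 1)),
                    int(rng.integers(-spec.boundary_jitter, spec.boundary_jitter + 1)),
                )
                for k in range(spec.n_sses)
            } if spec.boundary_jitter else {}
            offsets = (
                {k: spec.threading_offset for k in range(spec.n_sses)}
                if spec.threading_offset
                else {}
            )
            model = _build_model(spec, model_id, variants[variant], jitter, offsets, rng)
            if _min_inter_sse_distance(model) > 2.5:
                break
        else:
            raise ValueError(f"unresolvable steric clashes generating {model_id}")
        models.append(model)
        variant_of_model[model_id] = variant

    truth = _build_model(spec, "truth", variants[spec.truth_variant], {}, {}, None)
    common = match_common_sses(models)
    ensemble = ModelEnsemble(
        target_id=f"fixture_seed{spec.seed}",
        models=models,
        common_sses=common,
    )
    info = {"variants": variants, "variant_of_model": variant_of_model}
    return ensemble, truth, info


def two_helix_ensemble(
    n_models: int = 10,
    separation: float = 8.0,
    length: int = 12,
    coordinate_noise: float = 0.0,
    seed: int = 0,
) -> ModelEnsemble:
    """Minimal ensemble: two parallel ideal helices a fixed distance apart.

    Used for single-SSE-pair cross-link planning studies; every model has
    the pair in contact for separations around 8 Å.
    """
    rng = np.random.default_rng(seed)
    models = []
    for i in range(n_models):
        residues = []
        annotations = []
        for k in range(2):
            start = k * (length + SEQUENCE_GAP) + 1
            end = start + length - 1
            center_t = (start + end) / 2.0
            for r in range(start, end + 1):
                ca, cb = _sse_coords("H", k * separation, float(r), center_t)
                if coordinate_noise > 0:
                    shift = rng.normal(0.0, coordinate_noise, 3)
                    ca, cb = ca + shift, cb + shift
                residues.append(Residue(index=r, aa="A", ca=ca, cb=cb))
            annotations.append(SSEAnnotation("H", start, end))
        models.append(StructuralModel(f"model_{i:03d}", residues, annotations))
    common = match_common_sses(models)
    return ModelEnsemble(target_id="two_helix", models=models, common_sses=common)


# ---------------------------------------------------------------------------
# PDB output (for round-trips and inspection)

_AA3 = {"A": "ALA", "G": "GLY", "C": "CYS", "X": "UNK"}


def write_pdb(model: StructuralModel, path: str | Path) -> None:
    """Write a model as a PDB file with HELIX/SHEET records and
    N/CA/C/CB atoms (N and C interpolated along the Cα trace; glycine
    gets no CB record)."""
    path = Path(path)
    lines = []
    for ser, ann in enumerate(model.sses, start=1):
        if ann.kind == "H":
            lines.append(
                "HELIX  " + f"{ser:3d} " + f"{ser:3d} " + "ALA " + "A "
                + f"{ann.start:4d} " + " " + "ALA " + "A " + f"{ann.end:4d} " + " 1"
            )
        else:
            lines.append(
                "SHEET  " + f"{ser:3d} " + "  S" + " 1" + " " + "ALA "
                + "A" + f"{ann.start:4d} " + " " + "ALA " + "A" + f"{ann.end:4d} " + " 0"
            )
    serial = 1

    def atom_line(name: str, res: Residue, resname: str, xyz: np.ndarray) -> str:
        nonlocal serial
        line = (
            f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} A{res.index:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {name[0]:>2s}"
        )
        serial += 1
        return line

    residues = model.residues
    for p, res in enumerate(residues):
        resname = _AA3.get(res.aa, "ALA")
        prev_ca = residues[p - 1].ca if p > 0 and residues[p - 1].index == res.index - 1 else None
        next_ca = (
            residues[p + 1].ca
            if p + 1 < len(residues) and residues[p + 1].index == res.index + 1
            else None
        )
        toward_prev = prev_ca - res.ca if prev_ca is not None else (
            res.ca - next_ca if next_ca is not None else np.array([1.0, 0, 0])
        )
        toward_next = next_ca - res.ca if next_ca is not None else (
            res.ca - prev_ca if prev_ca is not None else np.array([-1.0, 0, 0])
        )
        n_pos = res.ca + 0.45 * toward_prev
        c_pos = res.ca + 0.47 * toward_next
        lines.append(atom_line("N", res, resname, n_pos))
        lines.append(atom_line("CA", res, resname, res.ca))
        lines.append(atom_line("C", res, resname, c_pos))
        if res.aa != "G":
            lines.append(atom_line("CB", res, resname, res.cb))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_fixture_pdbs(models: Sequence[StructuralModel], directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in models:
        p = directory / f"{m.model_id}.pdb"
        write_pdb(m, p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# simulated data and evaluation


def simulate_outcomes(
    truth: StructuralModel,
    plans: Sequence[CrossLinkPlan],
    threshold: float = SIM_XLINK_DISTANCE,
    sigmoid: SigmoidParams = SigmoidParams(),
) -> tuple[dict[tuple[int, int], list[int]], dict[tuple[int, int], int]]:
    """Read simulated cross-link outcomes off the ground-truth structure.

    A planned link forms (y = 1) iff its Cβ–Cβ distance in the truth is
    strictly below ``threshold`` (9 Å — deliberately tighter than the
    19 Å cross-linkable planning window).  The SSE-pair contact data X
    follow by interpreting each plan's outcome vector.
    """
    Y: dict[tuple[int, int], list[int]] = {}
    X: dict[tuple[int, int], int] = {}
    for plan in plans:
        outcomes = []
        for i, j in plan.links:
            if not (truth.has_residue(i) and truth.has_residue(j)):
                warnings.warn(f"truth lacks residue {i} or {j}; outcome set to 0")
                outcomes.append(0)
                continue
            outcomes.append(int(cb_distance(truth, i, j) < threshold))
        Y[plan.sse_pair] = outcomes
        X[plan.sse_pair] = interpret_xlink_data(outcomes, plan, sigmoid).contact
    return Y, X


def label_models(
    ensemble: ModelEnsemble,
    truth: StructuralModel,
    r_values: Sequence[float],
    min_contacts: int = 5,
    contact_distance: float = 9.0,
) -> dict[float, dict[str, bool]]:
    """Fold labels: is each model the same fold as the truth, per r threshold."""
    from .topology import build_contact_graph

    if not ensemble.common_sses:
        raise ValueError("ensemble has no common SSEs to label against")
    pairs = ensemble.sse_pairs()
    out: dict[float, dict[str, bool]] = {}
    for r in r_values:
        truth_sig = fold_signature(
            build_contact_graph(truth, ensemble, min_contacts, r, contact_distance), pairs
        )
        out[r] = {}
        for m in ensemble.models:
            sig = fold_signature(
                build_contact_graph(m, ensemble, min_contacts, r, contact_distance), pairs
            )
            out[r][m.model_id] = sig.states == truth_sig.states
    return out


def roc_analysis(
    model_likelihoods: dict[str, float], fold_labels: dict[str, bool]
) -> tuple[float | None, list[tuple[float, float]]]:
    """ROC curve and AUC for ranking models by likelihood.

    Returns (None, []) when the labels are degenerate (no positives or no
    negatives), rather than a fabricated 0 or 1.  Ties in likelihood are
    handled by the midrank convention of the trapezoidal AUC.
    """
    from sklearn.metrics import roc_curve, auc as sk_auc

    ids = sorted(model_likelihoods)
    y_true = np.array([bool(fold_labels[i]) for i in ids])
    y_score = np.array([model_likelihoods[i] for i in ids])
    if y_true.all() or not y_true.any():
        return None, []
    fpr, tpr, _ = roc_curve(y_true, y_score)
    return float(sk_auc(fpr, tpr)), list(zip(fpr.tolist(), tpr.tolist()))


def run_end_to_end(spec: FixtureSpec, config: RunConfig | None = None) -> SimulationReport:
    """Full pipeline on a synthetic fixture: generate → contact graphs →
    fingerprint → cross-link plans → simulated outcomes → interpretation →
    fold labels → ROC, with none-of-the-above detection."""
    config = config or RunConfig()
    ensemble, truth, info = generate_fixture(spec)
    graphs = build_contact_graphs(
        ensemble,
        min_contacts=config.min_contacts,
        min_residue_fraction=config.min_residue_fraction,
        contact_distance=config.contact_distance,
    )
    prob_model = estimate_contact_probs(graphs, q=config.q)
    fingerprint = select_fingerprint(
        prob_model, stop_threshold=config.stop_threshold, max_pairs=config.max_pairs
    )
    if not fingerprint.pairs:
        raise ValueError("fingerprint selection returned no SSE pairs")
    assess_fingerprint(fingerprint, prob_model, graphs)

    tiers = LinkProbTiers(config.p_near, config.p_mid, config.p_far)
    sigmoid = SigmoidParams(k0=config.k0)
    noise = build_noise_model(
        ensemble.models,
        delta_max=config.delta_max,
        decay=config.decay,
        n_samples=config.enm_samples,
        amplitude_max=config.enm_amplitude,
        enm_cutoff=config.enm_cutoff,
        kT=config.enm_kT,
    )
    plans = plan_for_fingerprint(
        ensemble,
        fingerprint.pairs,
        graphs,
        noise,
        tiers,
        config.plan_size,
        prob_model.pr_c,
        sigmoid,
        compute_epsilon=False,
        max_distance=config.xlink_max_distance,
    )
    Y, X = simulate_outcomes(truth, plans, config.sim_distance, sigmoid)

    planned_pairs = [p.sse_pair for p in plans]
    X_vector = [X[p] for p in planned_pairs]
    signatures = {
        g.model_id: fold_signature(g, planned_pairs) for g in graphs
    }
    decision = interpret_fold_data(X_vector, planned_pairs, signatures, q=config.q)
    labels = label_models(
        ensemble, truth, config.r_values, config.min_contacts, config.contact_distance
    )
    roc = {r: roc_analysis(decision.likelihoods, labels[r]) for r in config.r_values}
    truth_models = [
        mid for mid, v in info["variant_of_model"].items() if v == spec.truth_variant
    ]
    return SimulationReport(
        spec=spec,
        fingerprint=fingerprint,
        plans=plans,
        simulated_Y=Y,
        simulated_X=X,
        decision=decision,
        fold_labels=labels,
        roc=roc,
        nota_detected=decision.none_of_the_above,
        truth_variant_models=sorted(truth_models),
        variant_of_model=info["variant_of_model"],
    )


def agreeing_models(
    ensemble: ModelEnsemble,
    plans: Sequence[CrossLinkPlan],
    Y: dict[tuple[int, int], list[int]],
    delta_max: int,
    near_distance: float = SIM_XLINK_DISTANCE,
) -> list[str]:
    """Models whose geometry explains every simulated outcome within ±δ.

    A model agrees with the data for one SSE pair when some per-SSE
    register shift (δ_a, δ_b), |δ| ≤ delta_max, makes the near/far state
    of every resolvable planned link (Cβ–Cβ < ``near_distance``) match
    its outcome; links whose shifted residues leave the modeled SSE are
    unresolvable under that shift and excluded (at least one link must
    remain).  A model agrees overall when it agrees on every planned
    pair.  The count is monotone non-decreasing in delta_max.
    """
    out = []
    deltas = range(-delta_max, delta_max + 1)
    for model in ensemble.models:
        ok = True
        for plan in plans:
            y = Y[plan.sse_pair]
            pair_ok = False
            for da in deltas:
                for db in deltas:
                    match = True
                    resolved = 0
                    for (i, j), obs in zip(plan.links, y):
                        ii, jj = i + da, j + db
                        if not (model.has_residue(ii) and model.has_residue(jj)):
                            continue
                        resolved += 1
                        if int(cb_distance(model, ii, jj) < near_distance) != obs:
                            match = False
                            break
                    if match and resolved > 0:
                        pair_ok = True
                        break
                if pair_ok:
                    break
            if not pair_ok:
                ok = False
                break
        if ok:
            out.append(model.model_id)
    return out
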
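"""SSE contact graphs and fold comparison.

A model's fold is encoded as the binary contact pattern over the common
SSE pairs.  An SSE pair is in contact when enough residue pairs are close
(Cβ–Cβ < 9 Å, at least 5 such pairs by default) and a sufficient fraction
of each SSE's residues (20% by default) has a contact partner in the other
SSE.  The residue fraction threshold doubles as the fold-labelling
parameter r in the simulation study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import ModelEnsemble, StructuralModel, cb_distance

__all__ = [
    "SSEContactGraph",
    "FoldSignature",
    "model_sse_interval",
    "build_contact_graph",
    "build_contact_graphs",
    "fold_signature",
    "fold_equal",
    "contact_edge_table",
    "contact_matrix",
]

DEFAULT_CONTACT_DISTANCE = 9.0
DEFAULT_MIN_CONTACTS = 5
DEFAULT_MIN_RESIDUE_FRACTION = 0.20


@dataclass
class SSEContactGraph:
    """Per-model binary contact states over the common SSE set."""

    model_id: str
    sse_ids: list[int]
    contacts: set[frozenset[int]] = field(default_factory=set)

    def has_contact(self, a: int, b: int) -> bool:
        return frozenset((a, b)) in self.contacts

    def state(self, pair: tuple[int, int]) -> int:
        return int(self.has_contact(*pair))


@dataclass(frozen=True)
class FoldSignature:
    """Binary contact states over an ordered collection of SSE pairs."""

    sse_pairs: tuple[tuple[int, int], ...]
    states: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sse_pairs) != len(self.states):
            raise ValueError("signature states must match sse_pairs in length")


def model_sse_interval(
    model: StructuralModel, ensemble: ModelEnsemble, sse_id: int, overlap_fraction: float = 0.5
) -> tuple[int, int]:
    """Residue interval a model uses for a common SSE.

    For ensemble members this is the matched annotation (consensus interval
    if unmatched).  A foreign model (e.g. the ground-truth structure in a
    simulation) is matched ad hoc: its best same-kind annotation with
    Jaccard overlap >= overlap_fraction against the consensus interval,
    else the consensus interval itself.
    """
    sse = ensemble.common_sse(sse_id)
    if model.model_id in sse.members:
        return sse.members[model.model_id]
    if any(m.model_id == model.model_id for m in ensemble.models):
        return sse.start, sse.end
    consensus = sse.interval
    best, best_ov = None, 0.0
    for ann in model.sses:
        if ann.kind != sse.kind:
            continue
        ov = len(ann.interval & consensus) / len(ann.interval | consensus)
        if ov > best_ov:
            best, best_ov = ann, ov
    if best is not None and best_ov >= overlap_fraction:
        return best.start, best.end
    return sse.start, sse.end


def _sse_residues(model: StructuralModel, interval: tuple[int, int]) -> list[int]:
    s, e = interval
    return [i for i in range(s, e + 1) if model.has_residue(i)]


def _pair_in_contact(
    model: StructuralModel,
    res_a: list[int],
    res_b: list[int],
    min_contacts: int,
    min_residue_fraction: float,
    contact_distance: float,
) -> bool:
    if not res_a or not res_b:
        return False
    ca = np.array([model.residue(i).cb for i in res_a])
    cb = np.array([model.residue(j).cb for j in res_b])
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    close = d < contact_distance
    if int(close.sum()) < min_contacts:
        return False
    frac_a = close.any(axis=1).mean()
    frac_b = close.any(axis=0).mean()
    return frac_a >= min_residue_fraction and frac_b >= min_residue_fraction


def build_contact_graph(
    model: StructuralModel,
    ensemble: ModelEnsemble,
    min_contacts: int = DEFAULT_MIN_CONTACTS,
    min_residue_fraction: float = DEFAULT_MIN_RESIDUE_FRACTION,
    contact_distance: float = DEFAULT_CONTACT_DISTANCE,
) -> SSEContactGraph:
    """Binary SSE contact graph of one model over the ensemble's common SSEs.

    A pair (a, b) is in contact iff at least ``min_contacts`` residue pairs
    sit closer than ``contact_distance`` (Cβ–Cβ, strict) and at least
    ``min_residue_fraction`` of *each* SSE's residues have a partner in the
    other.
    """
    ids = ensemble.sse_ids()
    residues = {
        s: _sse_residues(model, model_sse_interval(model, ensemble, s)) for s in ids
    }
    graph = SSEContactGraph(model_id=model.model_id, sse_ids=ids)
    for a, b in ensemble.sse_pairs():
        if _pair_in_contact(
            model, residues[a], residues[b], min_contacts, min_residue_fraction, contact_distance
        ):
            graph.contacts.add(frozenset((a, b)))
    return graph


def build_contact_graphs(ensemble: ModelEnsemble, **kwargs) -> list[SSEContactGraph]:
    """Contact graphs for every model of the ensemble (shared thresholds)."""
    return [build_contact_graph(m, ensemble, **kwargs) for m in ensemble.models]


def fold_signature(
    graph: SSEContactGraph, pairs: list[tuple[int, int]]
) -> FoldSignature:
    """Binary fold signature of a graph restricted to an ordered pair list."""
    return FoldSignature(
        sse_pairs=tuple(tuple(p) for p in pairs),
        states=tuple(graph.state(p) for p in pairs),
    )


def fold_equal(
    a: StructuralModel,
    b: StructuralModel,
    ensemble: ModelEnsemble,
    r: float,
    min_contacts: int = DEFAULT_MIN_CONTACTS,
    contact_distance: float = DEFAULT_CONTACT_DISTANCE,
) -> bool:
    """True iff the two models share the same fold at residue-fraction r.

    Both models' full-universe fold signatures are computed with
    ``min_residue_fraction = r``; equality of the signatures defines
    fold equality.
    """
    pairs = ensemble.sse_pairs()
    sigs = []
    for model in (a, b):
        g = build_contact_graph(
            model,
            ensemble,
            min_contacts=min_contacts,
            min_residue_fraction=r,
            contact_distance=contact_distance,
        )
        sigs.append(fold_signature(g, pairs))
    return sigs[0].states == sigs[1].states


def contact_edge_table(graphs: list[SSEContactGraph]) -> str:
    """Tab-separated edge list: model_id, sse_a, sse_b."""
    lines = ["model_id\tsse_a\tsse_b"]
    for g in graphs:
        for edge in sorted(tuple(sorted(e)) for e in g.contacts):
            lines.append(f"{g.model_id}\t{edge[0]}\t{edge[1]}")
    return "\n".join(lines) + "\n"


def contact_matrix(graphs: list[SSEContactGraph], pairs: list[tuple[int, int]]):
    """Model × SSE-pair binary contact matrix as a pandas DataFrame."""
    import pandas as pd

    data = {
        g.model_id: [g.state(p) for p in pairs] for g in graphs
    }
    cols = [f"{a}-{b}" for a, b in pairs]
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)
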
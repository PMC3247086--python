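"""Structural models, SSE annotation, and Cβ geometry.

This module reads candidate structural models of one target protein (PDB
format, single- or multi-MODEL), establishes the secondary-structure
elements (SSEs) common to the ensemble, and provides the geometric
primitives — per-residue Cβ positions and Cβ–Cβ distances — that the
topology and cross-link planning stages consume.

Secondary-structure source preference is: sidecar annotation file >
HELIX/SHEET records in the PDB > the internal Cα-geometry assigner.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

__all__ = [
    "Residue",
    "SSEAnnotation",
    "StructuralModel",
    "CommonSSE",
    "ModelEnsemble",
    "FormatError",
    "virtual_cb",
    "read_models",
    "read_sidecar_annotations",
    "assign_sses",
    "match_common_sses",
    "cb_distance",
    "ensemble_summary",
]

#: Ideal Cα–Cβ bond length in Å.
CB_BOND_LENGTH = 1.53
#: Ideal tetrahedral angle (N–Cα–Cβ and C–Cα–Cβ), radians.
TETRAHEDRAL_ANGLE = math.radians(109.5)


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as expected."""


@dataclass(frozen=True)
class Residue:
    """One residue: sequence index, amino acid, Cα and (virtual) Cβ positions."""

    index: int
    aa: str
    ca: np.ndarray
    cb: np.ndarray

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"residue index must be >= 1, got {self.index}")
        if not (np.all(np.isfinite(self.ca)) and np.all(np.isfinite(self.cb))):
            raise ValueError(f"non-finite coordinates for residue {self.index}")


@dataclass(frozen=True)
class SSEAnnotation:
    """A helix ('H') or strand ('E') spanning residues start..end inclusive."""

    kind: str
    start: int
    end: int
    sse_id: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("H", "E"):
            raise ValueError(f"SSE kind must be 'H' or 'E', got {self.kind!r}")
        if self.start > self.end:
            raise ValueError(f"SSE interval reversed: {self.start}..{self.end}")

    @property
    def interval(self) -> set[int]:
        return set(range(self.start, self.end + 1))

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class StructuralModel:
    """One candidate structure: ordered residues plus SSE annotations."""

    model_id: str
    residues: list[Residue]
    sses: list[SSEAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"model {self.model_id}: residue indices not strictly increasing")
        self._by_index = {r.index: r for r in self.residues}

    def residue(self, index: int) -> Residue:
        try:
            return self._by_index[index]
        except KeyError:
            raise KeyError(f"model {self.model_id} has no residue {index}") from None

    def has_residue(self, index: int) -> bool:
        return index in self._by_index

    def residue_indices(self) -> list[int]:
        return [r.index for r in self.residues]


@dataclass
class CommonSSE:
    """An SSE shared across the ensemble, with consensus interval and per-model matches."""

    sse_id: int
    kind: str
    start: int
    end: int
    members: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def interval(self) -> set[int]:
        return set(range(self.start, self.end + 1))


@dataclass
class ModelEnsemble:
    """Aligned candidate structures of one target with the common SSE set."""

    target_id: str
    models: list[StructuralModel]
    common_sses: list[CommonSSE]
    sse_presence_fraction: float = 0.5

    def __post_init__(self) -> None:
        self._by_id = {m.model_id: m for m in self.models}
        self._sse_by_id = {s.sse_id: s for s in self.common_sses}

    def model(self, model_id: str) -> StructuralModel:
        return self._by_id[model_id]

    def common_sse(self, sse_id: int) -> CommonSSE:
        return self._sse_by_id[sse_id]

    def sse_ids(self) -> list[int]:
        return [s.sse_id for s in self.common_sses]

    def model_interval(self, model_id: str, sse_id: int) -> tuple[int, int]:
        """Residue interval of a common SSE in one model.

        Falls back to the consensus interval when the model has no matched
        annotation, so every model exposes a state for every common SSE.
        """
        sse = self._sse_by_id[sse_id]
        return sse.members.get(model_id, (sse.start, sse.end))

    def sse_pairs(self) -> list[tuple[int, int]]:
        """All unordered common-SSE pairs, lexicographically ordered."""
        ids = self.sse_ids()
        return [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]


# ---------------------------------------------------------------------------
# geometry


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector in Cβ construction")
    return v / n


def virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal virtual Cβ from backbone N/Cα/C with tetrahedral geometry.

    The Cβ direction makes the tetrahedral angle with both the Cα→N and
    Cα→C bonds and sits on the side of the N–Cα–C plane that gives the
    L-amino-acid configuration.  Bond length 1.53 Å.  Used for glycine so
    that Cβ–Cβ distance criteria apply uniformly to every residue type.
    """
    u = _unit(np.asarray(n, float) - ca)
    v = _unit(np.asarray(c, float) - ca)
    bis = _unit(u + v)
    perp = _unit(np.cross(u, v))
    cos_half = float(np.dot(bis, u))
    a = -math.cos(TETRAHEDRAL_ANGLE) / cos_half  # component along -bisector
    b = math.sqrt(max(0.0, 1.0 - a * a))  # component along u×v (L chirality)
    direction = -a * bis + b * perp
    return np.asarray(ca, float) + CB_BOND_LENGTH * _unit(direction)


def cb_distance(model: StructuralModel, i: int, j: int) -> float:
    """Euclidean Cβ–Cβ distance (Å) between residues i and j of a model."""
    ri, rj = model.residue(i), model.residue(j)
    return float(np.linalg.norm(ri.cb - rj.cb))


# ---------------------------------------------------------------------------
# SSE assignment from Cα geometry (P-SEA-style distance windows)

# Windows on the |Cα_i − Cα_{i+k}| distances, k = 2, 3, 4, in Å.
_HELIX_WINDOWS = {2: (5.0, 6.0), 3: (4.8, 5.8), 4: (5.8, 7.0)}
_STRAND_WINDOWS = {2: (6.1, 7.3), 3: (9.0, 10.8), 4: (11.3, 13.5)}
_MIN_SSE_LEN = {"H": 4, "E": 3}


def assign_sses(model: StructuralModel) -> list[SSEAnnotation]:
    """Assign helix/strand segments from Cα geometry alone.

    A residue is labelled helix (strand) when its Cα distances to the
    residues 2, 3 and 4 positions downstream all fall inside the
    characteristic helix (strand) windows; consecutive labels of one kind
    are merged and extended to cover the residues the distances span.
    Segments shorter than 4 residues (helix) or 3 (strand) are discarded.
    Deterministic; returns an empty list for coil-only chains.
    """
    residues = model.residues
    labels: list[tuple[int, str]] = []  # (position in residue list, kind)
    for p in range(len(residues) - 4):
        window = residues[p : p + 5]
        # only contiguous stretches of sequence numbering qualify
        if window[-1].index - window[0].index != 4:
            continue
        d = {k: float(np.linalg.norm(window[0].ca - window[k].ca)) for k in (2, 3, 4)}
        for kind, wins in (("H", _HELIX_WINDOWS), ("E", _STRAND_WINDOWS)):
            if all(wins[k][0] <= d[k] <= wins[k][1] for k in (2, 3, 4)):
                labels.append((p, kind))
                break

    annotations: list[SSEAnnotation] = []
    run: list[tuple[int, str]] = []

    def _flush() -> None:
        # require two consecutive qualifying positions: a lone hit is noise
        if len(run) < 2:
            run.clear()
            return
        kind = run[0][1]
        start = residues[run[0][0]].index
        end = residues[run[-1][0] + 4].index
        if end - start + 1 >= _MIN_SSE_LEN[kind]:
            annotations.append(SSEAnnotation(kind, start, end))
        run.clear()

    for p, kind in labels:
        if run and (kind != run[-1][1] or p != run[-1][0] + 1):
            _flush()
        run.append((p, kind))
    _flush()
    return annotations


# ---------------------------------------------------------------------------
# reading models


def _parse_ss_records(path: Path) -> list[SSEAnnotation]:
    """HELIX/SHEET records from a PDB file (fixed-column per the PDB spec)."""
    annotations = []
    with open(path) as fh:
        for line in fh:
            try:
                if line.startswith("HELIX"):
                    annotations.append(
                        SSEAnnotation("H", int(line[21:25]), int(line[33:37]))
                    )
                elif line.startswith("SHEET"):
                    annotations.append(
                        SSEAnnotation("E", int(line[22:26]), int(line[33:37]))
                    )
            except ValueError as exc:
                raise FormatError(f"{path}: malformed secondary-structure record: {line.rstrip()}") from exc
    return annotations


def read_sidecar_annotations(path: str | Path) -> dict[str, list[SSEAnnotation]]:
    """Read a sidecar SSE annotation file.

    One whitespace-delimited line per SSE: ``model_id kind(H|E) start end``
    with 1-based inclusive residue indices.  Lines starting with '#' are
    comments.
    """
    out: dict[str, list[SSEAnnotation]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 'model_id kind start end'")
            model_id, kind, start, end = parts
            try:
                ann = SSEAnnotation(kind, int(start), int(end))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out.setdefault(model_id, []).append(ann)
    return out


def _residues_from_biopdb(chain_residues, path: Path, model_id: str) -> list[Residue]:
    out = []
    for res in chain_residues:
        if "CA" not in res:
            continue
        index = res.id[1]
        if index < 1:
            continue
        ca = res["CA"].get_coord().astype(float)
        aa = seq1(res.get_resname(), custom_map={"UNK": "X"}) or "X"
        if "CB" in res:
            cb = res["CB"].get_coord().astype(float)
        elif "N" in res and "C" in res:
            cb = virtual_cb(res["N"].get_coord(), ca, res["C"].get_coord())
        else:
            cb = ca.copy()
        out.append(Residue(index=index, aa=aa, ca=ca, cb=cb))
    out.sort(key=lambda r: r.index)
    return out


def read_models(
    paths: Sequence[str | Path],
    annotations: str | Path | None = None,
    target_id: str = "target",
    presence_fraction: float = 0.5,
    overlap_fraction: float = 0.5,
) -> ModelEnsemble:
    """Read candidate models and assemble the ensemble with common SSEs.

    Each path may hold one model or a multi-MODEL PDB file.  SSE
    annotations come from the sidecar file if given, else from HELIX/SHEET
    records, else from :func:`assign_sses`.  Models left with fewer than
    two SSEs are excluded with a warning.
    """
    sidecar = read_sidecar_annotations(annotations) if annotations else {}
    parser = PDBParser(QUIET=True)
    models: list[StructuralModel] = []
    for path in paths:
        path = Path(path)
        try:
            structure = parser.get_structure(path.stem, str(path))
        except Exception as exc:
            raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
        records = _parse_ss_records(path)
        biomodels = list(structure)
        if not biomodels:
            raise FormatError(f"{path}: no models found")
        multi = len(biomodels) > 1
        for bm in biomodels:
            model_id = f"{path.stem}_{bm.serial_num}" if multi else path.stem
            chain_residues = [r for chain in bm for r in chain]
            residues = _residues_from_biopdb(chain_residues, path, model_id)
            if not residues:
                raise FormatError(f"{path}: model {model_id} has no Cα coordinates")
            model = StructuralModel(model_id=model_id, residues=residues)
            if model_id in sidecar:
                model.sses = list(sidecar[model_id])
            elif not multi and path.stem in sidecar:
                model.sses = list(sidecar[path.stem])
            elif records:
                model.sses = list(records)
            else:
                model.sses = assign_sses(model)
            if len(model.sses) < 2:
                warnings.warn(
                    f"model {model_id} has fewer than 2 SSEs after assignment; excluded"
                )
                continue
            models.append(model)
    common = match_common_sses(models, presence_fraction, overlap_fraction)
    return ModelEnsemble(
        target_id=target_id,
        models=models,
        common_sses=common,
        sse_presence_fraction=presence_fraction,
    )


# ---------------------------------------------------------------------------
# common-SSE matching


def _jaccard(a: set[int], b: set[int]) -> float:
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / len(a | b)


def _consensus_interval(intervals: Iterable[tuple[int, int]]) -> tuple[int, int]:
    """Per-position majority membership over member intervals."""
    intervals = list(intervals)
    counts: dict[int, int] = {}
    for s, e in intervals:
        for i in range(s, e + 1):
            counts[i] = counts.get(i, 0) + 1
    need = len(intervals) / 2.0
    member = sorted(i for i, c in counts.items() if c >= need)
    if not member:  # degenerate; fall back to the first interval
        return intervals[0]
    return member[0], member[-1]


def match_common_sses(
    models: Sequence[StructuralModel],
    presence_fraction: float = 0.5,
    overlap_fraction: float = 0.5,
) -> list[CommonSSE]:
    """Cluster SSE annotations across models into a common SSE set.

    Greedy clustering: annotations are matched to a growing cluster of the
    same kind when the Jaccard overlap of residue intervals with the
    cluster consensus is at least ``overlap_fraction``; ties broken by
    larger overlap then lower start.  Clusters present in at least
    ``presence_fraction`` of the models become common SSEs, numbered 1..K
    in order of consensus start.  At most one annotation per model joins a
    cluster.
    """
    if len(models) < 2:
        raise ValueError("common-SSE matching needs at least 2 models")
    # clusters: list of dicts model_id -> (start, end), plus kind
    clusters: list[dict] = []
    # process models sorted by id for order-independence, annotations by start
    for model in sorted(models, key=lambda m: m.model_id):
        for ann in sorted(model.sses, key=lambda a: (a.start, a.end)):
            best = None
            best_key = (0.0, 0)
            for cl in clusters:
                if cl["kind"] != ann.kind or model.model_id in cl["members"]:
                    continue
                cs, ce = _consensus_interval(cl["members"].values())
                ov = _jaccard(ann.interval, set(range(cs, ce + 1)))
                if ov >= overlap_fraction and (ov, -cs) > best_key:
                    best, best_key = cl, (ov, -cs)
            if best is not None:
                best["members"][model.model_id] = (ann.start, ann.end)
            else:
                clusters.append({"kind": ann.kind, "members": {model.model_id: (ann.start, ann.end)}})

    need = presence_fraction * len(models)
    kept = [cl for cl in clusters if len(cl["members"]) >= need]
    if not kept:
        raise ValueError("no common SSEs across the ensemble")
    enriched = []
    for cl in kept:
        s, e = _consensus_interval(cl["members"].values())
        enriched.append((s, e, cl))
    enriched.sort(key=lambda t: (t[0], t[1]))
    return [
        CommonSSE(sse_id=k, kind=cl["kind"], start=s, end=e, members=dict(cl["members"]))
        for k, (s, e, cl) in enumerate(enriched, start=1)
    ]


def ensemble_summary(ensemble: ModelEnsemble) -> str:
    """Tab-separated summary: model_id, n_residues, n_sses, matched_common_sses."""
    lines = ["model_id\tn_residues\tn_sses\tmatched_common_sses"]
    for m in ensemble.models:
        matched = sum(1 for s in ensemble.common_sses if m.model_id in s.members)
        lines.append(f"{m.model_id}\t{len(m.residues)}\t{len(m.sses)}\t{matched}")
    return "\n".join(lines) + "\n"
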
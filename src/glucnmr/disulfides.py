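"""Disulfide connectivity from S-gamma distance statistics across an ensemble.

When several cysteines cluster (GLuc's C52/C56/C123/C127), NOE data alone
may not resolve which pairs are bonded.  The approach implemented here scans
every structure of a calculation pool for cysteine pairs whose S-gamma atoms
lie within bonding reach (default: strictly < 3.0 A), converts the
per-model observations into pair frequencies, and formalises "pick the most
favoured pairs" as a maximum-weight perfect matching on those frequencies.
Pair occurrences are counted independently per pair — one S-gamma may be
under threshold to two partners within one model — and disjointness is only
imposed at the matching step, so the frequencies reproduce ensemble
statistics of the 92.4% / 56.1% kind.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .structure_io import Ensemble, StructureError

__all__ = [
    "CysteinePairStats",
    "PairingAssignment",
    "sg_distance_table",
    "pair_frequency",
    "assign_pairing",
    "models_consistent_with_pairing",
    "DEFAULT_SG_THRESHOLD",
]

#: Bonding-distance threshold on the S-gamma pair distance, A (strict "<").
DEFAULT_SG_THRESHOLD = 3.0


@dataclass
class CysteinePairStats:
    """Per-model S-gamma distances for one cysteine pair, plus sub-threshold frequency."""

    pair: tuple[int, int]
    distances: np.ndarray
    frequency: float | None = None


@dataclass
class PairingAssignment:
    """Disjoint cysteine pairing with its total-frequency score."""

    pairs: frozenset[tuple[int, int]]
    score: float
    unpaired: frozenset[int]


def _sg_coords(ensemble: Ensemble, cysteines: Sequence[int]) -> np.ndarray:
    coords = np.empty((ensemble.n_models, len(cysteines), 3))
    for mi, model in enumerate(ensemble.models):
        for ci, sid in enumerate(cysteines):
            res = model.residue(sid)
            atom = res.atom("SG")
            if atom is None:
                raise StructureError(
                    f"model {model.model_id}: residue {sid} has no SG atom"
                )
            coords[mi, ci] = atom.coords
    return coords


def sg_distance_table(
    ensemble: Ensemble, cysteines: Sequence[int] | None = None
) -> list[CysteinePairStats]:
    """Euclidean S-gamma/S-gamma distances for all unordered cysteine pairs.

    Default cysteine list: every CYS in the ensemble sequence.
    """
    if cysteines is None:
        cysteines = [sid for sid, aa in zip(ensemble.seq_ids, ensemble.sequence) if aa == "C"]
    cysteines = sorted(cysteines)
    if len(cysteines) < 2:
        raise StructureError("need at least two cysteines")
    coords = _sg_coords(ensemble, cysteines)
    out = []
    for (ia, a), (ib, b) in combinations(enumerate(cysteines), 2):
        d = np.linalg.norm(coords[:, ia] - coords[:, ib], axis=1)
        out.append(CysteinePairStats(pair=(a, b), distances=d))
    return out


def pair_frequency(
    stats: Iterable[CysteinePairStats], threshold: float = DEFAULT_SG_THRESHOLD
) -> list[CysteinePairStats]:
    """Fill frequencies: fraction of models with distance strictly below threshold."""
    out = []
    for s in stats:
        freq = float(np.mean(s.distances < threshold))
        out.append(CysteinePairStats(pair=s.pair, distances=s.distances, frequency=freq))
    return out


def assign_pairing(
    stats: Iterable[CysteinePairStats],
    fixed_pairs: Iterable[tuple[int, int]] | None = None,
) -> PairingAssignment:
    """Maximum-weight perfect matching of the cysteines on pair frequencies.

    `fixed_pairs` (e.g. bonds already unambiguous from the structures) are
    honored verbatim; the matching is over the remaining cysteines.  An odd
    number of free cysteines is an error — a fully oxidized protein pairs
    all of them.
    """
    stats = list(stats)
    if any(s.frequency is None for s in stats):
        raise ValueError("frequencies not computed; call pair_frequency first")
    cysteines = sorted({c for s in stats for c in s.pair})
    fixed = {tuple(sorted(p)) for p in (fixed_pairs or [])}
    fixed_members = {c for p in fixed for c in p}
    if len(fixed_members) != 2 * len(fixed):
        raise ValueError("fixed_pairs share a cysteine")
    free = [c for c in cysteines if c not in fixed_members]
    if len(free) % 2:
        raise ValueError(
            f"odd number of free cysteines ({len(free)}); a perfect pairing is impossible"
        )
    weights = {tuple(sorted(s.pair)): s.frequency for s in stats}

    g = nx.Graph()
    g.add_nodes_from(free)
    for (a, b), w in weights.items():
        if a in fixed_members or b in fixed_members:
            continue
        # shift weights so max_weight_matching's cardinality maximization
        # yields the maximum-weight *perfect* matching
        g.add_edge(a, b, weight=w + 1.0)
    matching = nx.max_weight_matching(g, maxcardinality=True)
    pairs = {tuple(sorted(e)) for e in matching} | fixed
    matched = {c for p in pairs for c in p}
    if free and len(matched & set(free)) != len(free):
        raise ValueError("no perfect matching exists on the given pair set")
    score = sum(weights.get(p, 0.0) for p in pairs)
    return PairingAssignment(
        pairs=frozenset(pairs),
        score=float(score),
        unpaired=frozenset(set(cysteines) - matched),
    )


def models_consistent_with_pairing(
    ensemble: Ensemble,
    pairing: PairingAssignment | Iterable[tuple[int, int]],
    threshold: float = DEFAULT_SG_THRESHOLD,
) -> tuple[int, list[int]]:
    """Count models in which *every* pair of the pairing is under threshold.

    Returns (count, zero-based model indices).
    """
    pairs = pairing.pairs if isinstance(pairing, PairingAssignment) else list(pairing)
    pairs = [tuple(sorted(p)) for p in pairs]
    cysteines = sorted({c for p in pairs for c in p})
    coords = _sg_coords(ensemble, cysteines)
    idx = {c: i for i, c in enumerate(cysteines)}
    ok = np.ones(ensemble.n_models, dtype=bool)
    for a, b in pairs:
        d = np.linalg.norm(coords[:, idx[a]] - coords[:, idx[b]], axis=1)
        ok &= d < threshold
    indices = [int(i) for i in np.nonzero(ok)[0]]
    return len(indices), indices
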
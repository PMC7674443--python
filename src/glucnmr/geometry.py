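"""Ensemble geometry: superposition, RMSD statistics, representative selection.

The representative member of an NMR ensemble is defined as the model with
the lowest average pairwise RMSD against all other members; ensemble
precision is then summarised as the mean +/- SD of the RMSD of each other
model to the representative, over a stated heavy-atom or C-alpha selection.
Per-residue displacement profiles (mean distance of an atom from its
position in the representative, after core superposition) localise the
disordered segments.

Superposition is least-squares rigid-body (Kabsch, via SVD) with reflections
excluded.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure_io import Ensemble, StructureError, select_coords

__all__ = [
    "SuperpositionResult",
    "RmsdMatrix",
    "DisplacementProfile",
    "kabsch_superpose",
    "pairwise_rmsd_matrix",
    "select_representative",
    "rmsd_to_reference_stats",
    "per_residue_displacement",
    "heavy_atom_coords",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference, and its RMSD (A)."""

    rotation: np.ndarray  # 3x3, proper orthonormal
    translation: np.ndarray  # 3-vector, A
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RmsdMatrix:
    """Symmetric pairwise superposition-RMSD matrix over a stated selection."""

    values: np.ndarray
    atom_name: str
    residue_ranges: tuple[tuple[int, int], ...]


@dataclass
class DisplacementProfile:
    """Per-residue mean/SD displacement (A) from the representative model."""

    seq_ids: np.ndarray
    mean: np.ndarray
    sd: np.ndarray


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of `mobile` onto `reference`.

    Both arrays are (n, 3) with matched rows, n >= 3 and not collinear.
    The returned rotation is proper (det = +1); reflections are excluded.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matched (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 atoms for superposition, got {n}")

    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    x = mobile - mc
    y = reference - rc
    # collinearity check: rank of the centered configuration
    if min(np.linalg.matrix_rank(x, tol=1e-8), np.linalg.matrix_rank(y, tol=1e-8)) < 2:
        raise ValueError("degenerate (collinear) atom configuration")

    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    moved = x @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def pairwise_rmsd_matrix(
    ensemble: Ensemble,
    atom_name: str,
    residue_ranges: Sequence[tuple[int, int]],
) -> RmsdMatrix:
    """All-against-all superposition RMSD over the stated atom selection."""
    coords = select_coords(ensemble, atom_name, residue_ranges)
    n = coords.shape[0]
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = kabsch_superpose(coords[i], coords[j]).rmsd
            m[i, j] = m[j, i] = r
    return RmsdMatrix(values=m, atom_name=atom_name, residue_ranges=tuple(map(tuple, residue_ranges)))


def select_representative(matrix: RmsdMatrix | np.ndarray) -> int:
    """Index of the model minimizing the mean RMSD to all other models.

    Ties break to the lowest index.
    """
    values = matrix.values if isinstance(matrix, RmsdMatrix) else np.asarray(matrix, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 models to select a representative")
    row_means = (values.sum(axis=1)) / (n - 1)  # zero diagonal
    return int(np.argmin(row_means))


def rmsd_to_reference_stats(
    ensemble: Ensemble,
    representative: int,
    atom_name: str,
    residue_ranges: Sequence[tuple[int, int]],
) -> tuple[float, float]:
    """Mean and SD (A) of per-model RMSD to the representative on a selection.

    Averaged over the non-representative models, mirroring ensemble
    precision statements such as "backbone C-alpha 1.39 +/- 0.39 A".
    """
    coords = select_coords(ensemble, atom_name, residue_ranges)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 models")
    ref = coords[representative]
    rmsds = [
        kabsch_superpose(coords[i], ref).rmsd for i in range(n) if i != representative
    ]
    return float(np.mean(rmsds)), float(np.std(rmsds))


def heavy_atom_coords(ensemble: Ensemble, residue_ranges: Sequence[tuple[int, int]]):
    """Aligned heavy-atom coordinate arrays over a selection, for all models.

    Atoms missing in any model are dropped pairwise across the whole ensemble
    with a warning (NMR models occasionally omit atoms).  Returns
    (n_models, n_atoms, 3) plus the list of (seq_id, atom_name) kept.
    """
    seq_ids = [s for lo, hi in residue_ranges for s in range(lo, hi + 1)]
    keys: list[tuple[int, str]] = []
    for sid in seq_ids:
        names = [a.name for a in ensemble.models[0].residue(sid).heavy_atoms()]
        for name in names:
            if all(
                (m.residue(sid).atom(name) is not None) for m in ensemble.models
            ):
                keys.append((sid, name))
            else:
                warnings.warn(f"heavy atom {name} of residue {sid} missing in some models; dropped")
    if not keys:
        raise StructureError("no common heavy atoms in selection")
    out = np.empty((ensemble.n_models, len(keys), 3))
    for mi, model in enumerate(ensemble.models):
        for ki, (sid, name) in enumerate(keys):
            out[mi, ki] = model.residue(sid).atom(name).coords
    return out, keys


def rmsd_to_reference_stats_heavy(
    ensemble: Ensemble,
    representative: int,
    residue_ranges: Sequence[tuple[int, int]],
) -> tuple[float, float]:
    """Heavy-atom analogue of :func:`rmsd_to_reference_stats`."""
    coords, _ = heavy_atom_coords(ensemble, residue_ranges)
    ref = coords[representative]
    rmsds = [
        kabsch_superpose(coords[i], ref).rmsd
        for i in range(coords.shape[0])
        if i != representative
    ]
    return float(np.mean(rmsds)), float(np.std(rmsds))


def per_residue_displacement(
    ensemble: Ensemble,
    representative: int,
    atom_name: str,
    superpose_ranges: Sequence[tuple[int, int]],
    measure_ranges: Sequence[tuple[int, int]] | None = None,
) -> DisplacementProfile:
    """Mean/SD distance of each residue's atom from the representative.

    Each non-representative model is superposed onto the representative on
    `superpose_ranges` (the rigid core); the displacement is then measured
    for every residue in `measure_ranges` (default: all residues carrying
    the atom in every model).
    """
    if measure_ranges is None:
        sids = [
            sid
            for sid in ensemble.seq_ids
            if all(m.residue(sid).atom(atom_name) is not None for m in ensemble.models)
        ]
        measure_ranges = [(s, s) for s in sids]
    fit = select_coords(ensemble, atom_name, superpose_ranges)
    meas = select_coords(ensemble, atom_name, measure_ranges)
    seq_ids = np.array([s for lo, hi in measure_ranges for s in range(lo, hi + 1)])

    ref_fit = fit[representative]
    ref_meas = meas[representative]
    disp = []
    for i in range(ensemble.n_models):
        if i == representative:
            continue
        sup = kabsch_superpose(fit[i], ref_fit)
        moved = sup.apply(meas[i])
        disp.append(np.linalg.norm(moved - ref_meas, axis=1))
    d = np.asarray(disp)
    return DisplacementProfile(seq_ids=seq_ids, mean=d.mean(axis=0), sd=d.std(axis=0))
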
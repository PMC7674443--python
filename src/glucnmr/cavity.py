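"""Interior-cavity and surface-pocket detection by grid flood fill.

A cubic grid (default 0.6 A spacing) is laid over the model's bounding box
plus a margin; grid cells within (van der Waals radius + probe radius,
default probe 1.4 A) of any heavy atom are occupied.  Flood-filling the
empty cells from the box boundary marks the exterior solvent; remaining
empty connected components (6-connectivity) of at least `min_volume` are
interior cavities, sorted by volume.

Open-mouthed pockets — like the coelenterazine-binding cavity of GLuc,
which communicates with solvent through an entrance — escape that
definition, so a second mode closes them artificially: an exterior flood
fill with an enlarged probe (default 3.0 A, sized so a substrate-scale
mouth seals) defines an envelope, and pocket voxels are the
envelope-interior cells that are empty at the normal probe.

The van der Waals radii are the Bondi set.  Lining residues are those with
a heavy atom within a cutoff (default 4.5 A) of any cavity voxel center,
and their composition is summarised in the surface-chemistry classes
positive {R,K,H}, negative {E,D}, hydrophobic {A,V,L,I,M,F,W,Y,P}, polar
(remainder).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structure_io import Model, StructureError

__all__ = [
    "CavityResult",
    "detect_cavities",
    "lining_residues",
    "annotate_composition",
    "BONDI_RADII",
]

#: Bondi van der Waals radii, A.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85,
}
_DEFAULT_RADIUS = 1.70

POSITIVE = set("RKH")
NEGATIVE = set("ED")
HYDROPHOBIC = set("AVLIMFWYP")


@dataclass
class CavityResult:
    """One cavity/pocket: voxel centers (A), volume (A^3), lining and composition."""

    voxels: np.ndarray  # (n, 3) voxel centers
    volume: float
    spacing: float
    lining_residues: list[int]
    composition: dict[str, int]
    mode: str = "cavity"


def _heavy_atom_arrays(model: Model):
    coords, radii = [], []
    for res in model.residues:
        for atom in res.heavy_atoms():
            coords.append(atom.coords)
            elem = (atom.element or atom.name[:1]).upper()
            radii.append(BONDI_RADII.get(elem, _DEFAULT_RADIUS))
    if not coords:
        raise StructureError("model has no heavy atoms")
    return np.asarray(coords), np.asarray(radii)


def _occupancy(coords, radii, origin, shape, spacing, probe):
    """Boolean occupancy grid: cells within (vdW + probe) of any atom."""
    grid_idx = np.indices(shape).reshape(3, -1).T
    centers = origin + grid_idx * spacing
    tree = cKDTree(centers)
    occ = np.zeros(shape, dtype=bool).reshape(-1)
    rmax = radii.max() + probe
    for xyz, r in zip(coords, radii):
        for idx in tree.query_ball_point(xyz, r + probe):
            occ[idx] = True
    return occ.reshape(shape)


def _exterior(occupied: np.ndarray) -> np.ndarray:
    """Empty cells connected to the grid boundary (6-connectivity)."""
    empty = ~occupied
    labels, _ = ndimage.label(empty)  # default structure = 6-connectivity in 3D
    boundary_labels = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            boundary_labels |= set(np.unique(labels[tuple(sl)]))
    boundary_labels.discard(0)
    return np.isin(labels, sorted(boundary_labels))


def detect_cavities(
    model: Model,
    spacing: float = 0.6,
    probe: float = 1.4,
    min_volume: float = 30.0,
    mode: str = "cavity",
    envelope_probe: float = 3.0,
    lining_cutoff: float = 4.5,
) -> list[CavityResult]:
    """Detect interior cavities (or, in pocket mode, open pockets) of a model.

    Returns cavities sorted by decreasing volume, each annotated with lining
    residues and composition.
    """
    if mode not in ("cavity", "pocket"):
        raise ValueError(f"mode must be 'cavity' or 'pocket', got {mode!r}")
    coords, radii = _heavy_atom_arrays(model)
    margin = radii.max() + max(probe, envelope_probe if mode == "pocket" else probe) + 2 * spacing
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))

    occupied = _occupancy(coords, radii, lo, shape, spacing, probe)
    exterior = _exterior(occupied)
    interior_empty = ~occupied & ~exterior

    if mode == "pocket":
        occupied_large = _occupancy(coords, radii, lo, shape, spacing, envelope_probe)
        exterior_large = _exterior(occupied_large)
        candidate = ~occupied & ~exterior_large  # envelope-interior empty cells
    else:
        candidate = interior_empty

    labels, n = ndimage.label(candidate)
    results: list[CavityResult] = []
    voxel_vol = spacing**3
    for lab in range(1, n + 1):
        mask = labels == lab
        count = int(mask.sum())
        volume = count * voxel_vol
        if volume < min_volume:
            continue
        idx = np.argwhere(mask)
        centers = lo + idx * spacing
        lining = lining_residues_from_voxels(centers, model, cutoff=lining_cutoff)
        comp = annotate_composition_ids(lining, model)
        results.append(
            CavityResult(
                voxels=centers,
                volume=volume,
                spacing=spacing,
                lining_residues=lining,
                composition=comp,
                mode=mode,
            )
        )
    return sorted(results, key=lambda c: -c.volume)


def lining_residues_from_voxels(
    voxels: np.ndarray, model: Model, cutoff: float = 4.5
) -> list[int]:
    """Residues with >= 1 heavy atom within `cutoff` of >= 1 voxel center."""
    tree = cKDTree(np.asarray(voxels))
    lining = []
    for res in model.residues:
        pts = [a.coords for a in res.heavy_atoms()]
        if pts and tree.query(np.asarray(pts), k=1)[0].min() <= cutoff:
            lining.append(res.seq_id)
    return sorted(lining)


def lining_residues(cavity: CavityResult, model: Model, cutoff: float = 4.5) -> list[int]:
    """Lining residues of an already-detected cavity (recomputable at any cutoff)."""
    return lining_residues_from_voxels(cavity.voxels, model, cutoff)


def annotate_composition(residues: list[int], sequence: str) -> dict[str, int]:
    """Class counts over 1-based residue ids against a full-protein sequence."""
    counts = {"positive": 0, "negative": 0, "hydrophobic": 0, "polar": 0}
    for sid in residues:
        if not (1 <= sid <= len(sequence)):
            raise ValueError(f"residue {sid} outside sequence of length {len(sequence)}")
        aa = sequence[sid - 1]
        if aa in POSITIVE:
            counts["positive"] += 1
        elif aa in NEGATIVE:
            counts["negative"] += 1
        elif aa in HYDROPHOBIC:
            counts["hydrophobic"] += 1
        else:
            counts["polar"] += 1
    return counts


def annotate_composition_ids(residues: list[int], model: Model) -> dict[str, int]:
    counts = {"positive": 0, "negative": 0, "hydrophobic": 0, "polar": 0}
    for sid in residues:
        aa = model.residue(sid).aa
        if aa in POSITIVE:
            counts["positive"] += 1
        elif aa in NEGATIVE:
            counts["negative"] += 1
        elif aa in HYDROPHOBIC:
            counts["hydrophobic"] += 1
        else:
            counts["polar"] += 1
    return counts
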
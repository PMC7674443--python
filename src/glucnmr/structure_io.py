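"""Multi-model PDB input/output and typed access to ensembles.

NMR structure calculations deliver ensembles: several alternative models of
the same polypeptide, stored in one PDB file as MODEL/ENDMDL blocks.  This
module reads such files into light-weight typed containers (`Atom`,
`ResidueRecord`, `Model`, `Ensemble`), enforces that every model carries the
identical residue sequence, and writes ensembles back out in standard
fixed-column PDB layout.

Residue numbering is taken verbatim from the file — for GLuc that means the
mature-chain convention counting from the first residue (a lysine) after the
secretion tag.  Alternate locations other than blank/'A' are dropped with a
warning; insertion codes are rejected (solution-NMR ensembles do not use
them).  Hydrogens are read but excluded from heavy-atom selections by the
analysis modules.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "ResidueRecord",
    "Model",
    "Ensemble",
    "StructureError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "select_coords",
    "extract_sequence",
    "three_to_one",
    "read_fasta",
]


class StructureError(ValueError):
    """Raised for malformed or inconsistent structure files/ensembles."""


#: three-letter -> one-letter amino-acid codes, canonical 20 plus MSE.
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",  # selenomethionine, treated as Met
}

_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items() if k != "MSE"}

_CANONICAL = set("ACDEFGHIKLMNPQRSTVWYX")


def three_to_one(resname: str) -> str:
    """Map a three-letter residue name to one-letter code, X (+warning) if unknown."""
    code = _THREE_TO_ONE.get(resname.strip().upper())
    if code is None:
        warnings.warn(f"unknown residue name {resname!r}; mapped to X")
        return "X"
    return code


@dataclass
class Atom:
    """One atom: PDB atom label, element symbol, Cartesian coordinates in A."""

    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.name:
            raise StructureError("atom name must be non-empty")
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class ResidueRecord:
    """One residue: sequence number (1-based), one-letter code, atoms."""

    seq_id: int
    aa: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seq_id < 1:
            raise StructureError(f"residue seq_id must be >= 1, got {self.seq_id}")
        if self.aa not in _CANONICAL:
            raise StructureError(f"residue {self.seq_id}: invalid one-letter code {self.aa!r}")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Model:
    """One ensemble member: ordered residues with strictly increasing seq_ids."""

    model_id: int
    residues: list[ResidueRecord]

    def __post_init__(self) -> None:
        ids = [r.seq_id for r in self.residues]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise StructureError(
                f"model {self.model_id}: residue seq_ids must be strictly increasing"
            )
        self._by_id = {r.seq_id: r for r in self.residues}

    def residue(self, seq_id: int) -> ResidueRecord:
        try:
            return self._by_id[seq_id]
        except KeyError:
            raise StructureError(f"model {self.model_id}: no residue {seq_id}") from None

    def __contains__(self, seq_id: int) -> bool:
        return seq_id in self._by_id


@dataclass
class Ensemble:
    """Ordered collection of models sharing one residue sequence."""

    models: list[Model]
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            raise StructureError("ensemble must contain at least one model")
        ref = [(r.seq_id, r.aa) for r in self.models[0].residues]
        for m in self.models[1:]:
            cur = [(r.seq_id, r.aa) for r in m.residues]
            if cur != ref:
                for (sid_a, aa_a), (sid_b, aa_b) in zip(ref, cur):
                    if (sid_a, aa_a) != (sid_b, aa_b):
                        raise StructureError(
                            f"sequence mismatch between model {self.models[0].model_id} and "
                            f"model {m.model_id}: residue {sid_a} {aa_a} vs residue {sid_b} {aa_b}"
                        )
                raise StructureError(
                    f"model {m.model_id} has {len(cur)} residues, "
                    f"model {self.models[0].model_id} has {len(ref)}"
                )
        if not self.sequence:
            self.sequence = extract_sequence(self.models[0])

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def seq_ids(self) -> list[int]:
        return [r.seq_id for r in self.models[0].residues]


def extract_sequence(model: Model) -> str:
    """One-letter sequence of a model in residue order."""
    return "".join(r.aa for r in model.residues)


def _convert_gemmi_model(gmodel: gemmi.Model, model_id: int) -> Model:
    chains = list(gmodel)
    if len(chains) != 1:
        raise StructureError(
            f"model {model_id}: expected a single chain, found {len(chains)} "
            "(multi-chain files are out of scope)"
        )
    residues = []
    for gres in chains[0]:
        if gres.seqid.icode not in (" ", "", "\x00"):
            raise StructureError(
                f"model {model_id}: residue {gres.seqid.num}{gres.seqid.icode} "
                "carries an insertion code; insertion codes are not supported"
            )
        atoms = []
        for ga in gres:
            if ga.altloc not in ("", "A", "\x00"):
                warnings.warn(
                    f"model {model_id} residue {gres.seqid.num}: dropping altloc "
                    f"{ga.altloc!r} copy of atom {ga.name}"
                )
                continue
            atoms.append(
                Atom(
                    name=ga.name,
                    element=ga.element.name if ga.element else "",
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                )
            )
        residues.append(ResidueRecord(seq_id=gres.seqid.num, aa=three_to_one(gres.name), atoms=atoms))
    return Model(model_id=model_id, residues=residues)


def read_multimodel_pdb(path: str | Path) -> Ensemble:
    """Read a (possibly multi-model) PDB file into an :class:`Ensemble`.

    One :class:`Model` per MODEL/ENDMDL block; a file with plain ATOM records
    and no MODEL keyword yields a single-model ensemble.  Models with
    mismatched sequences raise :class:`StructureError` naming the first
    discrepant residue.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"could not parse {path}: {exc}") from exc
    st.setup_entities()
    models = []
    for i, gmodel in enumerate(st):
        try:
            mid = int(getattr(gmodel, "num", None) or gmodel.name)
        except (ValueError, TypeError, AttributeError):
            mid = i + 1
        models.append(_convert_gemmi_model(gmodel, mid))
    if not models or all(not m.residues for m in models):
        raise StructureError(f"{path}: no ATOM records found")
    return Ensemble(models=models)


_COORD_MIN, _COORD_MAX = -999.999, 9999.999


def _format_atom_name(name: str, element: str) -> str:
    # PDB convention: 1-2 letter element names start in column 14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4}"
    return f" {name:<3}"


def write_multimodel_pdb(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble in standard MODEL/ATOM/ENDMDL fixed-column layout.

    Coordinates outside the %8.3f column range raise :class:`StructureError`
    rather than being clamped.
    """
    lines: list[str] = []
    multi = ensemble.n_models > 1
    for model in ensemble.models:
        if multi:
            lines.append(f"MODEL     {model.model_id:4d}")
        serial = 0
        for res in model.residues:
            resname = _ONE_TO_THREE.get(res.aa, "UNK")
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.coords
                for v in (x, y, z):
                    if not (_COORD_MIN <= v <= _COORD_MAX):
                        raise StructureError(
                            f"coordinate {v:.4f} of atom {atom.name} in residue "
                            f"{res.seq_id} does not fit the fixed-width PDB columns"
                        )
                lines.append(
                    f"ATOM  {serial:5d} {_format_atom_name(atom.name, atom.element)} "
                    f"{resname:>3} A{res.seq_id:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{atom.element.upper():>2}"
                )
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def select_coords(
    ensemble: Ensemble,
    atom_name: str,
    residue_ranges: Sequence[tuple[int, int]],
) -> np.ndarray:
    """Per-model coordinate arrays of `atom_name` over inclusive residue ranges.

    Returns an (n_models, n_residues, 3) array aligned across models.  Every
    requested residue must exist and carry the atom in every model; missing
    residues or atoms are reported by residue number, never silently dropped.
    """
    seq_ids: list[int] = []
    for lo, hi in residue_ranges:
        if hi < lo:
            raise StructureError(f"invalid residue range {lo}-{hi}")
        seq_ids.extend(range(lo, hi + 1))
    if not seq_ids:
        raise StructureError("empty residue selection")

    missing_res = [sid for sid in seq_ids if sid not in ensemble.models[0]]
    if missing_res:
        raise StructureError(f"residues not present in ensemble: {missing_res}")

    out = np.empty((ensemble.n_models, len(seq_ids), 3), dtype=float)
    missing_atoms: list[tuple[int, int]] = []
    for mi, model in enumerate(ensemble.models):
        for ri, sid in enumerate(seq_ids):
            atom = model.residue(sid).atom(atom_name)
            if atom is None:
                missing_atoms.append((model.model_id, sid))
            else:
                out[mi, ri] = atom.coords
    if missing_atoms:
        listing = ", ".join(f"model {m} residue {s}" for m, s in missing_atoms[:10])
        raise StructureError(
            f"atom {atom_name} missing in {len(missing_atoms)} place(s): {listing}"
        )
    return out


def read_fasta(path: str | Path) -> str:
    """Read the first record of a FASTA file as a one-letter string."""
    seq_lines: list[str] = []
    started = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if started:
                break
            started = True
            continue
        seq_lines.append(line)
    seq = "".join(seq_lines).upper()
    if not seq:
        raise StructureError(f"{path}: no sequence found")
    bad = set(seq) - _CANONICAL
    if bad:
        raise StructureError(f"{path}: invalid residue letters {sorted(bad)}")
    return seq
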
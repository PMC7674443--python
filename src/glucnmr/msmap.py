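"""Disulfide mapping by limited proteolysis and LC-MS mass matching.

With disulfide bonds intact, tryptic fragments that are covalently linked
through cystines elute as one species whose mass is the sum of the member
peptide masses minus two hydrogens per disulfide.  Matching observed LC-MS
masses against an in-silico enumeration of such linked species constrains
the connectivity: GLuc's observed 4259.01 Da species is the three-fragment
combination A50-R54 + G55-K64 + D106-K129 carrying three disulfides, which
requires the C52/C127 bond plus a second inter-fragment bond.

Masses default to the average scale (matching the printed values); the
monoisotopic scale and a uniform-15N label (+0.99703 Da per nitrogen) are
supported.  The digest follows the plain trypsin rule — cleave C-terminal
to K or R except when the next residue is proline.

The residue mass tables are shipped here as package data; tests cross-check
them against element-composition masses computed independently by pyteomics.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
from pyteomics import parser as _pyt_parser

__all__ = [
    "Peptide",
    "LinkedSpecies",
    "MassMatch",
    "digest",
    "peptide_mass",
    "enumerate_linked_species",
    "match_mass",
    "connectivity_implications",
    "AVERAGE_RESIDUE_MASS",
    "MONO_RESIDUE_MASS",
    "RESIDUE_NITROGENS",
]

# Residue (amino-acid minus water) masses, Da.  Version: IUPAC 2021 atomic
# weights / CODATA monoisotopic values, rounded at the 4th decimal.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
MONO_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406, "N": 114.04293,
    "D": 115.02694, "Q": 128.05858, "K": 128.09496, "E": 129.04259, "M": 131.04049,
    "H": 137.05891, "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
#: Nitrogen atoms per residue (backbone amide + side chain).
RESIDUE_NITROGENS: dict[str, int] = {
    "G": 1, "A": 1, "S": 1, "P": 1, "V": 1, "T": 1, "C": 1, "L": 1, "I": 1,
    "M": 1, "F": 1, "Y": 1, "D": 1, "E": 1, "W": 2, "N": 2, "Q": 2, "K": 2,
    "H": 3, "R": 4,
}

WATER_AVERAGE = 18.01528
WATER_MONO = 18.010565
HYDROGEN_AVERAGE = 1.00794
HYDROGEN_MONO = 1.0078250319
N15_SHIFT = 0.99703  # Da per nitrogen atom for uniform 15N labelling

#: cleave C-terminal to K/R unless followed by P
TRYPSIN_RULE = r"[KR](?!P)"


@dataclass(frozen=True)
class Peptide:
    """Proteolytic fragment: inclusive 1-based span, sequence, cysteine positions."""

    span: tuple[int, int]
    sequence: str
    cys_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        lo, hi = self.span
        if len(self.sequence) != hi - lo + 1:
            raise ValueError(f"peptide {self.span}: sequence length mismatch")

    @property
    def n_cys(self) -> int:
        return len(self.cys_positions)


@dataclass(frozen=True)
class LinkedSpecies:
    """Peptides joined by inter/intra-peptide disulfides, with computed mass (Da)."""

    peptides: tuple[Peptide, ...]
    n_disulfides: int
    mass: float
    label: str = "none"  # none | 15N
    mass_type: str = "average"

    @property
    def cysteines(self) -> tuple[int, ...]:
        return tuple(sorted(c for p in self.peptides for c in p.cys_positions))


@dataclass(frozen=True)
class MassMatch:
    """One observed mass matched to a linked species within tolerance."""

    observed: float
    species: LinkedSpecies
    delta: float  # observed - computed


def _make_peptide(start0: int, seq: str) -> Peptide:
    lo = start0 + 1
    return Peptide(
        span=(lo, lo + len(seq) - 1),
        sequence=seq,
        cys_positions=tuple(lo + i for i, a in enumerate(seq) if a == "C"),
    )


def digest(
    sequence: str, protease: str = "trypsin", max_missed_cleavages: int = 0
) -> list[Peptide]:
    """In-silico digest with spans in the original numbering.

    Only trypsin is implemented (cleave after K/R, not before P); peptides
    with 0..max_missed_cleavages missed sites are returned, sorted by span.
    """
    if protease != "trypsin":
        raise ValueError(f"unsupported protease {protease!r}")
    if not sequence:
        raise ValueError("empty sequence")
    bad = sorted(set(sequence) - set(AVERAGE_RESIDUE_MASS))
    if bad:
        raise ValueError(f"unknown residue letters in sequence: {bad}")
    pieces = _pyt_parser.icleave(
        sequence, TRYPSIN_RULE, missed_cleavages=max_missed_cleavages
    )
    peptides = [_make_peptide(start, pep) for start, pep in pieces]
    return sorted(set(peptides), key=lambda p: (p.span, -len(p.sequence)))


def peptide_mass(
    peptide: Peptide | str, mass_type: str = "average", label: str = "none"
) -> float:
    """Peptide mass in Da: residue masses + water, plus the 15N shift if labelled."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    if mass_type == "average":
        table, water = AVERAGE_RESIDUE_MASS, WATER_AVERAGE
    elif mass_type == "mono":
        table, water = MONO_RESIDUE_MASS, WATER_MONO
    else:
        raise ValueError(f"mass_type must be 'average' or 'mono', got {mass_type!r}")
    try:
        m = sum(table[a] for a in seq) + water
    except KeyError as exc:
        raise ValueError(f"unknown residue letter {exc.args[0]!r}") from None
    if label == "15N":
        m += N15_SHIFT * sum(RESIDUE_NITROGENS[a] for a in seq)
    elif label != "none":
        raise ValueError(f"label must be 'none' or '15N', got {label!r}")
    return m


def _species_mass(
    peptides: Sequence[Peptide], n_disulfides: int, mass_type: str, label: str
) -> float:
    h = HYDROGEN_AVERAGE if mass_type == "average" else HYDROGEN_MONO
    return sum(peptide_mass(p, mass_type, label) for p in peptides) - 2.0 * h * n_disulfides


def enumerate_linked_species(
    peptides: Sequence[Peptide],
    max_peptides: int = 3,
    oxidation: str = "all-cysteines-paired",
    mass_type: str = "average",
    label: str = "none",
    max_candidates: int = 200_000,
) -> list[LinkedSpecies]:
    """All disulfide-linked species of up to `max_peptides` fragments.

    Multi-peptide species require every member to carry >= 1 cysteine (the
    link must be covalent).  Under the default fully-oxidized assumption the
    species carries floor(total cys / 2) disulfides; in 'free-thiol' mode
    one species per possible disulfide count is generated.
    """
    if max_peptides < 1:
        raise ValueError("max_peptides must be >= 1")
    if oxidation not in ("all-cysteines-paired", "free-thiol"):
        raise ValueError(f"unknown oxidation model {oxidation!r}")
    peptides = list(dict.fromkeys(peptides))
    cys_peps = [p for p in peptides if p.n_cys > 0]
    n_candidates = len(peptides)
    for k in range(2, max_peptides + 1):
        # multi-peptide combinations draw from cysteine-bearing fragments only
        c = 1
        for i in range(k):
            c = c * max(len(cys_peps) - i, 0) // (i + 1)
        n_candidates += c
    if n_candidates > max_candidates:
        raise ValueError(
            f"candidate species count {n_candidates} exceeds cap {max_candidates}; "
            "raise max_candidates or reduce max_peptides/missed cleavages"
        )

    out: list[LinkedSpecies] = []
    groups: list[tuple[Peptide, ...]] = [(p,) for p in peptides]
    for k in range(2, max_peptides + 1):
        groups.extend(combinations(cys_peps, k))
    for group in groups:
        total_cys = sum(p.n_cys for p in group)
        if oxidation == "all-cysteines-paired":
            counts = [total_cys // 2]
        else:
            counts = list(range(total_cys // 2 + 1))
        for n_ds in counts:
            if len(group) > 1 and n_ds < len(group) - 1:
                continue  # not enough bonds to hold the peptides together
            out.append(
                LinkedSpecies(
                    peptides=tuple(sorted(group, key=lambda p: p.span)),
                    n_disulfides=n_ds,
                    mass=_species_mass(group, n_ds, mass_type, label),
                    label=label,
                    mass_type=mass_type,
                )
            )
    return out


def match_mass(
    observed: float, species: Iterable[LinkedSpecies], tolerance: float = 0.5
) -> list[MassMatch]:
    """Species within `tolerance` Da of the observed mass, sorted by |delta|."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    matches = [
        MassMatch(observed=observed, species=s, delta=observed - s.mass)
        for s in species
        if abs(observed - s.mass) <= tolerance
    ]
    return sorted(matches, key=lambda m: abs(m.delta))


def _perfect_matchings(items: Sequence[int]):
    if not items:
        yield ()
        return
    first, rest = items[0], list(items[1:])
    for i, partner in enumerate(rest):
        for sub in _perfect_matchings(rest[:i] + rest[i + 1 :]):
            yield ((first, partner),) + sub


def connectivity_implications(
    match: MassMatch | LinkedSpecies,
    candidate_pairs: Iterable[tuple[int, int]] | None = None,
) -> dict:
    """Which cysteine pairings could realize a multi-peptide linked species.

    Enumerates every perfect matching of the species' cysteines that (a)
    keeps the peptide graph connected and (b) uses only `candidate_pairs`
    when given.  Returns per-cysteine partner options, pairs present in
    every valid matching ("implied") and in at least one ("compatible").
    Single-peptide species carry no inter-peptide information: empty result.
    """
    species = match.species if isinstance(match, MassMatch) else match
    empty = {"partner_options": {}, "implied_pairs": set(), "compatible_pairs": set()}
    if len(species.peptides) < 2:
        return empty
    cys = list(species.cysteines)
    if len(cys) % 2 or species.n_disulfides * 2 != len(cys):
        return empty
    owner = {c: i for i, p in enumerate(species.peptides) for c in p.cys_positions}
    allowed = (
        {tuple(sorted(p)) for p in candidate_pairs} if candidate_pairs is not None else None
    )

    valid: list[tuple[tuple[int, int], ...]] = []
    for matching in _perfect_matchings(cys):
        pairs = tuple(tuple(sorted(p)) for p in matching)
        if allowed is not None and not all(p in allowed for p in pairs):
            continue
        # peptide connectivity via union of cross-peptide bonds
        g = nx.Graph()
        g.add_nodes_from(range(len(species.peptides)))
        for a, b in pairs:
            if owner[a] != owner[b]:
                g.add_edge(owner[a], owner[b])
        if nx.is_connected(g):
            valid.append(pairs)
    if not valid:
        return empty
    partner: dict[int, set[int]] = {c: set() for c in cys}
    all_pairs = [set(m) for m in valid]
    for m in valid:
        for a, b in m:
            partner[a].add(b)
            partner[b].add(a)
    implied = set.intersection(*all_pairs)
    compatible = set.union(*all_pairs)
    return {
        "partner_options": partner,
        "implied_pairs": implied,
        "compatible_pairs": compatible,
    }
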
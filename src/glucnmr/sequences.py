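"""Reference sequence of the study protein.

GLuc, the coelenterazine-oxidizing luciferase of *Gaussia princeps*
(UniProtKB Q9BLZ2).  The construct analysed here is the mature chain — the
17-residue secretion tag removed, so numbering starts at the first retained
residue, a lysine — with the two expression-enhancing substitutions E100A
and G103R.  168 residues, ten cysteines forming five disulfide bonds.
"""
from __future__ import annotations

#: Mature GLuc chain (tag removed, E100A/G103R), numbering from K1.
GLUC_MATURE: str = (
    "KPTENNEDFNIVAVASNFATTDLDADRGKLPGKKLPLEVLKEMEANARKA"
    "GCTRGCLICLSHIKCTPKMKKFIPGRCHTYEGDKESAQGGIGEAIVDIPA"
    "IPRFKDLEPMEQFIAQVDLCVDCTTGCLKGLANVQCSDLLKKWLPQRCAT"
    "FASKIQGQVDKIKGAGGD"
)

#: 1-based positions of the ten cysteines.
GLUC_CYSTEINES: tuple[int, ...] = tuple(
    i + 1 for i, aa in enumerate(GLUC_MATURE) if aa == "C"
)

#: The five native disulfide bonds (three unambiguous from the structures,
#: two resolved by ensemble statistics and LC-MS).
GLUC_DISULFIDES: tuple[tuple[int, int], ...] = (
    (52, 127),
    (56, 123),
    (59, 120),
    (65, 77),
    (136, 148),
)

#: Well-defined rigid-core residue ranges used for superposition and RMSD.
GLUC_CORE_RANGES: tuple[tuple[int, int], ...] = ((10, 18), (36, 81), (96, 145))

#: Intrinsically disordered segments and termini.
GLUC_FLEXIBLE_RANGES: tuple[tuple[int, int], ...] = (
    (1, 9),
    (19, 35),
    (82, 95),
    (146, 168),
)
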
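"""Shared alphabets: backbone atoms, amino acids, secondary-structure states.

The encoder works over four protein backbone nuclei whose chemical shifts
are routinely assigned in solution NMR: the amide nitrogen (15N), the alpha
carbon (13Ca), the alpha proton (1Ha) and the amide proton (1HN).  Atom
order is fixed package-wide so that feature-vector blocks are always emitted
in the same order.
"""

from __future__ import annotations

# Fixed atom emission order: 15N, 13Ca, 1Ha, 1HN.
ATOM_ORDER: tuple[str, ...] = ("N15", "C13A", "H1A", "H1N")
ATOMS: frozenset[str] = frozenset(ATOM_ORDER)

# Standard 20-letter alphabet, alphabetical (the order used by the
# composition features).
AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET: frozenset[str] = frozenset(AA_ORDER)

AA3_TO_1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3: dict[str, str] = {v: k for k, v in AA3_TO_1.items()}

# Three-state secondary structure: helix / strand / everything else.
SS_ORDER: tuple[str, ...] = ("H", "E", "C")
SS_SET: frozenset[str] = frozenset(SS_ORDER)

# Proline has no backbone amide proton: the (H1N, P, *) cells of an ACS
# table are structurally empty and the synthetic generator never emits them.
PROLINE: str = "P"


def check_atom(atom: str) -> str:
    if atom not in ATOMS:
        raise ValueError(f"unknown atom kind {atom!r}; expected one of {ATOM_ORDER}")
    return atom


def check_residue(residue: str) -> str:
    if residue not in AA_SET:
        raise ValueError(f"unknown residue {residue!r}; expected one of {AA_ORDER!r}")
    return residue


def check_ss(ss: str) -> str:
    if ss not in SS_SET:
        raise ValueError(f"unknown secondary-structure state {ss!r}; expected H, E or C")
    return ss
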
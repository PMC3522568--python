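"""Default coarse-graining schemes for B-DNA and protein chains.

DNA nucleotides are reduced to three backbone/sugar beads plus base beads:

* ``GP``  — phosphate group, placed on the P atom;
* ``GS1`` — C5' side of the deoxyribose, at the geometric center of
  C5'/C4'/O4';
* ``GS2`` — the C2'-containing part of the ring (C1'/C2'/C3'/O3' center).
  Deoxyribose lacks the 2'-hydroxyl, so this bead carries its own type,
  distinct from any ribose counterpart.

Base beads carry the base identity in their type code, which is what makes
the nucleotide sequence recoverable from a bead list.  Purines get three
beads, cytosine two, and thymine three — the third thymine bead sits on the
C7 methyl group, the major-groove feature that distinguishes T from U and C.

The protein scheme is deliberately compact: one backbone bead (``PB``, on
C-alpha) per residue plus one side-chain bead per residue type at the
geometric center of the side-chain heavy atoms (two beads for the long side
chains of Arg, Lys, Phe, Tyr and Trp; none for Gly).  Both schemes are plain
data and fully editable through the scheme-file format.
"""

from __future__ import annotations

from .cg_model import BeadEntry, BeadScheme

__all__ = [
    "default_dna_scheme",
    "default_protein_scheme",
    "dna_type_codes",
    "protein_type_codes",
    "BASE_BEAD_TO_LETTER",
    "BASE_BEAD_COUNTS",
]

# base-bead type code -> nucleotide letter
BASE_BEAD_TO_LETTER = {
    "GA1": "A", "GA2": "A", "GA3": "A",
    "GG1": "G", "GG2": "G", "GG3": "G",
    "GC1": "C", "GC2": "C",
    "GT1": "T", "GT2": "T", "GT3": "T",
}

#: base beads per nucleotide in the default scheme
BASE_BEAD_COUNTS = {"A": 3, "G": 3, "C": 2, "T": 3}

_DNA_RESIDUE_ALIASES = {"DA": "A", "DG": "G", "DC": "C", "DT": "T",
                        "A": "A", "G": "G", "C": "C", "T": "T"}

_DNA_BACKBONE = [
    ("p", "GP", ("P", "OP1", "OP2", "O5'"), "atom:P"),
    ("s1", "GS1", ("C5'", "C4'", "O4'"), "center"),
    ("s2", "GS2", ("C1'", "C2'", "C3'", "O3'"), "center"),
]

_DNA_BASES = {
    "A": [
        ("b1", "GA1", ("N9", "C8", "N7"), "center"),
        ("b2", "GA2", ("C5", "C6", "N6", "N1"), "center"),
        ("b3", "GA3", ("C2", "N3", "C4"), "center"),
    ],
    "G": [
        ("b1", "GG1", ("N9", "C8", "N7"), "center"),
        ("b2", "GG2", ("C5", "C6", "O6", "N1"), "center"),
        ("b3", "GG3", ("C2", "N2", "N3", "C4"), "center"),
    ],
    "C": [
        ("b1", "GC1", ("N1", "C2", "O2"), "center"),
        ("b2", "GC2", ("N3", "C4", "N4", "C5", "C6"), "center"),
    ],
    "T": [
        ("b1", "GT1", ("N1", "C2", "O2"), "center"),
        ("b2", "GT2", ("N3", "C4", "O4", "C5", "C6"), "center"),
        ("b3", "GT3", ("C7",), "atom:C7"),
    ],
}


def default_dna_scheme() -> BeadScheme:
    entries = []
    for resname, base in _DNA_RESIDUE_ALIASES.items():
        for name, code, atoms, placement in _DNA_BACKBONE + _DNA_BASES[base]:
            entries.append(BeadEntry(resname, name, code, atoms, placement))
    return BeadScheme(entries)


def dna_type_codes() -> list[str]:
    return ["GP", "GS1", "GS2"] + sorted(BASE_BEAD_TO_LETTER)


# ---------------------------------------------------------------------------
# protein
# ---------------------------------------------------------------------------

_BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")

# single side-chain bead: residue -> heavy atoms
_SINGLE_SIDECHAIN = {
    "ALA": ("CB",),
    "SER": ("CB", "OG"),
    "CYS": ("CB", "SG"),
    "THR": ("CB", "OG1", "CG2"),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PRO": ("CB", "CG", "CD"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
}

# two side-chain beads: residue -> (proximal atoms, distal atoms)
_SPLIT_SIDECHAIN = {
    "ARG": (("CB", "CG", "CD"), ("NE", "CZ", "NH1", "NH2")),
    "LYS": (("CB", "CG", "CD"), ("CE", "NZ")),
    "PHE": (("CB", "CG"), ("CD1", "CD2", "CE1", "CE2", "CZ")),
    "TYR": (("CB", "CG"), ("CD1", "CD2", "CE1", "CE2", "CZ", "OH")),
    "TRP": (("CB", "CG", "CD1"), ("CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")),
}

_AA_CODE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def default_protein_scheme() -> BeadScheme:
    entries = []
    for res, one in _AA_CODE.items():
        entries.append(BeadEntry(res, "bb", "PB", _BACKBONE_ATOMS, "atom:CA"))
        if res in _SINGLE_SIDECHAIN:
            entries.append(
                BeadEntry(res, "sc", f"S{one}", _SINGLE_SIDECHAIN[res], "center")
            )
        elif res in _SPLIT_SIDECHAIN:
            prox, dist = _SPLIT_SIDECHAIN[res]
            entries.append(BeadEntry(res, "sc1", f"S{one}1", prox, "center"))
            entries.append(BeadEntry(res, "sc2", f"S{one}2", dist, "center"))
    return BeadScheme(entries)


def protein_type_codes() -> list[str]:
    codes = ["PB"]
    for res, one in sorted(_AA_CODE.items()):
        if res in _SINGLE_SIDECHAIN:
            codes.append(f"S{one}")
        elif res in _SPLIT_SIDECHAIN:
            codes.extend([f"S{one}1", f"S{one}2"])
    return codes
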
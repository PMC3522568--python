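"""A physically reasonable default parameter table for the shipped schemes.

Trained protein-DNA parameter sets are not distributed with this package
(and no claim of numerical identity with any published training is made);
this module builds a sensible starting table instead, to be used directly
for exploratory docking or as the initialization of the two-stage trainer.

Sigma values combine per-type bead sizes (arithmetic mean), reflecting the
heavy-atom-group radii the beads stand for.  Epsilon defaults to a uniform
weak attraction with chemistry-flavoured adjustments: phosphate beads
attract basic side chains more strongly and interact repulsively with
acidic ones; base beads get a mild extra attraction to hydrophobic side
chains, strongest for the thymine methyl bead, the major-groove hydrophobic
patch that distinguishes T from C and U.
"""

from __future__ import annotations

import numpy as np

from .forcefield import PairParameterTable
from .schemes import dna_type_codes, protein_type_codes

__all__ = ["default_parameter_table", "bead_sizes"]

# per-type bead size (Angstrom); sigma_ij = (size_i + size_j) / 2
_BEAD_SIZES = {
    "GP": 4.2, "GS1": 4.0, "GS2": 3.9,
    "GA1": 3.8, "GA2": 3.8, "GA3": 3.8,
    "GG1": 3.8, "GG2": 3.8, "GG3": 3.8,
    "GC1": 3.8, "GC2": 3.9,
    "GT1": 3.8, "GT2": 3.9, "GT3": 3.4,
    "PB": 4.1,
    "SA": 3.6, "SC": 3.9, "SD": 4.0, "SE": 4.1, "SF1": 3.8, "SF2": 4.4,
    "SH": 4.3, "SI": 4.2, "SK1": 4.0, "SK2": 3.8, "SL": 4.2, "SM": 4.2,
    "SN": 4.0, "SP": 4.0, "SQ": 4.1, "SR1": 4.0, "SR2": 4.1, "SS": 3.6,
    "ST": 3.9, "SV": 4.0, "SW1": 4.0, "SW2": 4.6, "SY1": 3.8, "SY2": 4.5,
}

_BASIC = {"SR2", "SK2", "SH"}            # Arg/Lys distal, His
_ACIDIC = {"SD", "SE"}                   # Asp, Glu
_HYDROPHOBIC = {"SA", "SV", "SL", "SI", "SM", "SF2", "SW2", "SP", "SC"}
_BASE_BEADS = {c for c in _BEAD_SIZES if c.startswith("G") and c != "GP"
               and not c.startswith("GS")}
_BACKBONE_DNA = {"GP", "GS1", "GS2"}


def bead_sizes() -> dict[str, float]:
    return dict(_BEAD_SIZES)


def default_parameter_table() -> PairParameterTable:
    codes = dna_type_codes() + protein_type_codes()
    missing = [c for c in codes if c not in _BEAD_SIZES]
    if missing:
        raise AssertionError(f"no size for bead types {missing}")
    n = len(codes)
    size = np.array([_BEAD_SIZES[c] for c in codes])
    sigma = (size[:, None] + size[None, :]) / 2.0
    epsilon = np.full((n, n), 0.25)
    modes = np.full((n, n), "a", dtype=object)

    def idx(group):
        return [codes.index(c) for c in group if c in codes]

    for i in idx({"GP"}):
        for j in idx(_BASIC):
            epsilon[i, j] = epsilon[j, i] = 1.2
        for j in idx(_ACIDIC):
            epsilon[i, j] = epsilon[j, i] = 0.5
            modes[i, j] = modes[j, i] = "r"
    for i in idx(_BASE_BEADS):
        for j in idx(_HYDROPHOBIC):
            epsilon[i, j] = epsilon[j, i] = 0.45
    for i in idx({"GT3"}):
        for j in idx(_HYDROPHOBIC):
            epsilon[i, j] = epsilon[j, i] = 0.7
    return PairParameterTable(codes, sigma, epsilon, modes)
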
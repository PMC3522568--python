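"""Shared fixtures: tiny parameter tables, synthetic complexes, PDB writers."""

import numpy as np
import pytest

from cgdock.cg_model import CGMolecule
from cgdock.forcefield import PairEnergyModel, PairParameterTable
from cgdock.fixtures import make_toy_complex, make_universe


def pdb_atom(serial, name, resname, chain, resseq, xyz, occ=1.0,
             altloc=" ", element=None, record="ATOM"):
    """One fixed-column PDB coordinate line."""
    element = element or name.strip()[0]
    # four-character names start in column 13, shorter ones in column 14
    name_field = name if len(name) == 4 else f" {name:<3}"
    return (f"{record:<6}{serial:>5} {name_field}{altloc}{resname:<3}"
            f" {chain}{resseq:>4}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}  0.00"
            f"          {element:>2}")


def write_pdb(path, lines):
    path.write_text("\n".join(lines + ["END"]) + "\n")
    return path


@pytest.fixture(scope="session")
def universe():
    return make_universe(11)


@pytest.fixture(scope="session")
def toy_complex(universe):
    """A small verified planted-optimum complex (30 receptor + 8 ligand)."""
    return make_toy_complex(universe, 30, 8, seed=5)


@pytest.fixture(scope="session")
def toy_model(universe):
    return PairEnergyModel(universe.table, cutoff=8.0)


@pytest.fixture()
def two_type_table():
    """Minimal two-type table: one attractive, one repulsive pairing."""
    sigma = np.array([[3.0, 3.5], [3.5, 4.0]])
    epsilon = np.array([[1.0, 2.0], [2.0, 0.5]])
    modes = np.array([["a", "a"], ["a", "r"]], dtype=object)
    return PairParameterTable(["X", "Y"], sigma, epsilon, modes)


def single_bead(code, xyz, role=None, chain="A"):
    return CGMolecule(np.array([xyz], dtype=float), [code], np.array([0]),
                      ["RES"], [chain], role)
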
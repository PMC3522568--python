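"""All-atom PDB parsing and reduction to the coarse-grained bead model.

Beads replace groups of heavy atoms and are placed either directly on a
designated atom (e.g. the phosphate bead on P) or at the unweighted
geometric center of the group.  Hydrogens are ignored throughout: the
reduction is defined on heavy atoms, which is also all most X-ray
structures contain.  Beads whose member atoms are entirely missing from a
residue are dropped with a warning; partial member sets use the center of
whatever is present, so incomplete crystal structures still reduce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from Bio.PDB import PDBParser

from .errors import (EmptyStructureError, FormatError, RoleError,
                     UnmappedResidueError)

__all__ = [
    "Atom", "Residue", "Chain", "Structure",
    "BeadEntry", "BeadScheme", "CGMolecule",
    "read_pdb", "coarse_grain", "extract_sequence",
    "write_cg_structure", "read_cg_structure",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# light all-atom containers
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    name: str
    position: np.ndarray  # (3,) Angstrom


@dataclass
class Residue:
    name: str
    number: int
    icode: str
    atoms: dict[str, np.ndarray]

    @property
    def sort_key(self):
        return (self.number, self.icode)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]


@dataclass
class Structure:
    chains: list[Chain]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)


def read_pdb(path, model_selector: int = 0,
             include_hetero: bool = False) -> Structure:
    """Parse a PDB file into a plain chain/residue/atom structure.

    Waters and (by default) other heteroatoms are excluded.  Alternate
    locations resolve to the highest-occupancy conformer.  Hydrogens are
    dropped.  Residues are ordered by (residue number, insertion code).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    try:
        bio_structure = parser.get_structure("s", str(path))
    except Exception as exc:  # malformed coordinates etc.
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    models = list(bio_structure)
    if not models:
        raise EmptyStructureError(f"no models in {path}")
    if model_selector >= len(models):
        raise EmptyStructureError(
            f"model {model_selector} not present ({len(models)} model(s))"
        )
    model = models[model_selector]

    chains = []
    for bio_chain in model:
        residues = []
        for res in bio_chain:
            hetflag, resseq, icode = res.id
            if hetflag == "W":
                continue
            if hetflag.strip() and not include_hetero:
                continue
            atoms: dict[str, np.ndarray] = {}
            for atom in res:
                # DisorderedAtom yields its highest-occupancy child here
                if atom.element == "H":
                    continue
                atoms[atom.get_name()] = np.asarray(atom.get_coord(), dtype=float)
            if atoms:
                residues.append(Residue(res.get_resname().strip(), resseq,
                                        icode.strip(), atoms))
        if residues:
            residues.sort(key=lambda r: r.sort_key)
            chains.append(Chain(bio_chain.id, residues))
    structure = Structure(chains)
    if structure.n_atoms == 0:
        raise EmptyStructureError(f"no atoms selected from {path}")
    return structure


# ---------------------------------------------------------------------------
# bead scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadEntry:
    """One bead definition: residue name, bead name, type code, members."""

    residue_name: str
    bead_name: str
    type_code: str
    member_atoms: tuple[str, ...]
    placement: str = "center"  # "center" | "atom:<NAME>"

    def __post_init__(self):
        object.__setattr__(self, "member_atoms", tuple(self.member_atoms))
        if self.placement != "center":
            if not self.placement.startswith("atom:"):
                raise FormatError(
                    f"placement must be 'center' or 'atom:<NAME>', "
                    f"got {self.placement!r}"
                )
            anchor = self.placement[5:]
            if anchor not in self.member_atoms:
                raise FormatError(
                    f"on-atom anchor {anchor!r} not among member atoms "
                    f"of bead {self.bead_name!r}"
                )


class BeadScheme:
    """Declarative residue -> beads mapping.

    Within each residue, every member atom must belong to exactly one bead.
    """

    def __init__(self, entries: Iterable[BeadEntry]):
        self.entries = list(entries)
        self._by_residue: dict[str, list[BeadEntry]] = {}
        for e in self.entries:
            self._by_residue.setdefault(e.residue_name, []).append(e)
        for resname, beads in self._by_residue.items():
            seen: dict[str, str] = {}
            for b in beads:
                for a in b.member_atoms:
                    if a in seen:
                        raise FormatError(
                            f"atom {a!r} of residue {resname!r} appears in "
                            f"beads {seen[a]!r} and {b.bead_name!r}"
                        )
                    seen[a] = b.bead_name

    def residues(self) -> list[str]:
        return list(self._by_residue)

    def beads_for(self, residue_name: str) -> list[BeadEntry]:
        return self._by_residue.get(residue_name, [])

    def type_codes(self) -> list[str]:
        seen = dict.fromkeys(e.type_code for e in self.entries)
        return list(seen)

    def check_against_table(self, table) -> None:
        """Every referenced type code must exist in the parameter table."""
        missing = [c for c in self.type_codes() if c not in table.type_codes]
        if missing:
            raise FormatError(
                "scheme type codes absent from parameter table: "
                + ", ".join(missing)
            )

    # -- scheme-file I/O (YAML key-value text) -------------------------
    def save(self, path) -> None:
        doc: dict = {}
        for e in self.entries:
            doc.setdefault(e.residue_name, {})[e.bead_name] = {
                "type": e.type_code,
                "atoms": list(e.member_atoms),
                "placement": e.placement,
            }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def load(cls, path) -> "BeadScheme":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise FormatError(f"scheme file {path} is not a mapping")
        entries = []
        for resname, beads in doc.items():
            for bead_name, spec in beads.items():
                entries.append(BeadEntry(
                    str(resname), str(bead_name), str(spec["type"]),
                    tuple(spec["atoms"]), str(spec.get("placement", "center")),
                ))
        return cls(entries)


# ---------------------------------------------------------------------------
# coarse-grained molecule
# ---------------------------------------------------------------------------

@dataclass
class CGMolecule:
    """An ordered list of beads with provenance, for one rigid partner."""

    positions: np.ndarray            # (N, 3) Angstrom
    type_codes: list[str]
    residue_index: np.ndarray        # (N,) int, per-chain ordinal
    residue_names: list[str]
    chain_ids: list[str]
    role: str | None = None         # "receptor" | "ligand" | None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        n = len(self.positions)
        if n == 0:
            raise EmptyStructureError("molecule has no beads")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("bead positions must be finite")
        if not (len(self.type_codes) == len(self.residue_index)
                == len(self.residue_names) == len(self.chain_ids) == n):
            raise ValueError("bead attribute lengths disagree")
        for cid in dict.fromkeys(self.chain_ids):
            idx = self.residue_index[[c == cid for c in self.chain_ids]]
            if np.any(np.diff(idx) < 0):
                raise ValueError(
                    f"residue indices decrease within chain {cid!r}"
                )

    # -- basic geometry ------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    @property
    def bounding_radius(self) -> float:
        return float(np.max(np.linalg.norm(self.positions - self.centroid,
                                           axis=1)))

    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.chain_ids))

    def with_role(self, role: str) -> "CGMolecule":
        return CGMolecule(self.positions.copy(), list(self.type_codes),
                          self.residue_index.copy(), list(self.residue_names),
                          list(self.chain_ids), role)

    def copy(self) -> "CGMolecule":
        return CGMolecule(self.positions.copy(), list(self.type_codes),
                          self.residue_index.copy(), list(self.residue_names),
                          list(self.chain_ids), self.role)


def coarse_grain(structure: Structure, scheme: BeadScheme,
                 role: str | None = None) -> CGMolecule:
    """Reduce an all-atom structure to beads according to a scheme.

    Raises :class:`UnmappedResidueError` listing every residue name that has
    no scheme entry.  Beads with no member atoms present are skipped with a
    logged warning; partially present members use the center of what exists.
    """
    unmapped = sorted({
        r.name for c in structure.chains for r in c.residues
        if not scheme.beads_for(r.name)
    })
    if unmapped:
        raise UnmappedResidueError(unmapped)

    positions, codes, res_idx, res_names, chain_ids = [], [], [], [], []
    for chain in structure.chains:
        for ordinal, res in enumerate(chain.residues):
            for bead in scheme.beads_for(res.name):
                present = [res.atoms[a] for a in bead.member_atoms
                           if a in res.atoms]
                if not present:
                    logger.warning(
                        "bead %s of %s %s%s/%s has no atoms present; dropped",
                        bead.bead_name, res.name, res.number, res.icode,
                        chain.chain_id,
                    )
                    continue
                if bead.placement.startswith("atom:"):
                    anchor = bead.placement[5:]
                    pos = (res.atoms[anchor] if anchor in res.atoms
                           else np.mean(present, axis=0))
                else:
                    pos = np.mean(present, axis=0)
                positions.append(pos)
                codes.append(bead.type_code)
                res_idx.append(ordinal)
                res_names.append(res.name)
                chain_ids.append(chain.chain_id)
    if not positions:
        raise EmptyStructureError("coarse-graining produced no beads")
    return CGMolecule(np.array(positions), codes, np.array(res_idx),
                      res_names, chain_ids, role)


def extract_sequence(mol: CGMolecule) -> dict[str, str]:
    """Per-chain nucleotide strings (5'->3' by residue index) for a DNA molecule.

    The sequence is read from the base-bead type codes, so it works on any
    bead list produced by the default DNA scheme.  A molecule containing a
    residue with no recognizable base bead is rejected.
    """
    from .schemes import BASE_BEAD_TO_LETTER

    sequences: dict[str, str] = {}
    for cid in sorted(mol.chains()):
        mask = [c == cid for c in mol.chain_ids]
        per_residue: dict[int, str] = {}
        seen_residues = []
        for i, on in enumerate(mask):
            if not on:
                continue
            ridx = int(mol.residue_index[i])
            if ridx not in per_residue:
                seen_residues.append(ridx)
            letter = BASE_BEAD_TO_LETTER.get(mol.type_codes[i])
            if letter is not None:
                prev = per_residue.get(ridx, "")
                if prev and prev != letter:
                    raise RoleError(
                        f"conflicting base beads in chain {cid!r} residue {ridx}"
                    )
                per_residue[ridx] = letter
            else:
                per_residue.setdefault(ridx, "")
        missing = [r for r in seen_residues if not per_residue[r]]
        if missing:
            raise RoleError(
                f"chain {cid!r} has residues without base beads "
                f"(not DNA?): {missing[:5]}"
            )
        sequences[cid] = "".join(per_residue[r] for r in sorted(seen_residues))
    return sequences


# ---------------------------------------------------------------------------
# CG structure file (PDB-dialect + sidecar table)
# ---------------------------------------------------------------------------

def write_cg_structure(mol: CGMolecule, path, sidecar: bool = True) -> None:
    """Write one pseudo-ATOM line per bead; type code in the atom-name column.

    A tab-separated sidecar ``<path>.beads.tsv`` maps bead index to type
    code, residue and chain, preserving codes longer than the PDB column.
    """
    path = Path(path)
    lines = []
    for i in range(mol.n_beads):
        x, y, z = mol.positions[i]
        lines.append(
            "ATOM  {serial:>5} {name:<4} {res:<3} {chain:1}{resseq:>4}    "
            "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00".format(
                serial=i + 1, name=mol.type_codes[i][:4],
                res=mol.residue_names[i][:3], chain=str(mol.chain_ids[i])[:1],
                resseq=int(mol.residue_index[i]) % 10000, x=x, y=y, z=z,
            )
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    if sidecar:
        side = ["bead_index\ttype_code\tresidue_index\tresidue_name\tchain"]
        side += [
            f"{i}\t{mol.type_codes[i]}\t{int(mol.residue_index[i])}"
            f"\t{mol.residue_names[i]}\t{mol.chain_ids[i]}"
            for i in range(mol.n_beads)
        ]
        path.with_suffix(path.suffix + ".beads.tsv").write_text(
            "\n".join(side) + "\n"
        )


def read_cg_structure(path, role: str | None = None) -> CGMolecule:
    """Re-read a CG structure written by :func:`write_cg_structure`.

    Prefers the sidecar table for bead metadata; falls back to the PDB-dialect
    columns when the sidecar is absent.
    """
    path = Path(path)
    side = path.with_suffix(path.suffix + ".beads.tsv")
    positions = []
    for line in path.read_text().splitlines():
        if line.startswith("ATOM"):
            positions.append([float(line[30:38]), float(line[38:46]),
                              float(line[46:54])])
    if not positions:
        raise EmptyStructureError(f"no bead records in {path}")
    if side.exists():
        rows = [ln.split("\t") for ln in side.read_text().splitlines()[1:] if ln]
        if len(rows) != len(positions):
            raise FormatError(f"sidecar {side} disagrees with {path}")
        codes = [r[1] for r in rows]
        res_idx = [int(r[2]) for r in rows]
        res_names = [r[3] for r in rows]
        chain_ids = [r[4] for r in rows]
    else:
        codes, res_idx, res_names, chain_ids = [], [], [], []
        for line in Path(path).read_text().splitlines():
            if not line.startswith("ATOM"):
                continue
            codes.append(line[12:16].strip())
            res_names.append(line[17:20].strip())
            chain_ids.append(line[21:22])
            res_idx.append(int(line[22:26]))
    return CGMolecule(np.array(positions), codes, np.array(res_idx),
                      res_names, chain_ids, role)
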
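"""Binding-affinity analysis utilities.

Covers the record-level plumbing needed to compare force-field energies
with experimental binding free energies: the Tanimoto sequence-similarity
coefficient and the condition filters used to match thermodynamic records
to crystal structures, a contact-count binding estimate, Pearson
correlation, isosteric DNA base-pair mutation, and rescoring of docked
poses under altered DNA sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .cg_model import CGMolecule, extract_sequence
from .docking import DockingPose, batch_interaction_energies
from .errors import RoleError
from .forcefield import PairEnergyModel
from .geometry import RigidTransform

__all__ = [
    "AffinityRecord", "FilterConditions", "BaseTemplates",
    "tanimoto", "best_overlap", "strand_overlap_identity",
    "filter_records", "contact_estimate", "correlate",
    "default_base_templates", "mutate_dna", "randomize_sequence",
    "rescore_with_sequence",
    "read_affinity_table", "write_affinity_table",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_PAIRS = {"AT", "TA", "GC", "CG"}
_PURINES = frozenset("AG")


def _check_seq(seq: str, name: str = "sequence") -> str:
    seq = str(seq).upper()
    if not seq:
        raise ValueError(f"{name} must be non-empty")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"{name} contains non-DNA symbols: {sorted(bad)}")
    return seq


# ---------------------------------------------------------------------------
# sequence similarity
# ---------------------------------------------------------------------------

def best_overlap(seq_a: str, seq_b: str,
                 min_overlap: int = 1) -> tuple[int, int, int]:
    """Best ungapped overlap alignment of two sequences.

    Slides one sequence over the other through every offset with overlap at
    least ``min_overlap`` and maximizes the number of identical positions.
    Ties prefer the larger overlap, then the smaller offset magnitude.
    Returns ``(n_identical, overlap_length, offset)`` where ``offset`` is the
    position of ``seq_b``'s start relative to ``seq_a``'s.
    """
    a, b = _check_seq(seq_a, "seq_a"), _check_seq(seq_b, "seq_b")
    best = (-1, 0, 0)
    for offset in range(-(len(b) - 1), len(a)):
        lo_a, hi_a = max(0, offset), min(len(a), offset + len(b))
        overlap = hi_a - lo_a
        if overlap < min_overlap:
            continue
        sub_a = a[lo_a:hi_a]
        sub_b = b[lo_a - offset:hi_a - offset]
        nid = sum(x == y for x, y in zip(sub_a, sub_b))
        key = (nid, overlap, -abs(offset))
        if key > (best[0], best[1], -abs(best[2])):
            best = (nid, overlap, offset)
    return best


def tanimoto(seq_a: str, seq_b: str) -> float:
    """Tanimoto coefficient t_c = N_id / (N_1 + N_2 - N_id).

    N_id is the number of identical nucleotides in the best ungapped overlap
    alignment; N_1 and N_2 are the full sequence lengths, so a perfect match
    of a short fragment against a much longer construct still scores low.
    """
    nid, _, _ = best_overlap(seq_a, seq_b)
    return nid / (len(seq_a) + len(seq_b) - nid)


def strand_overlap_identity(seq_a: str, seq_b: str) -> float:
    """Identity over the overlapping part of the best ungapped alignment.

    The overlap must span at least half of the shorter sequence, so a
    spurious few-base match at a sequence end cannot claim high identity.
    """
    floor = max(1, min(len(seq_a), len(seq_b)) // 2)
    nid, overlap, _ = best_overlap(seq_a, seq_b, min_overlap=floor)
    return nid / overlap if overlap else 0.0


# ---------------------------------------------------------------------------
# records and filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffinityRecord:
    """One experimental measurement matched to a crystal structure."""

    complex_id: str
    delta_g: float                       # kcal/mol, negative = favorable
    temperature: float                   # degrees C
    ph: float
    ionic_mm: float                      # total ionic concentration, mM
    experimental_sequences: tuple[str, ...]
    structure_sequences: tuple[str, ...]

    def __post_init__(self):
        if not np.isfinite(self.delta_g):
            raise ValueError("delta_g must be finite")
        object.__setattr__(self, "experimental_sequences",
                           tuple(_check_seq(s) for s in self.experimental_sequences))
        object.__setattr__(self, "structure_sequences",
                           tuple(_check_seq(s) for s in self.structure_sequences))


@dataclass(frozen=True)
class FilterConditions:
    """Measurement-condition and sequence-similarity admission rules."""

    temperature_range: tuple[float, float] = (20.0, 25.0)
    ph_range: tuple[float, float] = (6.0, 8.5)
    max_ionic_mm: float = 200.0          # exclusive bound
    min_strand_identity: float = 0.8     # per strand, on the overlap
    min_tanimoto: float = 0.5


def filter_records(
    records: Sequence[AffinityRecord],
    conditions: FilterConditions | None = None,
) -> tuple[list[AffinityRecord], dict[str, str]]:
    """Apply the admission rules in order; average duplicate structures.

    Returns the surviving records (one per structure, duplicate measurements
    averaged into a single delta G) and a per-record-id rejection-reason map
    for the discarded ones.  Rules, in order: temperature window, pH window,
    ionic concentration below the bound, per-strand overlap identity, and
    the Tanimoto coefficient of each strand (length-aware similarity).
    """
    cond = conditions or FilterConditions()
    reasons: dict[str, str] = {}
    kept: list[AffinityRecord] = []
    for idx, rec in enumerate(records):
        key = f"{rec.complex_id}#{idx}"
        lo, hi = cond.temperature_range
        if not (lo <= rec.temperature <= hi):
            reasons[key] = "temperature"
            continue
        lo, hi = cond.ph_range
        if not (lo <= rec.ph <= hi):
            reasons[key] = "ph"
            continue
        if not (rec.ionic_mm < cond.max_ionic_mm):
            reasons[key] = "ionic"
            continue
        idents = [strand_overlap_identity(e, s) for e, s in
                  zip(rec.experimental_sequences, rec.structure_sequences)]
        if min(idents, default=0.0) < cond.min_strand_identity:
            reasons[key] = "strand_identity"
            continue
        tcs = [tanimoto(e, s) for e, s in
               zip(rec.experimental_sequences, rec.structure_sequences)]
        if min(tcs, default=0.0) < cond.min_tanimoto:
            reasons[key] = "tanimoto"
            continue
        kept.append(rec)
    # aggregate duplicate structures by mean delta G
    by_id: dict[str, list[AffinityRecord]] = {}
    for rec in kept:
        by_id.setdefault(rec.complex_id, []).append(rec)
    survivors = []
    for cid, group in by_id.items():
        if len(group) == 1:
            survivors.append(group[0])
        else:
            mean_dg = float(np.mean([r.delta_g for r in group]))
            survivors.append(replace(group[0], delta_g=mean_dg))
    return survivors, reasons


# ---------------------------------------------------------------------------
# binding estimates and correlation
# ---------------------------------------------------------------------------

def contact_estimate(receptor: CGMolecule, ligand: CGMolecule,
                     pose: RigidTransform | DockingPose,
                     cutoff: float = 8.0) -> int:
    """Number of inter-molecular bead pairs within ``cutoff`` in the pose."""
    transform = pose.transform if isinstance(pose, DockingPose) else pose
    lig = ligand.positions @ transform.matrix().T + transform.translation
    diff = lig[None, :, :] - receptor.positions[:, None, :]
    dist = np.sqrt(np.einsum("rlk,rlk->rl", diff, diff))
    return int(np.count_nonzero(dist <= cutoff))


def correlate(predicted: Sequence[float], experimental: Sequence[float]) -> float:
    """Pearson correlation between predicted energies and experimental dG."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(experimental, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-d samples of length >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("Pearson correlation undefined for zero variance")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# isosteric DNA mutation
# ---------------------------------------------------------------------------

@dataclass
class BaseTemplates:
    """Idealized base-bead geometries in a per-residue backbone frame.

    ``beads[base]`` lists (type code, offset) with offsets expressed in an
    orthonormal frame built from the residue's backbone beads, so replacing
    a base re-uses the local backbone geometry with no refinement.  Offsets
    are shared within the purine and pyrimidine classes (thymine may append
    extra beads for its methyl), which is what makes class-preserving swaps
    exactly isosteric.  ``frame_codes`` names the three backbone bead types
    (origin, axis, plane reference) used to build the frame.
    """

    beads: dict[str, list[tuple[str, np.ndarray]]]
    frame_codes: tuple[str, str, str] = ("GS2", "GS1", "GP")
    code_to_base: dict[str, str] = field(init=False)

    def __post_init__(self):
        self.code_to_base = {}
        for base, entries in self.beads.items():
            self.beads[base] = [(c, np.asarray(o, dtype=float))
                                for c, o in entries]
            for code, _ in self.beads[base]:
                if self.code_to_base.setdefault(code, base) != base:
                    raise ValueError(f"type code {code!r} used by two bases")

    def base_of_code(self, code: str) -> str | None:
        return self.code_to_base.get(code)


# shared class geometries: bases in one class occupy identical positions
_PURINE_OFFSETS = [(1.2, 2.2, 0.0), (1.8, 4.3, 0.3), (0.4, 4.1, -0.3)]
_PYRIMIDINE_OFFSETS = [(1.2, 2.2, 0.0), (1.2, 4.4, 0.0)]
_THYMINE_METHYL = (2.6, 5.6, 0.2)


def default_base_templates() -> BaseTemplates:
    """Templates matching the default DNA scheme's base-bead type codes."""
    return BaseTemplates({
        "A": [("GA1", _PURINE_OFFSETS[0]), ("GA2", _PURINE_OFFSETS[1]),
              ("GA3", _PURINE_OFFSETS[2])],
        "G": [("GG1", _PURINE_OFFSETS[0]), ("GG2", _PURINE_OFFSETS[1]),
              ("GG3", _PURINE_OFFSETS[2])],
        "C": [("GC1", _PYRIMIDINE_OFFSETS[0]), ("GC2", _PYRIMIDINE_OFFSETS[1])],
        "T": [("GT1", _PYRIMIDINE_OFFSETS[0]), ("GT2", _PYRIMIDINE_OFFSETS[1]),
              ("GT3", _THYMINE_METHYL)],
    })


def _residue_frame(mol: CGMolecule, bead_idx: Sequence[int],
                   frame_codes) -> tuple[np.ndarray, np.ndarray]:
    """(origin, 3x3 frame matrix) from a residue's backbone beads."""
    by_code = {mol.type_codes[i]: mol.positions[i] for i in bead_idx}
    try:
        origin = by_code[frame_codes[0]]
        axis_pt = by_code[frame_codes[1]]
        plane_pt = by_code[frame_codes[2]]
    except KeyError as exc:
        raise RoleError(
            f"residue lacks backbone bead {exc.args[0]!r} needed for the "
            "mutation frame"
        ) from None
    e1 = axis_pt - origin
    n1 = np.linalg.norm(e1)
    if n1 < 1e-9:
        raise RoleError("degenerate backbone frame (coincident beads)")
    e1 = e1 / n1
    v = plane_pt - origin
    e2 = v - (v @ e1) * e1
    n2 = np.linalg.norm(e2)
    if n2 < 1e-9:
        raise RoleError("degenerate backbone frame (collinear beads)")
    e2 = e2 / n2
    e3 = np.cross(e1, e2)
    return origin, np.stack([e1, e2, e3], axis=1)


def _duplex_pairing(mol: CGMolecule) -> tuple[str, str, list[int], list[int]]:
    chains = mol.chains()
    if len(chains) != 2:
        raise RoleError("isosteric mutation needs a two-chain duplex")
    a, b = chains
    res_a = sorted({int(mol.residue_index[i]) for i, c in
                    enumerate(mol.chain_ids) if c == a})
    res_b = sorted({int(mol.residue_index[i]) for i, c in
                    enumerate(mol.chain_ids) if c == b})
    if len(res_a) != len(res_b):
        raise RoleError("strands have unequal lengths; cannot pair")
    return a, b, res_a, res_b


def mutate_dna(mol: CGMolecule, position: int, new_base_pair: str,
               templates: BaseTemplates | None = None) -> CGMolecule:
    """Isosterically replace one base pair of a duplex.

    ``position`` indexes residues of the first chain (0-based, by residue
    index order); the partner residue on the second chain is the
    antiparallel mate (last pairs with first).  ``new_base_pair`` is the
    two-letter pair such as ``"GC"``: first letter goes to the first strand.
    Backbone and sugar beads are untouched (bitwise); base beads are
    replaced by the template geometry expressed in the residue's local
    backbone frame, with purines and pyrimidines occupying their shared
    class positions.
    """
    templates = templates or default_base_templates()
    pair = str(new_base_pair).upper()
    if pair not in _PAIRS:
        raise ValueError(f"{new_base_pair!r} is not a complementary base pair")
    chain_a, chain_b, res_a, res_b = _duplex_pairing(mol)
    if not (0 <= position < len(res_a)):
        raise ValueError(f"position {position} outside the duplex")
    targets = [
        (chain_a, res_a[position], pair[0]),
        (chain_b, res_b[len(res_b) - 1 - position], pair[1]),
    ]

    positions = [p for p in mol.positions]
    codes = list(mol.type_codes)
    res_idx = list(mol.residue_index)
    res_names = list(mol.residue_names)
    chain_ids = list(mol.chain_ids)

    for chain, ridx, new_base in targets:
        bead_idx = [i for i in range(len(codes))
                    if chain_ids[i] == chain and res_idx[i] == ridx]
        base_idx = [i for i in bead_idx
                    if templates.base_of_code(codes[i]) is not None]
        if not base_idx:
            raise RoleError(
                f"residue {ridx} on chain {chain!r} has no base beads"
            )
        origin, frame = _residue_frame(mol, bead_idx, templates.frame_codes)
        new_beads = [(code, origin + frame @ off)
                     for code, off in templates.beads[new_base]]
        insert_at = base_idx[0]
        template_row = insert_at
        keep = [i for i in range(len(codes)) if i not in base_idx]
        new_positions, new_codes = [], []
        new_res_idx, new_res_names, new_chain_ids = [], [], []
        inserted = False

        def _insert():
            for code, pos in new_beads:
                new_positions.append(pos)
                new_codes.append(code)
                new_res_idx.append(ridx)
                new_res_names.append(res_names[template_row])
                new_chain_ids.append(chain)

        for i in keep:
            if not inserted and i > insert_at:
                _insert()
                inserted = True
            new_positions.append(positions[i])
            new_codes.append(codes[i])
            new_res_idx.append(res_idx[i])
            new_res_names.append(res_names[i])
            new_chain_ids.append(chain_ids[i])
        if not inserted:
            _insert()
        positions, codes = new_positions, new_codes
        res_idx, res_names, chain_ids = new_res_idx, new_res_names, new_chain_ids

    return CGMolecule(np.array(positions), codes, np.array(res_idx),
                      res_names, chain_ids, mol.role)


# ---------------------------------------------------------------------------
# sequence-randomized rescoring
# ---------------------------------------------------------------------------

def randomize_sequence(seq: str, identity: float, seed: int = 0,
                       mode: str = "uniform") -> str:
    """Substitute bases to hit a target identity with the input sequence.

    Exactly ``round((1 - identity) * len(seq))`` positions (seeded choice)
    are replaced by a base different from the original, so the realized
    identity equals the target up to rounding.  ``mode="uniform"`` draws
    replacements uniformly from the other three bases; ``mode="class"``
    swaps within the purine/pyrimidine class (A<->G, C<->T), preserving
    base-bead class geometry.
    """
    seq = _check_seq(seq)
    if not (0.0 <= identity <= 1.0):
        raise ValueError("identity must be in [0, 1]")
    if mode not in ("uniform", "class"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(int(seed))
    n_mut = int(round((1.0 - identity) * len(seq)))
    sites = rng.choice(len(seq), size=n_mut, replace=False)
    swap = {"A": "G", "G": "A", "C": "T", "T": "C"}
    out = list(seq)
    for i in sites:
        if mode == "class":
            out[i] = swap[out[i]]
        else:
            others = [b for b in "ACGT" if b != out[i]]
            out[i] = str(rng.choice(others))
    return "".join(out)


def complement_sequence(seq: str) -> str:
    """Watson-Crick complement, 3'->5' reversed."""
    return _check_seq(seq).translate(_COMPLEMENT)[::-1]


def rescore_with_sequence(
    poses: Sequence[DockingPose], receptor_dna: CGMolecule,
    ligand: CGMolecule, new_sequence: str, model: PairEnergyModel,
    templates: BaseTemplates | None = None,
) -> tuple[list[DockingPose], CGMolecule]:
    """Re-rank docked poses after threading a new sequence onto the DNA.

    ``new_sequence`` replaces the first strand (the second strand follows by
    complementarity); every differing position is mutated isosterically and
    all pose energies are re-evaluated at the model cutoff and re-ranked.
    Returns the re-ranked pose list (new objects) and the mutated receptor.
    """
    templates = templates or default_base_templates()
    new_sequence = _check_seq(new_sequence)
    chains = sorted(extract_sequence(receptor_dna))
    current = extract_sequence(receptor_dna)[chains[0]]
    if len(new_sequence) != len(current):
        raise ValueError(
            f"sequence length {len(new_sequence)} != duplex length {len(current)}"
        )
    mutated = receptor_dna
    for i, (old, new) in enumerate(zip(current, new_sequence)):
        if old != new:
            pair = new + complement_sequence(new)
            mutated = mutate_dna(mutated, i, pair, templates)
    transforms = [p.transform for p in poses]
    energies = batch_interaction_energies(mutated, ligand, transforms, model)
    rescored = [
        DockingPose(p.transform, float(e), p.start_id, p.orientation_id,
                    cluster_id=p.cluster_id)
        for p, e in zip(poses, energies)
    ]
    for rank, pose in enumerate(sorted(rescored, key=DockingPose.sort_key), 1):
        pose.rank = rank
    return rescored, mutated


# ---------------------------------------------------------------------------
# affinity table I/O
# ---------------------------------------------------------------------------

_AFF_HEADER = ("complex_id\tdelta_g\ttemperature\tph\tionic_mm"
               "\texp_seq_1\texp_seq_2\tstruct_seq_1\tstruct_seq_2")


def write_affinity_table(records: Sequence[AffinityRecord], path) -> None:
    lines = [_AFF_HEADER]
    for r in records:
        e = list(r.experimental_sequences) + ["", ""]
        s = list(r.structure_sequences) + ["", ""]
        lines.append(f"{r.complex_id}\t{r.delta_g}\t{r.temperature}"
                     f"\t{r.ph}\t{r.ionic_mm}\t{e[0]}\t{e[1]}\t{s[0]}\t{s[1]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_affinity_table(path) -> list[AffinityRecord]:
    lines = Path(path).read_text().splitlines()
    records = []
    for line in lines[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        records.append(AffinityRecord(
            f[0], float(f[1]), float(f[2]), float(f[3]), float(f[4]),
            tuple(x for x in f[5:7] if x), tuple(x for x in f[7:9] if x),
        ))
    return records
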
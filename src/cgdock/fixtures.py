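"""Deterministic synthetic systems for exercising every docking stage.

Real training corpora require bulk structure downloads; these generators
replace them with abstract bead systems whose ground truth is known by
construction: a pair-parameter table is planted first, and toy complexes are
then built so that, under that table, the native pose is a verified deep
energy minimum.  Geometry is deliberately abstract (jittered lattices and
complementary surface patches, not pseudo-B-DNA): the point is to exercise
the search, scoring and training machinery, not to mimic real nucleic-acid
shapes.

Everything here is a pure function of its parameters and a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .cg_model import CGMolecule
from .docking import (DockingPose, SearchSettings, batch_interaction_energies,
                      minimize_pose)
from .errors import CgdockError
from .evaluate import ReferenceComplex, interface_rmsd, native_interface
from .forcefield import PairEnergyModel, PairParameterTable, R_M_FACTOR
from .geometry import RigidTransform

__all__ = [
    "SyntheticUniverse", "make_universe", "make_toy_complex",
    "make_decoys", "make_affinity_records",
]

logger = logging.getLogger(__name__)


@dataclass
class SyntheticUniverse:
    """A small closed world of bead types with a planted parameter table."""

    receptor_types: list[str]
    ligand_types: list[str]
    table: PairParameterTable
    seed: int

    @property
    def type_codes(self) -> list[str]:
        return self.receptor_types + self.ligand_types


def make_universe(seed: int = 0, n_receptor_types: int = 5,
                  n_ligand_types: int = 5) -> SyntheticUniverse:
    """Plant a valid random parameter table over a small type alphabet.

    Matched cross pairs (R_k, L_k) are strongly attractive — the
    lock-and-key signal a trained potential is supposed to encode — while
    every mismatched cross pair is mildly repulsive, the way unfavourable
    chemistry (like-charge proximity, buried polarity) shows up in
    knowledge-based statistics.  The repulsion makes misregistered
    interfaces pay for every wrong contact, so the planted register is a
    sharply selective optimum, while the matched attraction still dominates
    at long range and preserves the docking funnel.  Sigma values sit in
    the 3.6-4.6 Angstrom range typical of heavy-atom-group beads.
    """
    rng = np.random.default_rng(int(seed))
    rec = [f"R{i}" for i in range(n_receptor_types)]
    lig = [f"L{i}" for i in range(n_ligand_types)]
    codes = rec + lig
    n = len(codes)
    sigma = np.round(rng.uniform(3.6, 4.6, size=(n, n)), 4)
    sigma = (sigma + sigma.T) / 2.0
    epsilon = np.round(rng.uniform(0.15, 0.35, size=(n, n)), 4)
    epsilon = (epsilon + epsilon.T) / 2.0
    modes = np.full((n, n), "a", dtype=object)
    for i in range(n_receptor_types):
        for j in range(n_ligand_types):
            a, b = i, n_receptor_types + j
            if i == j:
                epsilon[a, b] = epsilon[b, a] = round(rng.uniform(2.4, 3.0), 4)
            else:
                epsilon[a, b] = epsilon[b, a] = round(rng.uniform(0.3, 0.6), 4)
                modes[a, b] = modes[b, a] = "r"
    table = PairParameterTable(codes, sigma, epsilon, modes)
    return SyntheticUniverse(rec, lig, table, int(seed))


# ---------------------------------------------------------------------------
# toy complexes with a planted optimum
# ---------------------------------------------------------------------------

def _lattice_slab(n: int, spacing: float, jitter: float,
                  rng: np.random.Generator):
    """A jittered two-layer lattice slab of n points, centred at the origin.

    Returns (points, top_layer_indices, top_layer_cells).  The top layer is
    fully exposed, so beads placed above it cannot be buried inside the
    receptor; its integer (i, j) lattice cells are returned so callers can
    lay out spatial type patterns.
    """
    per_layer = (n + 1) // 2
    m = int(np.ceil(np.sqrt(per_layer)))
    xy = [(i, j) for j in range(m) for i in range(m)]
    # order cells by distance from the grid centre so the slab stays compact
    xy.sort(key=lambda ij: ((ij[0] - (m - 1) / 2) ** 2
                            + (ij[1] - (m - 1) / 2) ** 2, ij))
    pts, top, cells = [], [], []
    for k in range(n):
        layer, cell = (1, k - (n - per_layer)) if k >= n - per_layer else (0, k)
        i, j = xy[cell]
        if layer == 1:
            top.append(k)
            cells.append((i, j))
        pts.append(((i - (m - 1) / 2) * spacing,
                    (j - (m - 1) / 2) * spacing,
                    layer * spacing))
    pts = np.asarray(pts, dtype=float)
    pts -= pts.mean(axis=0)
    return (pts + rng.uniform(-jitter, jitter, size=pts.shape),
            np.array(top), np.array(cells))


def _verification_settings() -> SearchSettings:
    return SearchSettings(cutoff_schedule=(8.0,), max_iterations=300,
                          tolerance=1e-9)


def make_toy_complex(
    universe: SyntheticUniverse, n_receptor_beads: int = 50,
    n_ligand_beads: int = 15, seed: int = 0, max_retries: int = 6,
) -> tuple[CGMolecule, CGMolecule, RigidTransform]:
    """Build a receptor blob plus a ligand docked into a planted optimum.

    The receptor is a jittered lattice blob.  The ligand is constructed over
    the receptor's upper surface: each ligand bead sits at the planted
    minimum-energy distance r_m above a distinct surface bead whose type it
    is matched to, so the returned (identity-refined) native transform is a
    deep minimum of the planted table.  Generation verifies this by
    re-minimizing from the native pose; a failed verification moves to the
    next seed, a bounded number of times.
    """
    if n_receptor_beads < 2 or n_ligand_beads < 2:
        raise ValueError("need at least 2 beads per partner")
    if n_ligand_beads > n_receptor_beads:
        raise ValueError("ligand cannot have more beads than the receptor")
    for attempt in range(max_retries):
        trial_seed = int(seed) + 104729 * attempt
        result = _try_toy_complex(universe, n_receptor_beads, n_ligand_beads,
                                  trial_seed)
        if result is not None:
            return result
        logger.warning("toy-complex verification failed for seed %d; retrying",
                       trial_seed)
    raise CgdockError(
        f"could not generate a verified toy complex from seed {seed}"
    )


def _try_toy_complex(universe, n_rec, n_lig, seed):
    rng = np.random.default_rng(seed)
    rec_pos, top, cells = _lattice_slab(n_rec, spacing=4.0, jitter=0.25,
                                        rng=rng)
    if n_lig > len(top):
        raise ValueError(
            f"ligand size {n_lig} exceeds the exposed receptor surface "
            f"({len(top)} beads)"
        )

    # the n_lig most central exposed beads form the binding patch
    lateral = np.linalg.norm(rec_pos[top, :2], axis=1)
    pick = np.argsort(lateral, kind="stable")[:n_lig]
    patch, patch_cells = top[pick], cells[pick]
    rec_types = list(rng.choice(universe.receptor_types, size=n_rec))
    n_types = len(universe.receptor_types)
    # Latin-square-like type pattern over lattice cells: no small rigid
    # shift of the patch can realign matched pairs, so the planted register
    # is the unique high-affinity alignment
    order = np.argsort(rec_pos[patch, 0], kind="stable")
    patch_order = patch[order]
    for idx, (ci, cj) in zip(patch, patch_cells):
        rec_types[idx] = universe.receptor_types[(ci + 2 * cj) % n_types]

    match = dict(zip(universe.receptor_types, universe.ligand_types))
    lig_pos, lig_types = [], []
    for idx in patch_order:
        r_code = rec_types[idx]
        l_code = match[r_code]
        sigma, _, _ = universe.table.pair(r_code, l_code)
        direction = np.array([0.0, 0.0, 1.0]) + rng.normal(0, 0.05, 3)
        direction /= np.linalg.norm(direction)
        lig_pos.append(rec_pos[idx] + direction * sigma * R_M_FACTOR)
        lig_types.append(l_code)
    lig_pos = np.asarray(lig_pos)

    receptor = CGMolecule(rec_pos, rec_types, np.arange(n_rec),
                          ["RES"] * n_rec, ["R"] * n_rec, role="receptor")
    ligand = CGMolecule(lig_pos, lig_types, np.arange(n_lig),
                        ["RES"] * n_lig, ["L"] * n_lig, role="ligand")

    model = PairEnergyModel(universe.table, cutoff=8.0)
    # relax the hand-built contact geometry into its true local minimum and
    # bake it into the ligand coordinates: the native transform is then the
    # identity, sitting exactly at a minimum of the planted table
    relaxed = minimize_pose(receptor, ligand, RigidTransform.identity(),
                            model, _verification_settings())
    ligand = CGMolecule(relaxed.transform.apply(ligand.positions), lig_types,
                        np.arange(n_lig), ["RES"] * n_lig, ["L"] * n_lig,
                        role="ligand")
    pose = minimize_pose(receptor, ligand, RigidTransform.identity(), model,
                         _verification_settings())
    moved = pose.transform.apply(ligand.positions) - ligand.positions
    if float(np.sqrt(np.mean(np.sum(moved**2, axis=1)))) > 0.1:
        return None

    # planted-funnel check: native beats random contact poses
    native = pose.transform
    e_native = pose.energy
    rand_poses = _random_contact_transforms(receptor, ligand, 200, rng)
    e_random = batch_interaction_energies(receptor, ligand, rand_poses, model)
    if e_native >= float(np.min(e_random)):
        return None

    # global-optimum check: a coarse multi-start search must not find a
    # deeper basin away from the native pose
    from .docking import systematic_search

    coarse = SearchSettings(start_spacing=20.0, orientations_per_start=24,
                            max_iterations=40)
    found = systematic_search(receptor, ligand, model, coarse, seed=seed)
    best = min(found, key=DockingPose.sort_key)
    if best.energy < e_native - 1e-9:
        moved = best.transform.apply(ligand.positions) \
            - native.apply(ligand.positions)
        if float(np.sqrt(np.mean(np.sum(moved**2, axis=1)))) > 0.5:
            return None
    return receptor, ligand, native


def _random_contact_transforms(receptor, ligand, n, rng):
    """Random ligand placements touching the receptor surface."""
    center = receptor.centroid
    rel = receptor.positions - center
    out = []
    for _ in range(n):
        rot = Rotation.random(random_state=rng)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        support = float(np.max(rel @ direction))
        dist = support + ligand.bounding_radius * rng.uniform(0.2, 0.9)
        point = center + direction * dist
        t = point - rot.apply(ligand.centroid)
        out.append(RigidTransform(rot.as_quat(), t))
    return out


# ---------------------------------------------------------------------------
# decoys
# ---------------------------------------------------------------------------

def make_decoys(
    receptor: CGMolecule, ligand: CGMolecule, native: RigidTransform,
    model: PairEnergyModel, n: int = 200, seed: int = 0,
    min_irmsd: float = 4.0, relax_iterations: int = 30,
) -> list[DockingPose]:
    """n clash-relaxed non-native poses, all beyond ``min_irmsd`` of native.

    Random contact placements are briefly minimized at the final cutoff (so
    decoys are locally relaxed, not trivially clashing) and kept only if
    their iRMSD from the native pose exceeds ``min_irmsd``, which excludes
    anything a CAPRI-style assessment could call a hit.
    """
    if n < 1:
        raise ValueError("need n >= 1 decoys")
    rng = np.random.default_rng(int(seed))
    reference = ReferenceComplex(receptor, ligand, native)
    interface = native_interface(reference, cutoff=8.0)
    settings = SearchSettings(cutoff_schedule=(model.cutoff,),
                              max_iterations=relax_iterations)
    decoys: list[DockingPose] = []
    guard = 0
    while len(decoys) < n and guard < 80 * n:
        guard += 1
        start = _random_contact_transforms(receptor, ligand, 1, rng)[0]
        pose = minimize_pose(receptor, ligand, start, model, settings)
        if interface_rmsd(pose, reference, interface) > min_irmsd:
            pose.start_id = -1
            pose.orientation_id = len(decoys)
            decoys.append(pose)
    if len(decoys) < n:
        raise CgdockError(f"could only generate {len(decoys)}/{n} decoys")
    return decoys


# ---------------------------------------------------------------------------
# synthetic affinity records
# ---------------------------------------------------------------------------

def make_affinity_records(n: int = 10, seed: int = 0):
    """Records with one planted violation per filter rule, plus survivors.

    Returns ``(records, expected_survivor_ids)`` where the survivor set is
    known by construction.  At least one record violates each rule
    (temperature, pH, ionic strength, per-strand identity, Tanimoto
    similarity) and one structure carries duplicate measurements that the
    filter must average.
    """
    from .affinity import AffinityRecord

    if n < 1:
        raise ValueError("need n >= 1 records")
    rng = np.random.default_rng(int(seed))
    bases = np.array(list("ACGT"))

    def random_seq(length):
        return "".join(rng.choice(bases, size=length))

    def complement(seq):
        return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]

    records, survivors = [], []
    violations = ["temperature", "ph", "ionic", "strand_identity", "tanimoto"]
    for i in range(n):
        cid = f"CPLX{i:03d}"
        seq = random_seq(16)
        duplex = (seq, complement(seq))
        kwargs = dict(
            complex_id=cid,
            delta_g=float(np.round(rng.uniform(-16.0, -5.0), 2)),
            temperature=float(np.round(rng.uniform(20.0, 25.0), 1)),
            ph=float(np.round(rng.uniform(6.5, 8.0), 2)),
            ionic_mm=float(np.round(rng.uniform(20.0, 150.0), 0)),
            experimental_sequences=duplex,
            structure_sequences=duplex,
        )
        rule = violations[i % len(violations)] if i % 2 else None
        if rule == "temperature":
            kwargs["temperature"] = 30.0
        elif rule == "ph":
            kwargs["ph"] = 5.0
        elif rule == "ionic":
            kwargs["ionic_mm"] = 250.0
        elif rule == "strand_identity":
            # first strand genuinely dissimilar from the structure strand
            # (verified, so the planted truth holds for any seed)
            from .affinity import strand_overlap_identity

            while True:
                other = random_seq(16)
                if strand_overlap_identity(other, seq) < 0.8:
                    break
            kwargs["experimental_sequences"] = (other, duplex[1])
        elif rule == "tanimoto":
            # high identity on a short overlap of a much longer construct:
            # passes the per-strand identity rule, fails the length-aware one
            long_a = random_seq(24) + seq + random_seq(24)
            kwargs["experimental_sequences"] = (long_a, complement(long_a))
        records.append(AffinityRecord(**kwargs))
        if rule is None:
            survivors.append(cid)
    # duplicate measurement for the first survivor
    if survivors:
        first = next(r for r in records if r.complex_id == survivors[0])
        dup = AffinityRecord(
            complex_id=first.complex_id, delta_g=first.delta_g - 1.0,
            temperature=first.temperature, ph=first.ph,
            ionic_mm=first.ionic_mm,
            experimental_sequences=first.experimental_sequences,
            structure_sequences=first.structure_sequences,
        )
        records.append(dup)
    return records, survivors
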
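"""Systematic rigid-body docking by multi-start energy minimization.

The mobile partner (ligand, here the protein) is minimized in its six rigid
degrees of freedom in the field of the fixed receptor (the DNA), starting
from positions distributed on a surface around the receptor and, at each
position, from a set of near-uniform initial orientations.  Each
minimization runs in five stages with the pairwise distance cutoff stepped
down from 50 to 8 Angstrom, so early stages feel long-range attraction while
the final stage scores tight interfaces only.  Converged solutions are
pooled, clustered by ligand-bead RMSD and ranked by energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from ._kernels import HAVE_NUMBA, pair_sum_energy, pair_sum_energy_grad
from .cg_model import CGMolecule
from .forcefield import PairEnergyModel, energy_and_bead_gradient
from .geometry import RigidTransform

__all__ = [
    "SearchSettings", "DockingPose",
    "generate_start_points", "generate_orientations",
    "minimize_pose", "systematic_search", "cluster_poses",
    "batch_interaction_energies", "write_poses", "read_poses",
]

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_SCHEDULE = (50.0, 30.0, 18.0, 11.0, 8.0)


@dataclass
class SearchSettings:
    """Knobs of the systematic search.

    ``start_spacing`` is the target distance between neighbouring start
    points on the surface around the receptor; ``cutoff_schedule`` lists the
    per-stage pairwise cutoffs (non-increasing).  ``clearance`` is the extra
    margin added beyond the ligand bounding radius when placing start
    points, so no start overlaps the receptor in any orientation.
    """

    start_spacing: float = 12.0
    orientations_per_start: int = 208
    cutoff_schedule: tuple[float, ...] = DEFAULT_CUTOFF_SCHEDULE
    max_iterations: int = 100
    tolerance: float = 1e-7
    clearance: float = 5.0
    cluster_cutoff: float = 3.0

    def __post_init__(self):
        self.cutoff_schedule = tuple(float(c) for c in self.cutoff_schedule)
        if not self.cutoff_schedule:
            raise ValueError("cutoff schedule must not be empty")
        if any(b > a for a, b in zip(self.cutoff_schedule,
                                     self.cutoff_schedule[1:])):
            raise ValueError("cutoff schedule must be non-increasing")
        if min(self.cutoff_schedule) <= 0:
            raise ValueError("cutoffs must be positive")
        if self.start_spacing <= 0:
            raise ValueError("start spacing must be positive")
        if self.orientations_per_start < 1:
            raise ValueError("need at least one orientation per start")


@dataclass
class DockingPose:
    """One converged solution: transform, final energy and bookkeeping."""

    transform: RigidTransform
    energy: float
    start_id: int = -1
    orientation_id: int = -1
    cluster_id: int | None = None
    rank: int | None = None
    improved: bool = True

    def sort_key(self):
        return (self.energy, self.start_id, self.orientation_id)


# ---------------------------------------------------------------------------
# start placements
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-evenly spread unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def generate_start_points(
    receptor: CGMolecule, ligand: CGMolecule, spacing: float = 12.0,
    clearance: float = 5.0,
) -> np.ndarray:
    """Ligand-center start positions on a surface offset from the receptor.

    Directions are sampled on a golden-spiral lattice; along each direction
    the point sits at the receptor support radius (the farthest bead
    projection) plus the ligand bounding radius plus ``clearance``, and is
    pushed further out if any receptor bead would still come closer than
    that.  The point count is chosen so neighbouring points are roughly
    ``spacing`` apart.  A single-bead receptor degenerates naturally to a
    sphere.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    center = receptor.centroid
    rel = receptor.positions - center
    offset = ligand.bounding_radius + clearance

    # surface-area estimate from support radii on a probe set of directions
    probe = _fibonacci_sphere(128)
    support = np.max(probe @ rel.T, axis=1)
    mean_sq_radius = float(np.mean((support + offset) ** 2))
    n = max(8, int(round(4.0 * np.pi * mean_sq_radius / spacing**2)))

    dirs = _fibonacci_sphere(n)
    radii = np.max(dirs @ rel.T, axis=1) + offset
    points = center + dirs * radii[:, None]
    # push out until the clearance holds for every receptor bead
    for k in range(len(points)):
        for _ in range(64):
            d = np.linalg.norm(receptor.positions - points[k], axis=1)
            short = offset - float(np.min(d))
            if short <= 1e-9:
                break
            points[k] = points[k] + dirs[k] * (short + 1e-6)
    return points


# ---------------------------------------------------------------------------
# orientations
# ---------------------------------------------------------------------------

_SF_PHI = np.sqrt(2.0)
_SF_PSI = 1.533751168755204288118041  # positive root of psi^4 = psi + 4


def generate_orientations(n: int, seed: int = 0) -> np.ndarray:
    """``n`` near-uniform unit quaternions (scalar-last), identity first.

    A deterministic low-discrepancy spiral on the rotation group
    (super-Fibonacci sampling) supplies the base set; it is shifted so the
    first element is the identity and then conjugated by a seeded random
    rotation, which re-seeds the set without disturbing its pairwise
    rotation angles or the identity element.
    """
    if n < 1:
        raise ValueError("need n >= 1 orientations")
    i = np.arange(n) + 0.5
    t = i / n
    d = 2.0 * np.pi * i
    r, big_r = np.sqrt(t), np.sqrt(1.0 - t)
    alpha, beta = d / _SF_PHI, d / _SF_PSI
    quat = np.stack([r * np.sin(alpha), r * np.cos(alpha),
                     big_r * np.sin(beta), big_r * np.cos(beta)], axis=1)
    rots = Rotation.from_quat(quat)
    rots = rots * rots[0].inv()              # first element -> identity
    scramble = Rotation.random(random_state=np.random.default_rng(int(seed)))
    rots = scramble * rots * scramble.inv()  # angle-preserving reseed
    out = rots.as_quat().reshape(n, 4)
    out[0] = (0.0, 0.0, 0.0, 1.0)
    # canonical sign for bit-stable output
    flip = out[:, 3] < 0
    out[flip] *= -1.0
    return out


# ---------------------------------------------------------------------------
# rigid-body minimization
# ---------------------------------------------------------------------------

class _RigidObjective:
    """Energy/gradient of one ligand pose in the fixed receptor field.

    Poses are manipulated in a local chart: rotation increments are applied
    about the current ligand centroid, which keeps the six degrees of
    freedom comparably scaled.  The chart is re-centred after every accepted
    step, so gradients are only ever required at the chart origin where they
    are exact and cheap.
    """

    def __init__(self, receptor: CGMolecule, ligand: CGMolecule,
                 model: PairEnergyModel):
        self.rec = np.ascontiguousarray(receptor.positions)
        self.lig = np.ascontiguousarray(ligand.positions)
        sigma, epsilon, repulsive = model.table.submatrices_for(
            receptor.type_codes, ligand.type_codes
        )
        self.sigma = np.ascontiguousarray(sigma)
        self.epsilon = np.ascontiguousarray(epsilon)
        self.repulsive = np.ascontiguousarray(repulsive)
        self._rep_u8 = np.ascontiguousarray(repulsive.astype(np.uint8))
        self._grad_buf = np.empty_like(self.lig)

    def energy_mt(self, mat: np.ndarray, t: np.ndarray, cutoff: float) -> float:
        world = self.lig @ mat.T + t
        if HAVE_NUMBA:
            return float(pair_sum_energy(self.rec, world, self.sigma,
                                         self.epsilon, self._rep_u8, cutoff))
        e, _ = energy_and_bead_gradient(self.rec, world, self.sigma,
                                        self.epsilon, self.repulsive, cutoff)
        return e

    def grad6_mt(self, mat: np.ndarray, t: np.ndarray, cutoff: float):
        """(E, 6-gradient, centroid) at the chart origin of pose (mat, t).

        Gradient layout: d/d(translation), then d/d(rotation vector) for a
        rotation applied about the current ligand centroid.
        """
        world = self.lig @ mat.T + t
        if HAVE_NUMBA:
            e = float(pair_sum_energy_grad(self.rec, world, self.sigma,
                                           self.epsilon, self._rep_u8, cutoff,
                                           self._grad_buf))
            g = self._grad_buf
        else:
            e, g = energy_and_bead_gradient(self.rec, world, self.sigma,
                                            self.epsilon, self.repulsive,
                                            cutoff)
        m = world.mean(axis=0)
        out = np.empty(6)
        out[:3] = g.sum(axis=0)
        out[3:] = np.cross(world - m, g).sum(axis=0)
        return e, out, m

    def energy(self, transform: RigidTransform, cutoff: float) -> float:
        return self.energy_mt(transform.matrix(), transform.translation,
                              cutoff)


def _rodrigues(w: np.ndarray) -> np.ndarray:
    """Rotation matrix of a rotation vector (angle = |w|, axis = w/|w|)."""
    theta2 = float(w @ w)
    k = np.array([[0.0, -w[2], w[1]],
                  [w[2], 0.0, -w[0]],
                  [-w[1], w[0], 0.0]])
    if theta2 < 1e-16:
        return np.eye(3) + k + 0.5 * (k @ k)
    theta = np.sqrt(theta2)
    return (np.eye(3) + (np.sin(theta) / theta) * k
            + ((1.0 - np.cos(theta)) / theta2) * (k @ k))


def _chart_step(mat, t, m, x):
    """Apply chart increment x = (dt, w): rotate about m by w, shift by dt."""
    a = _rodrigues(x[3:])
    return a @ mat, a @ (t - m) + m + x[:3]


def _minimize_stage(obj: _RigidObjective, mat: np.ndarray, t: np.ndarray,
                    cutoff: float, max_iter: int, tol: float):
    """BFGS with Armijo backtracking in the moving local chart."""
    h = np.eye(6)
    e, g, m = obj.grad6_mt(mat, t, cutoff)
    for _ in range(max_iter):
        gnorm = float(np.linalg.norm(g))
        if gnorm < tol:
            break
        d = -h @ g
        slope = float(g @ d)
        if slope >= 0.0:          # bad curvature estimate; reset to descent
            h = np.eye(6)
            d = -g
            slope = -gnorm**2
        # keep the first trial step below ~2 A / ~0.4 rad
        dmax = float(np.max(np.abs(d)))
        alpha = min(1.0, 2.0 / dmax) if dmax > 0 else 1.0
        accepted = False
        for _ls in range(30):
            mat_trial, t_trial = _chart_step(mat, t, m, alpha * d)
            e_trial = obj.energy_mt(mat_trial, t_trial, cutoff)
            if e_trial <= e + 1e-4 * alpha * slope:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        e_new, g_new, m_new = obj.grad6_mt(mat_trial, t_trial, cutoff)
        s = alpha * d
        y = g_new - g
        sy = float(s @ y)
        if sy > 1e-12:
            rho = 1.0 / sy
            v = np.eye(6) - rho * np.outer(s, y)
            h = v @ h @ v.T + rho * np.outer(s, s)
        else:
            h = np.eye(6)
        converged = abs(e - e_new) < tol * (1.0 + abs(e))
        mat, t, e, g, m = mat_trial, t_trial, e_new, g_new, m_new
        if converged:
            break
    return mat, t, e


def minimize_pose(
    receptor: CGMolecule, ligand: CGMolecule, start: RigidTransform,
    model: PairEnergyModel, settings: SearchSettings | None = None,
    start_id: int = -1, orientation_id: int = -1,
    _objective: _RigidObjective | None = None,
) -> DockingPose:
    """Staged rigid-body minimization of one start pose.

    One quasi-Newton minimization per cutoff in the schedule, each stage
    continuing from the previous stage's result.  The reported energy is
    evaluated at the final (smallest) cutoff.  If the minimization failed to
    improve on the start pose at that cutoff, the pose is returned with
    ``improved=False`` (the start pose itself is kept in that case).
    """
    settings = settings or SearchSettings()
    obj = _objective or _RigidObjective(receptor, ligand, model)
    final_cutoff = settings.cutoff_schedule[-1]
    e_start = obj.energy(start, final_cutoff)
    if not np.isfinite(e_start):
        raise FloatingPointError("non-finite energy at start pose")
    mat, t = start.matrix(), start.translation
    for cutoff in settings.cutoff_schedule:
        mat, t, _ = _minimize_stage(obj, mat, t, cutoff,
                                    settings.max_iterations,
                                    settings.tolerance)
    e_final = obj.energy_mt(mat, t, final_cutoff)
    if e_final > e_start:
        return DockingPose(start, e_start, start_id, orientation_id,
                           improved=False)
    transform = RigidTransform(Rotation.from_matrix(mat).as_quat(), t)
    return DockingPose(transform, e_final, start_id, orientation_id)


# ---------------------------------------------------------------------------
# search, clustering, ranking
# ---------------------------------------------------------------------------

def batch_interaction_energies(
    receptor: CGMolecule, ligand: CGMolecule,
    transforms: Sequence[RigidTransform], model: PairEnergyModel,
) -> np.ndarray:
    """Energies of many poses at the model cutoff, vectorized over poses."""
    obj = _RigidObjective(receptor, ligand, model)
    out = np.empty(len(transforms))
    for k, tr in enumerate(transforms):
        out[k] = obj.energy(tr, model.cutoff)
    return out


def systematic_search(
    receptor: CGMolecule, ligand: CGMolecule, model: PairEnergyModel,
    settings: SearchSettings | None = None, seed: int = 0,
) -> list[DockingPose]:
    """Full multi-start search: minimize, cluster, rank.

    One minimization per (start point x orientation).  Start orientations
    rotate the ligand about its own centroid before translating it to the
    start point.  Results are clustered by ligand-bead RMSD and ranked by
    final energy (rank 1 = lowest; ties broken by start then orientation
    index for determinism).
    """
    settings = settings or SearchSettings()
    starts = generate_start_points(receptor, ligand, settings.start_spacing,
                                   settings.clearance)
    quats = generate_orientations(settings.orientations_per_start, seed)
    obj = _RigidObjective(receptor, ligand, model)
    lig_centroid = ligand.centroid

    poses: list[DockingPose] = []
    for s_id, point in enumerate(starts):
        for o_id, q in enumerate(quats):
            rot = Rotation.from_quat(q)
            # rotate about the ligand centroid, then move centroid to point
            t = point - rot.apply(lig_centroid)
            start = RigidTransform(q, t)
            pose = minimize_pose(receptor, ligand, start, model, settings,
                                 start_id=s_id, orientation_id=o_id,
                                 _objective=obj)
            poses.append(pose)
    cluster_poses(poses, ligand, settings.cluster_cutoff)
    _assign_ranks(poses)
    return poses


def _assign_ranks(poses: list[DockingPose]) -> None:
    for rank, pose in enumerate(sorted(poses, key=DockingPose.sort_key), 1):
        pose.rank = rank


def pose_rmsd_matrix_row(coords: np.ndarray, others: np.ndarray) -> np.ndarray:
    diff = others - coords[None]
    return np.sqrt(np.einsum("nlk,nlk->n", diff, diff) / coords.shape[0])


def cluster_poses(
    poses: list[DockingPose], ligand: CGMolecule, rmsd_cutoff: float = 3.0
) -> list[DockingPose]:
    """Greedy leader clustering in energy order (in place).

    The lowest-energy unassigned pose seeds each cluster and all unassigned
    poses within ``rmsd_cutoff`` ligand-bead RMSD of it (transforms applied,
    no superposition) join.  The seed is therefore the lowest-energy member
    and the cluster representative.
    """
    if not poses:
        return poses
    order = sorted(range(len(poses)), key=lambda i: poses[i].sort_key())
    coords = np.stack([
        ligand.positions @ poses[i].transform.matrix().T
        + poses[i].transform.translation
        for i in range(len(poses))
    ])
    assigned = np.zeros(len(poses), dtype=bool)
    cluster = 0
    for leader in order:
        if assigned[leader]:
            continue
        rmsd = pose_rmsd_matrix_row(coords[leader], coords)
        members = (~assigned) & (rmsd <= rmsd_cutoff)
        members[leader] = True
        for i in np.nonzero(members)[0]:
            poses[i].cluster_id = cluster
        assigned |= members
        cluster += 1
    return poses


# ---------------------------------------------------------------------------
# pose table I/O
# ---------------------------------------------------------------------------

_POSE_HEADER = ("rank\tenergy\tcluster\tstart_id\torientation_id"
                "\tqx\tqy\tqz\tqw\ttx\tty\ttz")


def write_poses(poses: Sequence[DockingPose], path) -> None:
    lines = [_POSE_HEADER]
    for p in sorted(poses, key=DockingPose.sort_key):
        q = p.transform.quaternion
        t = p.transform.translation
        lines.append(
            f"{p.rank if p.rank is not None else ''}\t{p.energy:.10g}"
            f"\t{p.cluster_id if p.cluster_id is not None else ''}"
            f"\t{p.start_id}\t{p.orientation_id}"
            f"\t{q[0]:.12g}\t{q[1]:.12g}\t{q[2]:.12g}\t{q[3]:.12g}"
            f"\t{t[0]:.6f}\t{t[1]:.6f}\t{t[2]:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_poses(path) -> list[DockingPose]:
    lines = Path(path).read_text().splitlines()
    poses = []
    for line in lines[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        transform = RigidTransform(np.array(f[5:9], dtype=float),
                                   np.array(f[9:12], dtype=float))
        poses.append(DockingPose(
            transform, float(f[1]),
            start_id=int(f[3]), orientation_id=int(f[4]),
            cluster_id=int(f[2]) if f[2] else None,
            rank=int(f[0]) if f[0] else None,
        ))
    return poses
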
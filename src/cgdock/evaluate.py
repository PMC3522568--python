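"""CAPRI-style assessment of docked geometries against a reference complex.

The native interface is the set of inter-molecular bead pairs within a
cutoff (8 Angstrom by default) in the reference complex.  Two metrics are
computed per pose: the interface RMSD (iRMSD) after least-squares
superposition of the posed complex onto the reference over the interface
beads of both partners, and the fraction of native contacts (f_NC) still
within the contact cutoff.  Poses are then binned into the CAPRI-style
tiers high / medium / acceptable / incorrect, with "hit" meaning high or
medium quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cg_model import CGMolecule
from .docking import DockingPose
from .geometry import RigidTransform

__all__ = [
    "ReferenceComplex", "NativeInterface", "QualityLabel", "CapriThresholds",
    "kabsch", "native_interface", "interface_rmsd",
    "fraction_native_contacts", "classify", "hit_fraction_curve",
    "label_poses",
]


@dataclass
class ReferenceComplex:
    """Receptor and ligand with the ligand's native (reference) transform."""

    receptor: CGMolecule
    ligand: CGMolecule
    transform: RigidTransform = field(default_factory=RigidTransform.identity)

    def ligand_native_coords(self) -> np.ndarray:
        return (self.ligand.positions @ self.transform.matrix().T
                + self.transform.translation)


@dataclass
class NativeInterface:
    """Native contact pairs and the interface bead sets of both partners."""

    contact_pairs: np.ndarray       # (n_pairs, 2) receptor, ligand indices
    receptor_beads: np.ndarray      # sorted unique receptor indices
    ligand_beads: np.ndarray        # sorted unique ligand indices
    contact_cutoff: float = 8.0

    @property
    def n_contacts(self) -> int:
        return len(self.contact_pairs)


@dataclass(frozen=True)
class QualityLabel:
    """One of high / medium / acceptable / incorrect; hit = high or medium."""

    label: str

    _ORDER = ("incorrect", "acceptable", "medium", "high")

    def __post_init__(self):
        if self.label not in self._ORDER:
            raise ValueError(f"unknown quality label {self.label!r}")

    @property
    def is_hit(self) -> bool:
        return self.label in ("high", "medium")

    @property
    def tier(self) -> int:
        return self._ORDER.index(self.label)

    def __str__(self):
        return self.label


@dataclass(frozen=True)
class CapriThresholds:
    """Configurable quality thresholds (Angstrom / fraction)."""

    high_irmsd: float = 1.0
    high_fnc: float = 0.5
    medium_irmsd: float = 2.0
    medium_fnc: float = 0.3
    acceptable_irmsd: float = 4.0
    acceptable_fnc: float = 0.3


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares superposition of ``mobile`` onto ``target``.

    Returns (rotation matrix, translation, rmsd) such that
    ``mobile @ R.T + t`` best fits ``target``.  Proper rotations only
    (reflections are corrected by flipping the smallest singular vector).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise ValueError("need matching coordinate sets of >= 3 points")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    p, q = mobile - mc, target - tc
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = tc - r @ mc
    fitted = mobile @ r.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - target) ** 2, axis=1))))
    return r, t, rmsd


def native_interface(reference: ReferenceComplex,
                     cutoff: float = 8.0) -> NativeInterface:
    """All inter-molecular bead pairs within ``cutoff`` in the reference."""
    rec = reference.receptor.positions
    lig = reference.ligand_native_coords()
    diff = lig[None, :, :] - rec[:, None, :]
    dist = np.sqrt(np.einsum("rlk,rlk->rl", diff, diff))
    ri, li = np.nonzero(dist <= cutoff)
    pairs = np.stack([ri, li], axis=1) if len(ri) else np.empty((0, 2), int)
    if len(pairs) == 0:
        import logging
        logging.getLogger(__name__).warning(
            "no native contacts within %.1f A - empty interface", cutoff
        )
    return NativeInterface(pairs, np.unique(ri), np.unique(li), cutoff)


def _posed_ligand(pose, reference: ReferenceComplex) -> np.ndarray:
    transform = pose.transform if isinstance(pose, DockingPose) else pose
    return (reference.ligand.positions @ transform.matrix().T
            + transform.translation)


def interface_rmsd(pose, reference: ReferenceComplex,
                   interface: NativeInterface) -> float:
    """iRMSD of a pose: joint superposition over interface beads, then RMSD.

    The posed complex (fixed receptor + transformed ligand) is superposed
    onto the reference complex using the interface beads of both partners,
    so any global rigid motion of the whole assembled complex cancels.
    """
    n_beads = len(interface.receptor_beads) + len(interface.ligand_beads)
    if n_beads < 3:
        raise ValueError("interface has fewer than 3 beads; iRMSD undefined")
    rec = reference.receptor.positions[interface.receptor_beads]
    ref_lig = reference.ligand_native_coords()[interface.ligand_beads]
    posed_lig = _posed_ligand(pose, reference)[interface.ligand_beads]
    mobile = np.vstack([rec, posed_lig])
    target = np.vstack([rec, ref_lig])
    _, _, rmsd = kabsch(mobile, target)
    return rmsd


def fraction_native_contacts(pose, reference: ReferenceComplex,
                             interface: NativeInterface) -> float:
    """Fraction of native contact pairs preserved by the pose."""
    if interface.n_contacts == 0:
        raise ValueError("empty native interface; f_NC undefined")
    rec = reference.receptor.positions[interface.contact_pairs[:, 0]]
    lig = _posed_ligand(pose, reference)[interface.contact_pairs[:, 1]]
    dist = np.linalg.norm(lig - rec, axis=1)
    return float(np.mean(dist <= interface.contact_cutoff))


def classify(irmsd: float, fnc: float,
             thresholds: CapriThresholds | None = None) -> QualityLabel:
    """Map (iRMSD, f_NC) to a quality tier.

    high:       iRMSD <= 1 A and f_NC >= 0.5
    medium:     iRMSD <= 2 A and f_NC >= 0.3
    acceptable: iRMSD <= 4 A or  f_NC >= 0.3
    incorrect:  otherwise
    """
    if not (np.isfinite(irmsd) and np.isfinite(fnc)):
        raise ValueError("iRMSD and f_NC must be finite")
    t = thresholds or CapriThresholds()
    if irmsd <= t.high_irmsd and fnc >= t.high_fnc:
        return QualityLabel("high")
    if irmsd <= t.medium_irmsd and fnc >= t.medium_fnc:
        return QualityLabel("medium")
    if irmsd <= t.acceptable_irmsd or fnc >= t.acceptable_fnc:
        return QualityLabel("acceptable")
    return QualityLabel("incorrect")


def hit_fraction_curve(
    hit_ranks: Sequence[Sequence[int]], n_max: int = 100
) -> tuple[np.ndarray, float]:
    """Per-rank hit-fraction curve and its normalized area (AUC).

    ``hit_ranks[c]`` lists the ranks (1-based) of the hits found for complex
    ``c`` (empty if none).  ``curve[n-1]`` is the fraction of complexes with
    at least one hit of rank <= n; the AUC is the mean of the curve over
    n = 1..n_max, so 1.0 means every complex has a rank-1 hit and 0.0 means
    no hits within the first ``n_max`` solutions anywhere.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    n_complexes = len(hit_ranks)
    if n_complexes == 0:
        raise ValueError("need at least one complex")
    best = np.array([min(r) if len(r) else np.inf for r in hit_ranks])
    n = np.arange(1, n_max + 1)
    curve = np.mean(best[None, :] <= n[:, None], axis=1)
    return curve, float(curve.mean())


def label_poses(poses: Sequence[DockingPose], reference: ReferenceComplex,
                interface: NativeInterface | None = None,
                thresholds: CapriThresholds | None = None):
    """Per-pose (rank, energy, iRMSD, f_NC, label) table as a DataFrame."""
    import pandas as pd

    interface = interface or native_interface(reference)
    rows = []
    for p in sorted(poses, key=DockingPose.sort_key):
        irmsd = interface_rmsd(p, reference, interface)
        fnc = fraction_native_contacts(p, reference, interface)
        lab = classify(irmsd, fnc, thresholds)
        rows.append({"rank": p.rank, "energy": p.energy, "cluster":
                     p.cluster_id, "irmsd": irmsd, "fnc": fnc,
                     "label": str(lab), "is_hit": lab.is_hit})
    return pd.DataFrame(rows)
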
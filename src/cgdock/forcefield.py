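"""The distance-dependent 8-6 pair potential and its parameter tables.

Every bead-type pair (i, j) interacts through one of two forms governed by a
range parameter sigma_ij (Angstrom) and a strength parameter epsilon_ij
(force-field units):

attractive::

    U_attr(r) = eps * (sigma**8 / r**8 - sigma**6 / r**6)

which has its minimum at ``r_m = sigma * sqrt(4/3)`` with well depth
``U_m = -(27/256) * eps``, and a purely repulsive soft-core variant built
from the same curve::

    U_rep(r) = U_attr(r) + 2*|U_m|   for r <= r_m
             = -U_attr(r)            for r >  r_m

The repulsive branch is continuous at r_m (both sides equal ``|U_m|``),
positive everywhere, and decays to zero at large separation.  No explicit
electrostatic term is used: the pair parameters are meant to absorb all
effective interactions, as in knowledge-based potentials.

Energy units are arbitrary "force-field units"; all downstream comparisons
(ranking, Pearson correlation against experimental affinities) are invariant
to an overall positive scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError, ParameterLookupError
from .geometry import RigidTransform

__all__ = [
    "R_M_FACTOR",
    "WELL_DEPTH_FACTOR",
    "PairParameterTable",
    "PairEnergyModel",
    "pair_energy",
    "pair_gradient",
    "interaction_energy",
    "make_nonspecific",
]

#: r_m / sigma for the 8-6 form (argmin of the attractive branch).
R_M_FACTOR = float(np.sqrt(4.0 / 3.0))

#: |U_m| / epsilon for the 8-6 form.
WELL_DEPTH_FACTOR = 27.0 / 256.0


# ---------------------------------------------------------------------------
# scalar pair potential
# ---------------------------------------------------------------------------

def _attr_energy(r, sigma, epsilon):
    s2 = (sigma / r) ** 2
    s6 = s2 * s2 * s2
    return epsilon * (s6 * s2 - s6)


def _attr_derivative(r, sigma, epsilon):
    # dU_attr/dr = eps * (-8 sigma^8 / r^9 + 6 sigma^6 / r^7)
    s2 = (sigma / r) ** 2
    s6 = s2 * s2 * s2
    return epsilon * (-8.0 * s6 * s2 + 6.0 * s6) / r


def pair_energy(r, sigma: float, epsilon: float, mode: str = "attractive"):
    """Energy of one bead pair at separation ``r`` (Angstrom).

    ``mode`` is ``"attractive"`` or ``"repulsive"`` (``"a"``/``"r"``
    accepted).  Scalar or array ``r`` is supported; ``r <= 0`` raises.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0.0):
        raise ValueError("pair separation must be positive")
    if sigma <= 0.0 or epsilon <= 0.0:
        raise ValueError("sigma and epsilon must be positive")
    u = _attr_energy(r, sigma, epsilon)
    mode = _canonical_mode(mode)
    if mode == "a":
        out = u
    else:
        r_m = sigma * R_M_FACTOR
        shift = 2.0 * WELL_DEPTH_FACTOR * epsilon
        out = np.where(r <= r_m, u + shift, -u)
    return float(out) if out.ndim == 0 else out


def pair_gradient(r_vec, sigma: float, epsilon: float, mode: str = "attractive"):
    """Force ``-dU/dx`` on a bead at ``r_vec`` relative to a partner at the origin.

    At the repulsive-mode kink ``r == r_m`` the derivative of the outer
    (``r > r_m``) branch is used, so minimizer behaviour is deterministic.
    """
    r_vec = np.asarray(r_vec, dtype=float).reshape(3)
    r = float(np.linalg.norm(r_vec))
    if r <= 0.0:
        raise ValueError("pair separation must be positive")
    dudr = _attr_derivative(r, sigma, epsilon)
    if _canonical_mode(mode) == "r":
        r_m = sigma * R_M_FACTOR
        dudr = dudr if r < r_m else -dudr
    return -dudr * r_vec / r


def _canonical_mode(mode: str) -> str:
    m = str(mode).strip().lower()[:1]
    if m not in ("a", "r"):
        raise ValueError(f"unknown interaction mode {mode!r}")
    return m


# ---------------------------------------------------------------------------
# parameter table
# ---------------------------------------------------------------------------

@dataclass
class PairParameterTable:
    """Symmetric per-type-pair sigma/epsilon/mode matrices.

    ``type_codes`` fixes the matrix ordering.  ``modes`` holds single-letter
    strings (``'a'`` attractive, ``'r'`` repulsive) in a matrix of the same
    shape.  Validation checks symmetry, positivity and — numerically — that
    the attractive branch of every pair has its minimum at
    ``sigma * sqrt(4/3)`` and that the repulsive branch is continuous there.
    """

    type_codes: list[str]
    sigma: np.ndarray
    epsilon: np.ndarray
    modes: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.type_codes = [str(c) for c in self.type_codes]
        n = len(self.type_codes)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.modes = np.asarray(self.modes, dtype=object)
        for name, mat in (("sigma", self.sigma), ("epsilon", self.epsilon),
                          ("modes", self.modes)):
            if mat.shape != (n, n):
                raise FormatError(f"{name} matrix must be {n}x{n}, got {mat.shape}")
        if len(set(self.type_codes)) != n:
            raise FormatError("duplicate bead type codes in table")
        self.modes = np.vectorize(_canonical_mode)(self.modes).astype(object) \
            if n else self.modes
        self._index = {c: i for i, c in enumerate(self.type_codes)}
        self.validate()

    # -- queries ------------------------------------------------------
    def index_of(self, code: str) -> int:
        try:
            return self._index[code]
        except KeyError:
            raise ParameterLookupError(code) from None

    def pair(self, code_i: str, code_j: str) -> tuple[float, float, str]:
        i, j = self.index_of(code_i), self.index_of(code_j)
        return float(self.sigma[i, j]), float(self.epsilon[i, j]), str(self.modes[i, j])

    @property
    def repulsive_mask(self) -> np.ndarray:
        return np.asarray(self.modes == "r")

    def r_m(self) -> np.ndarray:
        """Minimum-energy distances of the attractive branch, per pair."""
        return self.sigma * R_M_FACTOR

    def u_m(self) -> np.ndarray:
        """Well depths (negative) of the attractive branch, per pair."""
        return -WELL_DEPTH_FACTOR * self.epsilon

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        if np.any(~np.isfinite(self.sigma)) or np.any(self.sigma <= 0):
            raise FormatError("sigma entries must be finite and positive")
        if np.any(~np.isfinite(self.epsilon)) or np.any(self.epsilon <= 0):
            raise FormatError("epsilon entries must be finite and positive")
        if not np.allclose(self.sigma, self.sigma.T, rtol=0, atol=0):
            raise FormatError("sigma matrix is not symmetric")
        if not np.allclose(self.epsilon, self.epsilon.T, rtol=0, atol=0):
            raise FormatError("epsilon matrix is not symmetric")
        if np.any(self.modes != self.modes.T):
            raise FormatError("mode matrix is not symmetric")
        self._check_minimum_numerically()

    def _check_minimum_numerically(self) -> None:
        # three-point check that r_m is a local minimum of the attractive
        # branch, and two-sided continuity of the repulsive branch at r_m
        rm = self.r_m()
        for h in (0.999, 1.001):
            if not np.all(
                _attr_energy(rm, self.sigma, self.epsilon)
                <= _attr_energy(rm * h, self.sigma, self.epsilon)
            ):
                raise FormatError("attractive minimum not at sigma*sqrt(4/3)")
        left = _attr_energy(rm * (1 - 1e-9), self.sigma, self.epsilon) \
            + 2.0 * WELL_DEPTH_FACTOR * self.epsilon
        right = -_attr_energy(rm * (1 + 1e-9), self.sigma, self.epsilon)
        if not np.allclose(left, right, rtol=1e-6):
            raise FormatError("repulsive branch discontinuous at r_m")

    # -- file I/O -----------------------------------------------------
    def save(self, path) -> None:
        """Write the sectioned text format (types, sigma, epsilon, mode)."""
        lines = ["# cgdock pair parameter table", "[types]",
                 " ".join(self.type_codes)]
        for name, mat in (("sigma", self.sigma), ("epsilon", self.epsilon)):
            lines.append(f"[{name}]")
            lines.extend(" ".join(f"{v:.10g}" for v in row) for row in mat)
        lines.append("[mode]")
        lines.extend(" ".join(row) for row in self.modes)
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "PairParameterTable":
        sections: dict[str, list[list[str]]] = {}
        current: list[list[str]] | None = None
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                current = sections.setdefault(line[1:-1].lower(), [])
                continue
            if current is None:
                raise FormatError(f"content before first section header: {raw!r}")
            current.append(line.split())
        for required in ("types", "sigma", "epsilon", "mode"):
            if required not in sections:
                raise FormatError(f"missing [{required}] section")
        codes = [c for row in sections["types"] for c in row]
        n = len(codes)

        def matrix(name, dtype):
            rows = sections[name]
            if len(rows) != n or any(len(r) != n for r in rows):
                raise FormatError(f"[{name}] must be a {n}x{n} matrix")
            return np.array(rows, dtype=dtype)

        return cls(codes, matrix("sigma", float), matrix("epsilon", float),
                   matrix("mode", object))

    # -- convenience --------------------------------------------------
    def copy(self) -> "PairParameterTable":
        return PairParameterTable(list(self.type_codes), self.sigma.copy(),
                                  self.epsilon.copy(), self.modes.copy())

    def submatrices_for(
        self, codes_a: Sequence[str], codes_b: Sequence[str]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(sigma, epsilon, repulsive-mask) blocks for two bead-code lists."""
        ia = np.array([self.index_of(c) for c in codes_a])
        ib = np.array([self.index_of(c) for c in codes_b])
        return (self.sigma[np.ix_(ia, ib)], self.epsilon[np.ix_(ia, ib)],
                self.repulsive_mask[np.ix_(ia, ib)])


def make_nonspecific(table: PairParameterTable) -> PairParameterTable:
    """Equalize every epsilon to the arithmetic mean; sigma and modes untouched.

    This isolates shape complementarity: interaction ranges stay pairwise
    specific while all strengths become identical, so bead chemical identity
    can no longer favour one contact over another of equal geometry.
    """
    out = table.copy()
    out.epsilon = np.full_like(out.epsilon, float(np.mean(table.epsilon)))
    return out


# ---------------------------------------------------------------------------
# energy model over whole molecules
# ---------------------------------------------------------------------------

@dataclass
class PairEnergyModel:
    """A parameter table plus a pairwise distance cutoff (Angstrom)."""

    table: PairParameterTable
    cutoff: float = 8.0

    def __post_init__(self) -> None:
        self.cutoff = float(self.cutoff)
        if self.cutoff <= float(np.max(self.table.sigma)):
            raise ValueError("cutoff must exceed the largest sigma")

    def with_cutoff(self, cutoff: float) -> "PairEnergyModel":
        return PairEnergyModel(self.table, cutoff)


def pairwise_energy_matrix(
    dist: np.ndarray, sigma: np.ndarray, epsilon: np.ndarray,
    repulsive: np.ndarray, cutoff: float,
) -> np.ndarray:
    """Per-pair energies for a distance matrix; zero beyond the cutoff."""
    with np.errstate(divide="ignore", over="ignore"):
        s2 = (sigma / dist) ** 2
        s6 = s2 * s2 * s2
        u = epsilon * (s6 * s2 - s6)
        shift = 2.0 * WELL_DEPTH_FACTOR * epsilon
        u_rep = np.where(dist <= sigma * R_M_FACTOR, u + shift, -u)
        out = np.where(repulsive, u_rep, u)
    return np.where(dist <= cutoff, out, 0.0)


def energy_and_bead_gradient(
    rec_pos: np.ndarray, lig_pos: np.ndarray, sigma: np.ndarray,
    epsilon: np.ndarray, repulsive: np.ndarray, cutoff: float,
) -> tuple[float, np.ndarray]:
    """Total inter-molecular energy and dE/d(ligand bead position).

    ``sigma``/``epsilon``/``repulsive`` are (n_rec, n_lig) per-pair blocks.
    Returns the summed energy and an (n_lig, 3) gradient array.
    """
    diff = lig_pos[None, :, :] - rec_pos[:, None, :]          # (R, L, 3)
    dist = np.sqrt(np.einsum("rlk,rlk->rl", diff, diff))
    dist = np.maximum(dist, 1e-12)
    within = dist <= cutoff
    energy = float(
        pairwise_energy_matrix(dist, sigma, epsilon, repulsive, cutoff).sum()
    )
    with np.errstate(divide="ignore", over="ignore"):
        s2 = (sigma / dist) ** 2
        s6 = s2 * s2 * s2
        dudr = epsilon * (-8.0 * s6 * s2 + 6.0 * s6) / dist
        # repulsive branch: +dU_attr/dr inside r_m, -dU_attr/dr at and beyond
        dudr = np.where(repulsive & (dist >= sigma * R_M_FACTOR), -dudr, dudr)
    dudr = np.where(within, dudr, 0.0)
    grad = np.einsum("rl,rlk->lk", dudr / dist, diff)
    return energy, grad


def interaction_energy(
    receptor, ligand, transform: RigidTransform, model: PairEnergyModel
) -> float:
    """Sum of pair energies over all receptor-ligand bead pairs within cutoff.

    Both partners are rigid: intra-molecular pairs contribute nothing.  The
    transform positions the ligand relative to the fixed receptor.
    """
    sigma, epsilon, repulsive = model.table.submatrices_for(
        receptor.type_codes, ligand.type_codes
    )
    lig_world = transform.apply(ligand.positions)
    energy, _ = energy_and_bead_gradient(
        receptor.positions, lig_world, sigma, epsilon, repulsive, model.cutoff
    )
    return energy
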
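"""Compiled inner loops for pair-energy evaluation.

The docking search evaluates the pair potential millions of times on small
bead sets, where numpy's per-call overhead dominates.  These numba kernels
compute the same quantities as the array code in :mod:`cgdock.forcefield`
(which remains the reference implementation and the fallback when numba is
unavailable).
"""

from __future__ import annotations



try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dep in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


_RM2 = 4.0 / 3.0                 # (r_m / sigma)^2
_DEPTH = 27.0 / 256.0


@njit(cache=True, fastmath=False)
def pair_sum_energy(rec, lig, sigma, epsilon, repulsive, cutoff):
    """Total energy over all receptor-ligand pairs within the cutoff."""
    n_r, n_l = rec.shape[0], lig.shape[0]
    c2 = cutoff * cutoff
    total = 0.0
    for i in range(n_r):
        rx, ry, rz = rec[i, 0], rec[i, 1], rec[i, 2]
        for j in range(n_l):
            dx = lig[j, 0] - rx
            dy = lig[j, 1] - ry
            dz = lig[j, 2] - rz
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > c2 or d2 <= 0.0:
                continue
            s = sigma[i, j]
            e = epsilon[i, j]
            s2 = s * s / d2
            s6 = s2 * s2 * s2
            u = e * (s6 * s2 - s6)
            if repulsive[i, j]:
                if d2 <= s * s * _RM2:
                    u = u + 2.0 * _DEPTH * e
                else:
                    u = -u
            total += u
    return total


@njit(cache=True, fastmath=False)
def pair_sum_energy_grad(rec, lig, sigma, epsilon, repulsive, cutoff, grad):
    """Energy plus dE/d(ligand bead position) accumulated into ``grad``."""
    n_r, n_l = rec.shape[0], lig.shape[0]
    c2 = cutoff * cutoff
    total = 0.0
    for j in range(n_l):
        grad[j, 0] = 0.0
        grad[j, 1] = 0.0
        grad[j, 2] = 0.0
    for i in range(n_r):
        rx, ry, rz = rec[i, 0], rec[i, 1], rec[i, 2]
        for j in range(n_l):
            dx = lig[j, 0] - rx
            dy = lig[j, 1] - ry
            dz = lig[j, 2] - rz
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > c2 or d2 <= 0.0:
                continue
            s = sigma[i, j]
            e = epsilon[i, j]
            s2 = s * s / d2
            s6 = s2 * s2 * s2
            u = e * (s6 * s2 - s6)
            # dU/dr / r  (attractive branch)
            dudr_r = e * (-8.0 * s6 * s2 + 6.0 * s6) / d2
            if repulsive[i, j]:
                if d2 <= s * s * _RM2:
                    u = u + 2.0 * _DEPTH * e
                    if d2 == s * s * _RM2:
                        dudr_r = -dudr_r  # kink: outer-branch derivative
                else:
                    u = -u
                    dudr_r = -dudr_r
            total += u
            grad[j, 0] += dudr_r * dx
            grad[j, 1] += dudr_r * dy
            grad[j, 2] += dudr_r * dz
    return total
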
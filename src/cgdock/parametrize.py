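"""Two-stage greedy Monte-Carlo optimization of the pair parameters.

Stage 1 tunes the range parameters (sigma): trial multiplicative
perturbations of one entry at a time are accepted when they lower an RMSD
score measuring how far native complexes drift during rigid energy
minimization.  The per-case penalty is hinged at 1 Angstrom — drift below
1 A is treated as equally good — so the score is
``sum(max(RMSD_case, 1.0))`` and the flat region does not attract spurious
acceptances.

Stage 2 tunes the strength parameters (epsilon) against decoy ranking: the
minimized native of each training case is scored against its cached decoy
set, and a trial is accepted when it improves, lexicographically, (number
of cases with the native at rank 1, sum of 1/rank over the remaining
cases).  After every round, hit-curve AUCs are evaluated on the training
and a held-out test set by rescoring; the returned table is the snapshot
with the highest test AUC, which is what guards against overfitting when
the training objective keeps improving.

Acceptance is greedy (no uphill moves); an optional temperature enables
Metropolis acceptance but defaults to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np


from .docking import (DockingPose, SearchSettings, batch_interaction_energies,
                      minimize_pose)
from .evaluate import ReferenceComplex, hit_fraction_curve
from .forcefield import PairEnergyModel, PairParameterTable

__all__ = [
    "TrainingCase", "OptimizationState", "SigmaSettings", "EpsilonSettings",
    "rmsd_score", "optimize_sigma", "ranking_score", "optimize_epsilon",
]

logger = logging.getLogger(__name__)


@dataclass
class TrainingCase:
    """A reference complex with its decoy set and split assignment."""

    reference: ReferenceComplex
    decoys: list[DockingPose] = field(default_factory=list)
    split: str = "train"
    case_id: str = ""
    rmsd_bead_indices: np.ndarray | None = None  # ligand beads for stage 1

    def ligand_rmsd_subset(self) -> np.ndarray:
        if self.rmsd_bead_indices is None:
            return np.arange(self.reference.ligand.n_beads)
        return np.asarray(self.rmsd_bead_indices, dtype=int)


@dataclass
class SigmaSettings:
    step: float = 0.05            # multiplicative trial size
    min_step: float = 0.005      # annealing floor for the trial size
    max_rounds: int = 50
    final_cutoff: float = 8.0
    minimize_iterations: int = 120
    sigma_bounds: tuple[float, float] = (2.0, 8.0)


@dataclass
class EpsilonSettings:
    step: float = 0.10
    cycles_per_round: int = 10
    max_rounds: int = 10
    final_cutoff: float = 8.0
    minimize_iterations: int = 120
    auc_n_max: int = 100
    epsilon_bounds: tuple[float, float] = (1e-3, 50.0)
    temperature: float = 0.0


@dataclass
class OptimizationState:
    """Round-by-round history plus the best-test-AUC snapshot."""

    table: PairParameterTable
    objective_history: list = field(default_factory=list)
    train_auc_history: list[float] = field(default_factory=list)
    test_auc_history: list[float] = field(default_factory=list)
    best_round: int = 0
    best_table: PairParameterTable | None = None

    def record_round(self, table: PairParameterTable, objective,
                     train_auc: float, test_auc: float) -> None:
        self.objective_history.append(objective)
        self.train_auc_history.append(train_auc)
        self.test_auc_history.append(test_auc)
        if self.best_table is None or test_auc > max(
            self.test_auc_history[:-1], default=-np.inf
        ):
            self.best_round = len(self.test_auc_history) - 1
            self.best_table = table.copy()


# ---------------------------------------------------------------------------
# shared machinery
# ---------------------------------------------------------------------------

def _native_minimization_settings(cutoff: float, iters: int) -> SearchSettings:
    # native complexes start at (or near) their minimum: a single stage at
    # the final cutoff is enough and keeps training desk-scale
    return SearchSettings(cutoff_schedule=(cutoff,), max_iterations=iters,
                          tolerance=1e-8)


def _minimize_native(case: TrainingCase, model: PairEnergyModel,
                     settings: SearchSettings) -> DockingPose:
    return minimize_pose(case.reference.receptor, case.reference.ligand,
                         case.reference.transform, model, settings)


def cross_pairs(cases: list[TrainingCase],
                table: PairParameterTable) -> list[tuple[int, int]]:
    """Adjustable (i, j) entries: type pairs that occur across an interface."""
    pairs: set[tuple[int, int]] = set()
    for case in cases:
        rec = {table.index_of(c) for c in case.reference.receptor.type_codes}
        lig = {table.index_of(c) for c in case.reference.ligand.type_codes}
        for i in rec:
            for j in lig:
                pairs.add((min(i, j), max(i, j)))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# stage 1: sigma vs. native-drift RMSD
# ---------------------------------------------------------------------------

def rmsd_score(cases: list[TrainingCase], table: PairParameterTable,
               settings: SigmaSettings | None = None) -> float:
    """Sum over cases of ``max(native-drift RMSD, 1.0)`` (lower is better).

    Each native complex is rigid-body minimized under ``table``; the RMSD is
    taken over the case's ligand bead subset between minimized and native
    coordinates (receptor frame fixed, no superposition).  Cases whose
    minimization fails are skipped with a warning.
    """
    settings = settings or SigmaSettings()
    model = PairEnergyModel(table, settings.final_cutoff)
    mset = _native_minimization_settings(settings.final_cutoff,
                                         settings.minimize_iterations)
    total = 0.0
    for case in cases:
        try:
            pose = _minimize_native(case, model, mset)
        except FloatingPointError:
            logger.warning("case %s: native minimization failed; skipped",
                           case.case_id)
            continue
        subset = case.ligand_rmsd_subset()
        native = case.reference.ligand_native_coords()[subset]
        moved = pose.transform.apply(case.reference.ligand.positions)[subset]
        rmsd = float(np.sqrt(np.mean(np.sum((moved - native) ** 2, axis=1))))
        total += max(rmsd, 1.0)
    return total


def optimize_sigma(
    cases: list[TrainingCase], initial_table: PairParameterTable,
    settings: SigmaSettings | None = None, seed: int = 0,
) -> tuple[PairParameterTable, list[float]]:
    """Greedy per-entry sigma optimization against :func:`rmsd_score`.

    Every round visits each adjustable sigma entry in seeded order and tries
    an increase and a decrease by the multiplicative step, accepting the
    first strict score improvement.  A round with no acceptance halves the
    trial step (the native-drift score is stepped, so a finer probe often
    still finds downhill moves); optimization stops once even the smallest
    step yields no change, mirroring "repeat until nothing changes".
    Returns the optimized table and the accepted-score history.
    """
    settings = settings or SigmaSettings()
    rng = np.random.default_rng(int(seed))
    table = initial_table.copy()
    entries = cross_pairs(cases, table)
    score = rmsd_score(cases, table, settings)
    history = [score]
    lo, hi = settings.sigma_bounds
    step = settings.step
    for _round in range(settings.max_rounds):
        accepted_any = False
        order = rng.permutation(len(entries))
        for k in order:
            i, j = entries[k]
            directions = (1.0 + step, 1.0 - step)
            if rng.random() < 0.5:
                directions = directions[::-1]
            for factor in directions:
                trial = table.copy()
                new = float(np.clip(trial.sigma[i, j] * factor, lo, hi))
                trial.sigma[i, j] = trial.sigma[j, i] = new
                trial_score = rmsd_score(cases, trial, settings)
                if trial_score < score:
                    table, score = trial, trial_score
                    history.append(score)
                    accepted_any = True
                    break
        if not accepted_any:
            step /= 2.0
            if step < settings.min_step:
                break
    return table, history


# ---------------------------------------------------------------------------
# stage 2: epsilon vs. decoy ranking
# ---------------------------------------------------------------------------

def _native_ranks(cases: list[TrainingCase], table: PairParameterTable,
                  cutoff: float, iters: int) -> list[int]:
    """Rank of each case's minimized native among its rescored decoys."""
    model = PairEnergyModel(table, cutoff)
    mset = _native_minimization_settings(cutoff, iters)
    ranks = []
    for case in cases:
        if not case.decoys:
            raise ValueError(f"case {case.case_id!r} has no decoys")
        pose = _minimize_native(case, model, mset)
        decoy_e = batch_interaction_energies(
            case.reference.receptor, case.reference.ligand,
            [d.transform for d in case.decoys], model,
        )
        ranks.append(1 + int(np.count_nonzero(decoy_e < pose.energy)))
    return ranks


def ranking_score(cases: list[TrainingCase], table: PairParameterTable,
                  settings: EpsilonSettings | None = None) -> tuple[int, float]:
    """(number of rank-1 natives, sum of 1/rank over the rest).

    The primary term drives towards natives scoring best among their
    decoys; the secondary term still rewards pushing a badly ranked native
    up the list.  Compare lexicographically, primary first.
    """
    settings = settings or EpsilonSettings()
    ranks = _native_ranks(cases, table, settings.final_cutoff,
                          settings.minimize_iterations)
    primary = sum(1 for r in ranks if r == 1)
    secondary = float(sum(1.0 / r for r in ranks if r > 1))
    return primary, secondary


def _auc(cases: list[TrainingCase], table: PairParameterTable,
         settings: EpsilonSettings) -> float:
    ranks = _native_ranks(cases, table, settings.final_cutoff,
                          settings.minimize_iterations)
    _, auc = hit_fraction_curve([[r] for r in ranks], settings.auc_n_max)
    return auc


def optimize_epsilon(
    cases_train: list[TrainingCase], cases_test: list[TrainingCase],
    table: PairParameterTable, settings: EpsilonSettings | None = None,
    seed: int = 0,
) -> tuple[PairParameterTable, OptimizationState]:
    """Greedy epsilon optimization with AUC-based early stopping.

    Each round runs ``cycles_per_round`` sweeps of seeded single-entry trial
    perturbations accepted on strict lexicographic improvement of
    :func:`ranking_score` on the training cases.  After every round the
    train and test hit-curve AUCs are evaluated by rescoring; the returned
    table is the snapshot with the maximum test AUC over all evaluated
    rounds (including round 0, the input table), so with ``max_rounds=0``
    the input table comes back unchanged.
    """
    settings = settings or EpsilonSettings()
    rng = np.random.default_rng(int(seed))
    table = table.copy()
    entries = cross_pairs(cases_train, table)
    score = ranking_score(cases_train, table, settings)
    state = OptimizationState(table)
    state.record_round(table, score, _auc(cases_train, table, settings),
                       _auc(cases_test, table, settings))
    lo, hi = settings.epsilon_bounds
    for _round in range(settings.max_rounds):
        for _cycle in range(settings.cycles_per_round):
            order = rng.permutation(len(entries))
            for k in order:
                i, j = entries[k]
                factor = (1.0 + settings.step if rng.random() < 0.5
                          else 1.0 - settings.step)
                trial = table.copy()
                new = float(np.clip(trial.epsilon[i, j] * factor, lo, hi))
                trial.epsilon[i, j] = trial.epsilon[j, i] = new
                trial_score = ranking_score(cases_train, trial, settings)
                accept = trial_score > score
                if not accept and settings.temperature > 0.0:
                    # Metropolis on the secondary term only
                    delta = trial_score[1] - score[1]
                    accept = (trial_score[0] == score[0] and
                              rng.random() < np.exp(delta / settings.temperature))
                if accept:
                    table, score = trial, trial_score
        state.record_round(table, score,
                           _auc(cases_train, table, settings),
                           _auc(cases_test, table, settings))
    assert state.best_table is not None
    state.table = table
    return state.best_table, state
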
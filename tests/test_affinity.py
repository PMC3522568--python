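"""Sequence similarity, record filtering, mutation and rescoring."""

import numpy as np
import pytest

from cgdock.affinity import (AffinityRecord, BaseTemplates, FilterConditions,
                             best_overlap, complement_sequence,
                             contact_estimate, correlate,
                             default_base_templates, filter_records,
                             mutate_dna, randomize_sequence,
                             read_affinity_table, rescore_with_sequence,
                             strand_overlap_identity, tanimoto,
                             write_affinity_table)
from cgdock.cg_model import CGMolecule, extract_sequence
from cgdock.docking import DockingPose, batch_interaction_energies

from cgdock.forcefield import (PairEnergyModel, PairParameterTable,
                               make_nonspecific)
from cgdock.geometry import RigidTransform


# ---------------------------------------------------------------------------
# sequence similarity
# ---------------------------------------------------------------------------

class TestTanimoto:
    def test_identical_sequences(self):
        seq = "ACGTACGTACGTACGTACGT"
        assert tanimoto(seq, seq) == 1.0

    def test_disjoint_alphabets(self):
        assert tanimoto("A" * 10, "C" * 10) == 0.0

    def test_direct_formula_case(self):
        # N_id = 5, N_1 = N_2 = 10 -> 5 / 15
        assert tanimoto("AAAAACCCCC", "AAAAATTTTT") == pytest.approx(1 / 3)

    def test_short_perfect_fragment_scores_low(self):
        # fragment embedded in a long construct: N_id = 8,
        # t_c = 8 / (40 + 8 - 8) = 0.2
        frag = "ACGTACGT"
        long = "T" * 16 + frag + "T" * 16
        assert tanimoto(long, frag) == pytest.approx(8 / 40)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), rng.integers(4, 15)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(4, 15)))
            assert tanimoto(a, b) == pytest.approx(tanimoto(b, a))

    def test_unity_only_for_identical(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            a = "".join(rng.choice(list("ACGT"), 12))
            b = "".join(rng.choice(list("ACGT"), 12))
            if a == b:
                continue
            assert tanimoto(a, b) < 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tanimoto("", "ACGT")

    def test_best_overlap_finds_shifted_match(self):
        nid, overlap, offset = best_overlap("AAACGTACGT", "CGTACGTTTT")
        assert nid == 7
        assert offset == 3


class TestStrandIdentity:
    def test_perfect_overlap(self):
        assert strand_overlap_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_half_mutated(self):
        a = "ACGTACGTACGTACGT"
        b = "TCGATCGATCGATCGA"
        assert strand_overlap_identity(a, b) < 0.8


# ---------------------------------------------------------------------------
# record filtering
# ---------------------------------------------------------------------------

def _record(**kw):
    seq = kw.pop("seq", "ACGTACGTACGTACGT")
    comp = complement_sequence(seq)
    defaults = dict(complex_id="C1", delta_g=-10.0, temperature=22.0, ph=7.0,
                    ionic_mm=100.0, experimental_sequences=(seq, comp),
                    structure_sequences=(seq, comp))
    defaults.update(kw)
    return AffinityRecord(**defaults)


class TestFilterRecords:
    def test_temperature_rejection_reason(self):
        kept, reasons = filter_records([_record(temperature=30.0)])
        assert kept == []
        assert list(reasons.values()) == ["temperature"]

    @pytest.mark.parametrize("field,value,reason", [
        ("ph", 5.0, "ph"),
        ("ph", 9.0, "ph"),
        ("ionic_mm", 200.0, "ionic"),
        ("temperature", 19.9, "temperature"),
    ])
    def test_condition_windows(self, field, value, reason):
        kept, reasons = filter_records([_record(**{field: value})])
        assert kept == []
        assert list(reasons.values()) == [reason]

    def test_boundary_values_admitted(self):
        kept, _ = filter_records([
            _record(temperature=20.0), _record(temperature=25.0),
            _record(ph=6.0), _record(ph=8.5), _record(ionic_mm=199.9),
        ])
        assert len(kept) == 1  # same complex_id: aggregated after passing

    def test_duplicates_averaged(self):
        kept, _ = filter_records([
            _record(delta_g=-10.0), _record(delta_g=-11.0)])
        assert len(kept) == 1
        assert kept[0].delta_g == pytest.approx(-10.5)

    def test_custom_conditions(self):
        loose = FilterConditions(temperature_range=(0.0, 100.0))
        kept, _ = filter_records([_record(temperature=30.0)], loose)
        assert len(kept) == 1


# ---------------------------------------------------------------------------
# contact estimate / correlation
# ---------------------------------------------------------------------------

def _mol(points, codes=None, role=None, **kw):
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    codes = codes or ["X"] * n
    return CGMolecule(pts, codes, kw.get("res_idx", np.arange(n)),
                      kw.get("names", ["R"] * n), kw.get("chains", ["A"] * n),
                      role)


class TestContactEstimate:
    def test_single_pair_inside(self):
        rec = _mol([(0, 0, 0)], role="receptor")
        lig = _mol([(7, 0, 0)], role="ligand")
        assert contact_estimate(rec, lig, RigidTransform.identity()) == 1

    def test_all_beyond_cutoff(self):
        rec = _mol([(0, 0, 0)], role="receptor")
        lig = _mol([(9, 0, 0)], role="ligand")
        assert contact_estimate(rec, lig, RigidTransform.identity()) == 0

    def test_matches_double_loop(self):
        rng = np.random.default_rng(2)
        rec = _mol(rng.uniform(-6, 6, (8, 3)), role="receptor")
        lig = _mol(rng.uniform(-6, 6, (6, 3)), role="ligand")
        count = contact_estimate(rec, lig, RigidTransform.identity(), 8.0)
        brute = sum(
            1 for i in range(8) for j in range(6)
            if np.linalg.norm(lig.positions[j] - rec.positions[i]) <= 8.0)
        assert count == brute

    def test_monotone_under_withdrawal(self):
        rng = np.random.default_rng(3)
        rec = _mol(rng.uniform(-6, 6, (10, 3)), role="receptor")
        lig = _mol(rng.uniform(-3, 3, (5, 3)) + [0, 0, 8], role="ligand")
        counts = [contact_estimate(rec, lig,
                                   RigidTransform(translation=[0, 0, dz]))
                  for dz in np.linspace(0, 20, 11)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestCorrelate:
    def test_perfect_positive_and_negative(self):
        x = [-12.0, -10.0, -8.0, -6.0]
        assert correlate(x, x) == pytest.approx(1.0)
        assert correlate(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_five_point_textbook_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 5.0, 9.0, 7.0])
        xc, yc = x - x.mean(), y - y.mean()
        expect = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert correlate(x, y) == pytest.approx(expect, rel=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r = correlate(x, y)
        assert correlate(3.0 * x + 7.0, y) == pytest.approx(r)
        assert correlate(x, 0.5 * y - 2.0) == pytest.approx(r)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# duplex construction helper (built from the default templates, so base
# beads sit exactly at template positions in each residue's backbone frame)
# ---------------------------------------------------------------------------

def build_duplex(seq, templates=None, rise=3.4, width=16.0):
    templates = templates or default_base_templates()
    comp = complement_sequence(seq)
    positions, codes, res_idx, names, chains = [], [], [], [], []

    def add_strand(strand_seq, chain, x0, direction):
        for k, base in enumerate(strand_seq):
            origin = np.array([x0, direction * 2.0, rise * k])
            e1 = np.array([0.0, 0.0, 1.0])
            e2 = np.array([-direction, 0.0, 0.0])
            frame = np.stack([e1, e2, np.cross(e1, e2)], axis=1)
            # GP placed so the frame mutate_dna reconstructs from the
            # backbone equals the frame used to lay down the base beads
            backbone = {
                "GS2": origin,
                "GS1": origin + frame @ np.array([2.0, 0.0, 0.0]),
                "GP": origin + frame @ np.array([0.5, 2.0, 0.0]),
            }
            for code, pos in backbone.items():
                positions.append(pos)
                codes.append(code)
                res_idx.append(k)
                names.append(f"D{base}")
                chains.append(chain)
            for code, off in templates.beads[base]:
                positions.append(origin + frame @ off)
                codes.append(code)
                res_idx.append(k)
                names.append(f"D{base}")
                chains.append(chain)

    add_strand(seq, "A", 0.0, +1)
    add_strand(comp, "B", width, -1)
    return CGMolecule(np.array(positions), codes, np.array(res_idx), names,
                      chains, role="receptor")


class TestMutateDna:
    def test_mutation_changes_only_target_pair(self):
        mol = build_duplex("ACGT")
        mutated = mutate_dna(mol, 1, "GC")   # C:G -> G:C at position 1
        seqs = extract_sequence(mutated)
        assert seqs["A"] == "AGGT"
        assert seqs["B"] == complement_sequence("AGGT")

    def test_backbone_coordinates_bitwise_unchanged(self):
        mol = build_duplex("ACGT")
        mutated = mutate_dna(mol, 0, "TA")
        backbone = ("GP", "GS1", "GS2")
        orig = [p for p, c in zip(mol.positions, mol.type_codes)
                if c in backbone]
        new = [p for p, c in zip(mutated.positions, mutated.type_codes)
               if c in backbone]
        assert np.array_equal(np.array(orig), np.array(new))

    def test_mutate_back_restores_type_codes(self):
        mol = build_duplex("ACGT")
        there = mutate_dna(mol, 2, "CG")     # G:C -> C:G
        back = mutate_dna(there, 2, "GC")
        assert back.type_codes == mol.type_codes

    def test_purine_swap_preserves_bead_count_thymine_excepted(self):
        mol = build_duplex("AG")
        swapped = mutate_dna(mol, 1, "AT")   # G:C -> A:T
        # A and G have equal base bead counts; C -> T adds the methyl bead
        assert swapped.n_beads == mol.n_beads + 1

    def test_only_target_base_beads_move(self):
        mol = build_duplex("ACGT")
        mutated = mutate_dna(mol, 1, "GC")
        keep = [(c, tuple(np.round(p, 9)))
                for p, c, r, ch in zip(mol.positions, mol.type_codes,
                                       mol.residue_index, mol.chain_ids)
                if not ((ch == "A" and r == 1) or (ch == "B" and r == 2))]
        kept = [(c, tuple(np.round(p, 9)))
                for p, c, r, ch in zip(mutated.positions, mutated.type_codes,
                                       mutated.residue_index,
                                       mutated.chain_ids)
                if not ((ch == "A" and r == 1) or (ch == "B" and r == 2))]
        assert keep == kept

    def test_bad_pair_and_position(self):
        mol = build_duplex("ACGT")
        with pytest.raises(ValueError):
            mutate_dna(mol, 0, "AG")
        with pytest.raises(ValueError):
            mutate_dna(mol, 9, "AT")


class TestRandomizeSequence:
    def test_target_identity_realized(self):
        seq = "ACGTACGTACGTACGTACGT"
        out = randomize_sequence(seq, 0.5, seed=3)
        same = sum(a == b for a, b in zip(seq, out))
        assert abs(same - 10) <= 1

    def test_class_mode_preserves_purine_pyrimidine(self):
        seq = "ACGTACGTACGTACGTACGT"
        out = randomize_sequence(seq, 0.25, seed=4, mode="class")
        for a, b in zip(seq, out):
            assert (a in "AG") == (b in "AG")

    def test_identity_one_is_unchanged(self):
        seq = "ACGTAC"
        assert randomize_sequence(seq, 1.0, seed=0) == seq

    def test_deterministic(self):
        seq = "ACGTACGTACGT"
        assert randomize_sequence(seq, 0.4, seed=9) == \
            randomize_sequence(seq, 0.4, seed=9)


# ---------------------------------------------------------------------------
# sequence rescoring
# ---------------------------------------------------------------------------

def class_uniform_table():
    """Base-bead sigmas equal within the whole base alphabet, distinct eps.

    With class-shared template geometry this makes the non-specific variant
    exactly sequence-blind under class-preserving substitutions.
    """
    codes = ["GP", "GS1", "GS2", "GA1", "GA2", "GA3", "GG1", "GG2", "GG3",
             "GC1", "GC2", "GT1", "GT2", "GT3", "LP"]
    n = len(codes)
    rng = np.random.default_rng(8)
    sigma = np.full((n, n), 4.0)
    epsilon = np.round(rng.uniform(0.2, 1.5, (n, n)), 3)
    epsilon = (epsilon + epsilon.T) / 2
    modes = np.full((n, n), "a", dtype=object)
    return PairParameterTable(codes, sigma, epsilon, modes)


def equal_count_templates():
    """Synthetic template set with two beads per base (no thymine methyl).

    Within each class the offsets are shared, so class-preserving swaps move
    nothing and change no bead counts — the geometry half of the
    sequence-blindness argument for the non-specific table.
    """
    pur = [(1.2, 2.2, 0.0), (1.8, 4.3, 0.3)]
    pyr = [(1.2, 2.2, 0.0), (1.2, 4.4, 0.0)]
    return BaseTemplates({
        "A": [("GA1", pur[0]), ("GA2", pur[1])],
        "G": [("GG1", pur[0]), ("GG2", pur[1])],
        "C": [("GC1", pyr[0]), ("GC2", pyr[1])],
        "T": [("GT1", pyr[0]), ("GT2", pyr[1])],
    })


@pytest.fixture()
def rescoring_setup():
    table = class_uniform_table()
    model = PairEnergyModel(table, cutoff=8.0)
    dna = build_duplex("ACGTACGTAC", templates=equal_count_templates())
    protein = _mol(np.array([[8.0, 0.0, z] for z in (5.0, 12.0, 20.0)]),
                   codes=["LP"] * 3, role="ligand")
    rng = np.random.default_rng(12)
    poses = []
    for k in range(6):
        t = rng.normal(0, 4, 3)
        poses.append(DockingPose(RigidTransform(translation=t), 0.0,
                                 start_id=k, orientation_id=k))
    energies = batch_interaction_energies(dna, protein,
                                          [p.transform for p in poses], model)
    for p, e in zip(poses, energies):
        p.energy = float(e)
    for rank, p in enumerate(sorted(poses, key=DockingPose.sort_key), 1):
        p.rank = rank
    return table, model, dna, protein, poses, equal_count_templates()


class TestRescoreWithSequence:
    def test_native_sequence_keeps_ranking(self, rescoring_setup):
        table, model, dna, protein, poses, tpl = rescoring_setup
        seq = extract_sequence(dna)["A"]
        rescored, _ = rescore_with_sequence(poses, dna, protein, seq, model,
                                          templates=tpl)
        assert [p.rank for p in rescored] == [p.rank for p in poses]
        for a, b in zip(rescored, poses):
            assert a.energy == pytest.approx(b.energy, rel=1e-10)

    def test_nonspecific_table_is_sequence_blind(self, rescoring_setup):
        table, _, dna, protein, poses, tpl = rescoring_setup
        ns_model = PairEnergyModel(make_nonspecific(table), cutoff=8.0)
        seq = extract_sequence(dna)["A"]
        new_seq = randomize_sequence(seq, 0.5, seed=7, mode="class")
        assert new_seq != seq
        base, _ = rescore_with_sequence(poses, dna, protein, seq, ns_model,
                                      templates=tpl)
        swapped, _ = rescore_with_sequence(poses, dna, protein, new_seq,
                                           ns_model, templates=tpl)
        for a, b in zip(base, swapped):
            assert a.energy == pytest.approx(b.energy, rel=1e-9)
        assert [p.rank for p in base] == [p.rank for p in swapped]

    def test_specific_table_feels_sequence(self, rescoring_setup):
        table, model, dna, protein, poses, tpl = rescoring_setup
        seq = extract_sequence(dna)["A"]
        new_seq = randomize_sequence(seq, 0.5, seed=7, mode="class")
        swapped, _ = rescore_with_sequence(poses, dna, protein, new_seq,
                                           model, templates=tpl)
        assert any(abs(a.energy - b.energy) > 1e-6
                   for a, b in zip(swapped, poses))

    def test_length_mismatch_rejected(self, rescoring_setup):
        _, model, dna, protein, poses, tpl = rescoring_setup
        with pytest.raises(ValueError):
            rescore_with_sequence(poses, dna, protein, "ACGT", model,
                                  templates=tpl)


class TestAffinityTableIO:
    def test_round_trip(self, tmp_path):
        records = [_record(), _record(complex_id="C2", delta_g=-7.25,
                                      seq="TTTTCCCCAAAAGGGG")]
        path = tmp_path / "aff.tsv"
        write_affinity_table(records, path)
        back = read_affinity_table(path)
        assert len(back) == 2
        assert back[0] == records[0]
        assert back[1] == records[1]
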
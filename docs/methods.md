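# Methods

## Coarse-grained representation

All-atom structures (PDB) are reduced to beads placed either on a
designated atom or at the unweighted geometric center of a heavy-atom
group. Hydrogens are ignored throughout. The default DNA scheme assigns
each nucleotide a phosphate bead (`GP`, on P), two sugar beads (`GS1` for
the C5'/C4'/O4' side, `GS2` for the C2'-containing half of the
deoxyribose — its own type, since the missing 2'-OH changes its contact
chemistry), and base beads that carry the base identity in their type
code: three for the purines, two for cytosine, three for thymine, whose
third bead sits on the C7 methyl — the hydrophobic major-groove feature
that distinguishes T. The protein scheme is one backbone bead per residue
(on Cα) plus one side-chain bead at the side-chain centroid (two for Arg,
Lys, Phe, Tyr, Trp; none for Gly). Both schemes are plain data, editable
through a YAML scheme file; correctness is defined against the scheme
file, not against any particular published bead table, which is why the
reduction machinery is scheme-agnostic.

Missing atoms are tolerated: a bead uses the centroid of whichever member
atoms are present and is dropped (with a warning) only when none are —
crystal structures routinely lack atoms and a hard failure would block
unbound docking. Alternate locations resolve to the highest-occupancy
conformer; residues are ordered by (number, insertion code). Coordinates
are Å everywhere.

## Pair potential

The interaction model is the 8-6 pair potential described in the README,
in attractive and soft-core repulsive variants, with pair-specific σ
(range, Å) and ε (strength, force-field units — the scale is arbitrary
and every downstream comparison is scale-free). The repulsive branch is
built from the attractive curve shifted by twice the well-depth magnitude
below r_m and mirrored above it; this is the standard soft-core
construction and the only reading that is continuous and positive.
Parameter tables store symmetric σ/ε/mode matrices in a sectioned text
format; loading validates symmetry, positivity, the location of the
attractive minimum (numerically) and the continuity of the repulsive
branch at r_m. At the repulsive kink the outer-branch derivative is used,
so minimizer behaviour at that measure-zero point is deterministic.

Total inter-molecular energy is the sum over receptor–ligand bead pairs
within a distance cutoff; intra-molecular terms are excluded (rigid
bodies), and the cutoff is sharp (no switching function) to match the
staged-cutoff protocol, whose final 8 Å stage dominates ranking.

The shipped default table for the biological schemes combines per-type
bead sizes into σ and a weak uniform attraction into ε, with
chemistry-flavoured adjustments (phosphate–basic side chain attraction,
phosphate–acidic repulsion, base–hydrophobic attraction strongest for the
thymine methyl bead). It is a documented starting point for the trainer,
not a claim about any previously trained parameter set.

## Docking search

Start points lie on a closed surface offset outward from the receptor by
the ligand bounding radius plus a 5 Å clearance, sampled on a golden-spiral
lattice with the point count chosen so neighbours are ~12 Å apart
(configurable); every point is pushed outward until no receptor bead is
closer than the clearance allows in any ligand orientation. Orientations
come from a deterministic low-discrepancy spiral on the rotation group
(super-Fibonacci sampling), shifted so the identity is included and
conjugated by a seeded random rotation — conjugation preserves all pairwise
rotation angles, so reseeding never degrades uniformity. The default count
is 208 per start point.

Each start is minimized in the six rigid degrees of freedom by BFGS with
Armijo backtracking in a moving local chart: rotation increments act about
the current ligand centroid, which keeps translational and rotational
coordinates comparably scaled, and the chart is re-centred after every
accepted step so gradients are only needed at the chart origin, where they
are exact. Minimization runs in five stages with the pairwise cutoff
stepped 50, 30, 18, 11, 8 Å (the intermediate values are a roughly
geometric interpolation; only the endpoints are fixed by the protocol),
each stage warm-starting from the last; the reported energy is always at
the final cutoff, and a pose that failed to improve on its start is
returned flagged. Default stage budget: 100 iterations, energy tolerance
1e-7. The pair-sum energy/gradient kernel is compiled with numba; the
numpy implementation remains as reference and fallback, and the two are
asserted to agree.

Converged poses are pooled, clustered by greedy leader clustering in
energy order (ligand-bead RMSD between transformed coordinates, no
superposition; default cutoff 3 Å — between the hit thresholds and the
start spacing), and ranked by energy with deterministic tie-breaking on
(start, orientation) indices.

## Evaluation

The native interface is every inter-molecular bead pair within 8 Å in the
reference complex. iRMSD superposes the posed complex onto the reference
by least squares over the interface beads of both partners jointly (own
Kabsch implementation; coarse-grained beads have no CAPRI atom classes, so
the joint-interface fit is the default and the fitting subset is
configurable) and takes the RMSD over those beads. f_NC is the fraction of
native contact pairs still within the contact cutoff. Quality tiers:
high (iRMSD ≤ 1 Å and f_NC ≥ 0.5), medium (≤ 2 Å and ≥ 0.3), acceptable
(iRMSD ≤ 4 Å or f_NC ≥ 0.3), else incorrect; "hit" = high or medium.
These are the CAPRI-consistent readings of the published thresholds (the
source text garbles two clauses); all thresholds are configurable.
Hit-fraction curves use the best-hit rank per complex (a step function)
averaged over complexes; the AUC is the mean of that curve over ranks
1..100, so 1.0 ⇔ every complex has a rank-1 hit and 0.0 ⇔ no hits in the
top 100.

## Parameter training

Stage 1 (σ): greedy single-entry multiplicative trial moves (±5%),
accepted on strict decrease of the drift score Σ max(RMSD_case, 1 Å),
where RMSD is measured between each native complex and its rigid-body
re-minimization under the trial table (single stage at 8 Å — natives start
at their minimum, so the staged schedule would be wasted work). The hinge
at 1 Å deliberately makes all tables with sub-1 Å drift equivalent, so σ
is identified only up to that equivalence class — recovery claims are
therefore stated in score terms, not σ-value terms. A round with no
acceptance halves the step (the drift landscape is stepped; a finer probe
often still finds downhill moves) down to a floor, then stops — "repeat
until no further change". Acceptance is strict-decrease: accepting
equal-score moves would never terminate that loop.

Stage 2 (ε): trial moves (±10%) accepted on strict lexicographic
improvement of (number of cases whose minimized native ranks 1 among its
cached, rescored decoys; Σ 1/rank over the rest). Decoys are rescored at
fixed geometry each trial — only the native is re-minimized — which keeps
a round affordable. After each round (10 sweeps by default) train and test
hit-curve AUCs are evaluated; the returned table is the snapshot with the
highest test AUC over all evaluated rounds including round 0, so zero
rounds returns the input unchanged and the early stop guards against the
training objective improving while held-out performance drops. Acceptance
is greedy; a Metropolis temperature on the secondary term exists but
defaults to 0.

## Affinity utilities

Tanimoto coefficient t_c = N_id/(N₁+N₂−N_id) with N_id from the best
ungapped overlap alignment, so a perfect short-fragment match against a
long construct still scores low. Record filters (in order): temperature
20–25 °C, pH 6.0–8.5, ionic concentration < 200 mM, per-strand overlap
identity ≥ 0.8 (computed on the best ungapped overlap spanning at least
half the shorter strand, to exclude spurious few-base matches), per-strand
t_c ≥ 0.5; duplicate measurements for one structure are averaged.
Gapped alignment is deliberately not used: the comparisons are short
duplexes and no indel convention is specified anywhere.

DNA mutants are built isosterically: backbone and sugar beads are
untouched bitwise, and base beads are replaced by idealized template
geometries expressed in an orthonormal frame built from the residue's
sugar and phosphate beads, with offsets shared within the purine and
pyrimidine classes ("no further refinement" means template placement, not
relaxation). Thymine's methyl bead makes T↔C swaps count-inequivalent;
energy comparisons across such mutations are flagged as such, and the
sequence randomizer offers both uniform and class-preserving modes. The
substitution count is ⌈(1−f)·L⌉ with replacements always different from
the original, so realized identity equals the target up to rounding — in
particular f = 0.25 corresponds to fully random sequences. Rescoring under
a new sequence mutates each differing position, re-evaluates all pose
energies at the final cutoff and re-ranks.

## Synthetic test systems

Real training corpora require bulk downloads, so every stage is exercised
on abstract planted-truth systems instead. A universe of 5 DNA-like
receptor types and 5 protein-like ligand types carries a planted table in
which matched cross pairs are strongly attractive
(ε 2.4–3.0) and all mismatched cross pairs mildly repulsive (ε 0.3–0.6).
The repulsion is what makes the planted register sharply selective: the
8-6 tail is long relative to the 4 Å bead lattice, and with neutral or
weakly attractive mismatches a misregistered pose can accumulate enough
medium-distance matched contacts to out-score the planted pose. Matched
attraction still dominates at long range, preserving the search funnel.

Toy complexes place the receptor as a jittered two-layer 4 Å lattice slab
and build the ligand over the exposed top surface: each ligand bead sits
at r_m above a surface bead whose type it matches, with the patch typed in
a Latin-square-like lattice pattern so no small rigid shift realigns
matched pairs. The hand-built contact geometry is relaxed once and baked
into the ligand coordinates, making the native transform the identity at a
true minimum. Generation then verifies the plant: re-minimization drift
< 0.1 Å, native deeper than 200 random contact poses, and a coarse
systematic search finding no deeper basin away from the native; failing
seeds regenerate deterministically.

Decoys are random contact placements briefly relaxed at the final cutoff
and kept only if their iRMSD from the native exceeds 4 Å (never hits, by
construction). Synthetic affinity records plant exactly one violation per
filter rule plus a duplicated measurement, and verify at generation that
each planted violation actually trips its rule, so the survivor set is
ground truth for any seed.

What these fixtures do not emulate: real B-DNA geometry, sequence-threaded
structures, conformational change on binding, or the contact statistics of
real interfaces. Tests passing on them show the machinery — reduction,
scoring, search, evaluation, training — is correct and self-consistent;
they say nothing about prediction accuracy on real complexes, which
depends on a trained table and a structural benchmark outside this
package's scope.

## Problem sizes and numerical choices

Default demonstrations and tests run the full search grid (12 Å spacing,
208 orientations) on a 50+15-bead complex (~9,000–10,000 minimizations,
a few minutes on one CPU) and train on 20+5 synthetic cases with 50
decoys each; these sizes exercise every code path while staying
desk-scale. Degenerate inputs are handled explicitly: a single-bead
receptor degrades the start surface to a sphere; an empty native
interface warns (metrics on it raise); zero-length sequences, non-finite
ΔG, non-duplex molecules and unknown bead types raise typed errors.
Energy at exactly r = cutoff counts as inside; ranking ties break by
(start, orientation) index; the native wins energy ties against decoys.

## Known limitations

Rigid bodies only — no side-chain copies, normal modes or any flexible
refinement; no electrostatics or solvation beyond what ε absorbs; no RNA,
modified bases or cofactors; the sharp cutoff makes the energy
discontinuous at the cutoff radius; trained parameter values shipped here
are synthetic-universe or default tables, not a claim about any published
force field's numbers.
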
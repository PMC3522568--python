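# cgdock

Coarse-grained rigid-body docking of proteins onto double-stranded DNA.

Protein–DNA complexes are central to gene regulation, replication and
repair, yet they are under-represented among solved structures. Docking —
predicting the complex from the structures of the free partners — is a
practical complement to crystallography, but all-atom searches are
expensive. `cgdock` takes the coarse-grained route: both partners are
reduced to beads standing for chemical groups, their interaction is scored
with a knowledge-based pair potential, and the complex is predicted by a
systematic multi-start rigid-body energy minimization with no prior
knowledge of the binding site.

## The model

Every bead pair (i, j) interacts through a distance-dependent 8-6
potential with pair-specific range σᵢⱼ (Å) and strength εᵢⱼ:

    U_attr(r) = εᵢⱼ (σᵢⱼ⁸/r⁸ − σᵢⱼ⁶/r⁶)

whose minimum sits at r_m = σᵢⱼ·√(4/3) with depth U_m = −(27/256)·εᵢⱼ, and
a purely repulsive soft-core variant for unfavourable pairs:

    U_rep(r) = U_attr(r) + 2|U_m|   for r ≤ r_m
             = −U_attr(r)           for r > r_m

No explicit electrostatics: the pair parameters absorb all effective
interactions. Docking minimizes the ligand (protein) energy in the field
of the fixed receptor (DNA) over the six rigid degrees of freedom, starting
from positions spread ~12 Å apart on a surface around the receptor with 208
near-uniform orientations each, in five stages with the pairwise cutoff
stepped 50 → 8 Å. Solutions are clustered by ligand-bead RMSD and ranked by
energy. Predictions are assessed CAPRI-style via interface RMSD (iRMSD) and
fraction of native contacts (f_NC); "hit" = high or medium quality.

The pair parameters can be re-trained with a two-stage greedy Monte-Carlo
procedure: σ against the drift of native complexes under minimization
(hinged at 1 Å), then ε against native-vs-decoy ranking with hit-curve-AUC
early stopping on a held-out test set.

## Worked example

Generate a synthetic benchmark complex with a planted optimum, dock, and
evaluate (real PDB input goes through `cgdock reduce` instead):

```bash
cgdock fixtures --kind complex --seed 5 --out-prefix fx
cgdock dock --receptor fx.receptor.pdb --ligand fx.ligand.pdb \
    --params fx.params.tab --spacing 24 --orientations 24 --seed 1 -o poses.tsv
cgdock evaluate --reference-receptor fx.receptor.pdb \
    --reference-ligand fx.ligand.pdb --poses poses.tsv -o metrics.tsv
```

which prints (seed 5 fixture, reduced 24 Å / 24-orientation grid):

```
toy complex -> fx.receptor.pdb / .ligand.pdb (native pose = identity)
288 poses -> poses.tsv
# hits: top1=True top10=True top100=True AUC=1.000
```

`metrics.tsv` holds one row per pose: rank, energy, cluster, iRMSD (Å),
f_NC, CAPRI-style label. Here the rank-1 pose is a high-quality hit — it
re-finds the planted binding mode — and AUC=1.000 means the best-ranked
solution of the (single) complex is a hit, the upper end of the 0–1 hit-curve
area used to monitor training.

Python API equivalent:

```python
from cgdock import (default_parameter_table, PairEnergyModel,
                    SearchSettings, systematic_search)
from cgdock.fixtures import make_universe, make_toy_complex

universe = make_universe(seed=5)
receptor, ligand, native = make_toy_complex(universe, 50, 15, seed=5)
model = PairEnergyModel(universe.table, cutoff=8.0)
poses = systematic_search(receptor, ligand, model, SearchSettings(), seed=1)
```

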
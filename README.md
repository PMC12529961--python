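# qubind

Lattice peptide-binder design by binary quadratic optimization.

`qubind` designs short peptide binders for a protein pocket in two stages:

1. **Joint pose + sequence design.** The pocket is filled with a cubic
   lattice (3.8 Å spacing, the peptide-bond length) clipped to lie near a
   reference pose and away from the receptor. Residues are grouped into
   `D` chemical families by least-squares clustering of a knowledge-based
   contact-energy matrix. Peptide conformations (self-avoiding chains
   between two anchor sites) and family sequences are encoded together as
   a QUBO Hamiltonian over site-occupancy, bond, and ancilla binaries,
   with penalty terms enforcing chain topology, single occupancy, and a
   soft chain-length constraint. A mean-field offset subtracts each
   residue type's average interaction with generic protein surfaces so
   designs are selective for the target rather than generically sticky.
2. **Full-alphabet refinement.** The best decoded chain geometry is
   frozen and the sequence is re-optimized over all 20 amino acids with a
   one-hot QUBO on the fixed positions.

Solvers include an exhaustive enumerator (exact, used as the correctness
oracle on small instances), a native single-flip simulated annealer, and
a pluggable backend protocol for external optimizers. The QUBO converts
losslessly to Ising form (`σ = 2q − 1`) for annealing hardware.

Validation utilities cover both assessment modes: precision–recall
analysis of ranked binding poses labeled by native-contact fraction
(`f_nat > 0.5`, CAPRI-style), and per-position family-frequency
comparison of designed versus reference sequence sets under a reduced
alphabet.

## Tests

```sh
python -m pytest tests/
```

The suite is self-contained: all receptors, pockets, and sequence sets
are generated programmatically (`qubind.synthetic_fixtures`). Acceptance
criteria live in `tests/test_acceptance.py`, one test per criterion, each
checked against an independent oracle (exhaustive enumeration, closed
forms, hand computation).

## Command line

```sh
qubind make-pocket --shape groove --dims 3 3 6 --seed 1 --out pocket.pdb
qubind grid --receptor pocket.pdb --ref-peptide pocket_ref.pdb --out grid.json
qubind cluster -D 5 --seed 1 --out families.txt
qubind design --receptor pocket.pdb --ref-peptide pocket_ref.pdb \
    --out-prefix design --config run.yaml
qubind solve --qubo model.json --solver sa --runs 300 --sweeps 10000 \
    --seed 7 --out spectrum.csv
qubind decode --grid grid.json -D 5 --bits bits.txt
qubind validate-pose --receptor rec.pdb --native native.pdb --poses poses.csv
qubind validate-seq --designed designed.fasta --reference ref.fasta \
    --map families.txt
qubind spectrum --csv spectrum.csv
```

`design` writes a FASTA of the refined sequence, a Cα-bead PDB of the
lattice chain, and a JSON report with the term-by-term energy breakdown
and the full configuration. Configuration files are YAML with strict
key checking; see `qubind.config.RunConfig` for every tunable and its
default (spacing 3.8 Å, include/exclude radii 7.6/1.5 Å, interaction
cutoff 8.5 Å, energy rescaling λ = 0.159 / e₀ = −2.27 k_BT, penalty
scale A = 20, D = 5).

Note on penalty scales: constraint terms are hard only when `A` exceeds
the summed magnitude of the soft coefficients
(`qubind.qubo_model.soft_coefficient_mass` computes a safe bound). At
lattice-contact distances the pair potential is strongly repulsive, so
realistic pockets need a much larger `A` than the toy default if the
solver is to avoid constraint-violating states; invalid solver states
are detected and skipped during decoding either way.

## Data files

`src/qubind/data/` packages the 20×20 residue contact-energy matrix
(k_BT units), per-residue van der Waals diameters derived from van der
Waals volumes, and residue surface frequencies. All are plain text and
overridable through the model-loading functions.
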
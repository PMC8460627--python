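# loopdyn

Analyses for enzymes whose active-site **flexible loop** swings between an
open (ligand-free) and a closed (ligand-bound) conformation — the situation
of bacterial type II L-asparaginase, a homotetramer whose catalytic loop
(residues 11–31, hinged at its flanking residues) folds over the substrate
pocket on binding, anchored partly by a residue borrowed from the companion
protomer of the intimate dimer (E283′).

The package is a library first (see `examples/`), with a thin `loopdyn`
command-line layer, and covers both sides of such a study:

**Trajectory statistics** (multi-model PDB interchange format)

* *Distance-fluctuation (DF) matrix*: for residues *i*, *j* with
  time-dependent Cα distance *d<sub>ij</sub>*,

  DF<sub>ij</sub> = ⟨(d<sub>ij</sub> − ⟨d<sub>ij</sub>⟩)²⟩

  the population variance of the inter-residue distance over frames. Low DF
  marks mechanically coordinated regions; the measure is exactly invariant
  under rigid-body motion of each frame.
* *Region-resolved RMSD series*: per-frame Kabsch superposition on one
  selection, measurement on another (whole protein, core-only, loop-only).
* *Stable contacts*: residue pairs whose Cα distance is **below 6 Å in more
  than 30 % of frames** (both inequalities strict, thresholds configurable),
  with conserved / lost / gained partitioning between two states.
* *H-bond occupancies*: N-donor/O-acceptor heavy-atom distance criterion
  (≤ 3.5 Å), inter-protomer filtering, and apo→holo stabilization calls.

**Crystal-structure comparisons**

* loop-opening angle about the hinge axis (angle at the hinge midpoint
  subtended by the two vertex-Cα positions after core superposition),
* polar anchoring contacts pinning the closed loop (same-chain or
  companion-chain partners),
* coordinated-water census of the binding pocket and positionally conserved
  waters between superposed structures,
* missing-residue (disordered-region) gap detection.

**Synthetic data.** A first-class generator builds toy tetramers with
planted ground truth — a symmetric loop arc whose rigid rotation about the
hinge axis is exactly recoverable, per-residue harmonic jitter, two-state
open/closed mixtures with planted contact breaks and H-bond occupancies,
and pocket waters with known coordination — so every estimator is validated
against quantities known by construction.

## Worked example

```python
import loopdyn as ld
from loopdyn import Selection

spec = ld.SyntheticSpec()            # 4 chains x 50 residues, loop 11-31
closed, truth = ld.make_toy_complex(spec)
traj, gt = ld.make_two_state_trajectory(
    closed, spec.loop_range, spec.hinge_pair, spec.planted_angle,
    open_fraction=0.3, n_frames=1000, sigma=0.2, seed=42)

contacts = ld.stable_contacts(
    traj,
    Selection.make(chains=["A"], residue_ranges=[spec.loop_range],
                   atom_names=["CA"]),
    Selection.make(atom_names=["CA"]))
print(contacts.fraction_of(("A", 21, "GLY"), ("C", 45, "GLY")))
```

Running `python examples/03_stable_contacts_and_hbonds.py` prints:

```
planted open fraction 0.3; realized on chain A: 0.293
22 stable contacts of the chain-A loop; anchor pair A21-C45 fraction = 0.707 (expected 1 - p = 0.707)
inter-protomer H-bond A21(N)-C45(O): occupancy 0.682
```

The planted loop-vertex/companion anchor (chain A residue 21 against chain
C residue 45) is bonded only while the loop is closed, so its contact
fraction recovers 1 − open-fraction exactly; the H-bond occupancy reads the
same truth through an independent criterion (slightly lower because thermal
jitter occasionally stretches the 3.0 Å bond past the 3.5 Å cutoff).

`python examples/04_contact_conservation_table.py` compares the packaged
bound/unbound stable-contact table: 53 bound-state pairs, 16 conserved
after ligand release, with the contacts gained by the free enzyme all
linking the loop to the 115–120 coil that props it open.

Each other example covers one capability (DF matrices, loop angles, pocket
waters, the full pipeline); `loopdyn --help` lists the equivalent shell
subcommands (`simulate`, `df`, `rmsd`, `contacts`, `hbonds`, `compare`,
`angle`, `anchors`, `waters`, `gaps`, `run`).

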
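# Methods

## Scope and model

`loopdyn` analyses the conformational dynamics of an oligomeric enzyme
with a mobile active-site loop, in two complementary regimes: statistics
over coordinate trajectories (frames of a fixed atom topology) and static
comparisons between crystal structures of different states. The package
does not simulate physics; trajectories come either from the user (any MD
engine, exported as multi-model PDB) or from the built-in synthetic
generator, which emulates the *statistical* structure the estimators
assume.

All residue identifiers are author numbers as printed in PDB columns,
insertion codes honoured, so published residue labels map directly onto
selections. Hydrogens are ignored everywhere: crystal structures carry
none, and using heavy atoms only keeps experimental and simulated inputs
comparable. Alternate locations collapse to the highest-occupancy
conformer (ties: alphabetically first altloc). The prime convention for
companion-protomer residues (e.g. E283′) is resolved through an explicit
chain pairing, default intimate dimers (A, C) and (B, D).

## Trajectory estimators

**Distance fluctuation.** DF<sub>ij</sub> = ⟨(d<sub>ij</sub> −
⟨d<sub>ij</sub>⟩)²⟩ with d<sub>ij</sub> the Cα–Cα distance and ⟨·⟩ the
time average. The estimator uses the *population* variance (divide by F),
matching the time-average definition, with all frames weighted equally
and no default stride or burn-in. Implementation: per-frame gram
matrices on frame-centred coordinates (distances are translation
invariant, and centring keeps the d² = |x|² + |y|² − 2x·y evaluation well
conditioned); a literal pair-and-frame double loop is kept as a reference
oracle and the two agree to < 1e-10 Å² in the tests. Tiny negative
variances from rounding are clipped to zero, the matrix is symmetrized
exactly and the diagonal forced to zero.

**RMSD series.** Each frame is superposed onto the reference by a plain
least-squares (Kabsch/SVD) fit on the *fit selection*, then RMSD is
measured on the *measure selection* — so "whole protein", "core without
the loop" and "loop only, fitted on the core" are all expressible. The
Kabsch fit requires ≥ 3 non-collinear points and always returns a proper
rotation (det +1). Note that visualization tools often superpose with
outlier rejection; a plain least-squares fit can therefore differ
slightly from angles or RMSDs read off such tools.

**Stable contacts.** A pair is in contact in a frame when its Cα
distance is strictly below `d_cut` (default 6 Å) and stable when its
contact fraction strictly exceeds `f_cut` (default 0.30) — strict on
both sides, so values exactly at a threshold are excluded. Pairs within
two sequence positions on the same chain are dropped as trivially in
contact (published contact tables list no i, i±1 pairs). State
comparison partitions canonical (lexicographically ordered) pairs into
conserved / lost / gained; the counts satisfy |holo| = conserved + lost
and |apo| = conserved + gained exactly.

**Hydrogen bonds.** Donor is any N, acceptor any O; the criterion is
heavy-atom distance ≤ `hb_cut` = 3.5 Å with no angle term, the
conventional heavy-atom cutoff when structures carry no hydrogens. Pairs
closer than two sequence positions on one chain are skipped (covalently
constrained backbone neighbours). "Stabilized on binding" means some
pair involving the residue gains ≥ `delta_cut` = 0.30 occupancy from apo
to holo (chosen symmetric with `f_cut`; configurable), annotated N- or
C-domain via a configurable residue split (default 190).

## Crystal comparisons

**Loop-opening angle.** No standard convention exists for "the angle the
loop vertex forms" between two conformations, so the package defines and
records one: superpose the mobile chain's core Cα (everything outside
the loop ± 3 flanking residues) onto the reference chain's; the angle is
measured at the midpoint of the reference's two hinge Cα, subtended by
the transformed mobile vertex Cα and the reference vertex Cα. This is
the simplest hinge-consistent reading; it recovers planted rigid
rotations exactly, is symmetric in its two arguments, but published
values measured under an unstated convention may shift by a few degrees.

**Anchoring contacts** report every (loop residue, non-loop residue)
pair with at least one N/O–N/O distance ≤ `polar_cut` (default 3.5 Å),
flagging whether the partner is on the same chain, the companion chain
of the intimate dimer, or another chain.

**Pocket waters.** A water is "coordinated" with ≥ `min_contacts` = 3
polar contacts within `coord_cut` = 3.5 Å to pocket-residue N/O atoms;
with `require_all_chains` a water counts only if each protomer, after
chain-to-chain Cα superposition, holds a positional equivalent within
`equiv_tol` = 1.0 Å. Conserved waters between two structures are matched
greedily by ascending distance after pocket-Cα superposition (ties
broken by residue number, each water used once) within `match_tol` =
1.0 Å. "Highly coordinated" and "same position" are qualitative in the
literature; these defaults are exposed in config, not claimed as facts.

**Missing residues** are maximal runs of expected residue numbers with
no atoms in a chain — the fingerprint of a disordered loop with no
electron density.

## Synthetic generator

The generator is the package's test bed: every planted quantity must be
recoverable by the corresponding estimator.

*Geometry.* Each chain is a smooth space curve with ~3.8 Å Cα spacing:
the core follows a 150 Å-radius arc (so distal core residues sit well off
the hinge axis, as in a folded domain) with a small non-planar wiggle,
and the loop is a circular arc between the two hinge Cα, symmetric about
the chord bisector. That symmetry puts the loop vertex's projection onto
the hinge axis exactly at the hinge midpoint, which makes the
loop-opening angle of a planted rotation equal the rotation angle
*exactly* (it also requires an odd number of loop residues, as in the
default 11–31 range). Backbone N and O pseudo-atoms sit ± 0.6 Å from
each Cα, providing polar donors/acceptors without side chains.

*Tetramer.* The companion chain of each intimate pair is placed by an
involutive 180° rotation chosen so the companion's anchor-partner O
atom lies 3.0 Å from the template's loop-vertex N; being an involution,
the reciprocal vertex-to-partner anchor holds automatically — each
protomer pins its neighbour's closed loop, as in the real dimer. The
second dimer is a 40 Å translated copy. Pocket waters are planted
between consecutive pocket residues (offset 1.5 Å off the backbone),
giving four polar contacts at ~2.5 Å each, replicated identically in
every protomer; a low-coordination variant (2 contacts) is available for
negative controls.

*Trajectories.* Harmonic trajectories add one isotropic Gaussian
displacement per residue per frame (σ per coordinate, rigid within the
residue, independent across residues and frames); at separations ≫ σ
the DF of such a pair tends to 2σ². Two-state trajectories flip each
chain's loop independently per frame to the hinge-rotated "open" pose
with probability `open_fraction`, add harmonic noise everywhere, and
record the realized per-chain open fractions; planted intermittent
H-bonds are realized with an exact frame count (round(q·F) bonded
frames), so their occupancy is recovered with zero sampling error.
Rigid-motion trajectories apply a random rotation + translation per
frame and are the invariance control for DF. All generators are pure
functions of (spec, seed), with per-chain random sub-streams.

*What the toy does not emulate:* side-chain chemistry, solvent, force
fields, realistic secondary structure, correlated backbone motion, or
crystallographic noise. Passing tests demonstrate estimator correctness
and calibration on data satisfying the estimators' assumptions — not
that any particular real system behaves like the toy.

## Problem sizes and defaults

The default study system is a 4 × 50-residue tetramer with loop 11–31,
hinges 10/32, planted opening angle 45.7°, σ = 0.2–0.3 Å and open
fraction 0.5 — a desk-scale stand-in for a 4 × 326-residue enzyme
sampled over hundreds of nanoseconds. Statistical checks use 2 000
frames (binomial recovery, 3 SE), 5 000 frames (variance calibration,
3 Monte-Carlo SE) or 100–300 frames (qualitative contrasts); the
pipeline default is 300 frames × 2 replicas, pooled before contact
statistics (replica frames are equally weighted, so pooled statistics
equal concatenated-trajectory statistics identically). Per-replica
counts are reported in the ground-truth sidecar.

## Numerical notes and edge cases

* Superposition refuses < 3 points or a collinear reference (the
  rotation would be under-determined).
* `rotate_loop` normalizes angles outside [0°, 180°] (with a warning)
  and leaves hinge residues untouched; angle 0 is the identity.
* Selections resolve to indices ordered by (chain, residue, insertion
  code, file order) and are deterministic; an empty selection warns and
  returns an empty list rather than raising, except where an analysis
  cannot proceed.
* PDB round trips are fixed points: write(read(write(s))) is
  byte-identical to write(s); coordinates are preserved at the 3-decimal
  column precision, and values outside the fixed-column range raise
  rather than truncate.
* Pipeline outputs use fixed float formatting, so identical configs
  yield byte-identical numeric artifacts (the provenance record echoes
  the output path and therefore differs across directories).

## Known limitations

* The loop-opening angle convention is this package's own; comparisons
  against values measured with other conventions (or outlier-rejecting
  superposition) are best-effort.
* H-bond detection without hydrogens or angle terms over-counts at the
  margins; it is a contact criterion, not a chemical assignment.
* Binary trajectory formats are out of scope; convert to multi-model
  PDB first (adapters can be layered on the same `Trajectory` type).
* The water-equivalence test across protomers assumes the protomers are
  conformationally similar enough for a global Cα superposition.
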
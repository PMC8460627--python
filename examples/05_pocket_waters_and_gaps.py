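"""Pocket-water census, conserved waters between states, and chain gaps.

Crystal structures of the free enzyme show ordered waters coordinated by
binding-pocket residues in every protomer; on ligand binding most are
displaced while a couple keep their exact position.  The toy complex
plants such waters, and a pruned copy emulates a disordered loop with no
electron density.
"""

from dataclasses import replace

import loopdyn as ld
from loopdyn import Selection, Structure

spec = ld.SyntheticSpec()
s, _ = ld.make_toy_complex(spec)

census = ld.pocket_water_census(s, range(40, 46), coord_cut=3.5,
                                min_contacts=3, require_all_chains=True)
chain_c = [w for w in census if w.water[0] == "C"]
print(f"coordinated pocket waters in protomer C (present in all 4): "
      f"{len(chain_c)}")
for w in chain_c:
    partners = ", ".join(f"{c}{r}" for c, r in w.coordinating_residues)
    print(f"  water {w.water[1]}: {w.n_polar_contacts} polar contacts "
          f"({partners})")

# a second state in which only two water sites keep their position
keep = {401, 402}
other = Structure([
    replace(a, coords=(a.coords[0] + 2.5, a.coords[1], a.coords[2]))
    if a.is_water and a.chain_id == "C" and a.res_seq not in keep else a
    for a in s.atoms])
pocket = Selection.make(chains=["C"], residue_ranges=[(40, 46)],
                        atom_names=["CA"])
matches = ld.conserved_waters(s, other, pocket, match_tol=1.0)
print(f"waters at identical positions in both states: {len(matches)} "
      f"({[m.water_a[1] for m in matches]})")

# disordered loop: remove residues 16-30 of chain B, then detect the gap
pruned = Structure([a for a in s.atoms
                    if not (a.chain_id == "B" and 16 <= a.res_seq <= 30)])
print(f"missing-residue gaps, chain B: "
      f"{ld.missing_residues(pruned, 'B', (1, 50))}")
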
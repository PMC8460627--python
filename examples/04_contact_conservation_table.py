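"""Conservation of stable contacts between bound and unbound states.

The package ships a transcription of the published stable-contact table
for the ligand-bound (HOLO) and ligand-free (APO) simulations of the
asparaginase tetramer.  Comparing the two sets partitions every pair into
conserved / lost-on-release / gained-on-release.
"""

from loopdyn import compare_contact_sets, load_reference_contacts

ref = load_reference_contacts()
result = compare_contact_sets(ref["HOLO"], ref["APO"])

print(f"bound-state stable contacts:   {len(ref['HOLO'])}")
print(f"unbound-state stable contacts: {len(ref['APO'])}")
print(f"conserved: {result.n_conserved}   lost on release: {result.n_lost}"
      f"   gained on release: {result.n_gained}")
print("\ncontacts gained by the free enzyme (loop parked on the 115-120 coil):")
for a, b in sorted(result.gained, key=repr):
    print(f"  {a[0]}{a[1]} - {b[0]}{b[1]}")
# Only 16 of the 53 bound-state contacts survive release of the ligand:
# the flexible loop trades its closed-state anchors for contacts that
# stabilize the open conformation.
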
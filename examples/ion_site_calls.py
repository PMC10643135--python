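"""Ion identification from first-shell coordination geometry.

Builds a buried alkali site — 3 backbone carbonyl oxygens + 2 waters at
2.4 Å — and classifies it against the Na+/K+/water decision table.
"""

from redoxmap import classify_site, find_coordination, fixtures

s = fixtures.make_ion_site("NA", cn=5, mean_dist=2.4,
                           ligand_classes=["carbonyl"] * 3 + ["water"] * 2)
shell = find_coordination(s, s.atoms[0], cutoff=3.0)
call = classify_site(shell)

print(f"coordination number: {shell.coordination_number}")
print(f"mean ligand distance: {shell.mean_distance:.2f} Å")
print(f"ligand classes: {shell.ligand_class_counts()}")
print(f"identity: {call.identity}  (score {call.score:.2f})")
for crit, ok in call.rationale:
    print(f"  [{'x' if ok else ' '}] {crit}")
print("-> CN 4-6 with all-oxygen ligands at 2.2-2.6 Å is the Na+ signature;")
print("   K+ would need longer (2.6-3.1 Å) contacts.")
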
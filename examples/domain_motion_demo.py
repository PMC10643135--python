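"""Rigid domain-motion quantification between two conformational states.

Builds a two-state hinge fixture: a static core helix plus a mobile domain
rotated 26 degrees about a hinge axis (the rotation reported for the
electron-shuttle subunit between its two docking sites), then recovers the
motion from coordinates alone.
"""

from redoxmap import SelectionSpec, domain_motion, fixtures

ref, mov = fixtures.make_hinge_pair(26.0)
dt = domain_motion(ref, mov,
                   core=SelectionSpec("A", ((1, 20),)),
                   domain=SelectionSpec("B", ((1, 20),)))
print(f"rotation angle:     {dt.rotation_angle:.2f} deg")
print(f"rotation axis:      {dt.rotation_axis.round(3)}")
print(f"max Cα displacement:{dt.max_displacement:7.2f} Å")
print(f"domain fit rmsd:    {dt.rmsd_domain:.2e} Å")
print("-> the domain moves as a rigid body (rmsd ~0) through the constructed")
print("   26 deg; the max displacement is the swing of its distal tip.")
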
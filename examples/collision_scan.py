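"""Walk a body along the DNA axis and score steric clash with a roadblock.

Builds an ideal B-DNA helix with two pseudo-atom blobs anchored on it 12
base pairs apart, advances the mobile blob one base pair at a time using
the helical screw transform, and reports the solvent-excluded-surface
overlap volume at each position, rescaled to zero at the start.
"""

from rnapcollide import SurfaceParams, scan_collision
from rnapcollide.structio import ResidueSelection
from rnapcollide.synthetic import make_collision_scene

mobile, fixed, dna = make_collision_scene(
    seed=0, mobile_radius=6.0, fixed_radius=6.0,
    fixed_position=28, mobile_position=16,
)
scan = scan_collision(
    mobile, fixed, dna,
    window=ResidueSelection((("T", 5, 14), ("N", 5, 14)), "window"),
    positions=range(16, 28),
    params=SurfaceParams(grid_spacing=0.6),
    reference_position=16,
    mobile_position=16,
)

print("position_nt  gap_A   overlap_A3")
for pos, value in zip(scan.positions, scan.rescaled_overlap):
    gap = (28 - pos) * 3.4 - 12.0
    print(f"{pos:11d}  {gap:5.1f}   {value:10.1f}")
print()
print("Overlap stays at zero while the surfaces are far apart and rises")
print("steeply once the bodies come within about two bases of contact --")
print("the steric signature that drives a colliding polymerase to backtrack.")
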
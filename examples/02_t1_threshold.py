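"""The geometric T1 threshold in the tension / isogonal-strain plane.

An interface collapses when its Voronoi reference length plus its
isogonal length reaches zero.  At zero isogonal strain the critical
relative tension is sqrt(2); isogonal stretching raises the threshold,
isogonal contraction lowers it (down to 1, where a hexagonal-reference
interface collapses with no tension change at all).
"""

import math

import tigon as tg

l0 = tg.DEFAULT_L0  # tension-to-length scale, um
print(f"l0 = {l0} um\n  dl_iso (um)   T_crit")
for dl in (-l0 / math.sqrt(3), -1.0, 0.0, 1.0, 1.9):
    print(f"  {dl:10.3f}   {tg.t1_threshold(dl, l0):.4f}")

kite = tg.TensionKite(shared=1.0, left=(1, 1), right=(1, 1))
print(f"\npost-exchange tension (120-degree angles before the flip): "
      f"{tg.flip_kite(kite).shared:.4f}")
# T_crit(0) = 1.4142 is the square (concyclic) configuration; the 1.7321
# after the flip is the long diagonal of the equilateral tension rhombus.
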
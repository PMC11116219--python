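"""Generate a skull-like phantom, carve a defect, and inspect the partition.

The synthetic generator produces hollow ellipsoidal shells standing in for
binary skull segmentations, and carves defects with a known ground-truth
implant: the defective shape and the implant partition the complete shape
exactly, which is what makes every later pipeline stage testable.
"""

import numpy as np

import cranioshape as cs

spec = cs.PhantomSpec(grid_shape=(64, 64, 64), radii=(24.0, 20.0, 22.0),
                      thickness=4.0)
skull = cs.generate_phantom(spec)
print(f"complete phantom: {skull.foreground_count} foreground voxels "
      f"on a {skull.shape} grid")

defect = cs.DefectSpec(kind="multi_lobe", size_fraction=0.25, count=2, seed=1)
defective, implant = cs.apply_defect(skull, defect)
n_components, sizes = cs.count_components(implant)
print(f"defective skull:  {defective.foreground_count} voxels")
print(f"implant (truth):  {implant.foreground_count} voxels "
      f"in {n_components} separate lobes of sizes {[int(s) for s in sizes]}")

exact_partition = (np.array_equal(defective.data | implant.data, skull.data)
                   and not np.any(defective.data & implant.data))
print(f"defective ∪ implant == complete, disjoint: {exact_partition}")
# The implant volume is ~25 % of the skull (the requested size_fraction),
# split over two disjoint lobes — emulating a skull with two defects.
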
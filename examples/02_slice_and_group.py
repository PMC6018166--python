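"""Slice a reference-sized volume into views and overlapping groups, and
propagate the slice-network layer shapes.

The reference brain box is 193 x 153 x 163 voxels stored coronal-first:
193 coronal slices, 153 sagittal, 163 axial.  With 15-slice groups every
9 slices the coronal view yields 20 groups, each feeding one 2D CNN whose
layer arithmetic is printed below.
"""

import numpy as np

from slicegru.cnn import compute_output_shapes, count_parameters, table2_architecture
from slicegru.volume_io import GroupingScheme, Volume, decompose, make_groups

vol = Volume(data=np.full((193, 153, 163), 0.1), view_axes={"coronal": 0, "sagittal": 1, "axial": 2})
scheme = GroupingScheme(group_size=15, stride=9)

for view in ("coronal", "sagittal", "axial"):
    n = len(decompose(vol, view))
    groups = make_groups(n, scheme)
    print(f"{view:9s}: {n:3d} slices -> {len(groups):2d} groups "
          f"(size {scheme.group_size}, stride {scheme.stride}, overlap {scheme.overlap})")

arch = table2_architecture()
print("\nslice-network layer shapes (valid convolutions, 1x150x150 input):")
for layer, shape in zip(arch.layers, compute_output_shapes(arch)):
    print(f"  {layer.kind:8s} {shape}")
print(f"total trainable parameters: {count_parameters(arch):,}")
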
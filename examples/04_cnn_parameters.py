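"""Build the two-tower CNN for both input regimes and count parameters.

The compact regime takes two 50x50 images at convolution stride 1; the
large regime takes 227x387 and 380x387 images at stride 2 (same layer
widths).  Parameter totals are pure functions of the architecture —
no training involved.
"""

import tabimg as ti

compact = ti.build_two_tower_cnn(ti.CNNSpec())
print("compact (2 x 50x50, stride 1):",
      f"{ti.count_trainable_parameters(compact):,} trainable parameters")
for name, shape in compact.tower_shapes[0]:
    print(f"  tower stage {name:8s} -> {shape}")

large = ti.build_two_tower_cnn(
    ti.CNNSpec(input_shapes=((227, 387), (380, 387)), conv_stride=2))
print("large (227x387 + 380x387, stride 2):",
      f"{ti.count_trainable_parameters(large):,} trainable parameters")
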
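"""Expand a labeled dataset with translations, rotations and flips.

Each augmented image keeps its label; over-enhanced images (those that
pushed most content out of frame) are rejected.
"""

from hemolyzer.geometric import AugmentConfig, augment_batch, hflip_point, rotate_point, translate_point
from hemolyzer.phantoms import sample_dataset

print("point algebra:")
print("  translate (2,3) by (1,1)     ->", translate_point((2, 3), 1, 1))
print("  hflip (2,5) at width 10      ->", hflip_point((2, 5), 10))
print("  rotate (1,0) by 90 degrees   ->", tuple(round(v, 6) for v in rotate_point((1, 0), 90)))

images = sample_dataset(20, seed=0)
cfg = AugmentConfig(max_translation=8, rotation_range=15, flip_probability=0.5, seed=1)
augmented = augment_batch(images, cfg)
print(f"\n{len(images)} originals -> {len(augmented)} augmented survivors")
print("labels preserved:", [a.label for a in augmented[:6]], "...")
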
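"""Walk one image through the network and print every feature-map shape.

Uses the desk-scale preset (128-px input, narrow channels).  At the full
640-px configuration the same schedule yields the published sizes:
C1..C4 = 96x160x160, 192x80x80, 384x40x40, 768x20x20 and P1..P6 sides
160, 80, 40, 20, 10, 5 at 256 channels — input side / 4, then halving.
"""

import numpy as np

from grainseg import tensor as T
from grainseg.config import Config
from grainseg.model import GrainSegModel
from grainseg.synthgrain import GrainSceneSpec, generate_scene

cfg = Config.tiny()
model = GrainSegModel(cfg)
scene = generate_scene(GrainSceneSpec(canvas=(128, 128), n_grains=6), seed=0)

x = model.normalize(scene.image)
with T.no_grad():
    stages = model.backbone(x)
    pyramid = model.fpn(stages)
    protos = model.protonet(pyramid["P1"])

print(f"input: {x.shape}  (normalised RGB)")
for k, v in stages.items():
    print(f"  backbone {k}: {tuple(v.shape[1:])}")
for k in sorted(pyramid, key=lambda s: int(s[1:])):
    print(f"  pyramid  {k}: {tuple(pyramid[k].shape[1:])}")
print(f"  prototypes: {tuple(protos.shape[1:])}  (k masks at 2x P1 side)")
print(f"anchors: {len(model.anchors)} = 3 per location over six levels")
print(f"parameters: {model.num_parameters():,}")
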
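"""Score a fused slice with the seven-metric fusion-quality suite.

Builds an identity fixture (ct = pet = fused) whose report pins the metric
conventions — RMSE 0, NMI at its lower bound 2, VIF 1 — then scores a real
fusion from a briefly trained model for comparison.
"""

import numpy as np

from spfn import (
    Image2D,
    ImagePair,
    ModelConfig,
    PhantomConfig,
    TrainConfig,
    evaluate_pair,
    fuse,
    generate_dataset,
    generate_phantom_pair,
    make_pair,
    minmax_normalize,
    train,
)


def show(tag, rep):
    print(
        f"{tag:>9}  mean {rep.mean:.3f}  std {rep.std:.3f}  AG {rep.avg_gradient:.4f}  "
        f"Ent {rep.entropy:.3f}  RMSE {rep.rmse:.3f}  NMI {rep.nmi:.3f}  VIF {rep.vif:.3f}"
    )


# identity fixture: the report's degenerate reference points
ct = minmax_normalize(generate_phantom_pair(PhantomConfig(ct_size=64, seed=3)).ct)
identity = ImagePair(
    ct=ct, pet=Image2D(ct.values, modality="PET", normalized=True), identifier="id"
)
show("identity", evaluate_pair(identity, Image2D(ct.values, "FUSED", True)))

# a trained fusion of a fresh phantom pair
pairs = [
    make_pair(p.ct, p.pet_native, identifier=str(i))
    for i, p in enumerate(generate_dataset(20, PhantomConfig(ct_size=64, seed=9)))
]
cfg = ModelConfig()
params, _ = train(pairs[:16], cfg, TrainConfig(epochs=8, batch_size=4, seed=0))
show("fused", evaluate_pair(pairs[16], fuse(pairs[16], params, cfg)))

print(
    "\nIdentity pins the conventions (RMSE 0, NMI 2, VIF 1); the fused row is a"
    "\nreal reconstruction: NMI well above 2 means the fusion carries"
    "\ninformation from both sources."
)
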
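"""Train the fusion network on phantoms and fuse a held-out pair.

Trains the siamese pyramid network for two epochs on 40 synthetic pairs at
64x64 (a desk-scale stand-in for the clinical 512x512 slices), then fuses
a pair the optimizer never saw. The SSIM columns show how much structure
from each source survives in the fused slice — the quantity the training
objective maximizes.
"""

from spfn import (
    ModelConfig,
    PhantomConfig,
    TrainConfig,
    fuse,
    generate_dataset,
    init_parameters,
    make_pair,
    ssim,
    train,
)

pairs = [
    make_pair(p.ct, p.pet_native, identifier=str(i))
    for i, p in enumerate(generate_dataset(44, PhantomConfig(ct_size=64, seed=1)))
]
train_set, held_out = pairs[:40], pairs[40:]

model_cfg = ModelConfig()
train_cfg = TrainConfig(epochs=2, batch_size=4, lam=1e-4, seed=0, learning_rate=0.01)

untrained = init_parameters(model_cfg, seed=0)
params, records = train(train_set, model_cfg, train_cfg)
print(f"loss: first batch {records[0].total:.3f} -> last batch {records[-1].total:.3f}")

print(f"\n{'pair':>4} {'SSIM(ct)':>9} {'SSIM(pet)':>9}  model")
for pair in held_out:
    for label, p in (("untrained", untrained), ("trained", params)):
        fused = fuse(pair, p, model_cfg)
        print(
            f"{pair.identifier:>4} {ssim(pair.ct, fused):>9.3f} "
            f"{ssim(pair.pet, fused):>9.3f}  {label}"
        )
print(
    "\nThe untrained network emits a near-constant slice (SSIM ~ 0); after two"
    "\nepochs the fusion preserves most of both sources' structure."
)
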
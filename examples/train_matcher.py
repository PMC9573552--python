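"""Train the permutation-invariant spot-to-lenslet matching network.

Spot-to-lenslet association is a per-point classification problem on an
unordered 2-D point set: a shared pointwise MLP lifts each centroid to 512
features, max pooling forms an order-independent global feature, and a
pointwise head scores every effective lenslet for every point.

This demo trains on 300 simulated wavefronts of a small 4x4 sensor (a
couple of minutes on one core); the full protocol is the same code with
more wavefronts and epochs.  Held-out per-point accuracy near 1.0 means
nearly every spot in every test frame is matched to its true lenslet.
"""

import shwfs
from shwfs.matcher import SamplerConfig, TrainingConfig, accuracy, make_dataset, train

geometry = shwfs.build_geometry(grid_shape=4, mask_rule="full")
print(f"sensor: 4x4 lenslets, k = {geometry.k_effective} classes")

train_set, test_set = make_dataset(
    n_wavefronts=300,
    geometry=geometry,
    sampler=SamplerConfig(rms_range=(0.2, 5.0)),  # spans beyond the classical range
    split=0.9,
    rng_seed=1,
    method="extract",  # full render + whole-frame extraction per sample
)
print(f"dataset: {len(train_set)} train / {len(test_set)} test point sets")

net = shwfs.MatchNetwork(k_classes=geometry.k_effective, seed=0)
history = train(net, train_set, TrainingConfig(epochs=25, batch_size=8, seed=0))

print(f"training loss: {history['epoch_loss'][0]:.4f} -> {history['epoch_loss'][-1]:.4f}")
print(f"held-out per-point accuracy: {accuracy(net, test_set):.4f}")

net.save("matcher_4x4.npz", geometry)
print("checkpoint written to matcher_4x4.npz")
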
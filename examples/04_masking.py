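"""Where is the task information embedded?  Prediction-time node masking.

Trains a 16-input/16-class model with a 10-node knot, then randomly
removes nodes of either the receptor (input) layer or the intermediate
layer during prediction only — no rescaling of survivors, modeling
physical ablation of signaling elements — and compares the accuracy cost.
"""

from bowtienet import (
    NetworkSpec, NoiseModel, TrainingConfig, init_network, make_prototypes,
    masking_curve, sample_dataset, train,
)

protos = make_prototypes(16, 16, rng_seed=21)
ds = sample_dataset(protos, NoiseModel(20), n_per_class=500, rng_seed=22)
model = train(init_network(NetworkSpec(16, 10, 16), 23), ds,
              TrainingConfig(epochs=100, rng_seed=24))

rates = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
for layer in ("input_layer", "intermediate_layer"):
    mc = masking_curve(model, ds, layer, rates, n_predictions=20_000, rng_seed=25)
    drops = [f"{mc.baseline_accuracy - a:.3f}" for a in mc.mean_accuracy]
    print(f"{layer:>18} drops at p={rates}: {drops}")
# If the narrow intermediate layer embeds the input information, the two
# rows should fall off with comparable magnitude as p grows.
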
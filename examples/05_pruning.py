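"""Node-centric vs connection-centric pruning without retraining.

Node removal (pseudogenization analogy) silences whole intermediate
units, least-important first (smallest L1 outgoing weight); connection
pruning (attenuated binding analogy) zeroes the globally smallest-
magnitude hidden weights.  Both curves are indexed by the fraction of
pooled hidden weights removed.
"""

from bowtienet import (
    NetworkSpec, NoiseModel, TrainingConfig, init_network, make_prototypes,
    pruning_equivalence, sample_dataset, train,
)

protos = make_prototypes(8, 16, rng_seed=31)
ds = sample_dataset(protos, NoiseModel(20), n_per_class=500, rng_seed=32)
model = train(init_network(NetworkSpec(16, 8, 8), 33), ds,
              TrainingConfig(epochs=100, rng_seed=34))

node, conn = pruning_equivalence(model, ds)
print("fraction removed:", [f"{f:.2f}" for f in node.removed_fraction])
print("node-centric acc:", [f"{a:.3f}" for a in node.accuracy])
print("fraction removed:", [f"{f:.2f}" for f in conn.removed_fraction])
print("connection acc:  ", [f"{a:.3f}" for a in conn.accuracy])
# Without retraining, whole-node removal is the harsher operation: each
# node costs 1/H of the pooled weights but carries correlated information.
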
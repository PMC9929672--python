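"""Generate a synthetic cytokine-response dataset and calibrate it.

Builds 15 binary class prototypes in 30 dimensions, samples noisy points
around them, and asks the Bayes oracle how separable the classes are —
the accuracy ceiling no trained classifier can beat.
"""

from bowtienet import (
    NoiseModel, bayes_oracle_accuracy, make_prototypes, sample_dataset,
    write_dataset,
)

protos = make_prototypes(n_classes=15, n_dims=30, rng_seed=1)
noise = NoiseModel(S=20)  # covariance I/S: per-element sd ~0.224
ds = sample_dataset(protos, noise, n_per_class=1000,
                    validation_fraction=1 / 3, rng_seed=2)

print(f"dataset: {ds.X.shape[0]} samples x {ds.X.shape[1]} inputs, "
      f"{ds.n_classes} classes, "
      f"{(ds.split == 'validation').mean():.0%} held out")

for S in (10, 20, 70):
    ceiling = bayes_oracle_accuracy(protos, NoiseModel(S), n_mc=50_000, rng_seed=3)
    print(f"Bayes-oracle accuracy at S={S:>2}: {ceiling:.4f}")

path = write_dataset(ds, "scratch_dataset.csv")
print(f"wrote {path} (+ JSON sidecar with seeds and parameters)")
# The oracle numbers rise with S: larger S means tighter classes. Any
# trained network's validation accuracy should sit at or below them.
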
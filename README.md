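# bowtienet

Simulation study of **bow-tie architectures** in JAK-STAT-like signaling
networks, modeled with small dense artificial neural networks.

Cytokine signaling funnels ~30 kinds of upstream receptor inputs through a
handful of STAT transcription factors into ~15 downstream cellular
responses — a bow-tie: wide fan-in, narrow knot, wide fan-out.  This
package asks, in a controlled synthetic setting, how much intermediate
("knot") complexity such a channel actually needs, and where the task
information ends up embedded.  It is aimed at computational/systems
biologists studying signaling-network evolution and at anyone who wants a
fully seeded, reproducible width-sweep benchmark for small classifiers.

## The model

Each of `C` response classes is a prototype vector `μ_c ∈ {0.3, 0.7}^D`
(signal absent / present per input).  Samples are drawn as

    x | c  ~  N(μ_c, I/S)

so the scalar `S` controls separability (larger `S` = lower noise).  Each
experiment uses 1000 samples per class, one third held out for validation.
With equal spherical covariances the Bayes-optimal classifier is
nearest-prototype; a Monte-Carlo oracle of it upper-bounds every trained
network (closed form `Φ(0.2·√S)` for the two-class, one-dimensional case).

The classifier is a three-dense-layer network `D → D → H → C` (ReLU, ReLU,
softmax) trained with Adam on categorical cross-entropy for 600 epochs
(defaults), where the intermediate width `H` is swept.  Three regimes model
pathway evolution:

* **pre-evolved** — the trailing half of the input columns is zeroed
  (receptors that have not yet evolved);
* **post-evolved** — all inputs available;
* **transfer** — the pre-evolved model continues training on full inputs.

The **saturation width** summarises each mean-accuracy curve: the smallest
`H` within `ε = 0.02` of the best accuracy on the grid.  Prediction-time
node masking (Bernoulli removal of a layer's units, no rescaling) and
node- vs connection-centric pruning probe where information is embedded.

## Worked example

```sh
python examples/02_width_sweep.py
```

runs a reduced sweep (8 classes, 16 inputs, S = 20, 2 replicates,
80 epochs) and prints, among the per-width table:

```
  pre_evolved: saturation at 12 nodes (plateau accuracy 0.761)
 post_evolved: saturation at 12 nodes (plateau accuracy 0.940)
     transfer: saturation at 12 nodes (plateau accuracy 0.937)
```

All three regimes flatten at the same knot width; the post-evolved curve
sits on top, and transfer learning closes almost the whole pre/post gap —
extra receptors help, but the intermediate layer does not need to grow
with them.  `examples/03_noise_gap.py` prints the pre/post plateau gap at
high vs low noise (0.183 at S = 10 vs 0.031 at S = 70 in the same reduced
setting): redundant inputs matter most when data are noisy.  Examples 01,
04 and 05 cover the generator/oracle, masking and pruning.

There is also a thin CLI (`bowtienet sweep|noise|iosweep|mask|prune|run|report`)
that writes results CSVs, plots and a provenance sidecar from a YAML config.

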
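# mscfnet

Joint **nucleus instance segmentation** and **virtual staining** for
IHC-like histopathology tiles.

Quantitative pathology needs two things from the same tile: the outline of
every nucleus, and its marker status (e.g. Ki-67 positive vs negative).
`mscfnet` trains both in one network so the outputs are co-registered by
construction: a shared multi-scale encoder feeds (i) an adversarially
trained generation decoder that synthesizes positive/negative marker
channels from the RGB input, and (ii) a segmentation decoder that consumes
those synthesized cues at every resolution level.  Three operators do the
coupling:

* **MDE blocks** — parallel dilated convolutions (rates 1, 2, 4) with
  squeeze-and-excitation reweighting and a residual path,
  `F~ = F* ⊙ γ(F*) + F`, used throughout the encoder;
* **TRADESGate** — a spatially varying convex fusion
  `f = g ⊙ f_m + (1−g) ⊙ f_a` of the main and auxiliary feature fields,
  regularized by total variation on the gate and by a TRADES-style
  consistency term `KL(p(f) ‖ p(f~))` against the worst-case bounded gate
  perturbation;
* **ATFiLM** — channel-wise affine skip modulation
  `s'_c = γ_c s_c + β_c` with (γ, β) inferred from the auxiliary features,
  identity at initialization, with its own KL consistency term.

The package ships a seeded synthetic-tile simulator (so everything is
testable without downloads), an instance-metric suite (Dice, IoU, pixel
accuracy, Aggregated Jaccard Index overall and per marker class,
positivity-index difference), an sklearn-style estimator, and a CLI.
The network and its training loop run on a small numpy autodiff core
included in the package — there is no deep-learning framework dependency.

## Worked example

```python
import numpy as np
from mscfnet import MSCFNetSegmenter, SynthParams, generate_dataset

data = generate_dataset(SynthParams(tile_size=64, n_nuclei=12,
                                    positive_fraction=0.3), 40, seed=7)
X = np.stack([s.image for s in data])          # (40, 64, 64, 3) RGB in [0,1]
y = np.stack([s.instances for s in data])      # (40, 64, 64) instance labels
aux = np.stack([np.stack([s.aux_pos, s.aux_neg]) for s in data])
classes = [s.classes for s in data]

est = MSCFNetSegmenter(depth=3, base_width=8, steps=300, random_state=7)
est.fit(X[:32], y[:32], classes=classes[:32], aux=aux[:32])
print("val Dice:", round(est.score(X[32:], y[32:]), 3))
labels = est.predict(X[32:])                   # instance label maps
```

The equivalent scripted run (`mscfnet.experiments.smoke_run(seed=7)`)
trains the depth-3, width-8 network for 300 alternating steps (60
generation-only warm-up steps) on 32 simulated tiles and prints, on the 8
held-out tiles:

```
pixacc 0.868   dice 0.801   iou 0.669
aji 0.368   aji_pos 0.405   aji_neg 0.364
ihc_quant_diff 0.069
```

Reading: 80 % foreground overlap (Dice) after ~2 minutes of CPU training;
the instance-aware AJI is much stricter than Dice because it also penalizes
merged/split nuclei among the densely packed, touching instances; the
predicted positivity index (fraction of marker-positive nuclei — the
quantity a Ki-67 read-out reports) is within 7 points of the truth.

The per-step loss table, checkpoints and metric reports are also available
through the CLI:

```bash
mscfnet simulate --out data --n-samples 40 --seed 7
mscfnet train --data data --out run
mscfnet infer --checkpoint run/checkpoint_final.npz --data data --out pred
mscfnet evaluate --pred pred --gt data --out eval
mscfnet ablate --variant atfilm_concat --out ablation   # single-change variants
```

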
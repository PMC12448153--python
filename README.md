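# ncrfseg

Conditional random fields with **learnable pairwise potentials** for medical
image segmentation, trained end to end through unrolled mean-field
inference — with classic fixed-kernel CRF baselines, 3D per-patient
evaluation metrics, and a synthetic MRI-phantom generator so everything is
testable without any data download.

The motivating problem is prostate zonal segmentation on T2-weighted MRI:
delineating the transition zone (TZ) and peripheral zone (PZ), which is
required for PI-RADS-style lesion assessment and downstream cancer
detection.  Plain encoder–decoder networks segment mid-gland slices well
but are inconsistent at the apex and base, and classic CRF refinements
built on intensity similarity are brittle under MRI noise, bias fields and
per-patient intensity shifts.  The package is aimed at researchers in
medical image analysis who want a structured, testable implementation of a
CRF head whose potentials are *learned* rather than hand-designed.

## Model

Pixel labels form a CRF on an 8-connected pixel graph, conditioned on deep
features `F ∈ R^{H×W×C}` extracted by a backbone network:

    P(X = x | O) ∝ exp(−E(x | O)),
    E(x|O) = Σ_ij ψ_u(x_ij | O) + Σ_{((i,j),(i',j'))∈E} ψ_b(x_ij, x_i'j' | O)

- **Unary** `ψ_u`: a linear layer on the pixel's feature vector.
- **Pairwise** `ψ_b`: features are augmented with a sinusoidal positional
  encoding (`o' = o + PE`, groups of `sin ωj, cos ωj, sin ωi, cos ωi` with
  `ω = 10000^(−4k/C)`), re-embedded by a shared MLP `φ = f(o')`, and each
  edge's `K×K` cost matrix is `M = exp(g(d(φ_p, φ_q)))` with `d` the
  elementwise squared difference — every quantity entering the pairwise
  term is learned.
- **Inference**: `Q ← softmax(−ψ_u)`, then `N = 5` synchronous mean-field
  updates `ψ̃(x_ij) = Σ_{edges} Σ_{x'} M[x_ij, x'] Q(x')`,
  `Q ← softmax(−(ψ_u + ψ̃))`, unrolled and differentiated end to end.

Baseline variants (`spatial`, `intensity`, `posterior`, `postproc`, `none`)
share the same graph, inference loop and training recipe, differing only in
how `ψ_b` is computed.  See `docs/methods.md` for conventions, defaults and
limitations.

The package runs on plain NumPy/SciPy: it ships a compact reverse-mode
autodiff engine (`ncrfseg.autodiff`) providing the convolution, pooling and
message-passing primitives the models need.

## Worked example

```python
import numpy as np
from ncrfseg import (PhantomParams, generate_dataset, ModelConfig,
                     BackboneConfig, SegmentationModel, TrainConfig, train)
from ncrfseg.experiments import evaluate_on_patients

dataset = generate_dataset(12, PhantomParams(), seed=0)
model = SegmentationModel(ModelConfig(
    variant="ncrf", iterations=5, seed=0,
    backbone=BackboneConfig(base_filters=8, depth=3)))
result = train(model, {"train": dataset["train"], "val": dataset["val"]},
               TrainConfig(learning_rate=1e-3, epochs=10, batch_size=8, seed=0))
print(f"best epoch: {result.best_epoch}, val DSC: {result.best_val_dsc:.3f}")
metrics = evaluate_on_patients(model, dataset["test"])
for key in ("dsc_tz", "dsc_pz", "ravd_tz", "ravd_pz", "assd_tz", "assd_pz"):
    print(f"{key}: {metrics[key]:.4f}")
```

Output:

```
best epoch: 9, val DSC: 0.967
dsc_tz: 0.9655
dsc_pz: 0.9573
ravd_tz: 0.0333
ravd_pz: 0.0217
assd_tz: 0.1263
assd_pz: 0.0740
```

Nine phantom patients' slices train the model for ten epochs; the best
validation checkpoint then segments the two held-out test patients.  The
per-class scores are 3D per-patient means: Dice overlap (1 is perfect),
relative absolute volume difference (0 is perfect), and average symmetric
surface distance in millimetres at (3.0, 0.625, 0.625) mm voxel spacing —
here the predicted zone boundaries sit about a tenth of an in-plane voxel
pitch from the reference on average.

The same pipeline is available from the shell:

```sh
ncrfseg generate --out data --n-patients 12 --seed 0
ncrfseg train --data data --out run --variant ncrf --seed 0
ncrfseg evaluate --checkpoint run/checkpoint.npz --data data --out report
```

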
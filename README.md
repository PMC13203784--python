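# hybridseg

Hybrid residual CNN–Transformer U-Net for binary breast-lesion
segmentation, with warm-start sequential transfer learning across
datasets and bootstrap-CI evaluation — implemented entirely on a compact
NumPy automatic-differentiation core, exercisable end to end on
synthetic multi-modality phantoms.

## Who this is for

Researchers and engineers who want a fully inspectable, dependency-light
reference implementation of the hybrid U-Net family used in medical
image segmentation: a residual encoder (32 → 64 → 128 → 256 channels
over four pooled stages), a Transformer bottleneck that flattens the
16×16×512 map into 256 tokens and runs 4 pre-norm encoder blocks with
8-head scaled dot-product attention (MLP ratio 4, GELU), a
skip-connected decoder with learned upsampling, and a 1×1 sigmoid head.
Training minimises the combined objective

    L = L_BCE + (1 − Dice),   Dice = (2Σy·p + ε)/(Σp + Σy + ε)

with Adam (lr 1e-4), ReduceLROnPlateau (×0.5 after 5 stagnant epochs),
early stopping (patience 12), and gradient clipping at global norm 5 —
all keyed on validation Dice. Incremental learning is plain warm-start
fine-tuning: each phase initialises from the previous best checkpoint by
non-strict name-and-shape matching and continues training on the next
dataset. Evaluation reports per-image Dice/IoU/accuracy/F1 with
1000-resample percentile-bootstrap 95% CIs, pooled one-vs-rest pixel
confusion statistics, and rank-based ROC-AUC.

No clinical datasets are required: `hybridseg.phantoms` generates
modality-flavoured phantoms (speckled ultrasound lesions, many small
histology nuclei, bright mammographic masses, MRI-like enhancing
regions) with exact ground-truth masks and patient grouping.

## Worked example

```bash
# 1. a synthetic ultrasound dataset: 20 patients x 2 images at 64 px
hybridseg generate-data --modality ultrasound --patients 20 \
    --images-per-patient 2 --image-size 64 --seed 1 --out runs/data

# 2. train the hybrid model (reduced width for CPU) on a 70/15/15
#    patient-level split, then evaluate the held-out test patients
hybridseg train --data runs/data/manifest.csv --out runs/hybrid \
    --variant hybrid-dicebce-aug --input-size 64 --base-channels 8 \
    --transformer-layers 1 --lr 1e-3 --epochs 8 --seed 1
hybridseg evaluate --checkpoint runs/hybrid/best.npz \
    --data runs/data/manifest.csv --split test --seed 1
```

The train command prints the selected checkpoint:

```
best val Dice 0.8586 at epoch 7
```

and `evaluate` reports, for the six held-out test images (abridged):

```json
{
  "point":    {"dice": 0.8693, "iou": 0.7718, "accuracy": 0.9807, "f1": 0.8693},
  "ci_lower": {"dice": 0.8289, "iou": 0.7100, ...},
  "ci_upper": {"dice": 0.9064, "iou": 0.8293, ...},
  "auc": 0.9992
}
```

i.e. the model recovers ~87% Dice overlap with the exact phantom masks
after eight epochs, with the bootstrap interval quantifying per-image
variability and AUC ≈ 1 showing the probability map ranks lesion pixels
above background almost perfectly. `predict` writes a binary mask PNG
for a single image; `transfer` chains warm-start phases across several
manifests; `run-suite` executes a YAML-defined grid of variants
(`hybrid-bce-noaug`, `hybrid-dicebce-aug`, `unet-dicebce-aug`, ...) and
consolidates a variant × split × metric table.

As a library:

```python
import numpy as np
from hybridseg import ArchitectureConfig, HybridUNet, combined_loss

model = HybridUNet(ArchitectureConfig(), np.random.default_rng(0))
probs = model(np.random.default_rng(1).random((1, 3, 256, 256), dtype=np.float32))
print(probs.shape)          # (1, 1, 256, 256), values in [0, 1]
```

See `docs/methods.md` for the model equations, the training protocol,
what the phantoms do and do not emulate, and known limitations.

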
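# mammoseg

Cascade 3D breast-lesion segmentation and multi-modal prediction of
pathologic complete response (pCR), exercised end to end on synthetic
two-center breast phantoms.

## The problem

Breast DCE-MRI volumes contain a posterior confounder — the heart —
whose contrast-enhanced intensity is close to that of malignant lesions,
so a single-shot lesion segmenter produces false positives outside the
breast. The package implements a two-step cascade: first segment the
mammary gland region, keep its largest connected component, and crop its
bounding box; then segment the lesion *within* that gland region. Both
steps use a 3D U-Net trained with the compound loss

    L_total = L_dice + L_ce,
    L_ce    = -1/N Σ_i Σ_k v_ik log u_ik,
    L_dice  = -2/K Σ_k (Σ_i u_ik v_ik) / (Σ_i u_ik + Σ_i v_ik),

sliding-window inference with Gaussian center weighting (stride =
patch/2), and largest-component post-processing. Cross-center intensity
shift is harmonized by gray-level histogram matching built on the
equalization map `s_k = (L-1)/M · Σ_{j≤k} n_j`.

Downstream, a multi-modal classifier predicts pCR after neoadjuvant
chemotherapy from the segmented lesion crop plus four molecular markers
(HER2, ER, PR, Ki-67): a 5-stage residual 3D conv branch is gated at
every stage by a 5-layer FC marker branch via channel-wise
multiplication. Paired-method comparison uses McNemar's test
(χ² = (b−c)²/(b+c), uncorrected) and a χ² goodness-of-fit test against
the ground-truth outcome distribution.

Because the clinical cohort behind the original study is
access-restricted, the package ships a first-class phantom generator:
two anterior gland half-ellipsoids, a posterior "heart" sphere whose
intensity is within one SD of the lesions', 1–3 lesion blobs inside a
gland, two simulated scanners with different intensity transforms, and a
known logistic link from markers + lesion volume to the pCR label. Every
claim the test suite makes is checked against this known ground truth.
See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from mammoseg import phantom, pipeline

# 20 phantoms from simulated center A: train on 10, hold out 10
spec = phantom.PhantomSpec()
vols, truths = pipeline.make_phantom_set(20, spec, "A", seed0=100)
gland_net, lesion_net = pipeline.train_cascade_models(vols[:10], truths[:10], seed=0)
ev = pipeline.evaluate_cascade(gland_net, lesion_net, vols[10:], truths[10:])
print("lesion Dice:", np.round(ev["lesion_dice"], 3))
print("mean: %.3f   heart-overlap voxels: %d"
      % (np.mean(ev["lesion_dice"]), sum(ev["heart_overlap_vox"])))
```

Output from this exact snippet:

```
lesion Dice: [0.996 0.957 0.972 0.993 0.871 0.992 0.828 0.81  0.993 0.795]
mean: 0.921   heart-overlap voxels: 0
```

Mean held-out lesion Dice is 0.921 at desk scale, and no predicted
lesion voxel falls inside the true heart mask — the cascade did its job
of excluding the look-alike confounder.

The same stages are available from the shell:

```bash
mammoseg phantom --n 20 --seed 0 --out-dir data/
mammoseg train-seg --task gland  --data-dir data/ --out gland.npz
mammoseg train-seg --task lesion --data-dir data/ --out lesion.npz
mammoseg infer --image data/P0000_image.nii.gz \
    --gland-model gland.npz --lesion-model lesion.npz --out pred.nii.gz
mammoseg evaluate --pred-mask pred.nii.gz --truth-mask data/P0000_lesion.nii.gz
mammoseg demo --seed 0          # full pipeline, prints a JSON report
```

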
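# dvaseg

Data variation-aware multi-variant segmentation, with the observer-study
analytics used to evaluate such methods.

## The problem

Organ delineation on medical images is ambiguous: experienced clinicians
contour the same organ differently (inter-observer variation), especially
near the cranial/caudal poles of the prostate (base and apex).  A standard
deep-learning segmenter trained on everyone's contours learns an *average*
delineation that reflects no single clinician's style.  `dvaseg`
implements an alternative paradigm: one shared U-Net encoder feeding K
decoder paths, where each decoder is trained on its own subset of the
training scans.  When the subsets align with delineation styles, each
decoder specializes, and the model proposes K plausible variants per scan
— the clinician picks the one matching their own style.

The subsets are found by maximizing the best-of-variants validation score

    score = (1/N) Σᵢ maxₖ S_ik ,     S_ik = ½ (DSC + surface DSC)

over assignments of training scans to K subsets, with a seeded
evolutionary search.  The row-wise max models the clinical-use situation:
for each scan, the preferred variant is kept.

The package also ships the analytics for a blinded observer study of such
a method — best-of-two grade/rank merging, count distributions, Pearson
chi-squared with Bonferroni correction, Cohen's kappa on variant
preferences, and base/mid/apex relative-area analysis — together with the
published study's count table and a synthetic-cohort generator that plants
per-scan delineation styles, so every component is testable at desk scale
with no data downloads.

## Worked example

```python
import numpy as np
from dvaseg import (StyleSpec, generate_cohort, train_dvas, predict_variants,
                    ModelConfig, volumetric_dsc, surface_dsc, MetricConfig)

# 9 synthetic scans; two planted styles contour +2 / -2 mm at the poles
styles = [StyleSpec(0, polar_offset_mm=+2.0, noise_sd_mm=0.3),
          StyleSpec(1, polar_offset_mm=-2.0, noise_sd_mm=0.3)]
cohort = generate_cohort(9, styles, [0.5, 0.5], (6, 2, 1), seed=21)

train = cohort.subset("train")
model = train_dvas([s.image for s in train], [s.reference for s in train],
                   assignment=[s.style_id for s in train],   # style-pure subsets
                   cfg=ModelConfig(n_decoders=2, encoder_width=6, epochs=15,
                                   learning_rate=5e-3, seed=0))

scan = cohort.subset("val")[0]
variants = predict_variants(model, scan.image)
for k, v in enumerate(variants.variants):
    print(f"variant {k}: {v.voxel_count} voxels, "
          f"DSC vs reference {volumetric_dsc(v, scan.reference):.3f}")
```

prints (decoder 0 was trained on the wide +2 mm style, decoder 1 on the
tight −2 mm style; the validation scan happens to be a tight-style scan,
so variant 1 matches its reference better):

```
variant 0: 13628 voxels, DSC vs reference 0.772
variant 1: 7860 voxels, DSC vs reference 0.908
```

The same pipeline is scriptable from the shell:

```bash
dvaseg simulate --n 24 --split 16,4,4 --seed 1 --out runs/sim
dvaseg search   --cohort runs/sim --k 2 --budget 30 --out runs/search
dvaseg train    --cohort runs/sim --k 2 --partition runs/search/search.json --out runs/train
dvaseg analyze  --out runs/analyze     # published observer-study table
```

## Layout

```
src/dvaseg/metrics.py     volumetric + surface Dice, cohort score
src/dvaseg/synthetic.py   style-planted synthetic cohorts, study fixtures
src/dvaseg/model.py       shared-encoder multi-decoder U-Net (NumPy)
src/dvaseg/search.py      partition evaluation backends + evolutionary search
src/dvaseg/study.py       observer-study analytics + published count table
src/dvaseg/io.py, cli.py  NIfTI/CSV/JSON I/O, run config, CLI
docs/methods.md           model, assumptions, design choices, limitations
```
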
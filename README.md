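# cmlcells

Segmentation, morphometry and rule-based maturation staging of
myeloid-series white blood cells in stained smear / bone-marrow images.

In chronic myeloid leukemia (CML) the bone marrow floods the blood with
myeloid precursors, and the differential count over the maturation series
— Myeloblast (MB) → Promyelocyte (PM) → Myelocyte (M) → Metamyelocyte
(MM) → Band (B) → Neutrophil (N) — is a core part of the diagnostic
workup.  `cmlcells` implements a fully automatic pipeline for this count
from ×1000 RGB microscopy images:

1. **Segmentation** — leukocytes are dark in the enhanced CMYK-yellow
   channel (linear stretch + histogram equalization, 3×3 minimum filter
   ×3, Otsu threshold, morphological cleanup); nuclei are extracted
   inside each cell from the heavily blurred CIELAB a\* channel (σ = 33 px)
   with a second Otsu pass; touching cells are separated by a
   marker-controlled watershed on the distance transform.
2. **Morphometry** — six features per cell:
   `Num` (nucleus lobe count), `AoN` (nucleus area, px),
   `ACoC` (mean CIELAB b\* of the cytoplasm),
   `T1` (minimum nucleus thickness from a modified bottleneck search:
   the shortest boundary-pair chord that pinches the shape without
   crossing background), `T2` (minimum convex-hull width, rotating
   calipers), `HD` (Hausdorff distance between nucleus and cell borders)
   and `P1` (perimeter of the smaller nucleus part after a validated
   bottleneck split).
3. **Classification** — a thirteen-stage threshold decision tree on
   (`Num`, `T1/T2`, `T1/HD`, `ACoC`, `AoN`, `P1`) mapping each cell to
   one of eight outcomes: the six stages plus the deliberate overlap
   classes MB|PM and PM|M for borderline cells.  Key cuts: `T1/T2` 0.92 /
   0.86 / 0.53 / 0.1, `T1/HD` 3.7 / 2.1, `ACoC` 24 / 27 / 30, `AoN`
   110 000 / 115 000 px, `P1` 475 px — all overridable via config.
4. **Evaluation** — per-class one-vs-rest sensitivity / specificity /
   accuracy and Cohen's kappa, κ = (p₀ − p_e)/(1 − p_e).
5. **Synthetic data** — a seeded generator of class-conditioned single-cell
   scenes (nucleus shape, N:C ratio, palette per maturation stage) with
   exact ground-truth masks, so the whole pipeline is testable end to end
   without clinical data.

## Worked example

```sh
cmlcells synth --out demo --seed 5 -n 1
cmlcells pipeline demo/images/*.png --out demo/run
```

which prints (per image, abbreviated):

```
INFO cmlcells.segmentation: segmented 1 regions (1 with nucleus)
INFO cmlcells.classifier: classified 6 cells: {'MB': 1, 'PM': 1, 'M': 1, 'MM': 1, 'B': 1, 'N': 1}
pipeline: 6 cell(s) -> demo/run/labels.csv
```

`demo/run/features.csv` holds one row per cell; for the myeloblast scene
it reads (rounded)

```
num=1  aon=128985  acoc=-24.5  t1=405  t2=405  hd=41.0  t1_over_t2=1.000  t1_over_hd=9.88  p1=0
```

— a single round nucleus (`T1/T2 = 1`) nearly filling the cell, so the
nucleus border runs close to the cell border (`HD` small, `T1/HD` ≫ 3.7)
and the tree labels it `MB` at its first regular-branch stage.  To score
the run against the generator truth, key the truth labels by the same
image-qualified cell ids the pipeline emits and compare:

```sh
python -c "import pandas as pd; t = pd.read_csv('demo/truth.csv'); \
  pd.DataFrame({'cell_id': t.scene_id + ':1', 'label': t.label}) \
    .to_csv('demo/ref.csv', index=False)"
cmlcells evaluate --pred demo/run/labels.csv --ref demo/ref.csv --out demo/metrics.json
```

which prints the macro averages over classes (full per-class table in
`demo/metrics.json`):

```
{
  "sensitivity": 100.0,
  "specificity": 100.0,
  "accuracy": 100.0,
  "kappa": 1.0
}
```

All six cells recover their generating stage, so sensitivity,
specificity and accuracy are 100 % for every class and Cohen's kappa is
1 (perfect chance-corrected agreement).  A second expert file can be
passed with `--ref2`; the comparison then runs on the subset of cells
where the two references agree.

The same functionality is available as a library:

```python
from cmlcells import segment_image, extract_features, classify, generate_dataset

scene = generate_dataset(1, seed=5)[0]
records = [r for r in segment_image(scene.image) if r.classifiable]
fv = extract_features(records[0], scene.image)
label, trace = classify(fv)
```

## Scope and limitations

The staging thresholds are fixed clinical-image constants at the
reference pixel pitch (2592×3872 full frame at ×1000); a `--scale`
factor rescales lengths linearly and areas quadratically for other
optics.  The synthetic generator emulates shape, size, N:C ratio and
coarse color phenomenology, not chromatin texture or staining
variability — see `docs/methods.md` for what passing tests do and do not
establish about clinical images.
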
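# plasmavoc

Identification of volatile organic compounds (VOCs) from still images of a
micro helium dielectric-barrier-discharge plasma.

When a VOC is carried into a helium plasma microchamber it ionizes and
shifts the plasma's color and shape in a compound-specific way. A phone
camera frame taken at peak ionization is therefore a chemical fingerprint:
n-pentane, benzene, acetone and their binary mixtures, each injected at
four gas-chromatograph inlet pressures (17/20/24/27 Psi), give 24
distinguishable image categories labeled `C-17` … `AB-27` (analyte code ×
pressure). `plasmavoc` implements the image-analysis side of that sensing
scheme, for analytical chemists and sensor developers who want a
training-free classifier for colorimetric plasma readout:

* fixed **region crops** of the frame (region 1: full plasma area,
  1080×1350 px; region 2: central plasma window, 360×324 px; region 3:
  faint bottom reflection band, 540×400 px),
* **block-grid mean-RGB features**: the crop is partitioned into
  `n_w × n_h` equal rectangles and each block is reduced to its mean
  (R̄, Ḡ, B̄), concatenated row-major into a feature vector of length
  `3·n_w·n_h`,
* **nearest-centroid cosine classification**: each category is summarized
  by the element-wise mean of its training vectors, and a test image is
  assigned the category `argmax_y S_c(x, y)` with

  `S_c(x, y) = x·y / (‖x‖‖y‖)`,

  plus the min–max rescaling `S_norm = (S_c − S_min)/(1 − S_min)` (run
  minimum over the whole test) used to visualize the near-1 similarity
  matrices,
* a **seeded synthetic plasma-image generator** that emulates the frames'
  structure (dark background, one or two vertical light columns with a
  category hue, pressure-dependent hue shift, blurred bottom reflection,
  pixel noise) so the whole pipeline is testable without the camera
  dataset.

## Worked example

Why does segmentation matter? Cosine similarity on the 1×1 grid sees only
the whole-image mean color — and two categories with the same hue but a
different light-column layout (a pentane-like single column vs. a
mixture's double column) have *identical* mean color. The default
synthetic dataset builds exactly that trap:

```python
from plasmavoc import (BlockGrid, default_voc_config, evaluate, featurize,
                       fit_centroids, generate_dataset)

config = default_voc_config()                 # 24 VOC categories
data = generate_dataset(config, seed=7)       # 120 train + 24 test images

for grid in (BlockGrid(1, 1), BlockGrid(4, 5), BlockGrid(8, 10)):
    train = [featurize(im, grid) for im in data.train]
    test = [featurize(im, grid) for im in data.test]
    report = evaluate(test, fit_centroids(train))
    errors = ", ".join(f"{m.true_label}->{m.predicted_label}"
                       for m in report.misclassified) or "none"
    print(f"grid {grid.render():>5} ({grid.n_blocks:3d} blocks): "
          f"accuracy {report.accuracy_percent:5.1f}%  misclassified: {errors}")
```

prints

```
grid   1x1 (  1 blocks): accuracy  75.0%  misclassified: A-27->AB-27, BC-17->C-17, BC-20->C-20, BC-24->C-24, BC-27->C-27, AB-17->A-17
grid   4x5 ( 20 blocks): accuracy 100.0%  misclassified: none
grid  8x10 ( 80 blocks): accuracy 100.0%  misclassified: none
```

Every whole-image error confuses a category with its deliberately
mean-color-matched partner at the same pressure (`BC`↔`C`, `AB`↔`A`);
any segmented grid separates them by tens of channel units per block and
classifies perfectly. `plasmavoc.experiments.run_sweep` automates this
table over regions, grids and concatenated region combinations, and the
`plasmavoc` command line exposes the pipeline step by step (`synth`,
`featurize`, `train`, `classify`, `evaluate`, `sweep`, `reconstruct`,
`stats`).

## Real camera data

The deposited plasma-image dataset (Zenodo record 20099619) is an
optional path: download and unpack it, write a `manifest.csv` with
columns `source_id,label,split`, and run the shipped full-scale schedule

```sh
plasmavoc sweep --preset table2 --manifest manifest.csv \
    --images-dir frames/ --out sweep.csv
```

`plasmavoc.experiments.table2_sweep()` carries the published grid
schedule for all three regions; region offsets within the original
1080×1920 frame are configurable (`plasmavoc.images.FULL_FRAME_REGIONS`,
or a YAML regions file) since they depend on camera framing. Nothing in
the test suite requires this download.

See `docs/methods.md` for the model assumptions, generator design and
numerical choices.
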
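# cristaseg

Trainable segmentation and morphometry of **mitochondrial cristae** in
live-cell super-resolution fluorescence micrographs.

Cristae — the invaginations of the inner mitochondrial membrane that house
the oxidative-phosphorylation machinery — sit at the ~100 nm resolution
limit of live-cell imaging (Airyscan, SIM). Plain intensity thresholding
cannot separate them from the bright mitochondrial matrix or from each
other, so counts, areas and shapes come out badly biased. `cristaseg`
implements the machine-learning alternative: a random-forest **pixel
classifier** trained from a handful of user strokes turns each micrograph
into a cristae **probability map**, which thresholds cleanly into discrete
particles whose geometry can then be measured in calibrated units.

The package provides, as importable modules and a CLI:

* rolling-ball background subtraction (exact grayscale opening);
* a multi-scale feature stack (Gaussian, Sobel, 30-orientation membrane
  projections);
* random-forest pixel classification from sparse stroke annotations, with
  ARFF import/export of training data;
* probability-map thresholding, particle extraction and the 0.017 µm²
  theoretical-minimum area filter;
* classical histogram auto-thresholds (MaxEntropy/Kapur, Shanbhag, Otsu,
  isodata) as comparison baselines;
* calibrated shape morphometry — area, perimeter, circularity
  (4π·A/P², capped at 1), moments-ellipse aspect ratio — and cristae
  density (count per µm² of mitochondrial-network area), aggregated per
  mitochondrion, per cell and per experiment;
* time-lapse organelle tracking with fission/fusion lineage events and
  **SD-per-minute** dynamic ranges of every cristae metric;
* a synthetic scene generator with full ground truth (tubular, ouroboros,
  fragmented organelles; lamellar, arched, jigsaw, radial, vesicular
  cristae; PSF blur, shot + read noise; scripted remodeling events) used
  to validate the whole chain.

See `docs/methods.md` for the conventions and design choices.

## Worked example

Train a classifier on two annotated synthetic scenes, then analyze a third
scene it has never seen:

```python
import cristaseg as cs
from cristaseg.classifier import TrainingSet
from cristaseg.segment import label_mask

# accumulate stroke annotations across two training images
training = TrainingSet()
for i, seed in enumerate((1000, 2000)):
    image, truth = cs.generate_scene(cs.SceneSpec(seed=seed))
    pre = cs.subtract_background(image)                    # rolling ball, r=50
    stack = cs.build_feature_stack(pre)                    # 17 feature planes
    strokes = cs.strokes_from_truth(truth, seed=100 + i)   # 400 px per class
    training = cs.add_annotations(training, stack, strokes)
classifier = cs.train_classifier(training, seed=42)        # 200-tree forest

# held-out scene through the full pipeline
image, truth = cs.generate_scene(cs.SceneSpec(seed=0))
pre = cs.subtract_background(image)
prob = cs.predict_probability(classifier, cs.build_feature_stack(pre), pre)
mask = cs.threshold_probability(prob, 0.5)
particles = cs.filter_particles(cs.connected_particles(mask), min_area_um2=0.017)
net_mask, net_area = cs.segment_mito_network(pre)
summary, records = cs.aggregate_cell(particles, label_mask(net_mask),
                                     image.pixel_size_um)
```

This prints (via the analogous summary statements):

```
cristae found:        30 (truth: 30)
mitochondria:         4
cristae density:      6.04 /um^2 (truth: 6.31)
mean crista area:     0.0479 um^2 (truth: 0.0076)
mean aspect ratio:    3.32
mean circularity:     0.57
```

Two things to read off: the classifier recovers the true count exactly and
the density within ~4%, while the **measured mean area exceeds the true
area ~6-fold** — true cristae are 20 nm wide, far below the ~100 nm PSF, so
every diffraction-limited measurement reports the blurred footprint. That
overestimation is a property of the imaging physics, and the pipeline
reproduces it rather than hiding it.

## Command line

```bash
cristaseg simulate --seed 0 --out-dir sim/            # scene + ground truth
cristaseg train --image sim/frames.tif --labels strokes.tif \
                --out-model model.joblib --out-arff training.arff
cristaseg predict --model model.joblib --image sim/frames.tif --out-prob prob.tif
cristaseg run --image sim/frames.tif --model model.joblib --out-dir results/
cristaseg compare --image sim/frames.tif --model model.joblib \
                  --methods max_entropy,shanbhag,otsu --out-csv compare.csv
cristaseg track --image movie.tif --model model.joblib \
                --frame-interval-s 2 --out-dir results/
```

Every run writes its exact configuration (`config.txt`) next to the output
CSVs; re-running from that file reproduces the tables bit-identically.

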
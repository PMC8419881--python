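# gonioagree

Inter-annotator variability analysis for polygonal layer annotations of
digital gonio photographs.

## The problem

Gonioscopy inspects the iridocorneal angle (ICA) of the eye, the region
where aqueous humor drains; its visible anatomical layers — iris root (IR),
ciliary body band (CBB), scleral spur (SS), trabecular meshwork (TM) and
cornea (C), in that order from inner to outer — are what clinicians assess
when grading glaucoma risk. When several ophthalmologists trace these
layers as polygons on digital sector images (e.g. with the VGG Image
Annotator), their delineations disagree, and anyone validating an automatic
segmentation model against such annotations needs to know by how much.

Two features of this setting break the standard multi-rater toolkit:

* annotations are **partial** — vignetting, defocus and low confidence
  leave part of every image un-annotated (NA), and NA is a deliberate
  abstention, not background;
* annotators may skip a layer entirely when they cannot identify it.

`gonioagree` implements three NA-aware analyses for a panel of A annotators
on M images:

1. **Annotation frequency** — how often each annotator delineated each
   layer, with the maximum pairwise percent difference
   `max_{a,b} |c_a − c_b| / max(c_a, c_b) × 100` per layer.
2. **Consensus vs. threshold** — for each layer and each threshold
   n ∈ {1…A}, every pixel somebody labeled as the layer is classified as
   *consensus* (≥ n annotators agree), *disagreement* (< n agree and at
   least one assigned a different layer) or *ignored* (< n agree, the rest
   abstained). The consensus-size curve reports
   `ratio(n) = consensus / (consensus + disagreement)` (ignored pixels
   affect neither side; two alternative normalizations are selectable).
   n = 1 gives the union of delineations, n = A their intersection.
3. **Pairwise agreement** — per annotator pair, a 5×5 confusion matrix over
   the pixels *both* labeled; per layer the one-vs-rest precision
   TP/(TP+FP), sensitivity TP/(TP+FN) and Dice
   2·p·s/(p+s) = 2TP/(2TP+FP+FN), then per-annotator means and sample SDs
   over the other annotators as reference. Undefined metrics (empty
   denominators) are excluded from averages, never imputed as zero.

Because clinical panels are rarely shareable, the package ships a synthetic
panel generator: ordered horizontal bands with per-annotator smooth
boundary jitter, lateral truncation (→ NA periphery) and per-layer omission
probabilities, with exact ground truth — enough structure to exercise and
verify every stage.

## Worked example

```python
from gonioagree import (SimConfig, simulate_panel, annotation_frequency,
                        max_percent_difference, consensus_curve,
                        annotator_summary, LayerLabel, rasterize_set)

config = SimConfig(seed=1)          # 20 images, 5 annotators, 320×240
panel = simulate_panel(config)
aset = panel.annotations
maps = rasterize_set(aset)

freq = annotation_frequency(aset)
print(max_percent_difference(freq, LayerLabel.SS).value)   # 22.222...

by_image = {m: [maps[(a, m)] for a in aset.annotator_ids]
            for m in aset.image_ids}
curve = consensus_curve(by_image, LayerLabel.SS)
print(round(curve.ratios[5], 4))                           # 0.1522

summary = annotator_summary(maps, aset.annotator_ids, aset.image_ids)
dice = summary[(summary.metric == "dice")]
print(dice.groupby("layer")["mean"].mean().round(4))
# C      0.9798
# CBB    0.8719
# IR     0.9815
# SS     0.7279
# TM     0.9195
```

The scleral spur — the thinnest band, with the highest omission probability
— shows the largest frequency gap (22 % between the extreme annotators),
the smallest full-agreement consensus (15 % of its non-ignored labeled
pixels survive at n = 5) and the lowest mean Dice (0.73), while the thick,
sharp-bordered iris root and cornea stay near Dice 0.98: the familiar
pattern that thin, ambiguous layers carry most of the inter-annotator
variability.

The same pipeline runs from the shell:

```sh
gonioagree simulate --out panel --seed 1
gonioagree report --manifest panel/manifest.csv --out report
```

which writes `frequency.csv`, `consensus_curves.csv` (all three
normalization modes), `confusion_matrices.csv`, `annotator_summary.csv`,
consensus-map PNGs and a `run_metadata.json` provenance record. Real VIA
2.x projects are analyzed the same way: list them in a manifest CSV
(`annotator_id, image_id, project_path, image_width, image_height`) and
point `gonioagree report` at it.

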
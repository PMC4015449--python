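# metasel

Metaphase-spread pre-screening for karyotyping: segment objects from
Giemsa-stained spread images, classify each object into four classes with a
calibrated geometric rule tree, and rank candidate images by how many
individually analyzable chromosomes they contain.

Classes:

1. straight individual chromosome
2. skewed/bent individual chromosome
3. touching or overlapping chromosomes
4. non-chromosome residue (small / large / short subtypes)

The pipeline is: global histogram equalization → Otsu binarization
(dark-on-light foreground) → 8-connected components → principal-axis
rotation to vertical → geometric ratio features (fill ratio of the
enclosing rectangle, rectangle-width ratio, height ratio, maximum-width
ratio, against a per-image average chromosome width with a 1.5× wide-object
discard) → fixed-threshold decision tree → per-image ranking
(individual-chromosome count, with the class-3-more / class-4-fewer
tie-break cascade).

The default decision constants (area gate 67.84 %, rectangle-width band
0.9897–1.5597, height-ratio cutoff 0.7507, maximum-width gate 2.3453,
discard factor 1.5) ship built in and can be overridden via a config file;
`metasel.calibrate` re-derives such constants from labeled feature samples
as the intercept of two fitted class-conditional Gaussians.

A synthetic-spread generator (`metasel.synthgen`) renders banded straight
and bent chromosome bodies, fused crossing clusters, and debris blobs with
per-object ground truth, so the whole pipeline is testable and scoreable
without clinical images.

## CLI

```sh
# classify + rank a directory of PNG/TIFF/JPEG/BMP spread images
metasel run <input_dir> -o <output_dir> [--config rules.cfg] \
    [--min-object-px N] [--overlays] [--recursive]

# generate synthetic spreads (JSON holds SynthSpec fields + "n_images")
metasel synth spec.json -o <dir>

# fit two class Gaussians to a labeled CSV (columns: value,label) and
# report their intercept threshold
metasel calibrate labeled.csv --feature wmax_ratio -o report.json [--plot fig.png]
```

`metasel run` writes `ranked_spreads.csv`/`.json` (rank, class counts,
individual-chromosome count), `objects.csv` (all per-object features and
labels), `skipped.txt` (unreadable inputs never abort the batch), and
optional `overlays/` with class-colored bounding boxes (green/blue/orange/
red for classes 1–4).

Config files are `key = value` lines; recognized keys are the
`RuleThresholds` field names (`area_gate`, `wrect_lo`, `wrect_hi`,
`hi_min`, `wmax_gate`, `discard_factor`) plus `branch_feature`
(`area_ratio` | `wrect_ratio`) and `class3_tiebreak` (`more` | `fewer`).

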
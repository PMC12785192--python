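# cotyquant

Quantification of calcium-deficiency-induced cell death and callose
deposition in *Arabidopsis thaliana* cotyledon micrographs.

Calcium deficiency disorders (blossom-end rot, tip burn) manifest as
spreading necrosis. A mechanistic question in this area is whether
callose — a β-1,3-glucan deposited in cell walls under stress — limits
the *initiation* of cell death or its *propagation* into neighboring
tissue. Separating the two requires per-cotyledon image statistics that
distinguish overall death from lesion coalescence and position:

* **Total dead area** — trypan-blue-stained pixels are selected with a
  box threshold in HSB color space (all channels scaled 0–255; default
  box hue 120–200, saturation 120–255, brightness 0–190), grouped into
  8-connected components, and summed over components ≥ 20 px (noise
  floor). This indexes overall cell death.
* **Largest necrotic spot** — the maximal component ≥ 1000 px (several
  neighboring dead cells at ~100–200 px per cell). This indexes necrosis
  expansion.
* **Lesion position** — the cotyledon outline is summarized by its
  area-matched second-moment ellipse; the largest spot's centroid is
  expressed in dimensionless coordinates (origin at the ellipse center
  of mass, tip and screen-right positive, each axis scaled by its own
  radius): `y_rel = (c − m)·û / a`, `x_rel = (c − m)·v̂ / b`.
* **Callose density** — aniline-blue puncta are counted in the center
  tile of a 3×3 grid of a square confocal field, above a global
  intensity floor calibrated so that no-stain control images exceed it
  with frequency ≤ ε (default 10⁻⁴), and reported per mm² of leaf area.
* **Statistics** — per Ca condition, a two-way factorial ANOVA
  (response ~ day + genotype + day:genotype, sequential sums of
  squares), per-(Ca, day) pooled-variance Student t-tests with
  `*`/`**`/`***` annotations, and a representative-image selector
  (smallest root sum of squared deviations of spot area, x, y from
  their group medians).

Because suitable public image sets with ground truth do not exist, the
package includes a first-class synthetic-image generator
(`cotyquant.synthetic`) that renders stained-cotyledon and confocal-like
images with exact per-pixel ground truth and simulates whole cohorts
with configurable genotype effects, so every stage — segmentation,
morphometry, counting, statistics — is testable end to end.

## Worked example

```python
from cotyquant import synthetic as syn, pipeline as pl, stats as st

spec = syn.default_cohort_spec(master_seed=7, days=(5, 6), ca_mM=(0.2,), n_per_cell=10)
cohort = syn.make_cohort(spec)
table = pl.quantify_necrosis_cohort([rec for rec, _ in cohort.leaf_images])

print(table.groupby("genotype")[["total_dead_area_px", "largest_spot_area_px", "y_rel"]]
      .mean().round(2))
for response in ("total_dead_area_px", "largest_spot_area_px", "y_rel"):
    res = st.two_way_anova(table, response)
    print(f"{response}: genotype p = {res.p_genotype:.4g}")
```

prints

```
          total_dead_area_px  largest_spot_area_px  y_rel
genotype
Col-0                3857.15               1767.33   0.60
gsl10-5              3327.25               2369.40   0.15
total_dead_area_px: genotype p = 0.2181
largest_spot_area_px: genotype p = 0.02095
y_rel: genotype p = 4.842e-05
```

Read: overall cell death does not differ between the wild type and the
callose-deficient mutant (p = 0.22), but the mutant's largest necrotic
spots are bigger (p = 0.02) and far less tip-biased (mean y_rel 0.15 vs
0.60, p < 10⁻⁴) — the signature of callose limiting necrosis spread
rather than cell-death initiation.

Real images are analyzed the same way through a CSV sample sheet
(`path,image_id,genotype,day,ca_mM,experiment,pixel_size_um,qc_excluded,qc_reason`)
and the CLI:

```sh
cotyquant quantify --sheet samples.csv --hue 120:200 --sat 120:255 --bri 0:190 \
    --min-area 20 --spot-floor 1000 --out results/
cotyquant position --sheet samples.csv --out positions.csv
cotyquant callose calibrate --controls controls.csv --out thr.yaml
cotyquant callose count --sheet callose.csv --thr thr.yaml --out callose_counts.csv
cotyquant stats anova --table results/cohort.csv --response total_dead_area_px --out anova.csv
```

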
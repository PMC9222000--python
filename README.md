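# nucleomorph

Nuclear morphometry for prostate-cancer grading: a reproducible pipeline
that measures a 38-descriptor battery on segmented nuclei and discriminates
low-grade (Gleason pattern ≤ 3) from high-grade (pattern ≥ 4) disease with
a 7-variable linear discriminant score.

Gleason grading is architectural and subject to substantial inter-observer
variability. An alternative signal lives inside the nuclei themselves:
size, boundary complexity, staining intensity and chromatin texture all
shift with grade. `nucleomorph` implements that idea end to end, for
pathology-image researchers who want the whole chain to be inspectable:

* **synth** — synthetic brightfield scenes of labeled nuclei with known
  ground truth, parameterised per grade group (G1–3 / G4 / G5) from
  published per-grade summary statistics, so the pipeline is testable
  without access to clinical slides;
* **morphometry** — per-nucleus descriptors: areas, chain-code perimeters
  (raw and corrected), centroid diameters and ferets on a 1° grid,
  moment-equivalent ellipse axes, box-counting fractal dimension of the
  boundary, gray levels per channel, optical density (OD = 256 − gray),
  integrated OD, and chromatin texture (margination, heterogeneity,
  clumpiness);
* **groupstats** — per-sample aggregation, one-way ANOVA across the three
  grade groups with Bonferroni pairwise post-hocs, and the chromatin/IOD
  summary table;
* **discriminant** — the published 7-variable discriminant score

  DS = 1331.50420234964 + 5.95568628644·r_min − 1479.27930311731·FD
  + 0.40274897061·gray_min + 0.53105523026·gray_max
  + 275.38324653827·margination − 0.89343166330·gray_green
  + 0.51289341737·gray_blue

  with decision cutoff −1.1134 (DS ≥ cutoff ⇒ high grade), plus
  Wilks-lambda forward stepwise LDA refitting and ROC analysis with
  Youden-optimal cutoff selection;
* **cli** — a `nucleomorph` command gluing the stages into a seeded,
  resumable pipeline.

## Worked example

```sh
nucleomorph run-all --grades 3,3,3 --nuclei 20 --image-size 384 --seed 1 --out demo
```

prints

```
wrote 9 scenes to demo/scenes
extracted 180 nuclei -> demo/features.csv
35 of 39 features significant at alpha=0.05
selected ['gray_blue', 'gray_green']; AUC=1.000 cutoff=0.4411 -> demo/model.json
scored 9 samples -> demo/scores.csv
AUC=1.000 cutoff=0.4411 sens=1.000 spec=1.000
pipeline complete -> demo
```

Reading it line by line: 9 synthetic biopsy scenes (3 per grade group, 20
nuclei each) are rendered and their 180 nuclei measured; 35 of the 39
feature columns separate the grade groups at α = 0.05 on this toy cohort;
stepwise selection builds a discriminant from the blue and green gray
levels (the channels whose per-grade means differ most in the generator);
the fitted scores separate low from high grade perfectly (AUC 1.0), and the
Youden-optimal cutoff 0.4411 classifies every sample correctly. The
per-sample output lands in `demo/scores.csv`:

```
sample_id,grade_group,score,call
g13_s00,G13,-36.94911795089831,low_grade_G13
g13_s01,G13,-35.086350838906355,low_grade_G13
...
```

To score samples with the published model instead of a refit one:

```sh
nucleomorph score --features demo/features.csv --model paper --out demo/paper_scores.csv
```

From Python, the same pieces compose directly:

```python
from nucleomorph import (CohortSpec, generate_cohort, extract_table,
                         aggregate, anova_screen, PAPER_MODEL, score)

cohort = generate_cohort(CohortSpec(n_samples_per_grade=(3, 3, 3),
                                    nuclei_per_sample=20, image_size=384,
                                    seed=1))
features = extract_table(cohort)          # one row per nucleus
samples = aggregate(features)             # one row per biopsy
screen = anova_screen(samples)            # per-feature ANOVA + Bonferroni
ds = score(samples.iloc[0], PAPER_MODEL)  # published discriminant score
```

## Layout

```
src/nucleomorph/     synth, morphometry, groupstats, discriminant, cli
src/nucleomorph/data/paper_model.json   the published model as a shipped asset
tests/               unit, property and acceptance suites
docs/methods.md      models, conventions, parameter choices, limitations
```
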
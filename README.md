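# phenonet

Cell-network tissue phenotyping for colorectal cancer histology, from
typed cell point maps to prognostic statistics for distant metastasis.

Whole-slide images of H&E-stained colorectal tumor sections can be
reduced, by cell detection/classification models, to *cell maps*: one
centroid per cell, labelled malignant epithelial (M), inflammatory
(I), spindle-shaped (S) or necrotic debris (N).  `phenonet` takes such
maps (and a categorical tissue mask from appearance-based
segmentation) and asks which cell types sit next to which, and what
that predicts:

1. **Cell networks** — each slide is cut into 200 × 200 µm tiles and
   each tile's cells are joined by their Delaunay triangulation, so an
   edge is a contact between neighbouring cells.  With 4 cell classes
   there are 10 connection types, and each tile becomes a
   10-component *connection-frequency* vector h on the simplex.
2. **Tissue phenotypes** — the pooled tile vectors of a cohort are
   clustered by k-medoids under the chi-squared distance
   d(h, m) = Σ (h_k − m_k)²/(h_k + m_k), with 100 random restarts and
   the minimum-cost replicate kept.  k is the largest value whose
   medoids stay ≥ 0.2 apart and whose per-case ratio features stay
   below |Spearman ρ| = 0.8.  On tissue this discovers phenotypes that
   read as smooth muscle, inflammation, tumor–stroma interface, tumor,
   stroma and necrosis.
3. **Per-case signatures** — the area ratio of each phenotype to the
   total tissue area (normal mucosa, fat and background excluded),
   appearance-based smooth-muscle and inflammation ratios,
   stroma–tumor and necrosis–tumor ratios, and the Morisita–Horn
   index of inflammatory/malignant spatial coexistence.
4. **Prognosis** — interquartile-scaled odds ratios (logistic,
   likelihood-ratio tests) and hazard ratios (Cox, score/Wald tests,
   bootstrap optimism-corrected AUC), Kaplan–Meier stratification at
   the minimum-p cutoff with Altman's correction, and multiple
   imputation with Rubin pooling for missing clinical data.

No patient data is included; a synthetic-data module simulates slides
(Poisson cell placement from six connection-frequency archetypes, plus
tissue masks) and cohorts (planted logistic and proportional-hazards
effects, right-censoring, missingness) so every stage runs and is
tested end to end.

## Worked example

Discover phenotypes from directly sampled tile vectors with a known
ground truth:

```python
import numpy as np
from phenonet.synthetic import default_archetypes, sample_frequency_vectors
from phenonet.phenotyping import kmedoids, assign_phenotypes, name_phenotypes
from sklearn.metrics import adjusted_rand_score

archetypes = default_archetypes()
vectors, truth = sample_frequency_vectors(archetypes, 100, concentration=150.0, seed=7)
model = kmedoids(vectors, k=6, n_restarts=100, seed=11)
labels = assign_phenotypes(model, vectors)
print("phenotypes:", name_phenotypes(model))
print("total cost:", round(model.cost, 2))
print("ARI vs planted archetypes:", adjusted_rand_score(truth, labels))
```

prints

```
phenotypes: ['tumor', 'smooth_muscle', 'inflammation', 'stroma', 'tumor_stroma_interface', 'necrosis']
total cost: 10.48
ARI vs planted archetypes: 1.0
```

— the six medoids land on the six planted archetypes (adjusted Rand
index 1.0 against the generator's labels), the total cost is the
summed chi-squared distance of all 600 tiles to their medoids, and the
dominant-pair heuristic names each medoid by the tissue pattern its
spectrum encodes.

The full analysis lives in `analysis/01_simulate_slides.py` through
`analysis/05_prognostic_analysis.py`: simulate a 30-case cohort, build
the tile networks, select k and fit the phenotype model, extract
per-case signatures, and run the prognostic battery.  Each script
prints what it found and writes its tables under `results/analysis/`.
On the default seeds the pipeline selects k = 6, and the prognostic
stage recovers the planted effect directions — e.g. an interquartile
increase in the smooth-muscle-like ratio multiplies the metastasis
odds by 2.43 while the inflammation-like ratio multiplies them by
0.03, matching the signs planted by the cohort generator.

A CLI mirrors the stages (`phenonet simulate`, `network`,
`phenotype fit/assign/select-k`, `stats logistic/cox/cutoff/impute`,
`run`); see `phenonet --help`.

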
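# plaqueomics

Analysis pipeline for fraction-resolved proteomics of advanced
atherosclerotic plaques.  Tissue proteins are solubilised sequentially
(0.5 M NaCl → SDS → 4 M GuHCl), separating the *soluble matrisome*, the
*cellular proteome* and the tightly bound *core matrisome*; the pipeline
takes the resulting log2 abundance matrices plus clinical metadata and
produces:

* **Differential signatures** — per-protein linear models with
  empirical-Bayes variance moderation.  For protein *g* with residual
  variance *s²_g* (*d_g* df), the moderated statistic is

      t̃_g = β̂_g / (u_g · s̃_g),   s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)

  on *d₀ + d_g* df, with the prior (d₀, s₀²) estimated across proteins by
  moment-matching of log s²_g (trigamma inversion), and Benjamini–Hochberg
  control across proteins.
* **Signature axes** — first-principal-component sample scores for the
  inflammation (S10A8/9, PERM, MMP9, …) and calcification (FETUA, OSTP,
  MGP, PROC, …) protein programs, which are strongly anti-correlated in
  plaque cores.
* **Matrisome networks** — Gaussian-copula (conditional) mutual information
  MI = −½·ln(1−ρ²) on normal scores, permutation-null edge significance,
  data-processing pruning of indirect edges, and average-linkage clusters
  with Fisher-exact enrichment.
* **Molecular plaque phenotypes** — PCA + k-means (k = 4) over the combined
  standardized proteome, point-biserial/Spearman characterization against
  clinical features, and Kaplan–Meier / log-rank survival stratification on
  the composite cardiovascular endpoint.
* **Minimal prognostic signatures** — NSGA-II over feature bitmasks and RBF
  SVM hyperparameters, trading mean stratified 10-fold CV AUC against
  subset size, plus elastic-net logistic regression for predicting
  phenotype clusters from plasma-style biomarkers.

Patient-level plaque cohorts are not redistributable, so the package ships
a synthetic cohort generator (`plaqueomics.synthetic`) that plants the
structure these analyses assume — anti-correlated inflammation/calcification
axes (r = −0.6), a sex-linked proteoglycan block anti-correlated with
estradiol, four molecular phenotypes, and hazards driven by a four-protein
signature (CNN1, PROC, SERPH, CSPG2) — with full ground truth for
validation.  See `docs/methods.md` for the model details and limitations.

## Worked example

The numbered drivers under `analysis/` run the full pipeline on the default
synthetic cohort and write tables under `results/`.  For example:

```bash
python analysis/01_simulate_cohort.py
python analysis/03_signature_axes.py
python analysis/06_outcome_prediction.py
```

prints (abridged):

```
cohort: 105 core samples; {'SDS': (1459, 105), 'NaCl': (283, 105), 'GuHCl': (286, 105)}
calcified: 60 symptomatic: 36 female: 29
latent inflammation~calcification r = -0.592

NaCl   inflammation~calcification r=-0.550 (p=1.2e-09)
GuHCl  inflammation~calcification r=-0.587 (p=4.6e-11)
proteoglycan block vs sex hits: OR=inf, q=0.0024

elastic net selected: ['MMP9', 'CATD', 'S10A8', 'S10A9', 'PERM', 'statin', 'echolucent']
planted prognostic proteins: ['CNN1', 'PROC', 'SERPH', 'CSPG2']
selected signature: ['CNN1', 'PROC', 'SERPH', 'CSPG2', 'NULL26']
CV AUC 83.8% (sd 11.9%)
```

Reading this: the generated cohort reproduces the planted axis
anti-correlation in both matrisome fractions; the sex-differential proteins
concentrate in the proteoglycan network cluster; all five plasma
inflammation biomarkers survive the elastic-net penalty; and the
evolutionary search recovers the four planted prognostic proteins (plus one
spurious passenger) with a cross-validated AUC of 84%.

The same functionality is scriptable through a thin CLI:

```bash
plaqueomics simulate --seed 7 --out cohort/
plaqueomics diff --abundance cohort/abundance_GuHCl.tsv --fraction GuHCl \
    --metadata cohort/metadata.tsv --contrast calcified \
    --covariates age,sex,statin --out diff.tsv
plaqueomics network --abundance cohort/abundance_GuHCl.tsv --fraction GuHCl \
    --n-perm 1000 --clusters 20 --out net.graphml
```

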
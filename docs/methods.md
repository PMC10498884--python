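# Methods

`plaqueomics` implements a fraction-resolved tissue-proteomics analysis of
advanced carotid plaques: per-protein differential abundance with
empirical-Bayes variance moderation, signature scoring, conditional-mutual-
information (CMI) association networks over the matrisome, unsupervised
molecular phenotyping with survival stratification, and supervised selection
of a minimal prognostic protein signature.  Because the patient-level cohorts
such analyses run on are not redistributable, the package ships a synthetic
cohort generator with planted ground truth; every statistical claim the test
suite and `scripts/acceptance.py` make is a recovery or calibration property
measured on those planted cohorts, or an equivalence against an independent
oracle.

## Data model

Proteins are extracted sequentially (0.5 M NaCl -> SDS -> 4 M GuHCl), giving
three abundance matrices per cohort: the *soluble matrisome* (NaCl), the
*cellular proteome* (SDS) and the *core matrisome* (GuHCl), each proteins x
samples on the log2 scale with missing values.  Metadata carries one row per
sample (region, sex, calcification, symptom status, statin use, age,
ultrasound class, follow-up and the composite cardiovascular endpoint,
optionally serum estradiol); the annotation table maps proteins to matrisome
classes and signature tags.

Filtering follows the conventional TMT workflow: proteins quantified in at
least 80% of samples are kept (`min_fraction_observed=0.8`, configurable),
matrisome fractions are restricted to ECM/extracellular proteins via the
annotation, and per-sample median centering is available for normalisation.
Missing values are handled by complete-case fitting in all inference
(differential models) and by per-protein median imputation only where a
complete matrix is mathematically required (PCA, k-means, network
reconstruction).  The rationale: imputation fabricates effect sizes in
per-protein inference but is harmless for variance-dominated matrix methods.

## Synthetic cohorts

The generator emulates a 105-core discovery cohort: 60 calcified, 36
symptomatic, 29 female samples.  (The three dichotomies cannot all sum to one
cohort size — the calcified comparison in real cohorts has its own
availability — so the noncalcified count is 45 here.)  Its components:

* **Latent axes.** Inflammation and calcification sample scores are drawn
  from an exact bivariate normal with correlation -0.6; weaker independent
  axes (proteoglycan, SMC, structural ECM) have sd 0.7.  Signature *anchor*
  proteins — S10A8/9, PERM, MMP9, TIMP1, DEF1, FRIL/FRIH, CD14, CATD, CATB,
  CD44 (inflammation); FETUA, OSTP, MGP, GAS6, FA9, FA10, PROC, PROZ, SPRC,
  OSTC (calcification); CSPG2, PGCA, HPLN1, HPLN3, SODE (proteoglycan);
  ACTA, TAGL, CNN1, CALD1 (SMC); CO1A1/2, CO3A1, SERPH (structural) — load
  on their axis with unit loading over noise sd 0.5.
* **Group labels from the axes.** Calcified = the top-60 samples by
  calcification propensity, symptomatic = top-36 by inflammation score,
  female = top-29 of a cluster-3-loaded propensity.  Deriving labels by
  ranking rather than adding independent group shifts keeps the planted axis
  correlation exactly -0.6 while still producing genuine group contrasts.
  Ground-truth log2FC per contrast is recorded as the *realized* noise-free
  group-mean difference, which is the exact estimand of the differential
  model under this mechanism.
* **Phenotypes.** Four molecular phenotype clusters (inflamed ECM-poor;
  SMC-rich; structural-ECM-high; calcified proteoglycan-rich,
  female-enriched) shift dedicated cluster-marker blocks (40 proteins per
  axis by default — tissue phenotype programs are large co-regulated protein
  sets).  `phenotype_separation` s scales the shift so that clusters at
  opposite centroid extremes differ by s within-noise sds per marker
  (default 3).  Marker blocks are distinct from the anchor blocks so axis
  recovery and phenotype recovery are separable properties.  The female and
  calcified propensities carry a cluster-3 bonus, making cluster 3 the
  female/calcified phenotype.
* **Sex and estradiol.** Proteoglycan anchors gain +0.8 log2 units in
  females (versican/aggrecan-type sex difference); estradiol is generated in
  females only with a negative slope (-0.5 sd) on the proteoglycan latent.
* **Survival.** Event times are exponential with log-hazard linear in the
  standardized noise-free abundance of CNN1 (-0.45), PROC (+0.45),
  SERPH (-0.45) and CSPG2 (+0.45), baseline 0.045 events/year,
  administrative censoring at 9 years plus exponential dropout (0.03/year),
  yielding roughly one third events.  Phenotype clusters are therefore not
  directly hazard-coupled: the cohort-level Kaplan-Meier demo across
  phenotypes is near-flat by construction, while the survival machinery is
  validated on its own planted two-group experiments.
* **Periphery (optional).** With `periphery=True` each patient gains a
  paired periphery sample whose molecular signal is attenuated (factor 0.4
  by default) around the same per-protein baseline — the disease processes
  concentrate in the core.  The default cohort is core-only, one sample per
  patient, so differential fits can treat samples as independent; a
  per-patient collapse is a pre-processing step (mean over a patient's core
  samples) the user applies before fitting if multiple cores per patient
  are simulated or supplied.
* **Missingness** is MCAR at 5% by default; an intensity-dependent mechanism
  (lower abundance, higher dropout — the real MS behaviour) is available but
  off by default so oracle computations stay simple.

What the generator does **not** emulate: peptide-level quantification, TMT
reporter compression and batch/plex structure, abundance-dependent
missingness (by default), core/periphery pairing beyond an optional
attenuated periphery matrix, and per-contrast sample availability.  Passing
the recovery tests therefore demonstrates correctness of the statistical
machinery under the stated generative assumptions, not performance on real
plaque data.

## Differential abundance

Each protein is fit by OLS on [intercept, contrast, covariates] over its
complete cases (defaults mirror the clinical adjustment: age, sex and statin
use; age and statin only for the sex contrast).  Residual variances are
shrunk by empirical Bayes: (d0, s0^2) are estimated once across proteins by
moment-matching the first two moments of log s_g^2 via digamma/trigamma
identities, with Newton inversion of the trigamma; non-positive excess
variance sets d0 = infinity (full shrinkage).  The moderated t uses the
posterior variance (d0 s0^2 + d_g s_g^2)/(d0 + d_g) on d0 + d_g df.  The
implementation agrees with the Bioconductor limma reference to ~1e-14 on the
same design (tested via Rscript), and holds its nominal type-I level on null
proteins with a planted prior.  Multiple testing uses Benjamini-Hochberg;
discovery-style scans report nominal p < 0.05, validation and enrichment use
q < 0.05 (both configurable).  One-vs-all cluster contrasts reduce to the
two-group model on an in-cluster indicator; top-n reports break ties by
|log2FC| then protein id so reports are deterministic.

## Signature scores, correlations, enrichment

A signature score is the first principal component of the standardized,
median-imputed member submatrix (samples as observations), sign-fixed so the
mean member loading is positive, then standardized.  Standardized (not raw)
abundances are used so high-variance members do not dominate the component.
Score-score correlations are Pearson or Spearman over shared samples;
protein-vs-marker-score matrices use Spearman with BH across the whole
matrix.  Set enrichment is the one-sided hypergeometric upper tail
(equivalently Fisher's exact test for enrichment) with BH across the sets
tested in one call; it agrees exactly with rational-arithmetic enumeration
for all tables with background <= 30.

## CMI network

Edge weights use a Gaussian-copula estimator: rank-transform each protein to
normal scores, then MI = -1/2 ln(1 - rho^2) nats with rho the (partial)
normal-scores correlation — closed-form, fast, and invariant to monotone
transforms of the raw intensities.  Edge significance: per permutation one
side of the pairing is shuffled over samples and the full null
cross-correlation matrix is computed at once (marginally per pair this is
exactly the shuffle-one-vector null); p = (1 + #null >= obs)/(1 + B),
B = 1000 by default, BH across pairs, keep q <= 0.05.  Indirect edges are
pruned ARACNE-style: for each kept edge the conditional MI given every
common neighbour is computed from partial correlations, and the edge is
dropped when min_k CMI(i;j|k) < 0.05 x MI — the signature of a chain.
Clusters come from average-linkage hierarchical clustering on
1 - |Spearman rho|, cut at 20 clusters per fraction by default; cluster
enrichment reuses the Fisher machinery.  GraphML export carries mi, cmi_min,
q and cluster attributes.

## Phenotyping and survival

The combined matrix z-scores each protein within its fraction after median
imputation, drops constant rows, and stacks fractions over the shared
samples.  PCA is a centered SVD with deterministic orientation (largest-
|loading| protein positive per component).  K-means (k-means++ seeding,
best of 25 starts) runs on the leading components; cluster ids are
renumbered by descending size for reproducibility — no claim is made that
they match any particular published numbering.  The display default retains
3 components; the *recovery experiment* retains 5, because in the synthetic
cohort the continuous inflammation/calcification continuum occupies the top
component and the three cluster discriminants sit beneath it.  A silhouette
scan over k = 2..8 is reported but not used for selection.  Cluster
characterization correlates one-hot cluster indicators with features —
point-biserial (Pearson on the 0/1 coding) for binary features, Spearman for
continuous — with BH across the whole matrix.  Survival uses the
Kaplan-Meier product-limit estimator per stratum and the unweighted
(Mantel-Haenszel) k-sample log-rank test, both via lifelines; the KM curve
equals the empirical survival function when censoring is absent, and the
log-rank permutation null is calibrated in the tests.

## Prediction

*Elastic net.* Penalized logistic regression (scikit-learn saga) with the
penalty chosen by stratified CV on deviance over a 26-point log-spaced C
grid.  By default the refit applies the 1-SE rule — the strongest penalty
within one standard error of the optimal CV deviance — the conventional
parsimony choice for selection; the deviance-minimising penalty was found to
admit over half of the null features in planted-truth checks.

*Minimal prognostic signature.* An NSGA-II loop searches chromosomes that
concatenate a feature bitmask with real-coded (log2 C, log2 gamma) for an
RBF SVM; objectives are (maximize mean stratified 10-fold CV AUC, minimize
subset size).  Operators: binary tournament on (rank, crowding), uniform
crossover on masks with arithmetic crossover on the reals, 1/L bit-flip and
occasional Gaussian hyperparameter mutation, empty masks repaired by
activating one random bit.  Defaults: population 64, generations 100,
log2 C in [-5, 15], log2 gamma in [-15, 3]; convergence-based early stopping
(front unchanged for N generations) is available and used in the validation
experiments.  Fold splits are drawn once per run and shared by all
individuals (common random numbers); because a fixed partition can be
overfit by the search, the final front is re-scored on an independent
validation fold assignment, and the reported AUCs, the non-dominated filter
and the parsimony rule (smallest subset within 0.01 of the best AUC) all use
those validation scores.  Per-fold AUCs use the rank-sum identity and
per-fold standardization computed once, which keeps an evaluation at the
cost of ten small SVM fits.  SVM fits are iteration-capped (max_iter=2000)
so pathological hyperparameter corners cannot dominate the runtime; weak
fits lose tournaments anyway.

The "best same-size null subset" baseline in the recovery experiment is made
tractable by exhaustively enumerating same-size subsets of the top-8 null
features ranked by single-feature CV AUC (with a small C grid): under the
null, combinations of individually chance-level features do not materially
beat the best-univariate pool, so the restriction is a faithful oracle at
desk scale.

## Problem sizes and numerical choices

Validation experiments run on reduced cohorts chosen so planted structure is
identifiable and runs stay fast: axis recovery uses 60-100 proteins per
fraction over 200 seeds, with each signature block padded to realistic size
(anchors plus 12 generic co-regulated members, via `extra_axis_members`)
because first-PC scores of very small signatures are attenuated relative to
the latent axis; phenotype recovery uses ~420 proteins over 100
seeds (small enough that the planted spikes exceed the Marchenko-Pastur bulk
after per-protein z-scoring at n = 105); the chain-pruning check uses
triples of n = 2000 over 100 seeds; log-rank power uses 500 two-group
replicates; signature recovery uses 20 replicates of n = 200 with
population 32 / 40 generations.  The eBayes calibration averages three
replicates of the 2000-protein experiment because a single replicate's
type-I estimate has Monte-Carlo sd ~0.005.

Other numerical conventions: trigamma inversion iterates Newton to relative
1e-10; MI correlations are clipped below 1 so the log stays finite; PCA uses
the full (deterministic) SVD solver; k-means determinism comes from a fixed
seed plus size-ordered relabeling; all randomness flows from
`numpy.random.default_rng` seeds, and regenerating any cohort with the same
config is bit-identical.

## Known limitations

Headline numbers from patient cohorts (cross-validated AUCs of published
plaque signatures, cohort-specific correlations) are functions of
unreleased data and are not reproduced here; the package validates the
*procedures* by planted-truth recovery instead.  The CMI estimator captures
monotone dependence only; the permutation null shares permutations across
pairs (exact marginally, mildly dependent jointly — BH is applied as usual);
and the MOEA, like any stochastic search, guarantees recovery only in the
statistical sense measured by the experiments.
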
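# Methods

This note documents the models, defaults, and design choices behind
`cocatype`, and what the synthetic validation does and does not establish.

## Synthetic cohorts

`cocatype.synthetic` generates matched multi-omics cohorts with planted
five-subtype structure. The generative choices, all additive and
deliberately simple so that each planted effect has a closed-form oracle:

* **Mutations.** Each sample's total substitution count is Poisson (mean
  100, a typical exome burden for TP53-mutant tumors). Trinucleotide
  contexts are drawn from the sample's mixture of signature profiles;
  per-sample signature exposures are Dirichlet, with each subtype's own
  signature up-weighted (concentration 8 vs 0.5) in the subtyped cohort.
  Profiles are sparse Dirichlet(0.15) draws over the 96 classes unless
  supplied. Half of all records are emitted on the purine strand to
  exercise pyrimidine normalization; no reference genome is consulted —
  the downstream motif matrix needs only context counts. Gene-level driver
  status is Bernoulli (default 0.6 in-subtype vs 0.05 background) over a
  127-gene consumed SMG-style list.
* **Copy number.** 84 abstract focal loci on the 5-level GISTIC scale.
  Background alteration ≈ 8% per entry, mostly shallow. Each subtype gets
  10 subtype-linked fragments at frequency 0.6 (one amplified and one
  deleted *driver* coupled to a mapped gene's expression at ±1.5 log2
  units, plus eight uncoupled fragments providing platform signal).
* **Methylation.** β values follow a two-mode Beta mixture — unmethylated
  Beta(2,10), methylated Beta(10,2) — matching the bimodality that the
  β ≥ 0.3 dichotomization assumes. Each subtype carries a block of
  hypermethylation-prone probes (frequency 0.8), one of which is a driver
  CpG depressing its gene's expression by −2·β. Normal-tissue β is
  Beta(2,20) for informative probes; a constitutively methylated background
  stratum, chrX probes, and SNP-overlapping probes exercise all three
  filter criteria.
* **Expression.** log2(TPM+0.001)-scale values: per-gene baseline
  Uniform(2,8) plus unit Gaussian noise, subtype marker shifts (+1.5 in 12
  genes per subtype), an inhibitory-checkpoint shift (+1.5 in the focal
  subtype's 15 inhibitory genes), and the driver couplings above. On top
  sits a shared low-rank component: 15 latent factors with per-gene
  loadings N(0, 0.32) and per-sample N(0,1) scores, spread over a
  ~2,700-gene universe. These factors emulate the dominant
  subtype-independent programs (proliferation, stroma, immune infiltrate)
  that real bulk cohorts show; without them, every axis of expression
  variation is subtype-linked and any projection-based screen (notably the
  imputed-AUC drug screen) sees spurious subtype contrasts everywhere.
  Loadings are fixed by the config seed so tumor cohorts and cell-line
  panels share them.
* **Survival.** Exponential event times with subtype-specific hazards
  (default 0.05/month; 0.15 in the focal subtype, i.e. HR 3), independent
  censoring: with probability 0.3 a subject is censored uniformly before
  its event. DSS mirrors OS with 10% of deaths reassigned to other causes.
* **Cell-line panels.** Same gene universe and subtype shifts; drug AUC =
  Uniform(3,7) drug baseline + N(0,0.5) noise + planted (drug, subtype)
  effects (default −1.0 for a sensitive pair); missing entries MCAR.

What passing tests show: each stage correctly recovers structure *of the
kind it assumes*, at realistic effect sizes and noise levels, with
controlled error on null data. What they do not show: robustness to
features the generator omits — batch effects beyond location/scale,
copy-number/methylation co-dependence, subclonality, non-proportional
hazards, informative censoring, or the heavy-tailed count noise of real
RNA-seq.

## Numerical and algorithmic choices

* **NMF.** Multiplicative updates under generalized Kullback–Leibler
  divergence (the Brunet variant standard for mutation signatures), via
  scikit-learn's `solver="mu"`; convergence at relative objective change
  < 1e-6 or 2,000 iterations; 50 restarts per rank by default (20 in the
  pipeline's desk-scale defaults), restart seeds derived from the master
  seed. Zero-count samples are excluded from factorization and given zero
  exposures. Signatures are row-normalized, exposures rescaled to preserve
  W·H.
* **Rank selection.** Restart stability per rank is the cophenetic
  correlation of the argmax-exposure consensus matrix. The selected rank
  is the largest rank before the first successive drop of the coefficient
  exceeding a tolerance (default 0.05). Observed curves often decline
  gently (a few 0.01 per rank) without any drop that large; in that regime
  "begins to fall" is operationalized as the stability peak — the global
  argmax, ties to the smaller rank. The alternative reading "largest rank
  within tolerance of the maximum" was rejected: on gently declining
  curves it always admits ranks past the peak, selecting the top of the
  evaluated range regardless of where stability actually degrades.
* **Clustering.** scipy's `ward` on raw observations (the Ward.D2
  convention: squared-Euclidean updates, unsquared inputs) and `average`
  linkage; cluster labels renumbered 1..k by first occurrence. `choose_k`
  maximizes mean silhouette width (ties to smaller k) — a stand-in for the
  unstated criterion of the original workflow's `eclust` step. Trinary
  copy-number values are treated as numeric under Euclidean distance.
* **Consensus integration.** Item fraction 0.8; 1,000 repetitions by
  default (250 in the pipeline's desk-scale defaults); features are never
  subsampled. Samples are processed in sorted-id order internally, making
  the result invariant to input permutation. Consensus = co-cluster count /
  co-sample count (never-co-sampled pairs → 0, counted and warned). Final
  labels come from average-linkage clustering of 1 − consensus at the
  selected K (the Monti convention), not from a single full-data
  clustering. K is the largest K with relative CDF-area gain
  Δ(K) = (A(K)−A(K−1))/A(K−1) ≥ 0.05, falling back to the smallest K when
  nothing qualifies.
* **Exact tests.** The two-sided Fisher P sums hypergeometric point
  probabilities ≤ the observed one, with a 1e-12 relative tie slack
  (distinct point masses on small tables differ by ≫ that, so the slack
  only absorbs float noise on exact ties). χ² tests are Pearson without
  continuity correction and fall back to Fisher whenever an expected cell
  is < 5 or a margin is empty. Driver screens use the raw thresholds
  P < 0.001 (enrichment) and P < 0.05 (concordance) with no
  multiple-testing correction, as the screening design specifies;
  Benjamini–Hochberg is available but off by default.
* **Driver conventions.** "Consistently enriched in one subtype" =
  significant-and-enriched in exactly one subtype one-vs-rest *and* that
  subtype carries the maximal alteration frequency. Concordance is
  one-sided (direction fixed by event type) and uses a rank-sum test for
  binary alteration indicators, Pearson correlation for continuous β. The
  pairwise-χ² requirement for methylation drivers is enforced on all pairs
  involving the candidate (most-methylated) subtype; an all-pairs switch
  exists. Precision/recall against planted truth scores enriched events
  only — a depleted call is the logical complement of an enrichment
  elsewhere, not a false positive.
* **ssGSEA.** Running-sum form: descending expression ranking
  (deterministic tie-break by gene id), in-set ECDF weighted by
  |value|^exponent (default 0.25), uniform out-of-set ECDF, score = sum of
  differences. Exponent 0 gives rank-only (monotone-invariant) scores.
  Cross-sample range normalization is off for single-sample use. Exact
  stimulatory/inhibitory ties are categorized stimulatory (fixed rule).
  The checkpoint sets are inputs (GMT); the repository ships a synthetic
  placeholder (`data/checkpoint_sets_synthetic.gmt`), not a curated list.
* **Classifier.** Lasso = L1-penalized logistic regression on per-gene
  standardized training expression; the penalty α is the per-observation
  L1 weight (sklearn C = 1/(n·α)), default 0.0015. Automatic selection
  uses repeated stratified 5-fold cross-validated deviance with the 1-SE
  rule (sparsest penalty within one standard error of the minimum);
  the repeat count defaults to 100, scaled down from the original
  workflow's 10,000 runs, with equivalent selection stability. Cohort
  harmonization = restrict to shared genes, z-score per gene within each
  cohort (idempotent; removes location/scale batch differences); an
  empirical-Bayes option is deliberately not implemented — the simple
  version is the documented stand-in for the unnamed "debatch" step. The
  neural net is a 500→1500→1700 fully connected softmax classifier (Adam,
  batch 200, 50 epochs, learning rate 0.001); CART is included alongside
  the six Methods-named algorithms. Model selection = argmax validation
  accuracy under the 80/20 stratified split.
* **Drug screen.** KNN imputation operates over drug rows (k = 5,
  RMS distance on co-observed cell lines), strictly after removing drugs
  > 20% missing — an over-missing drug never receives imputed values.
  Patient AUC = ridge regression of panel AUC on harmonized cell-line
  expression applied to harmonized patient expression; penalty by
  leave-one-out GCV over a log grid (no Box-Cox/power transform: the
  synthetic AUCs are linear-scale by construction; a transform targets
  IC50 skew). Per-drug comparisons pool all patients (two-sided rank-sum
  by default, Welch t optional); candidates must be significant with the
  lower-AUC direction in *both* panels, ranked by the worse of the two Ps.
* **Survival.** lifelines for KM/log-rank and Efron-tie Cox fits;
  Breslow ties route through statsmodels PHReg. OS and DSS are separate
  endpoint columns of one clinical table. Note that Efron's correction is
  not invariant under subject duplication (Breslow is); the tests pin this
  down.
* **Pipeline.** Stage seeds are `crc32(master_seed:stage_name)`, so stages
  have decoupled RNG streams and any stage can be disabled without
  perturbing the others. The cohort inclusion rule keeps cancer types with
  TP53-mutant frequency strictly > 0.10 and strictly > 50 complete-profile
  mutant samples. The methylation stage clamps the 1,000-site default to
  the retained-probe count on small synthetic cohorts (logged). The focal
  subtype is identified operationally as the COCA cluster with the most
  significant inhibitory-category enrichment.

## Problem sizes used in validation

Validation runs are sized for a single core: end-to-end recovery uses
n = 500 cohorts over 20 seeds (integration stages only — downstream stages
cannot alter the measured labels); signature recovery n = 200 over 10
seeds with 30 restarts; driver recovery n = 300 over 20 seeds plus 200
null simulations; the drug screen 150 cell lines × 51 drugs × 2 panels
over 20 seeds; survival 100–200 simulations at n = 200. The acceptance
script reports the same quantities at slightly reduced replication.

## Known limitations

* The cophenetic fall rule inherits the verbal vagueness of its source;
  on cohorts whose signature structure stays stable at higher ranks
  (near-one-hot exposures), rank over-selection is expected and harmless
  for exposure clustering, but rank values should not be over-interpreted.
* The CDF-area Δ rule occasionally over-splits (selects K above the
  planted 5) on noisy seeds; the extra clusters are small and ARI remains
  high, but K itself is a stochastic estimate.
* Criterion (a) of the CpG filter reads "β > 0.3 in no more than 5
  samples" as *normal* samples (the clause sits inside the normal-tissue
  criterion); a config switch flips the interpretation.
* The drug screen's rank-sum on imputed AUCs is scale-free: its null
  behavior depends on patient expression having dominant non-subtype
  variation (true of real cohorts, built into the generator). On data
  where all variation is subtype-linked the screen is anti-conservative
  by construction.
* All couplings in the generator are stand-ins chosen for testability;
  none estimate the joint distribution of real TCGA omics layers.
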
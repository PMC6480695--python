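# Methods

## Problem and scope

`icb-bench` benchmarks published predictive biomarkers of response to
immune-checkpoint inhibitors (anti-PD-1 / anti-PD-L1 / anti-CTLA4) and asks
whether combining them predicts better than any single one. It implements the
complete analysis chain over per-study inputs — a TPM expression matrix, a
MAF-like somatic mutation list, and a clinical table — and ships a
synthetic-cohort generator with known ground truth so the whole chain runs and
is testable without any external downloads. The package never recomputes the
TIDE or ImmunoPhenoScore algorithms: they are published external methods and
enter as plug-in score columns (the IPS gene list is stored for reference
only).

## Marker panel and scoring

The built-in panel has 18 markers: nine single immune genes (CD274, PDCD1,
PDCD1LG2, CTLA4, POLE, POLE2, POLE3, POLE4, AXL), six expression signatures
(IFN-γ reduced, 6 genes; IFN-γ expanded, 18; three ICB-resistance signatures of
14/4/2 genes; the 10-gene AXL pathway), tumor mutational load from WES, and
two plug-ins (TIDE, IPS).

Scoring rules:

* single gene — `log2(TPM + 1)`;
* gene-set signature — arithmetic mean of `log2(TPM + 1)` over the member
  genes found in the matrix. The source analyses do not state their
  aggregation rule; the mean of log-transformed values is the minimal
  convention for score-level signatures and is recorded in the run manifest.
  Member genes absent from a matrix are skipped (public matrices differ in
  symbol dialects) and reported, rather than failing; gene-symbol matching is
  exact and case-sensitive after whitespace trimming — alias resolution is
  deliberately out of scope (determinism over recall);
* mutational load — the raw variant-record count per patient ("absolute
  number of mutations"); duplicated records count as listed unless the dedup
  flag is set;
* TPM and FPKM are accepted interchangeably via a config flag; no cross-unit
  conversion is attempted.

## Response labelling

Clinical benefit is heterogeneous across source studies, so study vocabularies
are first mapped (user-supplied key-value config) onto six canonical codes and
then collapsed: CR, PR, SD and LB are responders; PD is rescued into the
responder group only when overall survival is known and strictly greater than
the cutoff (default 2 years); PD otherwise, and NB, are non-responders.
Survival equal to the cutoff is non-responder (the rescue is strict). Times
are converted internally to days with 1 year = 365.25 days. The rule is
monotone in the cutoff: raising it can only shrink the responder set.

## Individual marker evaluation

Each marker on each cohort is evaluated by an empirical ROC over every
achievable cutpoint: candidates are the midpoints between consecutive distinct
sorted scores plus ±∞, with "predict responder" meaning oriented score ≥
threshold. The trapezoidal area under this curve equals the Mann–Whitney pair
statistic with ties contributing ½ (property-tested against an O(n²) oracle).
The operating point maximizes Youden's J = sensitivity + specificity − 1,
computed on exact integer counts so mathematically tied cutpoints tie
bit-for-bit; ties break toward the smallest threshold (the most sensitive
cutoff).

Orientation is automatic: markers anti-correlated with response (resistance
signatures, AXL) are negated so the reported AUC is ≥ 0.5, with the direction
recorded. Patients missing a marker's score are excluded from that marker's
evaluation (complete-case per marker). AUC confidence intervals are not
computed. Per-marker AUCs are then joined across cohorts into min/mean/max and
their spread.

With the default availability pattern (RNA in three of five studies, WES in
all five) the 17 RNA markers and 1 DNA marker yield 17×3 + 1×5 = 56
evaluations.

## Combination by majority voting

The RNA cohorts are stacked into one merged set (118 patients under the
default shape), keeping each marker's *cohort-specific* Youden calls — the
per-dataset cutpoint step is deliberately reused rather than re-fit on the
merged data (a config switch allows re-fitting). Mutational load joins the
merged set when WES is present in every merged cohort.

Before searching, markers correlated at |Pearson r| > 0.5 with two-sided
p < 0.01 (pairwise-complete continuous scores) are pruned by removing a
**minimum vertex cover** of the correlation graph — the smallest marker set
whose removal eliminates every strong pair. The search is exact (feasible for
panels ≤ ~20 markers) and verified against exhaustive enumeration; ties
between equal-size covers are broken by removing the markers with the lowest
priority (default: mean individual AUC), so the better marker of a correlated
pair survives.

Every subset of ≥ 2 retained markers is then scored: a patient is predicted
responder when at least half the subset's calls vote responder (an exact tie
is a responder vote, reading "at least half" literally; a flag flips this).
For n retained markers there are Σ_{j=2}^{n} C(n,j) = 2ⁿ − n − 1 subsets —
131,054 for n = 17. A dichotomous predictor has a one-point ROC, so its AUC is
(sensitivity + specificity)/2. The search is vectorized over all subsets of
each size (one int8 matrix product per size) and completes in a few seconds
at n = 17 × ~120 patients. Combinations with AUC ≥ 0.65 are "acceptable", and
each marker's containment frequency among them is reported.

## GLM ensemble

The retained dichotomous calls also feed a binomial GLM (logit link) fitted by
plain maximum likelihood (statsmodels; no penalization). One full-data fit
provides the coefficient table — estimate, standard error, Wald statistic and
two-sided p-value from the normal approximation (the column is labelled
`t_value` to match the conventional supplementary-table header), with flags at
1% and 5%. Complete separation is detected (diverging coefficient norm or
non-finite standard errors) and flagged, masking the p-values, rather than
silently regularized: with 17 binary features on ~118 patients separation is a
real possibility and hiding it would fabricate inference.

Discrimination is estimated by repeated holdout: 10,000 iterations by default
(1,000 in the bundled scaled runs), each drawing a simple-random 20% test set
("randomly selected", with no stratification implied; a stratified option
exists), refitting on the remaining 80%, and computing the test ROC's AUC plus
its Youden-optimal ("best") sensitivity and specificity. Predicted
probabilities are *not* orientation-flipped — they already point toward
response, and flipping would bias a null model's mean AUC above 0.5.
Iterations whose train or test set lacks a class are skipped and counted; more
than 50% degenerate iterations raises an error. Everything is deterministic
given the seed.

## Synthetic cohort generator

The generator emulates the published study landscape: five cohorts (three
RNA+WES of 28/49/41 patients, two WES-only of 33/63), responder fractions
0.38–0.70, and per-marker effects spanning null to strongly predictive.

The model draws response first and conditions scores on it. Each marker's
latent score is `baseline + δ·y + e` with unit-variance residuals, so the
theoretical AUC has the binormal closed form Φ(δ/√2) — the anchor for the
calibration tests. Key parameters (all on `SimulationConfig`):

* `marker_effects` — per-marker δ, in residual standard deviations. Defaults
  are calibrated to the cross-study picture reported for these markers (TIDE
  strongest with mean AUC ≈ 0.71; the first ICB-resistance signature and
  CTLA4 ≈ 0.66–0.67; several members effectively null; resistance signatures
  and AXL negative, i.e. anti-correlated with response).
* `background_correlation` (0.3) — equicorrelation of all marker residuals,
  emulating the shared immune-activation signal that makes these markers
  partially redundant readouts rather than independent tests.
* `marker_correlations` — explicitly targeted Pearson pairs, induced through
  a Gaussian copula on the residuals; the residual correlation is solved from
  the target so the *observed* mixture correlation lands on it (±0.1 at
  n ≥ 200). The default configures one strong pair (PDCD1 with the reduced
  IFN-γ signature, r = 0.6), mirroring the one high-correlation pair the
  correlation-filter stage is meant to remove.
* `effect_heterogeneity` (0.3, relative) — each cohort realizes its own
  multiplicative version of every effect, emulating cross-study variability
  (tumor types, platforms, response criteria); multiplicative so true nulls
  stay exactly null.
* Expression back-fill: a gene owned by a single-gene marker carries that
  marker's latent exactly; every other panel gene belongs to the *first*
  gene-set signature containing it and gets the owner's latent plus
  independent N(0, `gene_noise_sd`=1) noise; `TPM = 2^max(log-value, 0) − 1`
  (the floor keeps TPM ≥ 0; `baseline_log_expression` = 5 keeps it rarely
  binding). Mean-of-log scoring then recovers the latent signature score.
  First-owner assignment (rather than averaging all parents) keeps the
  incidental correlation between the overlapping IFN-γ signatures near 0.3,
  clearly separated from the configured 0.6 pair. Genes shared across
  signatures (e.g. AXL in three markers) still induce mild, realistic
  coupling. 100 background genes with iid lognormal expression pad the
  matrix.
* Mutational load maps its latent through the Gaussian CDF onto a negative
  binomial (mean 200, dispersion 2 — whole-exome counts typical of melanoma),
  a rank-preserving transform so the configured AUC survives up to count
  ties; each count expands into that many MAF-like records.
* Clinical draw: responder categories CR/PR/SD/LB (0.2/0.4/0.3/0.1) with a
  `pd_longterm_fraction` (0.1) of responders instead labelled PD with
  exponential survival shifted beyond the 2-year cutoff; non-responders are
  NB (0.2) or PD with truncated-exponential survival below the cutoff, a
  fraction (`os_unknown_fraction` = 0.15) with survival unknown. By
  construction the survival-rescue labelling rule recovers the latent status
  exactly. Survival units (days/months/years) are stored explicitly.

Same seed ⇒ byte-identical output files (per-cohort generators are spawned
from one seed sequence).

### What the generator does and does not capture

It captures the pieces the pipeline's logic depends on: cohort shapes and
availability patterns, class balance, marker effect sizes with a closed-form
AUC anchor, inter-marker correlation (configured and incidental), cross-study
heterogeneity, count-valued mutational load, and survival-dependent labels.
It does **not** simulate read-level data, batch or platform effects, tumor
clonal evolution, or the messy vocabulary mapping of real clinical tables —
distributional details beyond counts and the responder range are stand-ins.

One consequence deserves emphasis: because per-cohort Youden cutpoints are
optimized in-sample on 28–49 patients and the merged combination search is
evaluated on those same calls, dichotomous performance is optimistic, and with
roughly half the synthetic panel carrying consistent signal nearly all
majority-vote subsets clear the 0.65 AUC floor and the holdout GLM reaches a
mean AUC around 0.9. Real cohorts — with weaker, less consistent markers —
sit far lower at the combination stage. Passing tests therefore validate the
pipeline's arithmetic and algorithms, not any claim about how real biomarker
panels will combine.

## Numerical choices and degenerate inputs

* Youden maximization uses exact integer counts (`tp·N − fp·P`), making
  cutpoint ties exact; ties break to the smallest threshold.
* Scores equal to a threshold predict positive (≥ rule).
* Single-class label vectors raise a degenerate-labels error everywhere; a
  marker with all-identical scores yields a flat ROC with AUC 0.5 and a
  warning.
* Correlation of a constant marker column is undefined and raises, naming the
  marker; correlation pairs need ≥ 3 complete observations.
* Duplicate gene rows in an expression file collapse by per-patient maximum
  with a warning; duplicate patient columns are an error; non-numeric cells
  are reported with row/column coordinates.
* Subset iteration is lexicographic within increasing size; combination
  output is sorted by AUC descending, then size ascending, for stable diffs.
* The correlation matrix used by the generator is projected to the nearest
  well-conditioned correlation matrix when target pairs make it indefinite.

## Problem sizes

The bundled analyses and the acceptance script run the generator's default
five-cohort study (214 patients, 118 in the merged RNA set), the full
exhaustive search over the retained markers (131,054 subsets when 17 are
retained), and a 1,000-iteration holdout GLM; the library default for the
holdout remains 10,000 iterations, which completes in well under a minute at
this scale. Oracle-based tests use 100–200 random instances of ≤ 50 points
and GLM parameter recovery uses 100 replicates at n = 2000.

## Known limitations

* The dichotomous-combination "AUC" is the one-point ROC value
  (sens + spec)/2; it is not comparable to a continuous marker's AUC.
* Minimum-vertex-cover pruning is exponential in the number of
  correlation-involved markers; it is exact and fast for panels ≤ 20 but not
  meant for hundreds of features.
* No survival modelling beyond the 2-year rescue rule; no multi-class ROC.
* Plug-in scores are taken at face value; identifier mismatches are fatal by
  design.
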
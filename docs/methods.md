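# Methods

## The integration model

`mirmeta` treats miRNA–target prediction as a meta-classification problem:
the unit of analysis is a (miRNA, target) pair, the inputs are whatever a
panel of published predictors said about that pair, and the output is a
binary binding call. The integrator is a soft-margin kernel SVM; the
contribution of this package is everything around it — the encoding that
makes eleven heterogeneous tools commensurable, the energy-stratified
construction of training sets, the CHL-driven feature selection, and the
evaluation conventions.

### Evaluation panel and the CHL index

All evaluation flows through confusion counts (TP, FN, FP, TN). Beyond the
standard Sn, Sp, Acc, Precision, F1 and MCC, the panel carries
MCC′ = (MCC + 1)/2 (an affine bijection of [−1, 1] onto [0, 1]) and the CHL
index, the harmonic mean of Acc, MCC′ and F1. Acc alone is vulnerable to
the accuracy paradox, F1 ignores true negatives entirely, and MCC rewards
degenerate all-negative predictors on imbalanced data; the harmonic mean of
the three sits between F1's positive focus and MCC's symmetry.

Undefined-value conventions (they matter for degenerate predictors, which
occur routinely when low-coverage tools are scored):

* Precision and F1 are **undefined** when the predictor makes no positive
  call (TP + FP = 0); CHL is undefined whenever F1 is. Reports render these
  as the literal string `null`.
* MCC with a vanishing denominator is **0**, the standard convention for
  all-positive/all-negative predictors. Consequently an all-negative
  predictor prints MCC 0.0000 and MCC′ 0.5000 alongside `null` F1/CHL.
* `chl_index` on explicit inputs returns 0 if an input is 0 but some
  pairwise product is positive, and undefined if all pairwise products
  vanish.

Values are carried at full precision; reports round half-up to 4 decimals.
`counts_from_rates` inverts printed Sn/Sp back to integer counts (nearest
rate; ties to the larger count — an arbitrary but fixed rule) so published
tables that print only rates can be checked for internal consistency. The
shipped benchmark fixture contains 42 published panel rows; one row is
flagged because its printed MCC and MCC′ disagree arithmetically (the CHL
cell coheres with MCC′, so the MCC cell is presumably a typo), and the
MCC→MCC′ identity check exempts exactly that row.

### Feature encoding

The `FeatureRegistry` fixes the order and meaning of every dimension. The
shipped default has 68 dimensions over six categories (energy, scoring
function, evolution evidence, binding type, sequence property, structure).
Encoding rules:

* **Continuous fields** (scores, p-values, energies) are copied verbatim;
  min–max scaling to [0, 1] happens at training time and the parameters are
  stored with the model (new data is clipped).
* **Seed types** are a 7-dimensional indicator pooled across the
  seed-reporting tools (TargetScan, PITA, MBSTAR, STarMirDB). The canonical
  list — 8mer, 7mer-m8, 7mer-A1, 6mer, offset-6mer, CDS-seed, seedless —
  is configurable; the default order is fixed in the registry.
* **Binding ranges** from range-aware tools (TargetScan, miRanda,
  RNAduplex, STarMirDB) become the nucleotide composition of the bound
  subsequence (A/C/G/U fractions, summing to 1, plus AU content).
  Position-only tools (PITA, MBSTAR, RNAhybrid) contribute a
  start/length-normalized scalar in [0, 1], a deliberate design choice
  where no numeric scheme is standard.
* **Categorical calls** (miRanda's score×conservation quartet, STarMirDB's
  region×seed sextet) are one-hot groups.
* **Missing results are zero**, not NA: a tool that did not score a pair
  contributes 0 in every dimension it sources. Absence of a prediction is
  itself informative for a meta-classifier.
* Coordinates are 1-based inclusive on the target, 5′→3′; DNA input is
  silently mapped to RNA (T→U). A converter from 0-based half-open
  intervals is provided.

Duplicate records from one tool for one pair are an error by default; an
opt-in aggregation rule keeps the record with the most stable energy.

### Training sets from the energy distribution

Binding free energy (kcal/mol, more negative = more stable) stratifies the
interaction table. For M miRNAs:

* **trA** (2M records): per miRNA, the most stable candidate is labelled
  positive and the most unstable negative.
* **trB** (4M): the two most stable vs the two most unstable.
* **trC** (4M): the extreme pair plus the two candidates nearest the
  per-miRNA *median* energy ("mid-range" is not standardized; nearest the
  median with ties to the more stable is this package's documented
  heuristic, and the more stable of the two mid-range picks is labelled
  positive).
* **trR**: a uniform seeded sample of a requested size (default 4M).

When a miRNA has fewer candidates than its quota, unfilled positive slots
are borrowed from the globally most stable unused pairs and negative slots
from the globally most unstable, so totals stay exactly 2M/4M. Energy ties
break by target id. The energy-extreme labels are a training convention —
the stable half of a curated positive database is the most trustworthy,
the unstable half the least — not a biological negative set; permutation
negatives (uniform draws from the miRNA × gene space minus known
positives) provide genuinely non-interacting pairs, and `enforce_pn_ratio`
subsamples to an exact positive:negative ratio (1:1 by default in the
pipeline).

### Feature selection

Relevance and redundancy are plug-in mutual information in bits.
Continuous features are discretized by equal-frequency binning, 10 bins by
default (no MI estimator is canonical here; equal-frequency binning is
robust to the heavy-tailed score distributions tools emit); binary and
one-hot columns pass through unbinned. The MIQ quotient divides relevance
by the mean MI with the already-selected set, floored at 2⁻²⁰ bits because
selected sets can contain mutually independent feature pairs. Ties break
lexicographically on feature name, making the ranking fully deterministic.

IFS evaluates every prefix of the ranking by k-fold cross-validated CHL
(k = 10 in the pipeline) and keeps the smallest prefix attaining the
maximum. A failed fit records an undefined point that is excluded from the
argmax. A `max_size` cap on the evaluated prefix length is available for
exploratory runs.

### The SVM and its defaults

RBF kernel, C = 1, gamma = 1/(number of features), sign decision threshold,
no probability calibration and no grid search by default — hyperparameter
search would make seeded runs incomparable across feature-subset sizes,
and the integration signal is strong enough that defaults suffice. All of
this is exposed in `SVMConfig`. Cross-validation uses stratified folds
(per-fold class counts within one record of balance); out-of-fold
predictions are pooled into a single confusion matrix and the headline
panel is computed from the pooled counts, not averaged over folds.

### Evaluating partial predictors

Tools cover different pair subsets. Under `missing_as_negative` (default)
an unscored pair counts as a non-binding call — a low-coverage tool pays in
sensitivity, which is the fair accounting when the question is "what would
this tool have told me about my pairs". Under `exclude_missing` unscored
pairs are dropped, which can flatter a tool that only answers easy cases;
both policies are reportable side by side.

## The synthetic generator

The generator stands in for the curated databases and upstream tool runs
that a production deployment consumes. It emulates:

* **Interactions:** each of `n_mirnas` (default 50) gets
  `targets_per_mirna` (default 20) positive targets from a gene universe
  twice the size of the positive set; an equal number of permutation
  negatives is drawn.
* **Energies:** a two-component Gaussian mixture, positives at −25 ± 3
  kcal/mol, negatives at −12 ± 3 (overlapping unimodal components, the
  qualitative shape of empirical duplex-energy distributions; exact
  parameters are configurable because no canonical values exist).
* **Tool outputs:** per tool, a Bernoulli coverage fraction of pairs gets a
  record; on covered pairs the binary call follows the tool's configured
  sensitivity/specificity. Payloads (scores, p-values, energies, sites,
  seed types, categories) are drawn from two overlapping distributions
  **conditioned on the emitted call, never on the truth** — so a
  chance-level tool's features are pure noise by construction, and feature
  recovery tests are meaningful. Default profiles are heterogeneous
  (sensitivities 0.55–0.95, one deliberately low-coverage tool at 30%) to
  mimic a realistic panel.
* **Sequences:** i.i.d. nucleotides at a configurable GC fraction (default
  0.5, length 500), one uniformly placed binding site per emitted record.

What the generator does **not** emulate: energy-detectability coupling
(real tools find stable duplexes more easily), shared failure modes between
tools that use similar algorithms, sequence-composition effects on binding,
and miRNA family structure. Passing tests therefore demonstrate that the
pipeline's machinery is correct and that integration beats single tools
*when tool errors are independent*; they do not certify performance on
real, correlated tool panels.

## Problem sizes and numerical choices

* The default end-to-end run (50 miRNAs × 20 targets, 68-feature registry,
  full IFS sweep with 10-fold CV) takes a few seconds; the integration
  properties (meta-CHL vs best tool, informative-tool feature recovery) are
  tested at 30 miRNAs × 10 targets over 10 seeds with 5-fold CV, sizes
  chosen to make the effects reproducible while keeping the suite fast.
* All randomness flows through explicit seeds via numpy `default_rng`
  seed sequences; independent generator streams are derived per stage so
  adding a stage never perturbs another's draws. Pipeline TSVs embed the
  config hash and seed and reruns are byte-identical.
* Benchmark identity tolerances: recomputing a quantity from inputs already
  rounded to 4 decimals can shift it by half an ULP propagated through the
  formula, so the CHL identity uses 1.01e−4 and the MCC′ identity 5.01e−5 —
  i.e. the recomputed value must agree with the printed cell to printed
  precision.

## Known limitations

* The default registry is one reasonable encoding of the tools' documented
  outputs, not a reconstruction of any particular deployment's feature
  file; registry YAML configs exist precisely so deployments can pin their
  own.
* Parsers for the upstream tools' native output formats are out of scope;
  records enter via the long-format interchange TSV.
* No probability calibration, ROC/PR analysis, or confidence intervals on
  panel metrics.
* trA labelling by energy extremes inherits the caveat above: the
  "negative" half are weakly-bound *positives*, a convention that works for
  training but must not be read as a biological negative set.
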
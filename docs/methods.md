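# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `ehrclust`, in the spirit of a package methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

The package targets cohort studies of Multiple Long-Term Conditions (MLTC)
in primary-care EHR databases: adults aged 50+ with multi-decade coded
histories of diagnoses, prescriptions and laboratory results. The goal is
gender-specific clusters of *patients* that reflect both which conditions
co-occur and the order in which they accumulate, together with transparent
cluster characterisation. Real source databases of this kind are
access-restricted, so all empirical claims in this repository are made on
synthetic cohorts with planted, recoverable structure.

## Sequence construction

Events are mapped to a controlled vocabulary: diagnoses and symptoms to
ICD-10 three-character categories (chapters A–S, with R-section symptom
codes), prescriptions to medication groups, lab results to abnormality
tokens. Unmappable codes are dropped. Tokens seen in fewer than
`min_patient_count` distinct patients (default 100; counts are per patient,
not per event) are pruned from the vocabulary; five special tokens (PAD,
UNK, CLS, SEP, MASK) are never pruned, and index order is deterministic
(specials first, then lexicographic).

Monthly-cadence medication groups are de-duplicated so refill streams do not
dominate: the first prescription is kept, later ones are suppressed until a
gap of at least 6 months separates consecutive raw prescriptions, after
which the rule restarts. Choices made where the rule is underdetermined:

- *Visit pooling* uses calendar months (`(year, month)` keys), not rolling
  30-day windows — deterministic and the simplest reading of "1-month
  period intervals".
- *The 6-month gap* is a fixed 183-day threshold, avoiding month-length
  ambiguity.
- *Cadence* ("monthly" vs ad-hoc) is a property of the medication group
  supplied in the `CodeMap`; no published list exists of which groups are
  continuous, so the shipped default marks the chronic-therapy groups
  (statins, ACE inhibitors, antidepressants, ...) monthly and leaves
  antibiotics/NSAIDs ad-hoc.
- *Truncation* keeps the most recent `max_len` (default 64) events, on the
  view that clustering targets the current phenotype; visit numbers are
  re-based to start at 1 after truncation.
- *Age* is integer completed years at the event date, clipped to 0–110;
  birth dates use a mid-year convention since only birth year is recorded.

## Encoder

The encoder is a disentangled-attention transformer over the token channel
plus four covariate channels. The input representation is the sum of token,
age, calendar-year, gender, visit-number and absolute-position embeddings,
layer-normalised. Attention at each head sums three terms — content·content,
content·relative-position, relative-position·content — scaled by
`1/sqrt(3 d_head)`; relative offsets are clipped to ±`max_relative_positions`
(default 16). A CLS position is prepended internally, carrying the first
event's age/year covariates.

**Pretraining (replaced-token detection).** A generator (shallower stack)
predicts dynamically masked events: each non-special position is masked
independently with probability 0.15, re-drawn every epoch, with at least one
mask per non-empty sequence. Replacements are sampled categorically
(temperature 1) from the generator softmax, excluding special tokens. The
discriminator (deeper stack) classifies every event position of the
corrupted sequence as original/replaced. Both models update jointly; the
combined loss is the generator cross-entropy plus 50× the discriminator
binary cross-entropy (the standard replaced-token-detection weighting). The
discriminator's token table is gradient-disentangled: it sees the shared
generator table as a constant and trains an additive delta, so
discriminator gradients cannot pull the generator's event embeddings.

**Fine-tuning (difference-based contrastive).** The pretrained *generator*
is fine-tuned: two dropout views of each sequence are pulled together
against in-batch negatives (temperature-scaled cosine similarities,
temperature 0.05), plus λ = 0.005 times a conditional replaced-token term —
a frozen copy of the pretrained generator edits 15% of events, and a small
head conditioned on the patient vector classifies each edited position.
This keeps the embedding sensitive to content edits while invariant to
dropout noise. Fine-tuning uses a reduced learning rate (2e-4 vs 1e-3 for
pretraining); at full rate the instance-discrimination pressure visibly
disperses coarse cluster structure on small corpora.

**Pooling.** The patient embedding is the masked mean of final hidden
states over real event positions (CLS and padding excluded), in evaluation
mode (no dropout). Single-position (CLS) pooling was evaluated and rejected
for this package's operating regime: at small hidden sizes the CLS state is
dominated by the sequence-level covariate embeddings and carries almost no
event content (planted-archetype recovery fails under CLS pooling and
succeeds under mean pooling; the test suite exercises the latter).

**Scale.** Defaults are desk-scale — hidden 64 (tests mostly use 16–32),
2 discriminator + 1 generator layers, 2 heads, 20 pretraining epochs, batch
32, Adam — chosen so the full pipeline runs in minutes on one CPU.
`paper_scale_config()` records a published-scale block (hidden 768, 6+3
layers, 12 heads, 100 epochs) that is documented but not exercised by the
tests. The optimizer, schedule and batch size are configuration with these
defaults; no authoritative values exist for them. The whole stack runs on a
small reverse-mode autodiff engine over numpy (`ehrclust.nn`), whose
gradients are checked against central finite differences in the test suite.

## Clustering and validation

Embeddings are clustered per gender stratum. The cluster count is chosen by
bootstrapped agglomerative clustering: each replicate draws an
equal-allocation stratified subsample (strata from a preliminary
high-k K-Means; default 1000 strata, 1% fraction, 500 replicates at
published scale — desk runs use smaller values stated in each test), builds
a Ward hierarchy on length-normalised embeddings, cuts at every candidate
k, and records silhouette, Davies–Bouldin and Calinski–Harabasz scores. The
chosen k maximises mean silhouette, ties breaking to the smaller k
(parsimony). Ward linkage is a choice — the agglomerative method's linkage
is not published — and pairs naturally with K-Means geometry. The default
candidate range 2–30 brackets the published optima (15 female / 17 male).

The final model is standard Euclidean K-Means with seeded restarts.
Stability checks:

- *Bootstrap centroids*: K-Means on stratified subsamples (default 25%,
  100 replicates) matched one-to-one to the final centroids by the
  Hungarian algorithm on cosine distances (1 − cosine similarity); the
  report gives the median matched distance per final cluster.
- *Temporal cohesion*: histories are spliced at each age cutoff (events at
  ages ≤ cutoff kept; patients with no records after the cutoff are
  ineligible for that cohort), re-embedded, assigned to the nearest final
  centroid *by cosine distance* (consistent with the cohesion metric, even
  though K-Means itself is Euclidean — recorded explicitly), and per-age
  median cohesion is compared with final-cluster cohesion.
- *Comorbidity similarity*: cosine similarity of established condition
  pairs in the input token-embedding table, against a random-couple
  reference distribution.

## Cluster characterisation

DF-IPF and c-DF-IPF use natural logarithms (the base rescales all weights
uniformly). Diseases present in no patient are excluded with a log entry;
diseases present in every patient (or every cluster) get weight 0 by the
`ln(K/K)` limit rather than exclusion. One-vs-all χ² tests use the 2×2
table (in-cluster vs rest × present/absent) with 1 df and no continuity
correction; the signed z is `sign(O−E)·√χ²`, which for 1 df satisfies
|z| = √χ² exactly, and the heatmap symbols apply thresholds at |z| = 10 and
50. Raw statistics are reported without multiple-testing correction (the
display is of z magnitudes, not adjusted p-values). Exclusivity is defined
as the fraction of all carriers of a condition who belong to the cluster
(sums to 1 over clusters); the cross-gender comparison is the Pearson
correlation of cluster c-DF-IPF profiles over shared conditions. Both are
explicit package definitions where the source material leaves the
construction unspecified.

## Latent class baseline

A mixture of locally independent Bernoulli item profiles fitted by EM:
responsibilities ∝ π_c Π_d ρ_cd^x (1−ρ_cd)^{1−x}, closed-form M-step, ρ
clipped to [1e−6, 1−1e−6], tolerance 1e−6 on the log-likelihood, 10 jittered
prevalence-based starts by default, best likelihood kept. The class count
minimises BIC (m = (C−1) + C·D parameters), with AIC reported and
disagreements logged; BIC is preferred when they disagree. Hard assignments
are maximum a posteriori responsibilities.

## Synthetic cohorts: what they emulate and what they do not

`table1_config` mirrors a large English primary-care cohort's marginals:
54.8% female; ethnicity recorded for 37.7% (93.4% White, 2.9% South Asian,
2.0% Black among recorded); IMD linkage for 51.3% (22.6% least-deprived to
15.8% most-deprived); five archetypes per gender (low-burden,
mental-health, cardiometabolic, respiratory, mixed) with mixing weights
taken from the published cluster-group shares and clinically plausible
per-condition prevalences and onset ages. Each patient is drawn from one
archetype (hard assignment); comorbidity pairs get an odds-ratio uplift
applied sequentially over lexicographically ordered conditions; linked
medications emit monthly refill streams from onset; some conditions emit
lab-abnormality tokens; a review event near registration end keeps records
current. The default condition list (~36 conditions and risk factors) is a
synthetic stand-in assembled from conditions named in the MLTC literature —
the full published 54+3 list lives in supplementary material that the
package does not reproduce; every interface accepts a user-supplied list.

`separable_archetype_config` plants *recoverable* ground truth: disjoint
condition blocks per archetype at high prevalence with distinct onset-age
profiles. This is the configuration under which embedding + K-Means is
required to recover the planted partition (ARI ≥ 0.9 in the tests); the
realistic overlapping archetypes of `table1_config` are deliberately harder
and are not a recoverability fixture. `gaussian_mixture_embeddings` plants
a known component count directly in embedding space (random-direction
centres with enforced minimum separation) for cluster-number-selection
checks.

Passing tests on these cohorts show the pipeline recovers structure it can
in principle see; they do not show that real EHR data contains such
structure. The generator does not model disease natural history, mortality
or censoring, practice-level coding variation, or calibration to true
prevalences.

## Degenerate inputs and numerical details

- Empty sequences are flagged and skipped at embedding time with a log
  entry; empty age cohorts and degenerate (all-identical) subsamples are
  skipped likewise.
- Zero-margin 2×2 tables yield z = 0 and a degenerate flag; zero-variance
  t-tests are flagged without a statistic; constant c-DF-IPF profiles give
  NaN correlations with a log entry.
- Masking rejects rates outside (0,1); K-Means requires k ≥ 2 and k ≤ n;
  Hungarian matching requires equal k.
- Stratified sampling allocates equally with floor-division quotas,
  round-robin remainders, and redistribution when a stratum is smaller than
  its quota.
- The pipeline splits one global seed into per-stage seeds via
  `SeedSequence`, writes every run into a fresh versioned directory with a
  manifest of outputs and content hashes, and refuses stages whose
  dependencies have not run.

## Problem sizes used by the checks

The test suite and acceptance script use desk-scale sizes chosen as
realistic for a single-CPU reproduction: cohorts of 60–500 patients for
training checks (100,000 for demographic-marginal convergence, which needs
no training), encoder widths 16–32, 8–20 pretraining epochs, 20,000×32
embeddings with 15 planted components for cluster-number selection (50
replicates of 5% subsamples over 1000 sampling strata), and n = 2,000 for
latent-class parameter recovery. Statistical assertions use 3-standard-error
bands around the planted values.

## Known limitations

- The encoder is validated at desk scale; behaviour at published scale
  (768-dimensional, millions of patients) is documented configuration, not
  a tested claim.
- The conditional replaced-token term uses a lightweight conditioned head
  rather than a full second transformer; at λ = 0.005 its contribution is
  small by construction.
- The relative-position scheme uses symmetric clipping, one shared
  relative-embedding table per model with per-layer projections; published
  variants differ in bucketing details.
- `summarize_demographics` reports percentages on recording-aware
  denominators but does not impute missing ethnicity or deprivation.
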
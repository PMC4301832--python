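# Methods

## Cohort model

The unit of observation is one insured patient-year of ambulatory diagnoses,
in long format: `(patient_id, gender, age, quarter, icd10)`. Three filters
turn claims into the analysis cohort:

* **Grouping.** ICD-10 codes map by prefix to 46 chronic diagnosis groups.
  The mapping config forbids overlapping prefixes, so a code maps to at most
  one group; codes outside the list are dropped and counted. The shipped
  prefix lists are representative stand-ins for the original (unpublished)
  grouping — adequate for synthetic data and as a template for real use, not
  a clinical artifact.
* **Persistence.** A condition counts for a patient only if its group is
  coded in ≥ 3 of the 4 calendar quarters (`min_quarters`, default 3).
  Distinct *quarters* are counted, not claims: five codes in one quarter
  count once. This suppresses transitory and accidental diagnoses.
* **Multimorbidity.** The cohort is restricted to patients with
  ≥ 3 chronic conditions (`min_conditions`, default 3).

Prevalence is always the column mean over one gender's multimorbid cohort;
the pipeline never pools genders, because prevalence differences between
women and men are large enough to change the association structure.

## Triad screen

For every unordered triple of groups, the expected prevalence under mutual
independence is the product of the three gendered marginals and
O/E = observed/expected. Selection requires observed prevalence ≥ `min_prev`
(default 0.01; the replication preset uses 0.0085 for data years with lower
coding intensity) and O/E ≥ `min_oe` (default 2.0), both inclusive. This is
a fixed-threshold relevance/association screen, not a hypothesis test, so no
multiple-testing correction is applied or appropriate. O/E is computed at
full precision; published tables round marginals to three decimals first, so
the shipped worked-example test feeds the printed rounded values. Triads
with expected prevalence 0 have no defined O/E and are excluded with a
warning.

## Tetrachoric correlation and clusters

Binary condition indicators are modelled as thresholded standard bivariate
normals. With thresholds fixed at the probit quantiles of the margins, the
ML estimate of the latent correlation is the ρ at which the model's
both-present quadrant probability equals the observed one; the estimator
solves that equation by bracketed root finding (|ρ| ≤ 0.9999, xtol 1e-10),
with a 0.5 continuity correction when any cell of the 2×2 table is zero, and
returns NaN for degenerate margins. An independent grid-search likelihood
maximizer backs this in the tests (agreement to 1e-3 on a 20-table battery;
symmetric tables also match the closed form cos(π/(1+√(ad/bc)))).

Pairwise tetrachoric matrices are routinely slightly indefinite; when that
happens the matrix is repaired by eigenvalue clipping at 0 plus diagonal
renormalization and flagged.

Factor analysis: the number of retained factors is the count of
correlation-matrix eigenvalues ≥ `eigen_threshold` (default 1.0, the Kaiser
rule — applied to the tetrachoric matrix itself, the most common reading for
exploratory factor analysis). Extraction is principal-axis factoring
(statsmodels), chosen over ML extraction for its robustness to Heywood cases
on tetrachoric inputs; with ≥ 2 factors the loadings are obliquely rotated
(oblimin, γ = 0, i.e. quartimin). The solution is canonicalized — factors
ordered by explained variance, sign fixed so each factor's largest loading
is positive — making it deterministic up to that convention. A condition is
assigned to every cluster on which |pattern loading| ≥ `loading_threshold`
(default 0.25); absolute loadings are used, and multiple membership is
allowed deliberately: overlap between clusters is the object of study.

**Triad classification** uses only cluster-assigned members: a triad whose
assigned members all sit in one cluster takes that cluster's label, a triad
spanning both clusters is labelled `both`, and a triad with no assigned
member is `none`. Unassigned ("no pattern") conditions never block a label.
This rule reproduces the section placement of all 108 published 2006 triads
given the published cluster membership.

## Disease network

Each selected triad contributes its three disease pairs; pairs are
deduplicated into an undirected simple graph whose edges remember their
supporting triads (support is not used as a weight — edges are plain lines).
Reported per node:

* `degree` — edge count;
* `degree_centrality_pct` — degree / degree-sum (= 2|E|) × 100. These shares
  sum to 100 and match the published per-node percentages (e.g. 16/200 =
  8.0%); the textbook degree/(n−1) is provided as
  `degree_centrality_classic`;
* `betweenness_pct` — the node's share of summed raw shortest-path
  betweenness × 100. This is the convention of the published table: its
  per-node values and its "average node betweenness" (identically 100/n:
  3.2% for 31 nodes, 3.4% for 29) are reproduced under it. One printed value
  (male joint arthrosis) is inconsistent with the printed triads under every
  convention examined and is treated as a printing error;
* `betweenness_norm_pct` — the standard normalization by (n−1)(n−2)/2 × 100,
  reported alongside; the two columns differ by the network-wide factor
  total-betweenness / ((n−1)(n−2)/2).

Layout is classical (Torgerson) MDS on the all-pairs shortest-path distance
matrix, per connected component with horizontal offsets; a seeded 1e-9
jitter breaks exact eigenvalue ties, making the layout deterministic per
seed. Plots scale node area with prevalence and colour by cluster label.

## Synthetic claims generator

The generator exists so the full pipeline, including parameter recovery, can
be exercised without insurer data. It emulates a gendered elderly (65+)
multimorbid cohort: 44.2% female; age Normal(73.3, 6.8²) for women and
Normal(72.2, 5.9²) for men, truncated to 65–105; 46 binary conditions whose
gender-specific marginal prevalences default to the published 2006 values
for the 35 conditions of the centrality table and to invented nominal values
(flagged `synthetic_prevalence` in the config) for the remaining 11.

Presence is a latent Gaussian threshold model: z ~ N(0, R), condition j
present iff z_j exceeds the probit quantile of 1 − p_j. This is exactly the
model under which the tetrachoric estimator is consistent, giving the
cluster stage a clean recovery target. R is built from a two-column loading
matrix (R = ΛΛᵀ outside the unit diagonal, PSD by construction): block
members load √0.5 on their block (within-block latent correlation 0.5,
strong enough for unambiguous recovery at n = 10⁴, weak enough to be
claims-plausible), bridge conditions (default: obesity and joint arthrosis,
mirroring the metabolic-syndrome ↔ musculoskeletal overlap) load √0.25 on
both blocks, and the remaining conditions are independent. Gender-restricted
conditions are forced absent in the excluded gender.

Claims emission inverts the persistence rule: a present condition is coded
in 3–4 distinct quarters with probability `persistence_prob` (default 0.9)
and in 1–2 quarters otherwise; transient noise diagnoses (1–2 quarters,
uniform over the gender-permitted groups) arrive Poisson(`noise_rate`,
default 1.0 per patient-year). With `persistence_prob = 1` and
`noise_rate = 0` the cohort builder inverts the generator bit-for-bit, which
the tests assert. All sampling flows from one configured seed in a fixed
patient-major order, so identical configs give identical claims tables.

What the generator does *not* emulate: longitudinal multi-year dynamics,
realistic within-group ICD code frequencies, age-dependent prevalence, and
claims-coding artifacts beyond simple transience. Passing recovery tests
therefore show the estimators are correct under the latent-threshold model,
not that real claims follow it.

## Test problem sizes and numerical choices

Statistical tests run at sizes where 3-SE binomial bands are tight but
runtimes stay in seconds: marginal calibration and cluster recovery on
n = 10,000 cohorts, O/E convergence on n = 20,000, the planted-cluster
recovery on a dedicated 12-condition two-block cohort (5 + 5 members, 2
bridges). The dedicated config matters: under the Kaiser rule, a sampled
correlation matrix containing many mutually independent conditions retains
spurious noise factors whose eigenvalues straddle 1, so "exactly two
factors" is a property of fully block-structured cohorts only — with the
full 46-group default the factor count is reported, not asserted. Betweenness
is validated against exhaustive path enumeration on a battery of structured
and random graphs of 3–8 nodes; triad counting against per-patient row
scans.

## Known limitations

* The 46-group ICD mapping is representative, not the original instrument.
* The published full-data results that depend on the insurer cohort
  (population counts, marginal prevalences, the 57/51 selection itself) are
  inputs via transcription fixtures, not reproducible outputs.
* Betweenness conventions vary across network tools; both supported
  conventions are reported, and one published per-node value resists all of
  them (see above).
* Factor-analysis defaults (principal-axis, oblimin γ = 0) are one standard
  choice among several; both thresholds and the extraction pathway are
  configurable.
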
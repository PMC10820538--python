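# Methods

## Cohort and transaction semantics

A discharge record carries demographics (sex, age, insurance type,
admission route, treatment outcome, length of stay, death, surgery,
hospital bed size), one principal ICD-10 diagnosis and a possibly empty
list of secondary diagnoses. The analysis cohort keeps records with age
≥ 19 and a principal category lexicographically within E00–E90 inclusive
(the endocrine chapter; E90 is read as inside the range). Ages partition
into the life-cycle strata 19–44, 45–64, 65–74 and ≥75, inclusive at both
ends as labeled.

Diagnoses are reduced to their 3-character category: codes are accepted
dotted (`E11.9`) or undotted (`E119`), upper- or lower-case; national
extensions beyond three characters are truncated to the category.
Duplicate secondary codes within one record are deduplicated at the
category level, because transactions are sets. Whether registries ever
code duplicates per discharge is not observable from published tables;
normalizing to sets is the safe convention and is applied on read.

A patient's transaction is the set of secondary-diagnosis categories. The
record's own principal category is removed from its itemset by default, so
"comorbidity" means conditions other than the admitting diagnosis;
endocrine categories still appear as items when coded as secondary on
other records. The flag `include_principal=True` switches this off — the
inclusion question cannot be settled from published outputs, so both
behaviors are first-class.

Unknown or missing categorical demographic values map to the explicit
`other` level where one exists (insurance, route, outcome) rather than
dropping the record; registry baseline tables carry explicit "Others"
rows, and dropping would silently shift denominators.

## Measures and thresholds

With `N_total` the number of cohort patients *including those with no
comorbidities*:

    support(A→B)    = N(A ∪ B) / N_total
    confidence(A→B) = support(A ∪ B) / support(A)
    lift(A→B)       = support(A ∪ B) / (support(A) · support(B))
    IS(A→B)         = sqrt(support · lift)
                    = support(A ∪ B) / sqrt(support(A) · support(B))

The full-cohort denominator is not cosmetic: published registry rule
tables only reproduce their printed supports when patients with empty
itemsets stay in the denominator (e.g. a printed count of 12,259 over
68,515 gives exactly the printed support 0.179).

Default retention thresholds are support > 0.02, confidence > 0.1 and
lift > 1, all strict. Strictness matters at boundaries (a pair with lift
exactly 1 is independent and carries no signal); `lift_strict=False`
provides the inclusive reading, since published threshold wording ("at
least 1") is ambiguous while every published retained rule in fact
exceeds 1. "Reliability" in such threshold statements is read as
confidence.

Reported tables round half-up to 3 decimals. IS is always computed from
*unrounded* support and lift — computing it from the rounded support fails
to reproduce published IS values (sqrt(0.051 · 5.239) ≈ 0.517, not the
printed 0.519). Filtering likewise uses unrounded measures. Support
comparisons use plain floating-point `count / total > min_support`; counts
and totals are exact integers, so ties at representable fractions behave
deterministically.

Both directions of a pair are distinct rules: support, lift and IS are
symmetric, confidence is not. Ranking sorts by IS descending, breaking
ties by support descending, then lexicographically by (antecedent,
consequent) so reruns and permuted inputs produce identical tables.

## Mining implementations

`apriori` is the production path: level-wise candidate generation joining
frequent (k−1)-itemsets that share a (k−2)-prefix, pruning any candidate
with an infrequent subset (downward closure), counting against a boolean
patient × item incidence matrix. No maximum itemset length is imposed by
default (published tables reach 4-item rules); `max_len` caps it when
vocabularies are large.

Two deliberately independent routes verify it. `brute_force_rules`
enumerates every itemset over the observed vocabulary (guarded to ≤ 14
items) and every antecedent split, with its own containment-scan counting.
`eclat` mines by depth-first vertical TID-set intersection — a different
search order and counting mechanism. The test suite requires exact
agreement of itemsets and counts and 1e−9 agreement of rule measures
across all three on random instances and on the full-size default
synthetic cohort.

## Descriptives

The baseline table reports categorical variables as within-sex counts and
percentages (1 decimal) and age / length of stay as mean ± SD, with a
Pearson chi-squared test per categorical variable. No Yates continuity
correction is applied, including for 2×2 tables — the standard
large-sample registry convention; published tables report only "<0.001"
thresholds, so the choice is not distinguishable from them and is fixed
here as the package convention. p-values below 0.001 render as `<0.001`.
The test itself delegates to `scipy.stats.chi2_contingency`; the suite
cross-checks it against the direct Σ(O−E)²/E formula.

## Synthetic cohort generator

The generator is a latent-class model: patient draws class k with
probability π_k, then carries each vocabulary category c independently
with probability p[k][c]. For any itemset S the exact probability is
P(S) = Σ_k π_k Π_{c∈S} p[k][c], so true support, confidence, lift and IS
of any rule are available in closed form (`true_measures`) — the property
that makes parameter-recovery testing possible. Within one class items
are independent, so K = 1 models are the null: every pair has true lift 1.

The default configuration emulates the scale and structure of a national
discharge registry extract of adult endocrine inpatients:

- n = 68,515 records; vocabulary of 26 three-character comorbidity
  categories (the categories a published frequency plot of that registry
  names);
- four classes — comorbidity-free-like (π = 0.13), mild metabolic
  (0.38), cardio-metabolic (0.31 — diabetes, hypertension, dyslipidemia),
  metabolic-renal (0.16 — concentrating N08/N18 with diabetic
  complications);
- calibrated once, at design time and from the closed form, so that
  type 2 diabetes (E11) and hypertension (I10) are the two most frequent
  items, the fraction of records with ≥ 1 comorbidity is ≈ 0.81 (the
  registry reports ~82.5% of men and ~80.2% of women), and the planted
  N08/N18 pair has true lift ≈ 5.1 (published pooled lift for that pair
  is ~5.2);
- demographic marginals (sex 46.9/53.1, age-group weights, insurance,
  route, outcome, bed size, surgery ≈ 17.6%) taken from the published
  baseline distribution; length of stay is rounded log-normal
  (log-mean 1.9, log-sd 1.0, giving a mean near 11 days with a heavy
  right tail).

Demographics are sampled independently of the comorbidity process: the
mining uses only diagnosis codes, so coupling would add realism the
pipeline cannot detect. The exception is the optional age-shift hook,
which multiplies per-item odds by an age-group factor and is on by
default: type 1 diabetes (E10) is concentrated in ages 19–44, reflux
disease (K21) in 45–64, liver disease (K76) under 65, electrolyte
disorders (E87), cerebrovascular sequelae (I69) and osteoporosis (M81) in
65+, ischemic heart disease (I25) and urinary disorders (N39) mostly in
≥75 — mirroring the kind of stratum-selective associations published
stratified analyses report. These planted shifts are a testing construct,
not an estimate of any real joint age × comorbidity distribution;
`true_measures` refers to the unshifted model. A single integer seed
drives one `numpy` generator stream; identical (model, n, seed) yield
bit-identical cohorts.

What passing on synthetic data does and does not show: it demonstrates
that the pipeline recovers known ground truth under a mixture-of-Bernoulli
co-occurrence structure at registry scale. Real discharge data add
features the generator deliberately omits — survey sampling weights,
hospital clustering, calendar drift in coding practice, age-correlated
comorbidity burden beyond the planted shifts — so agreement here validates
the software, not any clinical conclusion.

## Published rule table fixture

The 61-rule pooled table published from the (access-restricted) Korean
national discharge registry analysis ships as a CSV fixture: antecedent,
consequent, patient count N, confidence and lift as printed. Support and
IS are recomputed at load time from N / 68,515 and the printed lift, and
reproduce every printed 3-decimal value. The fixture provides real
published data for ranking, composition statistics (63.9% / 60.7% / 34.4%
involvement of E11 / I10 / both) and graph export; the underlying
microdata, and hence the mining that produced those 61 rules, remain
out of reach by design. The published stratified presence table also
lists a few codes with no marked cells or absent from the pooled table
(I48, N17, H43, I20, Z95); no rule is inferred for them here.

## Rule networks

Rules export as a bipartite digraph: item nodes plus one node per rule,
antecedent items → rule node → consequent items, so multi-item
antecedents are encoded faithfully (a flat item-to-item graph cannot
represent "E11, I10, N08 → N18"). Rule-node ids are content-based
(antecedent⇒consequent), making the graph reconstructible from the
exported rule CSV alone. Output is GraphML plus a flat edge list; layout
coordinates are presentation, not data, and are not computed.

## Problem sizes and numerical conventions in the test suite

Oracle-equivalence suites use 20 random databases of up to 10 items and
200 transactions with random thresholds; cross-implementation checks run
on the full 68,515-record default cohort; parameter recovery uses
n = 50,000 with 3-Monte-Carlo-SE tolerances (the lift tolerance uses the
delta-method approximation dominated by the joint-count term). Smoke and
stratified tests use 2,000–40,000 records, chosen as the smallest sizes at
which planted stratum-specific rules clear the 0.02 stratum-local support
threshold reliably.

## Known limitations

- Survey design (sampling weights, stratified cluster sampling) is out of
  scope; all estimates are unweighted.
- Only the support/confidence/lift/IS measure family is implemented — no
  conviction, leverage, or closed/maximal itemset compression.
- The chi-squared convention (no continuity correction) and the strict
  lift inequality are fixed package conventions where published wording is
  ambiguous; both are configurable where that ambiguity is substantive.
- The generator's independence of demographics and diagnoses (age shift
  aside) means sex-stratified comorbidity differences are not emulated.
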
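# Methods

## Transaction model and rule statistics

A survey cohort is modeled as a transaction database: respondent *i*
contributes the set of variable codes whose response was annotated 1.
Annotation is per-variable: a configured set of raw response codes maps to
1 (condition/behavior present), another to 0 ("no", "don't know",
"refused"), and a third to missing. Raw codes are compared as verbatim
strings — survey dialects disagree on numeric vs textual codes, so nothing
is coerced. Under the default complete-case policy a respondent missing on
*any* selected variable is excluded entirely and logged; the alternative
(`skip-variable`) drops only the missing item. Complete-case is the default
because the transaction encoding cannot distinguish "answered no" from
"not asked": keeping partially-missing records would silently deflate
supports. Retained transactions plus exclusions always partition the input
rows (asserted in tests).

For disjoint itemsets m, n over a database of N transactions:
support(m⇒n) = c(m∪n)/N, confidence = c(m∪n)/c(m), lift =
N·c(m∪n)/(c(m)·c(n)), where c(·) is an exact transaction count. Metrics
are derived from counts at the point of use; thresholds compare counts
(count ≥ ceil(minSup·N − ε)), which avoids float edge cases at bounds like
0.1·N. A rule whose antecedent or consequent never occurs raises an
explicit undefined-metric error rather than producing NaN.

## Mining

`apriori_mine` is the classic level-wise search: frequent k-candidates are
joined from frequent (k−1)-itemsets sharing a (k−2)-prefix, pruned unless
every (k−1)-subset is frequent, and counted by intersecting the
transaction-id sets of the two join parents (a vertical representation;
the cohort sizes this package targets never need sampling or FP-growth).
The support threshold is inclusive (≥), the standard Apriori convention.
Default `max_len` is 10, matching the common default of reference rule
miners; printed survey rules rarely exceed 6 items. `min_confidence`
defaults to 0 — rule quality is controlled downstream by the adaptive
selection, and a high confidence floor would silently censor the rule
population whose means that selection depends on.

Rule induction uses single-item consequents by default (every rule a
practitioner reads in this analysis style has one item on the right);
`max_consequent_len` generalizes this. `brute_force_oracle` enumerates all
candidate subsets directly, shares no code with the miner, and is guarded
to ≤ 16 items; it exists so the miner can be checked for *exact* equality
of itemsets and supports on randomized instances (100 instances in the
acceptance suite).

## Two-stage adaptive selection

Stage 1 keeps rules with support strictly greater than the mean support of
all mined rules **and** lift > 1; stage 2 keeps, from the stage-1
survivors, rules with lift strictly greater than the survivors' mean lift.
Strict comparison follows the "larger than" reading of the heuristic; an
`inclusive` flag switches both comparisons to ≥ (with strict means, a
population of identical rules selects nothing — visible, by design, in a
degenerate test). A second flag, `lift_gate_before_support_mean`, computes
the stage-1 support mean only over lift > 1 rules; the default computes it
over all mined rules, the reading consistent with applying the heuristic
after a mining-time support lower bound (0.1 for the survey run). The
selection report records the lower bound, both means and all three counts,
and the pipeline logs them at INFO, so any run can be audited.

Comorbidity subsetting keeps rules whose antecedent *or* consequent
intersects the condition's keyword codes. Top-k ranking orders by (lift
desc, count desc, rule string asc) — the tie-break is not part of the
method, it just makes output a pure function of the rule multiset.

## Correlation stage

Risk-factor and condition indicators (plus conjunction columns — both
conditions present) are correlated with Spearman's rank correlation with
average-rank ties, computed by scipy. On 0/1 indicators Spearman rho equals
the Pearson correlation of the raw values (the phi coefficient), which the
tests assert numerically. Correlations run over the full encoded
population, not the disease cohort — within the cohort the cohort-defining
condition is constant and its correlations undefined. Constant columns are
reported as explicit NaN entries with the offending pairs listed, never
dropped silently. P-values are computed and exported but nothing filters
on them.

## Literature stage

Predication records carry subject/object terms, their semantic-type codes,
a predicate, and a negation flag derived from the `NEG_` predicate prefix.
Filtering is deterministic and ordered: (1) one-hop adjacency to the seed
disease terms (the subgraph depth a practitioner would start with; deeper
expansion can be built by iterating the filter), (2) semantic-type
whitelist on both arguments, (3) generic-term blacklist, (4) negation.
Negated predications are *kept* by default: the literature reports both
signs for the same pair, and discarding negatives silently biases counts;
a flag drops them. Each surviving triple becomes the pair transaction
{subject, object} (self-loops dropped, duplicates kept — repetition across
citations is the evidence being counted; deduplicating identical
predications per citation is left to upstream preparation).

Absolute support/confidence thresholds on a pair store are corpus-size
artifacts (a 60-record store and a 4-million-record store need different
fractions for the same "attested at least twice" intent), so the miner is
parameterized by `min_count` (default 2) and derives minSup = min_count/N.
Selection keeps lift > 1, then lift above the mean lift of those. The
lifestyle filter keeps rules with at least one term of a focus semantic
type — daily or recreational activity (`dora`), food (`food`), hazardous
or poisonous substance (`hops`), individual behavior (`inbe`), mental or
behavioral dysfunction (`mobd`), finding (`fndg`) — and returns the
deduplicated keyword list. The bundled whitelist/blacklist configs are
seeded with the standard types and well-known generic offenders and are
meant to be extended per corpus.

## Synthetic generators

The survey generator draws independent Bernoulli items at configured
marginals and plants dependencies as conditional draws: Y ~
Bernoulli(P(Y|X)) where X = "all antecedent items present", else
Bernoulli(P(Y|¬X)). Expected metrics are closed-form (support =
P(X)·P(Y|X) with P(X) the product of antecedent marginals; lift =
P(Y|X)/P(Y)). Validation forbids an antecedent item from being another
rule's consequent, which keeps those closed forms exact. The default
fixture — 14 items, N = 20,000, planted lifts {2.105, 1.5, 1.0}, background
marginals 0.35–0.5 so item pairs clear a 0.1 support bound — exercises
both selection stages: the 2.105 rule must survive, the independent pair
must not. N = 20,000 is a realistic disease-cohort size for a national
survey and keeps the full suite in seconds.

What the generator does **not** emulate: survey skip logic, sampling
weights, and the cross-correlation structure of real behavioral items
(background items are mutually independent). Passing tests therefore
demonstrate correctness of counting, selection semantics and calibration —
not that any particular real-world rule list is clinically meaningful.

The predication generator emits each planted pair its configured number of
times (≥ 2, so planted pairs sit exactly at or above the attestation
boundary) and fills the store with background pairs, either freshly minted
unique terms (every background term occurs once — planted pair lifts are
then exactly N/k for repeat count k) or uniform draws from a vocabulary.
The default store (N = 60; repeat counts 3, 4, 5 → lifts 20, 15, 12)
plants *several* pairs because a strict mean-lift threshold makes a
single-pair store degenerate: a lone rule never exceeds its own mean.

## Numerical and design notes

- Supports are exact integer counts; identities like
  lift·support(consequent) = confidence hold to ~1e−16 and are asserted at
  1e−12.
- All generators are pure functions of (spec, seed) via
  `numpy.random.default_rng`; identical pipeline configs produce
  byte-identical rule CSVs.
- Monte-Carlo tolerances in tests are 3 standard errors: binomial for
  support and confidence, delta method (ignoring the small positive
  covariance term, hence slightly conservative) for lift.
- The pipeline persists every stage's output and a manifest of applied
  thresholds; selection stages can be re-run from saved rules without
  re-mining.

## Known limitations

- Rule selection is heuristic; no significance testing or multiplicity
  control is performed on rules (by design — the correlation stage's
  p-values are exported but unused).
- The literature stage consumes pre-extracted predication tables; concept
  extraction, UMLS normalization and term-to-survey-variable resolution
  are out of scope.
- Survey weighting and design effects are ignored; results describe the
  interviewed sample, not a weighted population.
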
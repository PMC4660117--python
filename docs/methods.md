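# Methods

## Analysis model

The pipeline treats each genetic test as a retrospective case–control
comparison embedded in an EHR snapshot. For one test, the four cohorts are
the background population A, the tested patients T, and the positive and
negative result groups P and N. For a clinical feature with patient-level
mention counts `n_A, n_T, n_P, n_N`:

- per-group frequency: `n_g / |g|`, computed at full precision and rounded
  only in reports (5 decimals by default, round-half-even);
- dominance statistic: the positive-vs-negative odds ratio
  `OR_PN = (n_P/(|P|−n_P)) / (n_N/(|N|−n_N))`;
- prevalence weight: the tested-vs-background odds ratio
  `OR_TA = (n_T/(|T|−n_T)) / (n_A/(|A|−n_A))`, which flags features that
  are common among tested patients even when they do not separate P from N
  (cirrhosis under the alpha-1-antitrypsin test is the canonical example:
  `OR_PN` ≈ 0.78 but `OR_TA` ≈ 150).

No continuity correction is applied by default: the plain cross-product
form is the reported statistic, and the published values are exactly the
uncorrected formula. A Haldane–Anscombe 0.5 correction is available as an
option for degenerate cells, and Woolf log-normal confidence limits can be
added as an output column; neither plays any role in selection. There is no
multiple-testing adjustment — ranking uses the raw odds ratio with a fixed
strict threshold of 1, matching the knowledge base's purpose of carrying
effect-direction weights rather than hypothesis tests.

Degenerate odds ratios use sentinels rather than errors: a zero numerator
odds gives 0.0, a zero denominator odds gives +inf, and 0/0 or inf/inf give
NaN. The retention filter (below) guarantees that every feature entering
the ranking has a finite, positive ratio.

### Group semantics

The four group sizes are treated as *independent denominators*, not as a
partition. The reference population A is supplied as an explicit id list
and may in principle overlap T. Within one test, P and N are disjoint;
patients whose result matches no classification rule stay in T but in
neither P nor N, and their count is logged. A patient any of whose orders
was cancelled is excluded from T even if another order completed — real
order streams contain "cancelled, ordered in duplicate" entries, so
|P| + |N| can exceed |T| (one of the five packaged tests has exactly this
shape: 70 + 464 > 514). The invariant that does hold universally is
`|P∩T| + |N∩T| + |unknown| = |T|`. Because of this, multiple records per
(patient, test) are an error by default and must be explicitly allowed
(`duplicate_policy="aggregate"`, used by `reproduce-paper`), or collapsed
(`keep_latest`).

### Result classification

The study this mechanizes reviewed free-text results manually; here an
ordered, case-insensitive regex rule file stands in. The packaged default
rules check cancellation markers first ("canceled"/"cancelled", "testing
accession", "NO CHARGE"), then positives ("copy/copies/mutation …
identified" — heterozygous-carrier results count as positive; the analysis
does not distinguish carrier from affected), then negatives ("none of the
listed mutations were detected", explicit "negative"). Anything else is
UNKNOWN. Rule order is significant and first-match-wins, so a cancelled
duplicate of a positive order classifies as cancelled.

### Annotation

Dictionary matching replaces a full clinical NLP engine. The matcher is a
token trie over case-folded alphanumeric tokens: scanning is left-to-right,
longest-match-first, non-overlapping, so "congestive heart failure" counts
as that entry and not additionally as "heart failure". This is a deliberate
semantic choice — it makes phrase counts unambiguous — and the synthetic
generator plants one sentence per carried surface form so that counts are
exact under it. Counts are patient-level booleans (a feature mentioned in
ten notes flags the patient once), because the frequency numerator is
"number of patients with the clinical feature".

Known limitations, carried over deliberately from the study design: no
negation or uncertainty detection, no family-history sections, no stemming
(near-duplicate terms such as "Seizure"/"Seizures" and British/American
spellings are separate lexicon entries with separate counts), and no
concept normalization beyond the packaged lexicon.

### Retention and dominance

A feature is retained for a test iff at least one P patient *and* at least
one N patient mention it. The conjunctive reading is the weakest one
consistent with every published retained row, and it guarantees finite
positive odds ratios; a disjunctive variant is selectable. Tests whose
retained set is empty are dropped with a logged notice (the packaged
lung-cancer test is the example: four lexicon terms, zero mentions).
Features with `OR_PN > 1` (strictly; ties excluded) are dominant. The
default enrichment flag is `freq_P > freq_N`, algebraically equivalent to
`OR_PN > 1` for finite ratios; a strict-monotone variant
(`freq_A < freq_T < freq_N < freq_P`) is available but not the default,
since the published dominance set corresponds to the positive-excess
criterion.

### Knowledge base and recommendation

Each dominant (test, feature) pair becomes one KB entry carrying both
weights, the P/N frequencies, the concept id, and the feature's synonyms
(non-dominant retained features can be kept with a flag, since a high
prevalence weight alone can make a feature a useful prescription signal).
Serialization is versioned JSON (`"igtkb_schema": 1`) plus a flat TSV.
Recommendation matches observed features against ids, terms, and synonyms
case-insensitively and scores each test by the sum of matched dominant
weights. The additive rule is the simplest monotone combination consistent
with odds-ratio weighting, but it lets one very strong single-feature match
outrank a multi-feature match; `max` and `count` rules are provided for
sensitivity analysis, and unmatched observations are reported, never fatal.

## Synthetic cohorts

### Deterministic fixture

The packaged tables (`igtkb/data/paper_tables.yaml`) record, for five
genetic tests, the group sizes, the 60 published (test, feature) mention
counts with their printed frequencies and odds ratios, and the per-test
lexicon sizes (9/86/4/74/131). The generator materializes:

- a background pool of 138,229 patient ids, with feature carriers assigned
  as prefix intervals so that every background count is exact;
- per-test P and N groups (disjoint across tests, a policy choice — the
  overlap structure of the real cohorts is unknown), carriers again as
  prefix intervals; the one test with |P|+|N| > |T| gets cancelled
  duplicate orders on mention-free negative patients;
- one note per mentioned patient containing exactly one neutral sentence
  per carried surface form, and nothing for mention-free patients.

Three reconciliations deserve explanation. First, lexicon rows may span
two tests: four published terms with identical background counts are
shared rows, which together with 57 shared synthetic filler rows makes the
inventory 243 distinct rows yet 304 (test, feature) pairs, matching both
published figures at once. Second, one term (hepatomegaly) is published
with *different* background counts under two tests (244 vs 235) — not
representable with one surface and one shared population, so the fixture
keeps two per-test rows and plants the 9 extra carriers with a private
single-token synonym of the larger row; this emulates per-disorder
extraction dictionaries that differ slightly between runs. Third, the 183
unpublished lexicon features are synthetic filler entries ("Synthetic
phenotype NNN") planted nowhere; they exist only so the lexicon inventory
has the right shape, and they carry zero counts everywhere.

The fixture consumes no randomness: its output is a pure function of the
spec, so the determinism guarantee (same seed, byte-identical files) holds
trivially, and the seed parameter exists for interface symmetry with the
stochastic generator.

What passing the fixture tests shows — and does not show. Exact
reproduction of the published tables demonstrates that group composition,
matching semantics, counting, and the statistics are implemented correctly
end to end. It does not exercise clinical language: planted sentences are
a single fixed template, so matcher recall is 1 by construction. Real
notes would add negations, abbreviations, misspellings, and section
structure that this package intentionally does not model.

### Stochastic cohorts

`generate_stochastic` draws each patient's carriage of each feature as an
independent Bernoulli with the group's prevalence (`numpy`
`default_rng(seed)`; one stream, fixed consumption order, so identical
seeds give identical files). This is the simplest generative process with
a known true odds ratio `(p_P/(1−p_P))/(p_N/(1−p_N))`; it has no
between-feature correlation, no per-patient frailty, and no note-length
variation. The packaged parameter-recovery conditions — prevalence 0.3 in
P vs 0.1 in N, 10,000 patients per group, 20 seeds — give a true ratio of
3.85714, and the mean estimate is required to fall within three standard
errors of it. A law-of-large-numbers check at n = 10,000 verifies
per-group frequency calibration against three binomial standard errors.

## Defaults and problem sizes

| parameter | default | rationale |
|---|---|---|
| `min_tested` | 100 patients in T | test-selection floor used for the five-test inventory |
| `duplicate_policy` | `error` | silent aggregation of duplicate orders is surprising; opt in |
| `retention_mode` | `conjunction` | finite odds ratios, weakest reading consistent with the published rows |
| `dominance_threshold` | 1.0 (strict) | effect direction boundary |
| reporting precision | 5 decimals | the published tables' precision |
| recovery conditions | 0.3 / 0.1, n = 10,000 × 2, 20 seeds | large-sample regime where the estimator's bias is negligible relative to its spread |

Tests with a single disorder are required by default; a test mapped to
several disorders in the catalog is excluded (override with
`allow_multi_disorder`), mirroring the exclusion of multi-disorder assays
from the five-test inventory.

The full fixture (138k background ids, ~43k notes, ~15 MB of generated
text) builds in well under a second and the complete pipeline runs in
about one second on one CPU; the parameter-recovery experiment is the most
expensive packaged computation at roughly a minute.
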
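# Methods

## The rule dialect and its semantics

Each of the seven SDOH domains ships with one search rule written in a small
Lucene-flavoured Boolean dialect (see `src/sdohscan/rules/`). The parser
accepts quoted phrases (straight or curly quotes), a `~N` proximity suffix,
bare terms with an optional trailing `*` wildcard, infix `OR`/`AND`
(case-insensitive), parentheses, and a single top-level `NOT` splitting a
rule into an include and an exclude side. Three conventions seen in
published rule text are handled explicitly:

* `~Nth` (e.g. `"social isolation"~10th`) is read as slop `N`; the trailing
  `th` is taken to be a display artifact of the source system, since `~N` is
  the only coherent proximity reading.
* A comma between quoted phrases is a synonym for `OR` (the finance rule's
  exclusion list uses one).
* Bare exclusion terms (`score OR lab OR echo …`) are single-term phrases,
  giving a uniform tree.

The shipped `.rule` files are the published rules verbatim except that curly
quotes are normalized to ASCII straight quotes; the tokenizer applies the
same mapping to rule and note text, so parsing and matching are unaffected.
Duplicate disjuncts (the finance rule lists "financial difficulty" twice;
the stress exclusion lists `myocardial` twice) are kept in the files and
dropped during parsing. Rendering produces a canonical single-line form
(`~N`, straight quotes, deduplicated) that reparses to the identical tree.

**Tokenization** is deliberately lossy: curly quotes/apostrophes → ASCII,
case folded, tokens are maximal runs of letters/digits with internal
apostrophes kept, everything else a separator, digit runs are tokens (the
social-isolation exclusion `"isolation 14"~6` needs them). All matching is
over these normalized tokens.

**Phrase matching.** A phrase of k terms with slop s matches every *minimal*
token window of length ≤ k + s containing an injective assignment of terms
to matching tokens. With s = 0 the terms must be adjacent and in order; with
s > 0 order is free. This is a simplification of Lucene's move-count slop:
it is deterministic, verifiable by exhaustive window enumeration (the test
suite checks agreement with an independent Hall's-condition oracle on
10,000 random instances), and reproduces the published example behaviour.
Whether the original engine treated `~N` windows as ordered is unknown; the
unordered reading is used for s > 0.

**NOT is document-scoped.** One exclusion hit anywhere in a note vetoes that
note for the rule, mirroring Boolean NOT over documents. Evidence spans are
collected from the include side and exported for review.

**Aggregation.** The unit of matching is the note; a patient is
narrative-positive for a domain when ≥ 1 note of an eligible type (progress
note, telephone encounter, history & physical, assessment & plan —
configurable) is positive. Empty or whitespace-only notes are negative, not
errors; patients with no eligible notes are reported in a "no notes" list.

A consequence of lossy tokenization worth knowing: the food rule's
exclusion entry `"Food insecure?"` tokenizes identically to its include
phrase `"food insecure"`, so that include entry can never fire on its own —
only `food insecurity`, `food pantry` and `food stamp` are effective. The
engine reproduces this faithfully rather than patching the rule.

## Structured arm and cohort

Domains map to Z-code stems (packaged in `data/domain_codes.csv`) with
hierarchical prefix matching, so unlisted children count toward a listed
parent (Z59.4 covers Z59.41). The social-connections grouping uses the
listed subcodes Z60.2/Z60.4/Z60.8; `load_default_code_map(widen_social=True)`
swaps in the whole Z60 category for sensitivity analyses, since summary and
prose descriptions of that grouping differ. Codes are normalized to
uppercase dotted form; bare numeric groupings ("59.4") are rejected unless a
chapter letter is supplied.

Cohort selection: ≥ 2 completed primary-care encounters on distinct dates
inside the closed window (default 2018-01-01..2019-12-31) and ≥ 1 E10/E11
diagnosis dated inside it. Age filtering applies only when ages are
supplied; otherwise all patients are treated as adults (synthetic data omits
birth dates).

## Comparison outputs

The prevalence table reports per-domain patient counts and percentages over
the full cohort, rounded half-up to two decimals. The narrative column can
be raw rule-positive counts or review-confirmed counts; the pipeline
defaults to review-confirmed when labels exist (the convention the published
prevalence figures follow) and stamps the mode in the report. The overlap
summary partitions rule-positive patients into those with and without a
structured code; the partition is conserved by construction.

## Validation statistics

* **Sampling:** per-domain simple random sample without replacement of size
  ⌈fraction·n⌉ (ceil guarantees non-empty samples at small n),
  deterministic in the seed.
* **PPV** = confirmed/flagged with a 95% Wilson score interval (well-behaved
  at small n and at the boundaries; the interval choice is this package's,
  as none is published). Zero flagged units → PPV undefined, flagged as such.
* **Agreement:** p_o is the fraction of aligned units with identical labels;
  κ = (p_o − p_e)/(1 − p_e) with p_e from the reviewers' marginals. When
  both reviewers are constant and equal (p_e = 1, which forces p_o = 1), κ
  is reported as *undefined*, never as a number — the standard convention
  for degenerate tables. The default unit of agreement is the note; κ is
  computed on the per-domain 10% re-review sample, since the two-step review
  design leaves the full-overlap denominator ambiguous.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
clinical prose. Defaults (all overridable in `SynthConfig`):

| parameter | default | rationale |
|---|---|---|
| n_patients | 4283 | reference cohort size |
| notes_per_patient | Poisson, mean 7.07 | 30,288 notes / 4,283 patients |
| true_prevalence | 0.010–0.065 per domain | see below |
| structured_doc_rate | 0.12 | structured prevalence = prev × rate lands in 0.1–0.9% |
| narrative_doc_rate | 0.8 | narrative prevalence = prev × rate lands in 0.8–5.2% |
| fp_snippet_rate | 0.02 | confusable snippet per patient-domain; yields review PPVs broadly in the observed 25–65% range |
| negation_rate | 0.01 | exclusion-protected snippet on non-cases |
| reviewer_error_rate | 0.02 | label flip probability per reviewer |

Per-domain true prevalences (stress 0.065, social/employment 0.058, finance
0.033, housing 0.032, food 0.030, education 0.010) were set once so that the
implied structured and narrative prevalence bands match the magnitudes of
the reference prevalence table; domains are planted independently (no
comorbid-SDOH correlation is modelled, as none is reported).

Design choices that make the planted-evidence properties exact rather than
probabilistic:

* **Disjoint filler.** Filler text is drawn from a vocabulary filtered so no
  word matches any rule term (exactly, or as a wildcard-stem prefix), so
  filler can neither create nor veto a hit.
* **One snippet per note.** Each planted snippet (true-positive, confusable,
  or negation) is placed in its own filler note, so snippets cannot
  interact across domains or kinds within a note. Planted recall is 1 by
  construction, and the note-level PPV under perfect review equals the
  planted true-positive fraction exactly.
* **Template validation.** True-positive templates are the published example
  snippets plus one snippet per include entry, each checked against the full
  rule at build time (the self-vetoing food entry above yields no template);
  negation templates are built from the exclusion entries and are verified
  never to flag any domain.

Simulated review labels every flagged note with the note-level ground truth
(does the note carry a true-positive plant for that domain?) flipped
independently per reviewer with the configured error rate.

**What passing synthetic tests does not show:** real notes have sections,
copy-forwarded text, negations outside the rules' explicit exclusion lists,
misspellings, and correlated social risks; none of these are emulated, so
synthetic PPV/recall say nothing about rule performance on real EHR text —
that is exactly why the manual-review statistics exist.

## Numerical and degenerate-input conventions

Percentages round half-up via exact decimal arithmetic; κ's p_e = 1 case is
detected with integer arithmetic (a = n or d = n), not float comparison;
minimal proximity windows are deduplicated by strict containment; empty
inputs (notes, label lists, zero flagged units) return defined negatives or
flagged-undefined values rather than raising, except where the contract
requires an error (aligned-list length mismatch, malformed codes, flags for
patients outside the cohort).

## Problem sizes used by the shipped checks

The end-to-end synthetic study in the test suite and acceptance script uses
2,000 patients (≈ 15,000 notes), large enough that every per-domain rate
check has its 3-standard-error band well inside the design range while a
full run stays in the seconds range; the proximity oracle comparison uses
10,000 random instances with streams up to 30 tokens, 2–4 terms and slop up
to 10.

## Known limitations

* Slop semantics are a documented approximation of Lucene's; ordered-window
  behaviour for s > 0 is not configurable.
* No general negation/uncertainty detection, section segmentation, stemming
  beyond trailing wildcards, or note deduplication.
* Sensitivity/specificity are computable only on synthetic data (real
  review covered flagged notes only); the package deliberately offers no
  real-data sensitivity estimate.
* The housing review percentage in the reference material is internally
  inconsistent (the tabulated row total and the prose total differ by 21
  patients); the worked examples follow the denominator consistent with the
  printed percentage.
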
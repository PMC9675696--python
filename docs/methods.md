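# Methods

## Scope and model

The package models the type-level diagnosis of pituitary neuroendocrine
tumours from immunohistochemistry (IHC) alone, under the WHO 2022
lineage taxonomy. A tumour is represented by a nine-slot profile — three
transcription factors (SF1, TPIT, PIT1) and six hormones (PRL, TSH, GH,
ACTH, LH, FSH) — each tri-state: positive, negative, or *not performed*.
The third state is load-bearing: tiered strategies deliberately leave
stains unordered, and the classifier must never read an unperformed
stain as negative. Granulation subtypes, proliferation markers (Ki67,
mitoses), cytokeratin patterns and prognosis are out of scope;
morphology enters only as three optional boolean flags (monomorphous,
immature, acidophil-stem-cell features) whose histological derivation is
external to the package.

## Binarization

Percent-positive-cells readings are converted to calls with an inclusive
threshold: positive iff percent ≥ threshold, default 10%. The clinical
rule is stated for transcription factors; the package applies the same
configurable threshold to hormone percentages for consistency, and
accepts pathologist-called `+`/`-` values as-is. The supplied percentage
is treated as the final per-tumour reading (no per-slide modelling).

## The decision table

`classify` evaluates, in order: (1) count positive transcription factors
*T*; (2) *T* = 0 with all six hormones performed and negative → null
cell; (3) *T* = 0 with any hormone positive → plurihormonal, no distinct
lineage; (4) *T* ≥ 2 → plurihormonal, no distinct lineage; (5)/(6)
*T* = 1 with SF1 or TPIT → gonadotroph or corticotroph, hormone results
never altering the type (out-of-lineage positivity and TPIT+/ACTH−
silence are surfaced as warnings); (7) *T* = 1 with PIT1 → a sub-table
on GH/PRL/TSH and the morphology flags.

Design choices made where the taxonomy is not operational:

* **Null cell is a diagnosis of exclusion.** With *T* = 0, no positive
  hormone and any hormone unperformed, the result is `unclassifiable`,
  never null cell.
* **PIT1 sub-table.** The mapping from hormone patterns and flags to the
  eight PIT1-lineage types is this package's documented convention and
  ships as an editable TSV (`data/pit1_subtable.tsv`), matched first-row
  wins: acidophil-stem-cell flag, then immature flag, then single-hormone
  rows (GH → somatotroph, PRL → lactotroph, TSH → thyrotroph), then
  GH+PRL+TSH− split by the monomorphous flag (true → mammosomatotroph,
  false → mixed somatotroph–lactotroph, unassessed → mammosomatotroph
  with a warning), then any other multi-hormone pattern → mature
  plurihormonal PIT1, and finally the hormone-silent row → immature PIT1
  with a warning. A missing GH/PRL/TSH stain yields `unclassifiable`
  naming the stain; a missing transcription-factor stain raises, since
  the table cannot start.
* **Clinical presentation never types.** It is carried on records for
  the functioning column of frequency tables and for plausibility
  warnings (e.g. acromegaly with GH-negative IHC).
* **Auditability.** Every classification records the ordered rule
  identifiers that fired (`R1-TF-COUNT[1] -> R7-PIT1-SUBTABLE -> P7-SOM`).

Over all 2⁹ fully performed profiles the table is total, deterministic
and never `unclassifiable`, and the returned type's lineage equals the
single positive transcription factor exactly when there is one (tested
exhaustively).

## Staining strategies

Strategies run against a *stain oracle* — the tumour block abstraction
that answers what any stain would show, identically on repeat. Tiers are
laboratory batches: all tier-1 results (SF1, TPIT, PIT1) are available
before tier 2 is chosen; there is no stain-by-stain adaptivity within a
tier, and no modelling of stain failure or repeats. With zero or
multiple positive transcription factors every algorithm reflexes to the
complete hormone panel (9 stains total). With exactly one positive, the
tier-2 orders are data (`data/algorithms.yaml`):

| branch | Algorithm 1 | Algorithm 2 | Algorithm 3 |
|---|---|---|---|
| SF1+ | LH, FSH (5 total) | none (3) | none (3) |
| TPIT+ | ACTH (4) | none (3) | none (3) |
| PIT1+ | all six (9) | all six (9) | GH, PRL, TSH (6) |

Algorithm 1's branch rules are reconstructed (lineage-confirmatory
hormones for SF1/TPIT, full panel for PIT1); this reconstruction
reproduces the published cohort-average stain count after rounding, and
because it is a data file a variant reading can be swapped in without
code changes. Stains are emitted in a fixed canonical order (SF1, TPIT,
PIT1; PRL, TSH, GH, ACTH, LH, FSH) so plans are byte-reproducible; cost
is stain count × unit cost (default $50 AUD), order-independent.

`diagnose_with_strategy` classifies from the tier-limited observed
profile only, exactly as a reporting pathologist would see it. The only
information a tiered algorithm discards is hormone results outside a
confirmed single lineage; since the decision table treats those as
warnings rather than type changes, the exhaustive 2⁹ audit finds an
empty discordant set — tier-limited and full-panel diagnoses agree on
every profile, not just the cohort's.

## Evaluation conventions

Concordance compares the tiered diagnosis with the full-panel diagnosis
per tumour, at type level by default; a lineage-level mode compares only
the defining transcription factor (keeping null cell and plurihormonal
distinct). Reported percentages and stain averages are rounded half-up
to 1 decimal (banker's rounding would turn the cohort's 4.75 into 4.7).
Average cost is the rounded average stain count × unit cost, to the
nearest whole unit — the derivation is printed in the report footer.
Totals are reported exactly as computed.

## The reconstructed cohort

The packaged 113-record cohort is rebuilt from the published summary:
per-type counts, per-type clinically-functioning fractions, and the 12
verbatim profiles of the no-distinct-lineage tumours (11 plurihormonal,
1 null cell). The 101 distinct-lineage tumours, whose individual
profiles were not published, receive the simplest profile consistent
with each type (defining transcription factor plus defining hormone(s)
positive, all else negative; morphology flags where the type requires
them), with functioning cases labelled first within each type
(acromegaly for GH-expressing types, prolactinoma for lactotrophs,
Cushing for corticotrophs, otherwise "other"). Tiered stain counts
depend only on the transcription-factor pattern, which the published
lineage assignment fixes, so these conventions do not move the
evaluation. The published raw stain totals exceed this reconstruction
by 1–5 stains — a few real cases evidently carried unpublished
co-expression — so the 1-decimal averages, which are invariant to that
gap, are the reproduction surface; the package reports its computed
totals (767/663/537) alongside.

## Synthetic cohorts

`generate` draws records i.i.d.: type from the observed cohort
frequencies (default), functioning status from the type's observed
fraction, then two noise mechanisms, both default 0:

* `hormone_silent_rate` — switches a distinct-lineage tumour's defining
  hormone(s) to negative, reference type unchanged (the "whispering"
  phenotype). It never creates out-of-lineage positives, so tiered/gold
  concordance is structurally unaffected.
* `aberrant_tf_rate` — adds one spurious transcription factor to a
  distinct-lineage tumour, making the reference type plurihormonal;
  these cases route to the multi-transcription-factor full-panel branch
  in every strategy.

One RNG stream with a fixed per-record draw order (type, functioning,
silencing, aberrance, aberrant-TF choice; every record consumes exactly
five draws) makes cohorts byte-identical for a fixed seed and
prefix-stable as *n* grows. The generator emulates cohort composition
and marker patterns only: it does not model tumour size, invasion,
biochemical hormone levels, inter-observer variation in percent
scoring, or out-of-lineage hormone aberrance (the one mechanism that
could break tiered/gold concordance — deliberately a separate, default-
off consideration, and not reported for the real cohort). Passing tests
on synthetic cohorts therefore certify the algorithmic machinery, not
the real-world frequency of the discordance-inducing phenotypes.

## Problem sizes and numerics

Exhaustive checks enumerate all 2⁹ = 512 profiles; statistical checks on
the generator use n = 200–1000 with fixed seeds (a binomial 3-standard-
error band for the frequency check). All money values are unit-cost
multiples with no intermediate rounding beyond the documented average;
no floating-point tolerance is needed anywhere in the decision logic,
which is exact.

## Known limitations

* The canonical profiles for the 101 distinct-lineage tumours are the
  simplest consistent choice, not the real (unpublished) data; per-case
  hormone co-expression in the real cohort is not recoverable.
* The PIT1 sub-table rows for flag-dependent types encode this package's
  convention where the taxonomy's histological criteria (monomorphous vs
  dimorphous populations, maturity) are not computable from IHC.
* The cost model is linear in stain count with a single unit price; no
  batching discounts, re-biopsy, stain failure or labour modelling.
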
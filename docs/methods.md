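# Methods

## The evaluation model

`hlatrio` evaluates HLA genotype calls without a curated gold standard by
exploiting pedigree structure. HLA class I alleles (loci A, B, C) segregate
in a Mendelian fashion: each child carries two alleles per locus, one
inherited from each parent. If a typing method is accurate, each child
allele it reports should also be reported in the assigned parent. The
package quantifies this with Descent Accuracy and complements it with
Method Agreement, homozygosity rates, and direct-counting allele
frequencies, all computed after explicit reduction of allele identifiers to
a working resolution.

### Allele identifiers and reduction

An identifier holds a gene symbol, one to four numeric fields, and an
optional expression-status letter. Field counts map to resolution levels:
one field (2-digit) is the serological allele group, two fields (4-digit)
the distinct protein, three and four fields add synonymous and non-coding
variation. Reduction to a target resolution keeps the left-most fields and
drops the rest (`A*02:01:01:02 → A*02:01`) together with the expression
suffix; an identifier at or below the target is returned unchanged, never
padded. Fields may hold 2–4 digit characters — real nomenclature exceeds
two digits (e.g. `A*02:101`) — and leading zeros are significant.
Expression suffixes are retained but ignored in comparisons by default
(a strict flag exists); `G`/`P` ambiguity-group identifiers are rejected
rather than silently truncated, since ambiguity-group expansion requires a
database this package deliberately does not ship.

### Descent Accuracy

For one child at one locus, the two child alleles are assigned to the two
*different* parents (one allele from each progenitor); a child allele is
explained when it equals, at the working resolution, one of the assigned
parent's alleles. `N_eq` at the locus is the maximum number of explained
child alleles over both parent orders, found by exhaustive enumeration of
the (at most 2 × 3 × 3) assignment configurations. Then

    DA = N_eq / N_alleles,    N_alleles = N_children · 2 · |loci|.

Design points:

* **One allele per parent.** A child cannot inherit both alleles from one
  parent. A laxer rule — each child allele explained by either parent
  independently — is available via `require_distinct_parents=False` for
  sensitivity analysis; it can only raise `N_eq`.
* **Homozygous children.** The two identical child alleles are distinct
  slots; both count only when both parents carry the allele.
* **Ties.** When several distinct maximal assignments exist (e.g. both
  child alleles occur in both parents), the first configuration in a fixed
  canonical enumeration (parent order, then parent slot order) is recorded
  and the locus is flagged ambiguous. Configurations differing only in
  which of two *identical* child slots is matched are considered the same
  assignment, so a homozygous child does not spuriously flag ambiguity.
* **Exclusions.** Only complete trios count, and a family enters a locus
  only when all three members have a call for the method there (finer-
  grained than dropping whole families); every exclusion is listed in the
  report.

Reduction can only merge alleles and therefore only create matches, so DA
at a coarser resolution is never below DA at a finer one. The same argument
applies to the homozygosity rate. This monotonicity is a theorem of the
matching definition and is verified on perturbed cohorts in the tests.

### Transmission phasing and Method Agreement

From the maximal trio assignment, each matched parent allele slot is marked
*transmitted* and its sibling slot *non-transmitted*; a parent with no
assigned child allele at a locus (including inconsistent loci with
`N_eq = 0`) is unresolved there. Ambiguous assignments are tie-broken as
above and flagged, not discarded.

Method Agreement between two methods is, per sample and locus, the size of
the multiset intersection of the two unordered allele pairs after reduction
(so `{a,a}` vs `{a,b}` agrees on one allele, not two), summed and divided
by `N_population · 2 · |loci|`. A sample enters only if both methods typed
it at every evaluated locus, keeping the denominator exact; partially typed
samples are excluded and listed. MA_T (resp. MA_NT) restricts both
numerator and denominator to transmitted (resp. non-transmitted) slots
under the phasing of a single configurable reference method (default: the
first method) — the two methods may phase differently, so one reference is
used for both. Child slots are all transmitted by definition; unresolved
slots are excluded from both splits and counted separately. When a slot's
agreement is needed, matches are assigned to the reference method's slots
in slot order, which makes the split deterministic. The per-individual
agreement counts (0 to 2·|loci|) feed a concordance histogram.

### Population statistics

The homozygosity rate per locus is `HR = N_hom / N_population`, where an
individual is homozygous iff its two alleles are equal *after* reduction to
the working resolution — this is what makes HR comparable across methods
reporting different native resolutions, and why HR can only rise under
reduction. HR and allele frequencies are computed on parents by default:
parental alleles are draws from the population, whereas a child's alleles
are a subset determined by its parents. A role flag enables other choices.
The overall HR pools counts across loci; the unweighted mean of per-locus
rates is also reported since both conventions exist.

Allele frequencies use direct counting: each allele occurrence (two for a
homozygote) over `2 × N_typed` chromosomes per locus; per-locus frequencies
sum to 1 by construction. Top-k ranking is by descending frequency with
exact ties broken by the canonical allele string. Reference comparison
matches cohort alleles to published per-population tables at 4-digit
resolution, reporting an explicit absent marker (`NA` in TSV, `null` in
JSON) where a population lacks the allele. CWD classification labels an
observed allele common iff its 4-digit reduction is in the catalogue;
a catalogue can also be built from a reference table using the standard
thresholds (frequency > 0.001 in a population of ≥ 1500 individuals), which
requires the optional `sample_size` column.

## The synthetic cohort generator

The simulator provides ground truth with known statistical structure:

* **Founders** are drawn i.i.d. under Hardy–Weinberg equilibrium: two
  independent allele draws per parent and locus from the configured
  frequency vector, so expected parental homozygosity is Σ pᵢ².
* **Transmission** gives each child one uniformly chosen allele from each
  parent per locus, so truth cohorts have DA = 1 at every resolution by
  construction.
* **Error processes**, applied independently per individual × locus in a
  fixed order: (1) homozygote inflation — with probability η a heterozygous
  pair {a,b} becomes {a,a}, emulating typers that spuriously call
  homozygous loci; (2) miscalls — each allele slot is replaced with
  probability ε, with probability σ by a different allele from the same
  2-digit serotype group (miscalls that preserve the serological group are
  a characteristic typer failure mode), otherwise by a uniformly chosen
  different pool allele; (3) truncation of the observed call to the
  method's output resolution (4 or 8 digits). Every applied operator is
  recorded as provenance. A `novel_replacement` mode draws miscalls from
  allele group 99, which generated pools never contain, so a miscalled
  child allele is guaranteed unexplainable — this makes expected DA exactly
  1 − ε under children-only errors and is used for calibration checks.

Defaults: 50 families; loci A, B, C; 12 alleles per locus arranged in four
serotype groups (each group holds two alleles sharing their 4-digit protein
but differing in the non-coding field, plus one distinct protein, so
reduction genuinely merges alleles) with frequencies drawn from a symmetric
Dirichlet(1.5); ε = 0.05, σ = 0.5, η = 0.02. The error rates are
illustrative defaults — no quantitative rates are established for the
failure modes they emulate — and should be set per study.

Determinism: each (seed, method, sample, locus) tuple keys its own
pseudo-random stream (CRC-32 of the string keys fed into a seed sequence),
so identical configurations produce byte-identical outputs regardless of
iteration order, and different method labels are independent. Errors are
independent across family members; real method biases that hit a whole
family identically are *not* emulated, which is a known limitation — DA on
real data can stay high while both methods are consistently wrong, which is
exactly why MA complements DA. Loci are simulated independently (no linkage
disequilibrium), read-level effects are out of scope, and the allele pools
are far smaller than the real HLA allele universe; passing recovery tests
therefore validates the estimators and the error-model plumbing, not the
behaviour of any real typer.

## Numerical and interface choices

* Unordered allele pairs are stored sorted by canonical string; equality
  and hashing are order-independent and homozygotes keep both copies.
* Frequency references store alleles reduced to 4-digit on read (the one
  reader that reduces; all other comparisons reduce explicitly downstream).
* Per-locus frequency sums in references may be below 1 (partial tables)
  but error above 1 + 1e-6.
* Reports expose every numerator and denominator; TSV and JSON outputs
  carry identical values with deterministic column order.
* Validation sizes: truth identities and oracle equivalence run on
  exhaustive small alphabets (all 216 trios over 3 alleles; all 36
  pair-of-pairs) plus 10,000 random 10-allele trios; parameter-recovery
  checks use 500-family cohorts (1000 parents, 3000 child alleles) and
  3-standard-error bands; monotonicity uses 100 perturbed 20-family
  cohorts. These sizes give stable statistics while keeping the whole
  suite fast.
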
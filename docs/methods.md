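# Methods

## Classification model

Variants are classified on the ordered five-level scale B < LB < VUS < LP < P
by combining invoked ACMG/AMP evidence codes. All 28 codes of the guideline
are modelled (PVS1; PS1–4; PM1–6; PP1–5; BA1; BS1–4; BP1–7); direction and
strength are fixed by the code family, and each code is used only at its
default strength — strength modulation (e.g. upgrading PM3 with multiple
in-trans observations) is deliberately out of scope, since the analysis this
package supports only ever invokes codes at default strength.

The combining rules are encoded as count predicates over
(PVS, PS, PM, PP, BA, BS, BP):

* **Pathogenic** — PVS1 with (≥1 PS | ≥2 PM | 1 PM + 1 PP | ≥2 PP); ≥2 PS;
  1 PS with (≥3 PM | 2 PM + ≥2 PP | 1 PM + ≥4 PP).
* **Likely pathogenic** — PVS1 + 1 PM; 1 PS + 1–2 PM; 1 PS + ≥2 PP; ≥3 PM;
  2 PM + ≥2 PP; 1 PM + ≥4 PP.
* **Benign** — BA1, or ≥2 BS. **Likely benign** — 1 BS + 1 BP, or ≥2 BP.

Exact-count clauses are encoded with ≥ thresholds wherever the larger count
is already covered by a stronger rule; the exhaustive enumeration test pins
the resulting behaviour against an independently coded literal transcription
of the rule table.

**Conflict resolution.** Automated interpretation platforms resolve mixed
evidence conservatively: strong benign evidence alongside a pathogenic
combination yields VUS rather than LP/P. We therefore return VUS whenever a
pathogenic combination fires while *any* benign-direction assessment is
present, and symmetrically when a benign combination fires alongside any
pathogenic-direction assessment. This is deliberately broader than "both a
pathogenic and a benign combination fire": a single BS (e.g. BS1 from an
elevated sub-population frequency) is enough to pull an otherwise-LP variant
to VUS, which is exactly the behaviour the high-frequency discordance
mechanism describes. The policy is monotone — adding pathogenic evidence
never lowers the ordinal class, adding benign evidence never raises it —
verified exhaustively over all 2^11 subsets of a representative code panel.

**PVS1 / NMD escape.** A null variant escapes nonsense-mediated decay when it
lies in the last exon or within the final 50 bp (inclusive; a variant exactly
50 bases from the exon end still escapes) of the penultimate exon;
single-exon transcripts always escape. PVS1 is withheld for escaping
variants unless clinical cases with LP/P variants 3′ of the variant exist.

**In-silico consensus.** For nonsynonymous variants, PP3/BP4 require a strict
majority of the missense predictors with a call (CADD, PolyPhen, SIFT,
MutationTaster); ties and all-no-call panels invoke nothing. For synonymous
or intronic variants both splicing predictors (MaxEntScan, GeneSplicer) must
be concordant.

**BS1.** Exposed in two modes, because it is genuinely ambiguous whether the
"frequency greater than expected for the disorder" comparison should use the
maximum sub-population frequency (what automated tools do) or the global
frequency (what manual review effectively does): `subpopulation_max` fires
when any population exceeds the disorder's maximum credible frequency,
`global` only when the global frequency does. Global mode can never fire
when sub-population mode does not. BA1 has no dedicated frequency operation
and is supplied directly as an assessment when needed.

## Consensus and funnel

A variant's archive consensus is built from qualifying submissions only:
whitelisted submitter, assertion criteria provided, and dated *strictly*
before the snapshot cutoff (a literal reading of "prior to" the cutoff
date). Fewer than two qualifying submissions ⇒ insufficient; mixed
positive/negative strata ⇒ discordant; otherwise high confidence with the
shared binary label — sub-type disagreement within a stratum (P vs LP, B vs
LB) is tolerated. A high-confidence consensus contradicting the analysing
laboratory's own binary interpretation is demoted to a lab conflict and
excluded from analysis. Assertion-criteria provenance is modelled as a
per-record boolean; the per-laboratory "majority of submissions provide
criteria" heuristic is approximated by the whitelist itself.

## Concordance and discordance taxonomy

The reporting dichotomy is P/LP = positive, VUS/LB/B = negative. Concordance
is tabulated per unique variant and per case (each variant weighted by its
cohort case count; the two coincide when all counts are 1). Percentages are
computed within each manual column at one decimal, rounding half up —
the convention of the tables this pipeline renders. Prior manual
interpretations are considered current for six calendar months; exactly six
months elapsed already triggers re-review (conservative boundary; month
arithmetic clamps to month ends, so 31 Aug + 6 months = 28 Feb).

Each discordant record is assigned exactly one of nine mechanistic
categories by the first matching rule in a fixed priority order (the source
analysis assigns one category per variant without stating a tie-break; a
fixed order makes the classifier deterministic and auditable):

1. automated-only PVS1 with the late-null flag → **late null variant**;
2. missed-archive-entry flag with manual-only PP5/BP6 → **ClinVar entry not
   identified**;
3. phenotype-mismatch flag with automated-only PM3/PP1/BS2/BP2 →
   **atypical phenotype**;
4. sub-population-frequency flag with automated-only BS1 on a positive
   consensus → **high-frequency pathogenic variant**;
5. healthy-in-population flag with automated-only BS2 on a positive
   consensus → **variable penetrance**;
6. manual-only literature-sourced PM3/PP1/BS2/BP2 → **case criteria not
   invoked**;
7. manual-only PS3/BS3 → **functional criteria not invoked**;
8. symmetric difference confined to PM1/PP3/BP4 → **functional prediction**;
9. otherwise → **expert decision**.

Specific flagged mechanisms precede the generic literature/functional
categories so that, e.g., a missed archive entry that also removed a case
criterion is attributed to the archive miss. Calling the classifier on a
concordant record is an error, never a silent "none".

## Synthetic cohort generator

The generator emulates the statistical structure of a one-year
carrier-screening interpretation study: ~116,721 observed variants of which
~4.75% reach high-confidence consensus, a 0.3% lab-conflict rate among those,
a 23.5% positive fraction among retained variants, a published mechanism mix
among discordances, and heavy-tailed per-variant case counts (~362 cases per
retained variant on average, ≈2 million observations at full scale).

For each variant it draws a funnel fate, a consensus stratum, a manual class
(positives 55% LP / 45% P; negatives 60% VUS / 25% LB / 15% B) and a manual
criteria set by rejection sampling over direction-appropriate code pools
(bounded attempts, loud failure). With the configured per-stratum
probability a discordance mechanism is chosen and injected: the automated
view is edited — codes removed weakest-first or added from small filler
pools, iterating until the binary class actually flips, because the
combining rules are nonlinear and no single edit is guaranteed to flip —
and the result is verified to (a) be discordant and (b) classify to exactly
the injected mechanism; incompatible manual draws are resampled. Qualifying
submissions (2–5 per high-confidence variant, sub-type jitter within the
stratum), single or stratum-mixed submissions for insufficient/discordant
variants, and an internal label opposite the archive consensus for
lab-conflict variants complete the cohort. All randomness flows through one
seeded generator, so identical configuration and seed give byte-identical
cohorts.

Case counts default to a lognormal family (μ ≈ 2.77, σ = 1.5, mean ≈ 362);
a Zipf family with configurable exponent is also available, and σ = 0 with
μ = 0 degenerates to a point mass at 1. Discordant positive variants have
their expected count multiplied by the amplification factor (preset: 6,
the approximate ratio implied by the published per-variant and per-case
positive-discordance rates); for the lognormal family the log-mean is
shifted by log A, for the Zipf family a count is the sum of
⌊A⌋ + Bernoulli(A − ⌊A⌋) draws — either way the expectation scales exactly
by A.

**Preset stratum assignment.** Each mechanism is assigned wholly to one
consensus stratum: false-negative mechanisms (case criteria, high frequency,
functional criteria, expert decision, variable penetrance, missed archive
entry) act on positives at rates count/1,299; false-positive mechanisms
(atypical phenotype, functional prediction, late null) act on negatives at
rates count/4,232. The published tables are mutually inconsistent by nine
variants (295 + 73 = 368 discordant variants per the confusion table, 359
per the mechanism tabulation), so no assignment can match both exactly; the
preset reproduces the mechanism mix exactly in expectation and the
per-variant discordance margins approximately (23.2% expected vs 22.7%
published on positives; 1.35% vs 1.7% on negatives).

**What the generator does not emulate.** Manual criteria sets for positive
(negative) variants are drawn from pathogenic-direction (benign-direction)
codes only, so a sampled manual set never self-conflicts — real manual
interpretations can carry opposing evidence. Case counts are i.i.d. given
the discordance mask, whereas real counts correlate with gene, population
and variant identity; in particular the generator does not give
consensus-negative variants the much larger counts they have in the real
cohort, so *overall* per-case concordance in a simulated cohort is lower
than the published 99.5% even though the positive-column amplification
(≈23% per-variant → ≈63–74% per-case discordance) reproduces. Submission
dates are uniform over the year before the cutoff; real submission dates
cluster. Passing tests therefore demonstrate correctness of the pipeline's
accounting and the direction and rough magnitude of frequency
amplification, not distributional realism of archive data.

## Problem sizes and numerical choices

The test suite and acceptance script run the enumeration oracle over all
2,048 subsets of an 11-code panel, the fixture analyses at full published
size (5,531 comparison records; 2,004,273 weighted observations; 116,721
consensus results), and synthetic-cohort checks on 2,000–10,000-variant
cohorts with every variant high-confidence (5,000 retained records for the
recovery analysis — with the realistic 4.75% funnel fraction a cohort of
that size would retain too few discordances to test the mechanism mix
statistically). Monte-Carlo recovery checks use 99% binomial intervals.
Percentages use exact decimal arithmetic with half-up rounding; floating
error cannot move a printed value across a rounding boundary.

## Known limitations

* The per-case false-positive cell of the published per-case table prints an
  internally inconsistent percentage (0.01 where the cells imply ≈0.06%);
  the pipeline reports the computed value (0.1% at one decimal) and does not
  reproduce the printed one.
* The nine-variant gap between the discordance tabulation total (359) and
  the confusion-table discordance count (368) is preserved as-is: both
  numbers are reported and never forced to agree.
* The qualifying-submitter whitelist is configuration (default
  `lab_01`–`lab_06`); no real laboratory identities are modelled.
* HGVS parsing, variant-effect prediction, and live database access are out
  of scope; variant keys are opaque identity tokens and all evidence arrives
  as structured input.
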
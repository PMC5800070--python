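# Methods

## Data model and coordinate conventions

All imbalances are stored with hg19 coordinates exactly as reported in
clinical tables and treated as half-open intervals `[start, end)`:
length is `end − start`, and two intervals that merely touch
(`a.end == b.start`) do not overlap. This convention is self-consistent
with the packaged call series, in which every reported size equals
`end − start` bit-exactly, and it makes interval arithmetic unambiguous
(intersection `[max(starts), min(ends))`, empty when non-positive).

Clinical classification labels (pathogenic / likely pathogenic /
uncertain / likely benign) are *inputs*: the package consumes expert
ACMG-style assignments, it does not derive them. Inheritance strings are
normalized through a fixed table ("Unk" → unknown, "Not mat" →
not-maternal, "Mat"/"Pat" → maternal/paternal, "--" → unknown);
unrecognized strings map to unknown with a logged warning rather than an
error, because origin labels in clinical tables are free text.

Age strata are infants [0, 24), children [24, 120), adolescents
[120, 240) and adults [240, ∞) months — the month cuts chosen as the
unambiguous, testable reading of the year-based groups the field uses.
The cuts partition every non-negative age (property-tested).

## The packaged cohort

The fixture is a fully transcribed clinical case series: 61 patients of
a 279-patient syndromic-obesity referral screen who carried clinically
reportable CNVs — 74 rows, of which 68 are pathogenic imbalances
(49 deletions, 19 duplications) and 6 are second-site variants of
uncertain/benign significance that accompany a pathogenic event in five
patients plus one uncertain deletion. Complex events are stored one row
per segment (`rearrangement_kind` marks translocation and complex
components). Two sub-5-Mb partner duplications of derivative
rearrangements are deliberately not carried as separate imbalances; with
that reading, and with inheritance counted once per patient (priority
de novo > inherited > not-maternal > unknown), every summary row of the
yield table reconciles simultaneously — imbalance-level 68/49/19/21 and
patient-level 30/6/19/6 over 61 carriers. Size, type and the > 5 Mb
split are therefore counted per imbalance; inheritance and all
catalog-overlap figures per patient. Each tally entry records its own
denominator because yield tables mix the two levels.

The "patients with any imbalance" line of a screen (carriers of *any*
variant class over the whole cohort) is only computable when benign
calls of CNV-negative patients are present; on a reportable-only table
the tally marks it unavailable instead of guessing.

## The locus catalog

Recurrence is counted against a catalog of named genomic-disorder
regions, not by raw overlap, because a terminal and an interstitial
deletion of the same syndrome region belong to one locus even when the
segments themselves do not intersect (raw single-linkage clustering
remains available separately). The region bounds are an editorial layer:
each is drawn around the disorder's critical region, tightly enough that
neighbouring loci on one arm stay distinct. Two bounds matter and are
set deliberately: the proximal (DiGeorge) 22q11.2 region ends at
21.46 Mb so the distal-deletion carriers are not pulled into it, and the
13q12.3 region starts at 31.04 Mb so the large 13q11q12.3 duplication
territory does not match the 13q12.3 microdeletion locus. 8p23 is split
into a terminal-deletion region and the classic REPD–REPP 8p23.1 region;
they do not overlap. A single-gene CDKL5 entry is carried with
`known_genomic_disorder = false` — it annotates but does not count as a
genomic-disorder region. Matching uses a 1-bp minimum overlap by
default; a call may match several regions, and each patient contributes
once per locus.

Causality flags are CNV-type aware (`causal_cnv_type`): deletion for the
nine established deletion loci (1p36, 1p21.3, 2p25.3, 2q37, 6q16,
9q34.3, both 16p11.2 intervals, 17p11.2) and duplication for
12p13.31/GNB3, since only those type/locus combinations are established
causes of syndromic obesity; the reciprocal events count as
known-disorder hits but not as causal.

## Statistics

Fisher's exact test (two-sided, via scipy) reports the sample odds ratio
`ad/bc` (∞ when `bc = 0`); a zero margin is an undefined test and raises
rather than returning 1. The phenotype-pair analysis tests, for each
unordered feature pair, the indicator "patient shows both features"
against carrier status with Pearson's chi-square, no continuity
correction by default (a flag enables Yates, and a both/one/neither
three-level coding is available behind a flag); pairs whose 2×2 has a
zero margin are marked non-evaluable rather than dropped silently. No
multiple-testing correction is applied by default, matching the raw
p < 0.05 convention of exploratory cohort heat maps. The network draws
an edge per significant pair; the core is the set of nodes whose degree
reaches the upper quartile of the *distinct* positive degrees (rounded
upward, ties kept) — chosen so a single dominant hub is not diluted by
many degree-1 spokes — or alternatively a top-k rule. Unknown phenotype
status is excluded from both margins everywhere, so each feature and
pair carries its own denominator.

Percentages in reports use round-half-up at the printed precision
(integer or one decimal), implemented with decimal arithmetic so
`62.5 → 63` regardless of binary rounding.

## Anthropometry

LMS z-scores and their inverse use the standard Box-Cox forms; the
inverse at percentile p is `M(1 + L·S·z_p)^{1/L}` (L ≠ 0), exact rather
than iterative, and mutual inversion is property-tested to 1e-6. For
L < 0 the transform's support caps attainable z at `−1/(L·S)`; requests
beyond it raise. Reference lookup interpolates L, M and S componentwise
linearly between tabulated rows (nearest-row mode is provided; exact
midpoint ties resolve to the lower row). Classification is
age-group-appropriate: infants by weight-for-height z (> 1.0 flags the
excessive-gain referral criterion; the threshold is configurable since
"about one SD" is not operational), children and adolescents by
BMI-for-age percentile with the moderate/severe split at 120% of the
95th-percentile BMI (an epsilon keeps a BMI constructed as exactly
1.2 × P95 on the severe side), adults by absolute BMI ≥ 30. Patients
referred as obese without measurements stay in the cohort but are
unclassifiable and drop out of severity strata.

The packaged LMS tables are **synthetic**: smooth curves with realistic
magnitudes (pediatric BMI median ~16.5 dipping then rising to ~21 kg/m²
by age 20; weight-for-height near a power law), both sexes, half-month
steps, in the CDC CSV dialect. They exercise every code path and make
severity grading reproducible offline, but absolute percentiles computed
from them are not population-calibrated: analyses that need real
centiles should point the same reader at the official tables.

## Synthetic cohorts

The generator's defaults are the study conditions of the emulated
screen: n = 279, carrier prevalence 61/279, 55% male, age-group weights
19/153/98/10, severity mix 23/77 moderate/severe among obese
children/adolescents, missing-anthropometrics rate 42/279, and a
15-feature phenotype spectrum whose non-carrier base rates and carrier
log-odds shifts derive from the cohort's aggregate feature counts (kept
as an explicit table in the source). Carrier CNVs are placed inside
catalog regions (size within 200 kb of the region, uniform placement),
so generated cohorts always validate against the catalog and hg19
bounds.

Pair effects use the Plackett bivariate Bernoulli: given margins and a
target odds ratio, the four cell probabilities come from the closed-form
quadratic, so planted pair odds ratios are exact and
`expected_summaries` returns analytic truth for every planted quantity.
Each feature may join at most one pair (keeping the joint law exact);
any positive odds ratio is feasible at interior margins, degenerate
margins raise. Anthropometrics are drawn by sampling the
percent-of-95th-percentile ratio (moderate uniform on [1.0, 1.2), severe
1.2 plus an exponential tail capped at 1.9) and multiplying by the P95
of the same LMS reference the classifier uses — hence classification
recovers the planted category exactly, which is the key recovery
invariant in the tests. All randomness flows from one numpy generator in
a fixed column-wise draw order indexed by patient position, so outputs
are byte-reproducible for a seed and independent of container insertion
order (the per-patient-substream design this replaces would give the
same guarantee at higher cost).

## What the tests do and do not show

Fixture-derived checks (yield tallies, recurrence, SROs) are exact
reproductions of a real case series and carry its evidential weight.
Statistical behaviour is checked on synthetic cohorts against
independent oracles: per-base bitmap intersection for interval algebra,
an explicit union-find for clustering, exhaustive hypergeometric
enumeration for Fisher (all tables with N ≤ 18 plus randomized coverage
to N = 40), the Σ(O−E)²/E closed form for chi-square, null calibration
(pair-significance rate over 1000 seeded cohorts of n = 400 stays at the
nominal level) and planted-odds-ratio recovery (±15% median over 50
seeds at n = 5000; the planted-pair power check uses carrier-enriched
margins, the regime the method targets). Problem sizes were chosen so
the full suite runs in well under a minute per module. What synthetic
cohorts do not emulate: array platform noise and CNV-calling artifacts,
correlated missingness of clinical records, family structure, and
population stratification — conclusions about those require real data.

## Known limitations

* Gene identity is by trimmed case-sensitive symbol; no alias
  resolution, so totals computed against external gene lists depend on
  the lists' symbol vintage. The licensed text-mined/epidemiological
  lists are not bundled; loaders accept one-symbol-per-line files.
* The catalog's region bounds are an interpretive choice; the packaged
  bounds reproduce the case series' locus grouping and are meant to be
  edited for other cohorts.
* Phenotype-pair results depend on which features are recorded; the
  operations take the feature list as input rather than fixing one.
* No genome-build liftover and no raw array-format parsing.
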
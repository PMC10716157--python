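# Methods

This note documents the models, numerical choices and limitations behind
`bifidoprof`, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Two-tier profiling model

The package assumes a cohort profiled twice: a *groEL* amplicon run that
resolves the within-genus composition of *Bifidobacterium* (as ZOTU
counts), and a whole-community 16S run that supplies, per sample, the
genus's fraction of the total bacterial community (`bif16s`, a number in
[0, 1] consumed as input). The composite abundance of species *s* in
sample *i* is

    abundance_i(s) = reads_i(s) / reads_i(genus) * bif16s_i,

where the denominator counts reads in ZOTUs assigned anywhere within the
genus. Reads in discarded ZOTUs, or in ZOTUs assigned outside the genus,
enter neither numerator nor denominator; genus-only assignments form a
"Bifidobacterium (unclassified)" feature. Row sums therefore equal
`bif16s` exactly (a conservation law the tests assert to 1e-12), and the
result is invariant to per-sample sequencing depth. Abundances are
relative throughout; no absolute quantification is attempted.

## Reference-database construction

Amplicons are located by in-silico PCR: an IUPAC-degeneracy-aware scan
for a forward-primer site followed by the nearest downstream
reverse-primer site, on both strands, with up to 3 mismatches per primer
(roughly the 10% error a trimming tool would allow on a ~25-nt primer;
degenerate code overlap counts as a match). The reverse primer is given
5'→3' on the opposite strand, so a forward-strand product reads
`F + insert + revcomp(R)`. Primer bases are removed from the reported
insert, and inserts outside a 350–600 nt window (centered on the ~460 nt
expected product) are rejected; when several reverse sites follow a
forward site, the nearest one with an in-window insert wins and the
others are logged at debug level. Exact-string duplicates are collapsed
to the first-seen record, separately for in-group and outgroup
sequences. Whether the original trimming retained primer bases, and
whether the quoted product length includes them, is not documented for
the upstream protocol; removal (the trimming-tool default) is adopted,
and the length window is wide enough to absorb the difference.

Identity QC aligns record pairs globally (match +1, mismatch −1, gap
open −2, extend −0.5) and reports matching columns over alignment
length. The contract is the identity definition, not the aligner: any
sensible global aligner gives the same picture, namely in-group pairs
far above a 75% identity floor and the outgroup well below it.

## Dual-database taxonomy

Per database, hits are filtered on e-value ≤ 1e-10, query coverage ≥ 60,
identity ≥ 75 (inclusive bounds), capped at 1000 per ZOTU by bit score;
the file parser additionally caps rows per query at 2000. The
per-database taxonomy is the top-percent LCA: drop hits under 100 bits,
keep hits within 10% of the best bit score, return the longest common
lineage prefix. A minimum-support parameter would be a no-op at
per-ZOTU granularity and is not exposed.

Arbitration between the NT- and BIF-derived taxonomies is a total,
deterministic decision tree evaluated in order: (1) no hits anywhere →
discard; (2) NT lineage outside the genus and NT bit score strictly
dominant (absent BIF treated as score 0) → discard; (3) identical
taxonomies → assign; (4) tied scores, or BIF ahead by less than a factor
of 1/0.9 → assign the finer-rank path (rank tie → BIF); (5) BIF ahead by
1/0.9 or more → assign BIF; (6) otherwise → assign NT with a warning
(the configuration the original analysis reports never occurring).
"Finer" interprets the source description's "higher taxonomy level",
consistent with the pipeline's goal of species-level resolution. Score
comparisons are exact on parsed values; no epsilon is applied, since
alignment tools print limited precision and the 0.9 factor dominates.

## Diversity

Shannon uses the natural log (so does the Jensen–Shannon divergence,
making its range [0, ln 2]; users of base-2 conventions divide by ln 2).
JSD is the divergence itself, not its square root. Faith's PD includes
the path to the root, matching the common QIIME2 convention, and is
computed by summing branch lengths over the union of observed-tip-to-root
paths (cross-checked in tests against scikit-bio and a brute-force
oracle). Rarefaction draws a multivariate hypergeometric sample
(without replacement) at depth 2,000 under a recorded seed and drops
shallower samples; alpha and beta diversity use the rarefied table,
everything else the raw table. The adjacent-age trajectory floors ages
to integer bins (infants under 1 in bin 0) and emits all cross-pair
Bray–Curtis distances between each bin and its predecessor; age trends
report a loess curve (default span 0.75; narrow spans localize curvature
better, at the cost of noise), an OLS slope ± SE, and the curve values
at ages 16 and 30 — descriptive annotation ages, not detected change
points.

## Association battery

**dbRDA.** The distance matrix is Gower-centered (−D²/2, double
centering) and eigendecomposed; negative-eigenvalue axes are dropped
with a logged warning (no Lingoes/Cailliez correction — the simplest
defensible default). R² is the fraction of retained inertia captured by
the hat projection onto the column-centered covariate design
(multi-level categories enter as full dummy blocks; the design's rank is
the model d.f. m), adjusted by Ezekiel's formula
1 − (1−R²)(n−1)/(n−m−1). The permutation p permutes covariate rows
(999 by default), p = (1 + exceedances)/(1 + permutations).

**Stepwise dbRDA.** Forward selection adds, per step, the candidate with
the largest adjusted R² among those improving it, accepts it only if its
added-term permutation p ≤ 0.05 (current terms held fixed), and stops
when the candidate model's adjusted R² would exceed the global
(all-candidates) model's — the scope rule. A property of this rule worth
knowing (verified against the reference R implementation): when all
co-candidates are pure noise, the global adjusted R² is a coin flip above
or below a real driver's marginal adjusted R², and selection legitimately
halts empty about half the time. Recovery guarantees are therefore
stated for the realistic regime where co-candidates carry some signal.

**Ridge.** The response and continuous covariates are z-scored;
categorical covariates are dummy-coded against declared reference levels
(female, Han, rice, rural, April) and centered so the intercept drops
out. The penalty is chosen by the semi-automatic principal-components
estimator (k components covering 90% of design variance;
λ = k·σ̂²/Σα̂², the Hoerl–Kennard–Baldwin form generalized to PCR) —
chosen over generalized cross-validation (still available via
`lam="gcv"`) because GCV shrinks weak-signal features hard and the
resulting coefficient bias under correlated covariates distorts the
t-tests; the semi-automatic penalty keeps them near nominal level.
Standard errors use the ridge sandwich
σ̂²(X'X+λI)⁻¹X'X(X'X+λI)⁻¹ with σ̂² on n − edf degrees of freedom.
λ = 0 reproduces OLS to machine precision (asserted to 1e-8). BH
adjustment runs across features within a model term.

**Other tests.** Mantel correlates lower-triangle entries under
simultaneous row/column permutation (one-sided, greater). Fisher's LSD
uses the pooled ANOVA MSE, BH-adjusts the pairwise p-values (the letters
threshold is adjusted p < 0.1, not the classical unadjusted LSD), and
renders compact letters as maximal cliques of the
not-significantly-different graph. Mann–Whitney is exact (full
enumeration of group assignments of the pooled, tie-ranked observations)
for pooled samples up to 16, normal-approximate with tie correction
beyond; constant pooled data gives p = 1 by convention. Geography
correlations use haversine great-circle distances; the latitudinal
component is |Δlat| along a meridian and the longitudinal one |Δlon|
scaled by cos(mean latitude). Significance conventions default to raw
p < 0.05 and BH-adjusted p < 0.1.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated: 600 samples, 10 species (nine named species with baselines
proportional to their reported cohort means, 2.85% down to 0.01%, plus
one genus-only species exercising the unclassified bucket), 40 ZOTUs
(each species owns at least one), read depths negative binomial with
mean 15,000 truncated at the rarefaction depth, and eight sampling sites
spanning latitude 23–49°N, longitude 76–128°E and altitude 5–3650 m with
site-dependent ethnicity, staple-food and urbanization probabilities
(wheat prevails in the north, rice in the south; a high-altitude site is
predominantly Tibetan and pastoral).

Species compositions are logistic-normal: per-sample log-abundances =
baseline + planted effects + N(0, 1) noise, softmaxed to a composition.
Effects are additive on the log scale — continuous covariates per
z-unit, categorical levels as offsets, and age as piecewise-linear
segments with change points at 16 and 30 years. Default plantings
include the two wheat responders (+0.8 log-units each), latitude
gradients, ethnicity offsets and an urbanization shift; every planted
effect is emitted in a truth table.

The genus-level 16S fraction is a Beta(2, 30) draw scaled by the
sample's realized bifidobacterial load relative to baseline (clipped at
0.99). This load-tilt is deliberate: it encodes that covariates which
boost member species expand the genus as a whole rather than
redistributing a fixed genus share, and it makes the within-genus
closure denominator cancel on the composite-abundance scale — so a
planted per-species log effect is recovered as-is and unplanted species
are genuinely null. With an independent genus fraction instead, simplex
closure would give every unplanted species a real negative response to
any planted positive effect, and no false-discovery statement would be
testable.

What the generator does *not* emulate: sequence-level read errors and
chimeras, realistic alignment-score distributions (hit tables encode
ordering constraints only), within-species ZOTU phylogenetic structure,
covariate missingness patterns, and the long-tailed site/province
structure of a real national cohort. Passing tests therefore demonstrate
correctness of the statistical machinery under a controlled
data-generating process, not field performance on real sequencing runs.

A calibration note: with the planted wheat effect present, the empirical
FDR (mean false-discovery proportion) of the BH-at-0.1 wheat-term screen
sits slightly above nominal (~0.10–0.12 across simulation blocks) while
per-null-species flag rates stay at 0.06–0.07 and fully-null cohorts are
calibrated (raw p uniform by KS). The excess traces to heavy-tailed
(lognormal × Beta) abundance residuals making raw-scale ridge t-tail
probabilities slightly optimistic once BH's threshold is lifted by the
true discoveries — a property of regressing raw relative abundances
that users should keep in mind when interpreting borderline adjusted
p-values.

## Problem sizes and determinism

All randomness flows from explicit seeds (rarefaction, permutation
tests, simulation); a fixed seed reproduces outputs byte-for-byte, and
the pipeline manifest records seeds and input checksums. Validation
sizes are chosen to make the statistical guarantees sharp at desk scale:
recovery simulations use 100 replicate cohorts of n = 600; null
calibrations use n = 100 with 199-permutation tests; exact oracles
(arbitration truth table, LCA brute force, BH definition, small-sample
Mann–Whitney enumeration) run exhaustively. Permutation counts in
simulations (49–199) trade resolution for replicate count; single
analyses default to 999.

## Known limitations

* No Lingoes/Cailliez correction for negative PCoA eigenvalues (axes are
  dropped); strongly non-Euclidean dissimilarities lose some inertia.
* Ridge p-values are approximate (penalized estimator, sandwich SE);
  they are anti-conservative in heavy upper tails, see above.
* The compact-letter display enumerates maximal cliques; fine for the
  ≤ 10 groups typical of ethnicity/zone comparisons, not for hundreds.
* The exact Mann–Whitney path enumerates C(n1+n2, n1) assignments and is
  capped at pooled n = 16.
* Loess is a smoother, not a change-point estimator; the age-16/30
  annotations are descriptive.
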
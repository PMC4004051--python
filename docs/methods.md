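# Methods

## Scope and data model

`dimerscan` screens pairs of position weight matrices (PWMs) for
overrepresented rigid arrangements — *motif complexes* — in genome-wide
region sets.  The pipeline is: region preparation → threshold calibration →
motif scanning → complex enumeration → instance counting → Bernoulli testing
→ Bonferroni correction → redundancy clustering → spacing-flexibility
analysis.  `DimerEnrichmentModel` holds the data and configuration;
`fit()` returns a `DimerResults` with the predictions, clusters,
diagnostics and writers.

Coordinates are BED-style 0-based half-open throughout.  Strong datasets are
reduced to their cell-type-unique base pairs by subtracting the union of all
*other* strong sets; weak datasets pass through unchanged; the control is
the union of all input regions, taken *before* subtraction (the subtracted
portions are shared regulatory sequence and belong in the background
universe).  Replicates listed under one dataset name are merged by union.
Regions extending past chromosome ends are clipped with a warning.

## Motif model

Counts are stored as 4×L matrices (A, C, G, T rows).  Probabilities use a
symmetric pseudocount of 0.25 per base: `p = (c + 0.25) / (Σc + 1)`.  This
keeps every log-odds score finite; it is configurable, and a pseudocount of
0 reproduces textbook closed forms (uniform column → 0 bits, one-hot → 2
bits).  Column information content is `2 + Σ_b p log2 p` with `0·log 0 = 0`.

**Score thresholds.**  The match threshold of a motif is calibrated from the
exact distribution of the log-odds score of sequences drawn from the motif's
own probability model, computed by dynamic programming over columns with
per-column scores discretised to 0.01-bit bins.  Scores are discretised by
*flooring*, so the discretised score never exceeds the true score and the
realised sensitivity can only exceed the 0.8 target (rounding to nearest
accumulates up to L/2 bins of error and can silently exclude the score class
at the boundary — observed as a sensitivity drop from 0.84 to 0.49 on a
7-informative-column motif before the fix).  The mapping from the
sensitivity parameter to a score cutoff via the motif's own score
distribution is this package's convention; both the sensitivity and the bin
width are configurable.

**Background model.**  Log-odds scores use 0-order base frequencies
estimated from the control dataset's sequence, averaged with their
complement (A with T, C with G).  Scanning is double-stranded, so the
background must assign a site and its reverse complement consistent scores;
strand-averaging also makes the entire pipeline exactly invariant under
reverse-complementing the input genome, which is one of the acceptance
checks.  Ambiguous bases (N) contribute zero log-odds.

## Complexes and counting

Spacing is the number of intervening base pairs between proximal motif
edges; negative spacing is overlap.  The default spacing window is
`-(min(L1, L2) - 1) … 50`: motifs may overlap up to one base pair short of
the shorter motif being fully contained, because coincident starts make the
left/right ordering ill-defined.  Both limits are configurable.

A complex equals its reverse complement as a double-stranded object; the
canonical form is the lexicographically smaller of the two equivalent
`(left_id, right_id, left_strand, right_strand, spacing)` tuples.  Instances
are hit pairs within one region (never across regions) matching a canonical
complex in either genomic orientation; placements sharing the same genomic
span and canonical complex count once, which handles palindromic motifs
hitting both strands at one interval.

Possible placements of a complex with footprint `span = L1 + L2 + s` in a
region of length G are `max(0, G - span + 1)`, times 2 for
non-self-complementary complexes and 1 for self-complementary ones
(convergent/divergent palindromes have no second orientation).

**Pair-level probabilities.**  `f12` (target) and `b12` (control) are the
total instance count of the pair over *all* screened canonical structures,
divided by the total possible placements summed over those structures.  The
screened structure space defines the pair's baseline; the choice of window
is therefore part of the hypothesis, and both probabilities use the same
window.

**Degenerate cases.**  A hypothesis with zero placements or a pair never
seen in the control is skipped (logged) but still counted in the Bonferroni
total, so skipping can never make results more significant.  A complex seen
in the target but never in the control receives the pseudo-probability
`1/(N12_control + 1)`.  A success probability above 1 (possible when the
plug-in estimates are extreme) is clamped with a warning.  Complexes with
fewer than 5 target instances (configurable) are not reported: their
empirical background rates and dimer PWMs would rest on too few
observations.

The binomial upper tail is computed via the regularised incomplete beta
function (scipy); the acceptance suite verifies it against exact
integer-arithmetic summation to ≤1e-10 relative error for all N ≤ 1000 over
a grid of success probabilities.

## Clustering

Bonferroni-significant results are ranked by raw p-value (ties broken by
complex signature, then dataset, for determinism) and greedily merged.  For
result Rn, earlier-ranked results Rk are checked in order with three tests:
identity (only if Rk is a cluster seed), PWM similarity
`ED² < α·IC(PWM_k) + β` (only if Rk is a *signature* complex — a seed or an
identity-joined member), and instance overlap (if Rk is a signature or
similarity-joined member *from the same dataset*; overlap between instance
sets in different datasets is not meaningful since strong targets are
disjoint).  The first success joins Rn to Rk's cluster; otherwise Rn seeds a
new cluster.

`ED²` is minimised over all relative offsets with ≥1 overlapping column and
both strands; non-overlapping columns are compared against the uniform
distribution.  Dimer PWMs are base-frequency counts over instance spans read
in canonical orientation.

Test 3 counts Rn instances having an Rk instance at the single most common
relative offset among all overlapping instance pairs (ties broken toward
the smallest absolute offset, negative first), and joins when that count
reaches `γ·(C12 − E12)`.  When `C12 ≤ E12` the right-hand side is ≤ 0 and
the inequality would hold vacuously; at least one overlapping instance is
additionally required.

Defaults `α = 0.05`, `β = 0.5`, `γ = 0.5` were chosen once on synthetic
fixtures so that near-identical composite PWMs (differing by a one-column
shift or small perturbations) join under test 2 while unrelated random PWMs
do not, and so that shadow predictions sharing half their excess instances
join under test 3; all three are exposed in the configuration and echoed in
the output header.

## Flexibility analysis

Groups collect significant predictions with the same motif pair, orientation
class, left-right ordering and dataset, differing only in spacing.  Reported
spacings are recomputed between the proximal edges of the trimmed motifs
(flanks with IC ≤ 0.25 bit removed; trimming is used *only* here, never for
scanning); motifs that trim to zero length drop out with a warning.  Per
group the table lists the number of distinct spacings, their mean and sample
SD (0 for singletons).  Across groups the package reports Pearson r of
spacing count versus mean spacing and of spacing SD versus mean spacing, and
a two-sided Mann–Whitney U test comparing mean spacings of rigid (one
spacing) versus flexible groups (scipy's implementation: exact for small
samples without ties, normal approximation with tie correction otherwise).
The outlier rule removes groups whose mean spacing exceeds Q3 + 5·IQR with
linear-interpolation (type-7) quantiles — the quantile convention is this
package's choice — and both filtered and unfiltered statistics are
available.  Predictions from different sources can be merged before grouping
by giving them one dataset name; by default grouping stays within dataset.

## Synthetic data generator

`generate_fixture` emulates the study conditions of a dimer screen: one
chromosome of i.i.d. (or first-order Markov) background sequence; per
dataset, `n_regions` non-overlapping regions tiled with 10-bp gaps; per
`PlantSpec`, a deterministic `round(rate · n_regions)` instances of one
complex, each a sequence sampled column-wise from the composite-site model
and placed at a uniform in-region offset on a uniform genomic strand.  For
overlapping complexes the overlap columns are sampled from the normalised
product of the two oriented motif columns — the natural model of a shared
composite core; planted overlapping heterodimers in fixtures additionally
share their overlap consensus (`compatible_overlap_partner`), as real
overlapping dimers do.  Plants never overwrite one another (offsets are
resampled against an occupancy map; extremely crowded regions spill to a
random other region); earlier versions that let later plants overwrite
earlier ones produced an order-dependent bias in benchmark scores.

`BackgroundPairSpec` plants pair instances at *random* orientations and
spacings in every dataset.  This models the genome-wide baseline
co-occurrence of motif pairs, which the `f12/b12` correction normalises
against.  It is essential to the statistic's behaviour: if a pair co-occurs
*only* as the planted complex, the control attributes all pair occurrences
to that structure and the null fully explains the signal — with a baseline,
dataset-specific structure stands out.  Default fixture conditions (chosen
once, as the desk-scale analogue of a many-cell-type compendium): 200
regions × 500 bp per dataset, one target plus five background datasets
diluting the control, plant rate 0.3, baseline rate 0.1, motif length 8 with
consensus probability 0.85 (≈10-bit motifs).

What the generator does **not** emulate: real base composition and repeats,
chromatin-driven correlation between datasets, motif self-similarity within
a library, peak-calling artefacts, and copy-number structure.  Passing tests
therefore demonstrate correctness of the statistics and machinery under the
stated model, not performance on real compendia.

The benchmark builds dedicated two-motif pairs for a known set and a random
set (dedicated on both sides, so the two sets are exchangeable under no
planting), optionally plants the known pairs' complexes in the target at
rate 0.3, screens only the target dataset (the background datasets
contribute to the control), scores each pair by its best raw p-value, and
reports the ROC and trapezoid AUC over p-value thresholds.  A bundled
*synthetic* example registry (`data/known_dimers_synthetic.tsv`)
demonstrates the machine-readable gold-standard format (motif ids,
orientation, spacing or spacing range, citation).

## Numerical and implementation choices

- Binomial tails: `scipy.stats.binom.sf`, stable to N12 ≈ 1e7.
- Interval arithmetic (merge, union, subtract) is a direct sorted sweep —
  the three operations needed are small enough that a dataframe-based
  interval library would add overhead without clarity.
- Ranking ties (identical p-values) break by complex signature then dataset.
- Threads parallelise over motif pairs; results merge in canonical pair
  order, so threaded and serial runs are byte-identical.
- Determinism: every stochastic step flows from one seed;
  re-running a configuration reproduces outputs byte-for-byte.

## Problem sizes used in verification

The test and acceptance fixtures use 100–200 regions of 300–500 bp per
dataset, 2–6 datasets, 3–40 motifs of length 8, and spacing windows of
15–20 bp; the binomial oracle covers N ≤ 1000 exhaustively.  These sizes
exercise every code path (overlap, palindromes, homodimers, skipped
hypotheses) at desk scale; the engine itself scales linearly in total region
length per motif and quadratically in local hit density per pair.

## Known limitations

- Only dimers (no trimeric or higher-order complexes), fixed spacing per
  hypothesis (no flexible-window co-occurrence test).
- Bonferroni only, as the correction over billions of structured hypotheses;
  no FDR variant.
- The empirical control is contaminated by the target's own instances
  (targets are subsets of the union); with few datasets this is
  conservative — strongly dataset-specific complexes lose significance —
  and it fades as the control grows.  Real screens should supply as many
  datasets as possible, exactly as the union-control design intends.
- 0-order background; no higher-order sequence models or DNA shape.
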
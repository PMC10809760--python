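# Methods

This note records the scientific model behind `redoxlag`, the design
decisions that were genuinely open, and what the synthetic validation does —
and does not — demonstrate about real sediment data.

## Redox zonation

A core slice `[top, bottom)` (cm below the sediment surface) is assigned to
oxic, nitrogenous, or ferruginous by its depth midpoint against the site's
O2 and NO3 penetration depths. Half-open boundaries send a midpoint lying
exactly on a penetration depth to the deeper zone. Whether a study assigns
slices by midpoint, top, or whole-slice containment is rarely stated; the
midpoint is the least biased single representative of a slice and is used
consistently everywhere a sample needs one depth (zone assignment, depth
profiles, age conversion). In situ penetration depths are only known to
roughly ±2 cm, so `annotate_zones(..., boundary_buffer=...)` can flag
samples within a buffer of either boundary as transitional; zone means can
then exclude them. The default buffer is 0 (no exclusion).

## Guild classification

Capabilities are Boolean functions of annotated gene presence:

* **Module completeness** is the fraction of a module's steps with at least
  one alternative ortholog present, computed in exact rational arithmetic so
  that the `>= 50%` threshold is decided without floating-point rounding
  (2 of 4 steps passes; 49% of steps does not). Module definitions are
  *input data*, not code: KEGG content is versioned, so the package ships
  only small illustrative three-step definitions for the three oxidase
  classes and accepts any definitions in the same TSV dialect.
* **Nitrogen rules** follow the printed subunit thresholds: napAB, nrfAH,
  and nirBD need both subunits; narGHI needs any two of narG/narH/narI;
  nirK/S and norBC need one; nosZ is a single gene. A full denitrifier has a
  nitrate reductase plus nirK/S, norBC, and nosZ.
* **dsrAB** requires both subunits by default — single-subunit hits in draft
  genomes are commonly fragments — and is relaxable to either subunit via
  `ClassifierConfig(dsr_require_both=False)`. The flag deliberately records
  gene *presence*: dsrAB runs in both the reductive and oxidative
  directions, and the classifier does not adjudicate which.
* **Taxon override**: family-rank membership (default *Nitrosopumilaceae*)
  marks a MAG aerobic regardless of oxidase modules, because the archaeal
  ammonia-oxidizer Complex IV is too divergent for standard module
  definitions. The override list is configurable.
* **Fermenter** is the complement: no aerobic, nitrogen, sulfur, or metal
  capability. It is an operational label — such genomes may well respire by
  pathways outside the analyzed set.

The rule engine is verified exhaustively against a literal truth-table
oracle over all 2^12 subsets of the anaerobic marker universe, and
property-tested for monotonicity (adding genes never revokes a capability;
the fermenter flag is antitone).

## Abundances and depth profiles

Relative abundance is the within-sample fraction of summed mean coverage.
Group abundances sum member fractions; a MAG carrying several labels (e.g.
aerobic *and* nitrogen) contributes fully to each, so guild curves may sum
above 1 while any partition sums to exactly 1. CAZyme-family abundance is
presence-weighted — the summed abundance of MAGs carrying the family,
irrespective of copy number — matching the "abundance of MAGs containing
the gene" reading rather than a copy-weighted one.

Secreted-CAZyme strata count **distinct families with at least one secreted
copy** per MAG, with eight default bins {0, 1, 2, 3, 4, 5, 6–8, >8}. The
choice of distinct families over gene copies, and the exact bin boundaries,
are conventions (copy counting is available behind `count_copies=True`; the
scheme is a config object).

Depth profiles align horizons across sites by exact `(top, bottom)`
intervals and report mean ± standard error (`sd/sqrt(n)`) over sites;
horizons present at fewer than two sites carry `n_sites = 1` and a missing
SE rather than a fabricated zero.

## Age model and kinetics

With a constant sedimentation rate ω (mm/yr), `age(z) = 10·z/ω` years. This
neglects compaction and assumes steady accumulation — adequate over the
upper decimeters of slowly accumulating sediment where ω comes from
lead-210 profiles.

Exponential fits are ordinary least squares of `ln a` on age: treating the
multiplicative scatter of coverage-derived abundances as lognormal makes
log-OLS the maximum-likelihood estimator, and it is exact on noise-free
exponentials (verified to 1e-9 relative error). A nonlinear least-squares
variant on the linear scale (`method="nls"`) is provided and must agree on
clean input. Interpreting relative-abundance decay as cell decay assumes a
constant total cell density over depth; the package inherits this assumption
and the simulator enforces it by construction.

Numerical conventions: zero abundances inside a fit window are dropped (an
exponential never reaches zero; zeros are detection failures) and counted;
if more than half the window is zero the fit is refused rather than
extrapolated. A fitted slope whose sign contradicts the requested direction
returns a result flagged `converged=False` instead of raising, so batch
runs over many site × guild combinations degrade gracefully. Half-life is
`ln 2/λ` to 1e-12 relative identity. Decay windows default to
[ferruginous-zone top, deepest horizon] per site; growth windows must be
explicit (default pipeline config: 6.5–9.5 cm). Cross-site summaries are
(min, max) over per-site fits — no pooling, matching the "ranged between"
style of reporting.

## Ordination and tests

Bray–Curtis uses the standard ratio form; a pair of all-zero samples is
defined to have dissimilarity 0 (with a warning) rather than NaN. PCoA is
classical scaling of the Gower-centered squared-distance matrix; negative
eigenvalues of non-Euclidean inputs are reported as-is (a Cailliez
correction is available behind a flag, default off). PCA is the covariance
eigendecomposition of column-centered data; applied to Hellinger-transformed
abundances this is the standard transformation-based PCA for compositional
community data (a correlation-based variant was considered and rejected
because Hellinger rows are already on a common scale).

PERMANOVA uses Anderson's pseudo-F with the add-one permutation estimator
`p = (1 + #{F* >= F}) / (1 + n_perm)`, which is never exactly zero and is
slightly conservative by construction. Permutations derive deterministically
from the caller's seed; pairwise tests spawn per-pair substreams in
lexicographic pair order and adjust with Benjamini–Hochberg. Type-I error
at α = 0.05 is verified to land in [0.035, 0.065] over 1000 null
simulations. Ward ordering sorts rows lexicographically before linkage so
leaf order is reproducible under ties.

## Synthetic data: what it emulates

The simulator plants one archetype per guild (see the table in
`redoxlag.synthetic_data`) with gene content that is sufficient *and*
necessary to trigger exactly the intended classifier flags, and generates a
multi-site core study: slices of 1 cm down to 10 cm and 2.5 cm below
(20 cm cores by default), O2 penetration spanning 2.6–4.1 cm across sites,
NO3 penetration at 8 cm, sedimentation rates spanning 0.29–0.76 mm/yr, and
respiratory half-lives spanning 135–367 yr across the six default sites.

Depth trajectories are piecewise log-linear in age with C0 continuity:
aerobic/nitrogen archetypes hold their surface share through the oxic and
nitrogenous zones and decay exponentially below nitrate penetration;
fermenters plateau, double every 1.4 cm inside the 6.5–9.5 cm window, and
plateau again. All aerobic archetypes at a site share one planted decay
constant so that the *guild-level* mixture remains exactly exponential and
the planted value is recoverable to machine precision. A subsurface
sulfate-reducer pool absorbs the remaining share at every depth, which (i)
keeps total coverage constant — the assumption under which relative
abundance reads as cell density — and (ii) mimics the replacement of the
surface community by deep-biosphere lineages. Surface shares (0.20 strict
aerobes, 0.30 aerobe+nitrogen duals, 0.12 nitrifiers, 0.02 anammox, 0.03
sulfate reducers, 0.02 metal reducers, 0.03 fermenters) were chosen once as
round values in the range reported for surficial communities of this kind,
with the dual fraction set so that most cytochrome-c MAGs also respire
nitrogen.

Noise is multiplicative lognormal per coverage cell, `exp(σZ)` with
σ = 0.3 by default — coverage data are positive and heavy-tailed, and the
generating process is silent on error structure, so the simplest
scale-free model was chosen. Fermenter secreted-CAZyme richness follows a
zero-inflated geometric capped at 12 so all eight strata have support.

**What passing tests do not show.** The simulator produces clean
single-exponential guilds, aligned horizon grids, complete per-site
metadata, and noise that is independent across cells. Real MAG data add
compositional coupling between guilds, mapping biases correlated across
depths, incomplete genomes that break the classifier's gene-presence
assumptions, and age models distorted by turbidites and compaction.
Parameter recovery here therefore validates the *estimators and plumbing*,
not the field accuracy of any particular half-life.

## Problem sizes used in validation

The shipped validation uses 72-MAG, six-site cores (14 horizons each), 20
replicate cores for noisy half-life recovery, 2^12 gene subsets for the
classifier check, and 1000 null simulations × 999 permutations for
PERMANOVA calibration. These sizes give stable summary statistics (the
recovery median and the type-I rate move by well under their tolerance
bands across seeds) while keeping the whole suite fast to run routinely.

## Known limitations

* The age model is linear in depth; no compaction or hiatus handling.
* Module completeness treats steps as unordered AND; KEGG's nested Boolean
  definition grammar is not parsed — definitions must be pre-flattened to
  steps of alternatives.
* Pairwise PERMANOVA controls FDR only across the pairs of one call.
* The simulator's non-focal guilds (sulfur, metal) hold constant shares;
  no claim of realism is made for their depth structure.
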
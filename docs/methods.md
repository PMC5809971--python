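# Methods

This note documents the models, estimators, numerical conventions and
deliberate design choices behind `ylineage`, and what its synthetic-data
validation does and does not establish.

## Model and assumptions

The MSY is treated as a single non-recombining haploid locus evolving under
the infinite-sites model: each mutation hits a previously unmutated site,
so every biallelic SNP corresponds to exactly one branch of the sample
genealogy and the derived-carrier sets form a laminar family (a perfect
phylogeny).  Departures from infinite sites — recurrent mutation,
triallelic sites — are handled after the tree is built, by exact
small parsimony on the fixed topology.  Time is measured in years
throughout; mutation rates are per site per year, so generation time never
enters any formula.

## Dating

* **Rho.** `rho(v)` is the arithmetic mean over all descendant tips of the
  mutation count on the node→tip path.  It deliberately averages over
  *ancient tips as well, uncorrected for their age*: this is the convention
  under which the per-node chronology of a tree containing dated ancient
  genomes is internally consistent, and the age deficit of ancient tips is
  instead exploited by the calibration estimator.  `rho` satisfies the
  recursion `rho(v) = Σ_c (n_c/n)(rho(c)+l_c)`, which the tests check
  against direct tip-path summation on random trees.
* **Saillard SD.** `SD²(rho) = Σ_b l_b (n_b/n)²` over branches below the
  node, i.e. the delta-method variance of `rho` treating each branch count
  as Poisson.  Equivalent recursion:
  `SD²(v) = Σ_c (n_c/n)² (l_c + SD²(c))`.
* **Time conversion.** `t = rho / (mu·L)`.  Defaults: `mu = 0.735e-9`
  /site/year and `L_eff = 3,335,000` bp, equivalently 408 years per
  mutation; both are configurable and the chronology table accepts either a
  `RateCalibration` or a bare years-per-mutation constant.  `sd_time`
  converts `SD(rho)` with the same constant and does **not** fold in the
  rate's own uncertainty (±0.03e-9); that uncertainty lives on the
  `RateCalibration` object and is reported separately.  Folding it in would
  change the per-node SD column's meaning from "genealogical sampling
  noise" to a mixture, and would break the published-table arithmetic the
  package reproduces.
* **Star-like index.** `S = rho/(n·SD²)`, in `[1/n, 1]`, with `S ≥ 0.5`
  flagged high.  For a pure star `rho = Σl/n` and `SD² = Σl/n²`, so `S = 1`
  identically — an exact algebraic fact the tests assert to 1e-12.
* **Split-node interpolation.** Nodes known only from genotyped markers
  (no full mutation count below them) are dated linearly in mutations
  between their dated neighbours:
  `t = parent − (parent−child)·m_above/(m_above+m_below)`.
* **Method concordance.** Two dating vectors over the same nodes are
  compared by squared Pearson correlation.

## Rate calibration

The original analysis obtained its rate from a Bayesian tip-dating run; the
package uses a transparent moment estimator with the same information
content.  For a calibration tip `c` of age `a_c`, the deficit
`Δ_c = rho_modern(parent(c)) − m_c` (modern-tip average minus the ancient
tip's own terminal count) has expectation `mu·L·a_c`, whatever the parent's
age, so `mu_hat = ΣΔ_c/(L·Σa_c)`.  Negative deficits are legitimate noise
and are kept; age-0 tips carry no signal and are excluded; the SD comes
from the delta method with Poisson path counts.  The estimator is validated
by parameter recovery on simulation (20 replicates at study scale recover
the generating rate to well within 15%), not by matching any published
value on data this package does not have.

## Synthetic data

The simulator emulates the study design: ~146 modern chromosomes plus four
ancient tips at 8,055 / 9,712 / 13,665 / 44,890 years BP, `mu = 0.735e-9`,
`L = 3.3` Mb of callable sequence.  The genealogy is a serially-sampled
Kingman coalescent — ancient tips enter the process at their age — with the
haploid timescale expressed directly in years (`effective_size_years` is
the inverse pairwise coalescence rate; default 130,000, a free parameter
chosen to put the simulated TMRCA in the few-hundred-kya range of deep Y
phylogenies, since the original demographic parameters are not published).
Optional exponential growth compresses coalescences toward the root.
Mutations are Poisson per branch (`mu·L·duration`), placed uniformly
without replacement (infinite sites) except for a configurable recurrent
fraction that re-uses occupied positions; artifact clusters add ≥2 private
SNPs within a window on random terminal branches, with a ledger for exact
filter scoring.  A single seeded RNG stream drives everything; identical
config + seed reproduces byte-identical exports.

What passing on this generator shows: the estimators are unbiased and the
reconstruction is exact *under the model the analysis itself assumes*.
What it does not show: robustness to real-data pathologies the generator
omits — reference bias, ancient-DNA damage, coverage heterogeneity
correlated along the chromosome, non-uniform mutation spectra, population
structure among moderns.

## Filtering conventions

* Callable mask: a base is callable iff every sample's depth is in
  `[min_depth, max_depth_factor × that sample's mean]` (defaults 8 and
  2.0); the upper bound proxies collapsed duplications.  The exact
  thresholds of the original pipeline are not published; these defaults are
  explicit, configurable and logged in the pipeline manifest.
* Direct filter defaults: QUAL ≥ 20, missingness ≤ 0.1; report-only, with
  one verdict per site and `off_mask` taking precedence.
* Cluster filter: "close proximity" is a chained gap rule — maximal runs of
  same-branch sites with consecutive gaps ≤ `window_bp` (default 10 bp,
  unquantified in the original text) and size ≥ 2 are flagged, not
  dropped, replacing manual alignment review with a machine-readable
  report.

## Tree construction conventions

* Polarity: ancestral states come from a designated outgroup sample when
  given (mirroring the use of basal A00/A0-T lineages), else from the
  majority state (ties → reference).  Only outgroup polarisation counts as
  anchored; without it, a single-change site on a branch adjacent to a
  two-child root is classified `unassigned_direction`, since the event
  could belong to either side.
* Site acceptance order is by decreasing carrier count, then position;
  identical carrier sets share a branch; children are ordered by smallest
  descendant sample id and node ids are assigned in pre-order, so the tree
  is a deterministic function of the input matrix.
* Incompatible and triallelic sites are placed by exact unit-cost Sankoff
  DP (correct on multifurcations, verified against exhaustive enumeration
  on ≤8-tip trees); missing calls are free to take the change-minimising
  state; ties prefer the parent's state, then ancestral.  ≥2 changes ⇒
  `recurrent`; each allele of a triallelic site is placed independently.
* Zero-mutation internal branches of simulated truth trees are collapsed to
  multifurcations before topology comparison — they are unobservable in a
  SNP matrix, and real trees display the corresponding multifurcations.
* Midpoint rooting maximises the tip-to-tip mutation path, breaking ties by
  the lexicographically smallest endpoint pair; a midpoint inside a branch
  splits its mutation list by genomic position (smaller positions on the
  nearer-endpoint side).  All-zero branch lengths are an error.

## Population statistics

* Haplogroup assignment returns the deepest derived marker whose typed
  ancestors are all derived; derived-below-ancestral genotypes are flagged
  inconsistent rather than silently reassigned.
* The collapsed 3×k proportion matrix drops nomadic populations, drops
  lineages with total count < 2 (the "singleton" rule, configurable),
  merges NE+NW Africa into "Northern Africa" and the sub-Saharan
  macro-regions (Bantu groups included) into "Sub-Saharan Africa", keeps
  "American admixed", and row-normalises counts — correlations are computed
  on within-region relative proportions, the quantity the regional
  comparison is defined on, never on raw counts.  A region with zero
  carriers cannot be normalised and is an error.
* Spearman uses the tie-corrected rank correlation with the two-sided t
  approximation (n−2 df).  Mann–Whitney is exact by full enumeration of
  partitions when `n_a+n_b ≤ 12` — unlike textbook exact tables this
  handles ties, which population frequency data are full of — and otherwise
  uses the normal approximation with continuity and tie correction.

## Problem sizes

The validation suite runs at deliberately chosen scales: 50 replicates of
50-tip infinite-sites simulations for topology recovery, 20 replicates at
full study scale (150 tips, 3.3 Mb) for calibration recovery, 20 replicates
with injected artifact clusters for filter scoring, 500 replicates for the
closed-form TMRCA check and 1,000 random trees for the Saillard
cross-check.  These sizes give Monte-Carlo standard errors comfortably
inside the asserted tolerances while keeping the whole suite under a
minute.

## Known limitations

* The perfect-phylogeny builder resolves conflicts greedily
  (larger carrier sets win); with heavily conflicting data this is a
  reasonable deterministic choice, not a maximum-parsimony search over
  topologies.
* Missing calls are treated as ancestral during tree building (conservative
  for clade support) and as free states during placement; with high
  missingness these conventions can differ from a joint imputation.
* The calibration estimator assumes calibration tips are correctly placed
  in the tree; a misplaced ancient tip biases `mu_hat` directly.
* Bayesian (MCMC) dating, relaxed clocks, bootstrap support and frequency
  surface mapping are out of scope.
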
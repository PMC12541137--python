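# Methods notes

This note documents the statistical procedures, the synthetic community
the tests run against, and the design decisions taken where the
methodology left genuine freedom. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Filtering and quality control

**Mammal marker (host identification).** Within each PCR, MOTUs with a
read share below 1% are removed, then MOTUs shorter than 40 bp (typical
bacterial artifacts); PCRs retaining fewer than 500 reads are rejected.
Thresholds are read literally: a PCR with exactly 500 reads is retained,
499 is not. The host is the most abundant MOTU exactly matching a
reference sequence. When more than one mammal species survives
filtering, the dominant species must be at least twice as abundant as
the runner-up; we compare the *top MOTU per species* rather than
species-aggregated read sums, since aggregation could manufacture
dominance from many minor MOTUs. Ties are ambiguous by construction. A
single surviving MOTU is recorded with an infinite dominance ratio.

**Plant marker (replicate QC).** Each sample has three technical PCR
replicates. Replicates are converted to within-PCR proportions; the
sample *barycenter* is the arithmetic mean of its replicate proportion
vectors. Distances of replicates to their own barycenter ("PCR
distances") should be small relative to distances between barycenters
("sample distances"). We fit a normal to log sample distances (maximum
likelihood) and use its 5th percentile, `exp(μ̂ − 1.6449·σ̂)`, as an
upper bound on acceptable PCR distances. The distance is Bray–Curtis on
proportions by default — chosen for consistency with the dissimilarity
used in the ordination — with Euclidean-on-Hellinger available via the
`metric` argument. Estimation requires at least 20 positive sample
distances (configurable); below that an explicit threshold must be
supplied. With zero estimated variance the common distance itself is
returned.

Discard order is fixed: depth (< 1000 reads) → distance (> threshold,
with barycenters recomputed over depth-passing replicates) →
control-like. "Clustering with controls" is operationalized as a
deterministic k-nearest-neighbour rule (default k = 5): a replicate
whose majority of k nearest compositional neighbours (over all replicate
and control vectors) are controls is discarded. This is a seed-free,
testable surrogate for a visual graph-partitioning step; it behaves
sensibly when sample replicates are numerous relative to controls, which
is the regime of these designs. Samples with fewer than two surviving
replicates are dropped.

**Averaging and MOTU filters.** Counts are averaged across surviving
replicates on proportion vectors and rescaled by the mean depth, so each
replicate carries equal weight regardless of sequencing depth
(raw-count averaging is available via `mode="counts"`). MOTUs below 95%
best-match similarity are removed; after recomputing RRA, MOTUs whose
maximum RRA over all samples is below 2.5% are dropped as sporadic. The
sporadic filter is applied after replicate averaging, following the
order in which diet quantification is defined. The distance threshold is
estimated globally (per-library estimation can be done by running the QC
per subset).

## Niche statistics

* **Richness** S = number of taxa with RRA > 0 per sample, counted on
  the post-QC, pre-collapse MOTU table (after the sporadic filter), i.e.
  the final dataset a sample contributes to.
* **Dunn tests** on pooled mid-ranks with tie-corrected variance
  `z = (R̄ᵢ−R̄ⱼ)/√[(N(N+1)/12 − T)(1/nᵢ+1/nⱼ)]`,
  `T = Σ(t³−t)/(12(N−1))`, two-sided normal p-values and
  Benjamini–Hochberg adjustment across pairs. Groups with fewer than two
  observations are excluded.
* **DNW** = exp(H′) of a stratum's average diet (order-1 Hill number,
  the effective number of food taxa). The average diet is the
  *unweighted* mean of sample RRA vectors — RRA exists precisely to give
  samples equal statistical weight — renormalized before the entropy.
* **Pianka's overlap** O(u,v) = Σuᵢvᵢ/√(Σuᵢ²Σvᵢ²) ∈ [0,1] by
  Cauchy–Schwarz. Intraspecific overlap on a transect × season is the
  mean over all unordered conspecific sample pairs (≥ 2 samples
  required). Interspecific overlap is the Pianka index between the two
  species' mean diets on the transect — well defined with one sample per
  species, matching per-transect replication; a mean-over-pairs variant
  is available (`inter_method="pair_mean"`). Summary tables flag cells
  resting on fewer than 4 transects.
* **Jacob's D** = (r − p)/(r + p − 2rp), r the dietary proportion of a
  food category (transect-average diet), p its availability in the
  species' browsing-height range (roe 0–1.5 m, fallow 0–1.8 m, red
  0–2.3 m, moose 0–3 m). D is undefined only at r = p = 0 and
  r = p = 1 (returned as NaN with the record skipped/reasoned). A
  category eaten but absent from the availability survey is scored with
  p = 0, hence D = 1. Single-transect strata are flagged (no SD).

## Ordination and species separation

Hellinger transform (√RRA), Bray–Curtis dissimilarity, then PCoA by
Gower double-centering `B = −½ J D² J` and symmetric eigendecomposition.
Axes with positive eigenvalues are kept, scaled by √eigenvalue; negative
eigenvalues are reported but not corrected (no Cailliez/Lingoes by
default — magnitudes are small for these data and a correction would
change printed proportions). Axis signs follow a fixed convention (the
largest-magnitude score on each axis is positive) so ordinations are
reproducible run to run. The implementation is validated in the test
suite against the exact-embedding property of Euclidean configurations
and against an independent reference implementation.

Pairwise species separation on the first two axes is tested with a
permutation test on the centroid R² statistic
(1 − SS_within/SS_total); the exact statistic inside the published
pairwise factor-fitting routine is not specified, so this centroid-R²
surrogate is used and documented as such. p-values use the add-one
estimator `(1 + #{R²_perm ≥ R²_obs})/(1 + n_perm)` with Bonferroni
correction across pairs; the default is 10,000 permutations with a
mandatory seed. Compact letter displays are derived from the
non-significance graph. Taxon contributions are estimated by
least-squares fitting of each taxon's RRA onto the two axis scores
(vector fitting): arrows along the coefficient direction scaled by √R²,
permutation p by row shuffling, top six taxa by R² reported.

## Cervid index and beta regression

The cervid index pools pellet-group counts of all four deer species:
`Σ groups / Σ surveyed area × 100` (area counts each distinct
plot × species-class once — 100 m² for the large class, 10 m² for the
small — making the index invariant to how counts are split across
rows). Transects with fewer than 12 of 16 plots surveyed are excluded;
indices above 25 groups/100 m² are removed as outliers.

Overlap values are modelled as `y ~ Beta(μφ, (1−μ)φ)` with
`logit(μ) = Xβ` and constant φ on the log scale (log link guarantees
positivity; the precision link is otherwise a free choice), fitted by
maximum likelihood (statsmodels' beta-regression machinery; an
independent brute-force likelihood grid serves as the oracle in tests).
Standard errors come from the inverse observed information and two-sided
normal z-tests. Exact 0/1 responses are compressed with
`y′ = (y(n−1)+0.5)/n` — and only when a stratum actually contains
boundary values, to perturb the data minimally. The reported pseudo-R²
is the squared correlation of logit(ŷ) with logit(y), labelled as such
in the output since several inequivalent definitions circulate.
Strata with fewer than 8 transect observations are skipped with a note;
predictor pairs correlated beyond |r| = 0.3 are flagged. Near-separation
can produce very large coefficients; we report convergence diagnostics
rather than penalize.

## Synthetic community

The generator emulates a two-landscape, four-species, three-season
sampling design: a coastal-boreal landscape (cervid index mean 0.43,
SD 0.62 groups/100 m²; arable 5.3% ± 7.9; habitat H′ 1.95 ± 0.17) versus
a boreo-nemoral landscape (4.88 ± 2.17; 15.7% ± 14.4; 2.10 ± 0.19).
Transect-level index targets are drawn from gamma distributions matching
those moments (a truncated normal would inflate the low-density mean);
pellet counts are Poisson around the target. Habitat diversity and
arable fraction are drawn independently, so predictor collinearity stays
below the 0.3 screening level in expectation.

Diets are Dirichlet draws around species × season × landscape mean
vectors over a pool of 210 plant MOTUs in 77 families. The means encode
the browser-to-grazer gradient: moose winter/spring diets are
pine-dominated (> 50% mean RRA boreo-nemoral, 35–40% coastal-boreal,
~15% in summer–autumn) and graminoid-free (< 1%); graminoid and forb use
rises from roe over red to fallow deer, with forbs in the smaller deer's
boreo-nemoral winter diets emulating supplementary feeding. Per-species
evenness (within-category weight decay and baseline mass) and Dirichlet
concentrations were set so that per-sample richness in the final
filtered dataset reproduces the reported ordering and approximate ranges
(moose lowest, fallow highest) and so that within-species diet
variability is larger in the growing season — the source of the
winter-to-summer decline in intraspecific overlap. The concentration
also orders species (moose most homogeneous, fallow least).

Reads are two-stage Dirichlet-multinomial: each of the three plant
replicates perturbs the latent diet with replicate-level overdispersion
(default 1/300; 0 gives identical replicates) and draws a multinomial at
log-normal depth (median 20,000 reads). Two failure mechanisms match the
two QC discard branches: 3% of replicates draw a low depth (< 1000
reads) and 2% a control-like composition. Controls receive Poisson reads
from a contamination profile of ubiquitous taxa (positive controls from
a dedicated marker MOTU); eight artifact MOTUs below the 95% similarity
threshold receive ~1% of reads to exercise the similarity filter without
touching the 210-MOTU diet pool. Mammal PCRs mix the host MOTU (mean
share 0.93) with one cross-species MOTU, a 36-bp artifact and an
unmatched MOTU. All randomness flows from one master seed through
deterministically spawned child streams; identical seeds give
byte-identical tables.

Default problem sizes are a scaled-down version of the field design:
17 + 16 transects (the seasonal-collection subset) and ~2.5 expected
samples per transect × species × season (~900 samples total, versus
2568 in a full field campaign), with fallow deer rarer in the
coastal-boreal landscape. These sizes keep a full pipeline run in
seconds while leaving every stratum populated enough for transect-level
overlap and the beta regressions.

**What the generator does not emulate** — and hence what passing tests
do not establish about field data: PCR amplification bias and
chloroplast copy-number variation (latent diets are taken as the truth
RRA converges to), tag-jumping and chimeras beyond generic artifact
MOTUs, spatial autocorrelation among transects, observer effects in
pellet counts, and year-to-year variation (a single nominal year is
simulated).

## Numerical choices and degenerate inputs

Proportions are validated to sum to 1 within 1e-9; TSV round-trips
preserve floats to ≤ 1e-12. Zero-total rows are dropped (with a warning
path) before RRA. Pianka's index is undefined for zero vectors (error),
and clipped into [0,1] against floating-point drift. PCoA treats
eigenvalues within `1e-12·max|λ|` of zero as zero. Permutation p-values
never return 0 (add-one estimator). Beta regression refuses responses on
the boundary rather than silently adjusting; `boundary_adjust` is
explicit. Dunn tests exclude groups with < 2 observations; BH adjustment
is applied over the pairs actually tested.

## Known limitations

* The k-NN control rule needs several controls and many sample
  replicates to be meaningful; with a handful of points, distance ties
  at 1.0 (disjoint compositions) can make neighbour sets arbitrary.
* The centroid-R² permutation test is sensitive to dispersion
  differences between groups, like the procedure it stands in for.
* Beta regression assumes independent transect observations; spatial
  structure is not modelled.
* Selectivity compares RRA to step-point availability; both are relative
  measures, so D is a ranking tool, not an absolute intake estimate.
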
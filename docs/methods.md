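# Methods

## Data model and ingestion

A study is a set of 16-channel TMT plexes. Each plex carries up to 15
biological samples (genotype ∈ {WT, quad} × treatment ∈ {mock, flg22} ×
time ∈ {3, 15} min × replicate) plus one pooled-reference channel made
from all samples, which is what makes plexes comparable. The central
in-memory objects are a validated design table (`SampleDesign`) and a
features × (plex, channel) `ReporterMatrix` (a pandas DataFrame with a
two-level column index). Missing intensities are NaN and are distinct from
zero everywhere: MaxQuant writes 0 when a reporter ion was not quantified,
and a count model must not read that as a measured zero, so zeros are
converted to missing on ingestion (configurable at the reader level by
pre-editing the table; the pipeline itself never imputes).

Site tables are filtered on read: decoy ("Reverse") and contaminant rows
are dropped, as are sites below the localization-probability cutoff
(default 0.75, the usual "class I" convention; the threshold is an
argument because the appropriate stringency is study-specific). MaxQuant
multiplicity columns (`___1/___2/___3`) are summed into one intensity per
site, since all downstream statements are about sites, not
site–multiplicity combinations. Site identifiers are
`<locus>_<residue><position>` with 1-based protein coordinates
(e.g. `AT3G26090_S428`).

## Normalization

**Sample loading (SL).** Within each plex, channel c is scaled by
mean(channel totals)/total(c), with totals computed over features complete
within that plex. This removes per-channel load/labeling differences; it
deliberately assumes total protein per channel is equal by design.

**Internal reference scaling (IRS).** Per feature j, with r_pj the
geometric mean of the reference-channel intensities in plex p and t_j the
geometric mean of r_pj over plexes, every channel of plex p is multiplied
by t_j/r_pj. Batch effects in isobaric data are feature-specific, so IRS
is applied per feature, not as a per-plex scalar. Features with a missing
or zero reference intensity in any plex cannot be placed on the common
scale; they are flagged not-cross-plex-comparable, left unscaled, and
excluded from cross-plex contrasts.

**Fixed-point composition.** One SL pass followed by one IRS pass does not
leave a matrix invariant under a second application: IRS reweights
features and thereby perturbs the within-plex totals SL had equalized (by
~1% on realistic data). `normalize_pipeline` therefore alternates SL and
IRS until both stages' factors are within 1e-12 of 1 (typically 3–5
cycles), and reports the accumulated factors. The output satisfies both
invariants simultaneously — equal complete-feature totals within plexes
and identical cross-plex reference profiles — and re-running the pipeline
is a no-op. The whole pipeline is scale-equivariant: multiplying the
input by c > 0 multiplies the output by c.

## Differential testing

The test is a two-class Poisson log-linear score test on count-like
reporter data.

*Counts.* Normalized intensities are divided by
(median positive intensity / target median count, default 500) and rounded
to the nearest integer (floor 0). `target_median_count=None` disables
rescaling for data already on a count scale. Rescaling to a smaller median
makes the implied counts underdispersed relative to true Poisson, i.e. the
test becomes slightly conservative — preferable to anticonservative for
FDR control.

*Depths.* Relative sample depths d_i (Σd = 1) are estimated iteratively:
start from column-sum proportions; compute each feature's Poisson
goodness-of-fit GOF_j = Σ_i (N_ij − d_i N_j·)²/(d_i N_j·); re-estimate d on
the features with GOF between the 25th and 75th percentiles (the least
differential set); repeat until max|Δd| < 1e-10 or 20 iterations. With
fewer than 20 features the estimate falls back to plain column sums with a
warning. This trimming keeps strongly differential features from biasing
the depths, which matters exactly when there is signal.

*Statistic and calibration.* T as given in the README; T = 0 when a
feature's total is 0. p-values come from the χ²(1) upper tail (default) or
from a label-permutation null pooled across features
(p = (1 + #{T* ≥ T})/(1 + B), deterministic given a seed). q-values are
Benjamini–Hochberg. Features are excluded (with a reason column) when not
cross-plex comparable, incomplete in the contrast's samples
(complete-case testing), or below a total of 10 counts.

log2 fold change is the depth-adjusted class-mean ratio
log2((n_a/D_a)/(n_b/D_b)); it is ±inf when one class sums to zero, which
is reported as-is rather than masked by a pseudocount.

## Dependence classification

For a scope (all sites, or sites on loci of the G-protein interactome), a
WT-significant site (q < cutoff) is *G-protein dependent* unless the same
site id is significant with the same direction in the quad mutant;
dependent_fraction = 1 − |same-sign quad hits| / |WT hits|. Sites never
detected in the quad experiment count as dependent by default — the
comparison is between significance calls, and an undetected site provides
no evidence of independence — with `count_undetected_as_dependent=False`
switching to a detection-conditional denominator. Direction calls per
protein are increased / decreased / both / none according to the signs of
its significant sites within a contrast. Both classifications are pure
functions of the significance table (no randomness).

## Network topology

Edge lists are merged into a simple undirected graph: unordered pairs
deduplicated, self-loops dropped and counted, each edge carrying the set
of contributing sources; directed or weighted inputs collapse to simple
edges (degree analysis is unweighted). Degree is the number of distinct
neighbors. The hub cutoff is the smallest realized degree c such that the
fraction of nodes with degree ≥ c is at most the requested top fraction
(default 5%); all ties at c are hubs, so the achieved fraction is only
approximately the requested one. Hub enrichment per scope (whole network,
immune node set, G-interactome node set) is a one-sided hypergeometric
test reported as both p_over = P(X ≥ x) and p_under = P(X ≤ x); the two
share the P(X = x) atom, so p_over + p_under ≥ 1. No multiplicity
correction is applied across scopes (raw p-values are reported, with the
≤ 0.001 convention left to the caller). The degree shift between
phosphorylated and other nodes uses Welch's t-test by default (pooled-
variance and Mann–Whitney variants by flag; raw degrees by default, log1p
behind a flag). When both groups have zero variance the test is
degenerate: p is reported as the smallest positive float with a warning.

## Synthetic data generator

The generator emulates the study's design, not its mass spectra: no
peptides, missed cleavages or co-isolation interference are modeled.
Per feature, a log-normal baseline (default log2 mean 10, sd 1.5 — median
~1000 counts, a realistic reporter depth) is modified by a planted log2
effect (N(1, 0.25) by default, applied to flg22 samples at both time
points) in a `frac_differential` subset (default 10%); a
`frac_quad_suppressed` subset of those (default 95%) has zero effect in
quad — the planted G-protein-dependent fraction. The pooled reference's
expectation is the mean of its plex's sample expectations, mirroring how
the pool is made. Nuisance structure is multiplicative: per-channel
loading factors uniform on [0.7, 1.3] and per-(plex, feature) log-normal
batch factors (log2 sd 0.5) — precisely what SL and IRS are built to
remove, making their correctness testable by construction. Counts are
Poisson (default) or gamma-mixed negative binomial. Everything is a pure
function of (parameters, seed).

Networks are Barabási–Albert preferential-attachment graphs (the hub
analysis presumes a heavy-tailed degree distribution). The phospho label
of a node of degree d is Bernoulli with probability
logistic(α + bias·log d), α solved by root-finding so the expected phospho
fraction matches the request; other category labels are uniform, i.e.
independent of topology.

What passing tests on these data do *not* show: robustness to real-data
features the generator omits — non-Poisson technical variance from
co-isolation, missingness correlated with abundance, shared peptides
across sites, or curation biases in real interactome databases.

## Problem sizes and numerics

Simulation-based tests use 2000 features × 26 channels (two 16-plexes) and
10 seeds per claim, 5000-node networks × 100 seeds for enrichment power,
and exhaustive enumeration of hypergeometric configurations up to N = 12
plus 100,000-draw permutation checks up to N = 50 — sizes at which every
Monte-Carlo tolerance in the suite has comfortable margin. Convergence
tolerances: depth iteration 1e-10 (max 20 iterations), normalization fixed
point 1e-12 (max 50 cycles). χ²(1) p-values are floored at the smallest
positive float so downstream logs never see 0. BH is used exactly
(step-up with monotonicity), so reordering features never changes a
q-value.

## Known limitations

- No moderated-variance (limma-style) alternative, paired designs, or
  multi-class tests; contrasts are two-group.
- Single imputation-free complete-case policy; sites missing any channel
  of a contrast are simply not tested there.
- IRS requires every plex to share reference-observed features; studies
  without pooled references cannot be cross-plex normalized here.
- The overlap summary operates at the protein (locus) level only.
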
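# Methods

## Data model and scales

The pipeline operates on a probe × sample matrix of non-negative
linear-scale intensities with a matching detection p-value matrix and a
sample design (donor, donor group, cell type, replicate).  Pre-logged input
is declared with a flag rather than inferred, because the coefficient of
variation is scale sensitive.  Non-positive intensities are floored at a
configurable small value (default 1.0) before log₂; background correction
is deliberately not performed.

Detection filtering follows the platform convention for bead arrays: a
probe passes in a (donor group, cell type) stratum when at least 75% of
that stratum's *donors* have detection p ≤ 0.01, a donor counting as
detected if any of its replicate samples is.  By default a probe is kept if
it passes in at least one stratum (`scope="any_group"`); the per-stratum
lists are also available.  The per-donor min-p aggregation is this
package's choice — the convention only speaks of "individuals".

## Normalization regimes

Five regimes, all applied after log₂: (i) log₂ only; (ii) median
normalization with all probes (subtract each sample's median log₂ value);
(iii) median normalization computed over detected probes only;
(iv) quantile normalization (each sample's sorted values replaced by the
cross-sample rank means; tied values receive the mean of the reference
values over their rank span, which keeps the map deterministic);
(v) a monotone quantile-anchored spline: each sample's anchor quantiles are
mapped onto the mean quantile profile through a PCHIP curve.  The spline
regime is an approximation of robust spline normalization, not a
re-implementation of any particular package's internals; the five regimes
are treated as interchangeable and a concordance table (pairwise and
overall Jaccard overlap of the low/high constraint classes) quantifies how
much the downstream classification depends on the choice.  On synthetic
data the overall concordance is high (≈ 89% low, ≈ 92% high at the default
conditions), consistent with treating quantile normalization as the default
for all downstream analysis.

## CV and constraint classes

CV is computed per gene per group as sample standard deviation (n−1) over
arithmetic mean, by default on linear intensities recovered from the
normalized log₂ matrix (CV of logged values is poorly behaved near zero).
A pooled all-samples column accompanies the per-group columns.  Thresholds
are the 25th/75th linear-interpolation (type 7, the R default) percentiles
of a reference vector — pooled all-donors CVs by default, the control
group's CVs as an option, since published practice is ambiguous between the
two.  Classification is strict: low iff CV < t_low, high iff CV > t_high,
boundary-equal values are mid, so the classes partition the defined CVs.
Genes with non-positive mean (undefined CV) are excluded and counted.

## Group comparisons

Genome-wide variance differences: two-sample t-test on log₂ CV over the
common gene universe, Welch by default (the unqualified "two-sample t-test"
of common practice; the pooled variant is a flag).  Zero CVs are excluded
with a logged count.  The same test applied to per-gene mean log₂
expression serves as the negative control that variance differences are not
mean-expression artifacts.

Compositional differences: Pearson χ² goodness of fit with df = 2 and no
continuity correction, observed (low, mid, high) counts against either the
theoretical split implied by the cutoffs (25:50:25 at defaults) or the
control group's counts rescaled to the set size.  Any expected cell < 1 is
an error advising a larger set.  Cutoff sensitivity re-runs
classification + test at (25,75), (10,90), (5,95) by default and reports the
sign of the low-class excess per cutoff.

A calibration subtlety, verified by simulation and enforced in the test
suite: the log₂-CV t-test treats genes as independent observations.  When
per-gene dispersion is heterogeneous and shared between groups — the
realistic case — the two CV vectors are positively correlated gene-wise and
the test is strongly conservative; it is exactly calibrated only under the
exchangeable null (equal variance scales *and* homogeneous per-gene
dispersion), which is the null the calibration tests simulate.  Similarly,
a group's whole-genome class counts tested against 25:50:25 are *not*
calibrated when the thresholds come from the pooled reference (the group CV
estimate is noisier than the pooled one, inflating both tails by
construction); the calibrated use — and the one the per-pathway analysis
performs — is testing a gene *subset* of a classification whose universe
proportions are 25:50:25 by construction.

## Core-pathway discovery

Per gene, a one-way ANOVA F across phenotype classes (vectorized sums of
squares, p from the F distribution).  Per gene set: a Welch t-test of
in-set versus out-of-set log(F + 1e-8) — the ε admits F = 0 genes — with BH
adjustment across sets; sets with adjusted p < 0.05 are retained and ranked
descending by detected-probe count (ties by adjusted p, then name).  The
gene-set statistic and the informativeness criterion below are this
package's concrete choices where published descriptions defer details; each
is isolated behind a single function for substitution, and they are
validated by FDR-control and recovery properties rather than by matching
any published pathway list (which is annotation-version-dependent).

Synexpression decomposition: average-linkage hierarchical clustering of the
significant in-set genes on 1 − Pearson correlation, cutting the dendrogram
at the smallest k (up to max_groups = 10) at which every cluster's mean
member-to-mean-profile correlation reaches min_corr = 0.85; singletons are
dropped; fewer than 3 eligible genes yield one trivial group.
Informativeness is recorded as the within-group MSE about the mean profile.
Expansion adds every gene whose profile correlates with the group *mean*
profile at ≥ 0.85 (signed r; anti-correlated genes never enter); expansion
is monotone in the threshold and O(universe).

## Network topology

Genes map to nodes through an explicit, possibly many-to-one node map;
degree comes from the undirected simple graph (self-loops removed,
duplicate edges collapsed at ingestion).  Per constraint class, degrees are
summarized by a Gaussian KDE (Scott's reference-rule bandwidth, density
normalized on its grid) — descriptive only, never used for testing.  The
primary comparison of two class degree distributions is the two-sample KS
test (exact small-sample p where available); a χ² on jointly binned counts
(pooled-sample quantile bins merged until every expected cell ≥ 5) is
reported alongside, because both statistics appear in published practice.
Degree–CV association is a Spearman correlation; when several probes share
a node, the node's CV is the minimum over probes ("most constrained wins",
mean as an option).

## Replicate variance

Within-donor variability: per donor with ≥ 2 samples, the mean over genes
of the CV across that donor's replicates.  Between-donor variability: per
group, the mean gene CV across donors, plus a sample-size-matched version —
random subsets of 4 donors (default), one randomly chosen sample per donor,
100 subsets — so the two sides are estimated at the same n.  Each subset
draws from its own named substream, so increasing the subset count extends
rather than reshuffles earlier draws.  The summary comparison is a Welch
t-test of per-donor within means against the pooled subset means.

## Enrichment

Upper-tail hypergeometric p for the overlap of a query list with each term
(term size counted within the universe; terms with K < 3 skipped), BH
adjusted within each ontology class, each (class, query) stratum an
independent family.  Terms significant in both the high- and
low-constraint lists can be excluded so only class-unique terms remain.
The universe defaults to the detected, annotated genes.

## Synthetic data: what it emulates and what it does not

Per gene g: a baseline log₂ mean μ_g ~ N(8, 2²) and a dispersion expressed
as a linear-scale CV, drawn from a Gamma with mean 0.2 and shape 2 (a
long-tailed, right-skewed genome-wide CV distribution).  A sample of donor
d in group k is log-normal:

    log₂ x = μ_g + shift_g(cell type) + a_{g,d} + e,

where the donor effect a and residual e split the group-scaled standard
deviation s_k·σ_g so that the donor effect carries a fraction f = 0.8 of it
(total between-donor sd stays s_k·σ_g; replicates of one donor vary with
sd √(1−f²)·s_k·σ_g).  The implied true per-group CV,
√(exp((s_k σ_g ln2)²) − 1), is recorded as ground truth.  Group variance
scales default to 1.0 (control, 11 donors), 0.5 (variance-deflated SZ-like,
9 donors) and 1.6 (variance-inflated PD-like, 13 donors); the donor counts
follow the emulated study design, while the effect sizes are fixture
conventions chosen to be unambiguous at those sample sizes — no published
estimates exist for them.  Pathway gene blocks receive a log₂ mean shift
between cell types (the signal the ANOVA discovery looks for) and
optionally a dispersion override.  Detection p-values are U(0, 0.005) for
expressed entries and U(0.1, 1) for dropouts — cleanly separable around the
0.01 threshold — with an optional fraction of probes undetected in every
sample (default acceptance conditions use 0.32, leaving ≈ two-thirds of the
array detected).  The interaction network assigns each gene a latent
propensity mixing the reversed CV rank (weight = coupling) with independent
noise and draws a fixed number of edges with endpoint probabilities
increasing in that propensity, so Spearman(degree, CV) ≈ −coupling.

Not emulated: probe sequences and array geometry, batch/chip effects,
mean-variance coupling beyond the log-normal law, correlated expression
between pathways, and annotation structure (GO graphs are taken as flat
term lists).  Passing tests therefore demonstrate correctness and
calibration of the statistics under a clean generative model, not
robustness to the artifacts of real array data.

All randomness descends from one seed through named substreams (CRC32 of
the stream name combined with the seed), so adding a pipeline stage never
perturbs another stage's draws and bit-identical reproduction only requires
the seed.

## Numerical choices and degenerate inputs

Type-7 percentiles throughout; Welch t-tests by default; χ² without
continuity correction; log-F ε = 1e-8; KDE grids of 256 points spanning
±3 bandwidths; quantile-normalization ties averaged over the rank span;
spline anchors at 15 quantiles with duplicate anchors dropped and linear
behavior outside the anchor range; constant profiles get correlation 1 with
themselves and 0 against varying profiles in the clustering step.  Errors
are raised (never silently coerced) for: groups of one sample, expected χ²
cells < 1, empty queries, degenerate single-bin degree histograms,
out-of-range p-values, cutoffs outside 0 < low < high < 100, and malformed
input files (with line numbers).

## Problem sizes used in validation

The test suite and acceptance script run at desk scale, chosen to keep the
Monte-Carlo error of every calibration check well inside its tolerance:
2,000 genes × 10 donors/group × 1,000 replicates for null calibration, 100
seeds for directional recovery, 50 seeds for the replicate-variance
contract, and a 6,000-gene, 33-donor, two-cell-type study for the
end-to-end acceptance run.  Headline published analyses of this design are
an order of magnitude larger in probe count (≈ 22,000), but every statistic
here is either exact or has calibration error shrinking in sample size, so
desk scale is the conservative regime for validating correctness.

## Known limitations

The gene-set statistic and informativeness metric are documented stand-ins
for the companion-method internals they summarize; the spline regime
approximates robust spline normalization; probe→node resolution and
per-donor detection aggregation are explicit choices where published
descriptions are silent; and the log₂-CV t-test should be interpreted as
conservative on real data (shared per-gene dispersion between groups), per
the calibration note above.
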
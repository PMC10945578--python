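# Methods

This note records the statistical models implemented in `gdcat`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that a
careful user (or re-implementer) needs to know.

## Robust correlation core

**Biweight midcorrelation.** Every correlation in the package is the
biweight midcorrelation. For a vector x with median `med` and median
absolute deviation `mad`, observations are mapped to
`u_i = (x_i − med)/(9·mad)`, given Tukey biweights
`w_i = (1 − u_i²)²·𝟙(|u_i| < 1)`, and standardised as
`a_i = (x_i − med)w_i / √Σ((x_j − med)w_j)²`; the coefficient is the dot
product of the two transformed vectors, clamped to [−1, 1]. The constant
9 is the conventional tuning of the biweight: points more than nine MADs
from the median get zero weight, which caps the influence of any single
subject — the property that motivates using bicor instead of Pearson on
population expression data, where single-donor artefacts are common.

Degenerate inputs follow the behaviour of the widely used reference
implementation of bicor: a vector whose MAD is zero but whose variance is
not falls back to the Pearson standardisation for that vector only (each
occurrence is logged); a vector with zero dispersion makes the
correlation undefined, which surfaces as an error in scalar calls and as
a NaN statistic in vectorised sweeps. The same fallback guards the rare
case where every off-median point lies beyond the biweight window.

**P-values.** Two-sided p-values use the Student-t large-sample
approximation `t = r·√((n−2)/(1−r²))` with n − 2 degrees of freedom, the
same treatment applied to Pearson's r. This is an approximation for
bicor, so its calibration is verified empirically: on i.i.d. Gaussian
panels the fraction of tests below α tracks α within binomial error at
α = 0.05, 0.01 and 0.001 (see `tests/test_acceptance.py`). `|r| = 1`
yields p = 0 exactly; p-values are reported as computed, without clamping
to machine epsilon.

**Multiple testing.** Benjamini–Hochberg step-up q-values (delegated to
`statsmodels`, with NaN pass-through so unevaluable tests do not shrink
the family). The adjustment family is always *all tests emitted by one
operation*: a pan-tissue query adjusts over every gene-tissue record
jointly rather than per tissue, because the tissue-binned summaries
compare tissues within a single adjusted family and per-tissue adjustment
would distort that comparison. The pathway survey likewise adjusts over
the pathway's full cross-tissue test family.

**Missing data.** Pairwise-complete deletion per gene pair. Records with
fewer than `min_n` complete subjects (default 10 in panel sweeps) are
emitted with NaN statistics rather than dropped, so downstream counts
remain auditable. The vectorised sweep groups genes by missingness
pattern; with tissue-level subject dropout (the dominant real pattern)
this reduces to one biweight transform and a matrix product per tissue.

## Expression filtering

Panels are filtered to genes whose observed values are strictly positive
("expressed in everyone"), the guard against genes detected only in some
individuals, whose zeros would manufacture spurious cross-tissue
structure. The filter is applied per tissue by default — a gene may
survive in liver and be dropped from spleen — with a `global` mode that
drops a gene everywhere once it fails anywhere. Per-tissue is the default
because it preserves signal in well-measured tissues; which family the
original filtering convention intended is ambiguous, so both are exposed.
A missing cell is treated as *missing*, not as a zero: missingness is
handled downstream by pairwise deletion, and conflating NA with zero
would empty sparse tissues entirely.

## Pan-tissue queries

A query correlates one source gene-tissue against every other gene-tissue
combination (the source tissue's other genes included; the source itself
excluded), attaches q-values over the whole family, and summarises
per-tissue counts of significant records at q < 0.1, 0.01, 0.001. Counts
are of gene-tissue records: a gene significant in two tissues contributes
to both bins. Top-correlate lists rank by |r| (or signed r) with ties
broken by p, then gene symbol, then tissue — an arbitrary but fixed order
chosen so repeated runs are byte-identical. The group-mean summary for
subject strata (sex, age bracket) is deliberately descriptive (mean, sd,
n) with no inferential statistic attached.

## Enrichment

**Preranked GSEA.** The ranked list is the query's bicor coefficients in
one target tissue, sorted descending, used as rank weights with exponent
1 (the coefficients as given). The running sum gains
`|w_i|/Σ_members|w|` at member genes and loses `1/(N − N_members)`
elsewhere; the enrichment score is the signed maximum deviation (ties
between equal positive and negative deviations resolve positive). The
null permutes *membership labels* over the ranked universe — with only a
coefficient list available, sample permutation is not definable, so the
standard preranked gene-label null is used. The permutation p-value is
sign-stratified with an add-one correction, so p ∈ [1/(nperm+1), 1] and
is never zero; NES divides ES by the mean |ES| of same-sign permutations.
The universe is the set of genes expressed (post-filter) in the target
tissue, not the whole genome: unexpressed genes cannot rank. Set-size
bounds default to [10, 500] and nperm to 1000; both are configurable and
a seed is mandatory. A set spanning the entire universe has no misses —
its running sum climbs monotonically to exactly 1, which is reported with
a log notice rather than an error.

**ORA.** One-sided hypergeometric upper tail on the overlap between a
top-N list and a set, members intersected with the universe first; BH
across sets when applied to a collection. N = 500 within-tissue genes is
the conventional list size.

## Correlation networks

Nodes are the query source plus its top `n_within` and `n_peripheral`
correlates by |r| (defaults 30/30; by default only records at q < 0.1 are
eligible, with a flag for pure-|r| ranking). Edges are *recomputed* from
the raw panel over pairwise-complete subjects — not copied from the query
table — so peripheral–peripheral edges exist. An edge is kept when
0.6 ≤ |r| ≤ 0.99: the floor keeps only strong relations and is applied to
|r| because negative edges are first-class (signed, for display as
blue/red); the ceiling guards against near-duplicate transcripts.
Zero-dispersion nodes are excluded with a warning; the source node is
always present even if isolated. Exports are edge-list TSV or GraphML
with node roles preserved.

## Deconvolution

Per subject, cell-type proportions solve non-negative least squares
`min ‖S f − b‖₂, f ≥ 0` on the genes shared between bulk and signature
(≥ 20 required; the signature must be full column rank on them), and the
solution is renormalised to the probability simplex. The
scale-then-normalise formulation was chosen over a hard sum-to-one
equality because it makes the estimate exactly invariant to positive
rescaling of the bulk vector (TPM-like and count-like inputs agree),
while still recovering noiseless mixtures exactly and returning simplex
rows. The per-subject residual is reported on the unit-sum scale. A
subject whose fit is identically zero receives a uniform row with a
warning. Bulk and signature are expected in linear units; a heuristic
warns when a matrix looks log-scaled (max < 30). Signature construction,
marker discovery and alternative deconvolution families are out of scope.

## Cross-tissue connectivity survey

For a pathway's member genes, every (gene in tissue a) × (gene in tissue
b) pair with a ≠ b is tested; within-tissue pairs are omitted because the
survey asks specifically about *between*-organ structure. Counts of tests
passing p < 1e-3, p < 1e-6, q < 0.1 and q < 0.01 (defaults) fill a
symmetric tissue × tissue matrix with zero diagonal, normalised by
pathway size. The counting unit is the significant gene-pair test, with a
`unique-genes` mode counting distinct member genes involved in ≥ 1
significant test, since both conventions appear in practice. Per-tissue
totals sum each tissue's row (both members of a pair are attributed, so
totals are symmetric and sum to twice the cell total); tissues are ranked
once at a reference threshold and counts at other thresholds are
re-reported in that fixed order. Size-matched random gene sets drawn from
the genes common to all tissues provide the null; on i.i.d. panels their
per-tissue rankings show no concordance (Kendall's W consistent with
zero), whereas planted pathway structure survives.

**Missingness diagnostic.** Per tissue, the missing-data burden is the
count of absent subject-gene values against the full subject registry
(an unassayed subject contributes one missing value per gene; a
per-individual breakdown is exposed for audit). Within a tertile of the
connectivity ranking (size ⌊T/3⌋, middle tertile absorbing the
remainder), the diagnostic correlates missingness with significant-count
totals. It accepts a list of rankings and pools the (tissue, pathway)
points across pathways — a single ranking's tertile of three or four
tissues cannot support a powered test, and the pooled form matches how
the question is actually asked: *are low-ranked tissues low because their
data are sparse?* Zero dispersion (no missing data anywhere) returns the
NaN marker rather than an error.

## Phenotype correlation

Gene ~ trait bicor at the strain/subject level over pairwise-complete
identifiers, BH across traits, direction = sign(r). Strain-level means
are expected as input; the module performs no within-strain aggregation.
Top traits are ranked by p (the −log10 p display convention) with trait
name as tie-break, and each record carries flags for the conventional
p = 0.05 and p = 0.001 reference lines.

## Synthetic panels

The generator is a Gaussian latent-factor design: each gene-tissue has a
standard-normal latent vector across subjects; hub partners are
`r·z + √(1−r²)·ε` against the hub's latent, block members load √ρ on a
shared factor (pairwise latent correlation ρ), traits couple linearly to
a driver gene, and cell-type mixtures are Dirichlet fractions through a
marker-structured signature with truncated Gaussian noise. Latents map to
expression as `exp(0.25·z + 2)` — positive, mildly log-normal values
(~7 units median) so the positivity filter is meaningful. Because bicor
is not invariant under nonlinear monotone maps, planted correlations are
specified on the latent scale; the mild log-scale keeps the expression-
scale bicor within the tolerances asserted in the tests (empirically
within ±0.06 of the latent target at r = 0.8, n = 500). Missingness is
per-tissue Bernoulli subject dropout, the dominant structure of real
multi-tissue panels. Every planted edge is recorded in a manifest, and
all outputs are pure functions of (config, seed).

**What the generator does not emulate:** read-count noise
(negative-binomial overdispersion), batch and library-size effects,
heavy-tailed single-donor artefacts beyond what the log-normal map
produces, gene-length and GC biases, genetic relatedness between strains,
and within-tissue correlation of missingness with phenotype. Tests
passing on these panels therefore demonstrate that the *algorithms*
recover the structure they target at the configured effect sizes and
sample sizes — not that real-data effect sizes will be as clean, nor
that normalisation artefacts cannot masquerade as signal.

## Study-condition defaults used in verification

The acceptance checks (tests and `scripts/acceptance.py`) run at fixed
problem sizes chosen to represent the intended regime while keeping the
suite fast: null calibration on 3 tissues × 300 genes × 200 subjects over
20 seeds; hub recovery with 10 partners at latent r = 0.8, n = 200;
pathway surveys on 50-gene sets across 3 tissues (~7,500 cross-tissue
tests per panel); a 12-tissue panel with a dropout gradient
(0.2/0.4/0.6/0.75 on the bottom four tissues) and four 12-gene pathways
at ρ = 0.45 for the missingness diagnostic; 100 Dirichlet mixtures at 5%
noise for deconvolution; and 1000 label permutations for GSEA positive
controls with full enumeration on an 8-gene universe as the exactness
check.

## Known limitations

- The Student-t p-value is an approximation for bicor; it is verified by
  simulation at moderate n, not proved, and may drift for n ≲ 10.
- BH q-values assume the positive-dependence regime; pan-tissue families
  are strongly positively dependent, which keeps BH conservative on
  average but individual queries can still produce occasional full-null
  rejections at q < 0.1 (as FDR control permits).
- The deconvolution module implements one method (simplex-constrained
  least squares); no attempt is made to compare deconvolution families.
- Gene sets are flat lists: no GO DAG traversal or ancestor propagation.
- The CLI reads whole panels per invocation; there is no caching layer,
  which is acceptable at the panel sizes the package targets.
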
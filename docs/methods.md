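# Methods

This note documents the statistical procedures implemented in
`rhizonet`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic-data tests do and do not demonstrate.

## Table handling and rarefaction

Count tables are integer OTU × sample matrices in the classic
tab-separated layout (OTUs as rows, optional trailing `taxonomy`
column). Two filters are applied before any diversity analysis: OTUs
with a total below 20 reads are removed (strict `<`), as are OTUs whose
lineage contains `mitochondria` or `chloroplast` as a case-insensitive
substring — robust to rank-prefix dialects like `c__Chloroplast`.

Rarefaction draws, for each sample, an exact subsample of `depth` reads
without replacement (a multivariate hypergeometric draw via numpy's
generator). Samples below the target depth are dropped with a warning.
The default depth is the post-filter minimum sample total — standard
practice when the source data do not prescribe one. A single seeded
draw is exposed; callers wanting rarefaction averaging can loop over
seeds. Per-OTU subsampled counts are unbiased for depth × proportion,
which the test suite verifies against the hypergeometric expectation.

## Alpha diversity and group comparisons

Shannon diversity uses log base 2 (bits), matching the convention of
the classic QIIME-era toolchain this pipeline mirrors; base e is
selectable. Chao1 defaults to the bias-corrected form
S_obs + F₁(F₁−1)/(2(F₂+1)); the classic form S_obs + F₁²/(2F₂) is
selectable and falls back to the bias-corrected value when F₂ = 0.

Group comparisons run one-way ANOVA followed by Tukey HSD. The
compact-letter display assigns one letter per maximal clique of the
"not separated at α" graph, ordered by descending clique mean; two
levels share a letter iff Tukey does not separate them. Habitat
contrasts within each site use the two-sample equal-variance Student's
t-test with Benjamini–Hochberg correction across taxa ("FDR" always
means BH here).

## Weighted UniFrac, PCoA, PERMANOVA

Weighted UniFrac is computed from a branch × sample matrix of
descendant read proportions accumulated in one postorder pass;
d(A,B) = Σ_b ℓ_b |p_A(b) − p_B(b)|. The raw (non-normalized) form is
the default — the metric named `weighted_unifrac` in the QIIME 1.9
toolchain — with the abundance-weighted normalizer
Σ_b ℓ_b (p_A(b) + p_B(b)) selectable, which bounds distances in [0,1].
The implementation accepts multifurcating trees; it is verified against
both a brute-force branch-enumeration oracle and scikit-bio on
bifurcating trees.

PCoA is the classical eigendecomposition of the Gower-centered squared
distance matrix (delegated to scikit-bio); negative eigenvalues are
reported but excluded from explained-variance proportions.

PERMANOVA (ADONIS) partitions tr(G), G the Gower-centered matrix, by a
single factor. Categorical factors are dummy-coded; continuous
covariates (N, P, K, organic matter, pH in the motivating design) enter
as a centered single-term distance-based linear model
(McArdle–Anderson), reproducing vegan's one-term `adonis` behavior.
Significance comes from free permutation of sample labels with
p = (exceedances + 1)/(permutations + 1). Exceedances are counted with
a strict `>` (plus a 1e-10 relative float tolerance): permutations that
merely reproduce the observed partition tie the pseudo-F exactly and
carry no evidence against the null; under a continuous null the
convention is equivalent to `>=`, and type-I calibration is verified by
simulation (500 null datasets, rejection rate within [0.03, 0.07] at
α = 0.05). Saturated one-level-per-sample designs return R² = 1 with an
undefined p rather than an error.

## Rhizosphere specificity and the core microbiome

An OTU is flagged rhizosphere-specific for a site when all four
criteria hold: presence in every rhizosphere replicate; summed
rhizosphere count strictly greater than 20; mean fold change ≥ 3
against the reference; Student's t-test p < 0.05 between habitats. The
reference is bulk soil in the spatial design and the pooled bulk + bare
samples in the temporal design (falling back to bulk with a warning
when bare soil is absent). Decisions the source convention left open:

- Fold changes are computed on rarefied counts so habitats are compared
  at equal depth; this choice is logged in the report.
- The `> 20 reads` criterion applies to the summed group total (the
  natural reading of "among the three replicates").
- The fold criterion defaults to `≥ 3`, with the strict `> 3` variant
  as a config switch (`strict_fold`) since both conventions appear in
  practice.
- OTUs absent from every reference replicate are additionally flagged
  *exclusive*; their fold change uses a pseudo-reference of 0.5 counts
  so it stays finite and they remain inside the specific set.
- No FDR is applied within the specificity filter by default (the
  criterion is a per-OTU p < 0.05); a BH switch exists and is recorded
  in the output.

The core microbiome is the straight set intersection of per-site
specific sets; all 2ᵏ−1 Venn regions are reported. The temporal overlap
takes the active-rhizosphere specific set on one side and every OTU
present in the dormant rhizosphere on the other, reporting percent
change of mean relative abundance.

## Ensemble co-occurrence network

The pipeline follows the ensemble-inference design of CoNet-style
analyses:

1. **Merging.** Fungal and bacterial tables are row-concatenated
   (identical sample sets required; id collisions get `F_`/`B_`
   prefixes) and OTUs under 500 total reads are dropped. Counts are not
   normalized before scoring, which reduces compositional artifacts.
2. **Scoring.** Every OTU pair is scored under four measures on
   per-sample relative abundances: Bray–Curtis similarity
   (1 − dissimilarity), negated symmetrized Kullback–Leibler divergence
   of the pseudocounted (1e-6) row profiles, Pearson, and Spearman.
   Pairs undefined under a measure (constant profile under a
   correlation) are skipped for that measure.
3. **Candidates.** Per measure, the 1,000 strongest co-presence and
   1,000 strongest mutual-exclusion pairs (an initial network of 2,000
   edges, interpreted per measure and split evenly; ties broken by pair
   id) are kept; the candidate set is the union across measures.
4. **ReBoot null.** For each candidate and measure, 100 permutations
   shuffle one OTU's counts across samples. For Pearson/Spearman the
   shuffled table is renormalized per sample (column totals recomputed)
   before converting to proportions — this is the
   permutation-renormalization step that preserves the compositional
   coupling the null must account for; the distance-type measures
   shuffle the relative-abundance profile directly. Because 100
   permutations cannot resolve p < 0.01 empirically, the two-sided p
   comes from a Gaussian fit (mean, sd) to the null scores; zero null
   variance yields p = 1 with a warning.
5. **Bootstrap stability.** 100 resamples of the sample set with
   replacement (degenerate single-sample draws are redrawn, at most 10
   times); a measure-edge is kept only if the observed score lies
   within the [2.5, 97.5] percentile interval of its bootstrap
   distribution. Note the plug-in property of this rule: the observed
   score sits near the center of its own bootstrap distribution for
   smooth statistics, so the screen trims roughly the nominal 5% and
   widens — rather than reliably rejects — edges carried by single
   outlier samples; the tests characterize exactly this behavior.
6. **Brown's method.** Surviving per-measure p-values are combined by
   Fisher's statistic X = −2Σ ln pᵢ referred to a scaled χ² with
   moments matched to E[X] = 2k and Var[X] = 4k + 2Σ cov(−2 ln pᵢ,
   −2 ln pⱼ). Covariances are estimated empirically across all
   candidate edges (pairwise-complete, clipped to the theoretical
   χ²(2)-margin range [−4, 4]). With zero covariance the method reduces
   exactly to Fisher's; with perfectly duplicated p-values it returns
   the single p.
7. **Retention.** Merged p-values are BH-corrected across candidate
   edges; an edge is retained when q < 0.05 and at least 3 measures
   agree with the majority direction (direction of correlation measures
   from their sign; of distance measures from the pair's Spearman
   sign; direction ties drop the edge). Consortia are the connected
   components of the retained graph, and their per-sample summed
   relative abundance is compared across site × habitat groups with
   ANOVA/Tukey letters.

The permutation unit is pair-wise per-OTU shuffling and the initial
edge budget is per measure; both points are ambiguous in the original
descriptions of such pipelines and are fixed here and echoed in the
edge report.

## Synthetic data generator

The generator emulates the survey design the analysis expects: sites ×
habitats (rhizosphere/bulk/bare) × replicates, with defaults of 3 sites
× 2 habitats × 3 replicates and 100 fungal + 300 bacterial OTUs — a
desk-scale stand-in for the thousands of OTUs of a real survey.

The abundance model is compositional: OTU i has latent log abundance
μᵢ + siteᵢₛ + εᵢⱼ with μᵢ ~ N(0, 0.8²) (≈ two orders of magnitude of
base abundance spread), site offsets N(0, 1²) and replicate noise
N(0, 0.1²). Replicate noise is deliberately small: a field replicate in
this design is a composite of many pooled individual plants, which
averages plant-to-plant variation down. Sequencing depth is
log-normal(ln 10⁴, 0.1) — a depth-balanced run — and counts are
multinomial at the drawn depth, so all compositional coupling is
present. A Dirichlet-style overdispersion layer is intentionally
omitted to keep closed-form expectations for the tests.

**Planted enrichment.** `planted_enriched` OTUs get their latent
abundance multiplied by `enrichment_fold` (default 5) in rhizosphere
samples. Enrichment targets are drawn from the 25th–55th percentile
band of base abundance: sub-dominant taxa are the biologically typical
candidates for specific enrichment, are abundant enough to be
detectable at 10⁴ reads with 3 replicates, and keep the *compositional
squeeze* small — multiplying abundant OTUs would inflate rhizosphere
totals and drag everyone's realized fold toward 1. Even so, the
realized rhizosphere/bulk ratio concentrates around fold/(1+(f−1)·s)
for enriched mass share s, i.e. slightly below the planted fold, with a
per-OTU log-scale spread floor of ≈ √(1/(3·c_bulk)) from Poisson count
noise — at c_bulk ≈ 10 reads that is ≈ 0.2, which is why individual
realized folds scatter roughly ±40% around the center.

**Planted consortia.** Members of a consortium share a per-sample
latent factor: memberᵢ = μᵢ + σ_c·sᵢ·(√ρ·g + √(1−ρ)·eᵢ) with signs
sᵢ = +1 (or half −1 for mutual exclusion), giving pairwise latent
correlation exactly ±ρ. Consortium members take this construction
*instead of* site offsets and replicate noise, so the planted
correlation is exact by design; consortia are therefore
site-independent in the generator. Mutual exclusion via negated factors
(rather than structural zeros) keeps tables dense enough for the
correlation measures. One consequence worth knowing: a strong
consortium's mass fluctuations induce a compositional common mode
across all *other* OTUs, and when independent replicate noise is very
small this common mode can dominate and correlate everything — the
recovery tests therefore use moderate independent noise (0.5–0.7),
which is also the more realistic regime for unpooled comparisons.

**Ground truth** records enriched OTU ids with folds and consortium
membership/signs, from which the planted edge list (co-presence within
a sign class, exclusion across) is derived for recovery scoring.

The temporal variant generates two years at one site from shared base
abundances: the rainy year has the enrichment active; the dry year
removes it (dormant rhizosphere) and adds a per-OTU year offset
N(0, 1²).

## What the synthetic tests show — and do not

Passing recovery tests demonstrate that the pipeline detects the
planted effects under the generator's assumptions: log-normal
abundances, multinomial sampling, exact latent correlations,
site-independent consortia, balanced designs. Real data add
overdispersion beyond multinomial, taxon-specific amplification bias,
unbalanced and missing samples, phylogenetic correlation between OTUs
and consortia entangled with habitat structure; none of these are
emulated, so recovery rates here are upper bounds, not forecasts. The
false-discovery control result (retained edges ≪ 5% of candidates on
null tables) is similarly contingent on exchangeable samples.

## Problem sizes and numerical choices

The verification suite runs at deliberately desk-scale sizes chosen as
the package's own test conditions: 200-OTU × 18-sample null tables (20
seeds) for FDR control, 80-OTU × 30-sample tables for consortium
recovery, 550 OTUs × 6 samples for specificity recovery, 500 synthetic
datasets for PERMANOVA calibration, 100 random 8-leaf trees for the
UniFrac oracle. Tolerances: 1e-10 for oracle equivalence and the
Brown–Fisher reduction, 1e-8 for PCoA embedding, simulation bands
elsewhere as stated in the tests. p-values are clipped at 1e-300 before
logs; empirical Brown covariance is clipped to [−4, 4]; eigenvalue ties
in PCoA order by axis index; rarefaction and every permutation/bootstrap
step take explicit seeds, and the pipeline splits its master seed into
per-stage substreams so stages stay independently reproducible.

## Known limitations

- One-factor PERMANOVA only (no multifactor or stratified designs, no
  PERMDISP); unweighted UniFrac is not implemented.
- The bootstrap-stability screen inherits the plug-in property
  discussed above.
- Brown's covariance estimate pools all candidate edges; edges with few
  surviving measures borrow covariance information from the pool.
- The generator's placeholder taxonomy is minimal; taxa-aggregation
  workflows are exercised mainly through unit tests with explicit
  lineages.
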
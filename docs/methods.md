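# Methods

## The measurement model

MSAP is a dominant, anonymous fingerprint: each locus is a capillary-scored
fragment bin, and each sample contributes one binary presence/absence call
per restriction digest. Because *Hpa*II and *Msp*I cut the same CCGG site
with different methylation sensitivity, the pair of calls at a cell encodes
a methylation state (Types I–IV, see README). Two caveats shape everything
downstream:

- The (0,0) pattern is ambiguous: it is conventionally read as "fully
  methylated" (Type IV), but it can equally mean the restriction site is
  absent from that genome. The MSL binary recode therefore supports two
  policies — `fully_methylated` (default: IV counts as methylated) and
  `missing` (IV cells are set missing) — and the state-frequency tables
  report Type IV as its own class so the reader can discount it.
- Markers are dominant: allele frequencies are not estimable per sample, so
  diversity uses the binary Shannon index and differentiation uses
  distance-based Φ statistics rather than allelic F-statistics.

## MSL/NML partition and the scoring-error floor

A locus is Methylation-Susceptible when the fraction of its non-missing
samples in the discordant states {II, III} strictly exceeds the
`error_rate` threshold (default 0.05, the convention of the established
MSAP R tooling); ties at the threshold are NML. The comparison counts only
unambiguous discordance — (0,0) is concordant — and is invariant to sample
and locus order. Loci with fewer than 50% non-missing calls (configurable),
including all-missing loci, carry too little evidence and are assigned NML
with a logged warning; they are listed in `LocusPartition.low_call_ids`, so
the msl ∪ nml = all-loci invariant holds while the low-evidence set remains
identifiable.

Independent per-cell mis-scoring at rate e makes a truly concordant locus
appear discordant in a sample with probability 2e(1−e) (exactly one of the
two enzyme calls flipped). Any threshold below this floor misclassifies
NML systematically once sample counts grow. `suggest_error_threshold(e, n)`
returns `2e(1−e) + 2·SD_binomial(n)`; with the generator's default e = 0.03
and n = 144 that is ≈ 0.10, and the acceptance script uses this rule. The
library default stays at 0.05 for comparability with existing practice;
choosing the threshold from the observed duplicate reproducibility is the
recommended workflow.

## AMOVA and Φ

For N samples in two groups with squared pairwise distances d²:

    SS_total  = (1/N) Σ_{i<j} d²_ij
    SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij,  SS_among = SS_total − SS_within
    σ²_w = SS_within/(N−2),  σ²_a = (SS_among − σ²_w)/n0,
    n0 = N − (n_a² + n_b²)/N
    Φ = σ²_a/(σ²_a + σ²_w), clamped to [0, 1]

Negative among-group components are clamped to zero for Φ (the unclamped
value is kept in `sigma2_among_raw`). Φ_PT and Φ_ST are the same engine on
different inputs: raw band matrices per enzyme vs the MSL/NML binary
recodes. Distances are mismatch counts ("squared Hamming", the squared
Euclidean distance of 0/1 rows) computed pairwise-complete over missing
cells; this can diverge from tools that delete incomplete loci list-wise.
Significance uses random relabellings with fixed group sizes (default
9,999) and the add-one estimator p = (1 + #{Φ* ≥ Φ})/(n_perm + 1), so p is
never zero and a fixed seed gives bit-identical p-values. A group of size
one is allowed with a warning; an empty group is an error.

PCoA applies Gower double-centering to −½ d², keeps axes with positive
eigenvalues (scaled by √λ) and reports negative eigenvalues rather than
silently truncating; percent variance is over the positive spectrum. PCA
(for binary recodes) mean-imputes missing cells per locus, which shrinks
incomplete loci toward zero contribution — acceptable at the few-percent
missingness this assay produces. Combined-primer ordinations concatenate
the per-primer matrices locus-wise before computing distances; this treats
loci from different primer combinations as exchangeable columns.

## Exact tests and FDR

Each MSL yields a 2 × k contingency table of group × state counts over the
states actually observed there (empty state columns are dropped so the
exact test stays well defined; a `binary` flag collapses II/III/IV to one
methylated class). The Freeman–Halton p-value enumerates all tables with
the observed margins and sums the multivariate-hypergeometric point
probabilities not exceeding the observed table's, with a 1e−10 relative
tolerance so exactly tied tables are included despite floating point; the
2 × 2 case reduces to the classical two-sided Fisher test. Enumeration is
vectorised over a ≤ (c₁+1)×…×(c_{k−1}+1) grid, comfortable for the ≤ 48+48
samples and k ≤ 4 states this assay produces.

Benjamini–Hochberg adjustment is applied within each genotype × primer
family by default (the family a heatmap is drawn from); a `pooled` mode
adjusts across primers instead. Significance means q < 0.05.

## Clustering and heatmaps

UPGMA agglomerates with size-weighted average linkage; node heights are
half the merge distance, so leaf-to-leaf tree distance equals the cluster
distance and the tree is ultrametric by construction. Ties are broken
toward the pair containing the smallest original leaf index, making leaf
order and Newick output deterministic. Heatmap rows are samples in
dendrogram leaf order with a propagation colour strip; columns are the
significant loci; cells use one colour per Type I–IV. A TSV twin is always
written; with zero significant loci the TSV is header-only and no image is
produced.

## The synthetic-study generator

`simulate()` emulates the target study design rather than any particular
dataset: 3 genotypes × (field, micro) × 24 ramets, two primer combinations
of 240 loci, 70% MSL, and a global state mixture of 21.5/11.2/19.3/48.2%
for Types I/II/III/IV. Per genotype, each MSL draws its baseline state
distribution from a Dirichlet around the mixture (concentration 50: mild
between-locus heterogeneity); a `dm_fraction` of MSL (default 0.15) gets a
micropropagation effect that moves probability mass toward an alternative
state — one drawn among the non-dominant states, since a methylation shift
into the already-dominant state is unobservable. `dm_effect` is calibrated
to be the realized total-variation distance between the group
distributions (default 0.6); when the target state lacks headroom the
shift saturates at a point mass with a warning. NML draw a genotype-level
presence frequency from Beta(8, 1) (mean ≈ 0.89, giving mean NML Shannon
diversity ≈ 0.2–0.3, the range typical of clonal material) and emit
concordant bands; an optional `genetic_polymorphism` offset adds a
propagation effect to NML frequencies (default 0: the emulated effect is
epigenetic). States map to band pairs by inverting the state-calling rule;
then symmetric per-cell bit-flips at `error_rate` (default 0.03, the
midpoint of the 2–9% implied by 91–98% duplicate reproducibility) and
missingness at `missing_rate` (default 0: scored matrices are typically
complete) are injected per enzyme. Technical duplicates copy the pre-error
states of their source sample and receive independent errors, which is
what makes duplicate reproducibility ≈ 1 − 2e(1−e).

What the generator does **not** emulate: correlated peak-height artifacts,
fragment-size-dependent scoring bias, shared epialleles across genotypes,
block effects, and PCR competition. Passing tests therefore demonstrate
the statistics are computed correctly under independent-error sampling,
not that the assay's systematic artifacts are handled.

## Problem sizes and numerical choices

- The test suite exercises the permutation-null calibration on 5,000
  one-genotype null studies (8+8 samples, 40 loci, 999 permutations) and
  the FDR/recall benchmark on 200 studies (24+24 samples, 100 loci, 20
  seeded loci); both are sizes at which the checked properties are
  size-free while the suite stays fast.
- AMOVA permutation indicators are generated per permutation from one
  `numpy` Generator, and all pipeline stages derive child seeds from the
  global seed via `SeedSequence([seed, crc32(stage_name)])`, so stages can
  be re-run in isolation with identical results.
- Floating-point output uses the `%.10g` format everywhere, which is what
  makes same-seed pipeline runs byte-identical.
- Distances of a sample pair with no jointly scored locus, NaN in a
  distance matrix passed to PCoA, empty groups, and zero-variance paired
  differences are hard errors; zero-variance PCA input degrades to
  all-zero scores with a warning.

## Known limitations

- Only two-level (two-group) AMOVA is implemented; the target design never
  compares more than field vs micropropagated within a genotype.
- Locus identities are primer-scoped opaque strings; no matching of loci
  across primer combinations and no genomic annotation (MSAP markers are
  anonymous).
- The Wilcoxon "significance of the Shannon index" contrast is reported in
  two forms (field vs micro per-locus S within each locus class, and MSL
  vs NML per-locus S) because the convention varies between published
  analyses; neither is privileged.
- No support for raw capillary (.fsa) traces: the binary score matrix is
  the entry point.
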
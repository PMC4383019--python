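# Methods

`papevo` re-implements, as a tested library, the analysis stages of a
multi-region papillary renal cell carcinoma (pRCC) sequencing study:
somatic-variant filter cascades, mutation-spectrum statistics, arm-level and
focal somatic copy-number analysis with purity/ploidy harmonization and
mirrored-allelic-imbalance detection, cancer-cell-fraction (CCF) clonality
clustering, and UPGMA region phylogenies.  Raw sequencing data are not
required: a first-class synthetic-data module generates multi-region read
counts and SNP-array-like probe data with known ground truth, and the
cohort's published per-sample summary tables ship as validated fixtures.

## Synthetic data model

A tumour is a rooted clone tree.  Clone CCFs per region are generated by
stick-breaking: each parent's CCF is split among its present children with
symmetric Dirichlet weights, one extra stick retaining mass for the parent's
own cells.  This enforces the phylogenetic sum rule (parent CCF ≥ Σ child
CCFs) *by construction*, so it holds to machine precision rather than within
a tolerance.  A clone (with its whole subtree) may be absent from a region
with probability `p_clone_absent` (default 0.25), which produces the
region-private mutation blocks that multi-region sequencing is designed to
detect.  Regional tumour purity is uniform on a configurable interval,
default [0.3, 0.9], the plausible range for macrodissected kidney-tumour
pieces.

SNV read counts follow the standard purity/copy-number emission: a mutation
with multiplicity m on total copy number q carried by a clone at CCF f in a
region of purity α has expected VAF

    ξ = α·f·m / (α·q + 2(1−α)).

Sequencing depth is Poisson around the platform mean (default 100× for the
exome platform, 500× for ultra-deep validation), truncated at ≥1 read;
alt counts are Binomial(depth, ξ).  There is deliberately no overdispersion
or sequencing-error floor: the clustering model downstream assumes binomial
emission, and the generator emulates exactly the conditions that model
assumes.  Consequences for interpretation: passing recovery tests show the
inference machinery is correct under its own assumptions; they do not show
robustness to FFPE artefacts, mapping bias, or overdispersed real data.
Multiplicity is fixed at 1 and q at 2 unless an SCNA is explicitly placed;
both are exposed as truth columns rather than guessed.

Probe data (logR/BAF) place equally spaced probes on each arm of a
six-chromosome synthetic genome (40 Mb p-arms, 60 Mb q-arms — enough arms to
exercise arm-level calling without hg19-scale tables; any UCSC cytoBand file
can be substituted).  An arm-level event on haplotype A or B of a clone
shifts the clone-weighted haplotype copy numbers; expected logR is
log2((α·q̄ + 2(1−α))/2) and het-probe BAF follows the phase of the affected
haplotype, so gains of opposite haplotypes in different regions produce the
mirrored major/minor inversion the concordance test looks for.  Gaussian
noise (default sd 0.05 on logR, half that on BAF) is probe-level.
Germline het fraction is 0.4.  All randomness flows from one integer seed
through `numpy.random.SeedSequence` spawning, giving reproducible
independent sub-streams per tumour and stage.

## Variant filter cascades

Four exclusion cascades are implemented as ordered rule lists (burden,
driver, M-seq SNV, M-seq indel); the kept set is the conjunction of all
rules and is provably order-independent — rule order only attributes the
first failing rule to each removed variant.  Missing annotations raise
rather than silently passing.  Choices worth noting:

* the benign-prediction exclusion for driver candidates is a conjunction —
  a missense SNV is dropped only when SIFT > 0.3 **and** PolyPhen2 < 0.7
  (both predictors must call it benign); protein-truncating and splice
  variants are always retained, in-frame indels are retained as
  moderate-effect;
* "any read in the paired normal" means normal alt count ≥ 1 with no
  quality weighting;
* population frequencies are plain input columns (no live lookups); the
  local-panel exclusion is an optional blacklist flag;
* ultra-deep presence calls use VAF ≥ 1% with ≥1 supporting read; a
  zero-depth cell is *unevaluable* (NaN), never "absent".

## Mutation spectra

Substitutions fold onto the pyrimidine strand into the six canonical
classes.  Ts:Tv and dN/dS are count ratios, flagged undefined on zero
denominators.  The per-sample deviation test compares a sample's six-class
counts to the pooled spectrum of *all other* samples (leave-one-out, so a
hypermutant sample cannot drag the reference toward itself) with a Pearson
chi-square statistic and a Monte-Carlo null (default 10,000 seeded draws).
Because the reference proportions are estimates, the null resamples both the
test sample and the reference at their observed totals (parametric
bootstrap); with a fixed reference the test is measurably anticonservative.
The reported q-value is weighted Benjamini–Hochberg with weights
proportional to sample mutation count, mean-normalized (plain BH by flag):
"weighted" FDR puts more power on high-burden samples, which is where
spectrum shifts are interpretable.  Trunk-vs-branch spectra use a 6×2
contingency chi-square, switching to a seeded conditional Monte-Carlo null
when any expected count is below 5.  96-class trinucleotide profiles are
out of scope (no signature fitting).

## Copy-number pipeline

**Normalization.** Probe logR columns are quantile-normalized to the mean
empirical distribution across regions, then winsorized at 2.5 scaled MADs
around a centred 25-probe running median (the winsorization constant is a
package default; it bounds single-probe outliers without flattening real
breakpoints).

**Joint segmentation.** Per chromosome, the exact minimizer of

    Σ_regions Σ_probes (logR − segment mean)² + γ · (#breakpoints)

with breakpoints shared across all regions of a patient, by O(n²)
dynamic programming over prefix sums.  Exactness is tested against
exhaustive search over all breakpoint subsets on ≤12-probe instances.
The default γ = 1000 suits genome-scale probe counts; tests use small γ on
small instances.

**Purity/ploidy.** Grid search, purity 0.05–1.00 (step 0.01), ploidy within
±0.5 of a prior (step 0.05) from e.g. the flow-cytometry DNA index.  A
segment's observed relative ratio 2^logR is assigned the nearest lattice
point (α·q + 2(1−α))/(α·τ + 2(1−α)), q ∈ [0, 8], and scored under a
Gaussian with probe-level sd σ (default 0.05; a segment mean of n probes
has sd σ/√n), weighted by probe count.  Relative copy ratios carry an exact
degeneracy: (α/2, 2τ−2) with q′ = 2q−2 reproduces any profile bit-for-bit,
so maximum likelihood alone cannot recover purity.  A karyotype-parsimony
prior of 0.01 log-units per probe per |q−2| breaks these ties toward the
least-aberrant karyotype; it is orders of magnitude smaller than genuine
likelihood gaps and the alternate models remain visible in the top-k
ranking.  Note the simulator's probe logR is diploid-referenced
(denominator 2) while the fit models mean-normalized ratios (denominator
α·τ + 2(1−α)); these coincide for the near-diploid genomes simulated here,
and the recovery experiments generate profiles under the fit's own
convention.

**Harmonization.** One model per region is chosen by exhaustive search over
the ≤ top-k^R combinations, maximizing Σ log-likelihood − λ · Σ pairwise
mean |modal CN difference| across shared segments.  λ defaults to twice the
mean per-segment log-likelihood magnitude, making the agreement term worth
about one segment of fit; a lexicographic mode (distance first, likelihood
as tie-break) is provided because the underlying trade-off is genuinely
ambiguous.

**Arm events and accounting.** Gain/loss baselines are absolute (q ≠ 2),
not sample-ploidy-relative — the cohort is near-diploid and the published
per-sample gain/deletion strings are written against a diploid baseline.
An arm event requires >30% of the arm affected; both arms in the same
direction collapse to one whole-chromosome event.  Arms with zero probe
coverage (acrocentric p-arms) are uncallable.  Cohort recurrence uses
involvement semantics: a whole-chromosome event involves both arms.  In the
packaged cohort table, two rows print a total-changes count that differs by
one from the number of listed gain/deletion strings; the printed totals are
treated as authoritative for total/median/range accounting and the
discrepancy is surfaced by the loader.

**Co-occurrence.** For a set of recurrent gains, the per-sample probability
of carrying ≥2 of them under independence is computed from the marginal
frequencies (Poisson-binomial by expansion) and the observed count of such
samples is tested one-sided against Binomial(n, p₀).  This construction is
one of several defensible readings of an "exact binomial co-occurrence
test"; its null calibration is property-tested.

**Mirrored allelic imbalance.** Het probes in the event span are classed
major/minor (BAF ≷ 0.5) in the reference region (highest cellularity
carrying the event); every other region's flip fraction is tested two-sided
against 0.5 by exact binomial test.  Inverted (flip > 0.5, p < 0.05) is
read as the alternate haplotype being affected — parallel evolution;
fewer than 20 informative het probes gives "indeterminate" with the count
reported.

**Focal events.** Segments < 1 Mb with q ≠ 2 are reported unless a single
germline CNV covers more than 50% of the segment.

## Clonality

CCF = VAF · (α·q + 2(1−α)) / (α·m), with a Clopper–Pearson interval mapped
through the same linear transform; point estimates are clipped at 1.2 for
clustering with the overshoot retained for diagnostics.  Arm-level gains
can be folded into the clustering as pseudo-variants: the aberrant-cell
fraction is estimated from the mean major-allele BAF over het probes in the
span (ρ = (2m̄−1)/(1−m̄) for a single-copy gain), converted to a CCF, and
encoded as a dummy (depth, alt) pair at q=2, m=1 with effective depth =
het-probe count × 40 — the event then behaves exactly like an SNV of that
CCF inside the sampler.  The dummy-read construction is the package's own
documented convention.

Clustering is a Chinese-restaurant-process Gibbs sampler over per-region
CCF vectors φ ∈ [0,1]^R with a uniform base measure and binomial emission
ξ = a·φ (a the purity/CN factor above).  The new-cluster predictive
integral has a closed form through the regularized incomplete beta
function; cluster CCFs are redrawn by griddy Gibbs on a 101-point grid; the
DP concentration is resampled under a gamma(1,1) prior (Escobar–West).
Missing regions are missing data, never zeros.  The reported clustering is
a consensus: average-linkage cut at 0.5 of the posterior co-assignment
matrix — invariant to label switching and to input order.  Default MCMC
settings are 10,000 iterations / 2,000 burn-in / thin 5; the recovery
experiments use 500 / 150 / 2, which reach stable consensus on the
simulated depth-500 data (problem sizes: 20 tumours, 2–10 clones, 4
regions, 30 SNVs per clone).  The cluster with the highest mean CCF is the
major clone; clusters within 0.9× of it are co-labelled major, the rest
sub-clonal.  Known limitation: no beta-binomial overdispersion and no
integration over copy-number genotypes, so clone counts on overdispersed
real data would be inflated.

## Phylogenies

Region trees are UPGMA over the number-of-differences distance (discordant
presence calls, unevaluable cells skipped pairwise).  Merge ties are broken
lexicographically by sorted leaf labels; internally the algorithm tracks
*sums* of leaf-pair distances rather than running averages, so equal
averages compare exactly equal and tie-breaking is deterministic (a running
Lance–Williams average breaks exact ties through floating-point rounding).
Bootstrap support is the percentage of column-resampled replicate trees
containing each clade (default 1,000 replicates, seeded); a matrix with no
discordance is flagged uninformative.  Mutations map onto the unique edge
whose clade equals their presence set; sets matching no clade are flagged
homoplasic (candidate parallel evolution, reversion, or validation noise).
The normal sample is not an outgroup leaf; the trunk (mutations present in
all regions) is reported as the trunk length.  No false-negative rescue
rule is applied to validation calls.

## Verification strategy

Every non-trivial algorithm is checked against an independent route: filter
cascades against a one-expression predicate oracle; segmentation against
exhaustive search; UPGMA against a naive textbook implementation (and
against scipy average linkage on tie-free continuous distances); the
deviation test against its nominal type-I error; purity/ploidy, clone
count, heterogeneity and concordance against simulator ground truth.
`scripts/acceptance.py` re-runs all of these from scratch plus the packaged
cohort-table accounting and writes the numbers as JSON.
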
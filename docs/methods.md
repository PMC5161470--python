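# Methods

## Mutual-information estimation

Genotypes are tri-level (0/1/2 ALT-allele counts) while the metaSNP
consensus is continuous, so association is measured with a soft-binned MI
estimator: each vector is min–max rescaled onto the support of a B-spline
basis (`num_bins` = 4 basis functions of `spline_order` = 2, knot domain
[0, num_bins − order + 1]), and each observation contributes its basis
weights to the bin distribution. Marginal bin probabilities are column means
of the (P × 4) weight profile; the joint distribution of a pair is the
sample mean of the outer products of their profile rows. Entropies are in
bits. Order 2 lets a continuous value be shared by at most two adjacent
bins; order 1 reduces exactly to histogram binning. A constant vector maps
to the domain midpoint and carries zero entropy.

**Normalization.** Soft binning inflates the column-mean entropy: a single
observation spread over two bins adds apparent uncertainty, so for
`x = [0,0,1,1,2,2]` the profile entropy is 1.918 bits while the raw MI of
`x` with itself is 1.585 bits. Dividing raw MI by the column-mean entropies
would therefore give self-similarity < 1 and break the seed initialization
(the seed's own weight must start at 1). We normalize instead by the
*effective* entropy H̃(x) = I_raw(x, x) = 2·H(x) − H(x, x), the entropy the
estimator itself assigns to a perfectly dependent pair:

I(x, y) = I_raw(x, y) / min(H̃(x), H̃(y)),  clamped to [0, 1].

This makes I(x, x) = 1 identically and is provably equal to the plug-in
normalized MI on discrete tri-level data at the default binning, because the
three genotype levels rescale to 0, 1.5 and 3 and their basis profiles
occupy disjoint bin supports — so on genotype-genotype pairs the whole
estimator coincides with the contingency-table plug-in, while continuous
metaSNP arguments get the intended smoothing. At order 1 the definition
degenerates to the familiar I_raw / min(H(x), H(y)). A geometric-mean
denominator (√(H̃x·H̃y)) is available via
`SimilarityConfig(normalization="sqrt")`. Zero-entropy arguments
(monomorphic SNPs, constant consensus vectors) are defined to have
similarity 0: they carry no diversity and must not attract weight. Negative
raw MI from round-off is clamped at 0.

**Missing calls.** The public estimator drops samples missing in either
argument (pairwise-complete) and rescales over the retained subset. The
attractor engine, for speed, bins each variant once over its own non-missing
samples and reuses those cached basis rows on pairwise-complete subsets; the
two differ only when a subset loses every copy of an extreme genotype, which
is negligible at realistic missingness.

## The attractor iteration

From seed *k*, initial weights are w(i) = I(sᵢ, s_k)^α; then the metaSNP
M = Σ w(i)·sᵢ (per sample, renormalized by the summed weight of that
sample's non-missing variants, so missing calls neither contribute nor bias
scale) and the weight update w(i) = I(sᵢ, M)^α alternate. Convergence is
declared when Σᵢ (w_new − w_old)² < ε with ε = 1e-7; a cap of 100
iterations (converged flag false beyond it) guards the rare oscillating
case, which the convergence criterion itself does not exclude. The
iteration is deterministic; identical inputs give bit-identical results.
The seed's weight is recomputed like any other after the first update.

If the seed itself has missing calls, the initial consensus M = s_k is
undefined at those samples (the renormalized average has an empty support
there); the missing entries are filled with the seed's non-missing mean for
that first step only — the minimal completion consistent with the weighted
-average definition.

Exponent semantics: α = 2 (prescreen) keeps weakly linked structure visible;
α = 5 (full runs) pushes everything but the sharpest associations toward
zero. Both are exposed in `AttractorConfig` together with ε, the window
sizes (10,001 main / 101 short), the attractee rule (5th-largest weight
≥ 0.5) and the strength rank (n = 10).

## Scan, degeneracy and deduplication

Running the iteration from all N seeds is wasteful because many seeds are
"attractees" of the same attractor. The two-layer scan first runs a short
(101-SNP window) attractor at α = 2 for every SNP and keeps seeds whose
converged 5th-largest weight reaches 0.5; each survivor then gets a full
10,001-SNP-window run at α = 5. Windows truncate (never wrap) at chromosome
ends, so edge SNPs remain taggable.

Every SNP is trivially a fixed point of the iteration (weight 1 on itself,
≈ 0 elsewhere). Seeds can pass the permissive prescreen by *drifting* into a
nearby block and still collapse to this trivial fixed point in the sharper
full run; kept naively, these single-SNP self-attractors flood the output
with junk tags. An attractor is therefore kept only if its second-largest
weight reaches the attractee bar re-expressed at the run's exponent,
`attractee_threshold^(α/α_prescreen)` (0.5^2.5 ≈ 0.177 at the defaults) —
the same normalized-MI cutoff the prescreen applies, demanding that at
least two variants be mutually associated at that level. No new tuning
constant is introduced.

Attractors are considered equivalent when they select the same tag SNP (the
observable that matters downstream); among equivalents the largest-strength
attractor survives, and output is ordered by tag position. An optional
workload optimization (`coalesce_seeds`, off by default) skips seeds already
inside a found attractor's top-weight set; it leaves results unchanged on
block-structured data.

## Tag selection, strength, ranking

The tag is the attractor's maximum-weight SNP. Weights tied within 1e-9
(absolute — far below meaningful MI differences) are co-top; the co-top SNP
closest to the median of the tied genomic positions wins, an even count
taking the mean of the two central positions and distance ties breaking
toward the smaller coordinate. Strength S is the unnormalized MI in bits
between the SNP with the n-th largest weight (n = 10) and the metaSNP; an
attractor with fewer than n positive weights uses its smallest
positive-weight SNP. Ranking is by descending S, position-ascending on
ties — a deterministic total order.

## Coverage rate

For tag set T, samples are grouped by their genotype pattern at T; within
group *i*, Gᵢ is the largest count of identical full-length sequences, and
R = Σ Gᵢ / P. Refining T can only split groups, so R is monotone
non-decreasing under tag addition, and 1/P ≤ R ≤ 1 on complete data.

With missing calls both pattern identity and sequence identity use
per-comparison exclusion (a missing entry is compatible with anything).
Because wildcard identity is not transitive, grouping is made deterministic:
samples fully observed at T form exact groups first; each remaining sample
joins the largest compatible group (hence a sample missing at every tag
locus joins the largest group) or founds a new one; within a group Gᵢ is the
maximum, over member sequences used as templates, of the number of members
compatible with that template. On complete data this reduces exactly to the
plain definition. A locus missing in every sample behaves as if dropped from
the tag set.

## Synthetic data

The generator plants LD blocks by founder copying: per block, each sample
chromosome draws one founder allele at the block's founder MAF; every SNP in
the block copies that allele with probability `copy_prob` (default 0.95) and
flips it otherwise; background SNPs are i.i.d. at per-SNP MAFs drawn from
(0.05, 0.5). Diploid genotypes sum two independent haplotypes; haplotype
mode emits the binary columns directly. Missing entries are masked i.i.d.
Block founder MAFs in the bundled multi-block builder default to
uniform(0.1, 0.5), the common-variant range tagging panels target. Copy
probability 1 gives within-block r² = 1 exactly; 0.95 leaves pairwise
genotype correlation ≈ (1 − 2·0.05)² ≈ 0.81, i.e. clearly linked but well
short of perfect.

This emulates what the algorithm needs for validation — controllable block
membership truth — and deliberately not population-genetic realism: no
coalescent genealogy, no recombination map, no allele-frequency spectrum,
no population structure, and blocks have hard edges with mutually
independent background. Passing the planted-block tests shows the scan
recovers known high-LD clusters under calibrated noise; it does not certify
behavior on real LD landscapes with nested or overlapping block structure.

Validation scale: the planted-block acceptance test uses 20 replicates of
20 blocks (8–50 SNPs each) in 2,000 SNPs × 100 samples — large enough that
the full 101-SNP prescreen windows and multi-block deduplication are
exercised while a replicate scan stays in the tens of seconds on one core.

## Numerical choices and degenerate inputs

- Convergence uses the squared Euclidean norm as printed, not its root.
- Rescaled values are clipped to the spline support to absorb round-off.
- Monomorphic seeds raise a degenerate-seed error (all similarities 0);
  weight collapse mid-iteration raises a degenerate-attractor error; the
  scan logs and skips both.
- A sample with no genotyped SNP under positive weight makes the metaSNP
  undefined and is an error rather than silently imputed.
- Stable sorts everywhere ties appear, so output is permutation-invariant
  and byte-reproducible.

## Known limitations

- **Allele-coding orientation.** Normalized MI is invariant to recoding
  (I(s, 2−s) = 1) but the metaSNP average is not: perfectly anti-phased SNPs
  cancel, in the extreme to an exactly constant consensus that collapses the
  attractor. The bundled 4-locus coverage illustration contains such a
  complementary pair and yields no tags under scan — the coverage metric,
  not the scan, is the point of that fixture. Real blocks with mixed ALT
  orientations will have their weights attenuated; harmonizing orientation
  before scanning is the practical workaround.
- Blocks with fewer members than the attractee rank (5) are invisible to
  the prescreen by design.
- Low-frequency blocks (founder MAF ≪ 0.1) carry little entropy and may
  fall below the degeneracy bar at α = 5.
- One chromosome per matrix; no trans-LD discovery.
- The MI estimator is the plug-in kind: positively biased at small P. The
  bias cancels in relative comparisons the algorithm makes but inflates
  absolute strengths for small samples.
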
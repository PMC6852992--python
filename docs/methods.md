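# Methods

This note documents the models, parameter choices and numerical details
behind triokit, and what the synthetic-data validation does and does not
establish about behaviour on real genomes.

## De novo SNV/indel model

A de novo mutation (DNM) is an offspring variant absent from both
parental germlines. The detector is a deterministic five-criterion
cascade over biallelic autosomal sites (multiallelic VCF records are
split per alternative allele first; alleles of a different alt count as
reference in the split record):

| criterion | condition | default |
|---|---|---|
| i | locus outside all exclusion masks | user-supplied BEDs |
| ii | offspring DP within bounds and AB within bounds | DP ∈ [10, 120], AB ∈ [0.3, 0.7] |
| iii | GQ at or above threshold in all three members | GQ ≥ 50 |
| iv | no alt-supporting read in either parent | exact zero |
| v | parents homref, offspring het or homalt | — |

Allele balance is `ad_alt / (ad_ref + ad_alt)` with closed (inclusive)
bounds; with zero informative reads it is undefined and criterion ii
fails. Depth comes from the call's DP field when present, else from
`ad_ref + ad_alt` (caller dialects differ; the explicit precedence keeps
the filters deterministic). Criterion v is evaluated first as the
candidate-pattern gate when assigning a rejection reason — a homref
offspring is reported as failing v, not as having a bad allele balance —
while the audit record keeps every criterion's outcome. Indels use the
same cascade as SNVs. Sex chromosomes are excluded throughout.

## Callability and the mutation rate

The per-family rate divides the DNM count by an effective number of
haploid site-generations rather than a raw site count:

    mu_k = n_DNM(k) / (2 * sum_s C_k(s))

C_k(s) is modelled as the product of (a) the indicator that the site is
unmasked, all three members' depths lie in [10, 120], all genotype
qualities reach 50, and both parents show zero alt reads, and (b) the
exact Binomial(d, 1/2) probability that a true heterozygote at the
offspring's observed depth d yields an allele balance inside the closed
band — the band [ceil(0.3 d), floor(0.7 d)] evaluated with a 1e-9 slack
against float rounding (at d = 10 the band is 3..7 alt reads,
probability 912/1024 = 0.890625). This makes numerator and denominator
conditions exactly congruent, which is what makes the estimator
calibrated: every stochastic filter that can remove a true DNM is
accounted for with its actual probability.

Monotonicity of C_k in depth is *not* claimed — binomial band widths
oscillate with the integer cutoffs — but C_k ∈ [0, 1] always holds.
Rates are reported per analysed site per generation, separately per
variant type; the denominator for each type sums callability over that
type's sites.

## CNV pipeline

Calls are deletions (CN < 2) or duplications (CN > 2) strictly longer
than 100 bp (shorter events are indel territory and dropped at load).
The two-caller merge keeps a call iff the other caller has a same-type
call at ≥ 50% reciprocal overlap — reciprocal meaning the shared span
reaches the threshold as a fraction of *both* lengths — and the mask
filters pass: any single-base overlap with repeat/low-complexity
intervals removes a call, while gap/segmental-duplication intervals
remove it only at ≥ 50% union coverage. Concordant pairs are emitted
once with the caller-A breakpoints (`--prefer-caller`; the choice of
representative is arbitrary and documented rather than inferred).

De novo CNV detection proceeds in three steps: (1) drop offspring calls
matched by a same-type parental call at ≥ 50% reciprocal overlap;
(2) re-genotype the interval in both parents from windowed depth —
CN = round(2 · mean depth in interval / autosomal mean) — and drop calls
where a parental CN is consistent with the offspring's type (CN < 2 for
DEL, CN > 2 for DUP); (3) emit survivors with a per-call evidence report
(parental CNs and depth ratios) mirroring a manual review step. Missing
depth profiles skip step 2 with the call marked `unverified`. The
windowed depth-ratio re-genotyper replaces the original caller's
genotyping model, whose internals are out of scope here.

Novelty against a CNV database uses the same 50% reciprocal-overlap
rule; database records of any type can match by default
(`match_svtype` restricts to same-type). The de novo CNV rate is
de novo / total calls in the offspring, reported both exactly and
rounded to one significant digit. Sharing classes are assigned with MLS
(≥ 1 Orang Asli and ≥ 1 North Bornean trio) taking precedence over OA
(all of BTQ, MDQ, SMI), then NGO (BTQ and MDQ), NB (DSN and MRT),
private (exactly one trio), other. Cross-trio regions come from
single-linkage clustering of same-type calls at ≥ 50% reciprocal
overlap, represented by the longest member.

## Summaries

Heterozygosity proportion is het / (het + homalt) per sample and type.
Ti/Tv counts A↔G and C↔T as transitions. Novelty is exact
(chrom, pos, ref, alt) absence from a known-variant table; no fuzzy
matching. The hotspot scan tiles each chromosome in 1 Mb windows from
position 0 (a final partial window is kept only at ≥ 0.5 Mb), drops
windows overlapping telomere/centromere intervals padded by 1 Mb, counts
genotype observations passing GQ ≥ 50, DP ∈ [10, 120], AB ∈ [0.3, 0.7]
pooled across samples (`--per-sample` available), and returns the top
ceil(1%) of windows extended through ties at the cutoff count — ceiling
plus tie-extension keeps the result deterministic and order-independent.
SNVs and indels are scanned separately.

Novel-insertion (NI) classification is pure set logic over presence
flags: inherited means present in the offspring and ≥ 1 parent;
archaic categories from (Neanderthal, Denisovan) presence are
specific-to-one, specific-to-the-other, or shared-with-both, with
archaic-like their union — so archaic-like always equals the sum of the
three subcategories. Contig assembly and archaic-genome alignment that
would produce such flags are out of scope; the package consumes a
presence table.

## Trio phasing

Pre-phasing removes sites with missing-genotype fraction > 10% across
all samples or Mendelian errors in ≥ 2 trios (a single-trio error may be
a genuine DNM; a recurrent one is almost certainly artefactual). Every
Mendelian-consistent site that is not heterozygous in all three members
then phases deterministically: homozygous children trivially, a
heterozygous child whenever at least one parent is homozygous (the
homozygous parent's transmitted allele is forced). Output order is
`paternal|maternal` — a documented convention, not an inference. The
triple-heterozygous residue is emitted unphased with a count in the
report; resolving it requires a population haplotype-frequency model,
which is deliberately outside this package. CNV "phasing" reduces to the
same transmission logic on presence/absence.

## Synthetic data generator

The generator emulates the study conditions: five trios (BTQ, MDQ, SMI,
DSN, MRT), mean depth 30× (Poisson, truncated below at 1), biallelic
polymorphic sites with allele frequencies uniform on [0.05, 0.95],
Hardy–Weinberg parents, Mendelian transmission, and DNMs planted on
transmitted reference alleles at a configurable per-allele rate.
Read counts are Binomial(DP, p) with p = ½ for heterozygotes and
p = error_rate (default 0.001, a typical alt-supporting error level) on
homozygous backgrounds. GQ is a monotone depth surrogate,
min(99, round(3.3·DP)) floored at 20 below depth 8; tests depend only on
its threshold crossings (GQ ≥ 50 at DP ≥ 15), not its shape. Transitions
are drawn at 2.1/3.1 of SNVs so the simulated Ti/Tv sits at the
genome-wide ~2.1.

The default panel (10⁶ sites on a 100 Mb pseudo-autosome) is a
scaled-down stand-in for the callable autosome. Per-site DNM rates are
scaled up accordingly (defaults 2×10⁻⁴ SNV, 1.5×10⁻⁴ indel per
transmitted allele) so that per-offspring event counts — the observable
the filters see — are study-like (tens of SNV DNMs); the estimator is
validated against whatever rate was planted, not against the human
per-base rate. With frequencies uniform on [0.05, 0.95] the expected
planted count is n_sites × rate (half of transmissions carry the
reference allele), and both parents are homozygous reference at ≈ 17.2%
of sites, which sets the detectable fraction.

CNVs segregate at non-overlapping population loci (frequency
U(0.05, 0.5)), transmit by Mendelian rules on presence, and de novo CNVs
are offspring-only deletions (matching the observation that de novo
events in this size range are overwhelmingly deletions). Two
pseudo-callers observe every true event minus dropout (default 5%) with
breakpoint jitter proportional to length (default 5%). Simulated CNV
lengths are log-uniform on [2, 50] kb: the 2 kb floor guarantees that
the 1 kb depth windows — whose values scale exactly with the
within-window copy-number fraction — resolve a single-copy change after
rounding, so depth re-genotyping is exact on clean data. Auxiliary
tables (known-variant set at 2.7%/2.3% novelty, NI presence tables with
the study's archaic-sharing proportions) are generated alongside.

What the generator does not model: linkage disequilibrium,
recombination, genotype-calling errors (genotypes are truth-derived;
only reads and qualities are noisy), mosaicism, indel length spectra,
multi-allelic CNV loci, and reference biases. Passing tests therefore
demonstrate correctness of the filtering/estimation logic under the
stated noise model, not robustness to every artefact of real pipelines —
the mask mechanism exists precisely because real data need externally
curated exclusion regions.

## Numerical and implementation choices

- Sampling at panel scale uses the Vose alias method over the
  numerically complete supports of Poisson(30) and Binomial(d, p)
  (exact to float64 pmf normalisation), and the SFC64 bit generator;
  streams are fully determined by the seed and verified byte-identical
  across reruns. Chi-square checks against the closed-form distributions
  guard the samplers.
- Coordinates: VCF positions are 1-based; all internal interval algebra
  and BED I/O are 0-based half-open. Masks are stored as merged sorted
  arrays, so coverage queries are exact union arithmetic.
- Allele-balance band edges use a 1e-9 slack when mapping fractional
  bounds to integer read counts, making the inclusive bounds exact for
  every depth.
- The rate-recovery validation runs 5 trios × 10⁷ sites × 20 seeds
  (~10 minutes on one CPU) with a planted rate of 10⁻⁶ — large enough
  for ≈ 15 detectable events per panel, small enough to keep the suite
  practical; the pooled estimate's seed-to-seed spread gives the
  standard error against which calibration is judged (observed
  z ≈ 0.25).
- The demonstration pipeline and the reproduction script use smaller
  panels (1.2×10⁴–2×10⁵ sites) chosen so the object-level (per-site,
  audited) code path is exercised end to end; the vectorised path used
  for large panels is cross-checked against it site by site in the test
  suite.

## Known limitations

- Callability uses the offspring's *observed* depth at each site as the
  depth a hypothetical DNM would have seen; at sites where the offspring
  carries a real variant this conflates two coverage distributions, a
  second-order effect at 30×.
- Parental-age effects on DNM rates are not modelled (no age data).
- CNV breakpoint precision is whatever the input callers provide; the
  merge keeps caller-A breakpoints rather than refining them.
- The de novo CNV re-genotyper assumes depth scales linearly with copy
  number; heavily GC-biased or repeat-dense intervals violate this, which
  is why masked regions are filtered before it runs.
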
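# Methods

This note documents the models behind `denovopop`, the choices made where
the design was genuinely open, and what the validation suite does and does
not establish.

## Genotype-calling model

Reads covering one site in one individual are modeled as independent
multinomial draws over (A, C, G, T). With per-read-base error rate ε,

* homozygote XX: P(read = b) = 1 − ε if b = X, else ε/3;
* heterozygote XY: P(read = b) = (1 − 2ε/3)/2 if b ∈ {X, Y}, else ε/3.

The genotype space is the 10 unordered base pairs; the 16 ordered
genotypes collapse onto these because XY and YX have identical
likelihoods and their Hardy–Weinberg priors add. The multinomial
coefficient is omitted everywhere — it is constant across genotypes and
cancels in posteriors (a property the tests verify explicitly).

ε is shared across the sites of a contig and estimated by maximum
likelihood with per-site allele frequencies profiled out:

1. given ε, per-site frequency vectors f maximize
   ∏ᵢ Σ_g HWE(g|f) · L(reads_i | g, ε) by EM over individuals with
   coverage (dosage-weighted posterior counts, normalized);
2. given the frequencies, ε is maximized by bounded scalar search on
   [10⁻⁸, 0.2] (`scipy.optimize.minimize_scalar`);
3. alternate until the log-likelihood gain is < 10⁻⁶ (≤ 200 rounds).

A contig with no mismatching reads drives ε̂ to the 0 boundary, which is
reported as exactly 0. The upper bound 0.2 is far above any plausible
per-base error and only prevents pathological fits on tiny contigs.

Calling: posterior(g) ∝ f-based HWE prior × likelihood, normalized over
the 10 genotypes. Threshold mode (default) calls argmax if ≥ 0.95, else
missing; exact posterior ties are missing. Sample mode draws one genotype
from the posterior (threshold-free control); all randomness flows from a
single seed. Coverage below `min_coverage` (10; 30 in the high-coverage
control) is missing in both modes. The coverage boundary is read as
"< 10 ⇒ missing" and is configurable, since "at least 10" vs "more than
10" is ambiguous in common usage.

## Hidden-paralogy likelihood-ratio test

Only the two SNP alleles a₁, a₂ enter the test; reads of other bases are
excluded from (kᵢ, Nᵢ) — the genotyper's error channel accounts for them
— and their count is kept for QC. The allele-1 read count is
beta-binomial, kᵢ ~ BetaBin(Nᵢ, m, ρ), parameterized by mean m and
overdispersion ρ (shapes α = m(1−ρ)/ρ, β = (1−m)(1−ρ)/ρ; ρ → 0 is
binomial). ρ absorbs allele-specific expression bias and amplification
stochasticity.

For a genotype configuration whose allele-1 dosage fraction is y, the
expected allele-1 read fraction is m = y(1 − 2ε′) + ε′ with ε′ = ε/3 —
the first-order within-pair error channel consistent with the genotyper
(homozygote mean 1 − ε/3, heterozygote exactly 1/2).

* One-locus model (2 free parameters f, ρ): genotypes at HWE(f) over
  dosages {2, 1, 0}.
* Two-locus model (4 free parameters p, f₁, f₂, ρ): each individual
  carries both loci; locus 1 contributes a fixed proportion p of reads,
  shared across individuals; y = p·x₁/2 + (1−p)·x₂/2 over the 9
  per-locus genotype pairs, each at HWE of its own frequency. A collapse
  therefore predicts both an excess of apparent heterozygotes and
  *correlated* read-count asymmetry across individuals — which is what
  separates it from expression bias (absorbed by ρ, shared by both
  models).

Fitting is deterministic: a coarse grid (p ∈ {0.1..0.9},
f ∈ {0, 0.25, 0.5, 0.75, 1}, ρ ∈ {10⁻⁴, 0.05, 0.2}, fully vectorized)
followed by L-BFGS-B refinement (≤ 30 iterations) from the grid optimum
and from a nested start at p → 1 reproducing the one-locus optimum, so
logL₁ ≥ logL₀ always holds up to tolerance. λ = 2(logL₁ − logL₀) is
referred to χ² with df = 2 (the added p and second frequency). The
mixture/boundary geometry makes this reference conservative — simulated
genuine heterozygous sites reject at well below the nominal 0.001 — so
the realized filter is slightly gentler than its nominal level, and the
power figures in the tests are the honest operating characteristics.
Sites without a called heterozygote are not tested and are retained.

## Coding-sequence statistics

Unphased diploid calls are expanded into two pseudo-haplotypes per
individual. This is valid because every statistic computed here is a
function of per-site genotype counts, never of phase.

Cleaning order is fixed and order-dependent: (1) drop codon sites with
> 50% missing states (exactly 50% is kept), (2) drop focal haplotypes
with > 50% missing over the remaining sites, (3) drop alignments with
< 10 codon sites; outgroup analyses additionally require an ORF > 100
codons. Statistics use complete, biallelic sites only (no missing state,
≤ 2 bases).

Synonymous/non-synonymous site counting is Nei–Gojobori-style on the
consensus codon: each position contributes a synonymous weight equal to
the fraction of its non-stop single-base changes that preserve the amino
acid; L_N = 3·codons − L_S. The scheme is isolated behind one function
so a per-allele-averaging alternative can be swapped in.

Per-site diversity at a biallelic site with haplotype counts (n₁, n₂) is
n₁n₂/C(n,2); π_S = Σ site-π over synonymous SNPs / L_S (π_N analogous).
F_IS = 1 − ΣHobs/ΣHexp across SNPs (ratio of sums, robust to tiny-Hexp
sites) with the plug-in Hexp = 2p̂q̂. The plug-in is biased low by
(2n−1)/2n, so under exact HWE the default statistic centers on −1/(2n−1)
≈ −0.05 at n = 10 rather than 0; `corrected=True` applies Nei's
2n/(2n−1) factor and recenters it. The default stays plug-in so the
boundary fixtures (all-het → −1, all-hom → +1) are exact.

Fixed differences require focal monomorphism at a complete site and a
differing non-missing outgroup base; d_N, d_S are uncorrected counts per
L_N, L_S site (close outgroups assumed). Contigs with dS at least two
sample standard deviations above the median are dropped as dubious
orthology (skipped when all dS are equal or fewer than three are
available). Species-level means weight each contig by its analyzed site
count of the relevant class (L_S for π_S), which gives every SNP equal
weight; NI and derived quantities use counts summed across contigs,
(Σp_N/Σp_S)/(Σd_N/Σd_S) — averaging per-contig ratios instead is known
to bias such estimates downward and is available but not default.
Confidence intervals are percentile bootstrap over contigs, seeded.

## Site-frequency spectra

A SNP observed at minor count i among m non-missing haplotypes
contributes hypergeometric mass C(i,j)C(m−i,n−j)/C(m,n) to subsample
count j at the fixed projection size n = 12; SNPs with m < n are
discarded, mass on classes 0 and n is dropped without renormalization
(the SNP partially leaves the subsample), and classes j, n−j fold to
min(j, n−j). Tajima's D uses the standard constants with S the total
(possibly fractional) projected mass and θ_π from the folded masses via
the k(n−k) symmetry; on ξ_k ∝ 1/k it is exactly 0 for every n, which the
suite checks across n = 4..20.

## Simulator: what it emulates, and what a green test establishes

The generator draws, per contig: a random stop-free coding sequence; SNP
positions at rate θ·a₁ per site with derived counts k ∝ 1/k on the 2I
sampled haplotypes (placed exactly when F_IS = 0; drawn from inbred HWE
proportions otherwise — exact-count placement cannot represent
within-individual allele correlation); Poisson coverage with optionally
unequal per-individual means; beta-binomial(½, ρ) allele splits in
heterozygotes; and a uniform ε error channel per read base. Paralog
contigs carry one collapsed fixed-difference site mixing at a shared p.
PCR duplicates are geometric — a stress model for the collapsing filter,
not a claim about library chemistry.

Because the generator matches the calling model's assumptions, green
recovery tests establish *internal consistency* (the estimators recover
the parameters of their own model at realistic sizes) — not robustness
to what the generator omits: linkage, indels, alternative splicing,
mapping bias, base-quality structure, coverage autocorrelation along
contigs, or more than two collapsed copies.

Two interactions of the stated scenarios with the paper-style filters
are worth knowing:

* At 10X mean coverage with `min_coverage = 10`, roughly half of all
  per-individual genotypes are missing, so the 50%-missing cleaning and
  the complete-sites rule leave essentially no analyzable codon sites.
  Error-rate, genotype and F_IS recovery are therefore validated at 10X,
  while diversity recovery (π_S within 10% of θ) is validated on the
  30X scenario.
* π_S recovers θ to ≈ −5% at 30X: ~2% because SNPs at non-complete
  sites are dropped while their codons still count in L_S, ~3% because
  simulated stop-creating mutations are EXCLUDED from classification
  while the site-count denominator reweights by valid changes. Both are
  consequences of the published filtering conventions, not estimator
  defects.

## Numerical choices

* Frequency EM: convergence at max|Δf| < 10⁻¹⁰, ≤ 500 iterations,
  initialized from pooled read proportions; zero-coverage sites get
  uniform frequencies flagged uninformative.
* Beta-binomial log-pmf: explicit gammaln/betaln expression (validated
  against `scipy.stats.betabinom`), binomial branch below ρ = 10⁻⁹,
  degenerate means m ∈ {0, 1} return log 0/1 rather than raising.
* Projection weights via `scipy.stats.hypergeom.pmf` (log-space gamma
  internally, stable for large m).
* Ties: argmax posterior ties → missing call; equal-length ORFs →
  leftmost start; SNP allele order by descending count then base.
* Determinism: one seed in the pipeline config feeds genotype sampling
  and the bootstrap; simulator seeds are mandatory.

## Known limitations

Single-contig error rate assumed constant across sites; no indel or
base-quality handling; at most two collapsed copies modeled; no
multiple-hit correction on divergence; ORF finder is a longest-ORF
heuristic (no hexamer scoring); outgroup sequences must be pre-aligned
to contig coordinates.
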
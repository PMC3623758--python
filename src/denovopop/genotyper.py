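"""Maximum-likelihood genotype calling from mapped read counts.

The model treats the reads covering one site in one individual as draws from
a multinomial over (A, C, G, T) whose cell probabilities depend on the
individual's diploid genotype and on a sequencing/mapping error rate
``epsilon`` shared across all sites of a contig:

* homozygote XX:  P(read b) = 1 - eps if b = X, else eps/3
* heterozygote XY: P(read b) = (1 - 2 eps/3)/2 if b in {X, Y}, else eps/3

Per contig, ``epsilon`` is estimated by maximum likelihood with per-site
allele frequencies profiled out (alternating maximization: per-site
frequency EM given epsilon, then bounded 1-D optimization of epsilon given
frequencies).  Genotype posteriors combine the read likelihood with a
Hardy-Weinberg prior built from the site's estimated allele frequencies:
prior(XX) = f_X^2, prior(XY) = 2 f_X f_Y.  The genotype space is the 10
unordered base pairs (the 16 ordered genotypes collapse onto these after
merging XY/YX, which have identical likelihood and summed prior).

In the default threshold mode a genotype is called when the best posterior
reaches the threshold (0.95), otherwise the position is coded missing; in
sample mode one genotype is drawn from the posterior (threshold-free
calling).  Positions with fewer than ``min_coverage`` reads (10 by default,
30 in the high-coverage control) are missing regardless.  Base qualities
are deliberately unused: the error rate is estimated from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .counts import BASES, ContigCountMatrix

# The 10 unordered genotypes in lexicographic order.
GENOTYPE_PAIRS: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (0, 2), (0, 3),
    (1, 1), (1, 2), (1, 3),
    (2, 2), (2, 3),
    (3, 3),
)
GENOTYPE_NAMES = tuple(BASES[x] + BASES[y] for x, y in GENOTYPE_PAIRS)
_HOM = np.array([x == y for x, y in GENOTYPE_PAIRS])

# Allele dosage per genotype: DOSAGE[g, b] = copies of base b in genotype g.
DOSAGE = np.zeros((10, 4))
for _g, (_x, _y) in enumerate(GENOTYPE_PAIRS):
    DOSAGE[_g, _x] += 1
    DOSAGE[_g, _y] += 1

EPS_UPPER = 0.2  # search bound for the per-contig error rate


@dataclass
class ErrorModel:
    contig_id: str
    epsilon: float
    log_likelihood: float


@dataclass
class SiteAlleleFrequencies:
    contig_id: str
    site: int
    freqs: np.ndarray  # 4-vector over A,C,G,T
    informative: bool = True


@dataclass
class GenotypeCall:
    site: int
    individual: str
    genotype: tuple[int, int] | None  # base indices, None = MISSING
    best_posterior: float
    coverage: int


@dataclass
class CallerConfig:
    posterior_threshold: float = 0.95
    min_coverage: int = 10
    mode: str = "threshold"  # "threshold" | "sample"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 < self.posterior_threshold <= 1.0):
            raise ValueError("posterior_threshold must be in (0.5, 1]")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.mode not in ("threshold", "sample"):
            raise ValueError(f"unknown calling mode {self.mode!r}")


def base_log_probs(epsilon: float) -> np.ndarray:
    """10 x 4 matrix of log P(read base | genotype) at error rate epsilon."""
    if not (0.0 <= epsilon < 0.75):
        raise ValueError(f"epsilon {epsilon} outside [0, 0.75)")
    probs = np.full((10, 4), epsilon / 3.0)
    for g, (x, y) in enumerate(GENOTYPE_PAIRS):
        if x == y:
            probs[g, x] = 1.0 - epsilon
        else:
            probs[g, x] = probs[g, y] = (1.0 - 2.0 * epsilon / 3.0) / 2.0
    with np.errstate(divide="ignore"):
        return np.log(probs)


def genotype_log_likelihoods(counts4: np.ndarray, epsilon: float) -> np.ndarray:
    """Log-likelihood of each of the 10 genotypes given one site/individual's
    base counts.  The multinomial coefficient is omitted (constant across
    genotypes, cancels in posteriors).  Zero coverage gives equal values."""
    counts4 = np.asarray(counts4, dtype=float)
    if (counts4 < 0).any():
        raise ValueError("negative base count")
    logp = base_log_probs(epsilon)
    # 0 * -inf := 0 so that eps = 0 stays well-defined
    with np.errstate(invalid="ignore"):
        terms = np.where(counts4 > 0, logp * counts4, 0.0)
    return terms.sum(axis=1)


def _loglik_tensor(counts: np.ndarray, epsilon: float) -> np.ndarray:
    """(sites, individuals, 10) genotype log-likelihoods for a whole contig."""
    logp = base_log_probs(epsilon)  # (10, 4)
    finite = np.where(np.isfinite(logp), logp, 0.0)
    ll = counts @ finite.T  # (S, I, 10)
    if not np.isfinite(logp).all():
        # eps == 0: genotypes with any count on a zero-probability base get -inf
        impossible = (counts[:, :, None, :] > 0) & ~np.isfinite(logp)[None, None]
        ll[impossible.any(axis=3)] = -np.inf
    return ll


def _hwe_log_priors(freqs: np.ndarray) -> np.ndarray:
    """(sites, 10) log HWE priors from per-site frequencies (sites, 4)."""
    f1 = freqs[:, [x for x, _ in GENOTYPE_PAIRS]]
    f2 = freqs[:, [y for _, y in GENOTYPE_PAIRS]]
    prior = np.where(_HOM[None, :], f1 * f2, 2.0 * f1 * f2)
    with np.errstate(divide="ignore"):
        return np.log(prior)


def _site_freq_em(
    counts: np.ndarray,
    epsilon: float,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """EM for per-site allele frequencies on a (S, I, 4) count block.

    Returns (freqs (S,4), informative (S,) bool).  Individuals with zero
    coverage at a site are excluded from that site's E-step.  Sites with no
    coverage at all get uniform frequencies flagged uninformative.
    """
    S, I, _ = counts.shape
    ll = _loglik_tensor(counts, epsilon)  # (S, I, 10)
    covered = counts.sum(axis=2) > 0  # (S, I)
    n_cov = covered.sum(axis=1)  # (S,)
    informative = n_cov > 0

    totals = counts.sum(axis=1) + 1e-9  # (S, 4) pooled, pseudocount
    freqs = totals / totals.sum(axis=1, keepdims=True)

    active = informative.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        logprior = _hwe_log_priors(freqs[active])  # (s, 10)
        logpost = logprior[:, None, :] + ll[active]  # (s, I, 10)
        logpost -= logsumexp(logpost, axis=2, keepdims=True)
        w = np.exp(logpost)
        w = np.where(covered[active][:, :, None], w, 0.0)
        new = (w.sum(axis=1) @ DOSAGE) / (2.0 * n_cov[active][:, None])
        new /= new.sum(axis=1, keepdims=True)
        delta = np.abs(new - freqs[active]).max(axis=1)
        freqs[active] = new
        still = delta >= tol
        idx = np.flatnonzero(active)
        active[idx[~still]] = False

    freqs[~informative] = 0.25
    return freqs, informative


def _contig_loglik(counts: np.ndarray, freqs: np.ndarray, epsilon: float) -> float:
    """Total log-likelihood of a contig given per-site frequencies."""
    ll = _loglik_tensor(counts, epsilon)
    logprior = _hwe_log_priors(freqs)
    per = logsumexp(logprior[:, None, :] + ll, axis=2)  # (S, I)
    covered = counts.sum(axis=2) > 0
    return float(np.where(covered, per, 0.0).sum())


def estimate_site_frequencies(
    site_counts: np.ndarray, epsilon: float, contig_id: str = "", site: int = 0
) -> SiteAlleleFrequencies:
    """ML allele frequencies at one site (individuals x 4 counts) by EM."""
    counts = np.asarray(site_counts, dtype=float)[None]
    freqs, informative = _site_freq_em(counts, epsilon)
    return SiteAlleleFrequencies(contig_id, site, freqs[0], bool(informative[0]))


def estimate_error_rate(
    matrix: ContigCountMatrix,
    tol: float = 1e-6,
    max_outer: int = 200,
) -> tuple[ErrorModel, np.ndarray]:
    """Per-contig ML error rate with frequencies profiled out.

    Alternates (i) per-site frequency EM given epsilon and (ii) bounded 1-D
    maximization of epsilon given frequencies, until the log-likelihood gain
    drops below ``tol``.  Returns the fitted model and the final per-site
    frequencies (sites x 4).
    """
    counts = np.asarray(matrix.counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError(f"contig {matrix.contig_id} has no informative sites")

    epsilon = 0.005
    freqs, _ = _site_freq_em(counts, epsilon)
    last = _contig_loglik(counts, freqs, epsilon)
    for _ in range(max_outer):
        res = minimize_scalar(
            lambda e: -_contig_loglik(counts, freqs, e),
            bounds=(1e-8, EPS_UPPER),
            method="bounded",
            options={"xatol": 1e-9},
        )
        epsilon = float(res.x)
        freqs, _ = _site_freq_em(counts, epsilon)
        cur = _contig_loglik(counts, freqs, epsilon)
        if cur - last < tol:
            last = max(cur, last)
            break
        last = cur
    # snap the boundary: no mismatching reads means a zero error rate
    if epsilon < 2e-8:
        at_zero = _contig_loglik(counts, freqs, 0.0)
        if at_zero >= last - tol:
            epsilon, last = 0.0, at_zero
    return ErrorModel(matrix.contig_id, epsilon, last), freqs


def genotype_posteriors(
    counts: np.ndarray, freqs: np.ndarray, epsilon: float
) -> np.ndarray:
    """(sites, individuals, 10) genotype posteriors: HWE prior x likelihood,
    normalized over the 10 unordered genotypes."""
    ll = _loglik_tensor(np.asarray(counts, dtype=float), epsilon)
    logpost = _hwe_log_priors(freqs)[:, None, :] + ll
    logpost -= logsumexp(logpost, axis=2, keepdims=True)
    return np.exp(logpost)


def call_genotypes(
    matrix: ContigCountMatrix,
    error_model: ErrorModel,
    freqs: np.ndarray,
    config: CallerConfig | None = None,
) -> list[GenotypeCall]:
    """Call one genotype (or MISSING) per site and individual.

    threshold mode: argmax posterior if >= threshold, else MISSING; exact
    posterior ties are MISSING.  sample mode: draw from the posterior with
    the seeded generator.  Coverage below ``min_coverage`` is MISSING in
    both modes.
    """
    config = config or CallerConfig()
    post = genotype_posteriors(matrix.counts, freqs, error_model.epsilon)
    coverage = matrix.coverage
    S, I = coverage.shape
    rng = np.random.default_rng(config.rng_seed)

    calls = []
    if config.mode == "sample":
        u = rng.random((S, I))
        cum = np.cumsum(post, axis=2)
        drawn = (u[:, :, None] > cum).sum(axis=2)

    best = post.argmax(axis=2)
    best_p = post.max(axis=2)
    # a tie for the argmax leaves the call undecidable in threshold mode
    tied = (np.isclose(post, best_p[:, :, None], rtol=0.0, atol=0.0)).sum(axis=2) > 1

    for s in range(S):
        for i in range(I):
            cov = int(coverage[s, i])
            bp = float(best_p[s, i])
            if cov < config.min_coverage:
                g = None
            elif config.mode == "sample":
                g = GENOTYPE_PAIRS[int(drawn[s, i])]
            elif bp >= config.posterior_threshold and not tied[s, i]:
                g = GENOTYPE_PAIRS[int(best[s, i])]
            else:
                g = None
            calls.append(GenotypeCall(s, matrix.individuals[i], g, bp, cov))
    return calls


@dataclass
class SNPRecord:
    """A polymorphic site among called genotypes."""

    contig_id: str
    site: int
    alleles: tuple[int, ...]  # base indices, major allele order by count
    genotypes: dict[str, tuple[int, int] | None]
    n_missing: int
    multiallelic: bool = False
    maf: float = 0.0
    synonymy: str | None = None  # "SYN" | "NONSYN" | "EXCLUDED" | None
    paralog_flag: bool = False
    paralog_p: float | None = None

    @property
    def n_called(self) -> int:
        return sum(1 for g in self.genotypes.values() if g is not None)

    def allele_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for g in self.genotypes.values():
            if g is not None:
                for a in g:
                    counts[a] = counts.get(a, 0) + 1
        return counts


def identify_snps(
    calls: list[GenotypeCall], contig_id: str
) -> list[SNPRecord]:
    """Aggregate genotype calls into SNP records: a site is a SNP when at
    least two distinct alleles appear among non-missing genotypes.  Sites
    with more than two alleles are flagged multi-allelic (excluded from
    downstream statistics)."""
    by_site: dict[int, dict[str, tuple[int, int] | None]] = {}
    for c in calls:
        by_site.setdefault(c.site, {})[c.individual] = c.genotype

    snps = []
    for site in sorted(by_site):
        genotypes = by_site[site]
        counts: dict[int, int] = {}
        for g in genotypes.values():
            if g is not None:
                for a in g:
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) < 2:
            continue
        alleles = tuple(sorted(counts, key=lambda a: (-counts[a], a)))
        n_missing = sum(1 for g in genotypes.values() if g is None)
        total = sum(counts.values())
        maf = min(counts.values()) / total if len(counts) == 2 else 0.0
        snps.append(
            SNPRecord(
                contig_id=contig_id,
                site=site,
                alleles=alleles,
                genotypes=dict(genotypes),
                n_missing=n_missing,
                multiallelic=len(counts) > 2,
                maf=maf,
            )
        )
    return snps


def write_vcf(
    snps: list[SNPRecord],
    error_models: dict[str, ErrorModel],
    contig_lengths: dict[str, int],
    path,
) -> None:
    """Minimal VCF 4.2 with GT:DP-free genotype fields (GT only), 1-based
    positions, per-record EPS (contig error rate) and AF in INFO, and the
    ``paralog`` FILTER for sites failing the paralogy test."""
    inds: list[str] = []
    for snp in snps:
        for ind in snp.genotypes:
            if ind not in inds:
                inds.append(ind)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=denovopop\n")
        for cid, length in contig_lengths.items():
            fh.write(f"##contig=<ID={cid},length={length}>\n")
        fh.write('##INFO=<ID=EPS,Number=1,Type=Float,Description="Contig error rate">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">\n')
        fh.write('##FILTER=<ID=paralog,Description="Paralogy likelihood-ratio test p < alpha">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(inds) + "\n")
        for snp in sorted(snps, key=lambda s: (s.contig_id, s.site)):
            ref = snp.alleles[0]
            alts = list(snp.alleles[1:])
            counts = snp.allele_counts()
            total = sum(counts.values())
            afs = ",".join(f"{counts[a] / total:.4g}" for a in alts)
            eps = error_models[snp.contig_id].epsilon if snp.contig_id in error_models else 0.0
            filt = "paralog" if snp.paralog_flag else "PASS"
            allele_idx = {a: i for i, a in enumerate(snp.alleles)}
            gts = []
            for ind in inds:
                g = snp.genotypes.get(ind)
                if g is None:
                    gts.append("./.")
                else:
                    i1, i2 = sorted(allele_idx[a] for a in g)
                    gts.append(f"{i1}/{i2}")
            fh.write(
                f"{snp.contig_id}\t{snp.site + 1}\t.\t{BASES[ref]}\t"
                f"{','.join(BASES[a] for a in alts)}\t.\t{filt}\t"
                f"EPS={eps:.6g};AF={afs}\tGT\t" + "\t".join(gts) + "\n"
            )
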
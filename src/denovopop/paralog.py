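"""Hidden-paralogy likelihood-ratio test for spurious SNPs.

When two paralogous loci are co-assembled into one contig, fixed differences
between the copies masquerade as SNPs at which most or all individuals look
heterozygous.  For every SNP with at least one called heterozygote this
module compares

* a one-locus model: one biallelic locus, allele-1 frequency f, genotypes at
  Hardy-Weinberg proportions, and
* a two-locus model: two loci contribute reads, locus 1 a proportion p of
  them (shared across individuals), each locus biallelic with its own
  allele-1 frequency, genotypes at HWE per locus.

Read counts of allele 1 out of the reads carrying either allele are
beta-binomial rather than binomial, with an overdispersion parameter rho
absorbing allele-specific expression bias and library amplification noise
(a Dirichlet-multinomial reduced to its two-category case).  The expected
allele-1 fraction for a genotype configuration with allele-1 dosage
fraction y is m = y (1 - 2 eps') + eps', where eps' = eps/3 is the chance
that a read from the other allele registers as allele 1 under the
genotyper's uniform error channel.

The statistic lambda = 2 (logL1 - logL0) is referred to a chi-square with
2 degrees of freedom (the added mixing proportion and second frequency);
boundary effects make this approximate, which is why the type-I error is
checked by simulation.  SNPs with p-value below alpha (default 0.001) are
flagged and removed from the analysis set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, gammaln, logsumexp
from scipy.stats import chi2

from .genotyper import SNPRecord

_RHO_MAX = 0.95
_RHO_TINY = 1e-9


@dataclass
class BiallelicSiteData:
    """Per-individual two-allele read counts at one candidate SNP.

    k: reads of allele 1; N: reads of allele 1 + allele 2; reads of other
    bases are excluded from the two-category test (the genotyper's error
    channel accounts for them) but recorded for QC.
    """

    contig_id: str
    site: int
    alleles: tuple[int, int]
    k: np.ndarray
    N: np.ndarray
    discarded: np.ndarray
    n_het_calls: int

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=np.int64)
        self.N = np.asarray(self.N, dtype=np.int64)
        self.discarded = np.asarray(self.discarded, dtype=np.int64)
        if ((self.k < 0) | (self.k > self.N)).any():
            raise ValueError("need 0 <= k <= N per individual")


@dataclass
class OneLocusFit:
    f: float
    rho: float
    logL0: float


@dataclass
class TwoLocusFit:
    p: float
    f1: float
    f2: float
    rho: float
    logL1: float


@dataclass
class ParalogTestResult:
    contig_id: str
    site: int
    lam: float
    df: int
    p_value: float | None
    flagged: bool
    tested: bool = True


def betabinom_logpmf(k, N, m, rho) -> np.ndarray:
    """Beta-binomial log pmf with mean m and overdispersion rho.

    Shapes alpha = m (1-rho)/rho, beta = (1-m)(1-rho)/rho; the rho -> 0
    limit is binomial(N, m).  m = 0 with k > 0 (or m = 1 with k < N) gives
    -inf, not an exception.  Broadcasts over array arguments; kept as an
    explicit gammaln expression because it sits in the hot loop of the grid
    search (scipy.stats.betabinom agrees and cross-checks it in the tests).
    """
    k = np.asarray(k, dtype=float)
    N = np.asarray(N, dtype=float)
    m = np.asarray(m, dtype=float)
    rho = np.asarray(rho, dtype=float)
    k, N, m, rho = np.broadcast_arrays(k, N, m, rho)
    out = np.full(k.shape, -np.inf)

    choose = gammaln(N + 1) - gammaln(k + 1) - gammaln(N - k + 1)

    interior = (m > 0) & (m < 1)
    bb = interior & (rho >= _RHO_TINY)
    if bb.any():
        nu = (1.0 - rho[bb]) / rho[bb]
        a = m[bb] * nu
        b = (1.0 - m[bb]) * nu
        out[bb] = choose[bb] + betaln(k[bb] + a, N[bb] - k[bb] + b) - betaln(a, b)
    binom = interior & (rho < _RHO_TINY)
    if binom.any():
        out[binom] = (
            choose[binom]
            + k[binom] * np.log(m[binom])
            + (N[binom] - k[binom]) * np.log1p(-m[binom])
        )
    # degenerate means: all mass on k = 0 or k = N
    at0 = m <= 0
    out[at0] = np.where(k[at0] == 0, 0.0, -np.inf)
    at1 = m >= 1
    out[at1] = np.where(k[at1] == N[at1], 0.0, -np.inf)
    return out if out.ndim else float(out)


def _bb_table(
    k: np.ndarray, N: np.ndarray, choose: np.ndarray, m: np.ndarray, rho: float
) -> np.ndarray:
    """(I, G) beta-binomial log pmf table for one site; hot-path version of
    :func:`betabinom_logpmf` with the binomial coefficients precomputed."""
    m = np.asarray(m, dtype=float)
    kk = k[:, None]
    NN = N[:, None]
    interior = np.clip(m, 1e-12, 1.0 - 1e-12)[None, :]
    if rho < _RHO_TINY:
        out = choose[:, None] + kk * np.log(interior) + (NN - kk) * np.log1p(-interior)
    else:
        nu = (1.0 - rho) / rho
        a = interior * nu
        b = (1.0 - interior) * nu
        out = choose[:, None] + betaln(kk + a, NN - kk + b) - betaln(a, b)
    at0 = m <= 0
    if at0.any():
        out[:, at0] = np.where(kk == 0, 0.0, -np.inf)
    at1 = m >= 1
    if at1.any():
        out[:, at1] = np.where(kk == NN, 0.0, -np.inf)
    return out


def _lse_rows(x: np.ndarray) -> np.ndarray:
    """logsumexp over the last axis, tolerant of all -inf rows."""
    mx = x.max(axis=-1)
    safe = np.where(np.isfinite(mx), mx, 0.0)
    out = safe + np.log(np.exp(x - safe[..., None]).sum(axis=-1))
    return np.where(np.isfinite(mx), out, -np.inf)


def _mean_fractions(dosage_frac: np.ndarray, epsilon: float) -> np.ndarray:
    """Error-adjusted expected allele-1 read fraction for dosage fraction y:
    m = y (1 - 2 eps') + eps' with eps' = eps/3."""
    e = epsilon / 3.0
    return dosage_frac * (1.0 - 2.0 * e) + e


def _hwe3(f: float | np.ndarray) -> np.ndarray:
    """Genotype probabilities (dosage 2, 1, 0 of allele 1) under HWE."""
    if np.isscalar(f) or getattr(f, "ndim", 1) == 0:
        f = float(f)
        return np.array([f * f, 2 * f * (1 - f), (1 - f) * (1 - f)])
    f = np.asarray(f, dtype=float)
    return np.stack([f**2, 2 * f * (1 - f), (1 - f) ** 2], axis=-1)


def _one_locus_loglik(f, rho, k, N, epsilon, choose=None) -> float:
    if choose is None:
        choose = gammaln(N + 1) - gammaln(k + 1) - gammaln(N - k + 1)
    m = _mean_fractions(np.array([1.0, 0.5, 0.0]), epsilon)  # dosage 2,1,0
    with np.errstate(divide="ignore"):
        logprior = np.log(_hwe3(f))
    lp = _bb_table(k, N, choose, m, float(rho))
    with np.errstate(invalid="ignore"):
        return float(_lse_rows(logprior[None, :] + lp).sum())


def fit_one_locus(data: BiallelicSiteData, epsilon: float) -> OneLocusFit:
    """ML fit of the single-locus model over (f, rho): grid then L-BFGS-B."""
    k, N = data.k, data.N
    use = N > 0
    if use.sum() < 1:
        raise ValueError(f"no usable individuals at {data.contig_id}:{data.site}")
    k, N = k[use].astype(float), N[use].astype(float)
    choose = gammaln(N + 1) - gammaln(k + 1) - gammaln(N - k + 1)

    grid_f = np.linspace(0.0, 1.0, 11)
    grid_rho = (1e-4, 0.05, 0.2, 0.5)
    best = (-np.inf, 0.5, 1e-4)
    for f in grid_f:
        for rho in grid_rho:
            ll = _one_locus_loglik(f, rho, k, N, epsilon, choose)
            if ll > best[0]:
                best = (ll, f, rho)

    def nll(x):
        return -_one_locus_loglik(x[0], x[1], k, N, epsilon, choose)

    res = minimize(
        nll,
        x0=[best[1], best[2]],
        method="L-BFGS-B",
        bounds=[(0.0, 1.0), (0.0, _RHO_MAX)],
        options={"maxiter": 30},
    )
    if -res.fun >= best[0]:
        f, rho, ll = float(res.x[0]), float(res.x[1]), float(-res.fun)
    else:
        ll, f, rho = best
    return OneLocusFit(f=f, rho=rho, logL0=ll)


# two-locus genotype configurations: dosage of allele 1 at each locus
_X1, _X2 = np.meshgrid(np.array([2.0, 1.0, 0.0]), np.array([2.0, 1.0, 0.0]), indexing="ij")
_X1 = _X1.ravel()  # (9,)
_X2 = _X2.ravel()


def _two_locus_loglik(p, f1, f2, rho, k, N, epsilon, choose=None) -> float:
    if choose is None:
        choose = gammaln(N + 1) - gammaln(k + 1) - gammaln(N - k + 1)
    y = p * _X1 / 2.0 + (1.0 - p) * _X2 / 2.0  # (9,)
    m = _mean_fractions(y, epsilon)
    with np.errstate(divide="ignore"):
        logprior = np.log(_hwe3(f1)[:, None] * _hwe3(f2)[None, :]).ravel()
    lp = _bb_table(k, N, choose, m, float(rho))
    with np.errstate(invalid="ignore"):
        return float(_lse_rows(logprior[None, :] + lp).sum())


def fit_two_locus(
    data: BiallelicSiteData,
    epsilon: float,
    one_locus: OneLocusFit | None = None,
) -> TwoLocusFit:
    """ML fit of the collapsed two-locus model over (p, f1, f2, rho).

    Deterministic multi-start: a coarse grid (vectorized over all genotype
    configurations), local refinement from the best grid point, plus a
    nested start at p ~ 1 that reproduces the one-locus optimum so that
    logL1 >= logL0 always holds up to optimizer tolerance.
    """
    k, N = data.k, data.N
    use = N > 0
    if use.sum() < 1:
        raise ValueError(f"no usable individuals at {data.contig_id}:{data.site}")
    k, N = k[use].astype(float), N[use].astype(float)
    choose = gammaln(N + 1) - gammaln(k + 1) - gammaln(N - k + 1)

    grid_p = np.arange(0.1, 0.95, 0.1)  # 0.1 .. 0.9
    grid_f = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    grid_rho = np.array([1e-4, 0.05, 0.2])

    # m for every (p, configuration): (P, 9)
    y = grid_p[:, None] * _X1[None, :] / 2.0 + (1 - grid_p[:, None]) * _X2[None, :] / 2.0
    m = _mean_fractions(y, epsilon)
    # beta-binomial table: (R, P, 9, I)
    lp = betabinom_logpmf(
        k[None, None, None, :],
        N[None, None, None, :],
        m[None, :, :, None],
        grid_rho[:, None, None, None],
    )
    # priors for every (f1, f2) pair: (F, F, 9)
    with np.errstate(divide="ignore"):
        logprior = np.log(
            _hwe3(grid_f)[:, None, :, None] * _hwe3(grid_f)[None, :, None, :]
        ).reshape(len(grid_f), len(grid_f), 9)
    # total log-likelihood (R, P, F, F)
    total = logsumexp(
        logprior[None, None, :, :, None, :] + lp[:, :, None, None, :, :].transpose(0, 1, 2, 3, 5, 4),
        axis=5,
    ).sum(axis=4)
    ri, pi, f1i, f2i = np.unravel_index(int(np.argmax(total)), total.shape)
    starts = [
        (float(grid_p[pi]), float(grid_f[f1i]), float(grid_f[f2i]), float(grid_rho[ri]))
    ]
    if one_locus is not None:
        starts.append((0.999, one_locus.f, 0.5, max(one_locus.rho, 1e-6)))

    def nll(x):
        return -_two_locus_loglik(x[0], x[1], x[2], x[3], k, N, epsilon, choose)

    best_ll = float(total[ri, pi, f1i, f2i])
    best_x = starts[0]
    for x0 in starts:
        res = minimize(
            nll,
            x0=list(x0),
            method="L-BFGS-B",
            bounds=[(1e-3, 1 - 1e-3), (0.0, 1.0), (0.0, 1.0), (0.0, _RHO_MAX)],
            options={"maxiter": 30},
        )
        if -res.fun > best_ll:
            best_ll = float(-res.fun)
            best_x = tuple(float(v) for v in res.x)
    if one_locus is not None and best_ll < one_locus.logL0:
        # the nested point evaluated exactly; never report logL1 < logL0
        nested = (0.999999, one_locus.f, 0.5, one_locus.rho)
        ll = _two_locus_loglik(*nested, k, N, epsilon)
        if ll > best_ll:
            best_ll, best_x = ll, nested
        best_ll = max(best_ll, one_locus.logL0)
    return TwoLocusFit(p=best_x[0], f1=best_x[1], f2=best_x[2], rho=best_x[3], logL1=best_ll)


def paralog_lrt(
    data: BiallelicSiteData, epsilon: float, alpha: float = 0.001
) -> ParalogTestResult:
    """Likelihood-ratio test of hidden paralogy at one SNP.

    Only applicable where at least one heterozygote was called; otherwise
    the result is marked not tested and the SNP is retained.
    """
    if data.n_het_calls < 1:
        return ParalogTestResult(data.contig_id, data.site, 0.0, 2, None, False, tested=False)
    fit0 = fit_one_locus(data, epsilon)
    fit1 = fit_two_locus(data, epsilon, one_locus=fit0)
    lam = 2.0 * (fit1.logL1 - fit0.logL0)
    p = float(chi2.sf(max(lam, 0.0), df=2))
    return ParalogTestResult(data.contig_id, data.site, lam, 2, p, p < alpha)


def site_data_from_counts(
    snp: SNPRecord, counts: np.ndarray, individuals: list[str]
) -> BiallelicSiteData:
    """Assemble the two-allele read counts for one SNP from the contig's
    count matrix (counts: sites x individuals x 4)."""
    a1, a2 = snp.alleles[0], snp.alleles[1]
    row = counts[snp.site]  # (I, 4)
    k = row[:, a1]
    N = row[:, a1] + row[:, a2]
    discarded = row.sum(axis=1) - N
    n_het = sum(
        1
        for g in snp.genotypes.values()
        if g is not None and g[0] != g[1]
    )
    return BiallelicSiteData(
        contig_id=snp.contig_id,
        site=snp.site,
        alleles=(a1, a2),
        k=k,
        N=N,
        discarded=discarded,
        n_het_calls=n_het,
    )


def apply_filter(
    snps: list[SNPRecord], results: list[ParalogTestResult]
) -> tuple[list[SNPRecord], list[SNPRecord]]:
    """Split SNPs into (retained, flagged) by their paralogy test results.

    Untested SNPs (no heterozygote) are retained.  Flagged SNPs get their
    ``paralog_flag`` set for VCF FILTER annotation.
    """
    by_key = {(r.contig_id, r.site): r for r in results}
    retained, flagged = [], []
    for snp in snps:
        r = by_key.get((snp.contig_id, snp.site))
        if r is not None and r.tested:
            snp.paralog_p = r.p_value
        if r is not None and r.tested and r.flagged:
            snp.paralog_flag = True
            flagged.append(snp)
        else:
            retained.append(snp)
    return retained, flagged


def write_results_tsv(results: list[ParalogTestResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\tlambda\tdf\tp_value\tflagged\ttested\n")
        for r in results:
            p = "NA" if r.p_value is None else f"{r.p_value:.6g}"
            fh.write(
                f"{r.contig_id}\t{r.site}\t{r.lam:.6g}\t{r.df}\t{p}\t"
                f"{int(r.flagged)}\t{int(r.tested)}\n"
            )
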
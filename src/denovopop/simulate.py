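"""Synthetic read-count datasets with known truth for every pipeline stage.

The generator emulates the data-generating assumptions of the calling
model so that parameter recovery is a meaningful check: diploid genotypes
at Hardy-Weinberg equilibrium (optionally with inbreeding F_IS), allele
frequencies drawn from the neutral 1/k law, per-contig sequencing error
applied as a uniform per-base channel, Poisson coverage (optionally
unequal across individuals), beta-binomial allele-expression bias in
heterozygotes, geometric PCR duplication, and collapsed paralogous contig
pairs sharing one mixing proportion p across individuals.

Frequencies come from the normalized 1/k law rather than a coalescent
simulator: this reproduces the expected spectrum and E[pi] = theta for
every statistic tested here without extra dependencies.  A hook
(`simulate_from_genotypes`) accepts externally generated genotype
matrices for users who want coalescent input.  What the generator does
not emulate: linkage, indels, alternative splicing, mapping bias, and
base-quality structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .counts import BASES, ContigCountMatrix, ReadAlignmentRecord
from .orf import OrfAnnotation, STOP_CODONS
from .paralog import BiallelicSiteData

_NONSTOP_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
]


@dataclass
class SimulationConfig:
    """Stated world of one simulated dataset; all rates in [0, 1]."""

    n_individuals: int = 10
    n_contigs: int = 200
    contig_length: int = 201  # a whole number of codons
    mean_coverage: float = 10.0
    coverage_per_individual: list[float] | None = None  # unequal coverage
    epsilon_true: float = 0.005
    theta: float = 0.01  # per-site, all coding positions
    F_IS_true: float = 0.0
    rho_true: float = 0.0  # allelic-expression overdispersion
    paralog_fraction: float = 0.0  # fraction of contigs with one collapsed site
    paralog_p: float = 0.5
    pcr_duplicate_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("epsilon_true", "F_IS_true", "rho_true", "paralog_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.contig_length % 3:
            raise ValueError("contig_length must be a multiple of 3")
        if self.rng_seed is None:
            raise ValueError("an explicit rng_seed is mandatory")


@dataclass
class TruthTable:
    """Ground truth emitted alongside the count matrices."""

    genotypes: dict[str, np.ndarray]  # contig -> (sites, individuals, 2) base idx
    allele_freqs: dict[str, dict[int, float]]  # contig -> site -> minor freq
    snp_sites: dict[str, list[int]]
    paralog_sites: dict[str, list[int]]
    epsilon: dict[str, float]
    sequences: dict[str, str] = field(default_factory=dict)
    orfs: dict[str, OrfAnnotation] = field(default_factory=dict)


def _draw_genotypes(
    rng: np.random.Generator, n_ind: int, freq: float, f_is: float
) -> np.ndarray:
    """(n_ind,) dosages of the derived allele under HWE with inbreeding."""
    p, q = 1.0 - freq, freq
    probs = [p * p + f_is * p * q, 2 * p * q * (1 - f_is), q * q + f_is * p * q]
    return rng.choice(3, size=n_ind, p=probs)


def _neutral_freq(rng: np.random.Generator, n_hap: int) -> int:
    """Derived allele count k in 1..n_hap-1 with probability ~ 1/k."""
    k = np.arange(1, n_hap)
    w = 1.0 / k
    return int(rng.choice(k, p=w / w.sum()))


def _error_channel(
    rng: np.random.Generator, n: np.ndarray, src: int, epsilon: float
) -> np.ndarray:
    """Observed (len(n), 4) counts for n reads each truly of base src."""
    if epsilon == 0:
        out = np.zeros((len(n), 4), dtype=np.int64)
        out[:, src] = n
        return out
    p = np.full(4, epsilon / 3.0)
    p[src] = 1.0 - epsilon
    return rng.multinomial(n, p)


def _emit_contig_counts(
    rng: np.random.Generator,
    genotypes: np.ndarray,  # (L, I, 2) base indices
    coverage: np.ndarray,  # (L, I) realized read numbers
    epsilon: float,
    rho: float,
) -> np.ndarray:
    """(L, I, 4) observed base counts for a whole contig.

    Homozygous cells (the vast majority) are emitted in four vectorized
    multinomial batches; heterozygous cells get a beta-binomial allele
    split first.
    """
    L, I = coverage.shape
    counts = np.zeros((L, I, 4), dtype=np.int64)
    hom = genotypes[:, :, 0] == genotypes[:, :, 1]
    for b in range(4):
        cells = hom & (genotypes[:, :, 0] == b) & (coverage > 0)
        if cells.any():
            counts[cells] += _error_channel(rng, coverage[cells], b, epsilon)
    for s, i in zip(*np.nonzero(~hom)):
        n = int(coverage[s, i])
        if n == 0:
            continue
        a, b = int(genotypes[s, i, 0]), int(genotypes[s, i, 1])
        if rho > 0:
            m = rng.beta((1 - rho) / (2 * rho), (1 - rho) / (2 * rho))
        else:
            m = 0.5
        k = int(rng.binomial(n, m))
        if k:
            counts[s, i] += _error_channel(rng, np.array([k]), a, epsilon)[0]
        if n - k:
            counts[s, i] += _error_channel(rng, np.array([n - k]), b, epsilon)[0]
    return counts


def _random_coding_sequence(rng: np.random.Generator, length: int) -> str:
    codons = rng.choice(len(_NONSTOP_CODONS), size=length // 3)
    return "".join(_NONSTOP_CODONS[c] for c in codons)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[ContigCountMatrix], TruthTable]:
    """Simulate count matrices plus truth for a whole dataset.

    Sites are polymorphic with the 1/k neutral frequency law at rate
    theta per site (number of SNPs per contig ~ Poisson(theta * a1 * L));
    genotypes honor F_IS_true; heterozygote read counts are split
    beta-binomially with rho_true; every read base then passes the uniform
    error channel with epsilon_true.  In paralog contigs one extra site is
    replaced by a collapsed fixed difference between two loci mixing at
    proportion paralog_p shared across individuals.  Deterministic under
    the seed.
    """
    rng = np.random.default_rng(config.rng_seed)
    I = config.n_individuals
    L = config.contig_length
    n_hap = 2 * I
    a1 = sum(1.0 / k for k in range(1, n_hap))
    individuals = [f"ind{i:02d}" for i in range(I)]
    cov = (
        np.asarray(config.coverage_per_individual, dtype=float)
        if config.coverage_per_individual is not None
        else np.full(I, config.mean_coverage)
    )
    if len(cov) != I:
        raise ValueError("coverage_per_individual length != n_individuals")

    n_paralog = int(round(config.paralog_fraction * config.n_contigs))
    matrices = []
    truth = TruthTable({}, {}, {}, {}, {})
    for c in range(config.n_contigs):
        cid = f"contig{c:04d}"
        seq = _random_coding_sequence(rng, L)
        ref = np.array([BASES.index(b) for b in seq])
        genotypes = np.broadcast_to(ref[:, None, None], (L, I, 2)).copy()

        n_snps = rng.poisson(config.theta * a1 * L)
        sites = rng.choice(L, size=min(n_snps, L), replace=False)
        freqs: dict[int, float] = {}
        for s in sites:
            alt = int(rng.choice([b for b in range(4) if b != ref[s]]))
            k = _neutral_freq(rng, n_hap)
            if config.F_IS_true == 0:
                # the 1/k law governs sample counts: place exactly k copies
                # of the derived allele on randomly chosen haplotypes
                slots = rng.choice(n_hap, size=k, replace=False)
                dosages = np.bincount(slots // 2, minlength=I)
            else:
                # inbreeding correlates alleles within individuals; draw
                # genotypes at inbred HWE with expected frequency k / 2I
                dosages = _draw_genotypes(rng, I, k / n_hap, config.F_IS_true)
            g = genotypes[s]
            g[dosages >= 1, 0] = alt
            g[dosages == 2, 1] = alt
            freqs[int(s)] = k / n_hap

        coverage = rng.poisson(cov[None, :], size=(L, I))
        counts = _emit_contig_counts(
            rng, genotypes, coverage, config.epsilon_true, config.rho_true
        )

        paralog_sites: list[int] = []
        if c < n_paralog:
            free = [s for s in range(L) if s not in freqs]
            s = int(rng.choice(free))
            alt = int(rng.choice([b for b in range(4) if b != ref[s]]))
            site = simulate_paralog_site(
                p=config.paralog_p,
                f1=1.0,
                f2=0.0,
                coverage=coverage[s].astype(float),
                rho=config.rho_true,
                epsilon=config.epsilon_true,
                n_individuals=I,
                rng=rng,
                alleles=(int(ref[s]), alt),
            )
            row = np.zeros((I, 4), dtype=np.int64)
            row[:, ref[s]] = site.k
            row[:, alt] = site.N - site.k
            counts[s] = row
            paralog_sites.append(s)

        matrices.append(ContigCountMatrix(cid, L, list(individuals), counts))
        truth.genotypes[cid] = genotypes
        truth.allele_freqs[cid] = freqs
        truth.snp_sites[cid] = sorted(freqs)
        truth.paralog_sites[cid] = paralog_sites
        truth.epsilon[cid] = config.epsilon_true
        truth.sequences[cid] = seq
        truth.orfs[cid] = OrfAnnotation(cid, 0, L)
    return matrices, truth


def simulate_paralog_site(
    p: float,
    f1: float,
    f2: float,
    coverage: np.ndarray | float,
    rho: float,
    epsilon: float,
    n_individuals: int,
    rng: np.random.Generator,
    alleles: tuple[int, int] = (0, 1),
) -> BiallelicSiteData:
    """One collapsed site: two loci contribute reads, locus 1 a shared
    proportion p; per-locus genotypes at HWE with allele-1 frequencies
    f1, f2.  The default (f1=1, f2=0) is a fixed difference between the
    copies.  Returns two-allele read counts per individual."""
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    cov = np.broadcast_to(np.asarray(coverage, dtype=float), (n_individuals,))
    x1 = _draw_genotypes(rng, n_individuals, 1.0 - f1, 0.0)  # dosage of allele 1
    x1 = 2 - x1
    x2 = 2 - _draw_genotypes(rng, n_individuals, 1.0 - f2, 0.0)
    y = p * x1 / 2.0 + (1.0 - p) * x2 / 2.0
    e = epsilon / 3.0
    m = y * (1.0 - 2.0 * e) + e
    N = rng.poisson(cov)
    k = np.zeros(n_individuals, dtype=np.int64)
    for i in range(n_individuals):
        if N[i] == 0:
            continue
        mi = m[i]
        if rho > 0 and 0 < mi < 1:
            mi = rng.beta(mi * (1 - rho) / rho, (1 - mi) * (1 - rho) / rho)
        k[i] = rng.binomial(N[i], mi)
    return BiallelicSiteData(
        contig_id="paralog_sim",
        site=0,
        alleles=alleles,
        k=k,
        N=N,
        discarded=np.zeros(n_individuals, dtype=np.int64),
        n_het_calls=n_individuals,  # construction: every individual carries both loci
    )


def simulate_one_locus_site(
    f: float,
    coverage: float,
    rho: float,
    epsilon: float,
    n_individuals: int,
    rng: np.random.Generator,
    require_het: bool = True,
) -> BiallelicSiteData:
    """A genuine single-locus biallelic site under HWE, for type-I error
    calibration of the paralogy test.  With ``require_het`` genotype draws
    are repeated until at least one heterozygote appears (the test is only
    run on such sites)."""
    for _ in range(1000):
        dos = _draw_genotypes(rng, n_individuals, f, 0.0)
        n_het = int((dos == 1).sum())
        if not require_het or n_het >= 1:
            break
    y = dos / 2.0
    e = epsilon / 3.0
    m = y * (1.0 - 2.0 * e) + e
    N = rng.poisson(np.full(n_individuals, coverage))
    k = np.zeros(n_individuals, dtype=np.int64)
    for i in range(n_individuals):
        if N[i] == 0:
            continue
        mi = m[i]
        if rho > 0 and 0 < mi < 1:
            mi = rng.beta(mi * (1 - rho) / rho, (1 - mi) * (1 - rho) / rho)
        k[i] = rng.binomial(N[i], mi)
    return BiallelicSiteData(
        contig_id="one_locus_sim",
        site=0,
        alleles=(0, 1),
        k=k,
        N=N,
        discarded=np.zeros(n_individuals, dtype=np.int64),
        n_het_calls=n_het,
    )


def add_pcr_duplicates(
    records: list[ReadAlignmentRecord], rate: float, seed: int
) -> list[ReadAlignmentRecord]:
    """Duplicate each read k extra times, k geometric with the given rate
    (a stress model for the duplicate-collapsing filter, not a claim about
    real library chemistry)."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return list(records)
    rng = np.random.default_rng(seed)
    out = []
    for r in records:
        out.append(r)
        extra = rng.geometric(1.0 - rate) - 1
        out.extend([r] * int(extra))
    return out


def scenario_presets() -> dict[str, SimulationConfig]:
    """Named scenarios used by the validation suite."""
    return {
        "neutral-10x": SimulationConfig(
            n_individuals=10, n_contigs=200, contig_length=201,
            mean_coverage=10.0, epsilon_true=0.005, theta=0.01, rng_seed=0,
        ),
        "high-coverage-30x": SimulationConfig(
            n_individuals=10, n_contigs=200, contig_length=201,
            mean_coverage=30.0, epsilon_true=0.005, theta=0.01, rng_seed=0,
        ),
        "paralog-mix": SimulationConfig(
            n_individuals=10, n_contigs=100, contig_length=201,
            mean_coverage=20.0, epsilon_true=0.005, theta=0.01,
            paralog_fraction=0.2, paralog_p=0.5, rng_seed=0,
        ),
        "inbred": SimulationConfig(
            n_individuals=10, n_contigs=100, contig_length=201,
            mean_coverage=10.0, epsilon_true=0.005, theta=0.01,
            F_IS_true=0.3, rng_seed=0,
        ),
    }


def preset(name: str, seed: int | None = None, **overrides) -> SimulationConfig:
    cfg = scenario_presets()[name]
    if seed is not None:
        overrides["rng_seed"] = seed
    return replace(cfg, **overrides) if overrides else cfg
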
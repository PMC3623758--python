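"""Per-contig and species-level population-genomic statistics.

From cleaned codon alignments and SNP records this module computes, per
contig: synonymous and non-synonymous per-site diversity (pi_S, pi_N),
heterozygote deficiency (F_IS), counts of synonymous / non-synonymous
segregating sites (p_S, p_N) and, with an outgroup, fixed differences
(d_S, d_N).  Species-level summaries are length-weighted across contigs
(weight = analyzed site count of the relevant class, giving equal weight
to every SNP) with contig-bootstrap confidence intervals, and include the
McDonald-Kreitman neutrality index NI = (pN/pS)/(dN/dS), its
low-frequency-trimmed variant NI_0.2 (SNPs with minor allele frequency
below 0.2 removed), alpha = 1 - NI, and the adaptive substitution rate
omega_a = alpha * dN/dS.

Synonymous/non-synonymous site counting is Nei-Gojobori-style: each codon
position contributes a fractional synonymous weight equal to the fraction
of its possible single-base changes (stop-creating changes excluded) that
preserve the amino acid, evaluated on the consensus codon.  All statistics
are computed from complete, biallelic sites only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .counts import BASES
from .genotyper import GenotypeCall, SNPRecord
from .orf import MISSING, CodonAlignment

CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)

SYN, NONSYN, EXCLUDED = "SYN", "NONSYN", "EXCLUDED"


@dataclass
class ContigStats:
    contig_id: str
    length: int  # analyzed (complete) nucleotide sites
    L_S: float
    L_N: float
    pi_S: float | None
    pi_N: float | None
    F_IS: float | None
    p_S: int
    p_N: int
    d_S: float | None = None  # per-site rates
    d_N: float | None = None
    d_S_count: int = 0
    d_N_count: int = 0
    n_snps: int = 0


@dataclass
class SpeciesSummary:
    mean_pi_S: float
    mean_pi_N: float
    pi_N_over_pi_S: float | None
    mean_F_IS: float | None
    NI: float | None
    NI_02: float | None
    alpha: float | None
    alpha_02: float | None
    dN_over_dS: float | None
    omega_a: float | None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_contigs: int = 0


def site_pi(n1: int, n2: int) -> float:
    """Per-site diversity: mean pairwise difference among n1 + n2 haplotypes,
    n1 * n2 / C(n, 2)."""
    n = n1 + n2
    if n < 2:
        raise ValueError("site_pi needs at least 2 haplotypes")
    return n1 * n2 / (n * (n - 1) / 2)


def translate(codon: str) -> str | None:
    """Amino acid for a codon; '*' for stop; None if ambiguous."""
    if codon in STOP_CODONS:
        return "*"
    return CODON_TABLE.get(codon)


def classify_snp(
    codon: str, pos_in_codon: int, alleles: tuple[str, str]
) -> str:
    """SYN / NONSYN / EXCLUDED for a biallelic change at one codon position.

    The two codons differ only at the focal position (other positions at
    the consensus).  Any stop codon or ambiguous context is EXCLUDED.
    """
    if len(codon) != 3 or MISSING in codon or not (0 <= pos_in_codon < 3):
        return EXCLUDED
    c1 = codon[:pos_in_codon] + alleles[0] + codon[pos_in_codon + 1 :]
    c2 = codon[:pos_in_codon] + alleles[1] + codon[pos_in_codon + 1 :]
    aa1, aa2 = translate(c1), translate(c2)
    if aa1 is None or aa2 is None or aa1 == "*" or aa2 == "*":
        return EXCLUDED
    return SYN if aa1 == aa2 else NONSYN


def _syn_weight(codon: str, pos: int) -> float | None:
    """Fraction of the non-stop single-base changes at this position that
    are synonymous; None if no valid change exists."""
    aa = translate(codon)
    if aa is None or aa == "*":
        return None
    n_syn = n_valid = 0
    for b in BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        aa2 = translate(alt)
        if aa2 is None or aa2 == "*":
            continue
        n_valid += 1
        if aa2 == aa:
            n_syn += 1
    if n_valid == 0:
        return None
    return n_syn / n_valid


def consensus_codons(aln: CodonAlignment) -> list[str]:
    """Majority-rule consensus codon per codon site over focal haplotypes
    (ties broken alphabetically; all-missing columns give 'NNN')."""
    focal = aln.focal
    out = []
    for c in range(aln.n_codons):
        codon = []
        for j in range(3 * c, 3 * c + 3):
            col = focal[:, j]
            col = col[col != MISSING]
            if len(col) == 0:
                codon.append(MISSING)
                continue
            vals, cnt = np.unique(col, return_counts=True)
            codon.append(sorted(vals[cnt == cnt.max()])[0])
        out.append("".join(codon))
    return out


def syn_nonsyn_site_counts(
    aln: CodonAlignment, codons: list[str] | None = None
) -> tuple[float, float]:
    """(L_S, L_N): fractional synonymous and non-synonymous site counts over
    the consensus codons.  Codons containing missing bases or coding for a
    stop are skipped entirely."""
    if codons is None:
        codons = consensus_codons(aln)
    L_S = 0.0
    n_codons = 0
    for codon in codons:
        if MISSING in codon:
            continue
        aa = translate(codon)
        if aa is None or aa == "*":
            continue
        n_codons += 1
        for pos in range(3):
            w = _syn_weight(codon, pos)
            if w is not None:
                L_S += w
    return L_S, 3.0 * n_codons - L_S


def classify_alignment_snps(
    aln: CodonAlignment,
    snps: list[SNPRecord],
    complete_sites: list[int],
    codons: list[str] | None = None,
) -> list[SNPRecord]:
    """Assign synonymy classes to SNPs that fall on complete biallelic
    sites of the cleaned alignment; returns the analyzable subset."""
    if codons is None:
        codons = consensus_codons(aln)
    contig_pos = {}
    for codon_idx, start in enumerate(aln.codon_to_contig):
        for off in range(3):
            contig_pos[int(start) + off] = (codon_idx, off)
    complete = set(complete_sites)
    out = []
    for snp in snps:
        if snp.multiallelic:
            continue
        loc = contig_pos.get(snp.site)
        if loc is None:
            continue
        codon_idx, off = loc
        j = 3 * codon_idx + off
        if j not in complete:
            continue
        snp.synonymy = classify_snp(
            codons[codon_idx], off, (BASES[snp.alleles[0]], BASES[snp.alleles[1]])
        )
        out.append(snp)
    return out


def _haplotype_allele_counts(aln: CodonAlignment, j: int) -> dict[str, int]:
    col = aln.focal[:, j]
    vals, cnt = np.unique(col, return_counts=True)
    return {v: int(c) for v, c in zip(vals.tolist(), cnt.tolist()) if v != MISSING}


def alignment_site_pi(aln: CodonAlignment, j: int) -> float:
    """site_pi computed from the focal haplotype column at site j."""
    counts = sorted(_haplotype_allele_counts(aln, j).values(), reverse=True)
    if len(counts) == 1:
        counts.append(0)
    return site_pi(counts[0], counts[1])


def contig_diversity(
    aln: CodonAlignment,
    snps: list[SNPRecord],
    L_S: float,
    L_N: float,
) -> tuple[float | None, float | None, int, int]:
    """(pi_S, pi_N, p_S, p_N) over classified SNPs of one contig."""
    pos_of = {}
    for codon_idx, start in enumerate(aln.codon_to_contig):
        for off in range(3):
            pos_of[int(start) + off] = 3 * codon_idx + off
    sum_s = sum_n = 0.0
    p_S = p_N = 0
    for snp in snps:
        if snp.synonymy not in (SYN, NONSYN):
            continue
        j = pos_of[snp.site]
        pi = alignment_site_pi(aln, j)
        if snp.synonymy == SYN:
            sum_s += pi
            p_S += 1
        else:
            sum_n += pi
            p_N += 1
    pi_S = sum_s / L_S if L_S > 0 else None
    pi_N = sum_n / L_N if L_N > 0 else None
    return pi_S, pi_N, p_S, p_N


def fis(snps: list[SNPRecord], corrected: bool = False) -> float | None:
    """Heterozygote deficiency, 1 - sum(Hobs)/sum(Hexp) across SNPs.

    Hobs is the fraction of non-missing individuals heterozygous at the
    SNP; Hexp is the plug-in 2*p*q from haplotype counts.  The plug-in is
    biased low by the factor (2n-1)/2n, so under exact HWE the statistic
    centers on -1/(2n-1) rather than 0; ``corrected=True`` applies Nei's
    2n/(2n-1) factor and recenters it on 0.  The ratio of sums is robust
    to individual SNPs with tiny Hexp.
    """
    sum_obs = sum_exp = 0.0
    for snp in snps:
        called = [g for g in snp.genotypes.values() if g is not None]
        if not called:
            continue
        hobs = sum(1 for g in called if g[0] != g[1]) / len(called)
        counts = list(snp.allele_counts().values())
        total = sum(counts)
        if len(counts) < 2 or total < 2:
            continue
        p = counts[0] / total
        hexp = 2 * p * (1 - p)
        if corrected:
            hexp *= total / (total - 1)
        sum_obs += hobs
        sum_exp += hexp
    if sum_exp == 0:
        return None
    return 1.0 - sum_obs / sum_exp


def per_individual_heterozygosity(
    calls: list[GenotypeCall],
) -> dict[str, float | None]:
    """Proportion of heterozygous positions among non-missing calls, per
    individual; None for individuals with no called position."""
    het: dict[str, int] = {}
    tot: dict[str, int] = {}
    for c in calls:
        tot.setdefault(c.individual, 0)
        het.setdefault(c.individual, 0)
        if c.genotype is not None:
            tot[c.individual] += 1
            if c.genotype[0] != c.genotype[1]:
                het[c.individual] += 1
    return {
        ind: (het[ind] / tot[ind] if tot[ind] > 0 else None) for ind in tot
    }


def fixed_differences(
    aln: CodonAlignment,
    complete_sites: list[int],
    L_S: float,
    L_N: float,
    codons: list[str] | None = None,
) -> tuple[float | None, float | None, int, int]:
    """(d_S, d_N, d_S_count, d_N_count) between focal and outgroup.

    A fixed difference is a complete site at which the focal haplotypes are
    monomorphic and differ from the (non-missing) outgroup base; the change
    is classified SYN/NONSYN in the consensus codon context, with stop or
    ambiguous contexts excluded.  Rates are counts / L_S (or L_N), no
    multiple-hit correction (close outgroups assumed).
    """
    if not aln.has_outgroup:
        raise ValueError("fixed_differences requires an outgroup row")
    if codons is None:
        codons = consensus_codons(aln)
    og = aln.outgroup
    dS = dN = 0
    for j in complete_sites:
        col = aln.focal[:, j]
        states = set(col.tolist())
        if len(states) != 1:
            continue
        focal_base = next(iter(states))
        out_base = og[j]
        if out_base == MISSING or out_base == focal_base:
            continue
        cls = classify_snp(codons[j // 3], j % 3, (focal_base, str(out_base)))
        if cls == SYN:
            dS += 1
        elif cls == NONSYN:
            dN += 1
    d_S = dS / L_S if L_S > 0 else None
    d_N = dN / L_N if L_N > 0 else None
    return d_S, d_N, dS, dN


def neutrality_indices(
    p_N: int,
    p_S: int,
    d_N: int,
    d_S: int,
    snps: list[SNPRecord] | None = None,
    maf_cutoff: float = 0.2,
) -> dict[str, float | None]:
    """McDonald-Kreitman quantities from pooled counts.

    NI = (pN/pS)/(dN/dS); NI_0.2 recomputes pN, pS after discarding SNPs
    with minor allele frequency below ``maf_cutoff`` (same dN, dS); alpha =
    1 - NI, alpha_0.2 = 1 - NI_0.2; omega_a = alpha * dN/dS.  Zero
    denominators give None, never a crash.
    """
    def ratio(num, den):
        return num / den if den else None

    dnds = ratio(d_N, d_S)
    pnps = ratio(p_N, p_S)
    NI = ratio(pnps, dnds) if pnps is not None and dnds is not None else None
    NI02 = None
    if snps is not None:
        pN2 = sum(
            1 for s in snps if s.synonymy == NONSYN and s.maf >= maf_cutoff
        )
        pS2 = sum(1 for s in snps if s.synonymy == SYN and s.maf >= maf_cutoff)
        pnps2 = ratio(pN2, pS2)
        NI02 = ratio(pnps2, dnds) if pnps2 is not None and dnds is not None else None
    alpha = 1.0 - NI if NI is not None else None
    alpha02 = 1.0 - NI02 if NI02 is not None else None
    omega_a = alpha * dnds if alpha is not None and dnds is not None else None
    omega_a02 = alpha02 * dnds if alpha02 is not None and dnds is not None else None
    return {
        "NI": NI,
        "NI_02": NI02,
        "alpha": alpha,
        "alpha_02": alpha02,
        "dN_over_dS": dnds,
        "omega_a": omega_a,
        "omega_a_02": omega_a02,
    }


def _weighted_mean(values, weights) -> float | None:
    v = np.array([x for x, w in zip(values, weights) if x is not None and w > 0])
    w = np.array([w for x, w in zip(values, weights) if x is not None and w > 0])
    if len(v) == 0 or w.sum() == 0:
        return None
    return float((v * w).sum() / w.sum())


def _summary_point(stats: list[ContigStats], snps_by_contig=None, maf_cutoff=0.2):
    pi_S = _weighted_mean([s.pi_S for s in stats], [s.L_S for s in stats])
    pi_N = _weighted_mean([s.pi_N for s in stats], [s.L_N for s in stats])
    F = _weighted_mean(
        [s.F_IS for s in stats], [s.n_snps for s in stats]
    )
    pN = sum(s.p_N for s in stats)
    pS = sum(s.p_S for s in stats)
    dN = sum(s.d_N_count for s in stats)
    dS = sum(s.d_S_count for s in stats)
    snps = None
    if snps_by_contig is not None:
        snps = [s for st in stats for s in snps_by_contig.get(st.contig_id, [])]
    mk = neutrality_indices(pN, pS, dN, dS, snps, maf_cutoff)
    ratio = pi_N / pi_S if pi_S not in (None, 0) and pi_N is not None else None
    return {
        "mean_pi_S": pi_S,
        "mean_pi_N": pi_N,
        "pi_N_over_pi_S": ratio,
        "mean_F_IS": F,
        **mk,
    }


def species_summary(
    contig_stats: list[ContigStats],
    snps_by_contig: dict[str, list[SNPRecord]] | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
    maf_cutoff: float = 0.2,
) -> SpeciesSummary:
    """Length-weighted species-level summary with contig-bootstrap CIs.

    Diversity means weight each contig by its analyzed site count of the
    relevant class (L_S for pi_S, L_N for pi_N), which gives every SNP
    equal weight; NI and derived quantities come from counts summed across
    contigs.  Percentile 95% confidence intervals are computed over
    ``n_bootstrap`` resamples of contigs with replacement, seeded.
    """
    if len(contig_stats) < 2:
        raise ValueError("species_summary needs at least 2 contigs")
    point = _summary_point(contig_stats, snps_by_contig, maf_cutoff)
    rng = np.random.default_rng(seed)
    reps: dict[str, list[float]] = {k: [] for k in point}
    n = len(contig_stats)
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        rep = _summary_point(
            [contig_stats[i] for i in idx], snps_by_contig, maf_cutoff
        )
        for key, val in rep.items():
            if val is not None:
                reps[key].append(val)
    ci = {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for k, v in reps.items()
        if v
    }
    return SpeciesSummary(
        mean_pi_S=point["mean_pi_S"],
        mean_pi_N=point["mean_pi_N"],
        pi_N_over_pi_S=point["pi_N_over_pi_S"],
        mean_F_IS=point["mean_F_IS"],
        NI=point["NI"],
        NI_02=point["NI_02"],
        alpha=point["alpha"],
        alpha_02=point["alpha_02"],
        dN_over_dS=point["dN_over_dS"],
        omega_a=point["omega_a"],
        ci=ci,
        n_contigs=len(contig_stats),
    )


def pairwise_genetic_distance(
    ind_i: str, ind_j: str, snps: list[SNPRecord]
) -> float | None:
    """(H_b - H_w)/H_w between two individuals over shared non-missing sites.

    H_b is the probability of drawing two distinct alleles sampling one
    copy from each individual; H_w the average heterozygosity of the two.
    Both are averaged across shared sites before the ratio; monomorphic
    shared sites contribute zero to both and cancel from the ratio.
    Returns 0 when both sums are zero, None when no shared site exists or
    H_w = 0 with H_b > 0.
    """
    sum_b = sum_w = 0.0
    shared = 0
    for snp in snps:
        gi = snp.genotypes.get(ind_i)
        gj = snp.genotypes.get(ind_j)
        if gi is None or gj is None:
            continue
        shared += 1
        hb = sum(1 for a, b in itertools.product(gi, gj) if a != b) / 4.0
        hw = ((gi[0] != gi[1]) + (gj[0] != gj[1])) / 2.0
        sum_b += hb
        sum_w += hw
    if shared == 0:
        return None
    if sum_w == 0:
        return 0.0 if sum_b == 0 else None
    return (sum_b - sum_w) / sum_w


def distance_matrix(
    individuals: list[str], snps: list[SNPRecord]
) -> np.ndarray:
    """Symmetric matrix of pairwise genetic distances (NaN when undefined)."""
    n = len(individuals)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_genetic_distance(individuals[i], individuals[j], snps)
            mat[i, j] = mat[j, i] = np.nan if d is None else d
    return mat


def write_distance_matrix_tsv(
    individuals: list[str], snps: list[SNPRecord], path
) -> None:
    """Pairwise genetic-distance matrix TSV (NA where undefined)."""
    mat = distance_matrix(individuals, snps)
    with open(path, "w") as fh:
        fh.write("individual\t" + "\t".join(individuals) + "\n")
        for ind, row in zip(individuals, mat):
            cells = ["NA" if np.isnan(x) else f"{x:.6g}" for x in row]
            fh.write(ind + "\t" + "\t".join(cells) + "\n")


def write_contig_stats_tsv(stats: list[ContigStats], path) -> None:
    cols = [
        "contig", "length", "L_S", "L_N", "pi_S", "pi_N", "F_IS",
        "p_S", "p_N", "d_S", "d_N", "d_S_count", "d_N_count", "n_snps",
    ]
    def fmt(x):
        return "NA" if x is None else (f"{x:.6g}" if isinstance(x, float) else str(x))
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in stats:
            fh.write(
                "\t".join(
                    fmt(x)
                    for x in (
                        s.contig_id, s.length, s.L_S, s.L_N, s.pi_S, s.pi_N,
                        s.F_IS, s.p_S, s.p_N, s.d_S, s.d_N,
                        s.d_S_count, s.d_N_count, s.n_snps,
                    )
                )
                + "\n"
            )


def write_species_summary_tsv(summary: SpeciesSummary, path) -> None:
    fields = [
        "mean_pi_S", "mean_pi_N", "pi_N_over_pi_S", "mean_F_IS",
        "NI", "NI_02", "alpha", "alpha_02", "dN_over_dS", "omega_a",
    ]
    def fmt(x):
        return "NA" if x is None else f"{x:.6g}"
    with open(path, "w") as fh:
        fh.write("statistic\tvalue\tci_low\tci_high\n")
        for f in fields:
            val = getattr(summary, f)
            lo, hi = summary.ci.get(f, (None, None))
            fh.write(f"{f}\t{fmt(val)}\t{fmt(lo)}\t{fmt(hi)}\n")
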
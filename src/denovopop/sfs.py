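"""Folded site-frequency spectra by hypergeometric projection, Tajima's D.

Sample size varies across SNPs because genotypes are missing at different
individuals.  To build one spectrum the observed allele counts are
projected down to a fixed number of haplotypes n (default 12) with
hypergeometric subsampling weights: a SNP at minor count i among m
haplotypes spreads fractional mass C(i,j) C(m-i, n-j) / C(m,n) over
subsample counts j.  SNPs observed in fewer than n haplotypes are
discarded.  Mass landing on the monomorphic classes 0 and n is dropped
without renormalization (the SNP partially leaves the subsample); folding
merges classes j and n-j into min(j, n-j).

Tajima's D is computed from the (possibly fractional) projected spectrum
with the standard constants; on the idealized neutral spectrum
xi_k proportional to 1/k it is exactly zero for every n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom


@dataclass
class FoldedSFS:
    n: int
    counts: np.ndarray = field(repr=False)  # masses for classes 1..n//2
    n_snps_used: int = 0
    n_snps_discarded: int = 0

    @property
    def classes(self) -> np.ndarray:
        return np.arange(1, self.n // 2 + 1)


def projection_weights(i: int, m: int, n: int) -> np.ndarray:
    """Hypergeometric projection weights over j = 0..n for a SNP at allele
    count i among m haplotypes, projected to n <= m haplotypes:
    w(j) = C(i,j) C(m-i, n-j) / C(m,n)."""
    if not (0 <= i <= m):
        raise ValueError(f"allele count {i} outside [0, {m}]")
    if n > m:
        raise ValueError(f"cannot project {m} haplotypes up to {n}")
    j = np.arange(n + 1)
    # hypergeom.pmf(j; M=m, K=i, N=n) = C(i,j) C(m-i, n-j) / C(m,n)
    return hypergeom.pmf(j, m, i, n)


def fold(masses: np.ndarray, n: int) -> np.ndarray:
    """Fold an unfolded mass vector over j = 0..n into minor-allele classes
    1..n//2, dropping the monomorphic classes 0 and n."""
    masses = np.asarray(masses, dtype=float)
    out = np.zeros(n // 2)
    # the middle class j = n/2 maps to itself and is added exactly once
    for j in range(1, n):
        out[min(j, n - j) - 1] += masses[j]
    return out


def project_and_fold(snps, n: int = 12) -> FoldedSFS:
    """Build the folded fractional SFS from SNP records.

    Each SNP contributes its minor-allele count i among m = 2 * (called
    individuals) haplotypes; SNPs with m < n are discarded.  Multi-allelic
    SNPs are skipped (not analyzable).
    """
    masses = np.zeros(n // 2)
    used = discarded = 0
    for snp in snps:
        if getattr(snp, "multiallelic", False):
            continue
        counts = sorted(snp.allele_counts().values(), reverse=True)
        if len(counts) != 2:
            continue
        m = counts[0] + counts[1]
        i = counts[1]  # minor allele
        if m < n:
            discarded += 1
            continue
        used += 1
        masses += fold(projection_weights(i, m, n), n)
    return FoldedSFS(n=n, counts=masses, n_snps_used=used, n_snps_discarded=discarded)


def tajima_constants(n: int) -> dict[str, float]:
    """The Tajima (1989) normalization constants for sample size n."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    a1 = sum(1.0 / k for k in range(1, n))
    a2 = sum(1.0 / k**2 for k in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def theta_pi_from_sfs(sfs: np.ndarray, n: int, folded: bool) -> float:
    """Pairwise diversity from a spectrum: sum of xi_k k (n-k) / C(n,2);
    folding is handled through the k (n-k) symmetry."""
    sfs = np.asarray(sfs, dtype=float)
    pairs = n * (n - 1) / 2.0
    if folded:
        k = np.arange(1, len(sfs) + 1)
        return float((sfs * k * (n - k)).sum() / pairs)
    k = np.arange(1, n)
    return float((sfs * k * (n - k)).sum() / pairs)


def tajimas_d(sfs: np.ndarray, n: int, folded: bool = True) -> float | None:
    """Tajima's D from a fractional spectrum at sample size n.

    theta_pi comes from the spectrum, theta_W = S / a1 with S the total
    mass; fractional S (from hypergeometric projection) is allowed in the
    variance term.  Returns None when S = 0.
    """
    sfs = np.asarray(sfs, dtype=float)
    expected = n // 2 if folded else n - 1
    if len(sfs) != expected:
        raise ValueError(f"spectrum length {len(sfs)} != {expected} for n={n}")
    c = tajima_constants(n)
    S = float(sfs.sum())
    if S <= 0:
        return None
    theta_pi = theta_pi_from_sfs(sfs, n, folded)
    theta_w = S / c["a1"]
    var = c["e1"] * S + c["e2"] * S * (S - 1.0)
    if var <= 0:
        return None
    return (theta_pi - theta_w) / np.sqrt(var)


def neutral_expected_sfs(n: int, theta: float) -> np.ndarray:
    """Idealized neutral (Wright-Fisher equilibrium) unfolded spectrum:
    xi_k = theta / k for k = 1..n-1."""
    if n < 2 or theta <= 0:
        raise ValueError("need n >= 2 and theta > 0")
    return theta / np.arange(1, n)


def fold_unfolded(sfs: np.ndarray, n: int) -> np.ndarray:
    """Fold an unfolded spectrum xi_1..xi_{n-1} into minor-allele classes."""
    full = np.zeros(n + 1)
    full[1:n] = np.asarray(sfs, dtype=float)
    return fold(full, n)


def write_sfs_tsv(spectra: dict[str, FoldedSFS], path) -> None:
    """TSV of one or more folded spectra (e.g. SYN and NONSYN) with their
    Tajima's D values in a trailing comment-free summary block."""
    with open(path, "w") as fh:
        fh.write("spectrum\tclass\tmass\n")
        for name, sfs in spectra.items():
            for c, mass in zip(sfs.classes, sfs.counts):
                fh.write(f"{name}\t{c}\t{mass:.6g}\n")
        fh.write("spectrum\ttajimas_D\tn_snps_used\tn_snps_discarded\n")
        for name, sfs in spectra.items():
            d = tajimas_d(sfs.counts, sfs.n, folded=True)
            d_s = "NA" if d is None else f"{d:.6g}"
            fh.write(f"{name}\t{d_s}\t{sfs.n_snps_used}\t{sfs.n_snps_discarded}\n")
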
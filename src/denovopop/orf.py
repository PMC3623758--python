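"""ORF handling, codon alignments from genotype calls, and cleaning filters.

Called diploid genotypes are expanded into two pseudo-haplotypes per
individual (homozygote: same base twice; heterozygote: the two alleles in
arbitrary order).  This is legitimate here because every downstream
statistic is a function of per-site genotype counts and never of phase.
An optional outgroup sequence, pre-aligned to contig coordinates, is
carried as one extra row for divergence counting.

Cleaning order matters and is fixed: (1) drop codon sites with more than
50% missing states, (2) drop focal haplotypes with more than 50% missing
over the remaining sites, (3) drop the whole alignment if fewer than 10
codon sites remain.  The 50% boundaries are strict (exactly half missing
is kept).  With an outgroup, contigs whose focal ORF is 100 codons or
shorter are dropped before cleaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .counts import BASES
from .genotyper import GenotypeCall

MISSING = "N"
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfAnnotation:
    """0-based half-open ORF span on a contig; length a multiple of 3."""

    contig_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start < 3 or (self.end - self.start) % 3:
            raise ValueError(
                f"ORF [{self.start},{self.end}) on {self.contig_id} is not >= 1 codon "
                "with length a multiple of 3"
            )

    @property
    def n_codons(self) -> int:
        return (self.end - self.start) // 3


@dataclass
class CodonAlignment:
    """Haplotype x nucleotide matrix over an ORF.

    ``haplotypes`` has shape (n_rows, 3 * n_codons) of single characters in
    {A,C,G,T,N}; focal rows come first, the optional outgroup row last.
    ``codon_to_contig`` maps each codon index to the contig coordinate of
    its first base.
    """

    contig_id: str
    haplotypes: np.ndarray = field(repr=False)
    names: list[str] = field(default_factory=list)
    has_outgroup: bool = False
    codon_to_contig: np.ndarray = field(default=None, repr=False)

    @property
    def n_codons(self) -> int:
        return self.haplotypes.shape[1] // 3

    @property
    def focal(self) -> np.ndarray:
        return self.haplotypes[:-1] if self.has_outgroup else self.haplotypes

    @property
    def outgroup(self) -> np.ndarray | None:
        return self.haplotypes[-1] if self.has_outgroup else None

    def codon_missing(self) -> np.ndarray:
        """(n_focal, n_codons) bool: codon state wholly missing if any of
        its three bases is missing."""
        m = self.focal == MISSING
        return m.reshape(m.shape[0], -1, 3).any(axis=2)


def _candidate_orfs(seq: str, frame: int):
    """Maximal stop-terminated codon runs in one frame, as candidate ORFs.

    A run ending in a stop includes the stop codon; a run hitting the end
    of the last complete codon is taken as-is.  Within a run the ORF starts
    at the first ATG when one exists, else the whole run (fallback)."""
    n_codons = (len(seq) - frame) // 3
    run_start = 0
    for c in range(n_codons + 1):
        at_end = c == n_codons
        codon = seq[frame + 3 * c : frame + 3 * c + 3] if not at_end else ""
        if at_end or codon in STOP_CODONS:
            run_end = c if at_end else c + 1  # include the stop codon
            if run_end > run_start:
                atg = None
                for cc in range(run_start, c):
                    if seq[frame + 3 * cc : frame + 3 * cc + 3] == "ATG":
                        atg = cc
                        break
                begin = atg if atg is not None else run_start
                if run_end - begin >= 3:
                    yield frame + 3 * begin, frame + 3 * run_end
            run_start = c + 1


def longest_orf(sequence: str, contig_id: str = "") -> OrfAnnotation | None:
    """Longest ORF over the 3 forward frames.

    Candidates start at the first ATG of their stop-free run when one
    exists (else the whole run, a documented fallback for partial
    transcripts) and end at the stop codon (included) or the last complete
    codon.  Ties go to the leftmost start.  Returns None if no candidate
    reaches 3 codons.
    """
    sequence = sequence.upper()
    if len(sequence) < 9:
        return None
    best: tuple[int, int, int] | None = None  # (-length, start, end)
    for frame in range(3):
        for start, end in _candidate_orfs(sequence, frame):
            key = (-(end - start), start, end)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return OrfAnnotation(contig_id, best[1], best[2])


def build_codon_alignment(
    calls: list[GenotypeCall],
    orf: OrfAnnotation,
    contig_length: int,
    outgroup_sequence: str | None = None,
) -> CodonAlignment:
    """Expand genotype calls over an ORF into pseudo-haplotype rows.

    Sites without a call, or called MISSING, contribute N to both
    haplotypes of that individual.  The outgroup, when given, must be
    pre-aligned to contig coordinates (same length as the contig); gap or
    ambiguous characters become missing.
    """
    if orf.end > contig_length or orf.start < 0:
        raise ValueError(
            f"ORF [{orf.start},{orf.end}) outside contig {orf.contig_id} "
            f"of length {contig_length}"
        )
    inds: list[str] = []
    for c in calls:
        if c.individual not in inds:
            inds.append(c.individual)
    L = orf.end - orf.start
    n_rows = 2 * len(inds) + (1 if outgroup_sequence is not None else 0)
    mat = np.full((n_rows, L), MISSING, dtype="<U1")
    row = {ind: 2 * i for i, ind in enumerate(inds)}
    for c in calls:
        if not (orf.start <= c.site < orf.end) or c.genotype is None:
            continue
        j = c.site - orf.start
        r = row[c.individual]
        mat[r, j] = BASES[c.genotype[0]]
        mat[r + 1, j] = BASES[c.genotype[1]]
    names = [f"{ind}_{h}" for ind in inds for h in (1, 2)]
    if outgroup_sequence is not None:
        if len(outgroup_sequence) != contig_length:
            raise ValueError("outgroup sequence not aligned to contig coordinates")
        og = np.array(list(outgroup_sequence.upper()[orf.start : orf.end]), dtype="<U1")
        og[~np.isin(og, list(BASES))] = MISSING
        mat[-1] = og
        names.append("outgroup")
    return CodonAlignment(
        contig_id=orf.contig_id,
        haplotypes=mat,
        names=names,
        has_outgroup=outgroup_sequence is not None,
        codon_to_contig=np.arange(orf.start, orf.end, 3),
    )


def clean_alignment(
    aln: CodonAlignment,
    with_outgroup: bool = False,
    min_codons: int = 10,
    max_missing: float = 0.5,
    min_orf_codons_with_outgroup: int = 100,
) -> CodonAlignment | None:
    """Apply the missing-data cleaning filters, in order.

    Returns the cleaned alignment, or None when it is dropped (fewer than
    ``min_codons`` codon sites remaining, or outgroup analysis requested on
    an ORF of <= ``min_orf_codons_with_outgroup`` codons).
    """
    if with_outgroup and aln.n_codons <= min_orf_codons_with_outgroup:
        return None
    miss = aln.codon_missing()  # (n_focal, n_codons)
    keep_sites = miss.mean(axis=0) <= max_missing  # strict "above" drops
    miss = miss[:, keep_sites]
    if miss.shape[1] == 0:
        return None
    keep_rows_focal = miss.mean(axis=1) <= max_missing
    if keep_sites.sum() < min_codons or keep_rows_focal.sum() == 0:
        return None
    site_cols = np.repeat(keep_sites, 3)
    keep_rows = (
        np.concatenate([keep_rows_focal, [True]]) if aln.has_outgroup else keep_rows_focal
    )
    return CodonAlignment(
        contig_id=aln.contig_id,
        haplotypes=aln.haplotypes[np.ix_(keep_rows, site_cols)],
        names=[n for n, k in zip(aln.names, keep_rows) if k],
        has_outgroup=aln.has_outgroup,
        codon_to_contig=aln.codon_to_contig[keep_sites],
    )


def complete_biallelic_sites(aln: CodonAlignment) -> list[int]:
    """Nucleotide sites (ORF-relative indices) with no missing focal state
    and at most two distinct bases among focal haplotypes."""
    focal = aln.focal
    out = []
    for j in range(focal.shape[1]):
        col = focal[:, j]
        if (col == MISSING).any():
            continue
        if len(set(col.tolist())) <= 2:
            out.append(j)
    return out


def ds_outlier_filter(
    contig_stats: list, warn=None
) -> list:
    """Drop contigs whose synonymous divergence dS is at least two sample
    standard deviations above the median (dubious orthology/alignment).

    Contigs lacking a dS value pass through untouched.  With fewer than
    three dS values the filter is skipped.
    """
    ds = np.array([s.d_S for s in contig_stats if s.d_S is not None and np.isfinite(s.d_S)])
    if len(ds) < 3:
        if warn is not None:
            warn("dS outlier filter skipped: fewer than 3 contigs with dS")
        return list(contig_stats)
    sd = np.std(ds, ddof=1)
    if sd == 0:  # no spread, no outliers
        return list(contig_stats)
    cutoff = np.median(ds) + 2.0 * sd
    return [
        s
        for s in contig_stats
        if s.d_S is None or not np.isfinite(s.d_S) or s.d_S < cutoff
    ]


def read_orf_bed(path) -> dict[str, OrfAnnotation]:
    """ORF annotations from BED (0-based half-open)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            cid, start, end = parts[0], int(parts[1]), int(parts[2])
            out[cid] = OrfAnnotation(cid, start, end)
    return out


def read_orf_gff3(path) -> dict[str, OrfAnnotation]:
    """ORF annotations from GFF3 CDS lines (1-based closed, converted)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5 or parts[2] not in ("CDS", "ORF"):
                continue
            cid, start, end = parts[0], int(parts[3]) - 1, int(parts[4])
            out[cid] = OrfAnnotation(cid, start, end)
    return out


def write_alignment_fasta(aln: CodonAlignment, path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(aln.names, aln.haplotypes):
            fh.write(f">{name}\n{''.join(row.tolist())}\n")
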
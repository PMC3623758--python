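"""Read-count data model and I/O.

Transcriptome population genomics without a reference genome starts from
reads mapped to de-novo assembled contigs.  Everything downstream of mapping
consumes one object: a per-contig matrix of per-site, per-individual base
counts over (A, C, G, T).  This module defines that matrix, builds it from
simple alignment records or samtools-style text pileup, removes PCR
duplicates, and applies the per-individual mean-coverage contig filter.

Coordinates are 0-based, half-open throughout; only emitted VCF is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class ReadAlignmentRecord:
    """A single mapped read in contig (transcript) space.

    Contigs define the forward strand; no reverse-complement handling.
    ``N`` bases contribute to no base count.
    """

    contig_id: str
    start: int
    sequence: str
    individual_id: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} for read on {self.contig_id}")
        if len(self.sequence) < 1:
            raise ValueError("empty read sequence")


@dataclass
class ContigCountMatrix:
    """site x individual x 4 base counts for one contig.

    ``counts`` has shape ``(length, n_individuals, 4)`` in A, C, G, T order.
    Per-site per-individual coverage is the sum over the last axis.
    """

    contig_id: str
    length: int
    individuals: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        expected = (self.length, len(self.individuals), 4)
        if self.counts.shape != expected:
            raise ValueError(
                f"counts shape {self.counts.shape} != {expected} for {self.contig_id}"
            )
        if (self.counts < 0).any():
            raise ValueError(f"negative count in {self.contig_id}")

    @property
    def coverage(self) -> np.ndarray:
        """Per-site, per-individual coverage, shape (length, n_individuals)."""
        return self.counts.sum(axis=2)


@dataclass
class CoverageReport:
    contig_id: str
    mean_coverage_per_individual: float
    per_individual_coverage: dict[str, float]


def collapse_pcr_duplicates(
    records: list[ReadAlignmentRecord],
) -> list[ReadAlignmentRecord]:
    """Collapse sets of identical reads into a single read.

    Two reads are duplicates when they agree on (contig, individual, start,
    sequence); duplicates are a within-library artifact, so the individual is
    part of the key.  First occurrences are kept in input order.  Idempotent.
    """
    seen: set[tuple[str, str, int, str]] = set()
    out = []
    for r in records:
        key = (r.contig_id, r.individual_id, r.start, r.sequence)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def records_to_counts(
    records: list[ReadAlignmentRecord],
    contig_lengths: dict[str, int],
    individuals: list[str] | None = None,
) -> list[ContigCountMatrix]:
    """Tally retained reads into per-contig count matrices.

    Raises ValueError naming the offending record if a read extends past the
    end of its contig.  ``N`` bases are skipped.
    """
    if individuals is None:
        seen: dict[str, None] = {}
        for r in records:
            seen.setdefault(r.individual_id, None)
        individuals = list(seen)
    ind_index = {ind: i for i, ind in enumerate(individuals)}

    matrices = {
        cid: ContigCountMatrix(
            cid, length, list(individuals), np.zeros((length, len(individuals), 4), dtype=np.int64)
        )
        for cid, length in contig_lengths.items()
    }
    for r in records:
        if r.contig_id not in matrices:
            raise ValueError(f"read on unknown contig {r.contig_id!r}")
        m = matrices[r.contig_id]
        if r.start + len(r.sequence) > m.length:
            raise ValueError(
                f"read exceeds contig bounds: contig={r.contig_id} start={r.start} "
                f"len={len(r.sequence)} contig_length={m.length} individual={r.individual_id}"
            )
        i = ind_index[r.individual_id]
        for offset, base in enumerate(r.sequence):
            b = BASE_INDEX.get(base)
            if b is not None:
                m.counts[r.start + offset, i, b] += 1
    return [matrices[cid] for cid in contig_lengths]


COUNT_TABLE_HEADER = "contig\tpos\tindividual\tnA\tnC\tnG\tnT"


def write_count_table(matrices: list[ContigCountMatrix], path) -> None:
    """Write the TSV count table: one row per (contig, 0-based pos,
    individual) with coverage > 0."""
    with open(path, "w") as fh:
        fh.write(COUNT_TABLE_HEADER + "\n")
        for m in matrices:
            sites, inds = np.nonzero(m.coverage)
            for s, i in zip(sites.tolist(), inds.tolist()):
                c = m.counts[s, i]
                fh.write(f"{m.contig_id}\t{s}\t{m.individuals[i]}\t{c[0]}\t{c[1]}\t{c[2]}\t{c[3]}\n")


def read_count_table(
    path,
    contig_lengths: dict[str, int] | None = None,
    individuals: list[str] | None = None,
) -> list[ContigCountMatrix]:
    """Read the TSV count table back into count matrices.

    Without ``contig_lengths`` the length of each contig is inferred as
    (max position + 1); trailing zero-coverage sites are then unrecoverable,
    so callers wanting exact round-trips should pass lengths explicitly or
    ensure terminal sites are covered.  Individual order defaults to first
    appearance in the file.
    """
    rows: dict[str, list[tuple[int, str, np.ndarray]]] = {}
    seen_inds: dict[str, None] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != COUNT_TABLE_HEADER:
            raise ValueError(f"unexpected count-table header: {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ValueError(f"malformed count-table line {lineno}: {line!r}")
            contig, pos_s, ind = parts[0], parts[1], parts[2]
            try:
                pos = int(pos_s)
                c = np.array([int(x) for x in parts[3:]], dtype=np.int64)
            except ValueError as exc:
                raise ValueError(f"malformed count-table line {lineno}: {line!r}") from exc
            if pos < 0 or (c < 0).any():
                raise ValueError(f"negative value on count-table line {lineno}")
            rows.setdefault(contig, []).append((pos, ind, c))
            seen_inds.setdefault(ind, None)

    if individuals is None:
        individuals = list(seen_inds)
    ind_index = {ind: i for i, ind in enumerate(individuals)}

    out = []
    contigs = list(contig_lengths) if contig_lengths is not None else list(rows)
    for cid in contigs:
        entries = rows.get(cid, [])
        if contig_lengths is not None:
            length = contig_lengths[cid]
        else:
            length = max(pos for pos, _, _ in entries) + 1 if entries else 0
        counts = np.zeros((length, len(individuals), 4), dtype=np.int64)
        for pos, ind, c in entries:
            if pos >= length:
                raise ValueError(f"position {pos} beyond length {length} of {cid}")
            counts[pos, ind_index[ind]] = c
        out.append(ContigCountMatrix(cid, length, list(individuals), counts))
    return out


def coverage_report(matrix: ContigCountMatrix) -> CoverageReport:
    """Average coverage = total length of mapped reads / contig length,
    reported per individual and as the across-individual mean."""
    if matrix.length == 0:
        raise ValueError(f"zero-length contig {matrix.contig_id}")
    per_ind = matrix.coverage.sum(axis=0) / matrix.length
    return CoverageReport(
        contig_id=matrix.contig_id,
        mean_coverage_per_individual=float(per_ind.mean()) if len(per_ind) else 0.0,
        per_individual_coverage={
            ind: float(x) for ind, x in zip(matrix.individuals, per_ind)
        },
    )


def filter_low_coverage_contigs(
    matrices: list[ContigCountMatrix],
    min_mean_coverage_per_individual: float = 2.5,
) -> tuple[list[ContigCountMatrix], list[CoverageReport]]:
    """Discard contigs less covered than the per-individual mean threshold.

    The boundary is inclusive: a contig at exactly the threshold is retained.
    Reports are emitted for all contigs, retained or not.
    """
    reports = [coverage_report(m) for m in matrices]
    retained = [
        m
        for m, rep in zip(matrices, reports)
        if rep.mean_coverage_per_individual >= min_mean_coverage_per_individual
    ]
    return retained, reports


def parse_pileup(path, individual_id: str) -> list[tuple[str, int, str, np.ndarray]]:
    """Adapter from samtools-style 6-column text pileup for one individual.

    Returns (contig, 0-based pos, individual, counts4) tuples.  Indel marks
    (``+n<seq>``/``-n<seq>``), read starts (``^X``), read ends (``$``),
    deletions (``*``/``#``) and reference skips (``<``/``>``) are skipped;
    ``.``/``,`` count as the reference base; ``N`` is ignored.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"malformed pileup line {lineno}: {line!r}")
            contig, pos_s, ref, _depth, bases = parts[:5]
            pos = int(pos_s) - 1  # pileup is 1-based
            ref = ref.upper()
            counts = np.zeros(4, dtype=np.int64)
            i = 0
            while i < len(bases):
                ch = bases[i]
                if ch == "^":
                    i += 2  # mapping-quality character follows
                    continue
                if ch == "$":
                    i += 1
                    continue
                if ch in "+-":
                    i += 1
                    num = ""
                    while i < len(bases) and bases[i].isdigit():
                        num += bases[i]
                        i += 1
                    i += int(num)  # skip inserted/deleted sequence
                    continue
                if ch in ".,":
                    b = BASE_INDEX.get(ref)
                    if b is not None:
                        counts[b] += 1
                elif ch.upper() in BASE_INDEX:
                    counts[BASE_INDEX[ch.upper()]] += 1
                # '*', '#', '<', '>', 'N', 'n' fall through: no count
                i += 1
            out.append((contig, pos, individual_id, counts))
    return out


def pileup_to_count_table(pileup_paths: dict[str, str], out_path) -> None:
    """Convert per-individual pileup files into the count-table TSV.

    ``pileup_paths`` maps individual id -> pileup file path.
    """
    with open(out_path, "w") as fh:
        fh.write(COUNT_TABLE_HEADER + "\n")
        for ind, path in pileup_paths.items():
            for contig, pos, ind_id, c in parse_pileup(path, ind):
                if c.sum() > 0:
                    fh.write(f"{contig}\t{pos}\t{ind_id}\t{c[0]}\t{c[1]}\t{c[2]}\t{c[3]}\n")


def read_fasta(path) -> dict[str, str]:
    """Read contig sequences (wrapped or unwrapped), uppercased."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise ValueError("FASTA sequence before first header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
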
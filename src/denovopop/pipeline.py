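"""End-to-end pipeline: counts -> genotypes -> paralog filter -> statistics.

Stage order is fixed: duplicate collapsing (when starting from reads),
count matrices, 2.5X contig coverage filter, per-contig error-rate
estimation, genotype calling, paralogy LRT, ORF/codon alignment,
missing-data cleaning, SNP synonymy classification, per-contig and
species statistics, SFS projection.  Every stage logs its input/output
record counts; identical configuration and seed give identical artifacts.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import counts as cio
from . import genotyper as gt
from . import orf as orfmod
from . import paralog as par
from . import popgen as pg
from . import sfs as sfsmod

log = logging.getLogger("denovopop")


@dataclass
class PipelineConfig:
    min_contig_coverage: float = 2.5
    min_coverage: int = 10
    posterior_threshold: float = 0.95
    mode: str = "threshold"
    paralog_alpha: float = 0.001
    paralog_filter: bool = True
    maf_cutoff: float = 0.2
    projection_n: int = 12
    n_bootstrap: int = 1000
    seed: int = 0
    ds_outlier_filter: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


@dataclass
class PipelineResult:
    contig_stats: list = field(default_factory=list)
    summary: pg.SpeciesSummary | None = None
    snps: list = field(default_factory=list)
    flagged_snps: list = field(default_factory=list)
    paralog_results: list = field(default_factory=list)
    sfs: dict = field(default_factory=dict)
    error_models: dict = field(default_factory=dict)
    calls_by_contig: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)


def run_pipeline(
    matrices: list[cio.ContigCountMatrix],
    config: PipelineConfig | None = None,
    sequences: dict[str, str] | None = None,
    orfs: dict[str, orfmod.OrfAnnotation] | None = None,
    outgroups: dict[str, str] | None = None,
) -> PipelineResult:
    """Run every stage from count matrices onward.

    ``orfs`` defaults to the longest ORF of each contig sequence; contigs
    with neither an annotation nor a sequence are analyzed as non-coding
    (genotypes and SNPs only, no synonymy statistics).
    """
    config = config or PipelineConfig()
    res = PipelineResult()
    counts_log = res.stage_counts
    counts_log["input_contigs"] = len(matrices)

    matrices, _reports = cio.filter_low_coverage_contigs(
        matrices, config.min_contig_coverage
    )
    counts_log["contigs_after_coverage_filter"] = len(matrices)
    log.info("coverage filter: %d contigs retained", len(matrices))

    orfs = dict(orfs) if orfs else {}
    if sequences:
        for cid, seq in sequences.items():
            if cid not in orfs:
                o = orfmod.longest_orf(seq, cid)
                if o is not None:
                    orfs[cid] = o

    caller = gt.CallerConfig(
        posterior_threshold=config.posterior_threshold,
        min_coverage=config.min_coverage,
        mode=config.mode,
        rng_seed=config.seed,
    )

    all_snps: list[gt.SNPRecord] = []
    snps_by_contig: dict[str, list[gt.SNPRecord]] = {}
    for m in matrices:
        model, freqs = gt.estimate_error_rate(m)
        res.error_models[m.contig_id] = model
        calls = gt.call_genotypes(m, model, freqs, caller)
        res.calls_by_contig[m.contig_id] = calls
        snps = gt.identify_snps(calls, m.contig_id)
        snps_by_contig[m.contig_id] = snps
        all_snps.extend(snps)
    counts_log["snps_called"] = len(all_snps)
    log.info("genotyping: %d candidate SNPs", len(all_snps))

    by_cid = {m.contig_id: m for m in matrices}
    if config.paralog_filter:
        for snp in all_snps:
            if snp.multiallelic:
                continue
            data = par.site_data_from_counts(
                snp, by_cid[snp.contig_id].counts, by_cid[snp.contig_id].individuals
            )
            r = par.paralog_lrt(
                data, res.error_models[snp.contig_id].epsilon, config.paralog_alpha
            )
            res.paralog_results.append(r)
        retained, flagged = par.apply_filter(all_snps, res.paralog_results)
    else:
        retained, flagged = list(all_snps), []
    res.snps, res.flagged_snps = retained, flagged
    counts_log["snps_after_paralog_filter"] = len(retained)
    counts_log["snps_flagged_paralog"] = len(flagged)
    log.info("paralog filter: %d flagged, %d retained", len(flagged), len(retained))

    retained_by_contig = {}
    for snp in retained:
        retained_by_contig.setdefault(snp.contig_id, []).append(snp)

    stats: list[pg.ContigStats] = []
    analyzable_by_contig: dict[str, list[gt.SNPRecord]] = {}
    for m in matrices:
        orf = orfs.get(m.contig_id)
        if orf is None:
            continue
        outgroup = outgroups.get(m.contig_id) if outgroups else None
        aln = orfmod.build_codon_alignment(
            res.calls_by_contig[m.contig_id], orf, m.length, outgroup
        )
        aln = orfmod.clean_alignment(aln, with_outgroup=outgroup is not None)
        if aln is None:
            continue
        complete = orfmod.complete_biallelic_sites(aln)
        codons = pg.consensus_codons(aln)
        L_S, L_N = pg.syn_nonsyn_site_counts(aln, codons)
        snps = pg.classify_alignment_snps(
            aln, retained_by_contig.get(m.contig_id, []), complete, codons
        )
        analyzable_by_contig[m.contig_id] = snps
        pi_S, pi_N, p_S, p_N = pg.contig_diversity(aln, snps, L_S, L_N)
        d_S = d_N = None
        dSc = dNc = 0
        if aln.has_outgroup:
            d_S, d_N, dSc, dNc = pg.fixed_differences(aln, complete, L_S, L_N, codons)
        stats.append(
            pg.ContigStats(
                contig_id=m.contig_id,
                length=len(complete),
                L_S=L_S,
                L_N=L_N,
                pi_S=pi_S,
                pi_N=pi_N,
                F_IS=pg.fis(snps),
                p_S=p_S,
                p_N=p_N,
                d_S=d_S,
                d_N=d_N,
                d_S_count=dSc,
                d_N_count=dNc,
                n_snps=len([s for s in snps if s.synonymy in (pg.SYN, pg.NONSYN)]),
            )
        )
    counts_log["contigs_analyzed"] = len(stats)

    if config.ds_outlier_filter:
        stats = orfmod.ds_outlier_filter(stats, warn=log.warning)
        counts_log["contigs_after_ds_filter"] = len(stats)
    res.contig_stats = stats

    if len(stats) >= 2:
        res.summary = pg.species_summary(
            stats,
            analyzable_by_contig,
            n_bootstrap=config.n_bootstrap,
            seed=config.seed,
            maf_cutoff=config.maf_cutoff,
        )

    analyzed = [s for c in analyzable_by_contig.values() for s in c]
    syn = [s for s in analyzed if s.synonymy == pg.SYN]
    nonsyn = [s for s in analyzed if s.synonymy == pg.NONSYN]
    res.sfs = {
        "SYN": sfsmod.project_and_fold(syn, config.projection_n),
        "NONSYN": sfsmod.project_and_fold(nonsyn, config.projection_n),
    }
    counts_log["snps_analyzed"] = len(analyzed)
    return res


def write_artifacts(
    res: PipelineResult,
    outdir,
    contig_lengths: dict[str, int],
) -> dict[str, str]:
    """Write VCF, stats/SFS/paralog TSVs and the JSON run summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": str(outdir / "snps.vcf"),
        "contig_stats": str(outdir / "contig_stats.tsv"),
        "species_summary": str(outdir / "species_summary.tsv"),
        "sfs": str(outdir / "sfs.tsv"),
        "paralog": str(outdir / "paralog_tests.tsv"),
        "run_summary": str(outdir / "run_summary.json"),
    }
    gt.write_vcf(
        res.snps + res.flagged_snps, res.error_models, contig_lengths, paths["vcf"]
    )
    pg.write_contig_stats_tsv(res.contig_stats, paths["contig_stats"])
    if res.summary is not None:
        pg.write_species_summary_tsv(res.summary, paths["species_summary"])
    sfsmod.write_sfs_tsv(res.sfs, paths["sfs"])
    par.write_results_tsv(res.paralog_results, paths["paralog"])
    with open(paths["run_summary"], "w") as fh:
        json.dump(res.stage_counts, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
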
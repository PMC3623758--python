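"""Shared fixtures: simulated datasets with known truth.

The heavier end-to-end fixtures are session-scoped so that several
acceptance checks (error-rate recovery, genotype accuracy, F_IS, SFS)
share one genotyping pass.
"""

from __future__ import annotations

import numpy as np
import pytest

from denovopop import genotyper as gt
from denovopop import paralog as par
from denovopop import simulate as sim


@pytest.fixture(scope="session")
def neutral10x():
    """The neutral 10X scenario (10 individuals, 200 contigs x 201 sites,
    eps = 0.005, theta = 0.01) genotyped contig by contig."""
    cfg = sim.preset("neutral-10x")
    matrices, truth = sim.simulate_dataset(cfg)
    fits = {}
    calls = {}
    snps = {}
    for m in matrices:
        model, freqs = gt.estimate_error_rate(m)
        fits[m.contig_id] = (model, freqs)
        c = gt.call_genotypes(m, model, freqs)
        calls[m.contig_id] = c
        snps[m.contig_id] = gt.identify_snps(c, m.contig_id)
    return {
        "config": cfg,
        "matrices": matrices,
        "truth": truth,
        "fits": fits,
        "calls": calls,
        "snps": snps,
    }


@pytest.fixture(scope="session")
def paralog_mix():
    """The paralog-mix scenario (20% of contigs carry one collapsed
    fixed-difference site at p = 0.5) genotyped and LRT-tested."""
    cfg = sim.preset("paralog-mix")
    matrices, truth = sim.simulate_dataset(cfg)
    all_snps = []
    results = []
    for m in matrices:
        model, freqs = gt.estimate_error_rate(m)
        calls = gt.call_genotypes(m, model, freqs)
        for snp in gt.identify_snps(calls, m.contig_id):
            all_snps.append(snp)
            if snp.multiallelic:
                continue
            data = par.site_data_from_counts(snp, m.counts, m.individuals)
            results.append(par.paralog_lrt(data, model.epsilon, alpha=0.001))
    return {
        "config": cfg,
        "matrices": matrices,
        "truth": truth,
        "snps": all_snps,
        "results": results,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
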
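"""Diversity, F_IS, synonymy classification, MK statistics, distances."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from denovopop import popgen as pg
from denovopop.genotyper import SNPRecord
from denovopop.orf import CodonAlignment


def snp(genotypes, site=0, alleles=(0, 1), synonymy=None, maf=None, contig="c"):
    gdict = {f"i{j}": g for j, g in enumerate(genotypes)}
    rec = SNPRecord(contig, site, alleles, gdict,
                    sum(1 for g in genotypes if g is None))
    rec.synonymy = synonymy
    if maf is None:
        counts = rec.allele_counts()
        if len(counts) == 2:
            rec.maf = min(counts.values()) / sum(counts.values())
    else:
        rec.maf = maf
    return rec


class TestSitePi:
    @pytest.mark.parametrize(
        "n1,n2,expect", [(10, 10, 100 / 190), (1, 19, 0.1), (5, 0, 0.0)]
    )
    def test_worked_values(self, n1, n2, expect):
        assert pg.site_pi(n1, n2) == pytest.approx(expect)

    @given(n1=st.integers(0, 15), n2=st.integers(0, 15))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_equals_pair_enumeration(self, n1, n2):
        if n1 + n2 < 2:
            with pytest.raises(ValueError):
                pg.site_pi(n1, n2)
            return
        haps = [0] * n1 + [1] * n2
        pairs = list(itertools.combinations(haps, 2))
        oracle = sum(a != b for a, b in pairs) / len(pairs)
        assert pg.site_pi(n1, n2) == pytest.approx(oracle)


class TestClassifySnp:
    @pytest.mark.parametrize(
        "codon,pos,alleles,expect",
        [
            ("GGA", 2, ("A", "G"), pg.SYN),      # Gly <-> Gly
            ("AAA", 0, ("A", "G"), pg.NONSYN),   # Lys <-> Glu
            ("TAC", 2, ("C", "A"), pg.EXCLUDED), # TAA is a stop
            ("GNA", 2, ("A", "G"), pg.EXCLUDED), # ambiguous context
        ],
    )
    def test_rules(self, codon, pos, alleles, expect):
        assert pg.classify_snp(codon, pos, alleles) == expect


class TestSiteCounts:
    def _aln(self, seq):
        mat = np.array([list(seq), list(seq)], dtype="<U1")
        return CodonAlignment("c", mat, ["a", "b"], False, np.arange(0, len(seq), 3))

    def test_ggg_codon(self):
        # enumeration: 3rd-position changes all Gly (syn); 1st/2nd all nonsyn
        L_S, L_N = pg.syn_nonsyn_site_counts(self._aln("GGG"))
        assert L_S == pytest.approx(1.0)
        assert L_N == pytest.approx(2.0)

    def test_atg_has_no_synonym(self):
        L_S, L_N = pg.syn_nonsyn_site_counts(self._aln("ATG"))
        assert L_S == 0.0
        assert L_N == 3.0

    def test_additivity_over_codons(self):
        L_S, L_N = pg.syn_nonsyn_site_counts(self._aln("GGG" * 100))
        assert L_S == pytest.approx(100.0)
        assert L_N == pytest.approx(200.0)


class TestFis:
    def test_all_het_complete_excess(self):
        snps = [snp([(0, 1)] * 10)]
        assert pg.fis(snps) == pytest.approx(-1.0)

    def test_all_hom_complete_deficit(self):
        snps = [snp([(0, 0)] * 5 + [(1, 1)] * 5)]
        assert pg.fis(snps) == pytest.approx(1.0)

    def test_hwe_simulation_near_zero(self, rng):
        snps = []
        n_ind = 10
        for s in range(500):
            p = rng.uniform(0.1, 0.9)
            gts = []
            for _ in range(n_ind):
                a, b = rng.random(2) < p
                gts.append(tuple(sorted((int(not a), int(not b)))))
            rec = snp(gts, site=s)
            if len(rec.allele_counts()) == 2:
                snps.append(rec)
        # the plug-in Hexp makes the HWE expectation -1/(2n-1), not 0
        bias = -1 / (2 * n_ind - 1)
        assert pg.fis(snps) == pytest.approx(bias, abs=0.04)
        assert abs(pg.fis(snps, corrected=True)) < 0.04


class TestHeterozygosity:
    def test_proportions(self):
        from denovopop.genotyper import GenotypeCall

        calls = [GenotypeCall(s, "i1", (0, 0), 1.0, 20) for s in range(998)]
        calls += [GenotypeCall(998, "i1", (0, 1), 1.0, 20),
                  GenotypeCall(999, "i1", (0, 2), 1.0, 20)]
        calls += [GenotypeCall(0, "i2", None, 0.5, 3)]
        het = pg.per_individual_heterozygosity(calls)
        assert het["i1"] == pytest.approx(0.002)
        assert het["i2"] is None


class TestFixedDifferences:
    def _aln(self, focal_seq, out_seq):
        rows = [list(focal_seq), list(focal_seq), list(out_seq)]
        mat = np.array(rows, dtype="<U1")
        return CodonAlignment("c", mat, ["a", "b", "outgroup"], True,
                              np.arange(0, len(focal_seq), 3))

    def test_synonymous_fixed_difference(self):
        # GGA -> GGG third position: both Gly
        aln = self._aln("GGA", "GGG")
        d_S, d_N, dS, dN = pg.fixed_differences(aln, [0, 1, 2], 1.0, 2.0)
        assert (dS, dN) == (1, 0)
        assert d_S == pytest.approx(1.0)

    def test_nonsynonymous_fixed_difference(self):
        aln = self._aln("AAA", "GAA")  # Lys -> Glu
        _, _, dS, dN = pg.fixed_differences(aln, [0, 1, 2], 1.0, 2.0)
        assert (dS, dN) == (0, 1)

    def test_polymorphic_site_not_fixed(self):
        rows = [list("GGA"), list("GGG"), list("GGG")]
        mat = np.array(rows, dtype="<U1")
        aln = CodonAlignment("c", mat, ["a", "b", "outgroup"], True, np.array([0]))
        _, _, dS, dN = pg.fixed_differences(aln, [0, 1, 2], 1.0, 2.0)
        assert (dS, dN) == (0, 0)

    def test_requires_outgroup(self):
        mat = np.array([list("AAA")], dtype="<U1")
        aln = CodonAlignment("c", mat, ["a"], False, np.array([0]))
        with pytest.raises(ValueError):
            pg.fixed_differences(aln, [0], 1.0, 2.0)


class TestNeutralityIndices:
    def test_worked_example(self):
        r = pg.neutrality_indices(10, 20, 5, 40)
        assert r["NI"] == pytest.approx(4.0)
        assert r["alpha"] == pytest.approx(-3.0)

    def test_neutral_expectation(self):
        r = pg.neutrality_indices(5, 10, 20, 40)
        assert r["NI"] == pytest.approx(1.0)
        assert r["alpha"] == pytest.approx(0.0)

    def test_omega_a_formula(self):
        # alpha = 0.43 with dN/dS = 0.17 gives omega_a = 0.0731
        r = pg.neutrality_indices(969, 10000, 17, 100)
        assert r["alpha"] == pytest.approx(0.43)
        assert r["omega_a"] == pytest.approx(0.0731, abs=1e-6)

    def test_zero_denominators_give_none(self):
        r = pg.neutrality_indices(10, 0, 5, 40)
        assert r["NI"] is None and r["alpha"] is None
        r = pg.neutrality_indices(10, 20, 5, 0)
        assert r["NI"] is None

    def test_maf_cutoff_recomputes_polymorphism_only(self):
        snps = [
            snp([(0, 1)] + [(0, 0)] * 9, site=0, synonymy=pg.NONSYN),  # maf 0.05
            snp([(1, 1)] * 4 + [(0, 0)] * 6, site=1, synonymy=pg.NONSYN),  # maf 0.4
            snp([(1, 1)] * 4 + [(0, 0)] * 6, site=2, synonymy=pg.SYN),
        ]
        r = pg.neutrality_indices(2, 1, 10, 10, snps, maf_cutoff=0.2)
        assert r["NI"] == pytest.approx(2.0)
        assert r["NI_02"] == pytest.approx(1.0)  # low-MAF NONSYN dropped


class TestSpeciesSummary:
    def _stats(self):
        return [
            pg.ContigStats("c1", 100, 100, 200, 0.01, 0.001, 0.0, 2, 1, n_snps=3),
            pg.ContigStats("c2", 300, 300, 600, 0.02, 0.002, 0.0, 6, 3, n_snps=9),
        ]

    def test_weighted_mean(self):
        s = pg.species_summary(self._stats(), n_bootstrap=10, seed=0)
        assert s.mean_pi_S == pytest.approx(0.0175)

    def test_identical_contigs_zero_width_ci(self):
        stats = [
            pg.ContigStats(f"c{i}", 100, 100, 200, 0.01, 0.001, 0.0, 2, 1, n_snps=3)
            for i in range(4)
        ]
        s = pg.species_summary(stats, n_bootstrap=50, seed=0)
        lo, hi = s.ci["mean_pi_S"]
        assert lo == hi == pytest.approx(0.01)

    def test_bootstrap_seeded_reproducible(self):
        a = pg.species_summary(self._stats(), n_bootstrap=100, seed=42)
        b = pg.species_summary(self._stats(), n_bootstrap=100, seed=42)
        assert a.ci == b.ci

    def test_weighted_pi_equals_pooled_per_site_pi(self, rng):
        """Conservation: the L_S-weighted mean of per-contig pi_S equals the
        globally pooled sum(site pi)/sum(L_S)."""
        stats = []
        total_pi = total_ls = 0.0
        for i in range(20):
            ls = rng.uniform(30, 120)
            pis = rng.uniform(0, 0.03)
            stats.append(
                pg.ContigStats(f"c{i}", 100, ls, 2 * ls, pis, 0.0, 0.0, 1, 0, n_snps=1)
            )
            total_pi += pis * ls
            total_ls += ls
        s = pg.species_summary(stats, n_bootstrap=2, seed=0)
        assert s.mean_pi_S == pytest.approx(total_pi / total_ls)


class TestPairwiseDistance:
    def test_shared_het_site(self):
        snps = [snp([(0, 1), (0, 1)])]
        assert pg.pairwise_genetic_distance("i0", "i1", snps) == pytest.approx(-0.5)

    def test_identical_homozygotes(self):
        snps = [snp([(0, 0), (0, 0)], site=s) for s in range(3)]
        assert pg.pairwise_genetic_distance("i0", "i1", snps) == 0.0

    def test_hom_diff_plus_het_site(self):
        snps = [
            snp([(0, 0), (1, 1)], site=0),  # Hb = 1, Hw = 0
            snp([(0, 1), (0, 1)], site=1),  # Hb = 0.5, Hw = 1
        ]
        assert pg.pairwise_genetic_distance("i0", "i1", snps) == pytest.approx(0.5)

    def test_no_shared_sites_undefined(self):
        snps = [snp([(0, 0), None])]
        assert pg.pairwise_genetic_distance("i0", "i1", snps) is None

    def test_matrix_symmetric(self):
        snps = [snp([(0, 1), (0, 0), (1, 1)], site=s) for s in range(4)]
        m = pg.distance_matrix(["i0", "i1", "i2"], snps)
        assert np.allclose(m, m.T, equal_nan=True)

    def test_matrix_tsv_writer(self, tmp_path):
        snps = [snp([(0, 1), (0, 0)], site=s) for s in range(3)]
        path = tmp_path / "dist.tsv"
        pg.write_distance_matrix_tsv(["i0", "i1"], snps, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "individual\ti0\ti1"
        assert len(lines) == 3
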
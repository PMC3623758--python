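"""Genotype likelihoods, frequency EM, error-rate ML, posterior calling."""

import numpy as np
import pytest
from scipy.special import gammaln, logsumexp

from denovopop import counts as cio
from denovopop import genotyper as gt
from denovopop import simulate as sim


def idx(name):
    return gt.GENOTYPE_NAMES.index(name)


class TestGenotypeLogLikelihoods:
    def test_no_error_limit(self):
        ll = gt.genotype_log_likelihoods(np.array([10, 0, 0, 0]), 0.0)
        assert np.exp(ll[idx("AA")]) == pytest.approx(1.0)
        assert np.exp(ll[idx("AC")]) == pytest.approx(0.5**10)
        assert ll[idx("CC")] == -np.inf

    def test_balanced_het_example(self):
        ll = gt.genotype_log_likelihoods(np.array([5, 5, 0, 0]), 0.01)
        m_het = (1 - 2 * 0.01 / 3) / 2
        assert np.exp(ll[idx("AC")]) == pytest.approx(m_het**10, rel=1e-9)
        assert np.exp(ll[idx("AA")]) == pytest.approx(
            0.99**5 * (0.01 / 3) ** 5, rel=1e-9
        )

    def test_zero_coverage_all_equal(self):
        ll = gt.genotype_log_likelihoods(np.zeros(4), 0.01)
        assert np.allclose(ll, ll[0])

    def test_epsilon_out_of_range(self):
        with pytest.raises(ValueError):
            gt.genotype_log_likelihoods(np.array([1, 0, 0, 0]), 0.8)

    def test_posterior_invariant_to_multinomial_coefficient(self, rng):
        """Omitting the multinomial coefficient cannot change posteriors:
        adding it back (constant across genotypes) gives identical values."""
        counts = rng.integers(0, 8, size=4)
        ll = gt.genotype_log_likelihoods(counts, 0.01)
        n = counts.sum()
        coef = gammaln(n + 1) - gammaln(counts + 1).sum()
        for logprior in (np.zeros(10), np.log(np.full(10, 0.1))):
            a = logprior + ll
            b = logprior + ll + coef
            pa = np.exp(a - logsumexp(a))
            pb = np.exp(b - logsumexp(b))
            assert np.allclose(pa, pb)


def _site_loglik_oracle(site_counts, freqs, eps):
    """Direct evaluation of the site likelihood for the grid-search oracle."""
    ll = 0.0
    for c in site_counts:
        if c.sum() == 0:
            continue
        terms = []
        for g, (x, y) in enumerate(gt.GENOTYPE_PAIRS):
            prior = freqs[x] * freqs[y] * (1 if x == y else 2)
            terms.append(np.log(max(prior, 1e-300)) + gt.genotype_log_likelihoods(c, eps)[g])
        ll += logsumexp(terms)
    return ll


class TestSiteFrequencies:
    def test_monomorphic(self):
        counts = np.tile(np.array([20, 0, 0, 0]), (10, 1))
        f = gt.estimate_site_frequencies(counts, 0.001)
        assert f.freqs[0] > 0.999

    def test_balanced_two_allele_site(self):
        counts = np.array([[20, 0, 0, 0]] * 5 + [[0, 20, 0, 0]] * 5)
        f = gt.estimate_site_frequencies(counts, 0.005)
        assert f.freqs[0] == pytest.approx(0.5, abs=0.02)
        assert f.freqs[1] == pytest.approx(0.5, abs=0.02)

    def test_single_het_individual_matches_grid_oracle(self):
        """EM fixed point for counts (3,3,0,0) agrees with an exhaustive 1-D
        grid search of the site likelihood over f_A (f_C = 1 - f_A)."""
        counts = np.array([[3, 3, 0, 0]])
        f = gt.estimate_site_frequencies(counts, 0.01)
        grid = np.linspace(0, 1, 2001)
        lls = [
            _site_loglik_oracle(counts, np.array([fa, 1 - fa, 0, 0]), 0.01)
            for fa in grid
        ]
        f_star = grid[int(np.argmax(lls))]
        assert f.freqs[0] == pytest.approx(f_star, abs=1e-3)
        assert f.freqs[0] == pytest.approx(0.5, abs=1e-3)

    def test_all_zero_coverage_flagged(self):
        f = gt.estimate_site_frequencies(np.zeros((4, 4)), 0.01)
        assert not f.informative
        assert np.allclose(f.freqs, 0.25)


class TestErrorRate:
    def _hom_matrix(self, match, mismatch, sites=60, n_ind=5):
        """Every site/individual: `match` A reads + `mismatch` spread over CGT."""
        counts = np.zeros((sites, n_ind, 4), dtype=np.int64)
        counts[:, :, 0] = match
        for s in range(sites):
            for i in range(n_ind):
                b = 1 + (s + i) % 3
                counts[s, i, b] = mismatch
        return cio.ContigCountMatrix("c", sites, [f"i{k}" for k in range(n_ind)], counts)

    def test_homozygous_mismatch_fraction_recovers_epsilon(self):
        model, _ = gt.estimate_error_rate(self._hom_matrix(99, 1))
        assert model.epsilon == pytest.approx(0.01, abs=0.002)

    def test_no_mismatches_gives_zero_boundary(self):
        model, _ = gt.estimate_error_rate(self._hom_matrix(50, 0))
        assert model.epsilon < 1e-6

    def test_zero_informative_sites_error(self):
        m = cio.ContigCountMatrix("c", 5, ["i1"], np.zeros((5, 1, 4), dtype=int))
        with pytest.raises(ValueError, match="informative"):
            gt.estimate_error_rate(m)

    def test_invariant_to_relabeling_and_site_order(self, rng):
        cfg = sim.SimulationConfig(n_contigs=1, contig_length=60, rng_seed=7)
        (m,), _ = sim.simulate_dataset(cfg)
        model, _ = gt.estimate_error_rate(m)
        perm_i = rng.permutation(len(m.individuals))
        perm_s = rng.permutation(m.length)
        shuffled = cio.ContigCountMatrix(
            "c", m.length, [m.individuals[i] for i in perm_i],
            m.counts[np.ix_(perm_s, perm_i)],
        )
        model2, _ = gt.estimate_error_rate(shuffled)
        assert model2.epsilon == pytest.approx(model.epsilon, abs=1e-6)


class TestCallGenotypes:
    def _single_site_matrix(self, counts4):
        counts = np.asarray(counts4, dtype=np.int64).reshape(1, 1, 4)
        return cio.ContigCountMatrix("c", 1, ["i1"], counts)

    def _call(self, counts4, eps, freqs, **cfg):
        m = self._single_site_matrix(counts4)
        model = gt.ErrorModel("c", eps, 0.0)
        config = gt.CallerConfig(**cfg) if cfg else gt.CallerConfig()
        return gt.call_genotypes(m, model, np.array([freqs], dtype=float), config)[0]

    def test_balanced_het_called(self):
        c = self._call([5, 5, 0, 0], 0.01, [0.5, 0.5, 0, 0], min_coverage=10)
        assert c.genotype == (0, 1)
        assert c.best_posterior > 0.999

    def test_ambiguous_posterior_below_threshold_is_missing(self):
        c = self._call([12, 1, 0, 0], 0.001, [0.9, 0.1, 0, 0], min_coverage=10)
        assert c.genotype is None
        assert c.best_posterior == pytest.approx(0.925, abs=0.005)

    def test_low_coverage_missing(self):
        c = self._call([9, 0, 0, 0], 0.001, [1.0, 0, 0, 0], min_coverage=10)
        assert c.genotype is None
        assert c.coverage == 9

    def test_sample_mode_reproducible(self):
        kwargs = dict(mode="sample", rng_seed=7, min_coverage=1)
        a = self._call([3, 3, 0, 0], 0.01, [0.5, 0.5, 0, 0], **kwargs)
        b = self._call([3, 3, 0, 0], 0.01, [0.5, 0.5, 0, 0], **kwargs)
        assert a.genotype == b.genotype

    def test_zero_error_truth_recovered_exactly(self):
        cfg = sim.SimulationConfig(
            n_contigs=2, contig_length=90, epsilon_true=0.0,
            mean_coverage=20, rng_seed=3,
        )
        matrices, truth = sim.simulate_dataset(cfg)
        for m in matrices:
            model, freqs = gt.estimate_error_rate(m)
            calls = gt.call_genotypes(m, model, freqs, gt.CallerConfig(min_coverage=5))
            g = truth.genotypes[m.contig_id]
            for c in calls:
                if c.genotype is None:
                    continue
                i = m.individuals.index(c.individual)
                true = tuple(sorted(g[c.site, i].tolist()))
                if true[0] == true[1]:
                    assert c.genotype == true
                else:
                    # het recovered whenever both alleles were observed
                    obs = set(np.nonzero(m.counts[c.site, i])[0].tolist())
                    if set(true) <= obs:
                        assert c.genotype == true


class TestIdentifySNPs:
    def _calls(self, genotypes):
        return [
            gt.GenotypeCall(0, f"i{j}", g, 0.99, 20)
            for j, g in enumerate(genotypes)
        ]

    def test_monomorphic_not_snp(self):
        assert gt.identify_snps(self._calls([(0, 0)] * 10), "c") == []

    def test_single_het_is_snp(self):
        snps = gt.identify_snps(self._calls([(0, 0)] * 9 + [(0, 1)]), "c")
        assert len(snps) == 1
        assert snps[0].alleles == (0, 1)
        assert min(snps[0].allele_counts().values()) == 1
        assert not snps[0].multiallelic

    def test_three_alleles_flagged_multiallelic(self):
        snps = gt.identify_snps(self._calls([(0, 0), (1, 1), (2, 2)]), "c")
        assert snps[0].multiallelic
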
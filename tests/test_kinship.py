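"""Pair-genotype probabilities, likelihood ratios, and the sibling simulator."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from kinlr.kinship import (
    SIBLING,
    UNRELATED,
    LRRecord,
    RelatednessCoefficients,
    floor_frequencies,
    pair_genotype_log_probability,
    relationship_log_lr,
    simulate_relative,
)

from _oracles import enumerate_pair_probabilities

HALF = {1: 0.5, 2: 0.5}
QUARTERS = {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}
THREE = {1: 0.5, 2: 0.3, 3: 0.2}


class TestPairProbability:
    @pytest.mark.parametrize(
        "g1, g2, delta, freqs, expected",
        [
            # Hardy-Weinberg product for unrelated matching homozygotes: p^4
            ((1, 1), (1, 1), UNRELATED, HALF, 0.0625),
            # four distinct alleles under the sibling hypothesis: 1/4 * 4*p1p2p3p4
            ((1, 2), (3, 4), SIBLING, QUARTERS, 0.00390625),
        ],
    )
    def test_theta_zero_closed_forms(self, g1, g2, delta, freqs, expected):
        log_p = pair_genotype_log_probability(g1, g2, delta, 0.0, freqs)
        assert math.exp(log_p) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("theta", [0.0, 0.01, 0.05])
    @pytest.mark.parametrize(
        "delta",
        [SIBLING, UNRELATED, RelatednessCoefficients(0.1, 0.6, 0.3)],
    )
    def test_matches_enumeration_oracle(self, theta, delta):
        """Every configuration of a 3-allele locus matches exhaustive enumeration."""
        oracle = enumerate_pair_probabilities(delta, theta, THREE)
        for (g1, g2), expected in oracle.items():
            got = math.exp(pair_genotype_log_probability(g1, g2, delta, theta, THREE))
            assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("theta", [0.0, 0.01, 0.1])
    @pytest.mark.parametrize("freqs", [HALF, THREE, QUARTERS])
    def test_normalisation_over_genotype_pairs(self, theta, freqs):
        """Probabilities over all unordered genotype pairs sum to one."""
        delta = SIBLING
        total = sum(
            enumerate_pair_probabilities(delta, theta, freqs).values()
        )
        alleles = list(freqs)
        mine = 0.0
        import itertools

        genos = list(itertools.combinations_with_replacement(alleles, 2))
        for g1 in genos:
            for g2 in genos:
                mine += math.exp(
                    pair_genotype_log_probability(g1, g2, delta, theta, freqs)
                )
        assert total == pytest.approx(1.0, abs=1e-10)
        assert mine == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("theta", [0.0, 0.03])
    def test_symmetry_in_the_two_genotypes(self, theta):
        for g1, g2 in [((1, 2), (2, 3)), ((1, 1), (1, 3)), ((2, 3), (1, 1))]:
            ab = pair_genotype_log_probability(g1, g2, SIBLING, theta, THREE)
            ba = pair_genotype_log_probability(g2, g1, SIBLING, theta, THREE)
            assert ab == pytest.approx(ba, abs=1e-12)

    def test_rejects_bad_theta_and_zero_frequencies(self):
        with pytest.raises(ValueError, match="theta"):
            pair_genotype_log_probability((1, 1), (1, 1), SIBLING, 1.0, HALF)
        with pytest.raises(ValueError, match="zero assumed frequency"):
            pair_genotype_log_probability(
                (1, 2), (1, 2), SIBLING, 0.0, {1: 1.0, 2: 0.0}
            )
        with pytest.raises(ValueError, match="no assumed frequency"):
            pair_genotype_log_probability((1, 5), (1, 1), SIBLING, 0.0, HALF)


class TestLikelihoodRatio:
    def test_matching_homozygote_closed_form(self):
        # LR = (1+p)^2 / (4 p^2) = 2.25 at p = 0.5
        rec = relationship_log_lr((1, 1), (1, 1), HALF, theta=0.0)
        assert math.exp(rec.log_lr) == pytest.approx(2.25, rel=1e-12)
        assert rec.log_lr == pytest.approx(math.log(2.25), abs=1e-12)

    def test_matching_heterozygote_closed_form(self):
        rec = relationship_log_lr((1, 2), (1, 2), HALF, theta=0.0)
        assert math.exp(rec.log_lr) == pytest.approx(1.25, rel=1e-12)

    def test_additivity_over_independent_loci(self):
        g = np.array([[1, 1]] * 13)
        rec = relationship_log_lr(g, g, [HALF] * 13, theta=0.0)
        assert rec.log_lr == pytest.approx(13 * math.log(2.25), abs=1e-9)
        assert rec.per_locus_log_lr.shape == (13,)
        assert rec.log_lr == pytest.approx(rec.per_locus_log_lr.sum(), abs=1e-9)

    def test_record_rejects_inconsistent_total(self):
        with pytest.raises(ValueError, match="per-locus"):
            LRRecord("q", "c", 1.0, per_locus_log_lr=[0.2, 0.2])

    def test_mean_lr_of_unrelated_pairs_is_one(self):
        """E[LR | unrelated] = 1: the LR is a likelihood ratio of the truth."""
        rng = np.random.default_rng(5)
        labels = np.array([1, 2, 3])
        probs = np.array([0.5, 0.3, 0.2])
        freqs = dict(zip(labels.tolist(), probs.tolist()))
        n = 20000
        draws = rng.choice(labels, size=(n, 2, 2), p=probs)
        lrs = [
            math.exp(
                relationship_log_lr(
                    np.sort(draws[i, 0]), np.sort(draws[i, 1]), freqs, theta=0.0
                ).log_lr
            )
            for i in range(n)
        ]
        assert np.mean(lrs) == pytest.approx(1.0, abs=0.02)


class TestFloorFrequencies:
    def test_floor_value_and_renormalisation(self):
        # f_min = 1/(2*49 + 2) = 0.01
        out = floor_frequencies(np.array([0.7, 0.3, 0.0]), n_ref=49)
        assert out.min() == pytest.approx(0.01 / 1.01, rel=1e-9)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        # ordering preserved
        assert np.all(np.diff(out) < 0)

    def test_requires_reference_size(self):
        with pytest.raises(ValueError):
            floor_frequencies(np.array([1.0, 0.0]), n_ref=None)


class TestSimulateRelative:
    def _freqs(self, L, labels=(1, 2, 3), probs=(0.5, 0.3, 0.2)):
        return [(np.array(labels), np.array(probs))] * L

    def test_clone_when_both_alleles_shared(self):
        rng = np.random.default_rng(0)
        src = np.array([[1, 2], [2, 3], [1, 1]])
        clone_delta = RelatednessCoefficients(0.0, 0.0, 1.0)
        sim, ibd = simulate_relative(src, clone_delta, self._freqs(3), rng)
        assert np.array_equal(sim, src)
        assert np.all(ibd == 2)

    def test_unrelated_draws_match_mixture_distribution(self):
        """With no IBD the simulant's alleles follow the mixture frequencies."""
        rng = np.random.default_rng(1)
        L = 10_000
        src = np.tile([1, 2], (L, 1))
        sim, ibd = simulate_relative(src, UNRELATED, self._freqs(L), rng)
        assert np.all(ibd == 0)
        counts = np.bincount(sim.ravel(), minlength=4)[1:4]
        expected = np.array([0.5, 0.3, 0.2]) * 2 * L
        chi2 = sps.chisquare(counts, expected)
        assert chi2.pvalue > 0.01

    def test_sibling_ibd_state_frequencies(self):
        """Empirical IBD states over many loci match (1/4, 1/2, 1/4) within 3 SE."""
        rng = np.random.default_rng(2)
        L = 10_000
        src = np.tile([1, 3], (L, 1))
        _, ibd = simulate_relative(src, SIBLING, self._freqs(L), rng)
        freqs = np.bincount(ibd, minlength=3) / L
        expected = np.array([0.25, 0.5, 0.25])
        se = np.sqrt(expected * (1 - expected) / L)
        assert np.all(np.abs(freqs - expected) < 3 * se)

    def test_single_shared_allele_comes_from_source(self):
        rng = np.random.default_rng(3)
        # source homozygous 5/5 at every locus; mixture support excludes 5
        L = 500
        src = np.tile([5, 5], (L, 1))
        one_shared = RelatednessCoefficients(0.0, 1.0, 0.0)
        sim, ibd = simulate_relative(src, one_shared, self._freqs(L), rng)
        assert np.all(ibd == 1)
        assert np.all(np.sum(sim == 5, axis=1) == 1)
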
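"""Admixture EM, replicate alignment, and individual-weighted frequencies."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinlr.ancestry import (
    EMSettings,
    align_replicates,
    align_to,
    em_admixture,
    em_replicates,
    individual_frequencies,
    mixture_frequencies,
)
from kinlr.genotype_io import AlleleFrequencyTable, AncestryModel, GenotypeTable
from kinlr.synthetic_data import generate_dataset, generate_population_frequencies

from conftest import small_config


def _table_from_genotypes(genotypes, populations=None):
    genotypes = np.asarray(genotypes)
    n, L, _ = genotypes.shape
    return GenotypeTable(
        individuals=[f"i{k}" for k in range(n)],
        populations=populations or ["p"] * n,
        loci=[f"L{j}" for j in range(L)],
        forensic=np.zeros(L, dtype=bool),
        genotypes=np.sort(genotypes, axis=2),
    )


def _match_to_truth(Q, truth):
    """Mean absolute membership error after the best label permutation."""
    K = Q.shape[1]
    return min(
        np.abs(Q[:, list(perm)] - truth).mean()
        for perm in itertools.permutations(range(K))
    )


class TestEM:
    def test_single_cluster_closed_form(self):
        table = _table_from_genotypes([[[1, 2], [3, 3]], [[1, 1], [3, 4]]])
        model = em_admixture(table, EMSettings(K=1, n_replicates=1, seed=0))
        assert np.all(model.Q == 1.0)
        np.testing.assert_allclose(model.P.freqs["L0"][0], [0.75, 0.25])
        np.testing.assert_allclose(model.P.freqs["L1"][0], [0.75, 0.25])

    def test_disjoint_allele_sets_fully_separate(self):
        """Two populations with disjoint alleles are recovered exactly."""
        rng = np.random.default_rng(0)
        g1 = rng.choice([1, 2], size=(20, 8, 2))
        g2 = rng.choice([5, 6], size=(20, 8, 2))
        table = _table_from_genotypes(np.concatenate([g1, g2]))
        model = em_admixture(table, EMSettings(K=2, n_replicates=1, seed=1))
        hard = model.Q.argmax(axis=1)
        assert len(set(hard[:20])) == 1 and len(set(hard[20:])) == 1
        assert hard[0] != hard[-1]
        truth = np.zeros((40, 2))
        truth[:20, 0] = 1
        truth[20:, 1] = 1
        assert _match_to_truth(model.Q, truth) < 1e-6

    def test_loglik_monotone_and_convergence_flag(self):
        table, _ = generate_dataset(small_config(n_loci_total=20, seed=3))
        model = em_admixture(
            table, EMSettings(K=4, n_replicates=1, max_iterations=200, seed=2)
        )
        assert np.isfinite(model.log_likelihood)
        # the internal assertion guarantees monotonicity; spot-check shapes
        assert model.Q.shape == (table.n_individuals, 4)

    def test_nonconvergence_warns_and_returns_best(self):
        table, _ = generate_dataset(small_config(n_loci_total=20, seed=3))
        with pytest.warns(RuntimeWarning, match="did not converge"):
            model = em_admixture(
                table, EMSettings(K=4, n_replicates=1, max_iterations=2, seed=2)
            )
        assert not model.converged

    def test_excess_clusters_warn_degenerate(self):
        table = _table_from_genotypes([[[1, 1]], [[1, 1]], [[1, 2]]])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            em_admixture(table, EMSettings(K=3, n_replicates=1, max_iterations=5, seed=0))

    def test_label_permutation_equivariance(self):
        """Permuting the initialisation's cluster labels permutes the solution."""
        table, _ = generate_dataset(
            small_config(n_loci_total=15, n_forensic_loci=3, seed=5)
        )
        settings = EMSettings(K=3, n_replicates=1, max_iterations=40, seed=0)
        rng = np.random.default_rng(11)
        Q0 = rng.dirichlet(np.ones(3), size=table.n_individuals)
        P0 = generate_population_frequencies(
            small_config(
                n_populations=3,
                n_individuals_per_pop=(2, 2, 2),
                n_loci_total=15,
                n_forensic_loci=3,
                seed=6,
            )
        )
        perm = [2, 0, 1]
        P0_perm = AlleleFrequencyTable(
            groups=list(P0.groups),
            loci=list(P0.loci),
            alleles={l: P0.alleles[l] for l in P0.loci},
            freqs={l: P0.freqs[l][perm] for l in P0.loci},
        )
        with pytest.warns(RuntimeWarning):
            m1 = em_admixture(table, settings, init=(Q0, P0))
            m2 = em_admixture(table, settings, init=(Q0[:, perm], P0_perm))
        np.testing.assert_allclose(m2.Q, m1.Q[:, perm], atol=1e-8)

    def test_supervised_fixed_p_improves_with_more_loci(self):
        """Given the true cluster frequencies, more loci mean better memberships."""
        cfg = small_config(
            n_individuals_per_pop=(30, 30, 30, 30),
            n_loci_total=120,
            n_forensic_loci=13,
            drift_F=0.08,
            seed=8,
        )
        freqs = generate_population_frequencies(cfg)
        from kinlr.synthetic_data import generate_individuals

        table, truth = generate_individuals(freqs, cfg)
        settings = EMSettings(K=4, mode="supervised", n_replicates=1, seed=0)
        err = {}
        for name, loci in [("few", table.loci[:13]), ("many", table.loci)]:
            model = em_admixture(
                table, settings, loci=loci, fixed_P=freqs.subset_loci(loci)
            )
            err[name] = np.abs(model.Q - truth.true_memberships).mean()
        assert err["many"] < err["few"]


class TestAlignment:
    def _random_model(self, rng, K=4, n=30, L=6):
        Q = rng.dirichlet(np.ones(K), size=n)
        alleles = {f"L{j}": np.arange(1, 5) for j in range(L)}
        freqs = {f"L{j}": rng.dirichlet(np.ones(4), size=K) for j in range(L)}
        P = AlleleFrequencyTable(
            groups=[f"cluster{k+1}" for k in range(K)],
            loci=list(alleles),
            alleles=alleles,
            freqs=freqs,
        )
        return AncestryModel(Q=Q, P=P, log_likelihood=-1.0,
                             individuals=[f"i{k}" for k in range(n)])

    def _permuted(self, model, perm):
        P = model.P
        newP = AlleleFrequencyTable(
            groups=list(P.groups),
            loci=list(P.loci),
            alleles={l: P.alleles[l] for l in P.loci},
            freqs={l: P.freqs[l][list(perm)] for l in P.loci},
        )
        return AncestryModel(Q=model.Q[:, list(perm)], P=newP, log_likelihood=-1.0,
                             individuals=list(model.individuals))

    def test_recovers_inverse_permutation(self):
        rng = np.random.default_rng(0)
        ref = self._random_model(rng)
        perm = (2, 0, 3, 1)
        ens = align_replicates([ref, self._permuted(ref, perm)])
        aligned = ens.replicates[1]
        np.testing.assert_allclose(aligned.Q, ref.Q, atol=1e-12)
        for l in ref.P.loci:
            np.testing.assert_allclose(aligned.P.freqs[l], ref.P.freqs[l], atol=1e-12)

    def test_identical_replicates_consensus_is_replicate(self):
        rng = np.random.default_rng(1)
        ref = self._random_model(rng)
        ens = align_replicates([ref] * 10)
        np.testing.assert_allclose(ens.consensus.Q, ref.Q, atol=1e-12)
        for l in ref.P.loci:
            np.testing.assert_allclose(ens.consensus.P.freqs[l], ref.P.freqs[l], atol=1e-12)

    def test_noisy_permuted_replicates_all_recovered(self):
        """Small noise under random relabelling: permutations found, consensus close."""
        rng = np.random.default_rng(2)
        ref = self._random_model(rng, n=50)
        models = [ref]
        applied = []
        for _ in range(5):
            perm = tuple(rng.permutation(4))
            noisy_Q = np.abs(ref.Q + rng.normal(0, 0.01, ref.Q.shape))
            noisy_Q /= noisy_Q.sum(axis=1, keepdims=True)
            noisy = AncestryModel(
                Q=noisy_Q, P=ref.P, log_likelihood=-1.0,
                individuals=list(ref.individuals),
            )
            models.append(self._permuted(noisy, perm))
            applied.append(perm)
        ens = align_replicates(models)
        for found, used in zip(ens.permutations[1:], applied):
            # the recovered label map must invert the one applied
            assert tuple(used[i] for i in found) == tuple(range(4)) or tuple(
                found[i] for i in used
            ) == tuple(range(4))
        for aligned in ens.replicates[1:]:
            assert np.max(np.abs(aligned.Q - ref.Q)) < 0.05
        assert np.max(np.abs(ens.consensus.Q - ref.Q)) < 2 * 0.01
        assert np.mean(np.abs(ens.consensus.Q - ref.Q)) < 0.005

    def test_alignment_is_idempotent(self):
        rng = np.random.default_rng(3)
        ref = self._random_model(rng)
        ens = align_replicates([ref, self._permuted(ref, (1, 0, 2, 3))])
        again = align_replicates(ens.replicates)
        assert all(p == tuple(range(4)) for p in again.permutations)
        np.testing.assert_allclose(again.consensus.Q, ens.consensus.Q, atol=1e-12)

    def test_rejects_unsupported_k(self):
        rng = np.random.default_rng(4)
        big = self._random_model(rng, K=9, n=5)
        with pytest.raises(ValueError, match="K <= 8"):
            align_replicates([big, big])

    def test_align_to_relabels_across_locus_sets(self):
        rng = np.random.default_rng(5)
        ref = self._random_model(rng)
        other = self._permuted(ref, (3, 2, 1, 0))
        aligned = align_to(other, ref)
        np.testing.assert_allclose(aligned.Q, ref.Q, atol=1e-12)


class TestIndividualFrequencies:
    P = AlleleFrequencyTable(
        groups=["c1", "c2"],
        loci=["L1"],
        alleles={"L1": np.array([1, 2])},
        freqs={"L1": np.array([[0.2, 0.8], [0.6, 0.4]])},
    )

    def test_vertex_membership_returns_cluster_frequencies(self):
        out = individual_frequencies(np.array([1.0, 0.0]), self.P)
        np.testing.assert_array_equal(out["L1"], [0.2, 0.8])

    def test_even_mixture_is_midpoint(self):
        out = individual_frequencies(np.array([0.5, 0.5]), self.P)
        np.testing.assert_allclose(out["L1"], [0.4, 0.6])

    def test_negative_membership_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            individual_frequencies(np.array([-0.1, 1.1]), self.P)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=2))
    def test_output_is_a_probability_vector(self, raw):
        q = np.array(raw) / np.sum(raw)
        out = individual_frequencies(q, self.P)
        assert out["L1"].sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(out["L1"] >= 0)

    def test_batch_matches_single(self):
        Q = np.array([[0.3, 0.7], [1.0, 0.0]])
        batch = mixture_frequencies(Q, self.P)
        single = individual_frequencies(Q[0], self.P)
        np.testing.assert_allclose(batch["L1"][0], single["L1"])


class TestRecovery:
    def test_unsupervised_recovery_on_admixed_data(self):
        """Aligned EM memberships track the simulation truth on a mid-size study."""
        cfg = small_config(
            n_individuals_per_pop=(40, 40, 40, 40),
            n_loci_total=150,
            n_forensic_loci=13,
            drift_F=0.12,
            seed=13,
        )
        table, truth = generate_dataset(cfg)
        ens = em_replicates(
            table, EMSettings(K=4, n_replicates=2, max_iterations=300, seed=3)
        )
        err = _match_to_truth(ens.consensus.Q, truth.true_memberships)
        assert err < 0.06
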
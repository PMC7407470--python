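"""Admixture-model ancestry inference, replicate alignment, and Eq.-style mixtures.

The model: individual i has membership proportions q_i over K clusters;
each of its 2L allele copies originates from cluster k with probability
q_{ik} and is allele a with probability p_{k,ℓ,a}.  The maximum-likelihood
point estimates of (Q, P) are found by expectation–maximisation:

* E step — per allele copy, responsibilities r_k ∝ q_{ik} · p_{k,ℓ,a};
* M step — q_i is the row-normalised sum of its copies' responsibilities,
  and p_{k,ℓ,·} the normalised responsibility-weighted allele counts.

The log-likelihood is non-decreasing every iteration (asserted).  Because
cluster labels are arbitrary, replicate runs are aligned by an exhaustive
search over label permutations (exact for the small K of interest, K ≤ 8)
before averaging into a consensus model.

The individual-weighted allele frequency distribution — the convex
combination of cluster frequencies weighted by an individual's membership
vector — is the bridge from ancestry inference to kinship likelihoods.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import AlleleFrequencyTable, AncestryModel, GenotypeTable

__all__ = [
    "EMSettings",
    "AlignedEnsemble",
    "em_admixture",
    "em_replicates",
    "align_replicates",
    "individual_frequencies",
    "mixture_frequencies",
]

_MAX_EXHAUSTIVE_K = 8
_FREQ_FLOOR = 1e-12


@dataclass
class EMSettings:
    """Settings for one ensemble of admixture-EM runs."""

    K: int = 4
    mode: str = "unsupervised"
    n_replicates: int = 10
    max_iterations: int = 500
    relative_loglik_tolerance: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be at least 1")
        if self.mode not in ("unsupervised", "supervised"):
            raise ValueError("mode must be 'unsupervised' or 'supervised'")
        if self.relative_loglik_tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.n_replicates < 1 or self.max_iterations < 1:
            raise ValueError("counts must be positive")


@dataclass
class AlignedEnsemble:
    """Replicate ancestry models after label alignment, with their consensus."""

    replicates: list[AncestryModel]
    consensus: AncestryModel
    permutations: list[tuple[int, ...]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# flat encoding
# ---------------------------------------------------------------------------


def _flatten(genotypes: GenotypeTable, loci: list[str]):
    """Encode all allele copies as flat index arrays.

    Returns (ind_idx, allele_global_idx, locus_slices, allele_labels) where
    allele labels at locus j occupy the global index block
    locus_slices[j] = (start, stop).
    """
    sub = genotypes.subset_loci(loci)
    sub.require_complete()
    n, L = sub.n_individuals, sub.n_loci
    blocks = []
    slices = []
    labels = []
    start = 0
    for j in range(L):
        col = sub.genotypes[:, j, :]
        al = np.unique(col)
        idx = np.searchsorted(al, col) + start
        blocks.append(idx)
        slices.append((start, start + al.size))
        labels.append(al)
        start += al.size
    allele_idx = np.stack(blocks, axis=1).reshape(-1)  # (n*L*2,)
    ind_idx = np.repeat(np.arange(n), L * 2)
    return sub, ind_idx, allele_idx, slices, labels, start


def _normalise_P(P_flat: np.ndarray, slices) -> np.ndarray:
    for start, stop in slices:
        block = P_flat[:, start:stop]
        block = np.maximum(block, _FREQ_FLOOR)
        P_flat[:, start:stop] = block / block.sum(axis=1, keepdims=True)
    return P_flat


def _to_freq_table(P_flat, slices, labels, loci, K, n_ref) -> AlleleFrequencyTable:
    alleles = {}
    freqs = {}
    for j, locus in enumerate(loci):
        start, stop = slices[j]
        alleles[locus] = labels[j].astype(int)
        block = P_flat[:, start:stop]
        freqs[locus] = block / block.sum(axis=1, keepdims=True)
    return AlleleFrequencyTable(
        groups=[f"cluster{k + 1}" for k in range(K)],
        loci=list(loci), alleles=alleles, freqs=freqs, n_ref=n_ref,
    )


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def em_admixture(
    genotypes: GenotypeTable,
    settings: EMSettings,
    loci: list[str] | None = None,
    rng: np.random.Generator | None = None,
    init: tuple[np.ndarray, AlleleFrequencyTable] | None = None,
    fixed_P: AlleleFrequencyTable | None = None,
) -> AncestryModel:
    """One admixture-EM run returning point estimates of Q and P.

    ``loci`` restricts inference to a subset (default all loci; they must
    be complete).  ``init`` injects a starting (Q, P); otherwise the run
    is initialised randomly from ``rng`` (or a generator seeded from
    ``settings.seed``).  In supervised mode ``fixed_P`` holds the cluster
    frequencies fixed and only Q is estimated.
    """
    loci = list(loci) if loci is not None else list(genotypes.loci)
    sub, ind_idx, allele_idx, slices, labels, M = _flatten(genotypes, loci)
    n, L, K = sub.n_individuals, sub.n_loci, settings.K
    if rng is None:
        rng = np.random.default_rng(settings.seed)

    supervised = settings.mode == "supervised"
    if supervised and fixed_P is None and init is None:
        raise ValueError("supervised mode requires fixed_P (or an init) for the clusters")

    n_support = len({tuple(row.ravel()) for row in sub.genotypes})
    if K > n_support:
        warnings.warn(
            f"K={K} exceeds the number of distinct multilocus genotypes "
            f"({n_support}); the solution is degenerate",
            RuntimeWarning,
        )

    if fixed_P is not None:
        P_flat = _table_to_flat(fixed_P, loci, labels, slices, K, M)
        Q = rng.dirichlet(np.ones(K), size=n) if init is None else np.asarray(init[0], float).copy()
    elif init is not None:
        Q = np.asarray(init[0], dtype=float).copy()
        P_flat = _table_to_flat(init[1], loci, labels, slices, K, M)
    else:
        Q = rng.dirichlet(np.ones(K), size=n)
        # overall sample frequencies, perturbed per cluster
        counts = np.bincount(allele_idx, minlength=M).astype(float)
        base = counts.copy()
        for start, stop in slices:
            base[start:stop] /= base[start:stop].sum()
        P_flat = base[None, :] * rng.gamma(20.0, 1 / 20.0, size=(K, M))
        P_flat = _normalise_P(P_flat, slices)
    Q = np.maximum(Q, _FREQ_FLOOR)
    Q /= Q.sum(axis=1, keepdims=True)

    prev_ll = -np.inf
    converged = False
    for _ in range(settings.max_iterations):
        # E step
        r = Q[ind_idx] * P_flat[:, allele_idx].T  # (n*L*2, K)
        denom = r.sum(axis=1)
        ll = float(np.log(denom).sum())
        assert ll >= prev_ll - 1e-8 * max(1.0, abs(prev_ll)), "EM log-likelihood decreased"
        if prev_ll > -np.inf and abs(ll - prev_ll) <= settings.relative_loglik_tolerance * abs(prev_ll):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
        r /= denom[:, None]
        # M step
        Qnew = np.zeros_like(Q)
        np.add.at(Qnew, ind_idx, r)
        Q = np.maximum(Qnew / (2 * L), _FREQ_FLOOR)
        Q /= Q.sum(axis=1, keepdims=True)
        if fixed_P is None:
            Pnew = np.zeros((M, K))
            np.add.at(Pnew, allele_idx, r)
            P_flat = _normalise_P(Pnew.T, slices)
    if not converged:
        warnings.warn(
            "EM did not converge within max_iterations; returning best-so-far",
            RuntimeWarning,
        )
    return AncestryModel(
        Q=Q,
        P=_to_freq_table(P_flat, slices, labels, loci, K, n_ref=n),
        log_likelihood=prev_ll,
        loci=list(loci),
        individuals=list(sub.individuals),
        converged=converged,
    )


def _table_to_flat(table: AlleleFrequencyTable, loci, labels, slices, K, M) -> np.ndarray:
    if table.n_groups != K:
        raise ValueError("cluster count of the frequency table must equal K")
    P_flat = np.full((K, M), _FREQ_FLOOR)
    for j, locus in enumerate(loci):
        start, stop = slices[j]
        tab_labels = table.alleles[locus]
        idx = np.searchsorted(tab_labels, labels[j])
        ok = (idx < tab_labels.size) & (tab_labels[np.minimum(idx, tab_labels.size - 1)] == labels[j])
        block = np.full((K, labels[j].size), _FREQ_FLOOR)
        block[:, ok] = table.freqs[locus][:, idx[ok]]
        P_flat[:, start:stop] = block
    return _normalise_P(P_flat, slices)


def em_replicates(
    genotypes: GenotypeTable,
    settings: EMSettings,
    loci: list[str] | None = None,
    fixed_P: AlleleFrequencyTable | None = None,
) -> AlignedEnsemble:
    """Run ``n_replicates`` independently initialised EM runs and align them."""
    models = []
    for i in range(settings.n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence(settings.seed, spawn_key=(i,)))
        models.append(
            em_admixture(genotypes, settings, loci=loci, rng=rng, fixed_P=fixed_P)
        )
    return align_replicates(models)


# ---------------------------------------------------------------------------
# label alignment
# ---------------------------------------------------------------------------


def _permute_model(model: AncestryModel, perm: tuple[int, ...]) -> AncestryModel:
    """Relabel clusters so that new cluster k is old cluster perm[k]."""
    P = model.P
    newP = AlleleFrequencyTable(
        groups=list(P.groups),
        loci=list(P.loci),
        alleles={l: P.alleles[l].copy() for l in P.loci},
        freqs={l: P.freqs[l][list(perm)] for l in P.loci},
        n_ref=P.n_ref,
    )
    return AncestryModel(
        Q=model.Q[:, list(perm)],
        P=newP,
        log_likelihood=model.log_likelihood,
        loci=list(model.loci),
        individuals=list(model.individuals),
        converged=model.converged,
    )


def align_to(model: AncestryModel, reference: AncestryModel) -> AncestryModel:
    """Relabel ``model``'s clusters to best match ``reference``'s memberships.

    Unlike :func:`align_replicates` the two models need not share loci —
    only individuals and K — so a forensic-subset inference can be
    relabelled onto a full-data inference before their estimates are mixed.
    """
    if model.Q.shape != reference.Q.shape:
        raise ValueError("models must share individuals and cluster count")
    K = model.n_clusters
    if K > _MAX_EXHAUSTIVE_K:
        raise ValueError(f"exhaustive alignment supports K <= {_MAX_EXHAUSTIVE_K}")
    best = min(
        itertools.permutations(range(K)),
        key=lambda perm: (float(np.sum((model.Q[:, list(perm)] - reference.Q) ** 2)), perm),
    )
    return _permute_model(model, best)


def align_replicates(models: list[AncestryModel]) -> AlignedEnsemble:
    """Align replicate cluster labels to the first replicate and average.

    Each replicate's labels are permuted to minimise the squared
    element-wise difference of its Q against the reference Q, searching
    all K! permutations (exact; K ≤ 8 enforced).  Equally good
    permutations resolve to the lexicographically smallest.  The consensus
    is the element-wise mean of the aligned models, renormalised.
    """
    if not models:
        raise ValueError("no models to align")
    K = models[0].n_clusters
    if K > _MAX_EXHAUSTIVE_K:
        raise ValueError(f"exhaustive alignment supports K <= {_MAX_EXHAUSTIVE_K}")
    ref = models[0]
    for m in models[1:]:
        if m.Q.shape != ref.Q.shape or m.P.loci != ref.P.loci:
            raise ValueError("replicates must share K, individuals, and loci")
    aligned = [ref]
    perms: list[tuple[int, ...]] = [tuple(range(K))]
    for m in models[1:]:
        best_perm = min(
            itertools.permutations(range(K)),
            key=lambda perm: (float(np.sum((m.Q[:, list(perm)] - ref.Q) ** 2)), perm),
        )
        aligned.append(_permute_model(m, best_perm))
        perms.append(best_perm)
    Qc = np.mean([m.Q for m in aligned], axis=0)
    Qc /= Qc.sum(axis=1, keepdims=True)
    loci = list(ref.P.loci)
    freqs = {}
    for l in loci:
        f = np.mean([m.P.freqs[l] for m in aligned], axis=0)
        freqs[l] = f / f.sum(axis=1, keepdims=True)
    Pc = AlleleFrequencyTable(
        groups=list(ref.P.groups),
        loci=loci,
        alleles={l: ref.P.alleles[l].copy() for l in loci},
        freqs=freqs,
        n_ref=ref.P.n_ref,
    )
    consensus = AncestryModel(
        Q=Qc,
        P=Pc,
        log_likelihood=float(np.mean([m.log_likelihood for m in aligned])),
        loci=list(ref.loci),
        individuals=list(ref.individuals),
        converged=all(m.converged for m in aligned),
    )
    return AlignedEnsemble(replicates=aligned, consensus=consensus, permutations=perms)


# ---------------------------------------------------------------------------
# individual-weighted allele frequencies
# ---------------------------------------------------------------------------


def individual_frequencies(q: np.ndarray, P: AlleleFrequencyTable) -> dict[str, np.ndarray]:
    """Convex combination of cluster frequencies weighted by one membership vector."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("membership proportions must be non-negative")
    if abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("membership vector must sum to 1")
    if q.size != P.n_groups:
        raise ValueError("membership vector length must equal the cluster count")
    return {locus: q @ P.freqs[locus] for locus in P.loci}


def mixture_frequencies(Q: np.ndarray, P: AlleleFrequencyTable) -> dict[str, np.ndarray]:
    """Per-locus (n_individuals, n_alleles) mixture frequencies for a whole Q."""
    Q = np.asarray(Q, dtype=float)
    if np.any(Q < 0) or not np.allclose(Q.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("each membership row must be a probability vector")
    return {locus: Q @ P.freqs[locus] for locus in P.loci}
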
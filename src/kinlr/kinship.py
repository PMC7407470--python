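"""Pair-genotype probabilities, kinship likelihood ratios, and relative simulation.

The joint probability of two single-locus genotypes under a relatedness
hypothesis (Δ0, Δ1, Δ2) is computed by conditioning on the number S of
alleles the pair shares identical by descent.  Given S, the four allele
copies collapse to 4−S founder draws from the population, and founder
draws are priced sequentially under the coancestry (θ) sampling recursion

    P(type a | m prior copies of a among j prior draws)
        = (m·θ + (1−θ)·p_a) / (1 + (j−1)·θ),

the Dirichlet/Balding–Nichols "urn" that reduces to independent draws with
probabilities p at θ = 0.  All ordered configurations consistent with the
unordered genotypes — and, under Δ1, with which allele is the shared one —
are enumerated and summed, so combinatorial coefficients (the factor 2 for
heterozygotes, the factor 4 when all four alleles differ) arise
automatically rather than from transcribed case formulas.

The computation is vectorised over arrays of pairs, which makes scanning a
database of millions of candidate pairs feasible; scalar convenience
wrappers serve single-pair use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "RelatednessCoefficients",
    "SIBLING",
    "UNRELATED",
    "PARENT_OFFSPRING",
    "LRRecord",
    "pair_state_probabilities",
    "pair_genotype_log_probability",
    "relationship_log_lr",
    "batch_log_lr",
    "simulate_relative",
    "floor_frequencies",
]


@dataclass(frozen=True)
class RelatednessCoefficients:
    """Probabilities of sharing 0, 1 or 2 alleles identical by descent."""

    delta0: float
    delta1: float
    delta2: float

    def __post_init__(self) -> None:
        d = np.array([self.delta0, self.delta1, self.delta2])
        if np.any(d < 0):
            raise ValueError("relatedness coefficients must be non-negative")
        if abs(d.sum() - 1.0) > 1e-12:
            raise ValueError("relatedness coefficients must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.delta0, self.delta1, self.delta2])


#: full siblings share 0/1/2 alleles IBD with probabilities (1/4, 1/2, 1/4)
SIBLING = RelatednessCoefficients(0.25, 0.5, 0.25)
#: unrelated pairs share nothing identical by descent
UNRELATED = RelatednessCoefficients(1.0, 0.0, 0.0)
#: a parent and offspring always share exactly one allele IBD
PARENT_OFFSPRING = RelatednessCoefficients(0.0, 1.0, 0.0)


@dataclass
class LRRecord:
    """One query/candidate comparison: natural-log likelihood ratio and truth."""

    query_id: str
    candidate_id: str
    log_lr: float
    truth: str | None = None
    per_locus_log_lr: np.ndarray = field(default_factory=lambda: np.empty(0))
    frequency_source: str = ""

    def __post_init__(self) -> None:
        self.per_locus_log_lr = np.asarray(self.per_locus_log_lr, dtype=float)
        if self.per_locus_log_lr.size and not np.isclose(
            self.log_lr, self.per_locus_log_lr.sum(), atol=1e-9
        ):
            raise ValueError("log_lr must equal the sum of per-locus contributions")


# ---------------------------------------------------------------------------
# core: IBD-state probabilities for unordered genotype pairs
# ---------------------------------------------------------------------------


def _check_theta(theta: float) -> None:
    if not 0.0 <= theta < 1.0:
        raise ValueError(f"theta must be in [0, 1), got {theta}")


def pair_state_probabilities(a, b, c, d, pa, pb, pc, pd, theta: float):
    """P of the unordered genotype pair ({a,b}, {c,d}) given S = 0, 1, 2 alleles IBD.

    Parameters are broadcastable arrays: ``a <= b`` and ``c <= d`` are the
    allele labels of the two sorted genotypes, and ``pa..pd`` the population
    frequencies of those alleles under the assumed frequency vector (which
    may differ between pairs).  Returns arrays ``(P0, P1, P2)``.
    """
    _check_theta(theta)
    a, b, c, d = (np.asarray(x) for x in (a, b, c, d))
    pa, pb, pc, pd = (np.asarray(x, dtype=float) for x in (pa, pb, pc, pd))
    one = 1.0 - theta

    het1 = a != b
    het2 = c != d
    mult1 = np.where(het1, 2.0, 1.0)
    mult2 = np.where(het2, 2.0, 1.0)

    # sequential founder-draw prices; draw j has j prior draws
    def draw(p, m, j):
        return (m * theta + one * p) / (1.0 + (j - 1) * theta)

    # genotype 1 = first two founder draws (shared by all three states)
    g1_seq = pa * draw(pb, (b == a).astype(float), 1)

    # S = 0: four founder draws a, b, c, d
    t3 = draw(pc, (c == a).astype(float) + (c == b), 2)
    t4 = draw(pd, (d == a).astype(float) + (d == b) + (d == c), 3)
    p0 = mult1 * mult2 * g1_seq * t3 * t4

    # S = 2: the pair's genotypes coincide; two founder draws only
    p2 = np.where((a == c) & (b == d), mult1 * g1_seq, 0.0)

    # S = 1: one allele of genotype 1 (each copy with weight 1/2) is shared;
    # the other allele of genotype 2 is a third founder draw
    p1 = np.zeros(np.broadcast(a, b, c, d).shape)
    for s, _ps in ((a, pa), (b, pb)):
        match_c = s == c
        match_d = (s == d) & ~match_c
        free = np.where(match_c, d, c)
        pfree = np.where(match_c, pd, pc)
        m_free = (free == a).astype(float) + (free == b)
        term = 0.5 * mult1 * g1_seq * draw(pfree, m_free, 2)
        p1 = p1 + np.where(match_c | match_d, term, 0.0)
    return p0, p1, p2


def _freq_lookup(freqs, alleles: Sequence[int]) -> np.ndarray:
    """Frequencies of the given allele labels from a mapping or (labels, probs)."""
    if isinstance(freqs, Mapping):
        out = []
        for al in alleles:
            if al not in freqs:
                raise ValueError(f"allele {al} has no assumed frequency")
            out.append(float(freqs[al]))
        out = np.array(out)
    else:
        labels, probs = freqs
        labels = np.asarray(labels)
        idx = np.searchsorted(labels, alleles)
        bad = (idx >= labels.size) | (labels[np.minimum(idx, labels.size - 1)] != alleles)
        if np.any(bad):
            missing = np.asarray(alleles)[bad]
            raise ValueError(f"allele(s) {missing.tolist()} have no assumed frequency")
        out = np.asarray(probs, dtype=float)[idx]
    if np.any(out <= 0):
        bad = np.asarray(alleles)[out <= 0]
        raise ValueError(
            f"allele(s) {np.atleast_1d(bad).tolist()} have zero assumed frequency; "
            "apply floor_frequencies to the assumed table first"
        )
    return out


def pair_genotype_log_probability(
    g1: Sequence[int],
    g2: Sequence[int],
    delta: RelatednessCoefficients,
    theta: float,
    freqs,
) -> float:
    """Natural-log joint probability of one unordered genotype pair at one locus.

    ``freqs`` is either a mapping ``allele -> frequency`` or a pair of
    aligned arrays ``(allele_labels, probabilities)``.
    """
    a, b = sorted(int(x) for x in g1)
    c, d = sorted(int(x) for x in g2)
    pa, pb, pc, pd = _freq_lookup(freqs, [a, b, c, d])
    p0, p1, p2 = pair_state_probabilities(a, b, c, d, pa, pb, pc, pd, theta)
    prob = delta.delta0 * p0 + delta.delta1 * p1 + delta.delta2 * p2
    if prob <= 0:
        return -np.inf
    return float(np.log(prob))


def relationship_log_lr(
    g1,
    g2,
    freqs,
    theta: float = 0.0,
    related_delta: RelatednessCoefficients = SIBLING,
    unrelated_delta: RelatednessCoefficients = UNRELATED,
    query_id: str = "query",
    candidate_id: str = "candidate",
    truth: str | None = None,
    frequency_source: str = "",
) -> LRRecord:
    """Log likelihood ratio of related vs unrelated over one or many loci.

    ``g1``/``g2`` are single genotypes ``(a, b)`` or sequences of genotypes
    over loci; ``freqs`` correspondingly one frequency spec or a sequence.
    The same frequencies and θ enter numerator and denominator.
    """
    g1 = np.atleast_2d(np.asarray(g1))
    g2 = np.atleast_2d(np.asarray(g2))
    if g1.shape != g2.shape:
        raise ValueError("g1 and g2 must cover the same loci")
    L = g1.shape[0]
    # a Mapping or a single (labels, probs) tuple broadcasts over loci;
    # a list supplies one frequency spec per locus
    single = isinstance(freqs, Mapping) or (
        isinstance(freqs, tuple) and len(freqs) == 2 and np.ndim(freqs[0]) >= 1
    )
    freq_list = [freqs] * L if single else list(freqs)
    if len(freq_list) != L:
        raise ValueError("one frequency spec required per locus")
    per_locus = np.empty(L)
    for j in range(L):
        try:
            num = pair_genotype_log_probability(g1[j], g2[j], related_delta, theta, freq_list[j])
            den = pair_genotype_log_probability(g1[j], g2[j], unrelated_delta, theta, freq_list[j])
        except ValueError as exc:
            raise ValueError(f"locus {j}: {exc}") from None
        per_locus[j] = num - den
    return LRRecord(
        query_id=query_id,
        candidate_id=candidate_id,
        log_lr=float(per_locus.sum()),
        truth=truth,
        per_locus_log_lr=per_locus,
        frequency_source=frequency_source,
    )


def batch_log_lr(
    g1_alleles: np.ndarray,
    g2_alleles: np.ndarray,
    p1: np.ndarray,
    p2_: np.ndarray = None,
    *,
    theta: float = 0.0,
    related_delta: RelatednessCoefficients = SIBLING,
) -> np.ndarray:
    """Vectorised per-locus log LR for many pairs at one locus.

    ``g1_alleles``/``g2_alleles`` are ``(n, 2)`` sorted allele labels and
    ``p1`` a matching ``(n, 4)`` array of the frequencies of
    ``(a, b, c, d)`` under each pair's assumed frequency vector.
    """
    a, b = g1_alleles[:, 0], g1_alleles[:, 1]
    c, d = g2_alleles[:, 0], g2_alleles[:, 1]
    pa, pb, pc, pd = p1[:, 0], p1[:, 1], p1[:, 2], p1[:, 3]
    p0, p1s, p2s = pair_state_probabilities(a, b, c, d, pa, pb, pc, pd, theta)
    num = related_delta.delta0 * p0 + related_delta.delta1 * p1s + related_delta.delta2 * p2s
    return np.log(num) - np.log(p0)


# ---------------------------------------------------------------------------
# zero-frequency policy
# ---------------------------------------------------------------------------


def floor_frequencies(probs: np.ndarray, n_ref: int) -> np.ndarray:
    """Floor a frequency vector at 1/(2·n_ref + 2) and renormalise.

    A query allele can be absent from a misspecified reference table; the
    floor — the frequency an allele would have if it appeared once in a
    sample one individual larger — keeps likelihood ratios finite while
    preserving the ordering of observed frequencies.
    """
    if n_ref is None or n_ref < 1:
        raise ValueError("a positive reference sample size is required for flooring")
    probs = np.asarray(probs, dtype=float)
    fmin = 1.0 / (2 * n_ref + 2)
    out = np.maximum(probs, fmin)
    return out / out.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# relative simulation
# ---------------------------------------------------------------------------


def simulate_relative(
    genotypes: np.ndarray,
    delta: RelatednessCoefficients,
    mixture_freqs: Sequence[tuple[np.ndarray, np.ndarray]],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a relative of an individual, locus by locus.

    At each locus the number of alleles shared identical by descent is
    drawn from ``delta``; the shared copies are taken from the source
    genotype (the single copy chosen uniformly when one is shared) and the
    remaining copies are drawn independently from the individual-specific
    mixture frequency vector ``(allele_labels, probabilities)``.

    Returns the simulated genotype array (pairs sorted ascending) and the
    per-locus IBD-state trace.
    """
    genotypes = np.asarray(genotypes)
    L = genotypes.shape[0]
    if len(mixture_freqs) != L:
        raise ValueError("one mixture frequency vector required per locus")
    ibd = rng.choice(3, size=L, p=delta.as_array())
    out = np.empty((L, 2), dtype=genotypes.dtype)
    for j in range(L):
        labels, probs = mixture_freqs[j]
        s = ibd[j]
        copied = []
        if s == 2:
            copied = list(genotypes[j])
        elif s == 1:
            copied = [genotypes[j][rng.integers(2)]]
        n_new = 2 - s
        if n_new:
            drawn = labels[
                np.searchsorted(np.cumsum(probs), rng.random(n_new), side="right")
            ]
            copied.extend(int(x) for x in drawn)
        out[j] = sorted(copied)
    return out, ibd
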
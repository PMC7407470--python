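"""Independent brute-force oracles used by the test suite.

These deliberately take different computational routes from the package:
probabilities by exhaustive enumeration of ordered founder-draw sequences,
coancestry by a literal transcription of the two-population
variance-component formulas, AUC by counting concordant pairs.
"""

from __future__ import annotations

import itertools

import numpy as np


def urn_sequence_probability(seq, p, theta):
    """Probability of drawing the ordered allele sequence from the coancestry urn."""
    prob = 1.0
    counts: dict = {}
    for j, x in enumerate(seq):
        m = counts.get(x, 0)
        prob *= (m * theta + (1 - theta) * p[x]) / (1 + (j - 1) * theta)
        counts[x] = m + 1
    return prob


def enumerate_pair_probabilities(delta, theta, p):
    """Joint probabilities of every unordered genotype pair at one locus.

    Enumerates all ordered founder-draw sequences and IBD assignments:
    with S alleles shared identical by descent the pair has 4 - S founder
    draws; for S = 1 each of the first individual's two copies is the
    shared one with probability 1/2.
    """
    alleles = list(p)
    out: dict = {}

    def add(g1, g2, pr):
        key = (tuple(sorted(g1)), tuple(sorted(g2)))
        out[key] = out.get(key, 0.0) + pr

    for seq in itertools.product(alleles, repeat=4):
        add(seq[:2], seq[2:], delta.delta0 * urn_sequence_probability(seq, p, theta))
    for seq in itertools.product(alleles, repeat=3):
        for i in (0, 1):
            add(
                seq[:2],
                (seq[i], seq[2]),
                delta.delta1 * 0.5 * urn_sequence_probability(seq, p, theta),
            )
    for seq in itertools.product(alleles, repeat=2):
        add(seq, seq, delta.delta2 * urn_sequence_probability(seq, p, theta))
    return out


def wc_theta_two_pops(g1, g2):
    """Literal Weir & Cockerham (1984) θ̂ for two population samples.

    ``g1``/``g2`` are (n, L, 2) arrays of allele labels; returns the
    ratio-of-sums estimate over all loci and alleles.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    r = 2
    n1, n2 = g1.shape[0], g2.shape[0]
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    num = den = 0.0
    for j in range(g1.shape[1]):
        col1, col2 = g1[:, j], g2[:, j]
        for al in np.unique(np.concatenate([col1.ravel(), col2.ravel()])):
            p1 = np.mean(col1 == al)
            p2 = np.mean(col2 == al)
            h1 = np.mean(np.sum(col1 == al, axis=1) == 1)
            h2 = np.mean(np.sum(col2 == al, axis=1) == 1)
            pbar = (n1 * p1 + n2 * p2) / (r * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (r * nbar)
            a = (nbar / nc) * (
                s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


def auc_by_pair_counting(scores, labels):
    """AUC as the probability a related pair outscores an unrelated one (ties = 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for s in pos:
        wins += np.sum(s > neg) + 0.5 * np.sum(s == neg)
    return wins / (pos.size * neg.size)
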
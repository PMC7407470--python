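"""Structured/admixed STR dataset generator with known ground truth.

Emulates a worldwide microsatellite reference panel: K drift-differentiated
source populations, a small subset of highly polymorphic forensic
("CODIS-like") loci nested inside a much larger locus set, and
mostly-unadmixed individuals in uneven group sizes.  Population allele
frequencies follow the Balding–Nichols drift model: at each locus an
ancestral frequency vector is drawn once from a symmetric Dirichlet(1),
and population k's frequencies are a Dirichlet draw centred on it with
concentration (1−F_k)/F_k, so F_k plays the role of the population's
divergence (Fst-like) from the shared ancestor.

Individuals carry a membership vector q over the K populations; every one
of their 2L allele copies is generated by first picking a source
population from q and then an allele from that population's locus
frequencies — the same mixture model under which downstream ancestry
inference and individual-weighted allele frequencies operate.

One integer seed drives a hierarchical RNG stream per stage (ancestral
frequencies, drift, memberships, genotypes), so each stage is
independently reproducible and the whole dataset is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .genotype_io import AlleleFrequencyTable, GenotypeTable

__all__ = ["SyntheticConfig", "GroundTruth", "generate_population_frequencies",
           "generate_individuals", "generate_dataset"]

#: Dirichlet weight on an individual's own prior group in admixed mode;
#: with the default off-group concentration 0.1 the mean own-group
#: membership is ≈0.87, i.e. mostly-unadmixed with visible mixing.
_OWN_GROUP_CONCENTRATION = 2.0

#: minimum allele count at the most polymorphic (forensic-like) loci
_MIN_ALLELES = 2


@dataclass
class SyntheticConfig:
    """Study-design parameters of a synthetic structured STR dataset.

    Defaults mirror the HGDP-style study design: K=4 source populations of
    94/532/269/83 diploid individuals, 791 STR loci of which 13 are
    forensic markers, moderate drift (F=0.08 per population, in the range
    spanned by the pairwise θ̂ values of worldwide human groups), and
    mostly-unadmixed membership vectors.
    """

    n_populations: int = 4
    n_individuals_per_pop: tuple[int, ...] = (94, 532, 269, 83)
    n_loci_total: int = 791
    n_forensic_loci: int = 13
    alleles_per_locus: int | tuple[int, int] = (4, 12)
    drift_F: float | tuple[float, ...] = 0.08
    forensic_drift_attenuation: float = 0.6
    admixture_alpha: float | str = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_individuals_per_pop = tuple(int(n) for n in self.n_individuals_per_pop)
        if len(self.n_individuals_per_pop) != self.n_populations:
            raise ValueError("one group size required per population")
        if min(self.n_individuals_per_pop) < 1 or self.n_loci_total < 1:
            raise ValueError("all counts must be positive")
        if not 0 < self.n_forensic_loci <= self.n_loci_total:
            raise ValueError("n_forensic_loci must be in [1, n_loci_total]")
        lo, hi = self.allele_range
        if lo < _MIN_ALLELES:
            raise ValueError("alleles_per_locus must be at least 2")
        if hi < lo:
            raise ValueError("alleles_per_locus range must be (low, high)")
        for f in self.drift_vector:
            if not 0.0 < f < 1.0:
                raise ValueError("drift_F must lie in the open interval (0, 1)")
        if not 0.0 < self.forensic_drift_attenuation <= 1.0:
            raise ValueError("forensic_drift_attenuation must lie in (0, 1]")
        if isinstance(self.admixture_alpha, str):
            if self.admixture_alpha != "unadmixed":
                raise ValueError("admixture_alpha must be a number or 'unadmixed'")
        elif self.admixture_alpha <= 0:
            raise ValueError("admixture_alpha must be positive")

    @property
    def allele_range(self) -> tuple[int, int]:
        a = self.alleles_per_locus
        return (a, a) if isinstance(a, int) else (int(a[0]), int(a[1]))

    @property
    def drift_vector(self) -> tuple[float, ...]:
        f = self.drift_F
        if isinstance(f, (int, float)):
            return (float(f),) * self.n_populations
        if len(f) != self.n_populations:
            raise ValueError("one drift_F required per population")
        return tuple(float(x) for x in f)

    @property
    def population_names(self) -> list[str]:
        return [f"pop{k + 1}" for k in range(self.n_populations)]

    @property
    def locus_names(self) -> list[str]:
        forensic = [f"CODIS{j + 1:02d}" for j in range(self.n_forensic_loci)]
        other = [
            f"STR{j + 1:03d}" for j in range(self.n_loci_total - self.n_forensic_loci)
        ]
        return forensic + other

    @property
    def forensic_flags(self) -> np.ndarray:
        flags = np.zeros(self.n_loci_total, dtype=bool)
        flags[: self.n_forensic_loci] = True
        return flags

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-keyed RNG stream derived from the single global seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("n_individuals_per_pop", "drift_F", "alleles_per_locus"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "n_populations": self.n_populations,
            "n_individuals_per_pop": list(self.n_individuals_per_pop),
            "n_loci_total": self.n_loci_total,
            "n_forensic_loci": self.n_forensic_loci,
            "alleles_per_locus": (
                self.alleles_per_locus
                if isinstance(self.alleles_per_locus, int)
                else list(self.alleles_per_locus)
            ),
            "drift_F": (
                self.drift_F if isinstance(self.drift_F, float) else list(self.drift_F)
            ),
            "forensic_drift_attenuation": self.forensic_drift_attenuation,
            "admixture_alpha": self.admixture_alpha,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class GroundTruth:
    """Known quantities behind a synthetic dataset, for recovery tests."""

    true_frequencies: AlleleFrequencyTable
    true_memberships: np.ndarray  # (n, K), rows sum to 1
    pedigree: dict = field(default_factory=dict)  # relative id -> {source, ibd}

    def __post_init__(self) -> None:
        self.true_memberships = np.asarray(self.true_memberships, dtype=float)
        if not np.allclose(self.true_memberships.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("membership vectors must sum to 1")


def generate_population_frequencies(config: SyntheticConfig) -> AlleleFrequencyTable:
    """Draw per-population allele frequencies under the drift model.

    Forensic loci take the top of the allele-count range (they emulate the
    highly polymorphic forensic STR panel) and drift with an attenuated
    effective divergence ``F_k * forensic_drift_attenuation``: the high
    mutation rate that keeps forensic STRs diverse also holds their
    between-population differentiation below that of typical loci, so a
    forensic-subset coancestry estimate runs lower than the genome-wide
    one.  Other loci draw their allele count uniformly from the range.
    Allele labels are repeat counts starting at 6.
    """
    rng_anc = config.rng(0)
    rng_drift = config.rng(1)
    lo, hi = config.allele_range
    drift = config.drift_vector
    alleles: dict[str, np.ndarray] = {}
    freqs: dict[str, np.ndarray] = {}
    names = config.locus_names
    flags = config.forensic_flags
    for name, forensic in zip(names, flags):
        n_alleles = hi if forensic else int(rng_anc.integers(lo, hi + 1))
        ancestral = rng_anc.dirichlet(np.ones(n_alleles))
        mat = np.empty((config.n_populations, n_alleles))
        for k, f in enumerate(drift):
            if forensic:
                f = f * config.forensic_drift_attenuation
            conc = ancestral * (1.0 - f) / f
            # Dirichlet with tiny concentrations can underflow to an all-zero
            # draw; keep parameters numerically positive
            mat[k] = rng_drift.dirichlet(np.maximum(conc, 1e-9))
        mat /= mat.sum(axis=1, keepdims=True)
        alleles[name] = np.arange(6, 6 + n_alleles)
        freqs[name] = mat
    return AlleleFrequencyTable(
        groups=config.population_names,
        loci=names,
        alleles=alleles,
        freqs=freqs,
        n_ref=None,
    )


def _draw_memberships(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    K = config.n_populations
    rows = []
    for k, n_k in enumerate(config.n_individuals_per_pop):
        if config.admixture_alpha == "unadmixed":
            q = np.zeros((n_k, K))
            q[:, k] = 1.0
        else:
            alpha = np.full(K, float(config.admixture_alpha))
            alpha[k] = _OWN_GROUP_CONCENTRATION
            q = rng.dirichlet(alpha, size=n_k)
        rows.append(q)
    return np.vstack(rows)


def generate_individuals(
    freqs: AlleleFrequencyTable, config: SyntheticConfig
) -> tuple[GenotypeTable, GroundTruth]:
    """Sample diploid individuals under the admixture mixture model.

    Each individual receives a membership vector q (degenerate in
    unadmixed mode, otherwise Dirichlet biased toward the prior group);
    each allele copy picks a source population from q, then an allele from
    that population's frequencies at the locus.
    """
    missing = [l for l in config.locus_names if l not in freqs.freqs]
    if missing:
        raise ValueError(f"frequency table does not cover loci: {missing[:5]} ...")
    rng_q = config.rng(2)
    rng_g = config.rng(3)
    Q = _draw_memberships(config, rng_q)
    n = Q.shape[0]
    cum_q = np.cumsum(Q, axis=1)
    loci = config.locus_names
    L = len(loci)
    genotypes = np.empty((n, L, 2), dtype=np.int64)
    for j, locus in enumerate(loci):
        cum_f = np.cumsum(freqs.freqs[locus], axis=1)
        labels = freqs.alleles[locus]
        src = (rng_g.random((n, 2, 1)) > cum_q[:, None, :]).sum(axis=2)
        idx = (rng_g.random((n, 2, 1)) > cum_f[src]).sum(axis=2)
        genotypes[:, j, :] = labels[idx]
    genotypes.sort(axis=2)
    individuals = []
    populations = []
    for k, n_k in enumerate(config.n_individuals_per_pop):
        pop = config.population_names[k]
        populations.extend([pop] * n_k)
        individuals.extend(f"{pop}_ind{i + 1:04d}" for i in range(n_k))
    table = GenotypeTable(
        individuals=individuals,
        populations=populations,
        loci=list(loci),
        forensic=config.forensic_flags,
        genotypes=genotypes,
    )
    truth = GroundTruth(true_frequencies=freqs, true_memberships=Q)
    return table, truth


def generate_dataset(config: SyntheticConfig) -> tuple[GenotypeTable, GroundTruth]:
    """Frequencies plus individuals in one call."""
    freqs = generate_population_frequencies(config)
    return generate_individuals(freqs, config)
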
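"""End-to-end experiments: simulate siblings, scan pairs, summarise.

Two experiments mirror the two ways of choosing allele frequencies for a
familial-search likelihood ratio:

* *Predefined-Population* — score every (individual, simulated sibling)
  pair within each true population under each population's observed
  sample allele frequencies, producing a (assumed × true) grid of
  distinguishability values whose diagonal is the correctly-specified
  case.
* *Ancestry-Estimation* — score the same pairs under the query
  individual's own mixture allele frequencies (membership-weighted
  cluster frequencies), in three data-availability scenarios: full/full
  (frequencies and memberships from all loci), full/codis (full-data
  frequencies, forensic-only memberships) and codis/codis (both from the
  forensic loci alone).

Siblings are simulated once per study and reused across every frequency
scenario, so scenario contrasts reflect only the assumed frequencies.
A balanced down-sampling mode reruns the whole pipeline on random
same-size subsets of each prior group.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import kinship
from .ancestry import EMSettings, align_to, em_replicates, mixture_frequencies
from .genotype_io import AlleleFrequencyTable, AncestryModel, GenotypeTable, read_genotypes
from .kinship import SIBLING, RelatednessCoefficients, floor_frequencies
from .popgen_stats import DistinguishabilityResult, ROCCurve, distinguishability, roc, wc_theta
from .synthetic_data import GroundTruth, SyntheticConfig, generate_dataset

logger = logging.getLogger("kinlr")

__all__ = [
    "ExperimentConfig",
    "StudyData",
    "ScanResult",
    "DownsampleResult",
    "prepare_study",
    "run_predefined_population",
    "run_ancestry_estimation",
    "run_downsampled",
    "coancestry_report",
]

ANCESTRY_SCENARIOS = ("full/full", "full/codis", "codis/codis")


@dataclass
class ExperimentConfig:
    """Configuration of one study run.

    The dataset source is either a synthetic-data configuration or a path
    to a genotype file; exactly one must be given.
    """

    synthetic: SyntheticConfig | None = None
    genotypes_path: str | None = None
    genotypes_dialect: str = "tidy_table"
    n_siblings_per_individual: int = 10
    theta_lr: float = 0.01
    em: EMSettings = field(default_factory=EMSettings)
    related_delta: RelatednessCoefficients = SIBLING
    downsample_size: int | None = None
    downsample_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.genotypes_path is None):
            raise ValueError("provide exactly one of synthetic config or genotypes_path")
        if self.n_siblings_per_individual < 1:
            raise ValueError("n_siblings_per_individual must be at least 1")
        if not 0.0 <= self.theta_lr < 1.0:
            raise ValueError("theta_lr must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synthetic", None)
        if synth is not None:
            for key in ("n_individuals_per_pop", "drift_F", "alleles_per_locus"):
                if key in synth and isinstance(synth[key], list):
                    synth[key] = tuple(synth[key])
            synth = SyntheticConfig(**synth)
        em = EMSettings(**raw.pop("em", {}))
        return cls(synthetic=synth, em=em, **raw)


@dataclass
class StudyData:
    """A dataset plus everything derived from it that experiments share."""

    genotypes: GenotypeTable
    truth: GroundTruth | None
    full_model: AncestryModel
    codis_model: AncestryModel
    sib_genotypes: np.ndarray  # (n_sibs_total, L_forensic, 2) allele labels
    sib_source: np.ndarray  # (n_sibs_total,) index of the source individual
    sib_ids: list[str]
    sib_ibd: np.ndarray  # (n_sibs_total, L_forensic) IBD-state traces
    forensic_loci: list[str] = field(default_factory=list)


@dataclass
class ScanResult:
    """Per-pair log LRs and their per-(scenario, population) summaries."""

    d_grid: pd.DataFrame  # scenario (assumed) x true population
    details: dict[tuple[str, str], DistinguishabilityResult]
    rocs: dict[tuple[str, str], ROCCurve]
    records: pd.DataFrame  # scenario, true_pop, query, candidate, truth, log_lr


@dataclass
class DownsampleResult:
    predefined: list[pd.DataFrame]
    ancestry: list[pd.DataFrame]
    mean_predefined: pd.DataFrame
    mean_ancestry: pd.DataFrame
    subsets: list[list[str]]


# ---------------------------------------------------------------------------
# study preparation
# ---------------------------------------------------------------------------


def _child_seed(config_seed: int, prefix: tuple[int, ...], stage: int) -> int:
    seq = np.random.SeedSequence(config_seed, spawn_key=prefix + (stage,))
    return int(seq.generate_state(1)[0] % (2**31))


def _load_dataset(config: ExperimentConfig) -> tuple[GenotypeTable, GroundTruth | None]:
    if config.synthetic is not None:
        return generate_dataset(config.synthetic)
    table = read_genotypes(config.genotypes_path, dialect=config.genotypes_dialect)
    if not np.any(table.forensic):
        raise ValueError("the genotype file does not flag any forensic loci")
    return table, None


def prepare_study(
    config: ExperimentConfig,
    genotypes: GenotypeTable | None = None,
    truth: GroundTruth | None = None,
    seed_prefix: tuple[int, ...] = (),
) -> StudyData:
    """Generate/load data, infer ancestry (full and forensic-only), simulate siblings.

    Sibling genotypes are generated at the forensic loci from each
    individual's membership-weighted allele frequencies under the
    full-data consensus model, with sibling identity-by-descent drawn
    from the configured relatedness coefficients.
    """
    t0 = time.perf_counter()
    if genotypes is None:
        genotypes, truth = _load_dataset(config)
    forensic = genotypes.forensic_loci
    if not forensic:
        raise ValueError("dataset has no forensic loci")
    genotypes.require_complete(forensic)

    em_full = EMSettings(
        K=config.em.K,
        mode=config.em.mode,
        n_replicates=config.em.n_replicates,
        max_iterations=config.em.max_iterations,
        relative_loglik_tolerance=config.em.relative_loglik_tolerance,
        seed=_child_seed(config.seed, seed_prefix, 1),
    )
    em_codis = EMSettings(
        K=config.em.K,
        mode=config.em.mode,
        n_replicates=config.em.n_replicates,
        max_iterations=config.em.max_iterations,
        relative_loglik_tolerance=config.em.relative_loglik_tolerance,
        seed=_child_seed(config.seed, seed_prefix, 2),
    )
    logger.info("ancestry inference (all %d loci) ...", genotypes.n_loci)
    full_model = em_replicates(genotypes, em_full).consensus
    logger.info("ancestry inference (%d forensic loci) ...", len(forensic))
    codis_model = em_replicates(genotypes, em_codis, loci=forensic).consensus
    # cluster labels of the two independent inferences are arbitrary; relabel
    # the forensic-only model onto the full-data model so that mixing one
    # model's P with the other's Q pairs corresponding clusters
    codis_model = align_to(codis_model, full_model)
    logger.info("ancestry done in %.1fs", time.perf_counter() - t0)

    # per-individual mixture frequencies (full-data model) drive simulation
    P_f = full_model.P.subset_loci(forensic)
    mix = mixture_frequencies(full_model.Q, P_f)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=seed_prefix + (3,))
    )
    n = genotypes.n_individuals
    n_sib = config.n_siblings_per_individual
    forensic_table = genotypes.subset_loci(forensic)
    sib_genos = np.empty((n * n_sib, len(forensic), 2), dtype=np.int64)
    sib_ibd = np.empty((n * n_sib, len(forensic)), dtype=np.int8)
    sib_source = np.repeat(np.arange(n), n_sib)
    sib_ids = []
    for i in range(n):
        freqs_i = [(P_f.alleles[l], mix[l][i]) for l in forensic]
        for r in range(n_sib):
            g, ibd = kinship.simulate_relative(
                forensic_table.genotypes[i], config.related_delta, freqs_i, rng
            )
            sib_genos[i * n_sib + r] = g
            sib_ibd[i * n_sib + r] = ibd
            sib_ids.append(f"{genotypes.individuals[i]}_sib{r + 1}")
    if truth is not None:
        for s, sid in enumerate(sib_ids):
            truth.pedigree[sid] = {
                "source": genotypes.individuals[sib_source[s]],
                "ibd": sib_ibd[s],
            }
    logger.info("simulated %d siblings in %.1fs", len(sib_ids), time.perf_counter() - t0)
    return StudyData(
        genotypes=genotypes,
        truth=truth,
        full_model=full_model,
        codis_model=codis_model,
        sib_genotypes=sib_genos,
        sib_source=sib_source,
        sib_ids=sib_ids,
        sib_ibd=sib_ibd,
        forensic_loci=list(forensic),
    )


# ---------------------------------------------------------------------------
# pair scoring
# ---------------------------------------------------------------------------


def _union_alleles(study: StudyData) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Per-locus union allele labels and index-encoded genotypes (queries, sibs)."""
    table = study.genotypes.subset_loci(study.forensic_loci)
    labels = []
    Gq = np.empty_like(table.genotypes)
    Gs = np.empty_like(study.sib_genotypes)
    for j in range(len(study.forensic_loci)):
        u = np.unique(
            np.concatenate(
                [table.genotypes[:, j].ravel(), study.sib_genotypes[:, j].ravel()]
            )
        )
        labels.append(u)
        Gq[:, j] = np.searchsorted(u, table.genotypes[:, j])
        Gs[:, j] = np.searchsorted(u, study.sib_genotypes[:, j])
    return labels, Gq, Gs


def _expand_to_union(
    table: AlleleFrequencyTable, group: str, union: list[np.ndarray], loci: list[str]
) -> list[np.ndarray]:
    """One group's frequency vectors re-indexed on the union allele sets (zeros for absent)."""
    k = table.group_index(group)
    out = []
    for j, locus in enumerate(loci):
        vec = np.zeros(union[j].size)
        idx = np.searchsorted(union[j], table.alleles[locus])
        vec[idx] = table.freqs[locus][k]
        out.append(vec)
    return out


def _mixture_on_union(
    Q: np.ndarray, P: AlleleFrequencyTable, union: list[np.ndarray], loci: list[str]
) -> list[np.ndarray]:
    mix = mixture_frequencies(Q, P.subset_loci(loci))
    out = []
    for j, locus in enumerate(loci):
        mat = np.zeros((Q.shape[0], union[j].size))
        idx = np.searchsorted(union[j], P.alleles[locus])
        mat[:, idx] = mix[locus]
        out.append(mat)
    return out


def _floor_freqs(freq_per_locus: list[np.ndarray], n_ref: int) -> list[np.ndarray]:
    return [floor_frequencies(f, n_ref) for f in freq_per_locus]


def _score_population(
    Gq: np.ndarray,
    Gs: np.ndarray,
    pair_q: np.ndarray,
    pair_s: np.ndarray,
    freq_per_locus: list[np.ndarray],
    theta: float,
    related_delta: RelatednessCoefficients,
) -> np.ndarray:
    """Total log LR for each pair; frequencies may be shared vectors or per-query rows."""
    total = np.zeros(pair_q.size)
    for j, f in enumerate(freq_per_locus):
        a, b = Gq[pair_q, j, 0], Gq[pair_q, j, 1]
        c, d = Gs[pair_s, j, 0], Gs[pair_s, j, 1]
        if f.ndim == 1:
            pa, pb, pc, pd = f[a], f[b], f[c], f[d]
        else:
            pa, pb, pc, pd = f[pair_q, a], f[pair_q, b], f[pair_q, c], f[pair_q, d]
        p0, p1, p2 = kinship.pair_state_probabilities(a, b, c, d, pa, pb, pc, pd, theta)
        num = (
            related_delta.delta0 * p0
            + related_delta.delta1 * p1
            + related_delta.delta2 * p2
        )
        total += np.log(num) - np.log(p0)
    return total


def _pairs_for_population(
    study: StudyData, pop: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (individual, simulated-sibling) pairs within one true population.

    With n individuals and m siblings each this yields n·(m·n) pairs, of
    which n·m pair an individual with its own simulated siblings
    (related) and n·(m·n − m) pair it with siblings of others (unrelated).
    """
    members = study.genotypes.population_indices(pop)
    sib_idx = np.flatnonzero(np.isin(study.sib_source, members))
    pair_q = np.repeat(members, sib_idx.size)
    pair_s = np.tile(sib_idx, members.size)
    related = study.sib_source[pair_s] == pair_q
    return pair_q, pair_s, related


def _scan(
    study: StudyData,
    scenario_freqs: dict[str, list[np.ndarray]],
    theta: float,
    related_delta: RelatednessCoefficients,
    keep_records: bool = True,
) -> ScanResult:
    union, Gq, Gs = _union_alleles(study)
    del union
    pops = study.genotypes.population_names
    scenarios = list(scenario_freqs)
    d_grid = pd.DataFrame(
        np.nan,
        index=pd.Index(scenarios, name="assumed"),
        columns=pd.Index(pops, name="true"),
    )
    details: dict[tuple[str, str], DistinguishabilityResult] = {}
    rocs: dict[tuple[str, str], ROCCurve] = {}
    chunks = []
    for pop in pops:
        pair_q, pair_s, related = _pairs_for_population(study, pop)
        for scen in scenarios:
            t0 = time.perf_counter()
            log_lr = _score_population(
                Gq, Gs, pair_q, pair_s, scenario_freqs[scen], theta, related_delta
            )
            res = distinguishability(log_lr[related], log_lr[~related])
            d_grid.loc[scen, pop] = res.d_vh
            details[(scen, pop)] = res
            rocs[(scen, pop)] = roc(log_lr, related)
            logger.info(
                "scored %s / %s: %d pairs, D~VH=%.3f (%.1fs)",
                scen, pop, pair_q.size, res.d_vh, time.perf_counter() - t0,
            )
            if keep_records:
                chunks.append(
                    pd.DataFrame(
                        {
                            "scenario": scen,
                            "true_pop": pop,
                            "query": np.asarray(study.genotypes.individuals)[pair_q],
                            "candidate": np.asarray(study.sib_ids)[pair_s],
                            "truth": np.where(related, "related", "unrelated"),
                            "log_lr": log_lr,
                        }
                    )
                )
    records = pd.concat(chunks, ignore_index=True) if chunks else pd.DataFrame()
    return ScanResult(d_grid=d_grid, details=details, rocs=rocs, records=records)


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


def run_predefined_population(
    config: ExperimentConfig,
    study: StudyData | None = None,
    keep_records: bool = True,
) -> ScanResult:
    """Score every within-population pair under each population's sample frequencies."""
    if study is None:
        study = prepare_study(config)
    union, _, _ = _union_alleles(study)
    sample = study.genotypes.sample_frequencies(loci=study.forensic_loci)
    scenario_freqs: dict[str, list[np.ndarray]] = {}
    for pop in study.genotypes.population_names:
        vecs = _expand_to_union(sample, pop, union, study.forensic_loci)
        n_pop = study.genotypes.population_indices(pop).size
        scenario_freqs[pop] = _floor_freqs(vecs, n_pop)
    return _scan(study, scenario_freqs, config.theta_lr, config.related_delta, keep_records)


def run_ancestry_estimation(
    config: ExperimentConfig,
    study: StudyData | None = None,
    scenarios: Sequence[str] = ANCESTRY_SCENARIOS,
    keep_records: bool = True,
) -> ScanResult:
    """Score the same pairs under per-query mixture frequencies for each scenario."""
    if study is None:
        study = prepare_study(config)
    for scen in scenarios:
        if scen not in ANCESTRY_SCENARIOS:
            raise ValueError(f"unknown scenario {scen!r}; expected one of {ANCESTRY_SCENARIOS}")
    union, _, _ = _union_alleles(study)
    n = study.genotypes.n_individuals
    scenario_freqs: dict[str, list[np.ndarray]] = {}
    for scen in scenarios:
        P = study.full_model.P if scen.startswith("full/") else study.codis_model.P
        Q = study.full_model.Q if scen == "full/full" else study.codis_model.Q
        mats = _mixture_on_union(Q, P, union, study.forensic_loci)
        scenario_freqs[scen] = _floor_freqs(mats, n)
    return _scan(study, scenario_freqs, config.theta_lr, config.related_delta, keep_records)


def run_downsampled(config: ExperimentConfig) -> DownsampleResult:
    """Rerun both experiments on balanced random subsets of each prior group."""
    if config.downsample_size is None:
        raise ValueError("config.downsample_size must be set")
    genotypes, truth = _load_dataset(config)
    sizes = {p: genotypes.population_indices(p).size for p in genotypes.population_names}
    if config.downsample_size > min(sizes.values()):
        raise ValueError(
            f"downsample size {config.downsample_size} exceeds the smallest group "
            f"({min(sizes.values())})"
        )
    pre_grids, anc_grids, subsets = [], [], []
    for r in range(config.downsample_replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(1000 + r, 0))
        )
        chosen = []
        for pop in genotypes.population_names:
            members = genotypes.population_indices(pop)
            chosen.extend(
                sorted(rng.choice(members, size=config.downsample_size, replace=False))
            )
        chosen = sorted(chosen)
        # a subsample containing everyone is a no-op: reuse the standard seed path
        prefix = () if len(chosen) == genotypes.n_individuals else (1000 + r,)
        sub = genotypes.subset_individuals(chosen)
        study = prepare_study(config, genotypes=sub, truth=None, seed_prefix=prefix)
        pre = run_predefined_population(config, study, keep_records=False)
        anc = run_ancestry_estimation(config, study, keep_records=False)
        pre_grids.append(pre.d_grid)
        anc_grids.append(anc.d_grid)
        subsets.append([genotypes.individuals[i] for i in chosen])
    mean_pre = sum(pre_grids) / len(pre_grids)
    mean_anc = sum(anc_grids) / len(anc_grids)
    return DownsampleResult(
        predefined=pre_grids,
        ancestry=anc_grids,
        mean_predefined=mean_pre,
        mean_ancestry=mean_anc,
        subsets=subsets,
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def coancestry_report(genotypes: GenotypeTable) -> pd.DataFrame:
    """Pairwise θ̂ matrix: upper triangle all loci, lower triangle forensic loci."""
    pops = genotypes.population_names
    tables = {p: genotypes.subset_individuals(genotypes.population_indices(p)) for p in pops}
    out = pd.DataFrame(
        np.nan, index=pd.Index(pops, name="pop"), columns=pd.Index(pops, name="pop")
    )
    forensic = genotypes.forensic_loci
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1 :]:
            out.loc[p1, p2] = wc_theta(tables[p1], tables[p2], locus_set="all").theta_hat
            out.loc[p2, p1] = wc_theta(
                tables[p1], tables[p2], loci=forensic, locus_set="forensic"
            ).theta_hat
    return out
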
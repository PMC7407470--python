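"""Genotype, allele-frequency, and ancestry-model containers with text I/O.

Two external genotype dialects are supported:

``structure_two_row``
    The classic population-structure input convention: one header line of
    locus names, then two whitespace-separated rows per individual
    (``id  population  allele-at-locus-1 ...``), the first row carrying one
    allele copy per locus and the second row the other.

``tidy_table``
    A self-describing tab-separated table, one row per individual, genotype
    fields written ``a1/a2``.  An optional ``#forensic=...`` comment line
    names the forensic-marker subset.

Missing data are encoded ``-9`` on disk and :data:`MISSING` in memory.
Genotypes are stored as unordered pairs, sorted ascending, so two tables
are comparable element-wise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -9

__all__ = [
    "MISSING",
    "AlleleFrequencyTable",
    "GenotypeTable",
    "AncestryModel",
    "ParseError",
    "read_genotypes",
    "write_genotypes",
    "read_matrix",
    "write_matrix",
    "frequency_table_to_frame",
    "frame_to_frequency_table",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class AlleleFrequencyTable:
    """Per-group, per-locus categorical allele frequencies.

    Parameters
    ----------
    groups
        Ordered group (population or inferred-cluster) names.
    loci
        Ordered locus names.
    alleles
        Mapping locus -> sorted integer allele labels (repeat counts).
    freqs
        Mapping locus -> array of shape ``(n_groups, n_alleles)``; each row
        is a probability vector over that locus's alleles.
    n_ref
        Reference sample size (diploid individuals) behind the table, used
        by downstream zero-frequency flooring.  ``None`` when the table is
        exact (e.g. simulation ground truth).
    """

    groups: list[str]
    loci: list[str]
    alleles: dict[str, np.ndarray]
    freqs: dict[str, np.ndarray]
    n_ref: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, atol: float = 1e-9) -> None:
        for locus in self.loci:
            if locus not in self.alleles or locus not in self.freqs:
                raise ValueError(f"locus {locus!r} missing allele or frequency data")
            a = np.asarray(self.alleles[locus])
            if np.any(np.diff(a) <= 0):
                raise ValueError(f"allele labels at {locus!r} must be strictly increasing")
            f = np.asarray(self.freqs[locus], dtype=float)
            if f.shape != (len(self.groups), a.size):
                raise ValueError(
                    f"frequency matrix at {locus!r} has shape {f.shape}, "
                    f"expected {(len(self.groups), a.size)}"
                )
            if np.any(f < 0):
                raise ValueError(f"negative frequency at {locus!r}")
            if not np.allclose(f.sum(axis=1), 1.0, atol=atol):
                raise ValueError(f"frequencies at {locus!r} do not sum to 1")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_index(self, group: str) -> int:
        return self.groups.index(group)

    def group_vectors(self, group: str) -> dict[str, np.ndarray]:
        """Per-locus frequency vectors for one group."""
        k = self.group_index(group)
        return {locus: self.freqs[locus][k].copy() for locus in self.loci}

    def subset_loci(self, loci: Sequence[str]) -> "AlleleFrequencyTable":
        missing = [l for l in loci if l not in self.freqs]
        if missing:
            raise ValueError(f"loci not in table: {missing}")
        return AlleleFrequencyTable(
            groups=list(self.groups),
            loci=list(loci),
            alleles={l: self.alleles[l].copy() for l in loci},
            freqs={l: self.freqs[l].copy() for l in loci},
            n_ref=self.n_ref,
        )


@dataclass
class GenotypeTable:
    """Diploid unordered multiallelic genotypes with prior-population labels.

    ``genotypes`` has shape ``(n_individuals, n_loci, 2)`` with each pair
    sorted ascending; missing alleles are :data:`MISSING`.
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    forensic: np.ndarray
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.forensic = np.asarray(self.forensic, dtype=bool)
        self.genotypes = np.asarray(self.genotypes)
        self.validate()

    def validate(self) -> None:
        n, L = len(self.individuals), len(self.loci)
        if len(set(self.individuals)) != n:
            raise ValueError("duplicate individual identifiers")
        if len(self.populations) != n:
            raise ValueError("one population label required per individual")
        if self.forensic.shape != (L,):
            raise ValueError("forensic flag must have one entry per locus")
        if self.genotypes.shape != (n, L, 2):
            raise ValueError(
                f"genotype array has shape {self.genotypes.shape}, expected {(n, L, 2)}"
            )
        if np.any(self.genotypes[..., 0] > self.genotypes[..., 1]):
            raise ValueError("genotype pairs must be stored sorted ascending")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def forensic_loci(self) -> list[str]:
        return [l for l, f in zip(self.loci, self.forensic) if f]

    @property
    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def population_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.populations) == np.asarray(population))
        if idx.size == 0:
            raise KeyError(f"no individuals with prior population {population!r}")
        return idx

    def is_missing(self) -> np.ndarray:
        """Boolean (n, L) mask of genotypes with any missing allele."""
        return np.any(self.genotypes == MISSING, axis=2)

    def subset_individuals(self, indices: Sequence[int]) -> "GenotypeTable":
        indices = np.asarray(indices)
        return GenotypeTable(
            individuals=[self.individuals[i] for i in indices],
            populations=[self.populations[i] for i in indices],
            loci=list(self.loci),
            forensic=self.forensic.copy(),
            genotypes=self.genotypes[indices].copy(),
        )

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeTable":
        pos = {l: j for j, l in enumerate(self.loci)}
        missing = [l for l in loci if l not in pos]
        if missing:
            raise ValueError(f"loci not in table: {missing}")
        cols = [pos[l] for l in loci]
        return GenotypeTable(
            individuals=list(self.individuals),
            populations=list(self.populations),
            loci=list(loci),
            forensic=self.forensic[cols].copy(),
            genotypes=self.genotypes[:, cols].copy(),
        )

    def require_complete(self, loci: Sequence[str] | None = None) -> None:
        """Raise if any genotype at the given loci (default: all) is missing."""
        sub = self if loci is None else self.subset_loci(list(loci))
        if np.any(sub.is_missing()):
            bad = np.argwhere(sub.is_missing())[0]
            raise ValueError(
                f"missing genotype for individual {sub.individuals[bad[0]]!r} "
                f"at locus {sub.loci[bad[1]]!r}; these loci must be complete"
            )

    def sample_frequencies(
        self, loci: Sequence[str] | None = None, by_population: bool = True
    ) -> AlleleFrequencyTable:
        """Observed allele frequencies, per prior population (or pooled).

        Missing alleles are dropped from the counts.  ``n_ref`` is set to
        the smallest per-group diploid sample size.
        """
        sub = self if loci is None else self.subset_loci(list(loci))
        groups = sub.population_names if by_population else ["pooled"]
        group_rows = (
            [sub.population_indices(g) for g in groups]
            if by_population
            else [np.arange(sub.n_individuals)]
        )
        alleles: dict[str, np.ndarray] = {}
        freqs: dict[str, np.ndarray] = {}
        for j, locus in enumerate(sub.loci):
            col = sub.genotypes[:, j, :]
            observed = np.unique(col[col != MISSING])
            if observed.size == 0:
                raise ValueError(f"locus {locus!r} has no observed alleles")
            mat = np.zeros((len(groups), observed.size))
            for gi, rows in enumerate(group_rows):
                vals = col[rows].ravel()
                vals = vals[vals != MISSING]
                if vals.size == 0:
                    raise ValueError(
                        f"group {groups[gi]!r} has no data at locus {locus!r}"
                    )
                counts = np.bincount(
                    np.searchsorted(observed, vals), minlength=observed.size
                )
                mat[gi] = counts / counts.sum()
            alleles[locus] = observed.astype(int)
            freqs[locus] = mat
        n_ref = min(len(rows) for rows in group_rows)
        return AlleleFrequencyTable(
            groups=list(groups), loci=list(sub.loci), alleles=alleles, freqs=freqs,
            n_ref=n_ref,
        )


@dataclass
class AncestryModel:
    """Point estimates from one admixture-model inference run.

    ``Q`` holds per-individual membership proportions (rows sum to 1) and
    ``P`` the inferred cluster allele frequencies.
    """

    Q: np.ndarray
    P: AlleleFrequencyTable
    log_likelihood: float
    loci: list[str] = field(default_factory=list)
    individuals: list[str] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.Q.ndim != 2:
            raise ValueError("Q must be 2-D (individuals x clusters)")
        if self.Q.shape[1] != self.P.n_groups:
            raise ValueError("Q column count must match number of clusters in P")
        if np.any(self.Q < -1e-12):
            raise ValueError("negative membership proportion")
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Q rows must sum to 1")
        self.P.validate()

    @property
    def n_clusters(self) -> int:
        return self.P.n_groups


# ---------------------------------------------------------------------------
# genotype file formats
# ---------------------------------------------------------------------------

_DIALECTS = ("structure_two_row", "tidy_table")


def read_genotypes(
    path: str | Path,
    dialect: str = "tidy_table",
    forensic_loci: Sequence[str] | None = None,
    missing_code: int = MISSING,
) -> GenotypeTable:
    """Read a genotype file under the named dialect.

    ``forensic_loci`` overrides (or, for the two-row dialect, supplies) the
    forensic-subset flag; the tidy dialect stores the flag in the file.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    path = Path(path)
    lines = path.read_text().splitlines()
    if dialect == "structure_two_row":
        table = _parse_structure(lines, missing_code)
    else:
        table = _parse_tidy(lines, missing_code)
    if forensic_loci is not None:
        flags = np.array([l in set(forensic_loci) for l in table.loci])
        table = dataclasses.replace(table, forensic=flags)
    return table


def _parse_structure(lines: list[str], missing_code: int) -> GenotypeTable:
    content = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not content:
        raise ParseError("empty file")
    _, header = content[0]
    loci = header.split()
    body = content[1:]
    if len(body) % 2 != 0:
        raise ParseError(
            f"two-row dialect requires an even number of genotype rows, got {len(body)}"
        )
    individuals: list[str] = []
    populations: list[str] = []
    rows: list[np.ndarray] = []
    for (ln1, first), (ln2, second) in zip(body[::2], body[1::2]):
        g = np.empty((len(loci), 2), dtype=int)
        for slot, (lineno, line) in enumerate(((ln1, first), (ln2, second))):
            tok = line.split()
            if len(tok) != len(loci) + 2:
                raise ParseError(
                    f"line {lineno}: expected {len(loci) + 2} fields, got {len(tok)}"
                )
            if slot == 0:
                individuals.append(tok[0])
                populations.append(tok[1])
            elif tok[0] != individuals[-1]:
                raise ParseError(
                    f"line {lineno}: second row for {individuals[-1]!r} is labelled {tok[0]!r}"
                )
            try:
                g[:, slot] = [int(t) for t in tok[2:]]
            except ValueError as exc:
                raise ParseError(f"line {lineno}: unknown allele token ({exc})") from None
        rows.append(g)
    genotypes = _normalise(np.stack(rows), missing_code)
    return GenotypeTable(
        individuals=individuals,
        populations=populations,
        loci=loci,
        forensic=np.zeros(len(loci), dtype=bool),
        genotypes=genotypes,
    )


def _parse_tidy(lines: list[str], missing_code: int) -> GenotypeTable:
    forensic_names: set[str] = set()
    content: list[tuple[int, str]] = []
    for i, ln in enumerate(lines):
        if ln.startswith("#forensic="):
            forensic_names = {s for s in ln[len("#forensic="):].split(",") if s}
        elif ln.strip() and not ln.startswith("#"):
            content.append((i + 1, ln))
    if not content:
        raise ParseError("empty file")
    _, header = content[0]
    cols = header.rstrip("\n").split("\t")
    if len(cols) < 3 or cols[0] != "individual" or cols[1] != "population":
        raise ParseError("tidy header must start with 'individual\\tpopulation'")
    loci = cols[2:]
    individuals, populations, rows = [], [], []
    for lineno, line in content[1:]:
        tok = line.split("\t")
        if len(tok) != len(cols):
            raise ParseError(f"line {lineno}: expected {len(cols)} fields, got {len(tok)}")
        individuals.append(tok[0])
        populations.append(tok[1])
        g = np.empty((len(loci), 2), dtype=int)
        for j, cell in enumerate(tok[2:]):
            parts = cell.split("/")
            if len(parts) != 2:
                raise ParseError(
                    f"line {lineno}: genotype {cell!r} at locus {loci[j]!r} is not 'a1/a2'"
                )
            try:
                g[j] = [int(parts[0]), int(parts[1])]
            except ValueError:
                raise ParseError(
                    f"line {lineno}: unknown allele token in {cell!r} at locus {loci[j]!r}"
                ) from None
        rows.append(g)
    genotypes = _normalise(np.stack(rows), missing_code)
    return GenotypeTable(
        individuals=individuals,
        populations=populations,
        loci=loci,
        forensic=np.array([l in forensic_names for l in loci]),
        genotypes=genotypes,
    )


def _normalise(genotypes: np.ndarray, missing_code: int) -> np.ndarray:
    g = genotypes.copy()
    g[g == missing_code] = MISSING
    # a half-missing genotype is treated as missing
    half = np.any(g == MISSING, axis=2) & ~np.all(g == MISSING, axis=2)
    g[half] = MISSING
    return np.sort(g, axis=2)


def write_genotypes(
    table: GenotypeTable, path: str | Path, dialect: str = "tidy_table"
) -> None:
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    path = Path(path)
    out: list[str] = []
    if dialect == "tidy_table":
        if np.any(table.forensic):
            out.append("#forensic=" + ",".join(table.forensic_loci))
        out.append("\t".join(["individual", "population", *table.loci]))
        for i, ind in enumerate(table.individuals):
            cells = [f"{a}/{b}" for a, b in table.genotypes[i]]
            out.append("\t".join([ind, table.populations[i], *cells]))
    else:
        out.append(" ".join(table.loci))
        for i, ind in enumerate(table.individuals):
            for slot in (0, 1):
                alleles = " ".join(str(a) for a in table.genotypes[i, :, slot])
                out.append(f"{ind} {table.populations[i]} {alleles}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# matrix files (Q / P / frequency tables)
# ---------------------------------------------------------------------------


def write_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a labelled numeric matrix as tab-separated text.

    Numbers carry 17 significant digits so a read-back reproduces the
    values to better than 1e-12; explicit zeros are retained.
    """
    frame.to_csv(Path(path), sep="\t", float_format="%.17g", lineterminator="\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", index_col=0)


def frequency_table_to_frame(table: AlleleFrequencyTable) -> pd.DataFrame:
    """Long-format view: one row per (locus, allele), one column per group."""
    rows = []
    for locus in table.loci:
        for j, allele in enumerate(table.alleles[locus]):
            rows.append([locus, int(allele), *table.freqs[locus][:, j]])
    frame = pd.DataFrame(rows, columns=["locus", "allele", *table.groups])
    return frame.set_index("locus")


def frame_to_frequency_table(
    frame: pd.DataFrame, n_ref: int | None = None
) -> AlleleFrequencyTable:
    groups = [c for c in frame.columns if c != "allele"]
    loci = list(dict.fromkeys(frame.index))
    alleles: dict[str, np.ndarray] = {}
    freqs: dict[str, np.ndarray] = {}
    for locus in loci:
        block = frame.loc[[locus]]
        order = np.argsort(block["allele"].to_numpy())
        alleles[locus] = block["allele"].to_numpy()[order].astype(int)
        freqs[locus] = block[groups].to_numpy()[order].T
    return AlleleFrequencyTable(
        groups=groups, loci=loci, alleles=alleles, freqs=freqs, n_ref=n_ref
    )


def membership_frame(
    Q: np.ndarray, individuals: Sequence[str], clusters: Sequence[str] | None = None
) -> pd.DataFrame:
    """Label a membership matrix for writing with :func:`write_matrix`."""
    Q = np.asarray(Q)
    if clusters is None:
        clusters = [f"cluster{k + 1}" for k in range(Q.shape[1])]
    return pd.DataFrame(Q, index=pd.Index(individuals, name="individual"), columns=clusters)
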
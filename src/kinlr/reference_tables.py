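"""Reference summary tables for the four-group HGDP CODIS analysis.

These are the published summary statistics of the worldwide HGDP
microsatellite panel (978 individuals, 791 STR loci, 13 CODIS forensic
markers) grouped into four continental-scale populations — Sub-Saharan
African (A), European/Middle Eastern/Central-South Asian (EMC), East
Asian/Oceanian (EAO), and Native American (NA):

* the 4×4 distinguishability grid (assumed × true population) for
  sibling-vs-unrelated likelihood ratios under predefined-population
  allele frequencies,
* pairwise Weir–Cockerham coancestry estimates θ̂, from the 13 CODIS loci
  and from all 791 loci.

They allow the distinguishability-vs-coancestry regression to be rebuilt
without access to the genotype data: each of the 16 grid cells pairs a
distinguishability value with the CODIS θ̂ between its true and assumed
populations (0 when they coincide).
"""

from __future__ import annotations

import pandas as pd

from .popgen_stats import ols_line

__all__ = [
    "POPULATIONS",
    "distinguishability_grid",
    "coancestry_matrix",
    "regression_points",
    "distinguishability_regression",
]

POPULATIONS = ("A", "EMC", "EAO", "NA")

# rows: assumed population, columns: true population
_D_VH = [
    [6.52, 5.50, 5.27, 3.66],
    [5.78, 6.13, 5.87, 3.75],
    [5.61, 5.69, 6.17, 4.22],
    [4.55, 4.72, 4.39, 5.28],
]

# pairwise theta-hat; 13 CODIS loci
_THETA_CODIS = {
    ("A", "EMC"): 0.024,
    ("A", "EAO"): 0.036,
    ("A", "NA"): 0.081,
    ("EMC", "EAO"): 0.013,
    ("EMC", "NA"): 0.058,
    ("EAO", "NA"): 0.053,
}

# pairwise theta-hat; all 791 loci
_THETA_FULL = {
    ("A", "EMC"): 0.040,
    ("A", "EAO"): 0.056,
    ("A", "NA"): 0.100,
    ("EMC", "EAO"): 0.027,
    ("EMC", "NA"): 0.067,
    ("EAO", "NA"): 0.057,
}


def distinguishability_grid() -> pd.DataFrame:
    """Published D~VH grid, assumed population × true population."""
    return pd.DataFrame(
        _D_VH,
        index=pd.Index(POPULATIONS, name="assumed"),
        columns=pd.Index(POPULATIONS, name="true"),
    )


def coancestry_matrix(locus_set: str = "codis") -> pd.DataFrame:
    """Symmetric pairwise θ̂ matrix (zero diagonal) for one locus set."""
    table = {"codis": _THETA_CODIS, "full": _THETA_FULL}.get(locus_set)
    if table is None:
        raise ValueError("locus_set must be 'codis' or 'full'")
    mat = pd.DataFrame(
        0.0, index=pd.Index(POPULATIONS, name="pop1"), columns=pd.Index(POPULATIONS, name="pop2")
    )
    for (p1, p2), v in table.items():
        mat.loc[p1, p2] = v
        mat.loc[p2, p1] = v
    return mat


def regression_points(locus_set: str = "codis") -> pd.DataFrame:
    """The 16 (θ̂, D~VH) points behind the misspecification regression.

    One point per (true, assumed) population cell; θ̂ is the pairwise
    coancestry between the two populations under the given locus set,
    zero when true and assumed coincide.
    """
    grid = distinguishability_grid()
    theta = coancestry_matrix(locus_set)
    rows = []
    for assumed in POPULATIONS:
        for true in POPULATIONS:
            rows.append(
                {
                    "true": true,
                    "assumed": assumed,
                    "theta_hat": theta.loc[true, assumed],
                    "d_vh": grid.loc[assumed, true],
                }
            )
    return pd.DataFrame(rows)


def distinguishability_regression(locus_set: str = "codis") -> tuple[float, float]:
    """OLS fit of D~VH on pairwise θ̂ over the 16 points; (slope, intercept)."""
    pts = regression_points(locus_set)
    return ols_line(pts["theta_hat"].to_numpy(), pts["d_vh"].to_numpy())
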
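"""Association between fuel classes and categorical environmental covariates.

Ignition points carry two categorical labels — the phenological fuel class
(PFC) of the pixel they fell in and a covariate category (aggregated land
cover or climatic region).  Cross-tabulating them gives a two-way contingency
table; independence is tested with the Pearson χ² statistic and a
randomization scheme that permutes the covariate label vector across fires.
Because a permutation rearranges labels without changing either label's
tally, both margins of every randomized table equal the observed margins by
construction.

Cell-wise two-tailed p-values use the doubled-smaller-tail rule with add-one
continuity (consistent with the selectivity tests); the table-wide p is the
upper tail of the permuted χ² distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = ["ContingencyTable", "AssociationResult", "build_contingency",
           "pearson_chi2", "margin_fixed_randomization",
           "DEFAULT_CLC_MACRO_CLASSES"]

# Aggregation of detailed land-cover codes into seven combustible
# macro-classes; non-combustible surfaces map to "excluded".
DEFAULT_CLC_MACRO_CLASSES: tuple[str, ...] = (
    "urban_areas",
    "arable_lands",
    "permanent_crops",
    "heterogeneous_agricultural",
    "forests",
    "grasslands_pastures",
    "shrublands",
)


@dataclass
class ContingencyTable:
    """Integer counts of fires by covariate category (rows) × PFC (columns)."""

    counts: pd.DataFrame

    @property
    def row_margins(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def expected(self) -> pd.DataFrame:
        r = self.row_margins.to_numpy(float)
        c = self.col_margins.to_numpy(float)
        e = np.outer(r, c) / self.grand_total
        return pd.DataFrame(e, index=self.counts.index, columns=self.counts.columns)


@dataclass
class AssociationResult:
    chi2_observed: float
    p_value: float
    observed: pd.DataFrame
    expected: pd.DataFrame
    direction: pd.DataFrame        # '+' observed above null mean, '-' below
    cell_p: pd.DataFrame
    null_cell_mean: pd.DataFrame
    null_cell_sd: pd.DataFrame
    n_reps: int
    seed: int | None


def build_contingency(pfc_labels, covariate_labels,
                      row_order=None, col_order=None) -> ContingencyTable:
    """Cross-tabulate per-fire PFC and covariate labels.

    ``row_order``/``col_order`` fix the category schema; declared categories
    absent from the data are kept as zero rows/columns.
    """
    pfc = np.asarray(pfc_labels)
    cov = np.asarray(covariate_labels)
    if pfc.size != cov.size:
        raise ValueError("label vectors must have the same length")
    tab = pd.crosstab(pd.Series(cov, name="covariate"), pd.Series(pfc, name="pfc"))
    if row_order is not None:
        tab = tab.reindex(index=list(row_order), fill_value=0)
    if col_order is not None:
        tab = tab.reindex(columns=list(col_order), fill_value=0)
    return ContingencyTable(counts=tab.astype(int))


def pearson_chi2(table: ContingencyTable) -> float:
    """Pearson χ² = ΣΣ (O−E)²/E; zero-margin rows/columns are dropped."""
    counts = table.counts
    if counts.to_numpy().sum() == 0:
        raise ValueError("all-zero contingency table")
    keep_r = counts.sum(axis=1) > 0
    keep_c = counts.sum(axis=0) > 0
    trimmed = counts.loc[keep_r, keep_c]
    stat, _, _, _ = chi2_contingency(trimmed.to_numpy(), correction=False)
    return float(stat)


def margin_fixed_randomization(pfc_labels, covariate_labels, n_reps: int = 9999,
                               seed: int | None = None,
                               row_order=None, col_order=None,
                               tail: str = "double") -> AssociationResult:
    """Randomization test of PFC × covariate association with fixed margins.

    Each replicate permutes the covariate label vector across fires and
    re-tabulates, keeping the number of fires in every PFC and every
    covariate category constant.  Reports the table-wide χ² p-value and, per
    cell, a two-tailed p and the direction of departure from the null mean.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    obs = build_contingency(pfc_labels, covariate_labels,
                            row_order=row_order, col_order=col_order)
    o = obs.counts.to_numpy(float)
    expected = obs.expected()
    e = expected.to_numpy(float)
    live = e > 0
    chi2_obs = float(((o[live] - e[live]) ** 2 / e[live]).sum())

    rows = list(obs.counts.index)
    cols = list(obs.counts.columns)
    r_code = {lab: i for i, lab in enumerate(rows)}
    c_code = {lab: i for i, lab in enumerate(cols)}
    rv = np.array([r_code[v] for v in np.asarray(covariate_labels)])
    cv = np.array([c_code[v] for v in np.asarray(pfc_labels)])
    nr, nc = len(rows), len(cols)

    rng = np.random.default_rng(seed)
    n = rv.size
    chi2_null = np.empty(n_reps)
    cell_null = np.empty((n_reps, nr, nc))
    for i in range(n_reps):
        perm_rv = rv[rng.permutation(n)]
        tab = np.bincount(perm_rv * nc + cv, minlength=nr * nc).reshape(nr, nc)
        cell_null[i] = tab
        d = tab[live] - e[live]
        chi2_null[i] = (d * d / e[live]).sum()

    p_overall = ((chi2_null >= chi2_obs).sum() + 1) / (n_reps + 1)

    lo = (cell_null <= o).sum(axis=0) + 1
    hi = (cell_null >= o).sum(axis=0) + 1
    smaller = np.minimum(lo, hi)
    if tail == "single":
        cell_p = smaller / (n_reps + 1)
    else:
        cell_p = np.minimum(1.0, 2.0 * smaller / (n_reps + 1))
    null_mean = cell_null.mean(axis=0)
    null_sd = cell_null.std(axis=0, ddof=1)
    direction = np.where(o > null_mean, "+", "-")

    return AssociationResult(
        chi2_observed=chi2_obs,
        p_value=float(p_overall),
        observed=obs.counts,
        expected=expected,
        direction=pd.DataFrame(direction, index=rows, columns=cols),
        cell_p=pd.DataFrame(cell_p, index=rows, columns=cols),
        null_cell_mean=pd.DataFrame(null_mean, index=rows, columns=cols),
        null_cell_sd=pd.DataFrame(null_sd, index=rows, columns=cols),
        n_reps=n_reps,
        seed=seed,
    )
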
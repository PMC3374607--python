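"""Cohort-description statistics: the "Table 1" comparison of covariates
between disease phenotypes.

Categorical covariates are compared by the Pearson chi-square test on the
level x phenotype contingency table (no continuity correction, asymptotic
p); continuous covariates (age, BMI) by the Kruskal-Wallis rank test.
BH-FDR is applied across the table's p-values. The three-level anti-TNF
variable is tested as one variable (a single p for the three-row block).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model_selection import bh_fdr
from .tables_io import METADATA_SCHEMA

__all__ = ["ContingencyTable", "chi_square", "kruskal_wallis", "cohort_table"]


@dataclass(frozen=True)
class ContingencyTable:
    """Integer counts of variable levels (rows) by phenotype (columns)."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if c.shape[0] < 2 or c.shape[1] < 2:
            raise ValueError("contingency table needs at least 2 rows and 2 columns")
        if np.any(c < 0) or np.any(c != np.round(c)):
            raise ValueError("counts must be non-negative integers")


def chi_square(table: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square statistic and asymptotic p for an r x c table."""
    counts = np.asarray(table.counts, dtype=float)
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("degenerate contingency table: zero marginal row/column")
    stat, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), float(p)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square approximate p."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least 2 nonempty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.allclose(pooled, pooled[0]):
        return 0.0, 1.0
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


def cohort_table(
    metadata: pd.DataFrame,
    variables: list[str] | None = None,
    group: str = "phenotype",
) -> pd.DataFrame:
    """Per-variable phenotype comparison with p and BH-FDR columns.

    Categorical variables dispatch to :func:`chi_square`, numeric ones to
    :func:`kruskal_wallis` (per their declared type in the metadata schema,
    or by dtype for variables outside it). Categorical summaries show the
    percentage of the non-reference level (or of each level for multi-level
    variables); numeric summaries show median (range), per phenotype.
    """
    if variables is None:
        variables = [v for v in METADATA_SCHEMA if v != group]
    missing = [v for v in variables if v not in metadata.columns]
    if missing:
        raise KeyError(f"variables not in metadata: {missing}")
    phenotypes = sorted(metadata[group].dropna().unique(), key=str)

    rows = []
    for var in variables:
        sub = metadata[[group, var]].dropna()
        kind = METADATA_SCHEMA.get(var, (None, None))[0]
        is_continuous = (
            kind == "positive"
            or (kind is None and pd.api.types.is_numeric_dtype(sub[var]))
        )
        summary = {}
        if is_continuous:
            groups = [
                sub.loc[sub[group] == ph, var].to_numpy(dtype=float) for ph in phenotypes
            ]
            stat, p = kruskal_wallis(groups)
            test = "kruskal_wallis"
            for ph, g in zip(phenotypes, groups):
                summary[ph] = f"{np.median(g):.1f} ({g.min():.0f}-{g.max():.0f})"
        else:
            ct = pd.crosstab(sub[var].astype(str), sub[group])
            ct = ct.reindex(columns=phenotypes, fill_value=0)
            table = ContingencyTable(
                row_labels=tuple(ct.index),
                col_labels=tuple(ct.columns),
                counts=ct.to_numpy(),
            )
            stat, p = chi_square(table)
            test = "chi_square"
            shown = [lvl for lvl in ct.index if lvl not in ("False", "never")]
            for ph in phenotypes:
                col = ct[ph]
                total = col.sum()
                summary[ph] = "; ".join(
                    f"{lvl}: {100 * col[lvl] / total:.0f}%" for lvl in shown
                )
        rows.append({"variable": var, "test": test, **summary, "statistic": stat, "p": p})

    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out
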
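"""Forward stepwise term selection by permutation p-value, and BH-FDR.

Candidates (main effects of the cohort covariates plus all first-order
interactions) are tested one at a time as the LAST sequential term appended
to the current model; within one step every candidate shares the same
permutation stream so their p-values are comparable at fixed B. The
candidate with the smallest p enters if p <= alpha (exact-p ties broken by
pool order, where main effects precede interactions); selection stops when
no candidate passes, the pool is exhausted, or the design would saturate. Interaction hierarchy
is NOT enforced: interactions compete regardless of whether their parents
were selected. The final model is re-partitioned once in selection order and
Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .permanova import (
    DegenerateResponseError,
    _at_least,
    DistanceMatrix,
    ModelTerm,
    PartitionResult,
    _RANK_TOL,
    _SequentialBasis,
    _aligned_metadata,
    encode_term,
    gower_center,
    permutation_test,
    scalar_distance,
)

logger = logging.getLogger(__name__)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values,
    capped at 1; monotone in the raw p and never smaller than it.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a nonempty 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted


@dataclass(frozen=True)
class CandidatePool:
    """Candidate terms for stepwise selection.

    ``mains`` are covariate names; ``interactions`` are unordered pairs. The
    default pool is every covariate plus all first-order interactions.
    """

    mains: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...]

    def __post_init__(self):
        terms = [t.name for t in self.terms()]
        if len(set(terms)) != len(terms):
            raise ValueError("duplicate terms in candidate pool")
        known = set(self.mains)
        for a, b in self.interactions:
            if a not in known or b not in known:
                raise ValueError(f"interaction ({a}, {b}) references non-pool variables")

    @classmethod
    def full(cls, variables) -> "CandidatePool":
        variables = tuple(variables)
        pairs = tuple(
            (variables[i], variables[j])
            for i in range(len(variables))
            for j in range(i + 1, len(variables))
        )
        return cls(mains=variables, interactions=pairs)

    @classmethod
    def mains_only(cls, variables) -> "CandidatePool":
        return cls(mains=tuple(variables), interactions=())

    def terms(self) -> list[ModelTerm]:
        return [ModelTerm.main(v) for v in self.mains] + [
            ModelTerm.interaction(a, b) for a, b in self.interactions
        ]


@dataclass
class SelectionTrace:
    """Result of a stepwise run.

    ``steps`` records each entering term with its entry-step incremental R²
    and permutation p; ``final`` is the one-shot re-partition of the selected
    model in selection order, with a BH-FDR column; ``skipped`` lists
    candidates dropped for rank deficiency.
    """

    steps: pd.DataFrame
    final: PartitionResult | None
    stopping_reason: str
    skipped: list[str] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return self.steps["term"].tolist()


def _candidate_scan(
    g: np.ndarray,
    total: float,
    basis: _SequentialBasis,
    candidates: list[tuple[ModelTerm, np.ndarray]],
    perms: np.ndarray,
) -> pd.DataFrame:
    """Permutation p for each candidate appended last to the current model.

    All candidates are scored against the same permutations; the current
    model's permuted SS is computed once per permutation and shared.
    """
    n = g.shape[0]
    cur_q = basis.q[:, 1:]
    cur_df = cur_q.shape[1]

    blocks, names, dfs = [], [], []
    for term, new_cols in candidates:
        blocks.append(new_cols)
        names.append(term.name)
        dfs.append(new_cols.shape[1])
    stacked = np.hstack([cur_q] + blocks) if blocks else cur_q
    dfs = np.array(dfs)
    offsets = cur_df + np.concatenate([[0], np.cumsum(dfs)])
    res_df = n - 1 - cur_df - dfs

    def term_stats(q_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        per_col = np.einsum("nk,nk->k", q_rows, g @ q_rows)
        ss_cur = per_col[:cur_df].sum()
        ss_cand = np.add.reduceat(per_col[cur_df:], offsets[:-1] - cur_df)
        f = (ss_cand / dfs) / ((total - ss_cur - ss_cand) / res_df)
        return ss_cand, f

    ss_obs, f_obs = term_stats(stacked)
    exceed = np.zeros(len(dfs))
    scattered = np.empty_like(stacked)
    for perm in perms:
        scattered[perm] = stacked
        _, f_b = term_stats(scattered)
        exceed += _at_least(f_b, f_obs)
    p = (1.0 + exceed) / (1.0 + len(perms))
    return pd.DataFrame({"term": names, "df": dfs, "r2": ss_obs / total, "p": p})


def stepwise_select(
    response,
    pool: CandidatePool,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    n_permutations: int = 999,
    seed: int | None = None,
    max_terms: int | None = None,
) -> SelectionTrace:
    """Forward stepwise selection on a distance matrix or scalar response.

    Parameters
    ----------
    response
        A :class:`DistanceMatrix` (multivariate CLR analysis) or a 1-d
        scalar response aligned with ``metadata`` rows (per-category or
        qPCR ANCOVA).
    pool
        Candidate main effects and interactions.
    alpha
        Entry threshold on the permutation p-value.
    n_permutations
        Permutations per step (B); the attainable p floor is 1/(B+1).
    max_terms
        Optional cap on the number of entering terms.

    The final selected model is re-partitioned in selection order with a
    fresh seeded permutation run, and BH-FDR is applied across its terms
    (the FDR family is the rows of this one reported table).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if isinstance(response, DistanceMatrix):
        d = response
    else:
        d = scalar_distance(np.asarray(response, dtype=float), ids=metadata.index)
    metadata = _aligned_metadata(metadata, d)
    g = gower_center(d.values)
    total = float(np.trace(g))
    if total <= _RANK_TOL * d.n:
        raise DegenerateResponseError("degenerate response: total SS is zero")

    rng = np.random.default_rng(seed)
    remaining = pool.terms()
    basis = _SequentialBasis(d.n)
    steps: list[dict] = []
    skipped: list[str] = []
    stopping_reason = "pool exhausted"

    while remaining:
        if max_terms is not None and len(steps) >= max_terms:
            stopping_reason = "max_terms reached"
            break
        candidates = []
        for term in remaining:
            if d.n - 1 - basis.model_df - 1 <= 0:
                continue  # no residual df left even for a 1-df term
            new_cols = basis.try_add(encode_term(term, metadata))
            if new_cols is None:
                if term.name not in skipped:
                    skipped.append(term.name)
                    logger.info("stepwise: skipping rank-deficient candidate %r", term.name)
                continue
            if d.n - 1 - basis.model_df - new_cols.shape[1] <= 0:
                continue
            candidates.append((term, new_cols))
        if not candidates:
            stopping_reason = "design saturated or all candidates rank-deficient"
            break
        perms = np.array([rng.permutation(d.n) for _ in range(n_permutations)])
        scan = _candidate_scan(g, total, basis, candidates, perms)
        # smallest p; exact-p ties resolved by pool order (mains precede
        # interactions), since tied p-values — typically both at the 1/(B+1)
        # floor — carry no evidence for ranking nearly-collinear candidates
        best = min(range(len(scan)), key=lambda i: (scan["p"].iat[i], i))
        if scan["p"].iat[best] > alpha:
            stopping_reason = "no candidate below alpha"
            break
        winner, winner_cols = candidates[best]
        basis.add(winner_cols)
        remaining = [t for t in remaining if t.name != winner.name]
        steps.append(
            {
                "step": len(steps) + 1,
                "term": winner.name,
                "kind": winner.kind,
                "df": int(scan["df"].iat[best]),
                "entry_r2": float(scan["r2"].iat[best]),
                "entry_p": float(scan["p"].iat[best]),
            }
        )

    steps_df = pd.DataFrame(
        steps, columns=["step", "term", "kind", "df", "entry_r2", "entry_p"]
    )
    final = None
    if steps:
        selected_terms = [t for t in pool.terms() if t.name in set(steps_df["term"])]
        by_name = {t.name: t for t in selected_terms}
        ordered = [by_name[name] for name in steps_df["term"]]
        final = permutation_test(
            d,
            ordered,
            metadata,
            n_permutations=n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
        final.table["fdr"] = bh_fdr(final.table["p"].to_numpy())
    return SelectionTrace(
        steps=steps_df, final=final, stopping_reason=stopping_reason, skipped=skipped
    )
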
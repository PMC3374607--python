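"""Permutation-based repeated-measures ANCOVA across sequencing platforms.

Each subject contributes one scalar response per platform (the CLR value of
one category measured by Sanger, 454 V1-V3 and 454 V3-V5). The responses
are stacked long — m rows per subject — and partitioned sequentially:
between-subject terms first (in the supplied order, typically the union of
the terms selected by the per-platform analyses), then the within-subject
Measurements (platform) factor last.

Exchangeability differs between the two kinds of term, so two restricted
permutation schemes are used:

* between-subject terms — subjects are permuted as whole blocks (all m rows
  move together), which preserves the within-subject structure;
* Measurements — responses are shuffled within each subject's block, which
  fixes every block mean (the same conditioning as subtracting subject
  means) and leaves every between-subject term's SS invariant.

R² uses the total SS of the stacked response as denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .permanova import (
    ModelTerm,
    _at_least,
    PartitionResult,
    _SequentialBasis,
    encode_term,
    gower_center,
    scalar_distance,
    _observed_partition,
    _permuted_term_f,
)

MEASUREMENTS = "Measurements"


class IncompleteCasesError(ValueError):
    """Some subject lacks a value for one or more platforms."""


def rm_permutation_ancova(
    responses: pd.DataFrame,
    terms: list[ModelTerm],
    metadata: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PartitionResult:
    """Repeated-measures permutation ANCOVA with a Measurements row.

    Parameters
    ----------
    responses
        Wide frame, one row per subject (index = subject_id), one column per
        platform; complete cases only — use ``align_tables`` to build the
        complete-case set first.
    terms
        Ordered between-subject terms (mains first, then interactions, by
        caller's convention); the Measurements factor is appended last
        automatically.
    metadata
        Covariates indexed by subject_id.

    Returns a :class:`PartitionResult` whose last table row is the
    Measurements effect; each term's p comes from its restricted permutation
    scheme (subject blocks for between-subject terms, within-subject
    shuffles for Measurements).
    """
    if responses.isna().any().any():
        bad = responses.index[responses.isna().any(axis=1)].tolist()
        raise IncompleteCasesError(
            f"subjects with missing platform values: {bad[:5]}"
            f"{'...' if len(bad) > 5 else ''}; restrict to complete cases (align_tables)"
        )
    subjects = responses.index.astype(str)
    platforms = list(responses.columns)
    n_sub, m = responses.shape
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")

    meta = metadata.copy()
    meta.index = meta.index.astype(str)
    missing = [s for s in subjects if s not in meta.index]
    if missing:
        raise KeyError(f"metadata lacks subjects {missing[:5]}")
    meta = meta.loc[subjects]

    # stack long: subject-major, platform-minor, so block i occupies rows [i*m, (i+1)*m)
    y = responses.to_numpy(dtype=float).reshape(-1)
    long_ids = [f"{s}|{p}" for s in subjects for p in platforms]
    long_meta = meta.loc[np.repeat(subjects, m)].reset_index(drop=True)
    long_meta[MEASUREMENTS] = platforms * n_sub
    long_meta.index = long_ids

    rm_terms = list(terms)
    if m > 1:
        rm_terms.append(ModelTerm.main(MEASUREMENTS))

    n = n_sub * m
    d = scalar_distance(y, ids=long_ids)
    g = gower_center(d.values)
    basis = _SequentialBasis(n)
    for term in rm_terms:
        new_cols = basis.try_add(encode_term(term, long_meta))
        if new_cols is None:
            from .permanova import RankDeficiencyError

            raise RankDeficiencyError(term.name)
        basis.add(new_cols)
    result = _observed_partition(g, basis, rm_terms)
    f_obs = result.table["f"].to_numpy()

    rng = np.random.default_rng(seed)
    base = np.arange(n).reshape(n_sub, m)

    # between-subject terms: permute subject blocks
    block_perms = np.array(
        [base[rng.permutation(n_sub)].reshape(-1) for _ in range(n_permutations)]
    )
    f_between = _permuted_term_f(g, basis, block_perms, result.total_ss)

    p = np.empty(len(rm_terms))
    n_between = len(terms)
    exceed = _at_least(f_between[:, :n_between], f_obs[:n_between]).sum(axis=0)
    p[:n_between] = (1.0 + exceed) / (1.0 + n_permutations)

    if m > 1:
        # Measurements: shuffle within each subject's block
        within_rng = np.random.default_rng(
            seed if seed is None else seed + 1_000_003
        )
        within_perms = np.empty((n_permutations, n), dtype=int)
        for b in range(n_permutations):
            within_perms[b] = (
                np.take_along_axis(
                    base, np.argsort(within_rng.random((n_sub, m)), axis=1), axis=1
                ).reshape(-1)
            )
        f_within = _permuted_term_f(g, basis, within_perms, result.total_ss)
        exceed_m = _at_least(f_within[:, -1], np.asarray(f_obs[-1])).sum()
        p[-1] = (1.0 + exceed_m) / (1.0 + n_permutations)

    result.table["p"] = p
    result.n_permutations = n_permutations
    result.seed = seed
    result.check_additivity()
    return result
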
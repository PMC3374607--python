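"""Distance-matrix permutation inference (the adonis-style engine).

Given a symmetric distance matrix ``d`` and an ordered list of model terms,
the total sum of squares is partitioned sequentially through the Gower
double-centered inner-product matrix

    G = -(1/2) * C * d^2 * C,     C = I - 11'/n

using projection operators H of the cumulative design: each term's SS is
tr((H_k - H_{k-1}) G), its pseudo-F is (SS_term/df_term)/(SS_res/df_res),
and significance comes from permuting observation labels against the fixed
distance matrix (raw-data permutation). For a Euclidean distance on a single
variable the pseudo-F equals the classical sequential ANOVA/ANCOVA F.

Sequential (Type-I) SS are order-dependent by construction; the order is the
one supplied (for stepwise models, the selection order).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ModelTerm",
    "DistanceMatrix",
    "PartitionResult",
    "euclidean_distances",
    "gower_center",
    "partition",
    "permutation_test",
    "univariate_permutation_test",
]

_RANK_TOL = 1e-8

#: Relative tolerance when counting permuted statistics as "at least" the
#: observed one. Relabelings equivalent to the observed one reproduce F only
#: up to reordering round-off, so an exact float >= undercounts true ties.
_TIE_RTOL = 1e-10


def _at_least(f_perm: np.ndarray, f_obs: np.ndarray) -> np.ndarray:
    return f_perm >= f_obs - _TIE_RTOL * (1.0 + np.abs(f_obs))


class DegenerateResponseError(ValueError):
    """The response carries no variation (total SS = 0)."""


class RankDeficiencyError(ValueError):
    """A term adds no independent columns to the cumulative design."""

    def __init__(self, term_name: str):
        self.term_name = term_name
        super().__init__(f"term {term_name!r} is rank-deficient given the preceding terms")


@dataclass(frozen=True)
class ModelTerm:
    """A main effect or first-order interaction of metadata covariates.

    Categorical covariates are encoded as full-rank treatment dummies with
    the lexicographically first level as reference; numeric covariates enter
    linearly; interaction columns are elementwise products of the parent
    encodings.
    """

    name: str
    components: tuple[str, ...]
    kind: str  # "main" | "interaction"

    def __post_init__(self):
        if self.kind not in ("main", "interaction"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        n_expected = 1 if self.kind == "main" else 2
        if len(self.components) != n_expected or len(set(self.components)) != n_expected:
            raise ValueError(
                f"{self.kind} term needs {n_expected} distinct component(s), "
                f"got {self.components}"
            )

    @classmethod
    def main(cls, var: str) -> "ModelTerm":
        return cls(name=var, components=(var,), kind="main")

    @classmethod
    def interaction(cls, a: str, b: str) -> "ModelTerm":
        return cls(name=f"{a}*{b}", components=(a, b), kind="interaction")


def _encode_variable(series: pd.Series) -> np.ndarray:
    """n x k encoding of one covariate (dummies or a single linear column)."""
    if series.isna().any():
        raise ValueError(
            f"covariate {series.name!r} has missing values; drop incomplete "
            "subjects before model fitting"
        )
    if pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(series):
        return series.to_numpy(dtype=float).reshape(-1, 1)
    levels = sorted(series.unique(), key=str)
    # treatment coding, first level is the reference
    return np.column_stack(
        [(series == level).to_numpy(dtype=float) for level in levels[1:]]
    ) if len(levels) > 1 else np.empty((len(series), 0))


def encode_term(term: ModelTerm, metadata: pd.DataFrame) -> np.ndarray:
    """Design-matrix block for one term, aligned to metadata row order."""
    for var in term.components:
        if var not in metadata.columns:
            raise KeyError(f"covariate {var!r} not in metadata")
    blocks = [_encode_variable(metadata[var].infer_objects()) for var in term.components]
    if term.kind == "main":
        return blocks[0]
    a, b = blocks
    return np.einsum("ni,nj->nij", a, b).reshape(len(metadata), -1)


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise distances over an ordered subject list."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        d = self.values
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape does not match id list")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.ids)


def euclidean_distances(composition: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances between sample rows.

    On CLR-transformed compositions this is the Aitchison distance.
    """
    if len(composition) < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(composition.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(ids=tuple(str(i) for i in composition.index), values=d)


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix G = -(1/2) C d^2 C."""
    a = -0.5 * d.astype(float) ** 2
    return a - a.mean(axis=0) - a.mean(axis=1, keepdims=True) + a.mean()


class _SequentialBasis:
    """Incrementally orthonormalized cumulative design.

    Holds an n x r orthonormal basis starting from the intercept; each added
    term contributes the orthonormal complement of its encoded block, and
    the per-term column slices give tr(delta-H G) as sums of quadratic forms
    q'Gq over the term's basis columns.
    """

    def __init__(self, n: int):
        self.n = n
        self.q = np.ones((n, 1)) / math.sqrt(n)
        self.slices: list[slice] = []

    @property
    def model_df(self) -> int:
        return self.q.shape[1] - 1

    def try_add(self, block: np.ndarray) -> np.ndarray | None:
        """Orthonormal new columns for ``block``, or None if rank-deficient.

        Does not mutate the basis; call :meth:`add` with the result to commit.
        """
        if block.shape[1] == 0:
            return None
        resid = block - self.q @ (self.q.T @ block)
        # second pass guards against loss of orthogonality for near-collinear blocks
        resid = resid - self.q @ (self.q.T @ resid)
        u, s, _ = np.linalg.svd(resid, full_matrices=False)
        scale = max(1.0, float(np.linalg.norm(block, ord=2)))
        keep = s > _RANK_TOL * scale * math.sqrt(self.n)
        if not keep.any():
            return None
        return u[:, keep]

    def add(self, new_cols: np.ndarray) -> None:
        start = self.q.shape[1]
        self.q = np.hstack([self.q, new_cols])
        self.slices.append(slice(start, start + new_cols.shape[1]))


@dataclass
class PartitionResult:
    """Sequential SS partition of a distance matrix, with permutation p-values.

    ``table`` has one row per term (columns: term, kind, df, ss, r2, f, p);
    ``p`` is NaN when no permutations were run. Invariant: term SS plus
    residual SS equals total SS.
    """

    table: pd.DataFrame
    residual_ss: float
    residual_df: int
    total_ss: float
    n_permutations: int | None = None
    seed: int | None = None

    def check_additivity(self, atol: float = 1e-8) -> None:
        gap = abs(self.table["ss"].sum() + self.residual_ss - self.total_ss)
        if gap > atol * max(1.0, self.total_ss):
            raise AssertionError(f"SS additivity violated by {gap:g}")


def _build_basis(
    terms: list[ModelTerm], metadata: pd.DataFrame, n: int
) -> _SequentialBasis:
    basis = _SequentialBasis(n)
    for term in terms:
        new_cols = basis.try_add(encode_term(term, metadata))
        if new_cols is None:
            raise RankDeficiencyError(term.name)
        basis.add(new_cols)
    return basis


def _observed_partition(
    g: np.ndarray, basis: _SequentialBasis, terms: list[ModelTerm]
) -> PartitionResult:
    n = g.shape[0]
    total = float(np.trace(g))
    if total <= _RANK_TOL * n:
        raise DegenerateResponseError("degenerate response: total SS is zero")
    gq = g @ basis.q
    per_col = np.einsum("nk,nk->k", basis.q, gq)
    ss = np.array([per_col[sl].sum() for sl in basis.slices])
    df = np.array([sl.stop - sl.start for sl in basis.slices])
    residual_df = n - 1 - int(df.sum())
    if residual_df <= 0:
        raise ValueError(f"model is saturated: residual df = {residual_df}")
    residual_ss = total - float(ss.sum())
    f = (ss / df) / (residual_ss / residual_df)
    table = pd.DataFrame(
        {
            "term": [t.name for t in terms],
            "kind": [t.kind for t in terms],
            "df": df,
            "ss": ss,
            "r2": ss / total,
            "f": f,
            "p": np.nan,
        }
    )
    return PartitionResult(
        table=table, residual_ss=residual_ss, residual_df=residual_df, total_ss=total
    )


def partition(
    d: DistanceMatrix, terms: list[ModelTerm], metadata: pd.DataFrame
) -> PartitionResult:
    """Sequential SS/df/R²/pseudo-F partition, no permutation p-values.

    ``metadata`` rows must align with ``d.ids`` (reindexed by id).
    """
    metadata = _aligned_metadata(metadata, d)
    basis = _build_basis(list(terms), metadata, d.n)
    g = gower_center(d.values)
    result = _observed_partition(g, basis, list(terms))
    result.check_additivity()
    return result


def _aligned_metadata(metadata: pd.DataFrame, d: DistanceMatrix) -> pd.DataFrame:
    missing = [i for i in d.ids if i not in metadata.index.astype(str)]
    if missing:
        raise KeyError(f"metadata lacks subjects {missing[:5]}{'...' if len(missing) > 5 else ''}")
    meta = metadata.copy()
    meta.index = meta.index.astype(str)
    return meta.loc[list(d.ids)]


def _permuted_term_f(
    g: np.ndarray, basis: _SequentialBasis, perms: np.ndarray, total: float
) -> np.ndarray:
    """Pseudo-F of every term under each permutation (perms x terms).

    Permuting metadata rows by ``perm`` is equivalent to scattering the basis
    rows: q'G[perm,perm]q = qs'G qs with qs[perm] = q, which avoids gathering
    the full n x n matrix per permutation.
    """
    n = g.shape[0]
    q = basis.q[:, 1:]  # intercept SS is identically 0 on the centered G
    df = np.array([sl.stop - sl.start for sl in basis.slices])
    offsets = np.concatenate([[0], np.cumsum(df)])
    residual_df = n - 1 - int(df.sum())
    fs = np.empty((len(perms), len(df)))
    qs = np.empty_like(q)
    for b, perm in enumerate(perms):
        qs[perm] = q
        per_col = np.einsum("nk,nk->k", qs, g @ qs)
        ss = np.add.reduceat(per_col, offsets[:-1]) if len(df) else np.empty(0)
        residual_ss = total - ss.sum()
        fs[b] = (ss / df) / (residual_ss / residual_df)
    return fs


def permutation_test(
    d: DistanceMatrix,
    terms: list[ModelTerm],
    metadata: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PartitionResult:
    """Sequential partition with permutation p-values for every term.

    Whole metadata rows are permuted against the fixed distance matrix; all
    terms are evaluated on the same permutation stream. Monte-Carlo p-values
    use the +1/+1 correction p = (1 + #{F_b >= F_obs}) / (1 + B) (exceedance
    counted with a 1e-10 relative tie tolerance), so the
    smallest attainable p is 1/(B+1). With ``exhaustive=True`` all n!
    relabelings are enumerated instead and p is the exact tail proportion
    #{F_b >= F_obs} / n! (the identity relabeling is part of the null set,
    so no correction is applied).
    """
    terms = list(terms)
    metadata = _aligned_metadata(metadata, d)
    basis = _build_basis(terms, metadata, d.n)
    g = gower_center(d.values)
    result = _observed_partition(g, basis, terms)
    f_obs = result.table["f"].to_numpy()

    if exhaustive:
        if math.factorial(d.n) > 50_000:
            raise ValueError(f"exhaustive enumeration infeasible for n = {d.n}")
        perms = np.array(list(itertools.permutations(range(d.n))))
        fs = _permuted_term_f(g, basis, perms, result.total_ss)
        p = _at_least(fs, f_obs).mean(axis=0)
        result.n_permutations = len(perms)
    else:
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(d.n) for _ in range(n_permutations)])
        fs = _permuted_term_f(g, basis, perms, result.total_ss)
        p = (1.0 + _at_least(fs, f_obs).sum(axis=0)) / (1.0 + n_permutations)
        result.n_permutations = n_permutations
        result.seed = seed
    result.table["p"] = p
    result.check_additivity()
    return result


def scalar_distance(y, ids=None) -> DistanceMatrix:
    """Distance matrix |y_i - y_j| of a scalar response."""
    arr = np.asarray(y, dtype=float).reshape(-1, 1)
    if ids is None:
        ids = [str(i) for i in range(len(arr))]
    d = squareform(pdist(arr, metric="euclidean"))
    return DistanceMatrix(ids=tuple(str(i) for i in ids), values=d)


def univariate_permutation_test(
    y,
    terms: list[ModelTerm],
    metadata: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PartitionResult:
    """Permutation ANCOVA of a scalar response (one CLR category, or an
    empirical-logit qPCR value).

    The distance matrix is built from absolute differences of ``y`` (aligned
    with metadata row order), so the pseudo-F equals the classical
    sequential ANOVA/ANCOVA F and is invariant to affine rescaling of y.
    """
    arr = np.asarray(y, dtype=float)
    if arr.ndim != 1 or len(arr) != len(metadata):
        raise ValueError("y must be a 1-d vector aligned with metadata rows")
    d = scalar_distance(arr, ids=metadata.index)
    return permutation_test(
        d, terms, metadata, n_permutations=n_permutations, seed=seed, exhaustive=exhaustive
    )
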
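"""Compositional and proportion transforms.

The dependent variable of the multivariate analysis is the centered
log-ratio (CLR) of the six predominant categories: with adjusted counts
x (raw counts + a 0.5 pseudocount, Other excluded),

    clr_i = ln(x_i) - (1/6) * sum_j ln(x_j)

so each sample maps to a zero-sum real vector and Euclidean distances are
Aitchison distances. qPCR relative frequencies p in [0, 1] enter the
univariate analysis through the empirical logit

    ln((p + eps) / (1 - p + eps))

which remains finite at p = 0 and p = 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables_io import CLR_CATEGORIES


def clr_transform(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """CLR-transform a category count table.

    Drops the Other column, adds ``pseudocount`` to each of the six retained
    counts, and returns the per-sample centered log-ratios (natural log).
    The result is closure-invariant: proportional count vectors give
    identical rows, and every row sums to zero.

    Parameters
    ----------
    counts
        Subjects x categories table containing at least the six CLR
        categories; extra columns (Other) are ignored.
    pseudocount
        Added to every raw count before the log; must be > 0.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    present = [c for c in CLR_CATEGORIES if c in counts.columns]
    if len(present) < 2:
        raise ValueError(
            f"need at least 2 of the CLR categories, found {present or 'none'}"
        )
    adjusted = counts[present].to_numpy(dtype=float) + pseudocount
    logs = np.log(adjusted)
    clr = logs - logs.mean(axis=1, keepdims=True)
    out = pd.DataFrame(clr, index=counts.index, columns=present)
    out.attrs = dict(counts.attrs)
    return out


def empirical_logit(p, epsilon: float):
    """Empirical logit ln((p + eps) / (1 - p + eps)), elementwise.

    Strictly increasing in p, antisymmetric about p = 0.5, and finite on the
    closed interval [0, 1]; converges to the classical logit as eps -> 0 for
    interior p.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p must lie in [0, 1]")
    out = np.log((arr + epsilon) / (1.0 - arr + epsilon))
    return float(out) if np.isscalar(p) else out


def default_epsilon(frequencies) -> float:
    """Data-adaptive epsilon: half the smallest nonzero relative frequency.

    qPCR yields copy-number ratios rather than counts, so no count-based
    pseudocount is available; this keeps the transform finite while scaling
    with the resolution of the assay. Pass a fixed epsilon through
    configuration when exact reproducibility across datasets is needed.
    """
    arr = np.asarray(frequencies, dtype=float)
    nonzero = arr[arr > 0]
    if nonzero.size == 0:
        raise ValueError("all relative frequencies are zero; supply epsilon explicitly")
    return float(nonzero.min() / 2.0)
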
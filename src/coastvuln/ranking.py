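"""Percent ranking shared by every stage that scales scores to [0, 1].

A single policy is used everywhere a percentile rank is called for:
``rank(v) = #{u : u < v} / (n - 1)``, ties sharing the value. The minimum
(including a tied minimum) maps to exactly 0 and a unique maximum to exactly
1, which matches how a tied-lowest fishery-reliance group all receive a
sensitivity of zero. An alternative ``n`` denominator is available behind
the same interface for robustness checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["percent_rank", "rank_descending"]


def percent_rank(values, denominator: str = "n_minus_1") -> np.ndarray:
    """Percent-rank ``values`` into [0, 1], largest value = 1.

    Parameters
    ----------
    values
        1-D array-like of finite numbers.
    denominator
        ``"n_minus_1"`` (default): strictly-smaller count over ``n - 1``;
        ``"n"``: strictly-smaller count over ``n`` (never reaches 1).

    Returns
    -------
    numpy.ndarray of the same length, in [0, 1]. A single value ranks 0.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("percent_rank expects a 1-D array")
    if not np.all(np.isfinite(v)):
        raise ValueError("percent_rank requires finite values")
    n = v.size
    if n == 0:
        return v.copy()
    smaller = (v[None, :] < v[:, None]).sum(axis=1).astype(float)
    if denominator == "n_minus_1":
        denom = max(n - 1, 1)
    elif denominator == "n":
        denom = n
    else:
        raise ValueError(f"unknown percent-rank denominator policy {denominator!r}")
    return smaller / denom


def rank_descending(values, ids) -> pd.Series:
    """Integer ranks with 1 = largest value (most at risk / most vulnerable).

    Ties share the smallest (worst) rank of the tied block; residual order is
    deterministic by identifier.
    """
    df = pd.DataFrame({"id": list(ids), "v": np.asarray(values, dtype=float)})
    df = df.sort_values(["v", "id"], ascending=[False, True]).reset_index(drop=True)
    # shared-minimum rank within tied value blocks
    ranks = np.arange(1, len(df) + 1)
    first_pos = df.groupby("v", sort=False).cumcount()
    df["rank"] = ranks - first_pos.to_numpy()
    return df.set_index("id")["rank"]
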
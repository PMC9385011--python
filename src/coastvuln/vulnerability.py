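"""Vulnerability integration, quadrant classification, and rank diagnostics.

Vulnerability is the Euclidean combination of community risk and adaptive
capacity, V = sqrt(R^2 + AC^2), so V >= R and V >= AC and larger always
means worse. The risk x adaptive-capacity plane is split into quadrants
(high / medium-by-risk / medium-by-adaptive-capacity / low), and the signed
difference between a community's vulnerability rank and its risk rank shows
which communities the social axis re-orders.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from coastvuln.ranking import rank_descending

__all__ = [
    "classify_quadrant",
    "community_vulnerability",
    "rank_difference",
    "regional_summary",
    "run_pipeline",
]


def community_vulnerability(scores: pd.DataFrame) -> pd.DataFrame:
    """V = sqrt(R^2 + AC^2) on a frame carrying R and AC."""
    out = scores.copy()
    if ((out["AC"] < 0) | (out["AC"] > 1)).any():
        raise ValueError("AC must lie in [0, 1]")
    if ((out["R"] < 0) | (out["R"] > np.sqrt(2) + 1e-12)).any():
        raise ValueError("R must lie in [0, sqrt(2)]")
    out["V"] = np.sqrt(out["R"] ** 2 + out["AC"] ** 2)
    return out


def classify_quadrant(
    scores: pd.DataFrame,
    splits: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Label each community high / medium_high_risk / medium_low_ac / low.

    ``splits`` are absolute (r_split, ac_split) thresholds; when None, the
    midpoint of each axis's observed range is used. High means both axes at
    or above their split; the medium labels say which single axis is high.
    """
    out = scores.copy()
    if splits is None:
        r_split = (out["R"].min() + out["R"].max()) / 2
        ac_split = (out["AC"].min() + out["AC"].max()) / 2
    else:
        r_split, ac_split = splits
    hi_r = out["R"] >= r_split
    hi_ac = out["AC"] >= ac_split
    out["quadrant"] = np.select(
        [hi_r & hi_ac, hi_r & ~hi_ac, ~hi_r & hi_ac],
        ["high", "medium_high_risk", "medium_low_ac"],
        default="low")
    return out


def rank_difference(scores: pd.DataFrame) -> pd.DataFrame:
    """Ranks (1 = worst) for risk, adaptive capacity, and vulnerability,
    plus vuln_rank - risk_rank (negative = worse once AC is included)."""
    out = scores.copy()
    ids = out["community"]
    out["risk_rank"] = rank_descending(out["R"].to_numpy(), ids).loc[ids].to_numpy()
    out["ac_rank"] = rank_descending(out["AC"].to_numpy(), ids).loc[ids].to_numpy()
    out["vuln_rank"] = rank_descending(out["V"].to_numpy(), ids).loc[ids].to_numpy()
    out["rank_diff"] = out["vuln_rank"] - out["risk_rank"]
    return out


def regional_summary(
    scores: pd.DataFrame,
    percentile: float = 0.90,
) -> pd.DataFrame:
    """Per region: percent of its communities in the top (1 - percentile)
    tier of risk and of vulnerability (value >= the across-community
    quantile). Empty regions are omitted with a warning."""
    if "region" not in scores.columns:
        raise ValueError("scores need a 'region' column")
    empty = scores["region"].isna()
    if empty.any():
        warnings.warn("communities without a region omitted from the summary")
        scores = scores[~empty]
    r_cut = float(np.quantile(scores["R"], percentile))
    v_cut = float(np.quantile(scores["V"], percentile))
    rows = []
    for region, g in scores.groupby("region"):
        rows.append({
            "region": region,
            "n_communities": len(g),
            "pct_top_risk": 100.0 * (g["R"] >= r_cut).mean(),
            "pct_top_vulnerability": 100.0 * (g["V"] >= v_cut).mean(),
        })
    return pd.DataFrame(rows)


def __getattr__(name: str):
    # end-to-end orchestration lives in coastvuln.pipeline; re-exported here
    # lazily so the vulnerability stage exposes the full surface without a
    # circular import
    if name == "run_pipeline":
        from coastvuln.pipeline import run_pipeline
        return run_pipeline
    raise AttributeError(name)
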
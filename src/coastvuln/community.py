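"""Community-level exposure, sensitivity, and risk.

Exposure is the revenue-share-weighted mean of species ecological risks,
percent-ranked across communities; sensitivity is the percent-ranked
economic reliance on commercial fishing (tied-lowest communities score
exactly 0); risk is their Euclidean combination R = sqrt(E^2 + S^2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from coastvuln.ranking import percent_rank

__all__ = ["community_exposure", "community_risk", "community_sensitivity"]


def community_exposure(
    theta_bar: pd.DataFrame,
    shares: pd.DataFrame,
    rank_denominator: str = "n_minus_1",
) -> pd.DataFrame:
    """E_raw = sum_i theta_bar_i * p_{i,c}; E = percent rank of E_raw.

    ``theta_bar`` needs columns species, theta_bar; ``shares`` community,
    species, p. Every share species must carry a risk score (unscored
    species should already have been dropped when shares were built).
    """
    merged = shares.merge(theta_bar[["species", "theta_bar"]],
                          on="species", how="left")
    missing = sorted(merged.loc[merged["theta_bar"].isna(), "species"].unique())
    if missing:
        raise ValueError(f"species without an ecological risk score: {missing}")
    out = (merged.assign(w=merged["p"] * merged["theta_bar"])
           .groupby("community", as_index=False)["w"].sum()
           .rename(columns={"w": "E_raw"}))
    out["E"] = percent_rank(out["E_raw"].to_numpy(), denominator=rank_denominator)
    return out


def community_sensitivity(
    reliance: pd.DataFrame,
    rank_denominator: str = "n_minus_1",
) -> pd.DataFrame:
    """S = percent rank of commercial-fishing reliance.

    All communities tied at the minimum reliance receive exactly 0.
    """
    if (reliance["reliance"] < 0).any():
        raise ValueError("reliance values must be >= 0")
    out = reliance[["community", "reliance"]].copy()
    out["S"] = percent_rank(out["reliance"].to_numpy(),
                            denominator=rank_denominator)
    return out


def community_risk(scores: pd.DataFrame) -> pd.DataFrame:
    """R = sqrt(E^2 + S^2), rowwise, on a frame carrying E and S."""
    out = scores.copy()
    if ((out["E"] < 0) | (out["E"] > 1) | (out["S"] < 0) | (out["S"] > 1)).any():
        raise ValueError("E and S must lie in [0, 1]")
    out["R"] = np.sqrt(out["E"] ** 2 + out["S"] ** 2)
    return out
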
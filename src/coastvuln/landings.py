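"""Landings-receipt preparation and per-community revenue shares.

The filter cascade mirrors how fish-ticket data are prepared for a
dependence analysis:

1. aggregate receipts over the analysis years;
2. remove communities whose confidential share of landed weight exceeds a
   cut (default strictly > 20%), and drop confidential rows from survivors;
3. drop "other/miscellaneous" catch when it is a small share of community
   weight (default < 5%); larger miscellaneous shares are retained and
   flagged for review;
4. expand unidentified-group catch into member species using a split table,
   conserving weight and revenue exactly;
5. retain, per community, the smallest prefix of species (sorted by
   descending landed weight) whose cumulative weight share reaches 90% —
   the species crossing the boundary is included;
6. convert the retained species' revenue into shares p_{i,c} summing to 1
   per community (weight-based shares available as a robustness switch).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "aggregate_landings",
    "drop_misc",
    "expand_unidentified",
    "filter_confidential",
    "prepare_revenue_shares",
    "revenue_shares",
    "top90_by_weight",
]

_KEY = ["community", "port_group", "species", "category", "confidential"]


def aggregate_landings(receipts: pd.DataFrame,
                       years: tuple[int, int] | None = None) -> pd.DataFrame:
    """Sum weight and revenue over an inclusive year span.

    Keeps the confidential flag and category label in the aggregation key so
    the downstream filters can act on them.
    """
    df = receipts
    if years is not None:
        lo, hi = years
        if lo > hi:
            raise ValueError("year span is empty")
        df = df[(df["year"] >= lo) & (df["year"] <= hi)]
    if df.empty:
        warnings.warn("no receipts in the requested year span")
        return pd.DataFrame(columns=_KEY + ["weight", "revenue"])
    return (df.groupby(_KEY, as_index=False)[["weight", "revenue"]].sum()
            .sort_values(_KEY).reset_index(drop=True))


def filter_confidential(
    totals: pd.DataFrame,
    threshold: float = 0.20,
) -> tuple[pd.DataFrame, list[str]]:
    """Remove communities with confidential weight strictly above ``threshold``.

    Surviving communities keep only their non-confidential rows. Returns the
    filtered totals and the list of removed communities (whose sensitivity
    and adaptive capacity remain computable downstream).
    """
    if totals.empty:
        return totals.copy(), []
    by_comm = totals.groupby("community").apply(
        lambda g: g.loc[g["confidential"], "weight"].sum() / g["weight"].sum(),
        include_groups=False)
    removed = sorted(by_comm[by_comm > threshold].index)
    out = totals[~totals["community"].isin(removed) & ~totals["confidential"]]
    return out.reset_index(drop=True), removed


def drop_misc(
    totals: pd.DataFrame,
    threshold: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop small "other/miscellaneous" catch; flag communities where it is
    not small (share of community weight >= threshold) and keep those rows."""
    if totals.empty or not (totals["category"] == "other_misc").any():
        return totals.copy(), []
    comm_weight = totals.groupby("community")["weight"].transform("sum")
    misc = totals["category"] == "other_misc"
    share = totals["weight"] / comm_weight
    drop = misc & (share < threshold)
    flagged = sorted(totals.loc[misc & ~drop, "community"].unique())
    if flagged:
        warnings.warn("other/miscellaneous catch at or above "
                      f"{threshold:.0%} of weight retained and flagged for: {flagged}")
    return totals[~drop].reset_index(drop=True), flagged


def expand_unidentified(
    totals: pd.DataFrame,
    group_map: dict[str, dict[str, float]],
) -> pd.DataFrame:
    """Replace unidentified-group rows by member-species rows.

    ``group_map`` maps a group label to {species: fraction}; fractions are
    applied to both weight and revenue, so both are conserved exactly.
    """
    if totals.empty:
        return totals.copy()
    is_group = totals["category"] == "unidentified_group"
    unmapped = sorted(set(totals.loc[is_group, "species"]) - set(group_map))
    if unmapped:
        raise ValueError(f"unidentified group labels without a split rule: {unmapped}")
    kept = totals[~is_group]
    expanded = []
    for _, row in totals[is_group].iterrows():
        for member, frac in sorted(group_map[row["species"]].items()):
            new = row.copy()
            new["species"] = member
            new["category"] = "normal"
            new["weight"] = row["weight"] * frac
            new["revenue"] = row["revenue"] * frac
            expanded.append(new)
    out = pd.concat([kept, pd.DataFrame(expanded)], ignore_index=True) \
        if expanded else kept.copy()
    return (out.groupby(_KEY, as_index=False)[["weight", "revenue"]].sum()
            .sort_values(_KEY).reset_index(drop=True))


def top90_by_weight(totals: pd.DataFrame,
                    top_share: float = 0.90) -> pd.DataFrame:
    """Per community, retain species to cumulative weight share >= top_share.

    Species are sorted by descending weight (ties broken by identifier for
    determinism); the species crossing the boundary is included.
    """
    rows = []
    for comm, g in totals.groupby("community"):
        by_sp = (g.groupby("species", as_index=False)["weight"].sum()
                 .sort_values(["weight", "species"], ascending=[False, True])
                 .reset_index(drop=True))
        total = by_sp["weight"].sum()
        if total <= 0:
            continue
        cum = by_sp["weight"].cumsum() / total
        # first index where cumulative share reaches the cut (inclusive)
        cut = int(np.argmax(cum.to_numpy() >= top_share - 1e-12))
        for sp in by_sp.loc[:cut, "species"]:
            rows.append((comm, sp))
    return pd.DataFrame(rows, columns=["community", "species"])


def revenue_shares(
    totals: pd.DataFrame,
    retained: pd.DataFrame,
    scored_species: set[str] | None = None,
    weighting: str = "revenue",
) -> pd.DataFrame:
    """Shares p_{i,c} over retained (and climate-scored) species.

    Species without an ecological risk score are dropped and the remaining
    shares renormalized to sum to 1 per community; communities left with
    nothing are dropped with a warning.
    """
    if weighting not in ("revenue", "weight"):
        raise ValueError("weighting must be 'revenue' or 'weight'")
    col = "revenue" if weighting == "revenue" else "weight"
    merged = retained.merge(
        totals.groupby(["community", "species"], as_index=False)[[col]].sum(),
        on=["community", "species"], how="left").fillna({col: 0.0})
    if scored_species is not None:
        merged = merged[merged["species"].isin(scored_species)]
    sums = merged.groupby("community")[col].transform("sum")
    empty = sorted(merged.loc[sums <= 0, "community"].unique())
    if empty:
        warnings.warn(f"communities with no scored retained revenue dropped: {empty}")
        merged = merged[sums > 0]
        sums = sums[sums > 0]
    merged = merged.assign(p=merged[col] / sums)
    return merged[["community", "species", "p"]].reset_index(drop=True)


def prepare_revenue_shares(
    receipts: pd.DataFrame,
    group_map: dict[str, dict[str, float]] | None = None,
    scored_species: set[str] | None = None,
    years: tuple[int, int] | None = None,
    confidential_threshold: float = 0.20,
    misc_threshold: float = 0.05,
    top_share: float = 0.90,
    weighting: str = "revenue",
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Run the whole cascade; returns shares and a bookkeeping dict of
    removed/flagged identifiers per stage."""
    totals = aggregate_landings(receipts, years)
    totals, removed = filter_confidential(totals, confidential_threshold)
    totals, flagged = drop_misc(totals, misc_threshold)
    totals = expand_unidentified(totals, group_map or {})
    retained = top90_by_weight(totals, top_share)
    shares = revenue_shares(totals, retained, scored_species, weighting)
    log = {"removed_confidential": removed, "flagged_misc": flagged,
           "communities_with_shares": sorted(shares["community"].unique())}
    return shares, log
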
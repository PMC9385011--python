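"""Adaptive-capacity index from tract-level social indicators.

The index follows the CDC Social Vulnerability Index recipe: 15 metrics in
four themes (socioeconomic; household composition/disability; minority
status/language; housing/transportation), averaged from census tracts to
communities, percent-ranked per metric across communities, summed, and
percent-ranked again. Per-capita income is the one metric where a larger raw
value means better conditions, so its rank is reversed (1 - rank) before
summing. The result AC is in [0, 1] with 1 = least able to adapt, matching
the orientation of the exposure and sensitivity axes.

Alternative indicator tables are accepted through the same interface: any
per-community metric table plus a per-metric direction flag (adverse vs
beneficial) and theme assignment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from coastvuln.ranking import percent_rank

__all__ = [
    "ADVERSE_METRICS",
    "ALL_METRICS",
    "INCOME_METRIC",
    "THEMES",
    "composite_ac",
    "rank_and_reverse",
    "theme_correlations",
    "tracts_to_communities",
]

THEMES: dict[str, list[str]] = {
    "socioeconomic": ["below_poverty", "unemployed", "per_capita_income",
                      "no_hs_diploma"],
    "household": ["age65plus", "age17less", "disability", "single_parent"],
    "minority_language": ["minority", "limited_english"],
    "housing_transport": ["multiunit", "mobile_homes", "crowding",
                          "no_vehicle", "group_quarters"],
}

INCOME_METRIC = "per_capita_income"
ALL_METRICS: list[str] = [m for ms in THEMES.values() for m in ms]
ADVERSE_METRICS: list[str] = [m for m in ALL_METRICS if m != INCOME_METRIC]


def tracts_to_communities(
    tracts: pd.DataFrame,
    mapping: pd.DataFrame,
    metrics: list[str] | None = None,
    weighting: str = "unweighted",
) -> pd.DataFrame:
    """Average tract metrics into community-level values.

    Parameters
    ----------
    tracts
        One row per tract with a ``tract`` column and one column per metric.
    mapping
        Columns ``tract``, ``community``; a tract may intersect several
        communities and then contributes to each.
    weighting
        ``"unweighted"`` (default) or ``"population"`` (requires a
        ``population`` column in ``tracts``).
    """
    metrics = list(metrics) if metrics is not None else ALL_METRICS
    merged = mapping.merge(tracts, on="tract", how="left")
    missing_tracts = merged[merged[metrics[0]].isna()]["tract"].tolist()
    if missing_tracts:
        raise ValueError(f"tracts missing from the indicator table: {missing_tracts}")
    empty = set(mapping["community"].unique()) ^ set(merged["community"].unique())
    if empty:
        raise ValueError(f"communities with no mapped tract: {sorted(empty)}")
    if weighting == "unweighted":
        out = merged.groupby("community")[metrics].mean()
    elif weighting == "population":
        if "population" not in merged.columns:
            raise ValueError("population weighting requires a 'population' column")
        w = merged["population"].astype(float)
        out = (merged[metrics].multiply(w, axis=0).groupby(merged["community"]).sum()
               .div(w.groupby(merged["community"]).sum(), axis=0))
    else:
        raise ValueError(f"unknown tract weighting {weighting!r}")
    return out.sort_index()


def rank_and_reverse(
    community_metrics: pd.DataFrame,
    beneficial: list[str] | None = None,
    rank_denominator: str = "n_minus_1",
) -> pd.DataFrame:
    """Percent-rank every metric across communities to [0, 1], higher = worse.

    Metrics listed in ``beneficial`` (default: per-capita income) have their
    rank replaced by ``1 - rank`` so that higher always means worse
    conditions. A constant metric ranks 0 for everyone, with a warning.
    """
    if len(community_metrics) < 2:
        raise ValueError("ranking requires at least two communities")
    beneficial = list(beneficial) if beneficial is not None else [INCOME_METRIC]
    ranked = pd.DataFrame(index=community_metrics.index)
    for metric in community_metrics.columns:
        col = community_metrics[metric].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            warnings.warn(f"metric {metric!r} is constant across communities; "
                          "ranked 0 for all")
            r = np.zeros(col.size)
        else:
            r = percent_rank(col, denominator=rank_denominator)
            if metric in beneficial:
                r = 1.0 - r
        ranked[metric] = r
    return ranked


def composite_ac(
    ranked: pd.DataFrame,
    themes: dict[str, list[str]] | None = None,
    rank_denominator: str = "n_minus_1",
) -> pd.DataFrame:
    """Sum ranked metrics, percent-rank the sum into AC in [0, 1].

    Returns a frame with per-theme sums, the composite sum, and ``AC``.
    """
    themes = themes if themes is not None else THEMES
    out = pd.DataFrame(index=ranked.index)
    for theme, metrics in themes.items():
        present = [m for m in metrics if m in ranked.columns]
        out[f"theme_{theme}"] = ranked[present].sum(axis=1)
    out["composite_sum"] = ranked.sum(axis=1)
    out["AC"] = percent_rank(out["composite_sum"].to_numpy(),
                             denominator=rank_denominator)
    return out


def theme_correlations(
    ranked: pd.DataFrame,
    ac_table: pd.DataFrame,
) -> pd.Series:
    """Pearson correlation of AC with each ranked metric and each theme sum.

    Zero-variance columns yield NaN (reported missing, not an error).
    """
    if len(ac_table) < 3:
        raise ValueError("correlations require at least three communities")
    ac = ac_table["AC"]
    cols = pd.concat(
        [ranked, ac_table[[c for c in ac_table.columns if c.startswith("theme_")]]],
        axis=1)
    corr = {}
    for name in cols.columns:
        x = cols[name]
        if x.std(ddof=0) == 0 or ac.std(ddof=0) == 0:
            corr[name] = np.nan
        else:
            corr[name] = float(np.corrcoef(x, ac)[0, 1])
    return pd.Series(corr, name="correlation_with_AC")
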
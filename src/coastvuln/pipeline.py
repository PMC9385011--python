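"""End-to-end orchestration: inputs -> species risk -> community vulnerability.

``run_pipeline`` either generates a synthetic input bundle from the
configuration or loads one from disk, then runs every stage in order:

1. species-level exposure/sensitivity/risk from climate fields and ranges;
2. landings filter cascade to per-community revenue shares;
3. community exposure (share-weighted species risk, percent-ranked),
   sensitivity (percent-ranked reliance), risk R;
4. adaptive capacity from tract-level social indicators;
5. vulnerability V, quadrant labels, ranks, and regional diagnostics.

Everything is deterministic given the configuration: running twice with the
same seed writes byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from coastvuln import adaptive, community, landings, synthetic
from coastvuln import vulnerability as vuln
from coastvuln.climate import EcoScoreTable, build_eco_scores, model_agreement
from coastvuln.config import RunConfig
from coastvuln.io import InputBundle, validate_bundle, write_report, write_table

__all__ = ["PipelineResult", "generate_bundle", "run_pipeline"]


@dataclass
class PipelineResult:
    eco: EcoScoreTable
    shares: pd.DataFrame
    community_scores: pd.DataFrame
    agreement: pd.DataFrame
    ac_ranked: pd.DataFrame
    ac_table: pd.DataFrame
    theme_corr: pd.Series
    regional: pd.DataFrame
    log: dict


def generate_bundle(config: RunConfig) -> InputBundle:
    """Generate all five synthetic inputs from the run configuration."""
    cfg, scenario = config.synthetic, config.scenario
    tracts, mapping = synthetic.generate_social_indicators(cfg, scenario)
    return InputBundle(
        climate=synthetic.generate_climate_fields(cfg, list(config.models), scenario),
        ranges=synthetic.generate_species_ranges(cfg),
        receipts=synthetic.generate_landings(cfg, scenario),
        reliance=synthetic.generate_reliance(cfg, scenario),
        tracts=tracts,
        mapping=mapping,
        group_map=synthetic.default_group_map(cfg),
    )


def _stage(log: dict, name: str, **info) -> None:
    log.setdefault("stages", []).append({"stage": name, **info})


def run_pipeline(
    config: RunConfig,
    bundle: InputBundle | None = None,
    write: bool = True,
) -> PipelineResult:
    """Run every stage; optionally write all tables under config.output_dir."""
    config.validate()
    log: dict = {}
    if bundle is None:
        if config.input_dir is not None:
            from coastvuln.io import read_bundle

            bundle = read_bundle(config.input_dir)
        else:
            bundle = generate_bundle(config)
    violations = validate_bundle(bundle)
    if violations:
        raise ValueError("input validation failed:\n" + "\n".join(violations))
    _stage(log, "inputs", n_species=len(bundle.ranges),
           n_receipts=len(bundle.receipts),
           n_communities=bundle.reliance["community"].nunique())

    # 1. species-level ecological risk
    try:
        eco = build_eco_scores(bundle.ranges, bundle.climate, list(config.models),
                               config.thresholds, config.policies)
    except Exception as exc:  # annotate stage
        raise RuntimeError(f"stage ecological-risk failed: {exc}") from exc
    _stage(log, "ecological_risk", n_scored=eco.per_species["species"].nunique())

    # 2. landings cascade -> revenue shares
    scored = set(eco.per_species["species"])
    shares, cascade_log = landings.prepare_revenue_shares(
        bundle.receipts,
        group_map=bundle.group_map,
        scored_species=scored,
        confidential_threshold=config.thresholds.confidential,
        misc_threshold=config.thresholds.misc,
        top_share=config.thresholds.top_share,
        weighting=config.policies.share_weighting,
    )
    log["landings_cascade"] = cascade_log
    _stage(log, "landings", n_communities=shares["community"].nunique(),
           removed_confidential=len(cascade_log["removed_confidential"]))

    # 3. community exposure, sensitivity, risk
    denom = config.policies.rank_denominator
    expo = community.community_exposure(eco.per_species, shares, denom)
    sens = community.community_sensitivity(bundle.reliance, denom)
    scores = expo.merge(sens, on="community", how="inner")
    scores = community.community_risk(scores)
    _stage(log, "community_risk", n_communities=len(scores))

    # 4. adaptive capacity
    comm_metrics = adaptive.tracts_to_communities(
        bundle.tracts, bundle.mapping, weighting=config.policies.tract_weighting)
    comm_metrics = comm_metrics.loc[
        comm_metrics.index.intersection(scores["community"])]
    ranked = adaptive.rank_and_reverse(comm_metrics, rank_denominator=denom)
    ac_table = adaptive.composite_ac(ranked, rank_denominator=denom)
    theme_corr = adaptive.theme_correlations(ranked, ac_table)
    scores = scores.merge(ac_table[["AC"]], left_on="community",
                          right_index=True, how="inner")
    _stage(log, "adaptive_capacity", n_communities=len(scores))

    # 5. vulnerability, quadrants, ranks, diagnostics
    scores = vuln.community_vulnerability(scores)
    scores = vuln.classify_quadrant(scores, config.thresholds.quadrant_splits)
    scores = vuln.rank_difference(scores)
    if "region" in bundle.reliance.columns:
        scores = scores.merge(bundle.reliance[["community", "region"]],
                              on="community", how="left")
        regional = vuln.regional_summary(scores, config.thresholds.top_percentile)
    else:
        regional = pd.DataFrame()
    agreement = model_agreement(eco.per_model)
    scores = scores.sort_values("community").reset_index(drop=True)
    _stage(log, "vulnerability", n_communities=len(scores))

    result = PipelineResult(
        eco=eco, shares=shares, community_scores=scores, agreement=agreement,
        ac_ranked=ranked, ac_table=ac_table, theme_corr=theme_corr,
        regional=regional, log=log)
    if write:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(result.eco.per_variable, out / "eco_scores_per_variable.csv")
    write_table(result.eco.per_model, out / "eco_scores_per_model.csv")
    write_table(result.eco.per_species, out / "eco_scores_per_species.csv")
    write_table(result.shares, out / "revenue_shares.csv")
    write_table(result.community_scores, out / "community_scores.csv")
    write_table(result.agreement, out / "model_agreement.csv", index=True)
    write_table(result.ac_ranked, out / "ac_ranked_metrics.csv", index=True)
    write_table(result.ac_table, out / "ac_table.csv", index=True)
    write_table(result.theme_corr.to_frame(), out / "ac_theme_correlations.csv",
                index=True)
    if not result.regional.empty:
        write_table(result.regional, out / "regional_summary.csv")

    scores = result.community_scores
    top_cut = max(1, int(np.ceil(len(scores) * (1 - config.thresholds.top_percentile))))
    summary = {
        "n_communities": len(scores),
        "n_species_scored": result.eco.per_species["species"].nunique(),
        "quadrant_counts": scores["quadrant"].value_counts().to_dict(),
        "top_decile_by_risk": scores.nsmallest(top_cut, "risk_rank")
        ["community"].tolist(),
        "top_decile_by_vulnerability": scores.nsmallest(top_cut, "vuln_rank")
        ["community"].tolist(),
        "model_agreement": result.agreement,
        "ac_theme_correlations": result.theme_corr,
        "landings_cascade": result.log.get("landings_cascade", {}),
    }
    write_report(summary, out)
    lines = [f"{s['stage']}: " + ", ".join(f"{k}={v}" for k, v in s.items()
                                           if k != "stage")
             for s in result.log.get("stages", [])]
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")
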
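"""Species-level ecological exposure, sensitivity, and risk.

For each species, earth-system model, and climate variable (temperature, pH,
oxygen, chlorophyll) the historical and future values of the variable are
pooled over every (cell, month) inside the species' core range (occurrence
probability >= a threshold, default 0.4) intersected with the analysis
domain. Benthic species read bottom-layer fields, pelagic species surface.

* exposure  = 100 - percent of future values inside the historical
  [P5, P95] band (inclusive); high when the future distribution escapes the
  historically experienced conditions.
* sensitivity = 1 / (P95 - P5) of the historical values; a narrow climatic
  niche implies high sensitivity.

Raw scores are log10-transformed and min-max scaled to [0, 1] within each
(model, variable) slice across species, averaged over the four variables
with equal weight, and combined into ecological risk as the Euclidean
distance from the across-species minima within each model:

    theta = sqrt((e_bar - min e_bar)^2 + (s_bar - min s_bar)^2)

theta is finally averaged across models; the cross-model standard deviation
of averaged exposure is retained as an agreement diagnostic, alongside the
pairwise Spearman correlation of per-model risk rankings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from coastvuln.config import CLIMATE_VARIABLES, Policies, Thresholds
from coastvuln.grids import ClimateField, SpeciesRange

__all__ = [
    "EcoScoreTable",
    "NicheSample",
    "average_variables",
    "build_eco_scores",
    "compute_exposure",
    "compute_sensitivity",
    "ecological_risk",
    "extract_range_mask",
    "model_agreement",
    "sample_niche",
    "transform_and_scale",
]


@dataclass
class NicheSample:
    """Pooled within-range climate values for one species/model/variable."""

    species: str
    model: str
    variable: str
    historical_values: np.ndarray
    future_values: np.ndarray


@dataclass
class EcoScoreTable:
    """per_variable: (species, model, variable) raw + scaled scores;
    per_model: (species, model) e_bar, s_bar, theta;
    per_species: theta_bar and cross-model exposure sd."""

    per_variable: pd.DataFrame
    per_model: pd.DataFrame
    per_species: pd.DataFrame


def extract_range_mask(sp_range: SpeciesRange, threshold: float = 0.4) -> np.ndarray:
    """Boolean core-range mask: probability >= threshold (inclusive)."""
    if not 0 < threshold < 1:
        raise ValueError("occurrence threshold must be in (0, 1)")
    mask = sp_range.probability >= threshold
    if not mask.any():
        warnings.warn(f"species {sp_range.species!r} has no cell at or above "
                      f"occurrence {threshold}; no core range")
    return mask


def _pool(values: np.ndarray, cell_mask: np.ndarray, pooling: str) -> np.ndarray:
    if pooling == "annual":
        n_time = values.shape[0]
        if n_time % 12:
            raise ValueError("annual pooling requires whole years of monthly data")
        values = values.reshape(n_time // 12, 12, *values.shape[1:]).mean(axis=1)
    elif pooling != "monthly":
        raise ValueError(f"unknown pooling {pooling!r}")
    return values[:, cell_mask].ravel()


def sample_niche(
    sp_range: SpeciesRange,
    fields: list[ClimateField],
    model: str,
    variable: str,
    domain_mask: np.ndarray,
    threshold: float = 0.4,
    pooling: str = "monthly",
) -> NicheSample:
    """Pool every (cell, time) value within range mask ∩ domain mask.

    No area or probability weighting is applied; each retained cell-month
    contributes one value. The layer follows the species' habitat.
    """
    layer = sp_range.layer
    by_period = {}
    for period in ("historical", "future"):
        match = [f for f in fields
                 if f.key == (model, variable, layer, period)]
        if not match:
            raise ValueError(
                f"missing climate field model={model} variable={variable} "
                f"layer={layer} period={period}")
        by_period[period] = match[0]
    cell_mask = extract_range_mask(sp_range, threshold) & domain_mask
    if not cell_mask.any():
        raise ValueError(f"species {sp_range.species!r} has no core-range cell "
                         "inside the analysis domain")
    return NicheSample(
        species=sp_range.species, model=model, variable=variable,
        historical_values=_pool(by_period["historical"].values, cell_mask, pooling),
        future_values=_pool(by_period["future"].values, cell_mask, pooling),
    )


def compute_exposure(sample: NicheSample,
                     band: tuple[float, float] = (5.0, 95.0)) -> float:
    """Percent of future values escaping the historical [P5, P95] band.

    Percentiles use linear interpolation between order statistics; band
    membership is inclusive at both bounds.
    """
    hist = np.asarray(sample.historical_values, dtype=float)
    fut = np.asarray(sample.future_values, dtype=float)
    if fut.size == 0:
        raise ValueError("future_values is empty")
    if hist.size == 0:
        raise ValueError("historical_values is empty")
    if hist.size < 20:
        warnings.warn(f"low historical sample (n={hist.size}) for "
                      f"{sample.species}/{sample.model}/{sample.variable}")
    lo, hi = np.percentile(hist, band)
    inside = np.count_nonzero((fut >= lo) & (fut <= hi))
    return 100.0 - 100.0 * inside / fut.size


def compute_sensitivity(sample: NicheSample,
                        band: tuple[float, float] = (5.0, 95.0)) -> float:
    """Inverse historical climatic breadth 1 / (P95 - P5).

    Zero breadth (constant conditions) returns ``inf``; the table builder
    replaces it with the largest finite sensitivity of the same
    (model, variable) slice, on the view that a species experiencing no
    variability is maximally sensitive under this proxy.
    """
    hist = np.asarray(sample.historical_values, dtype=float)
    if hist.size == 0:
        raise ValueError("historical_values is empty")
    lo, hi = np.percentile(hist, band)
    breadth = hi - lo
    if breadth == 0:
        warnings.warn(f"zero climatic breadth for {sample.species}/"
                      f"{sample.model}/{sample.variable}; flagged degenerate")
        return np.inf
    return 1.0 / breadth


def _minmax_log10(raw: np.ndarray, floor: float | None = None) -> np.ndarray:
    v = raw.astype(float).copy()
    if floor is not None:
        v[v <= 0] = floor
    logv = np.log10(v)
    ptp = np.ptp(logv)
    if ptp == 0 or logv.size == 1:
        warnings.warn("degenerate scaling slice (single species or constant "
                      "values); scaled to 0")
        return np.zeros_like(logv)
    return (logv - logv.min()) / ptp


def transform_and_scale(per_variable: pd.DataFrame,
                        exposure_floor: float = 0.01) -> pd.DataFrame:
    """log10 then min-max scale to [0, 1] within each (model, variable) slice.

    Exposure and sensitivity are scaled separately across species. Zero raw
    exposure is floored at ``exposure_floor`` percent before the log; raw
    ordering is preserved by both transforms.
    """
    df = per_variable.copy()
    # resolve degenerate (infinite) sensitivities to the slice max first
    def _fix_inf(group: pd.Series) -> pd.Series:
        finite = group[np.isfinite(group)]
        if len(finite) < len(group):
            if finite.empty:
                raise ValueError("all sensitivities degenerate in one slice")
            group = group.where(np.isfinite(group), finite.max())
        return group

    df["raw_sensitivity"] = (df.groupby(["model", "variable"], sort=False)
                             ["raw_sensitivity"].transform(_fix_inf))
    df["scaled_exposure"] = (
        df.groupby(["model", "variable"], sort=False)["raw_exposure"]
        .transform(lambda g: _minmax_log10(g.to_numpy(), floor=exposure_floor)))
    df["scaled_sensitivity"] = (
        df.groupby(["model", "variable"], sort=False)["raw_sensitivity"]
        .transform(lambda g: _minmax_log10(g.to_numpy())))
    return df


def average_variables(per_variable: pd.DataFrame) -> pd.DataFrame:
    """Equal-weight mean of the scaled scores over the four climate variables.

    Species missing some variables average over what is present (with a
    warning); species with no variables at all are dropped.
    """
    n_vars = per_variable.groupby(["species", "model"])["variable"].nunique()
    incomplete = n_vars[n_vars < len(CLIMATE_VARIABLES)]
    if not incomplete.empty:
        warnings.warn("species with missing climate variables averaged over "
                      f"available ones: {sorted(set(incomplete.index.get_level_values(0)))}")
    out = (per_variable.groupby(["species", "model"], as_index=False)
           .agg(e_bar=("scaled_exposure", "mean"),
                s_bar=("scaled_sensitivity", "mean")))
    return out


def ecological_risk(per_model: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Euclidean risk from the per-model across-species minima.

    Returns the per-model frame with ``theta`` added and a per-species frame
    with ``theta_bar`` (mean over models) and the cross-model standard
    deviation of averaged exposure.
    """
    df = per_model.copy()
    mins = df.groupby("model")[["e_bar", "s_bar"]].transform("min")
    df["theta"] = np.sqrt((df["e_bar"] - mins["e_bar"]) ** 2
                          + (df["s_bar"] - mins["s_bar"]) ** 2)
    per_species = (df.groupby("species", as_index=False)
                   .agg(theta_bar=("theta", "mean"),
                        exposure_sd=("e_bar", lambda v: float(np.std(v, ddof=1))
                                     if len(v) > 1 else np.nan)))
    return df, per_species


def model_agreement(per_model: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation of per-model risk rankings of species.

    Undefined coefficients (constant theta vector) are reported as NaN.
    """
    pivot = per_model.pivot(index="species", columns="model", values="theta")
    models = list(pivot.columns)
    if len(models) < 2 or len(pivot) < 3:
        raise ValueError("model agreement requires >= 2 models and >= 3 species")
    mat = pd.DataFrame(np.eye(len(models)), index=models, columns=models)
    for i, a in enumerate(models):
        for b in models[i + 1:]:
            va, vb = pivot[a].to_numpy(), pivot[b].to_numpy()
            if np.ptp(va) == 0 or np.ptp(vb) == 0:
                rho = np.nan
            else:
                rho = float(stats.spearmanr(va, vb).statistic)
            mat.loc[a, b] = mat.loc[b, a] = rho
    return mat


def build_eco_scores(
    ranges: list[SpeciesRange],
    fields: list[ClimateField],
    models: list[str],
    thresholds: Thresholds | None = None,
    policies: Policies | None = None,
) -> EcoScoreTable:
    """Run the full species-level scoring for every species x model x variable.

    Species without a core range inside the domain are excluded with a
    warning and do not appear in the output.
    """
    thresholds = thresholds or Thresholds()
    policies = policies or Policies()
    domain = fields[0].mask
    rows = []
    for sp in ranges:
        core = extract_range_mask(sp, thresholds.occurrence)
        if not (core & domain).any():
            warnings.warn(f"species {sp.species!r} excluded: no core range in domain")
            continue
        for model in models:
            for var in CLIMATE_VARIABLES:
                sample = sample_niche(sp, fields, model, var, domain,
                                      threshold=thresholds.occurrence,
                                      pooling=policies.pooling)
                rows.append({
                    "species": sp.species, "model": model, "variable": var,
                    "raw_exposure": compute_exposure(sample, thresholds.percentile_band),
                    "raw_sensitivity": compute_sensitivity(sample,
                                                           thresholds.percentile_band),
                })
    per_variable = pd.DataFrame(rows)
    if per_variable.empty:
        raise ValueError("no species could be scored")
    per_variable = transform_and_scale(per_variable, thresholds.exposure_floor)
    per_model = average_variables(per_variable)
    per_model, per_species = ecological_risk(per_model)
    return EcoScoreTable(per_variable=per_variable, per_model=per_model,
                         per_species=per_species)
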
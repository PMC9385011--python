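"""Synthetic inputs with known, controllable structure.

The five pipeline inputs (climate fields, species ranges, landings receipts,
commercial-fishing reliance, tract-level social indicators) are generated
with seeded RNG streams, one per generator, so any single input can be
regenerated in isolation. Known structure means parameter recovery can be
tested: a :class:`~coastvuln.config.ScenarioSpec` fixes per-species future
shifts, per-community revenue compositions, reliance values, and social
severity, and downstream scores must recover the designed orderings.

Construction notes
------------------
* Climate fields are a smooth latitudinal gradient plus iid per-cell Gaussian
  noise; the future period adds a mean shift expressed in units of the
  per-cell temporal standard deviation, scaled per earth-system model to
  emulate ensemble spread. Gradients are concave in latitude (~ sqrt), so a
  fixed-width range band spans less of the gradient the further north it
  sits: northern species have narrower climatic niches by construction.
* Species ranges are contiguous latitudinal bands. Occurrence probability
  decays linearly from ``CORE_PROBABILITY`` at the band centre by
  ``PROBABILITY_DECAY`` per row, which makes the number of core cells
  (probability >= 0.4) analytically countable.
* Landings are generated once per port group and copied to each member
  community, mirroring how port-group-level reporting assigns identical
  compositions to every port in a group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from coastvuln.config import (
    CLIMATE_VARIABLES,
    LAYERS,
    PERIODS,
    ScenarioSpec,
    SyntheticConfig,
)
from coastvuln.grids import ClimateField, SpeciesRange

__all__ = [
    "CORE_PROBABILITY",
    "PROBABILITY_DECAY",
    "community_names",
    "core_rows_per_band",
    "default_group_map",
    "generate_climate_fields",
    "generate_landings",
    "generate_reliance",
    "generate_social_indicators",
    "generate_species_ranges",
    "model_shift_scales",
    "species_band_rows",
    "species_names",
]

CORE_PROBABILITY = 0.9
PROBABILITY_DECAY = 0.3

MISC_LABEL = "other_miscellaneous"
UNIDENTIFIED_LABEL = "unidentified_mixed"

# latitudinal gradient parameters per (variable, layer): value = base + span*sqrt(x)
_GRADIENTS = {
    ("temperature", "surface"): (18.0, -8.0),
    ("temperature", "bottom"): (10.0, -5.0),
    ("ph", "surface"): (8.15, -0.10),
    ("ph", "bottom"): (7.95, -0.10),
    ("oxygen", "surface"): (260.0, -60.0),
    ("oxygen", "bottom"): (180.0, -80.0),
    ("chlorophyll", "surface"): (1.0, 3.0),
    ("chlorophyll", "bottom"): (0.5, 1.5),
}

_STREAM = {"climate": 0, "ranges": 1, "landings": 2, "social": 3, "reliance": 4}


def _rng(cfg: SyntheticConfig, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAM[stream], *extra])


def species_names(cfg: SyntheticConfig) -> list[str]:
    return [f"sp{i + 1:02d}" for i in range(cfg.n_species)]


def community_names(cfg: SyntheticConfig) -> list[str]:
    return [f"C{i + 1:02d}" for i in range(cfg.n_communities)]


def port_group_names(cfg: SyntheticConfig) -> list[str]:
    return [f"PG{i + 1}" for i in range(cfg.n_port_groups)]


def port_group_of(cfg: SyntheticConfig) -> dict[str, str]:
    groups = port_group_names(cfg)
    return {c: groups[i % cfg.n_port_groups]
            for i, c in enumerate(community_names(cfg))}


def model_shift_scales(models: list[str]) -> dict[str, float]:
    """Per-model multipliers on the configured shift, spanning 0.8-1.2."""
    n = len(models)
    if n == 1:
        return {models[0]: 1.0}
    return {m: 0.8 + 0.4 * i / (n - 1) for i, m in enumerate(models)}


def species_band_rows(cfg: SyntheticConfig) -> list[tuple[int, int]]:
    """Contiguous, non-overlapping latitude row spans, one per species."""
    h = cfg.grid.n_lat // cfg.n_species
    if h < 1:
        raise ValueError("n_lat must be >= n_species")
    return [(s * h, (s + 1) * h) for s in range(cfg.n_species)]


def core_rows_per_band(cfg: SyntheticConfig) -> int:
    """Rows per band with probability >= 0.4 under the linear decay rule."""
    h = cfg.grid.n_lat // cfg.n_species
    d_max = int((CORE_PROBABILITY - 0.4) / PROBABILITY_DECAY + 1e-9)
    centre = h // 2
    lo = max(0, centre - d_max)
    hi = min(h - 1, centre + d_max)
    return hi - lo + 1


def domain_mask(cfg: SyntheticConfig) -> np.ndarray:
    """(lat, lon) boolean mask; the easternmost columns are land."""
    n_coast = max(1, cfg.grid.n_lon // 10)
    mask = np.ones((cfg.grid.n_lat, cfg.grid.n_lon), dtype=bool)
    mask[:, cfg.grid.n_lon - n_coast:] = False
    return mask


def _axes(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    lon0, lat0 = -126.0, 31.0
    lon = lon0 + cfg.grid.cell_size_deg * np.arange(cfg.grid.n_lon)
    lat = lat0 + cfg.grid.cell_size_deg * np.arange(cfg.grid.n_lat)
    return lon, lat


def _shift_profile(cfg: SyntheticConfig, scenario: ScenarioSpec | None) -> np.ndarray:
    """Per-latitude-row multiplier on the future shift (1 outside bands)."""
    profile = np.ones(cfg.grid.n_lat)
    if scenario is not None and scenario.species_shift_multipliers is not None:
        for (start, stop), mult in zip(species_band_rows(cfg),
                                       scenario.species_shift_multipliers):
            profile[start:stop] = mult
    return profile


def generate_climate_fields(
    cfg: SyntheticConfig,
    models: list[str],
    scenario: ScenarioSpec | None = None,
) -> list[ClimateField]:
    """Monthly fields for every model x variable x layer x period.

    The future field equals the historical structure plus
    ``climate_shift[var] * model_scale * band_multiplier`` expressed in units
    of the per-cell temporal standard deviation (``noise_sd[var]``), plus
    fresh noise. With all shifts zero, historical and future values are draws
    from the same per-cell distribution.
    """
    cfg.validate()
    if scenario is not None:
        scenario.validate(cfg)
    if not models:
        raise ValueError("at least one model identifier required")
    lon, lat = _axes(cfg)
    mask = domain_mask(cfg)
    n_time = 12 * cfg.n_years
    x = (np.arange(cfg.grid.n_lat) + 0.5) / cfg.grid.n_lat
    profile = _shift_profile(cfg, scenario)
    scales = model_shift_scales(list(models))

    fields: list[ClimateField] = []
    for mi, model in enumerate(models):
        for vi, var in enumerate(CLIMATE_VARIABLES):
            for li, layer in enumerate(LAYERS):
                base, span = _GRADIENTS[(var, layer)]
                gradient = base + span * np.sqrt(x)  # (lat,)
                sd = cfg.noise_sd[var]
                for pi, period in enumerate(PERIODS):
                    rng = _rng(cfg, "climate", mi, vi, li, pi)
                    noise = rng.normal(0.0, sd, size=(n_time, cfg.grid.n_lat,
                                                      cfg.grid.n_lon))
                    values = gradient[None, :, None] + noise
                    if period == "future":
                        shift = (cfg.climate_shift[var] * scales[model]
                                 * profile * sd)  # (lat,)
                        values = values + shift[None, :, None]
                    fields.append(ClimateField(
                        variable=var, layer=layer, period=period, model=model,
                        values=values, mask=mask, lon=lon, lat=lat))
    return fields


def generate_species_ranges(cfg: SyntheticConfig) -> list[SpeciesRange]:
    """Latitudinal-band ranges with linearly decaying occurrence probability."""
    cfg.validate()
    lon, lat = _axes(cfg)
    mask = domain_mask(cfg)
    rng = _rng(cfg, "ranges")
    bands = species_band_rows(cfg)
    h = cfg.grid.n_lat // cfg.n_species
    ranges = []
    for name, (start, stop) in zip(species_names(cfg), bands):
        habitat = "benthic" if rng.random() < 0.5 else "pelagic"
        prob = np.zeros((cfg.grid.n_lat, cfg.grid.n_lon))
        centre = start + h // 2
        for row in range(start, stop):
            p = CORE_PROBABILITY - PROBABILITY_DECAY * abs(row - centre)
            if p > 0:
                prob[row, mask[row]] = p
        ranges.append(SpeciesRange(species=name, habitat=habitat,
                                   probability=prob, lon=lon, lat=lat))
    return ranges


def default_group_map(cfg: SyntheticConfig) -> dict[str, dict[str, float]]:
    """Split rule resolving unidentified-group catch into member species."""
    sp = species_names(cfg)
    members = sp[: min(2, len(sp))]
    share = 1.0 / len(members)
    return {UNIDENTIFIED_LABEL: {s: share for s in members}}


def generate_landings(
    cfg: SyntheticConfig,
    scenario: ScenarioSpec | None = None,
) -> pd.DataFrame:
    """Receipt-level landings (community, port_group, species, year, weight,
    revenue, confidential, category).

    Each port group receives one composition (Dirichlet over a species
    subset, plus small "other/miscellaneous" and unidentified-group slices)
    and every community in the group receives the identical receipts. A
    scenario composition overrides its community's whole port group and
    suppresses the misc/unidentified slices so realized shares match the
    design exactly in expectation.
    """
    cfg.validate()
    if scenario is not None:
        scenario.validate(cfg)
    rng = _rng(cfg, "landings")
    sp = species_names(cfg)
    comms = community_names(cfg)
    pg_of = port_group_of(cfg)
    groups = port_group_names(cfg)

    # fixed per-species price, log-normal across species
    price = {s: float(np.exp(rng.normal(np.log(2.0), 0.5))) for s in sp}

    # default composition per port group over a sparse species subset
    composition: dict[str, dict[str, float]] = {}
    designed: dict[str, bool] = {}
    for g in groups:
        k = min(len(sp), 6)
        chosen = list(rng.choice(sp, size=k, replace=False))
        w = rng.dirichlet(np.full(k, 0.8))
        composition[g] = dict(zip(chosen, w.tolist()))
        designed[g] = False
    if scenario is not None and scenario.revenue_concentration is not None:
        for comm in sorted(scenario.revenue_concentration):
            g = pg_of[comm]
            composition[g] = dict(scenario.revenue_concentration[comm])
            designed[g] = True

    conf_comms: set[str] = set()
    if cfg.confidential_fraction > 0:
        conf_comms = set(cfg.confidential_communities
                         if cfg.confidential_communities is not None
                         else [comms[-1]])

    rows = []
    for g in groups:
        comp = composition[g]
        base_volume = float(np.exp(rng.normal(np.log(1000.0), 0.3)))
        misc_f = 0.0 if designed[g] else cfg.misc_fraction
        unid_f = 0.0 if designed[g] else cfg.unidentified_fraction
        species_f = 1.0 - misc_f - unid_f
        group_rows = []
        for year in range(2009, 2009 + cfg.n_years):
            for s in sorted(comp):
                weight = (comp[s] * species_f * base_volume
                          * float(np.exp(rng.normal(0.0, 0.05))))
                revenue = weight * price.get(s, 2.0) * float(np.exp(rng.normal(0.0, 0.1)))
                group_rows.append((s, year, weight, revenue, "normal"))
            if misc_f > 0:
                w = misc_f * base_volume * float(np.exp(rng.normal(0.0, 0.05)))
                group_rows.append((MISC_LABEL, year, w, w * 1.0, "other_misc"))
            if unid_f > 0:
                w = unid_f * base_volume * float(np.exp(rng.normal(0.0, 0.05)))
                group_rows.append((UNIDENTIFIED_LABEL, year, w, w * 2.0,
                                   "unidentified_group"))
        for comm in [c for c in comms if pg_of[c] == g]:
            f = cfg.confidential_fraction if comm in conf_comms else 0.0
            for s, year, weight, revenue, cat in group_rows:
                if f > 0:
                    rows.append((comm, g, s, year, weight * (1 - f),
                                 revenue * (1 - f), False, cat))
                    rows.append((comm, g, s, year, weight * f,
                                 revenue * f, True, cat))
                else:
                    rows.append((comm, g, s, year, weight, revenue, False, cat))
    return pd.DataFrame(rows, columns=["community", "port_group", "species",
                                       "year", "weight", "revenue",
                                       "confidential", "category"])


def generate_reliance(
    cfg: SyntheticConfig,
    scenario: ScenarioSpec | None = None,
) -> pd.DataFrame:
    """Per-community commercial-fishing reliance (skewed; some exact zeros)
    plus a coarse region label used by the regional diagnostics.

    Roughly a fifth of communities have no measurable reliance, so the
    tied-at-minimum percent-rank behaviour is exercised by default.
    """
    cfg.validate()
    rng = _rng(cfg, "reliance")
    comms = community_names(cfg)
    values = np.exp(rng.normal(0.0, 1.0, size=len(comms)))
    zero = rng.random(len(comms)) < 0.2
    values[zero] = 0.0
    reliance = dict(zip(comms, values))
    if scenario is not None and scenario.reliance_values is not None:
        reliance.update(scenario.reliance_values)
    regions = ["north", "central", "south"]
    n = len(comms)
    region = [regions[min(i * len(regions) // n, len(regions) - 1)]
              for i in range(n)]
    return pd.DataFrame({"community": comms,
                         "reliance": [reliance[c] for c in comms],
                         "region": region})


def generate_social_indicators(
    cfg: SyntheticConfig,
    scenario: ScenarioSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tract-level social metrics plus the tract-to-community mapping.

    Each community has a latent severity in [0, 1]; tracts draw a shared
    per-theme effect (correlating metrics within a theme) plus metric-level
    noise. All metrics are adverse percentages except per-capita income,
    which decreases with severity.
    """
    from coastvuln.adaptive import ADVERSE_METRICS, INCOME_METRIC

    cfg.validate()
    if scenario is not None:
        scenario.validate(cfg)
    rng = _rng(cfg, "social")
    comms = community_names(cfg)
    severity = {c: float(rng.uniform(0.2, 0.8)) for c in comms}
    if scenario is not None and scenario.social_metric_levels is not None:
        severity.update(scenario.social_metric_levels)

    from coastvuln.adaptive import THEMES

    theme_of = {m: t for t, ms in THEMES.items() for m in ms}
    rows = []
    mapping = []
    for comm in comms:
        for k in range(cfg.n_tracts_per_community):
            tract = f"{comm}_t{k + 1}"
            mapping.append((tract, comm))
            theme_eff = {t: rng.normal(0.0, 0.08) for t in THEMES}
            record: dict[str, object] = {"tract": tract}
            for metric in ADVERSE_METRICS + [INCOME_METRIC]:
                level = np.clip(severity[comm] + theme_eff[theme_of[metric]]
                                + rng.normal(0.0, 0.05), 0.0, 1.0)
                if metric == INCOME_METRIC:
                    record[metric] = 20000.0 + 60000.0 * (1.0 - level)
                else:
                    record[metric] = float(np.clip(5.0 + 60.0 * level, 0.0, 100.0))
            record["population"] = int(rng.integers(500, 8000))
            rows.append(record)
    tracts = pd.DataFrame(rows)
    mapping_df = pd.DataFrame(mapping, columns=["tract", "community"])
    return tracts, mapping_df
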
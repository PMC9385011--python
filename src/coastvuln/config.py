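"""Configuration objects and YAML round-tripping for the pipeline.

Three layers of configuration:

* :class:`SyntheticConfig` — knobs of the synthetic-data generator
  (grid geometry, counts, climate shift and noise per variable, ...).
* :class:`ScenarioSpec` — a designed scenario layered on top of the
  generator: per-species future-shift multipliers, per-community revenue
  concentration, reliance values, and social-severity levels. Used for
  parameter-recovery experiments where the "right answer" is known by
  construction.
* :class:`RunConfig` — thresholds and policy switches of the assessment
  itself plus input/output paths.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

CLIMATE_VARIABLES = ("temperature", "ph", "oxygen", "chlorophyll")
LAYERS = ("surface", "bottom")
PERIODS = ("historical", "future")
DEFAULT_MODELS = ("ESM-A", "ESM-B", "ESM-C")

# Spread of the ensemble: each earth-system model realises the configured
# shift with its own scale, mimicking disagreement between projections.
DEFAULT_MODEL_SHIFT_SCALES = {"ESM-A": 0.8, "ESM-B": 1.0, "ESM-C": 1.2}


@dataclass
class GridSpec:
    n_lon: int = 30
    n_lat: int = 100
    cell_size_deg: float = 0.1

    def validate(self) -> None:
        if self.n_lon < 1 or self.n_lat < 1:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size_deg <= 0:
            raise ValueError("cell_size_deg must be > 0")


def _default_shift() -> dict[str, float]:
    # sign encodes direction of change (warming, acidification, deoxygenation,
    # declining production); magnitude is in units of the per-cell temporal sd.
    return {"temperature": 1.0, "ph": -1.0, "oxygen": -1.0, "chlorophyll": -0.5}


def _default_noise() -> dict[str, float]:
    # per-cell temporal standard deviation, in each variable's units
    return {"temperature": 1.0, "ph": 0.02, "oxygen": 20.0, "chlorophyll": 0.5}


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults are the study conditions of the
    synthetic experiments (20 species, 25 communities in 8 port groups,
    10 years of monthly fields on a 30x100 coastal grid)."""

    seed: int = 0
    grid: GridSpec = field(default_factory=GridSpec)
    n_species: int = 20
    n_port_groups: int = 8
    n_communities: int = 25
    n_tracts_per_community: int = 3
    n_years: int = 10
    climate_shift: dict[str, float] = field(default_factory=_default_shift)
    noise_sd: dict[str, float] = field(default_factory=_default_noise)
    confidential_fraction: float = 0.0
    confidential_communities: tuple[str, ...] | None = None
    misc_fraction: float = 0.03
    unidentified_fraction: float = 0.05

    def validate(self) -> None:
        self.grid.validate()
        for name in ("n_species", "n_port_groups", "n_communities",
                     "n_tracts_per_community", "n_years"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.confidential_fraction <= 1.0:
            raise ValueError("confidential_fraction must be in [0, 1]")
        for d in (self.climate_shift, self.noise_sd):
            missing = set(CLIMATE_VARIABLES) - set(d)
            if missing:
                raise ValueError(f"missing climate variables in config: {sorted(missing)}")
        for var, sd in self.noise_sd.items():
            if sd <= 0:
                raise ValueError(f"noise_sd[{var!r}] must be > 0")


@dataclass
class ScenarioSpec:
    """Designed structure injected into the generator.

    All fields are optional; ``None`` means "let the generator draw it".
    ``revenue_concentration`` maps community -> {species: share}, shares
    summing to 1 per community.
    """

    species_shift_multipliers: Sequence[float] | None = None
    revenue_concentration: Mapping[str, Mapping[str, float]] | None = None
    reliance_values: Mapping[str, float] | None = None
    social_metric_levels: Mapping[str, float] | None = None

    def validate(self, cfg: SyntheticConfig | None = None) -> None:
        if self.species_shift_multipliers is not None:
            if any(m < 0 for m in self.species_shift_multipliers):
                raise ValueError("species_shift_multipliers must be >= 0")
            if cfg is not None and len(self.species_shift_multipliers) != cfg.n_species:
                raise ValueError("species_shift_multipliers length must equal n_species")
        if self.revenue_concentration is not None:
            for comm, shares in self.revenue_concentration.items():
                total = sum(shares.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"revenue shares for {comm} sum to {total}, expected 1")
                if any(s < 0 or s > 1 for s in shares.values()):
                    raise ValueError(f"revenue shares for {comm} must lie in [0, 1]")
        if self.reliance_values is not None:
            if any(v < 0 for v in self.reliance_values.values()):
                raise ValueError("reliance_values must be >= 0")
        if self.social_metric_levels is not None:
            if any(not 0 <= v <= 1 for v in self.social_metric_levels.values()):
                raise ValueError("social_metric_levels must be in [0, 1]")


@dataclass
class Thresholds:
    """Filtering and scoring thresholds, all configurable.

    occurrence: probability-of-occurrence cut defining a species' core range.
    confidential: communities with a larger confidential weight share are removed.
    misc: "other/miscellaneous" catch below this weight share is dropped.
    top_share: cumulative landed-weight share retained per community.
    percentile_band: historical band used by exposure/sensitivity.
    exposure_floor: percent floor replacing zero exposure before log10.
    """

    occurrence: float = 0.4
    confidential: float = 0.20
    misc: float = 0.05
    top_share: float = 0.90
    percentile_band: tuple[float, float] = (5.0, 95.0)
    exposure_floor: float = 0.01
    quadrant_splits: tuple[float, float] | None = None  # None = midpoint of range
    top_percentile: float = 0.90

    def validate(self) -> None:
        if not 0 < self.occurrence < 1:
            raise ValueError("occurrence threshold must be in (0, 1)")
        for name in ("confidential", "misc", "top_share"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} threshold must be in [0, 1]")
        lo, hi = self.percentile_band
        if not 0 <= lo < hi <= 100:
            raise ValueError("percentile_band must satisfy 0 <= lo < hi <= 100")
        if self.exposure_floor <= 0:
            raise ValueError("exposure_floor must be > 0")


@dataclass
class Policies:
    """Method switches; defaults are the reference configuration."""

    rank_denominator: str = "n_minus_1"  # or "n"
    share_weighting: str = "revenue"     # or "weight"
    pooling: str = "monthly"             # or "annual"
    tract_weighting: str = "unweighted"  # or "population"

    def validate(self) -> None:
        if self.rank_denominator not in ("n_minus_1", "n"):
            raise ValueError("rank_denominator must be 'n_minus_1' or 'n'")
        if self.share_weighting not in ("revenue", "weight"):
            raise ValueError("share_weighting must be 'revenue' or 'weight'")
        if self.pooling not in ("monthly", "annual"):
            raise ValueError("pooling must be 'monthly' or 'annual'")
        if self.tract_weighting not in ("unweighted", "population"):
            raise ValueError("tract_weighting must be 'unweighted' or 'population'")


@dataclass
class RunConfig:
    """Master configuration of an end-to-end run."""

    output_dir: Path = Path("results/run")
    input_dir: Path | None = None          # None: generate synthetic inputs
    seed: int = 0
    models: tuple[str, ...] = DEFAULT_MODELS
    thresholds: Thresholds = field(default_factory=Thresholds)
    policies: Policies = field(default_factory=Policies)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    species_aliases: dict[str, str] = field(default_factory=dict)
    group_splits: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        self.thresholds.validate()
        self.policies.validate()
        self.synthetic.validate()
        self.scenario.validate(self.synthetic)
        if len(self.models) < 1:
            raise ValueError("at least one climate model identifier is required")


_KNOWN_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=True)


def _build(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        typ = fields[name].type
        if name == "grid" and isinstance(value, dict):
            value = GridSpec(**value)
        elif name == "thresholds" and isinstance(value, dict):
            value = _build(Thresholds, value)
        elif name == "policies" and isinstance(value, dict):
            value = _build(Policies, value)
        elif name == "synthetic" and isinstance(value, dict):
            value = _build(SyntheticConfig, value)
        elif name == "scenario" and isinstance(value, dict):
            value = _build(ScenarioSpec, value)
        elif name in ("output_dir", "input_dir") and value is not None:
            value = Path(value)
        elif name in ("models", "confidential_communities") and value is not None:
            value = tuple(value)
        elif name in ("percentile_band", "quadrant_splits") and value is not None:
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = _build(RunConfig, data)
    cfg.validate()
    return cfg
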
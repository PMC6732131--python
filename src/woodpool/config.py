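"""Configuration objects for the synthetic landscape and the analysis pipeline.

Categorical vocabularies (stand types, dead-wood types, tree species, taxa)
are defined here and shared by every module.  A dead-wood item belongs to one
of four substrate classes:

* ``FWD`` — fine woody debris, diameter > 1 cm and < 10 cm;
* ``stump`` — standing dead wood, diameter > 10 cm, shorter than 50 cm;
* ``log`` — lying dead wood, diameter > 10 cm;
* ``snag`` — standing dead wood, diameter > 10 cm, taller than 50 cm.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

STAND_TYPES: tuple[str, ...] = ("clearcut", "young", "old", "unmanaged")
MANAGED_TYPES: tuple[str, ...] = ("clearcut", "young", "old")
DW_TYPES: tuple[str, ...] = ("FWD", "stump", "log", "snag")
TREE_SPECIES: tuple[str, ...] = ("pine", "spruce", "birch")
TAXA: tuple[str, ...] = ("fungi", "lichens", "beetles")

#: CLI measure aliases -> canonical measure names
MEASURE_ALIASES: dict[str, str] = {
    "volume": "volume_m3",
    "bark": "bark_area_m2",
    "barkfree": "barkfree_area_m2",
}

#: diameter class bounds in cm, (low, high); None means unbounded
DIAMETER_BOUNDS: dict[str, tuple[float, float | None]] = {
    "FWD": (1.0, 10.0),
    "stump": (10.0, None),
    "log": (10.0, None),
    "snag": (10.0, None),
}

#: height bound separating stumps from snags, in m
STUMP_MAX_HEIGHT_M = 0.5


class ConfigError(ValueError):
    """Raised when a configuration field violates its invariants."""


# Baseline expected densities of dead-wood items.  FWD, stumps and snags are
# expressed as items per hectare of surveyed plot area; logs as expected
# transect crossings per metre of survey line.  The managed/unmanaged
# asymmetry (stumps and slash concentrated in clearcuts and young stands,
# logs and snags in unmanaged stands) is encoded entirely in these numbers.
_BASE_INTENSITY: dict[tuple[str, str], float] = {
    ("clearcut", "FWD"): 900.0, ("clearcut", "stump"): 500.0,
    ("clearcut", "log"): 0.010, ("clearcut", "snag"): 5.0,
    ("young", "FWD"): 600.0, ("young", "stump"): 300.0,
    ("young", "log"): 0.015, ("young", "snag"): 10.0,
    ("old", "FWD"): 300.0, ("old", "stump"): 150.0,
    ("old", "log"): 0.025, ("old", "snag"): 20.0,
    ("unmanaged", "FWD"): 400.0, ("unmanaged", "stump"): 40.0,
    ("unmanaged", "log"): 0.060, ("unmanaged", "snag"): 60.0,
}

#: landscape-wide tree-species mix used for the default intensity table
_TREE_MIX: dict[str, float] = {"pine": 0.45, "spruce": 0.40, "birch": 0.15}


def default_deadwood_intensity() -> dict[tuple[str, str, str], float]:
    """Expected item density per (stand type, dead-wood type, tree species)."""
    return {
        (st, dw, sp): _BASE_INTENSITY[(st, dw)] * _TREE_MIX[sp]
        for st in STAND_TYPES
        for dw in DW_TYPES
        for sp in TREE_SPECIES
    }


@dataclass
class TruncatedLognormal:
    """Lognormal(mu, sigma) truncated to (low, high); high may be None."""

    mu: float
    sigma: float
    low: float
    high: float | None = None

    def validate(self, name: str) -> None:
        if self.sigma <= 0:
            raise ConfigError(f"{name}.sigma must be > 0, got {self.sigma}")
        if self.low < 0:
            raise ConfigError(f"{name}.low must be >= 0, got {self.low}")
        if self.high is not None and self.high <= self.low:
            raise ConfigError(f"{name}: high must exceed low")


@dataclass
class DetectionParams:
    """Per-taxon observation-process parameters.

    ``base_rate`` scales the Poisson intensity behind the per-item Bernoulli
    detection (fungi, lichens) or the mean count per m^2 of bark (beetles).
    ``cover_beta`` are the Beta shape parameters of the lichen cover fraction
    of an item's bark-free surface.  ``nb_dispersion`` is the negative
    binomial size parameter k for beetle counts (smaller = more aggregated).
    """

    base_rate: float
    cover_beta: tuple[float, float] = (1.5, 28.5)
    nb_dispersion: float = 1.0

    def validate(self, name: str) -> None:
        if self.base_rate < 0:
            raise ConfigError(f"{name}.base_rate must be >= 0")
        if min(self.cover_beta) <= 0:
            raise ConfigError(f"{name}.cover_beta shapes must be > 0")
        if self.nb_dispersion <= 0:
            raise ConfigError(f"{name}.nb_dispersion must be > 0")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic boreal-landscape generator.

    Defaults emulate a managed boreal forest landscape surveyed with a
    stratified design: four stand types, three tree species, four dead-wood
    substrate classes, and three saproxylic taxa observed with
    taxon-specific protocols (drill-sample presence for fungi, cover of
    bark-free wood for lichens, counts per sifted bark sample for beetles).
    """

    n_stands_by_type: dict[str, int] = field(
        default_factory=lambda: {"clearcut": 12, "young": 12, "old": 12, "unmanaged": 12}
    )
    #: lognormal (mu, sigma) of stand area in ha
    stand_area_params: tuple[float, float] = (2.3, 0.7)
    #: total area of each stand type in the landscape, ha (weighting basis)
    landscape_area_by_type: dict[str, float] = field(
        default_factory=lambda: {
            "clearcut": 2100.0, "young": 7100.0, "old": 8400.0, "unmanaged": 2650.0,
        }
    )
    deadwood_intensity: dict[tuple[str, str, str], float] = field(
        default_factory=default_deadwood_intensity
    )
    diameter_params: dict[str, TruncatedLognormal] = field(
        default_factory=lambda: {
            "FWD": TruncatedLognormal(1.1, 0.5, 1.0, 10.0),
            "stump": TruncatedLognormal(3.2, 0.35, 10.0, 80.0),
            "log": TruncatedLognormal(2.9, 0.40, 10.0, 100.0),
            "snag": TruncatedLognormal(3.0, 0.40, 10.0, 100.0),
        }
    )
    #: length for downed wood, height for standing wood, in m
    length_params: dict[str, TruncatedLognormal] = field(
        default_factory=lambda: {
            "FWD": TruncatedLognormal(0.0, 0.5, 0.1, 5.0),
            "stump": TruncatedLognormal(-1.2, 0.4, 0.05, 0.5),
            "log": TruncatedLognormal(1.4, 0.5, 0.5, 20.0),
            "snag": TruncatedLognormal(1.4, 0.6, 0.6, 25.0),
        }
    )
    bark_beta_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "FWD": (5.0, 1.5),
            "stump": (2.0, 2.0),
            "log": (2.0, 3.0),
            "snag": (2.0, 4.0),
        }
    )
    n_species_by_taxon: dict[str, int] = field(
        default_factory=lambda: {"fungi": 104, "lichens": 20, "beetles": 80}
    )
    #: Dirichlet concentration of substrate preference; < 1 = specialists
    affinity_concentration: float = 0.5
    detection_params: dict[str, DetectionParams] = field(
        default_factory=lambda: {
            "fungi": DetectionParams(base_rate=0.30),
            "lichens": DetectionParams(base_rate=0.40),
            "beetles": DetectionParams(base_rate=8.0),
        }
    )
    #: survey design constants per stand
    transect_length_m: float = 400.0
    snag_plot_area_ha: float = 0.2
    small_plot_area_ha: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for st, n in self.n_stands_by_type.items():
            if st not in STAND_TYPES:
                raise ConfigError(f"n_stands_by_type: unknown stand type {st!r}")
            if n < 0:
                raise ConfigError(f"n_stands_by_type[{st!r}] must be >= 0, got {n}")
        if sum(self.n_stands_by_type.values()) < 1:
            raise ConfigError("n_stands_by_type: at least one stand required")
        if self.stand_area_params[1] <= 0:
            raise ConfigError("stand_area_params: sigma must be > 0")
        for st, a in self.landscape_area_by_type.items():
            if a <= 0:
                raise ConfigError(f"landscape_area_by_type[{st!r}] must be > 0")
        for key, rate in self.deadwood_intensity.items():
            if rate < 0:
                raise ConfigError(f"deadwood_intensity[{key}] must be >= 0")
        for dw, p in self.diameter_params.items():
            p.validate(f"diameter_params[{dw!r}]")
            lo, hi = DIAMETER_BOUNDS[dw]
            if p.low < lo or (hi is not None and (p.high is None or p.high > hi)):
                raise ConfigError(
                    f"diameter_params[{dw!r}] bounds ({p.low}, {p.high}) violate "
                    f"the {dw} diameter class ({lo}, {hi})"
                )
        for dw, p in self.length_params.items():
            p.validate(f"length_params[{dw!r}]")
        if self.length_params["stump"].high is None or (
            self.length_params["stump"].high > STUMP_MAX_HEIGHT_M
        ):
            raise ConfigError("length_params['stump']: stump height must be < 0.5 m")
        if self.length_params["snag"].low < STUMP_MAX_HEIGHT_M:
            raise ConfigError("length_params['snag']: snag height must be > 0.5 m")
        for dw, (a, b) in self.bark_beta_params.items():
            if a <= 0 or b <= 0:
                raise ConfigError(f"bark_beta_params[{dw!r}] shapes must be > 0")
        for taxon, n in self.n_species_by_taxon.items():
            if taxon not in TAXA:
                raise ConfigError(f"n_species_by_taxon: unknown taxon {taxon!r}")
            if n < 1:
                raise ConfigError(f"n_species_by_taxon[{taxon!r}] must be >= 1")
        if self.affinity_concentration <= 0:
            raise ConfigError("affinity_concentration must be > 0")
        for taxon, dp in self.detection_params.items():
            dp.validate(f"detection_params[{taxon!r}]")
        if self.transect_length_m <= 0:
            raise ConfigError("transect_length_m must be > 0")
        if self.snag_plot_area_ha <= 0 or self.small_plot_area_ha <= 0:
            raise ConfigError("plot areas must be > 0")


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Either ``simulation`` is set (synthetic data are generated) or all three
    of ``stand_table``/``item_table``/``obs_tables`` point at CSV files.
    """

    simulation: SimulationConfig | None = None
    stand_table: str | None = None
    item_table: str | None = None
    obs_tables: dict[str, str] = field(default_factory=dict)
    taxa: Sequence[str] = TAXA
    max_managed_age: float = 100.0
    stand_blacklist: Sequence[str] = ()
    exclude_clearcuts: bool = False
    n_boot: int = 200
    n_subsamples: int = 20
    min_occurrences: int = 5
    n_permutations: int = 999
    seed: int = 0
    out_dir: str = "woodpool_out"

    def validate(self) -> None:
        if self.simulation is None and self.stand_table is None:
            raise ConfigError("either a simulation config or data paths are required")
        for t in self.taxa:
            if t not in TAXA:
                raise ConfigError(f"taxa: unknown taxon {t!r}")
        if self.simulation is not None:
            self.simulation.validate()


def _as_tln(obj: Mapping) -> TruncatedLognormal:
    return TruncatedLognormal(
        mu=float(obj["mu"]), sigma=float(obj["sigma"]),
        low=float(obj.get("low", 0.0)),
        high=None if obj.get("high") is None else float(obj["high"]),
    )


def simulation_config_from_dict(data: Mapping) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain (TOML/YAML) mapping.

    Nested intensity tables use string keys ``"standtype/dwtype/species"``.
    Omitted sections keep their defaults.
    """
    cfg = SimulationConfig()
    if "n_stands_by_type" in data:
        cfg.n_stands_by_type = {k: int(v) for k, v in data["n_stands_by_type"].items()}
    if "stand_area_params" in data:
        cfg.stand_area_params = tuple(float(v) for v in data["stand_area_params"])
    if "landscape_area_by_type" in data:
        cfg.landscape_area_by_type = {
            k: float(v) for k, v in data["landscape_area_by_type"].items()
        }
    if "deadwood_intensity" in data:
        intensity = dict(cfg.deadwood_intensity)
        for key, v in data["deadwood_intensity"].items():
            st, dw, sp = key.split("/")
            intensity[(st, dw, sp)] = float(v)
        cfg.deadwood_intensity = intensity
    if "diameter_params" in data:
        cfg.diameter_params.update(
            {dw: _as_tln(v) for dw, v in data["diameter_params"].items()}
        )
    if "length_params" in data:
        cfg.length_params.update(
            {dw: _as_tln(v) for dw, v in data["length_params"].items()}
        )
    if "bark_beta_params" in data:
        cfg.bark_beta_params.update(
            {dw: (float(v[0]), float(v[1])) for dw, v in data["bark_beta_params"].items()}
        )
    if "n_species_by_taxon" in data:
        cfg.n_species_by_taxon = {
            k: int(v) for k, v in data["n_species_by_taxon"].items()
        }
    if "affinity_concentration" in data:
        cfg.affinity_concentration = float(data["affinity_concentration"])
    if "detection_params" in data:
        for taxon, v in data["detection_params"].items():
            dp = DetectionParams(base_rate=float(v["base_rate"]))
            if "cover_beta" in v:
                dp.cover_beta = (float(v["cover_beta"][0]), float(v["cover_beta"][1]))
            if "nb_dispersion" in v:
                dp.nb_dispersion = float(v["nb_dispersion"])
            cfg.detection_params[taxon] = dp
    for scalar in (
        "transect_length_m", "snag_plot_area_ha", "small_plot_area_ha", "seed",
    ):
        if scalar in data:
            setattr(cfg, scalar, type(getattr(cfg, scalar))(data[scalar]))
    cfg.validate()
    return cfg


def pipeline_config_from_dict(data: Mapping) -> PipelineConfig:
    cfg = PipelineConfig()
    if "simulation" in data:
        cfg.simulation = simulation_config_from_dict(data["simulation"])
    for name in (
        "stand_table", "item_table", "max_managed_age", "exclude_clearcuts",
        "n_boot", "n_subsamples", "min_occurrences", "n_permutations",
        "seed", "out_dir",
    ):
        if name in data:
            setattr(cfg, name, data[name])
    if "obs_tables" in data:
        cfg.obs_tables = dict(data["obs_tables"])
    if "taxa" in data:
        cfg.taxa = tuple(data["taxa"])
    if "stand_blacklist" in data:
        cfg.stand_blacklist = tuple(data["stand_blacklist"])
    cfg.validate()
    return cfg


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from a TOML or YAML file (by extension)."""
    path = Path(path)
    if path.suffix in (".toml", ".tml"):
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    elif path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            data = yaml.safe_load(fh)
    else:
        raise ConfigError(f"unsupported config format: {path.suffix!r}")
    return pipeline_config_from_dict(data)
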
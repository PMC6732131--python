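"""Synthetic boreal landscape: stands, dead-wood items, species communities.

The generator produces the three table families every downstream analysis
consumes — a stand table, a dead-wood item table, and per-taxon observation
tables — with a fully known ground-truth structure, so that estimators such
as the subsample-standardized relative density can be checked against
analytic expectations.

Generative model
----------------
Stands of four types (clearcut, young, old, unmanaged) are surveyed with a
fixed design: FWD and stumps in small circular plots, snags in a larger
plot, and logs as crossings of a line transect.  Item counts are Poisson
with type-specific intensities; diameters and lengths are truncated
lognormals respecting the substrate class bounds; bark cover fractions are
Beta distributed.

Each species carries an :class:`AffinityProfile`: a Dirichlet-distributed
preference over the four substrate classes, a tree-species bias, and an
overall abundance.  The per-item observation intensity is

    lambda = base_rate * abundance * 4*preference[dw] * 3*bias[tree]

so that a uniform preference (0.25 each) and uniform bias leave the base
rate unscaled.  Fungi are recorded as presence per item with probability
1 - exp(-lambda); lichens likewise, with a Beta cover fraction of the
item's bark-free surface when present; beetle counts per sifted bark sample
are negative binomial with mean lambda * sampled area.

Separate random streams are used for stands, items, affinities, and each
taxon, all split from the master seed, so enlarging the species pool never
perturbs the item table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    DW_TYPES,
    STAND_TYPES,
    TAXA,
    TREE_SPECIES,
    ConfigError,
    SimulationConfig,
    TruncatedLognormal,
)
from .metrics import item_surface_areas

_STREAM_STANDS, _STREAM_ITEMS, _STREAM_AFFINITIES, _STREAM_TAXON0 = range(4)


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config_seed, spawn_key=(stream,)))


def sample_truncated_lognormal(
    params: TruncatedLognormal, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF sampling of a lognormal restricted to (low, high)."""
    dist = stats.lognorm(s=params.sigma, scale=np.exp(params.mu))
    lo = dist.cdf(params.low)
    hi = 1.0 if params.high is None else dist.cdf(params.high)
    u = rng.uniform(lo, hi, size=size)
    return dist.ppf(u)


def truncated_lognormal_mean(params: TruncatedLognormal) -> float:
    """Mean of the truncated lognormal by numerical integration (oracle)."""
    from scipy.integrate import quad

    dist = stats.lognorm(s=params.sigma, scale=np.exp(params.mu))
    hi = np.inf if params.high is None else params.high
    mass = dist.cdf(hi) - dist.cdf(params.low)
    num, _ = quad(lambda x: x * dist.pdf(x), params.low, hi)
    return num / mass


@dataclass
class AffinityProfile:
    """Ground-truth substrate association of one species."""

    species: str
    taxon: str
    #: preference over (FWD, stump, log, snag); non-negative, sums to 1
    preference: np.ndarray
    #: bias over (pine, spruce, birch); sums to 1
    tree_species_bias: np.ndarray
    overall_abundance: float

    def __post_init__(self) -> None:
        self.preference = np.asarray(self.preference, dtype=float)
        self.tree_species_bias = np.asarray(self.tree_species_bias, dtype=float)
        for vec, name, k in (
            (self.preference, "preference", 4),
            (self.tree_species_bias, "tree_species_bias", 3),
        ):
            if vec.shape != (k,) or (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-9:
                raise ConfigError(
                    f"{name} of {self.species} must be a length-{k} simplex vector"
                )
        if self.overall_abundance <= 0:
            raise ConfigError(f"overall_abundance of {self.species} must be > 0")


@dataclass
class ObservationTable:
    """Per-taxon species observations in long format.

    ``obs`` columns by taxon:
      fungi   — species, item_id                       (presence records)
      lichens — species, item_id, cover_cm2
      beetles — species, sample_id, item_id, count
    ``samples`` (beetles only) — sample_id, item_id, bark_area_m2 sampled.
    """

    taxon: str
    obs: pd.DataFrame
    samples: pd.DataFrame | None = None


def _survey_effort(config: SimulationConfig, dw: str) -> float:
    """Surveyed effort per stand in the unit matching the intensity table."""
    if dw in ("FWD", "stump"):
        return config.small_plot_area_ha
    if dw == "snag":
        return config.snag_plot_area_ha
    return config.transect_length_m  # log: crossings per metre


def generate_landscape(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the stand table and the dead-wood item table.

    Returns
    -------
    stands : DataFrame
        stand_id, stand_type, area_ha, age_yr and the survey-design columns
        (transect_length_m, snag_plot_area_ha, small_plot_area_ha).
    items : DataFrame
        item_id, stand_id, stand_type, tree_species, dw_type, diameter_cm,
        length_m (height for standing wood), bark_fraction.  Logs are
        transect crossings; other substrates are plot counts.
    """
    config.validate()
    rng_stands = _rng(config.seed, _STREAM_STANDS)
    rng_items = _rng(config.seed, _STREAM_ITEMS)

    age_ranges = {
        "clearcut": (3, 14), "young": (15, 59), "old": (60, 110),
        "unmanaged": (100, 250),
    }
    rows = []
    for st in STAND_TYPES:
        n = config.n_stands_by_type.get(st, 0)
        mu, sigma = config.stand_area_params
        areas = rng_stands.lognormal(mu, sigma, size=n)
        ages = rng_stands.uniform(*age_ranges[st], size=n)
        for i in range(n):
            rows.append(
                {
                    "stand_id": f"{st[:2]}{i:03d}",
                    "stand_type": st,
                    "area_ha": round(float(areas[i]), 3),
                    "age_yr": round(float(ages[i]), 1),
                    "transect_length_m": config.transect_length_m,
                    "snag_plot_area_ha": config.snag_plot_area_ha,
                    "small_plot_area_ha": config.small_plot_area_ha,
                }
            )
    stands = pd.DataFrame(rows)

    item_rows: list[pd.DataFrame] = []
    counter = 0
    for _, stand in stands.iterrows():
        st = stand["stand_type"]
        for dw in DW_TYPES:
            effort = _survey_effort(config, dw)
            for sp in TREE_SPECIES:
                lam = config.deadwood_intensity.get((st, dw, sp), 0.0) * effort
                n_items = int(rng_items.poisson(lam))
                if n_items == 0:
                    continue
                dp = config.diameter_params[dw]
                lp = config.length_params[dw]
                d = sample_truncated_lognormal(dp, n_items, rng_items)
                ln = sample_truncated_lognormal(lp, n_items, rng_items)
                # keep rounded values strictly inside the class bounds
                d = np.clip(
                    np.round(d, 2), dp.low + 0.01,
                    None if dp.high is None else dp.high - 0.01,
                )
                ln = np.clip(
                    np.round(ln, 3), lp.low + 0.001,
                    None if lp.high is None else lp.high - 0.001,
                )
                a, b = config.bark_beta_params[dw]
                bark = rng_items.beta(a, b, size=n_items)
                item_rows.append(
                    pd.DataFrame(
                        {
                            "item_id": [
                                f"i{counter + k:06d}" for k in range(n_items)
                            ],
                            "stand_id": stand["stand_id"],
                            "stand_type": st,
                            "tree_species": sp,
                            "dw_type": dw,
                            "diameter_cm": d,
                            "length_m": ln,
                            "bark_fraction": np.round(bark, 3),
                        }
                    )
                )
                counter += n_items
    if item_rows:
        items = pd.concat(item_rows, ignore_index=True)
    else:
        items = pd.DataFrame(
            columns=[
                "item_id", "stand_id", "stand_type", "tree_species", "dw_type",
                "diameter_cm", "length_m", "bark_fraction",
            ]
        )
    return stands, items


def generate_affinities(config: SimulationConfig) -> dict[str, list[AffinityProfile]]:
    """Draw species affinity profiles for every taxon from the master seed."""
    rng = _rng(config.seed, _STREAM_AFFINITIES)
    out: dict[str, list[AffinityProfile]] = {}
    for taxon in TAXA:
        n = config.n_species_by_taxon.get(taxon, 0)
        prefs = rng.dirichlet(np.full(4, config.affinity_concentration), size=n)
        biases = rng.dirichlet(np.full(3, 2.0), size=n)
        abund = rng.lognormal(-0.5, 1.0, size=n)
        out[taxon] = [
            AffinityProfile(
                species=f"{taxon[:3]}_sp{i:03d}",
                taxon=taxon,
                preference=prefs[i],
                tree_species_bias=biases[i],
                overall_abundance=float(abund[i]),
            )
            for i in range(n)
        ]
    return out


def _lambda_matrix(
    affinities: list[AffinityProfile], base_rate: float, items: pd.DataFrame
) -> np.ndarray:
    """Observation intensity per (species, item)."""
    dw_idx = items["dw_type"].map({dw: i for i, dw in enumerate(DW_TYPES)}).to_numpy()
    sp_idx = items["tree_species"].map(
        {sp: i for i, sp in enumerate(TREE_SPECIES)}
    ).to_numpy()
    pref = np.stack([a.preference for a in affinities])        # S x 4
    bias = np.stack([a.tree_species_bias for a in affinities])  # S x 3
    abund = np.array([a.overall_abundance for a in affinities])
    return (
        base_rate
        * abund[:, None]
        * 4.0 * pref[:, dw_idx]
        * 3.0 * bias[:, sp_idx]
    )


def generate_communities(
    items: pd.DataFrame,
    affinities: dict[str, list[AffinityProfile]],
    config: SimulationConfig,
) -> dict[str, ObservationTable]:
    """Generate per-taxon observation tables on the given item table."""
    for taxon in config.n_species_by_taxon:
        have = len(affinities.get(taxon, []))
        want = config.n_species_by_taxon[taxon]
        if have < want:
            raise ConfigError(
                f"affinities for {taxon!r} cover {have} species, config expects {want}"
            )
    out: dict[str, ObservationTable] = {}
    n_items = len(items)
    bark_m2, barkfree_m2 = item_surface_areas(
        items["diameter_cm"].to_numpy(),
        items["length_m"].to_numpy(),
        items["bark_fraction"].to_numpy(),
    ) if n_items else (np.array([]), np.array([]))

    for t_i, taxon in enumerate(TAXA):
        if taxon not in config.n_species_by_taxon:
            continue
        aff = affinities[taxon]
        dp = config.detection_params[taxon]
        rng = _rng(config.seed, _STREAM_TAXON0 + t_i)
        species = np.array([a.species for a in aff])
        if n_items == 0:
            lam = np.zeros((len(aff), 0))
        else:
            lam = _lambda_matrix(aff, dp.base_rate, items)

        if taxon == "fungi":
            present = rng.random(lam.shape) < -np.expm1(-lam)
            s_idx, i_idx = np.nonzero(present)
            obs = pd.DataFrame(
                {
                    "species": species[s_idx],
                    "item_id": items["item_id"].to_numpy()[i_idx],
                }
            )
            out[taxon] = ObservationTable(taxon, obs)

        elif taxon == "lichens":
            present = rng.random(lam.shape) < -np.expm1(-lam)
            s_idx, i_idx = np.nonzero(present)
            a, b = dp.cover_beta
            frac = rng.beta(a, b, size=len(s_idx))
            cover_cm2 = frac * barkfree_m2[i_idx] * 1e4
            obs = pd.DataFrame(
                {
                    "species": species[s_idx],
                    "item_id": items["item_id"].to_numpy()[i_idx],
                    "cover_cm2": np.round(cover_cm2, 3),
                }
            )
            out[taxon] = ObservationTable(taxon, obs)

        else:  # beetles: one bark sample per item carrying bark
            has_bark = bark_m2 > 1e-6
            samp_items = items.loc[has_bark].reset_index(drop=True)
            samp_area = np.minimum(0.5, bark_m2[has_bark])
            samples = pd.DataFrame(
                {
                    "sample_id": [f"b{k:06d}" for k in range(len(samp_items))],
                    "item_id": samp_items["item_id"],
                    "bark_area_m2": np.round(samp_area, 4),
                }
            )
            lam_s = lam[:, np.nonzero(has_bark)[0]] * samples["bark_area_m2"].to_numpy()
            k = dp.nb_dispersion
            # NB(mean=m, size=k): p = k/(k+m)
            counts = rng.negative_binomial(k, k / (k + np.maximum(lam_s, 1e-12)))
            counts[lam_s <= 0] = 0
            s_idx, i_idx = np.nonzero(counts)
            obs = pd.DataFrame(
                {
                    "species": species[s_idx],
                    "sample_id": samples["sample_id"].to_numpy()[i_idx],
                    "item_id": samples["item_id"].to_numpy()[i_idx],
                    "count": counts[s_idx, i_idx],
                }
            )
            out[taxon] = ObservationTable(taxon, obs, samples=samples)
    return out


def _tree_mix_by_dw(config: SimulationConfig) -> np.ndarray:
    """Expected tree-species mix among surveyed items of each dw type (4x3)."""
    w = np.zeros((len(DW_TYPES), len(TREE_SPECIES)))
    for d_i, dw in enumerate(DW_TYPES):
        effort = _survey_effort(config, dw)
        for s_i, sp in enumerate(TREE_SPECIES):
            w[d_i, s_i] = sum(
                config.n_stands_by_type.get(st, 0)
                * effort
                * config.deadwood_intensity.get((st, dw, sp), 0.0)
                for st in STAND_TYPES
            )
    totals = w.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(totals > 0, w / totals, 1.0 / len(TREE_SPECIES))
    return w


def true_relative_densities(
    affinities: dict[str, list[AffinityProfile]], config: SimulationConfig
) -> dict[str, pd.DataFrame]:
    """Analytic relative-density rows implied by the generative model.

    For every species the expected density on each substrate is computed in
    the same units the estimators use (occupancy probability for fungi,
    expected cover per bark-free area for lichens, expected individuals per
    bark area for beetles), mixing over the tree-species composition of each
    substrate, and normalized so the four substrate densities sum to one.
    """
    config.validate()
    mix = _tree_mix_by_dw(config)  # 4 x 3
    out: dict[str, pd.DataFrame] = {}
    for taxon, aff in affinities.items():
        dp = config.detection_params[taxon]
        rows = np.zeros((len(aff), len(DW_TYPES)))
        for s_i, a in enumerate(aff):
            lam = (
                dp.base_rate
                * a.overall_abundance
                * 4.0 * a.preference[:, None]
                * 3.0 * a.tree_species_bias[None, :]
            )  # 4 x 3
            if taxon == "beetles":
                dens = (mix * lam).sum(axis=1)
            else:
                dens = (mix * -np.expm1(-lam)).sum(axis=1)
            total = dens.sum()
            rows[s_i] = dens / total if total > 0 else np.nan
        out[taxon] = pd.DataFrame(
            rows, index=[a.species for a in aff], columns=list(DW_TYPES)
        )
    return out


def simulate_log_field(
    diameters_cm: np.ndarray,
    lengths_m: np.ndarray,
    field_side_m: float,
    rng: np.random.Generator,
    n_transects: int = 1,
) -> tuple[float, float]:
    """One Monte-Carlo replicate of line-intersect sampling of downed logs.

    Logs with the given dimensions are dropped uniformly at random with
    uniform orientation on a square field whose x-axis wraps (torus), and
    sampled with ``n_transects`` horizontal transects of full field width at
    random heights.  Returns ``(estimated, true)`` volume density in m^3/ha.
    The wrap removes edge effects so the classical estimator
    V = pi^2 * sum(d^2) / (8 L) is exactly unbiased here.
    """
    from .metrics import line_intersect_volume

    d = np.asarray(diameters_cm, dtype=float)
    ln = np.asarray(lengths_m, dtype=float)
    area_ha = field_side_m**2 / 1e4
    true_density = float(np.sum(np.pi * (d / 200.0) ** 2 * ln) / area_ha)

    yc = rng.uniform(0, field_side_m, size=len(d))
    theta = rng.uniform(0, np.pi, size=len(d))
    half_dy = np.abs(0.5 * ln * np.sin(theta))
    crossing_d2: list[np.ndarray] = []
    for _ in range(n_transects):
        y0 = rng.uniform(0, field_side_m)
        dy = yc - y0
        dy -= field_side_m * np.round(dy / field_side_m)  # wrap in y too
        crossed = np.abs(dy) <= half_dy
        crossing_d2.append(d[crossed])
    all_d = np.concatenate(crossing_d2) if crossing_d2 else np.array([])
    est = line_intersect_volume(all_d, n_transects * field_side_m)
    return est, true_density
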
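"""Habitat quality of dead-wood substrates via relative species densities.

A species' density on a substrate is taxon specific: for fungi the
proportion of surveyed dead-wood items occupied, for lichens the cover per
surveyed bark-free area, and for beetles individuals per sampled bark area.
Because survey effort differs enormously between substrate classes, effort
is standardized before densities are compared: using the substrate with the
smallest sample size as a base, each other substrate is repeatedly
subsampled to that size (20 random subsamples by default) and the per
species densities are averaged over subsamples.  Each species' four
densities are then normalized to sum to one ("relative densities"), giving
every species the same weight; the habitat-quality score of a substrate is
the sum of relative densities over all species with at least five
occurrences.  Differences among substrates are tested with a Kruskal-Wallis
rank-sum test and Dunn's post hoc pairwise comparisons, treating each
species as a sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import DW_TYPES
from .metrics import item_surface_areas
from .synthetic import ObservationTable


def _item_effort(items: pd.DataFrame, taxon: str) -> pd.Series:
    """Effort contributed by each surveyed item: 1 for fungi (drill sample),
    bark-free area m^2 for lichens."""
    if taxon == "fungi":
        return pd.Series(1.0, index=items["item_id"].to_numpy())
    if taxon == "lichens":
        _, barkfree = item_surface_areas(
            items["diameter_cm"].to_numpy(),
            items["length_m"].to_numpy(),
            items["bark_fraction"].to_numpy(),
        )
        return pd.Series(np.atleast_1d(barkfree), index=items["item_id"].to_numpy())
    raise ValueError(f"no per-item effort for taxon {taxon!r}")


def observation_units(
    table: ObservationTable, items: pd.DataFrame
) -> pd.DataFrame:
    """Sampling units with effort and substrate for one taxon.

    One row per unit: unit_id (item or bark sample), item_id, dw_type,
    tree_species, effort (items / m^2 bark-free / m^2 bark).
    """
    meta = items.set_index("item_id")
    if table.taxon == "beetles":
        if table.samples is None:
            raise ValueError("beetle observation table lacks its samples table")
        units = table.samples.rename(columns={"bark_area_m2": "effort"}).copy()
        units["unit_id"] = units["sample_id"]
    else:
        eff = _item_effort(items, table.taxon)
        units = pd.DataFrame(
            {"unit_id": items["item_id"], "item_id": items["item_id"],
             "effort": eff.to_numpy()}
        )
    units["dw_type"] = units["item_id"].map(meta["dw_type"]).to_numpy()
    units["tree_species"] = units["item_id"].map(meta["tree_species"]).to_numpy()
    units["stand_type"] = units["item_id"].map(meta["stand_type"]).to_numpy()
    return units.reset_index(drop=True)


def _unit_signal(table: ObservationTable) -> pd.DataFrame:
    """Per (species, unit) numerator of the density: presence, cover, count."""
    obs = table.obs
    if table.taxon == "fungi":
        return obs.assign(unit_id=obs["item_id"], signal=1.0)[
            ["species", "unit_id", "signal"]
        ]
    if table.taxon == "lichens":
        return obs.assign(unit_id=obs["item_id"], signal=obs["cover_cm2"] / 1e4)[
            ["species", "unit_id", "signal"]
        ]
    return obs.assign(unit_id=obs["sample_id"], signal=obs["count"].astype(float))[
        ["species", "unit_id", "signal"]
    ]


def species_density(
    table: ObservationTable,
    items: pd.DataFrame,
    unit_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Per-species density on a set of sampling units.

    fungi: occupied units / units; lichens: total cover / total bark-free
    area (both m^2); beetles: individuals / sampled bark area m^2.
    """
    units = observation_units(table, items)
    if unit_ids is not None:
        units = units[units["unit_id"].isin(set(unit_ids))]
    if len(units) == 0 or units["effort"].sum() <= 0:
        raise ValueError("zero surveyed effort on the requested units")
    total = units["effort"].sum() if table.taxon != "fungi" else float(len(units))
    sig = _unit_signal(table)
    sig = sig[sig["unit_id"].isin(set(units["unit_id"]))]
    dens = sig.groupby("species")["signal"].sum() / total
    return dens


def occurrence_counts(table: ObservationTable) -> pd.Series:
    """Occurrences per species: distinct dead-wood items with a record."""
    obs = table.obs
    if table.taxon == "beetles":
        obs = obs[obs["count"] > 0]
    elif table.taxon == "lichens":
        obs = obs[obs["cover_cm2"] > 0]
    return obs.groupby("species")["item_id"].nunique()


@dataclass
class RelativeDensityMatrix:
    """Species x substrate relative densities (rows sum to one)."""

    matrix: pd.DataFrame  # index species, columns DW_TYPES
    occurrences: pd.Series
    taxon: str
    n_subsamples: int
    seed: int
    base_dw_type: str
    target_effort: float


def standardize_subsamples(
    table: ObservationTable,
    items: pd.DataFrame,
    n_subsamples: int = 20,
    seed: int | np.random.Generator = 0,
    min_occurrences: int = 5,
    with_replacement: bool = False,
) -> RelativeDensityMatrix:
    """Effort-standardized relative densities per species.

    The substrate with the smallest total effort sets the target; every
    other substrate is subsampled ``n_subsamples`` times by drawing whole
    sampling units (without replacement by default) until the target effort
    is first reached or exceeded, computing densities on the realized
    effort, and averaging.  The occurrence filter (>= ``min_occurrences``
    distinct items, counted on the full data) is applied before the
    row normalization.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    units = observation_units(table, items)
    effort_by_dw = units.groupby("dw_type")["effort"].sum()
    missing = [dw for dw in DW_TYPES if effort_by_dw.get(dw, 0.0) <= 0]
    if missing:
        raise ValueError(
            f"substrates with zero surveyed effort: {', '.join(missing)}"
        )
    base_dw = effort_by_dw.idxmin()
    target = float(effort_by_dw.min())

    sig = _unit_signal(table)

    occ = occurrence_counts(table)
    keep_species = sorted(occ.index[occ >= min_occurrences])
    if not keep_species:
        raise ValueError(
            f"no species with >= {min_occurrences} occurrences"
        )

    dens = pd.DataFrame(0.0, index=keep_species, columns=list(DW_TYPES))
    for dw in DW_TYPES:
        dw_units = units[units["dw_type"] == dw].reset_index(drop=True)
        if dw == base_dw:
            draws = [dw_units]
        else:
            draws = []
            for _ in range(n_subsamples):
                order = rng.permutation(len(dw_units))
                eff = dw_units["effort"].to_numpy()[order]
                cum = np.cumsum(eff)
                stop = int(np.searchsorted(cum, target - 1e-12) + 1)
                idx = order[:stop]
                if with_replacement:
                    idx = rng.choice(len(dw_units), size=stop, replace=True)
                draws.append(dw_units.iloc[idx])
        acc = np.zeros(len(keep_species))
        for sub in draws:
            realized = (
                float(len(sub)) if table.taxon == "fungi"
                else float(sub["effort"].sum())
            )
            # multiplicity matters when drawing with replacement
            mult = sub["unit_id"].value_counts()
            s = sig[sig["unit_id"].isin(mult.index)]
            weighted = s["signal"] * s["unit_id"].map(mult).to_numpy()
            sums = weighted.groupby(s["species"]).sum()
            sums = sums.reindex(keep_species, fill_value=0.0)
            acc += sums.to_numpy() / realized
        dens[dw] = acc / len(draws)

    row_tot = dens.sum(axis=1)
    nonzero = row_tot > 0
    rel = dens.loc[nonzero].div(row_tot[nonzero], axis=0)
    return RelativeDensityMatrix(
        matrix=rel,
        occurrences=occ.reindex(rel.index),
        taxon=table.taxon,
        n_subsamples=n_subsamples,
        seed=-1 if isinstance(seed, np.random.Generator) else int(seed),
        base_dw_type=str(base_dw),
        target_effort=target,
    )


def quality_score(rdm: RelativeDensityMatrix | pd.DataFrame) -> pd.Series:
    """Summed relative density per substrate (equal weight per species)."""
    mat = rdm.matrix if isinstance(rdm, RelativeDensityMatrix) else rdm
    return mat.sum(axis=0)


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, int, float]:
    """Kruskal-Wallis H (mid-rank, tie-corrected), df, and chi-square p."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or sum(len(g) for g in groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 values in total")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return 0.0, len(groups) - 1, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), len(groups) - 1, float(p)


def dunn_posthoc(
    groups: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
    holm: bool = False,
) -> pd.DataFrame:
    """Dunn's z tests for all group pairs after a Kruskal-Wallis test.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum(t^3 - t) over tie groups; two-sided normal p values,
    unadjusted by default (``holm=True`` adds Holm-adjusted p).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    flat = np.concatenate(groups)
    n = len(flat)
    ranks = stats.rankdata(flat)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))
    ]
    _, tie_counts = np.unique(flat, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        denom = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / denom if denom > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z)) if denom > 0 else 1.0
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": z, "p": p})
    out = pd.DataFrame(rows)
    if holm:
        from .metrics import sequential_bonferroni

        out["p_holm"] = sequential_bonferroni(out["p"])["p_adjusted"]
    return out


def quality_analysis(
    table: ObservationTable,
    items: pd.DataFrame,
    n_subsamples: int = 20,
    seed: int | np.random.Generator = 0,
    min_occurrences: int = 5,
    holm: bool = False,
) -> dict:
    """Full habitat-quality workflow for one taxon.

    Returns the relative-density matrix, the per-substrate quality scores,
    the Kruskal-Wallis test, and Dunn's pairwise table, with species as
    replicates throughout.
    """
    rdm = standardize_subsamples(
        table, items, n_subsamples=n_subsamples, seed=seed,
        min_occurrences=min_occurrences,
    )
    cols = [rdm.matrix[dw].to_numpy() for dw in DW_TYPES]
    h, df, p = kruskal_wallis(cols)
    dunn = dunn_posthoc(cols, labels=list(DW_TYPES), holm=holm)
    return {
        "relative_densities": rdm,
        "quality": quality_score(rdm),
        "kruskal": {"H": h, "df": df, "p": p},
        "dunn": dunn,
    }
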
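"""End-to-end orchestration of the four analysis steps.

1. Dead-wood amounts: per-stand estimates for the three habitat measures,
   landscape-weighted means, and weighted t tests of managed vs unmanaged
   amounts with sequential Bonferroni correction.
2. Species richness: sample-based rarefaction per taxon and substrate,
   rescaled to habitat amount, compared against the unmanaged amount of
   each substrate (rank concordance).
3. Habitat quality: subsample-standardized relative densities, per
   substrate quality scores, Kruskal-Wallis and Dunn tests.
4. Composition: Morisita-Horn similarities between substrates and pairwise
   PermANOVA on stratified community profiles.

All randomness derives from the single seed in the pipeline config, split
into independent streams per step and taxon, so a rerun with the same
config reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .composition import community_vectors, distance_matrix, pairwise_permanova, permanova, substrate_similarity
from .config import DW_TYPES, MANAGED_TYPES, PipelineConfig
from .io import read_all, write_tables
from .metrics import (
    MEASURES,
    TAXON_MEASURE,
    compare_managed_unmanaged,
    landscape_weighted_mean,
    stand_amounts,
)
from .quality import observation_units, quality_analysis
from .rarefaction import (
    incidence_from_observations,
    rarefaction_band,
    rescale_to_amount,
    richness_vs_habitat,
)
from .synthetic import generate_affinities, generate_communities, generate_landscape

log = logging.getLogger("woodpool")

_STEP_SEEDS = {"rarefaction": 101, "quality": 202, "composition": 303}


def _derived_landscape_areas(stands: pd.DataFrame) -> dict[str, float]:
    """Landscape-type areas estimated from the sampled stands themselves
    (fallback when no independent landscape inventory is supplied)."""
    return stands.groupby("stand_type")["area_ha"].sum().to_dict()


def _filter_stands(stands: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    keep = ~stands["stand_id"].isin(config.stand_blacklist)
    keep &= ~(
        stands["stand_type"].isin(MANAGED_TYPES)
        & (stands["age_yr"] > config.max_managed_age)
    )
    return stands.loc[keep].reset_index(drop=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all four steps and write CSV outputs plus a JSON run report.

    Steps are independent: a failure in one is recorded in the report and
    the remaining steps still run.
    """
    config.validate()
    t_start = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        sim = config.simulation
        stands, items = generate_landscape(sim)
        affinities = generate_affinities(sim)
        obs_tables = generate_communities(items, affinities, sim)
        landscape_areas = sim.landscape_area_by_type
        write_tables(out_dir / "data", stands, items, obs_tables)
        log.info("simulated %d stands, %d items", len(stands), len(items))
    else:
        stands, items, obs_tables = read_all(
            config.stand_table, config.item_table,
            {t: p for t, p in config.obs_tables.items() if not t.endswith("_samples")},
            {t[:-8]: p for t, p in config.obs_tables.items() if t.endswith("_samples")},
        )
        landscape_areas = _derived_landscape_areas(stands)

    stands_f = _filter_stands(stands, config)
    items_f = items[items["stand_id"].isin(stands_f["stand_id"])].reset_index(drop=True)
    if config.exclude_clearcuts:
        species_stands = stands_f[stands_f["stand_type"] != "clearcut"]
    else:
        species_stands = stands_f
    species_items = items[
        items["stand_id"].isin(species_stands["stand_id"])
    ].reset_index(drop=True)

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "exclude_clearcuts": config.exclude_clearcuts,
        "n_stands": int(len(stands_f)),
        "n_items": int(len(items_f)),
        "steps": {},
    }

    # --- step 1: amounts and weighted tests -------------------------------
    unmanaged_amounts: dict[str, dict[str, float]] = {}
    try:
        t0 = time.time()
        all_est, all_means = [], []
        for measure in MEASURES:
            est = stand_amounts(items_f, stands_f, measure)
            est_sp = stand_amounts(items_f, stands_f, measure, by_tree_species=True)
            means = landscape_weighted_mean(
                pd.concat([est, est_sp], ignore_index=True), stands_f, landscape_areas
            )
            all_est.append(pd.concat([est, est_sp], ignore_index=True))
            all_means.append(means)
            um = means[
                (means["mclass"] == "unmanaged") & (means["tree_species"] == "all")
            ]
            unmanaged_amounts[measure] = dict(zip(um["dw_type"], um["mean"]))
        pd.concat(all_est, ignore_index=True).to_csv(
            out_dir / "stand_amounts.csv", index=False
        )
        pd.concat(all_means, ignore_index=True).to_csv(
            out_dir / "weighted_means.csv", index=False
        )
        tests = pd.concat(
            [
                compare_managed_unmanaged(
                    items_f, stands_f, landscape_areas, measure=m,
                    max_managed_age=config.max_managed_age,
                    stand_blacklist=config.stand_blacklist,
                )
                for m in MEASURES
            ],
            ignore_index=True,
        )
        tests.to_csv(out_dir / "weighted_t_tests.csv", index=False)
        report["steps"]["amounts"] = {
            "status": "ok", "seconds": round(time.time() - t0, 2),
            "unmanaged_amounts": unmanaged_amounts,
        }
        log.info("step 1 (amounts) done in %.1fs", time.time() - t0)
    except Exception as exc:  # noqa: BLE001 - step isolation is the contract
        log.exception("step 1 (amounts) failed")
        report["steps"]["amounts"] = {"status": "failed", "error": str(exc)}

    # --- step 2: rarefaction ---------------------------------------------
    try:
        t0 = time.time()
        rare_rows, concord_rows = [], []
        for t_i, taxon in enumerate(config.taxa):
            table = obs_tables[taxon]
            units = observation_units(table, species_items)
            measure = TAXON_MEASURE[taxon]
            curves = {}
            for dw in DW_TYPES:
                dw_units = units[units["dw_type"] == dw]
                if len(dw_units) < 2:
                    continue
                obs = table.obs
                if taxon == "beetles":
                    obs = obs.rename(columns={"item_id": "orig_item"}).rename(
                        columns={"sample_id": "item_id"}
                    )
                inc = incidence_from_observations(
                    obs, dw_units["unit_id"],
                    unit_sizes=dw_units["effort"].to_numpy(),
                )
                seed = np.random.SeedSequence(
                    config.seed,
                    spawn_key=(
                        _STEP_SEEDS["rarefaction"], t_i, DW_TYPES.index(dw),
                    ),
                )
                curve = rarefaction_band(
                    inc, n_boot=config.n_boot,
                    seed=np.random.default_rng(seed),
                )
                if taxon != "fungi":
                    curve = rescale_to_amount(curve, inc.mean_unit_size)
                curves[dw] = curve
                df = curve.to_frame()
                df.insert(0, "taxon", taxon)
                df.insert(1, "dw_type", dw)
                rare_rows.append(df)
            um = unmanaged_amounts.get(measure, {})
            if um and curves:
                concord = richness_vs_habitat(
                    curves, {dw: um.get(dw, np.nan) for dw in curves}
                )
                concord.insert(0, "taxon", taxon)
                concord["kendall_tau"] = concord.attrs["kendall_tau"]
                concord["standard_amount"] = concord.attrs["standard_amount"]
                concord_rows.append(concord)
        pd.concat(rare_rows, ignore_index=True).to_csv(
            out_dir / "rarefaction_curves.csv", index=False
        )
        if concord_rows:
            pd.concat(concord_rows, ignore_index=True).to_csv(
                out_dir / "richness_vs_habitat.csv", index=False
            )
        report["steps"]["rarefaction"] = {
            "status": "ok", "seconds": round(time.time() - t0, 2),
            "kendall_tau": {
                str(df["taxon"].iloc[0]): float(df["kendall_tau"].iloc[0])
                for df in concord_rows
            },
        }
        log.info("step 2 (rarefaction) done in %.1fs", time.time() - t0)
    except Exception as exc:  # noqa: BLE001
        log.exception("step 2 (rarefaction) failed")
        report["steps"]["rarefaction"] = {"status": "failed", "error": str(exc)}

    # --- step 3: habitat quality -----------------------------------------
    try:
        t0 = time.time()
        qual_rows, test_rows, dunn_rows = [], [], []
        for t_i, taxon in enumerate(config.taxa):
            res = quality_analysis(
                obs_tables[taxon], species_items,
                n_subsamples=config.n_subsamples,
                seed=np.random.default_rng(
                    np.random.SeedSequence(
                        config.seed, spawn_key=(_STEP_SEEDS["quality"], t_i)
                    )
                ),
                min_occurrences=config.min_occurrences,
            )
            rdm = res["relative_densities"]
            mat = rdm.matrix.copy()
            mat.insert(0, "taxon", taxon)
            mat.to_csv(out_dir / f"relative_densities_{taxon}.csv")
            qual_rows.append(
                pd.DataFrame(
                    {"taxon": taxon, "dw_type": res["quality"].index,
                     "quality": res["quality"].to_numpy(),
                     "n_species": len(rdm.matrix)}
                )
            )
            test_rows.append({"taxon": taxon, **res["kruskal"]})
            dunn = res["dunn"].copy()
            dunn.insert(0, "taxon", taxon)
            dunn_rows.append(dunn)
        pd.concat(qual_rows, ignore_index=True).to_csv(
            out_dir / "habitat_quality.csv", index=False
        )
        pd.DataFrame(test_rows).to_csv(out_dir / "kruskal_wallis.csv", index=False)
        pd.concat(dunn_rows, ignore_index=True).to_csv(
            out_dir / "dunn_tests.csv", index=False
        )
        report["steps"]["quality"] = {
            "status": "ok", "seconds": round(time.time() - t0, 2),
            "kruskal": {r["taxon"]: r["p"] for r in test_rows},
        }
        log.info("step 3 (quality) done in %.1fs", time.time() - t0)
    except Exception as exc:  # noqa: BLE001
        log.exception("step 3 (quality) failed")
        report["steps"]["quality"] = {"status": "failed", "error": str(exc)}

    # --- step 4: composition ---------------------------------------------
    try:
        t0 = time.time()
        sim_rows, perm_rows = [], []
        for t_i, taxon in enumerate(config.taxa):
            table = obs_tables[taxon]
            sim_mat = substrate_similarity(table, species_items)
            sm = sim_mat.copy()
            sm.insert(0, "taxon", taxon)
            sim_rows.append(sm)
            mat, dw_labels = community_vectors(table, species_items)
            dist = distance_matrix([mat[c].to_numpy() for c in mat.columns])
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    config.seed, spawn_key=(_STEP_SEEDS["composition"], t_i)
                )
            )
            overall = permanova(
                dist, dw_labels, n_perm=config.n_permutations, seed=rng
            )
            pw = pairwise_permanova(
                dist, dw_labels, n_perm=config.n_permutations, seed=rng
            )
            pw.insert(0, "taxon", taxon)
            pw["overall_p"] = overall.p
            perm_rows.append(pw)
        pd.concat(sim_rows).to_csv(out_dir / "morisita_horn.csv")
        pd.concat(perm_rows, ignore_index=True).to_csv(
            out_dir / "permanova.csv", index=False
        )
        report["steps"]["composition"] = {
            "status": "ok", "seconds": round(time.time() - t0, 2),
            "overall_p": {
                str(df["taxon"].iloc[0]): float(df["overall_p"].iloc[0])
                for df in perm_rows
            },
        }
        log.info("step 4 (composition) done in %.1fs", time.time() - t0)
    except Exception as exc:  # noqa: BLE001
        log.exception("step 4 (composition) failed")
        report["steps"]["composition"] = {"status": "failed", "error": str(exc)}

    report["seconds_total"] = round(time.time() - t_start, 2)
    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
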
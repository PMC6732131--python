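"""Dead-wood amount estimation and landscape-weighted comparisons.

Per-item geometry uses a cylinder model from the single recorded diameter
(no taper model is identifiable from one measurement).  Stand-level amounts
per hectare come from plot counts for FWD, stumps and snags, and from
line-intersect sampling for logs.  Landscape-scale means weight each
sampled stand by the area its stand type covers in the landscape divided by
the number of sampled stands of that type; managed and unmanaged stands are
compared with a Welch-type t test on weighted moments, with Holm's
sequential Bonferroni correction across the per-tree-species tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DW_TYPES, MANAGED_TYPES, TREE_SPECIES

#: measure name -> column label used in estimate tables
MEASURES = ("volume_m3", "bark_area_m2", "barkfree_area_m2")

#: default habitat measure per taxon
TAXON_MEASURE = {
    "fungi": "volume_m3",
    "beetles": "bark_area_m2",
    "lichens": "barkfree_area_m2",
}


def item_volume(diameter_cm, length_m):
    """Cylinder volume in m^3: pi * (d/200)^2 * L (d in cm, L in m)."""
    d = np.asarray(diameter_cm, dtype=float)
    ln = np.asarray(length_m, dtype=float)
    if (d <= 0).any() or (ln <= 0).any():
        raise ValueError("diameter and length must be positive")
    out = np.pi * (d / 200.0) ** 2 * ln
    return float(out) if out.ndim == 0 else out


def item_surface_areas(diameter_cm, length_m, bark_fraction):
    """Lateral surface split into (bark, bark-free) areas in m^2.

    Total lateral area is pi * (d/100) * L; the bark fraction partitions it.
    """
    d = np.asarray(diameter_cm, dtype=float)
    ln = np.asarray(length_m, dtype=float)
    bark = np.asarray(bark_fraction, dtype=float)
    if (d <= 0).any() or (ln <= 0).any():
        raise ValueError("diameter and length must be positive")
    if (bark < 0).any() or (bark > 1).any():
        raise ValueError("bark_fraction must lie in [0, 1]")
    lateral = np.pi * (d / 100.0) * ln
    bark_area = lateral * bark
    barkfree = lateral - bark_area
    if lateral.ndim == 0:
        return float(bark_area), float(barkfree)
    return bark_area, barkfree


def item_measure(items: pd.DataFrame, measure: str) -> np.ndarray:
    """Per-item value of one amount measure for a table of items."""
    if measure == "volume_m3":
        return item_volume(items["diameter_cm"], items["length_m"])
    bark, barkfree = item_surface_areas(
        items["diameter_cm"], items["length_m"], items["bark_fraction"]
    )
    if measure == "bark_area_m2":
        return np.atleast_1d(bark)
    if measure == "barkfree_area_m2":
        return np.atleast_1d(barkfree)
    raise ValueError(f"unknown measure {measure!r}")


def plot_density_estimate(
    values: Iterable[float], surveyed_area_ha: float
) -> float:
    """Amount per hectare: sum of per-item values over the surveyed area."""
    if surveyed_area_ha <= 0:
        raise ValueError("surveyed area must be > 0")
    return float(np.sum(np.fromiter(values, dtype=float)) / surveyed_area_ha)


def line_intersect_volume(
    diameters_cm: Iterable[float], transect_length_m: float
) -> float:
    """Volume density (m^3/ha) from transect-crossing diameters.

    Van Wagner's estimator V = pi^2 * sum(d^2) / (8 L); with d in cm and L
    in m the unit conversions cancel and the result is m^3 per ha.
    """
    if transect_length_m <= 0:
        raise ValueError("transect length must be > 0")
    d = np.asarray(list(diameters_cm), dtype=float)
    if d.size == 0:
        return 0.0
    return float(np.pi**2 * np.sum(d**2) / (8.0 * transect_length_m))


def line_intersect_density(
    values: Iterable[float],
    lengths_m: Iterable[float],
    transect_length_m: float,
) -> float:
    """Per-hectare density of any per-item attribute from transect crossings.

    An item of length l crosses a random transect with probability
    proportional to l, so each crossed item is expanded by pi/(2 l L); the
    1e4 converts per-m^2 to per-ha.  With the cylinder volume as attribute
    this reduces exactly to :func:`line_intersect_volume`.
    """
    if transect_length_m <= 0:
        raise ValueError("transect length must be > 0")
    v = np.asarray(list(values), dtype=float)
    ln = np.asarray(list(lengths_m), dtype=float)
    if v.size == 0:
        return 0.0
    if (ln <= 0).any():
        raise ValueError("item lengths must be > 0")
    return float(1e4 * np.pi * np.sum(v / ln) / (2.0 * transect_length_m))


def stand_amounts(
    items: pd.DataFrame,
    stands: pd.DataFrame,
    measure: str,
    by_tree_species: bool = False,
) -> pd.DataFrame:
    """Per-stand amount per hectare of each dead-wood type.

    Logs are estimated with the line-intersect expansion, all other
    substrates by dividing the plot totals by the surveyed plot area.
    Returns one row per stand x dw_type (x tree species when requested),
    including explicit zeros for surveyed combinations with no items.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    strata = list(TREE_SPECIES) if by_tree_species else ["all"]
    stand_meta = stands.set_index("stand_id")
    rows = []
    grouped = dict(tuple(items.groupby("stand_id"))) if len(items) else {}
    for stand_id, meta in stand_meta.iterrows():
        sub_all = grouped.get(stand_id)
        for dw in DW_TYPES:
            for sp in strata:
                if sub_all is None:
                    sub = None
                else:
                    mask = sub_all["dw_type"] == dw
                    if sp != "all":
                        mask &= sub_all["tree_species"] == sp
                    sub = sub_all.loc[mask]
                if sub is None or len(sub) == 0:
                    amount = 0.0
                    effort = (
                        meta["transect_length_m"] if dw == "log"
                        else meta["snag_plot_area_ha"] if dw == "snag"
                        else meta["small_plot_area_ha"]
                    )
                else:
                    vals = item_measure(sub, measure)
                    if dw == "log":
                        effort = meta["transect_length_m"]
                        if measure == "volume_m3":
                            amount = line_intersect_volume(
                                sub["diameter_cm"], effort
                            )
                        else:
                            amount = line_intersect_density(
                                vals, sub["length_m"], effort
                            )
                    elif dw == "snag":
                        effort = meta["snag_plot_area_ha"]
                        amount = plot_density_estimate(vals, effort)
                    else:
                        effort = meta["small_plot_area_ha"]
                        amount = plot_density_estimate(vals, effort)
                rows.append(
                    {
                        "stand_id": stand_id,
                        "stand_type": meta["stand_type"],
                        "dw_type": dw,
                        "tree_species": sp,
                        "measure": measure,
                        "amount_per_ha": amount,
                        "effort": effort,
                    }
                )
    return pd.DataFrame(rows)


def landscape_weights(
    stands: pd.DataFrame, landscape_area_by_type: dict[str, float]
) -> pd.Series:
    """Per-stand weight (A_k / sum A) / n_k indexed by stand_id.

    A_k is the landscape area covered by stand type k and n_k the number of
    sampled stands of that type, so each sampled stand represents an equal
    share of its type's landscape area.
    """
    counts = stands["stand_type"].value_counts()
    total_area = sum(
        landscape_area_by_type[t] for t in counts.index
    )
    w = {}
    for _, row in stands.iterrows():
        k = row["stand_type"]
        if k not in landscape_area_by_type or landscape_area_by_type[k] <= 0:
            raise ValueError(f"stand type {k!r} has no landscape area")
        w[row["stand_id"]] = landscape_area_by_type[k] / total_area / counts[k]
    return pd.Series(w, name="weight")


def weighted_mean_se(values, weights) -> tuple[float, float]:
    """Weighted mean and its SE with weights renormalized to sum to one.

    SE = sqrt(sum w_s^2 (x_s - xbar_w)^2), the standard error of a weighted
    sum of independent observations with plug-in residuals.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be > 0")
    w = w / w.sum()
    mean = float(np.sum(w * x))
    se = float(np.sqrt(np.sum(w**2 * (x - mean) ** 2)))
    return mean, se


def landscape_weighted_mean(
    estimates: pd.DataFrame,
    stands: pd.DataFrame,
    landscape_area_by_type: dict[str, float],
    management_classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Landscape-scale mean (+- SE) per management class, dw type and stratum.

    ``management_classes`` maps stand type -> class label; by default the
    three managed types collapse to "managed" and unmanaged stays separate.
    Weights are renormalized within each class.
    """
    if management_classes is None:
        management_classes = {t: "managed" for t in MANAGED_TYPES}
        management_classes["unmanaged"] = "unmanaged"
    w = landscape_weights(stands, landscape_area_by_type)
    est = estimates.copy()
    est["weight"] = est["stand_id"].map(w)
    est["mclass"] = est["stand_type"].map(management_classes)
    rows = []
    for (mclass, dw, sp, measure), grp in est.groupby(
        ["mclass", "dw_type", "tree_species", "measure"], sort=False
    ):
        mean, se = weighted_mean_se(grp["amount_per_ha"], grp["weight"])
        rows.append(
            {
                "mclass": mclass, "dw_type": dw, "tree_species": sp,
                "measure": measure, "mean": mean, "se": se, "n_stands": len(grp),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class WeightedTestResult:
    """Welch-type two-sample t test on weighted moments."""

    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    se_a: float
    se_b: float
    degenerate: bool = False


def weighted_t_test(
    values_a, weights_a, values_b, weights_b
) -> WeightedTestResult:
    """Two-sided weighted Welch t test.

    Weights are rescaled within each group to sum to the group size
    (effective n equals the count of stands), weighted means and weighted
    sample variances (denominator sum(w) - 1) are formed, and the Welch
    statistic with Satterthwaite degrees of freedom is evaluated on them.
    With unit weights this reduces exactly to the classical Welch test.
    """
    res = []
    for x, w in ((values_a, weights_a), (values_b, weights_b)):
        x = np.asarray(x, dtype=float)
        w = np.asarray(w, dtype=float)
        if (w <= 0).any():
            raise ValueError("weights must be > 0")
        n = len(x)
        if n < 2 or np.unique(x).size < 2:
            return WeightedTestResult(
                np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                degenerate=True,
            )
        w = w * n / w.sum()
        mean = np.sum(w * x) / n
        var = np.sum(w * (x - mean) ** 2) / (n - 1)
        res.append((n, mean, var))
    (na, ma, va), (nb, mb, vb) = res
    sa2, sb2 = va / na, vb / nb
    t = (ma - mb) / np.sqrt(sa2 + sb2)
    df = (sa2 + sb2) ** 2 / (sa2**2 / (na - 1) + sb2**2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WeightedTestResult(
        float(t), float(df), float(p), float(ma), float(mb),
        float(np.sqrt(sa2)), float(np.sqrt(sb2)),
    )


def sequential_bonferroni(
    p_values: Sequence[float], alpha: float = 0.05
) -> pd.DataFrame:
    """Holm step-down sequential Bonferroni.

    Sorted ascending, p_(i) is compared to alpha/(m - i + 1); testing stops
    at the first failure.  Returns the rejections and per-test thresholds in
    the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    order = np.argsort(p, kind="stable")
    thresh = np.empty(m)
    thresh[order] = alpha / (m - np.arange(m))
    return pd.DataFrame(
        {"p": p, "threshold": thresh, "p_adjusted": p_adj, "reject": reject}
    )


def compare_managed_unmanaged(
    items: pd.DataFrame,
    stands: pd.DataFrame,
    landscape_area_by_type: dict[str, float],
    measure: str = "volume_m3",
    max_managed_age: float = 100.0,
    stand_blacklist: Sequence[str] = (),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Weighted t tests of managed vs unmanaged amounts per dead-wood type.

    Managed stands older than ``max_managed_age`` years and blacklisted
    stands are removed before testing.  Tests run for each dw type overall
    and separately per tree species; the twelve per-species tests receive a
    Holm sequential-Bonferroni correction (the four overall tests are
    reported unadjusted, each dw type addressing a distinct hypothesis).
    """
    keep = ~stands["stand_id"].isin(stand_blacklist)
    keep &= ~(
        stands["stand_type"].isin(MANAGED_TYPES)
        & (stands["age_yr"] > max_managed_age)
    )
    stands = stands.loc[keep].reset_index(drop=True)
    items = items[items["stand_id"].isin(stands["stand_id"])].reset_index(drop=True)
    w = landscape_weights(stands, landscape_area_by_type)
    managed_ids = stands.loc[stands["stand_type"].isin(MANAGED_TYPES), "stand_id"]
    unmanaged_ids = stands.loc[stands["stand_type"] == "unmanaged", "stand_id"]

    rows = []
    for by_sp in (False, True):
        est = stand_amounts(items, stands, measure, by_tree_species=by_sp)
        for (dw, sp), grp in est.groupby(["dw_type", "tree_species"], sort=False):
            grp = grp.set_index("stand_id")
            a = grp.loc[grp.index.isin(managed_ids)]
            b = grp.loc[grp.index.isin(unmanaged_ids)]
            r = weighted_t_test(
                a["amount_per_ha"], w[a.index], b["amount_per_ha"], w[b.index]
            )
            rows.append(
                {
                    "dw_type": dw, "tree_species": sp, "measure": measure,
                    "t": r.t, "df": r.df, "p": r.p,
                    "mean_managed": r.mean_a, "mean_unmanaged": r.mean_b,
                    "se_managed": r.se_a, "se_unmanaged": r.se_b,
                    "degenerate": r.degenerate,
                }
            )
    out = pd.DataFrame(rows)
    species_mask = (out["tree_species"] != "all") & out["p"].notna()
    out["reject"] = out["p"] < alpha
    if species_mask.any():
        holm = sequential_bonferroni(out.loc[species_mask, "p"], alpha)
        out.loc[species_mask, "reject"] = holm["reject"].to_numpy()
        out.loc[species_mask, "p_adjusted"] = holm["p_adjusted"].to_numpy()
    return out
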
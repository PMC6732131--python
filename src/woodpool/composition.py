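"""Community composition: Morisita-Horn similarity and PermANOVA.

Community vectors are per-species density profiles (taxon-specific density
units) computed per substrate, optionally stratified by stand type and tree
species to provide replication.  The Morisita-Horn index quantifies
abundance-weighted overlap and is invariant to multiplying either community
by a constant; PermANOVA compares groups of communities directly on the
1 - similarity distance matrix with a permutation null, falling back to
exhaustive enumeration of relabelings when that is cheaper than sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

from .config import DW_TYPES
from .quality import ObservationTable, observation_units, species_density


def morisita_horn(x, y) -> float:
    """Morisita-Horn similarity C in [0, 1].

    C = 2 sum(x_i y_i) / ((sum x_i^2 / X^2 + sum y_i^2 / Y^2) X Y) with
    X = sum x, Y = sum y.  Equals 1 iff the two relative-abundance profiles
    coincide, 0 iff supports are disjoint.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("community vectors must share the species index")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("community vectors must be non-negative")
    bx, by = x.sum(), y.sum()
    if bx == 0 or by == 0:
        raise ValueError("all-zero community vector")
    num = 2.0 * np.dot(x, y)
    den = (np.dot(x, x) / bx**2 + np.dot(y, y) / by**2) * bx * by
    return float(num / den)


def distance_matrix(communities: list[np.ndarray]) -> np.ndarray:
    """Symmetric 1 - Morisita-Horn dissimilarity matrix."""
    k = len(communities)
    if k < 2:
        raise ValueError("need >= 2 communities")
    d = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        d[i, j] = d[j, i] = 1.0 - morisita_horn(communities[i], communities[j])
    return d


@dataclass
class PermanovaResult:
    f: float
    p: float
    n_permutations: int
    exhaustive: bool
    seed: int
    group_sizes: dict[str, int]


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from squared distances and integer group codes.

    SS_total = sum_{i<j} d2_ij / N; SS_within = sum_g (within-pair d2)/n_g.
    """
    n = len(codes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        ng = int(mask.sum())
        if ng < 2:
            continue
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * ng)
    ss_between = ss_total - ss_within
    df_b = n_groups - 1
    df_w = n - n_groups
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / df_b) / (ss_within / df_w)


def permanova(
    dist: np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> PermanovaResult:
    """One-way PermANOVA on a distance matrix.

    The p value is (#{F* >= F} + 1) / (n_perm + 1) over random label
    permutations; when the number of distinct relabelings is at most
    ``n_perm`` they are enumerated instead and the p value is exact
    (#{F* >= F} / #relabelings, the identity included).
    """
    dist = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    sizes = np.bincount(codes)
    d2 = dist**2
    f_obs = _pseudo_f(d2, codes, len(uniq))

    n_distinct = factorial(len(codes))
    for s in sizes:
        n_distinct //= factorial(int(s))
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if n_distinct <= n_perm:
        from sympy.utilities.iterables import multiset_permutations

        count = 0
        total = 0
        for perm in multiset_permutations(list(codes)):
            total += 1
            if _pseudo_f(d2, np.asarray(perm), len(uniq)) >= f_obs - 1e-12:
                count += 1
        p = count / total
        return PermanovaResult(
            float(f_obs), float(p), total, True,
            -1 if isinstance(seed, np.random.Generator) else int(seed),
            {str(u): int(s) for u, s in zip(uniq, sizes)},
        )
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, len(uniq)) >= f_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(
        float(f_obs), float(p), n_perm, False,
        -1 if isinstance(seed, np.random.Generator) else int(seed),
        {str(u): int(s) for u, s in zip(uniq, sizes)},
    )


def pairwise_permanova(
    dist: np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    holm: bool = False,
) -> pd.DataFrame:
    """PermANOVA restricted to each pair of groups; unadjusted p by default."""
    dist = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rows = []
    for a, b in combinations(uniq, 2):
        mask = (labels == a) | (labels == b)
        idx = np.nonzero(mask)[0]
        res = permanova(
            dist[np.ix_(idx, idx)], labels[idx], n_perm=n_perm, seed=rng
        )
        rows.append(
            {"group_a": a, "group_b": b, "pseudo_F": res.f, "p": res.p,
             "n_permutations": res.n_permutations, "exhaustive": res.exhaustive}
        )
    out = pd.DataFrame(rows)
    if holm:
        from .metrics import sequential_bonferroni

        out["p_holm"] = sequential_bonferroni(out["p"])["p_adjusted"]
    return out


def community_vectors(
    table: ObservationTable,
    items: pd.DataFrame,
    stratify: tuple[str, ...] = ("stand_type", "tree_species"),
) -> tuple[pd.DataFrame, list[str]]:
    """Per-cell species density profiles for composition analysis.

    Cells are dw_type x the stratification columns; cells with zero effort
    or no observed species are dropped.  Returns a species-by-cell density
    DataFrame and the dw_type label of each cell (column order).
    """
    units = observation_units(table, items)
    group_cols = ["dw_type", *stratify]
    vecs: dict[str, pd.Series] = {}
    dw_labels: list[str] = []
    for key, grp in units.groupby(group_cols, sort=True):
        if grp["effort"].sum() <= 0:
            continue
        dens = species_density(table, items, unit_ids=grp["unit_id"])
        if dens.sum() <= 0:
            continue
        label = "|".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        vecs[label] = dens
        dw_labels.append(str(key[0] if isinstance(key, tuple) else key))
    if len(vecs) < 2:
        raise ValueError("fewer than two non-empty community cells")
    mat = pd.DataFrame(vecs).fillna(0.0)
    return mat, dw_labels


def substrate_similarity(
    table: ObservationTable, items: pd.DataFrame
) -> pd.DataFrame:
    """Morisita-Horn similarity between pooled per-substrate communities."""
    mat, dw_labels = community_vectors(table, items, stratify=())
    present = [dw for dw in DW_TYPES if dw in dw_labels]
    out = pd.DataFrame(np.eye(len(present)), index=present, columns=present)
    for a, b in combinations(present, 2):
        c = morisita_horn(mat[a].to_numpy(), mat[b].to_numpy())
        out.loc[a, b] = out.loc[b, a] = c
    return out
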
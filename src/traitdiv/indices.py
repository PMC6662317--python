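"""Per-community diversity indices.

Four values per community:

* **FD** (Petchey–Gaston functional diversity): total branch length of the
  UPGMA dendrogram clustering the community's species by functional
  dissimilarity, excluding any segment above the root.  Presence-based.
* **FEve** (functional evenness): regularity of abundance along the minimum
  spanning tree of the community in trait space; in (0, 1], undefined for
  fewer than 3 species.
* **Q** (Rao quadratic entropy): expected dissimilarity between two
  individuals drawn at random, Q = sum_ij d_ij p_i p_j.
* **D_eq** (Jost-corrected Simpson, i.e. inverse Simpson): the taxonomic
  twin of Rao with all between-species distances set to 1.

Rao and Simpson are put on the "equivalent community" scale with the Jost
transform 1/(1 - x), so that D_eq equals species richness when all species
are equally abundant.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import cdist

from .distance import DissimilarityMatrix, TraitSpace, mst_edges
from .traits import CommunityMatrix, TraitTable, subgroup_masks

logger = logging.getLogger(__name__)

INDEX_NAMES = ("FD", "FEve", "Rao")


def fd_from_linkage(Z: np.ndarray) -> float:
    # each merge at height h contributes (h - h_left) + (h - h_right)
    n = Z.shape[0] + 1
    node_height = np.concatenate([np.zeros(n), Z[:, 2]])
    children = Z[:, :2].astype(int)
    return float(np.sum(2.0 * Z[:, 2] - node_height[children[:, 0]] - node_height[children[:, 1]]))


def fd(d_sub: np.ndarray) -> float:
    """Functional diversity of a community from its pairwise distance block.

    Builds the community's own UPGMA dendrogram and sums all branch lengths
    (leaf-to-node and node-to-node segments; nothing above the root).  A
    single species has no tree and FD = 0.
    """
    d_sub = np.asarray(d_sub, dtype=float)
    s = d_sub.shape[0]
    if s <= 1:
        return 0.0
    condensed = d_sub[np.triu_indices(s, k=1)]
    Z = sch.linkage(condensed, method="average")
    return fd_from_linkage(Z)


def feve(coords: np.ndarray, p: np.ndarray) -> float:
    """Functional evenness on the community minimum spanning tree.

    For each MST edge l joining species i and j, the abundance-weighted edge
    length EW_l = dist(i, j) / (p_i + p_j) is computed, normalized to
    PEW_l = EW_l / sum(EW), and compared with the perfectly even value
    1/(S-1):

        FEve = (sum_l min(PEW_l, 1/(S-1)) - 1/(S-1)) / (1 - 1/(S-1))

    Undefined (NaN) for S < 3, where the formula degenerates.
    """
    p = np.asarray(p, dtype=float)
    s = len(p)
    if s < 3:
        logger.info("FEve undefined for S = %d (< 3); returning missing", s)
        return float("nan")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    dist = cdist(coords, coords)
    edges = mst_edges(dist)
    ew = np.array([w / (p[i] + p[j]) for i, j, w in edges])
    total = ew.sum()
    if total <= 0:
        # all species coincide in trait space: evenness is maximal by convention
        return 1.0
    pew = ew / total
    thr = 1.0 / (s - 1)
    return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))


def rao(d_sub: np.ndarray, p: np.ndarray) -> float:
    """Rao quadratic entropy Q = sum_i sum_j d_ij p_i p_j (both orders counted)."""
    p = np.asarray(p, dtype=float)
    return float(p @ np.asarray(d_sub, dtype=float) @ p)


def jost_correct(x: float) -> float:
    """Equivalent-numbers transform 1/(1 - x) for a concave index in [0, 1)."""
    if not 0.0 <= x < 1.0:
        raise ValueError(f"index value {x} outside [0, 1): saturated or invalid")
    return 1.0 / (1.0 - x)


def simpson(p: np.ndarray) -> float:
    """Uncorrected Simpson diversity: probability two random individuals differ."""
    p = np.asarray(p, dtype=float)
    return float(1.0 - np.sum(p * p))


def simpson_eq(p: np.ndarray) -> float:
    """Jost-corrected Simpson (inverse Simpson), D_eq = 1 / sum p_i^2."""
    p = np.asarray(p, dtype=float)
    return float(1.0 / np.sum(p * p))


def community_profiles(
    community: CommunityMatrix,
    traits: TraitTable,
    d: DissimilarityMatrix,
    space: TraitSpace,
    subgroups: Iterable[str] = ("ALL",),
) -> pd.DataFrame:
    """Tidy per-site, per-subgroup table of S, FD, FEve, Q, Q_eq, D_eq.

    Sites with no member of a subgroup get S = 0 and missing index values;
    FEve is missing below 3 species.  ``d`` and ``space`` must cover every
    community species (typically built once on the regional pool).
    """
    community.check_against(traits)
    masks = subgroup_masks(traits, subgroups)
    sp_order = list(traits.species)
    col_idx = {s: i for i, s in enumerate(sp_order)}
    d_idx = d.index_of(sp_order)
    c_idx = space.index_of(sp_order)

    abund = community.abundance.reindex(columns=sp_order, fill_value=0.0).to_numpy(dtype=float)
    rows = []
    for si, site in enumerate(community.sites):
        if site in community.empty_sites:
            continue
        a = abund[si]
        present = a > 0
        for g in subgroups:
            member = present & masks[g]
            idx = np.flatnonzero(member)
            s_count = len(idx)
            rec = {
                "site_id": site,
                "landscape": community.meta.loc[site, "landscape"],
                "habitat": community.meta.loc[site, "habitat"],
                "subgroup": g,
                "S": s_count,
            }
            if s_count == 0:
                rec.update(FD=np.nan, FEve=np.nan, Q=np.nan, Q_eq=np.nan, D_eq=np.nan)
            else:
                idx = idx[np.argsort([sp_order[i] for i in idx])]
                p = a[idx] / a[idx].sum()
                dsub = d.values[np.ix_(d_idx[idx], d_idx[idx])]
                q = rao(dsub, p)
                rec["FD"] = fd(dsub)
                rec["FEve"] = feve(space.coordinates[c_idx[idx]], p)
                rec["Q"] = q
                rec["Q_eq"] = jost_correct(q)
                rec["D_eq"] = simpson_eq(p)
            rows.append(rec)
    return pd.DataFrame(rows)
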
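"""Trait-shuffle null models and standardized effect sizes.

The null model treats each landscape as the regional species pool and
reshuffles species names over the rows of the trait matrix.  Everything
except the name-to-phenotype assignment is conserved: trait covariance, the
set of phenotypes, site occupancy, per-site richness, abundance
distributions and beta diversity.  Each observed index is converted to a
standardized effect size

    SES = (observed - mean(null)) / sd(null)

with SES < 0 indicating functional clustering (niche filtering), SES > 0
overdispersion (limiting similarity), and SES near 0 neutral assembly.

Because a label shuffle only permutes which row of the (fixed) pool
dissimilarity matrix and trait-space coordinates a species points to, null
replicates are computed by index permutation — the Gower matrix, the
Cailliez-corrected principal coordinates and the pool geometry are built
once.  Ecological subgroup membership travels with the trait rows, so it is
re-derived from the permuted table inside every replicate.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import zlib

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import cdist

from . import indices as _ix
from .distance import DissimilarityMatrix, TraitSpace, gower, mst_edges, pcoa_cailliez
from .traits import CommunityMatrix, TraitTable, subgroup_masks

logger = logging.getLogger(__name__)

DEFAULT_N_NULL = 999


def shuffle_traits(traits: TraitTable, rng: np.random.Generator) -> TraitTable:
    """Uniform random permutation of species labels over unchanged trait rows.

    The returned table has the same species index (in the same order) but
    each species now points to the trait row of a uniformly chosen species,
    so the multiset of trait rows is exactly conserved.
    """
    perm = rng.permutation(traits.n_species)
    data = traits.data.iloc[perm].copy()
    data.index = traits.species
    return TraitTable(data, traits.schema)


def _evaluator(index: str, D: np.ndarray, C: np.ndarray):
    """Return f(rows, p) -> float computing one index from global row indices."""
    if index == "FD":
        def f(rows: np.ndarray, p: np.ndarray) -> float:
            s = len(rows)
            if s == 0:
                return float("nan")
            if s == 1:
                return 0.0
            dsub = D[np.ix_(rows, rows)]
            Z = sch.linkage(dsub[np.triu_indices(s, k=1)], method="average")
            return _ix.fd_from_linkage(Z)
    elif index == "Rao":
        def f(rows: np.ndarray, p: np.ndarray) -> float:
            if len(rows) == 0:
                return float("nan")
            return float(p @ D[np.ix_(rows, rows)] @ p)
    elif index == "FEve":
        def f(rows: np.ndarray, p: np.ndarray) -> float:
            s = len(rows)
            if s < 3:
                return float("nan")
            pts = C[rows]
            edges = mst_edges(cdist(pts, pts))
            ew = np.array([w / (p[i] + p[j]) for i, j, w in edges])
            total = ew.sum()
            if total <= 0:
                return 1.0
            pew = ew / total
            thr = 1.0 / (s - 1)
            return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))
    else:
        raise ValueError(f"unknown index {index!r}; expected one of {_ix.INDEX_NAMES}")
    return f


def ses_table(
    community: CommunityMatrix,
    traits: TraitTable,
    *,
    subgroups: Iterable[str] = ("ALL",),
    index_names: Iterable[str] = _ix.INDEX_NAMES,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
    d: DissimilarityMatrix | None = None,
    space: TraitSpace | None = None,
    shuffle_within_subgroup: bool = False,
) -> pd.DataFrame:
    """Standardized effect sizes for every site x subgroup x index.

    One RNG stream is spawned per (landscape, index, subgroup) from the
    master ``seed``, so adding a subgroup or index never perturbs the null
    distributions of the others.  Each replicate draws one landscape-level
    label permutation and re-evaluates every site under it; subgroup
    membership is re-derived from the permuted labels (unless
    ``shuffle_within_subgroup``, which permutes labels only among the
    subgroup's members — a sensitivity-analysis variant).

    Returns a tidy frame with columns site_id, landscape, habitat, subgroup,
    index, observed, null_mean, null_sd, ses, n_null, seed.  ``n_null``
    counts the replicates where the index was defined; a degenerate null
    (sd = 0) yields a missing SES with a logged warning.
    """
    community.check_against(traits)
    subgroups = tuple(subgroups)
    index_names = tuple(index_names)
    if d is None:
        d = gower(traits)
    if space is None and "FEve" in index_names:
        space = pcoa_cailliez(d)

    sp_order = list(traits.species)
    n_sp = len(sp_order)
    d_idx = d.index_of(sp_order)
    D = d.values[np.ix_(d_idx, d_idx)]
    C = space.coordinates[space.index_of(sp_order)] if space is not None else np.zeros((n_sp, 1))
    masks = subgroup_masks(traits, subgroups)

    abund = community.abundance.reindex(columns=sp_order, fill_value=0.0).to_numpy(dtype=float)
    site_list = [s for s in community.sites if s not in community.empty_sites]
    site_pos = {s: i for i, s in enumerate(community.sites)}

    from .traits import SUBGROUPS

    def stream_key(landscape: str, index: str, g: str) -> tuple[int, int, int]:
        # stable across runs and across which subgroups/indices are requested
        ii = _ix.INDEX_NAMES.index(index) if index in _ix.INDEX_NAMES else 99
        gi = SUBGROUPS.index(g) if g in SUBGROUPS else 99
        return (zlib.crc32(str(landscape).encode()), ii, gi)

    rows_out = []
    for landscape in sorted(set(community.meta["landscape"])):
        l_sites = [s for s in site_list if community.meta.loc[s, "landscape"] == landscape]
        if not l_sites:
            continue
        l_abund = abund[[site_pos[s] for s in l_sites]]
        pool = np.flatnonzero(l_abund.sum(axis=0) > 0)
        pool_pos = np.full(n_sp, -1, dtype=int)
        pool_pos[pool] = np.arange(len(pool))
        # per site: global indices of present species and their abundances
        site_sp = [np.flatnonzero(l_abund[k] > 0) for k in range(len(l_sites))]
        site_ab = [l_abund[k][sp] for k, sp in enumerate(site_sp)]
        site_in_pool = [pool_pos[sp] for sp in site_sp]

        for index in index_names:
            for g in subgroups:
                gmask = masks[g]
                f = _evaluator(index, D, C)
                rng = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=stream_key(landscape, index, g))
                )

                def site_value(mapped_rows: np.ndarray, a: np.ndarray) -> float:
                    member = gmask[mapped_rows]
                    rows = mapped_rows[member]
                    if len(rows) == 0:
                        return float("nan")
                    order = np.argsort(rows)
                    rows = rows[order]
                    a_m = a[member][order]
                    return f(rows, a_m / a_m.sum())

                observed = [site_value(sp, ab) for sp, ab in zip(site_sp, site_ab)]
                nulls: list[list[float]] = [[] for _ in l_sites]
                if shuffle_within_subgroup:
                    g_pool = pool[gmask[pool]]
                for _ in range(n_null):
                    if shuffle_within_subgroup:
                        mapped_pool = pool.copy()
                        mapped_pool[gmask[pool]] = rng.permutation(g_pool)
                    else:
                        mapped_pool = pool[rng.permutation(len(pool))]
                    for k, (in_pool, ab) in enumerate(zip(site_in_pool, site_ab)):
                        v = site_value(mapped_pool[in_pool], ab)
                        if not np.isnan(v):
                            nulls[k].append(v)

                for k, site in enumerate(l_sites):
                    nv = np.asarray(nulls[k])
                    obs = observed[k]
                    null_mean = float(nv.mean()) if len(nv) else float("nan")
                    null_sd = float(nv.std(ddof=1)) if len(nv) > 1 else float("nan")
                    if np.isnan(obs) or len(nv) < 2:
                        ses = float("nan")
                    elif null_sd <= 1e-12:
                        logger.warning(
                            "degenerate null (sd = 0) for site %s, %s/%s: SES missing",
                            site, index, g,
                        )
                        ses = float("nan")
                    else:
                        ses = (obs - null_mean) / null_sd
                    rows_out.append({
                        "site_id": site,
                        "landscape": landscape,
                        "habitat": community.meta.loc[site, "habitat"],
                        "subgroup": g,
                        "index": index,
                        "observed": obs,
                        "null_mean": null_mean,
                        "null_sd": null_sd,
                        "ses": ses,
                        "n_null": len(nv),
                        "seed": seed,
                    })
    return pd.DataFrame(rows_out)


def ses_profile(
    community: CommunityMatrix,
    traits: TraitTable,
    subgroup: str,
    index: str,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """SES records for one subgroup and one index (see :func:`ses_table`)."""
    return ses_table(
        community, traits,
        subgroups=(subgroup,), index_names=(index,),
        n_null=n_null, seed=seed, **kwargs,
    )
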
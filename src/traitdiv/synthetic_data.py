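"""Synthetic regional pools and two-landscape communities with known assembly.

The generator emulates the structure of a tropical bird survey in a mosaic
of mature forest and cacao agroforestry: a regional pool of species with 25
binary foraging traits plus a lognormal body mass in [2, 2172] g, and two
landscapes — a forest-dominated one (12 forest + 6 agroforestry sites) and
an agroforestry-dominated one (4 + 4) — whose sites are assembled from the
pool under one of three rules:

* ``neutral`` — species drawn uniformly without replacement;
* ``filtering`` — inclusion probability proportional to
  exp(-g_i^2 / (2 sigma_f^2)) where g_i is the Gower distance of species i
  to the habitat's optimum phenotype (a pool species drawn per habitat), so
  small sigma_f produces strong trait clustering;
* ``limiting_similarity`` — greedy max-min: starting from a random species,
  repeatedly add the species maximizing its minimum Gower distance to those
  already chosen, producing trait overdispersion.

Site abundances are lognormal and independent of traits by default.  The
generated tables always satisfy the trait-table and community-matrix
validation invariants, so every pipeline stage can be exercised without any
external data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .distance import DissimilarityMatrix, gower
from .traits import (
    CommunityMatrix,
    TraitSchema,
    TraitTable,
    default_schema,
)

logger = logging.getLogger(__name__)

ASSEMBLY_RULES = ("neutral", "filtering", "limiting_similarity")


@dataclass(frozen=True)
class ScenarioConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults mirror the emulated survey: two landscapes, 12 forest + 6
    agroforestry sites in landscape A and 4 + 4 in landscape B, body mass
    spanning 2-2172 g, and per-trait prevalences drawn from Beta(2, 2).
    """

    n_species_pool: int = 150
    mass_range: tuple[float, float] = (2.0, 2172.0)
    #: lognormal body-mass parameters (mean and sd of log-mass, grams)
    mass_mu: float = 3.6
    mass_sigma: float = 1.3
    #: Beta(a, b) from which each binary trait's prevalence is drawn
    prevalence_beta: tuple[float, float] = (2.0, 2.0)
    #: probabilities of high / medium / low forest dependency
    dependency_probs: tuple[float, float, float] = (0.3, 0.4, 0.3)
    #: landscape -> habitat -> number of sites
    sites: Mapping[str, Mapping[str, int]] = field(default_factory=lambda: {
        "A": {"forest": 12, "agroforestry": 6},
        "B": {"forest": 4, "agroforestry": 4},
    })
    richness_mean: float = 35.0
    richness_sd: float = 6.0
    #: sd of log abundance (lognormal species-abundance distribution)
    abundance_sigma: float = 1.0
    #: habitat -> assembly rule (any of ASSEMBLY_RULES)
    assembly: Mapping[str, str] = field(default_factory=lambda: {
        "forest": "neutral", "agroforestry": "neutral",
    })
    #: filtering strength, in Gower-distance units
    sigma_f: float = 0.08
    #: minimum inter-site spacing, planar units
    min_spacing: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species_pool < 2:
            raise ValueError("pool must contain at least 2 species")
        if self.sigma_f <= 0:
            raise ValueError("sigma_f must be positive")
        for h, rule in self.assembly.items():
            if rule not in ASSEMBLY_RULES:
                raise ValueError(f"unknown assembly rule {rule!r} for habitat {h!r}")

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["sites"] = {k: dict(v) for k, v in self.sites.items()}
        d["assembly"] = dict(self.assembly)
        return d


def generate_pool(
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
    schema: TraitSchema | None = None,
) -> TraitTable:
    """Draw a regional species pool satisfying all trait-table invariants.

    Binary traits are independent Bernoulli draws with per-trait prevalence
    from Beta(a, b); species violating the at-least-one food type / stratum
    constraints are redrawn (rejection).  Body mass is lognormal clipped to
    the configured range; forest dependency is categorical.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    schema = schema or default_schema()
    n = config.n_species_pool
    bin_cols = list(schema.binary_traits)
    a, b = config.prevalence_beta
    prevalence = rng.beta(a, b, size=len(bin_cols))

    X = (rng.random((n, len(bin_cols))) < prevalence).astype(int)
    food = [bin_cols.index(c) for c in schema.food_type_traits]
    strata = [bin_cols.index(c) for c in schema.stratum_traits]
    for _ in range(1000):
        bad = (X[:, food].sum(axis=1) == 0) | (X[:, strata].sum(axis=1) == 0)
        if not bad.any():
            break
        X[bad] = (rng.random((bad.sum(), len(bin_cols))) < prevalence).astype(int)
    else:  # pragma: no cover - prevalences would have to be absurdly extreme
        raise RuntimeError("could not satisfy food/stratum constraints by rejection")

    lo, hi = config.mass_range
    mass = np.clip(rng.lognormal(config.mass_mu, config.mass_sigma, size=n), lo, hi)
    dep = rng.choice(["high", "medium", "low"], size=n, p=config.dependency_probs)

    width = len(str(n - 1))
    ids = [f"sp{str(i).zfill(width)}" for i in range(n)]
    data = pd.DataFrame(X, columns=bin_cols, index=pd.Index(ids, name="species_id"))
    data.insert(0, schema.continuous[0], mass)
    data[schema.forest_dependency] = dep
    return TraitTable(data, schema)


def _filtering_choice(
    d_to_optimum: np.ndarray, richness: int, sigma_f: float, rng: np.random.Generator
) -> np.ndarray:
    w = np.exp(-(d_to_optimum ** 2) / (2.0 * sigma_f ** 2))
    w = np.maximum(w, 1e-300)
    return rng.choice(len(w), size=richness, replace=False, p=w / w.sum())


def _maxmin_choice(D: np.ndarray, richness: int, rng: np.random.Generator) -> np.ndarray:
    n = D.shape[0]
    chosen = [int(rng.integers(n))]
    min_d = D[chosen[0]].copy()
    min_d[chosen[0]] = -np.inf
    for _ in range(richness - 1):
        nxt = int(np.argmax(min_d))
        chosen.append(nxt)
        min_d = np.minimum(min_d, D[nxt])
        min_d[nxt] = -np.inf
    return np.asarray(chosen)


def assemble_site(
    pool: TraitTable,
    habitat: str,
    config: ScenarioConfig,
    rng: np.random.Generator,
    d_pool: DissimilarityMatrix | None = None,
    optimum: int | None = None,
) -> pd.Series:
    """Abundance vector (indexed by pool species) for one site.

    ``optimum`` is the pool index of the habitat's optimum phenotype
    (required for filtering).  Richness is drawn from a truncated normal
    (>= 3, <= pool size); abundances are iid lognormal counts (ceiling).
    """
    rule = config.assembly.get(habitat, "neutral")
    n = pool.n_species
    richness = int(np.clip(round(rng.normal(config.richness_mean, config.richness_sd)), 3, n))
    if richness > n:
        raise ValueError(f"target richness {richness} exceeds pool size {n}")

    if rule == "neutral":
        idx = rng.choice(n, size=richness, replace=False)
    elif rule == "filtering":
        if d_pool is None or optimum is None:
            raise ValueError("filtering assembly needs the pool distances and an optimum")
        idx = _filtering_choice(d_pool.values[optimum], richness, config.sigma_f, rng)
    else:  # limiting_similarity
        if d_pool is None:
            raise ValueError("limiting-similarity assembly needs the pool distances")
        idx = _maxmin_choice(d_pool.values, richness, rng)

    counts = np.ceil(rng.lognormal(0.0, config.abundance_sigma, size=richness))
    abund = pd.Series(0.0, index=pool.species)
    abund.iloc[idx] = counts
    return abund


def _site_coordinates(
    n_sites: int, bbox: tuple[float, float, float, float],
    min_spacing: float, rng: np.random.Generator,
) -> np.ndarray:
    x0, x1, y0, y1 = bbox
    pts: list[np.ndarray] = []
    for _ in range(20000):
        if len(pts) == n_sites:
            break
        cand = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
        if all(np.linalg.norm(cand - p) >= min_spacing for p in pts):
            pts.append(cand)
    else:
        raise ValueError(
            f"could not place {n_sites} sites with spacing {min_spacing} in {bbox}"
        )
    return np.array(pts)


def generate_landscapes(
    config: ScenarioConfig,
    schema: TraitSchema | None = None,
) -> tuple[TraitTable, CommunityMatrix, dict]:
    """Generate the pool and both landscapes' communities.

    Returns (traits, community, manifest); the manifest records the full
    configuration and the habitat optima for provenance.  Landscapes get
    disjoint planar bounding boxes; sites respect the minimum spacing.
    """
    master = np.random.SeedSequence(config.seed)
    k_pool, k_opt, k_sites = master.spawn(3)
    pool = generate_pool(config, np.random.default_rng(k_pool), schema)
    d_pool = gower(pool)

    rng_opt = np.random.default_rng(k_opt)
    optima = {h: int(rng_opt.integers(pool.n_species))
              for h in sorted({h for sm in config.sites.values() for h in sm})}

    rng = np.random.default_rng(k_sites)
    abund_rows, meta_rows, index = [], [], []
    for lx, (landscape, habitats) in enumerate(sorted(config.sites.items())):
        n_l = sum(habitats.values())
        bbox = (200.0 * lx, 200.0 * lx + 100.0, 0.0, 100.0)
        coords = _site_coordinates(n_l, bbox, config.min_spacing, rng)
        k = 0
        for habitat in sorted(habitats):
            for j in range(habitats[habitat]):
                site_id = f"{landscape}_{habitat[:3]}_{j:02d}"
                abund = assemble_site(pool, habitat, config, rng,
                                      d_pool=d_pool, optimum=optima[habitat])
                abund_rows.append(abund)
                meta_rows.append({
                    "landscape": landscape, "habitat": habitat,
                    "coord_x": coords[k, 0], "coord_y": coords[k, 1],
                })
                index.append(site_id)
                k += 1
    abundance = pd.DataFrame(abund_rows, index=pd.Index(index, name="site_id"))
    abundance = abundance.rename_axis(columns=None)
    meta = pd.DataFrame(meta_rows, index=abundance.index)
    community = CommunityMatrix(abundance, meta)
    manifest = {"config": config.to_manifest(), "habitat_optima": optima}
    return pool, community, manifest


def write_dataset(
    out_dir: str | Path,
    config: ScenarioConfig,
    schema: TraitSchema | None = None,
) -> tuple[TraitTable, CommunityMatrix]:
    """Emit traits.csv, communities.csv, schema.yaml and manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema = schema or default_schema()
    traits, community, manifest = generate_landscapes(config, schema)
    traits.to_csv(out / "traits.csv")
    community.to_csv(out / "communities.csv")
    schema.to_yaml(out / "schema.yaml")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return traits, community
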
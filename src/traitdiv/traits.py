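"""Species-by-trait tables, site-by-species community matrices, and ecological subgroups.

A :class:`TraitTable` holds one continuous trait (body mass, grams) and a set
of binary (0/1) foraging traits per species, together with a categorical
forest-dependency classification used to define the forest-specialist and
habitat-generalist subgroups.  A :class:`CommunityMatrix` holds site-level
abundances plus the site metadata (landscape, habitat, planar coordinates)
needed for habitat contrasts and spatial autocorrelation checks.

The trait schema — which columns are continuous, which are binary, and which
functional category each binary column encodes — is declared explicitly
(either in code or in a YAML sidecar file), never inferred from the data:
a 0/1-coded continuous column silently treated as binary is the main I/O
hazard for mixed-trait dissimilarities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Ecological subgroup labels: the whole community, forest specialists,
#: habitat generalists, frugivores/granivores, and invertebrate eaters.
SUBGROUPS = ("ALL", "SPE", "GEN", "FGr", "INV")

FOREST_DEPENDENCY_LEVELS = ("high", "medium", "low")
HABITATS = ("forest", "agroforestry")
METADATA_COLUMNS = ("landscape", "habitat", "coord_x", "coord_y")

CATEGORY_FOOD = "food_type"
CATEGORY_STRATUM = "foraging_stratum"


class ValidationError(ValueError):
    """A trait table or community matrix violates a declared invariant."""


@dataclass(frozen=True)
class TraitSchema:
    """Declares how trait columns are to be interpreted.

    Parameters
    ----------
    continuous
        Names of continuous trait columns (one by default: body mass in g).
    binary
        Mapping of binary trait column name -> functional category
        (``food_type``, ``foraging_stratum``, ``foraging_method``,
        ``activity_period``, ``mixed_flock``).
    forest_dependency
        Name of the categorical column with levels high/medium/low.
    frugivore_granivore_traits
        Binary columns whose union defines the FGr subgroup (diet contains
        fruits and/or seeds).
    invertebrate_traits
        Binary columns whose union defines the INV subgroup.
    asymmetric_binary
        If True, Gower treats binary traits as asymmetric (0/0 agreement
        carries no information and the pair's denominator shrinks).  The
        default is symmetric matching: absence of a foraging capability is
        as informative as its presence.
    log10_mass
        If True, body mass is log10-transformed before computing ranges and
        dissimilarities.
    """

    continuous: tuple[str, ...] = ("body_mass",)
    binary: Mapping[str, str] = field(default_factory=dict)
    forest_dependency: str = "forest_dependency"
    frugivore_granivore_traits: tuple[str, ...] = ("fruits", "seeds_grains")
    invertebrate_traits: tuple[str, ...] = ("invertebrates",)
    asymmetric_binary: bool = False
    log10_mass: bool = False

    @property
    def binary_traits(self) -> tuple[str, ...]:
        return tuple(self.binary)

    @property
    def trait_columns(self) -> tuple[str, ...]:
        return self.continuous + self.binary_traits

    @property
    def food_type_traits(self) -> tuple[str, ...]:
        return tuple(c for c, cat in self.binary.items() if cat == CATEGORY_FOOD)

    @property
    def stratum_traits(self) -> tuple[str, ...]:
        return tuple(c for c, cat in self.binary.items() if cat == CATEGORY_STRATUM)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "continuous": list(self.continuous),
            "binary": dict(self.binary),
            "forest_dependency": self.forest_dependency,
            "frugivore_granivore_traits": list(self.frugivore_granivore_traits),
            "invertebrate_traits": list(self.invertebrate_traits),
            "asymmetric_binary": self.asymmetric_binary,
            "log10_mass": self.log10_mass,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TraitSchema":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            continuous=tuple(payload["continuous"]),
            binary=dict(payload["binary"]),
            forest_dependency=payload.get("forest_dependency", "forest_dependency"),
            frugivore_granivore_traits=tuple(
                payload.get("frugivore_granivore_traits", ("fruits", "seeds_grains"))
            ),
            invertebrate_traits=tuple(payload.get("invertebrate_traits", ("invertebrates",))),
            asymmetric_binary=bool(payload.get("asymmetric_binary", False)),
            log10_mass=bool(payload.get("log10_mass", False)),
        )


def default_schema() -> TraitSchema:
    """The 26-trait avian foraging scheme: mean body mass plus 25 binary traits.

    Binary traits cover food types (7), foraging strata/substrates (7),
    foraging methods (8), activity period (2) and mixed-flock participation
    (1).  All traits receive equal weight in the Gower dissimilarity.
    """
    binary: dict[str, str] = {}
    for c in ("invertebrates", "fruits", "seeds_grains", "nectar", "flowers",
              "foliage_roots_tubers", "vertebrates"):
        binary[c] = CATEGORY_FOOD
    for c in ("canopy", "midstory", "understory", "ground", "water", "mud", "air"):
        binary[c] = CATEGORY_STRATUM
    for c in ("pursuit", "gleaning", "pouncing", "pecking", "grazing",
              "scavenging", "probing", "hawking"):
        binary[c] = "foraging_method"
    binary["diurnal"] = "activity_period"
    binary["nocturnal"] = "activity_period"
    binary["mixed_flock"] = "mixed_flock"
    return TraitSchema(binary=binary)


@dataclass(frozen=True)
class TraitTable:
    """A validated species-by-trait table.

    ``data`` is indexed by unique species labels and contains every column
    named by ``schema`` (continuous traits, binary traits, and the
    forest-dependency classification).
    """

    data: pd.DataFrame
    schema: TraitSchema

    def __post_init__(self) -> None:
        validate_trait_table(self.data, self.schema)

    @property
    def species(self) -> pd.Index:
        return self.data.index

    @property
    def n_species(self) -> int:
        return len(self.data)

    @property
    def mass(self) -> pd.Series:
        return self.data[self.schema.continuous[0]]

    @property
    def binary_matrix(self) -> pd.DataFrame:
        return self.data[list(self.schema.binary_traits)]

    @property
    def forest_dependency(self) -> pd.Series:
        return self.data[self.schema.forest_dependency]

    def continuous_ranges(self) -> dict[str, tuple[float, float]]:
        """Per continuous trait, the (min, max) over this species pool.

        Ranges are computed once on the regional pool and reused when
        dissimilarities are evaluated on subsets, so subgroup distances stay
        comparable across groups.
        """
        out = {}
        for c in self.schema.continuous:
            v = self.data[c].astype(float)
            if self.schema.log10_mass:
                v = np.log10(v)
            out[c] = (float(v.min()), float(v.max()))
        return out

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="species_id")


def validate_trait_table(data: pd.DataFrame, schema: TraitSchema) -> None:
    if data.index.has_duplicates:
        dup = data.index[data.index.duplicated()][0]
        raise ValidationError(f"duplicate species_id {dup!r}")
    if len(data) < 2:
        raise ValidationError("trait table needs at least 2 species")
    missing = [c for c in schema.trait_columns + (schema.forest_dependency,)
               if c not in data.columns]
    if missing:
        raise ValidationError(f"missing trait column(s): {missing}")
    for c in schema.continuous:
        v = pd.to_numeric(data[c], errors="coerce")
        bad = v.isna() | (v <= 0)
        if bad.any():
            sp = data.index[bad][0]
            raise ValidationError(
                f"non-positive or non-numeric value in continuous trait "
                f"{c!r} for species {sp!r}"
            )
    for c in schema.binary_traits:
        v = data[c]
        ok = v.isin((0, 1))
        if not ok.all():
            sp = data.index[~ok][0]
            raise ValidationError(
                f"non-binary value {v[sp]!r} in binary trait {c!r} for species {sp!r}"
            )
    dep = data[schema.forest_dependency]
    bad = ~dep.isin(FOREST_DEPENDENCY_LEVELS)
    if bad.any():
        sp = data.index[bad][0]
        raise ValidationError(
            f"forest_dependency must be one of {FOREST_DEPENDENCY_LEVELS}; "
            f"species {sp!r} has {dep[sp]!r}"
        )
    food = schema.food_type_traits
    strata = schema.stratum_traits
    if food:
        none = data[list(food)].sum(axis=1) == 0
        if none.any():
            raise ValidationError(
                f"species {data.index[none][0]!r} has no food-type trait set"
            )
    if strata:
        none = data[list(strata)].sum(axis=1) == 0
        if none.any():
            raise ValidationError(
                f"species {data.index[none][0]!r} has no foraging-stratum trait set"
            )


def load_trait_table(
    path: str | Path,
    schema: TraitSchema | str | Path | None = None,
) -> TraitTable:
    """Read a species-by-trait CSV (one species per row, ``species_id`` column).

    ``schema`` may be a :class:`TraitSchema`, a path to a YAML schema sidecar,
    or None to use :func:`default_schema`.
    """
    if schema is None:
        schema = default_schema()
    elif not isinstance(schema, TraitSchema):
        schema = TraitSchema.from_yaml(schema)
    df = pd.read_csv(path)
    if "species_id" not in df.columns:
        raise ValidationError("trait CSV must have a 'species_id' column")
    df = df.set_index("species_id")
    return TraitTable(df, schema)


@dataclass(frozen=True)
class CommunityMatrix:
    """Sites-by-species abundances plus site metadata.

    ``abundance`` is indexed by site_id with species columns; ``meta`` is
    indexed identically with columns landscape, habitat, coord_x, coord_y.
    ``empty_sites`` lists sites that lost all species during subsetting and
    are excluded downstream.
    """

    abundance: pd.DataFrame
    meta: pd.DataFrame
    empty_sites: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        validate_community(self.abundance, self.meta, allow_empty=set(self.empty_sites))

    @property
    def sites(self) -> pd.Index:
        return self.abundance.index

    @property
    def species(self) -> pd.Index:
        return self.abundance.columns

    @property
    def landscapes(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.meta["landscape"]))

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.abundance.sum(axis=1)
        totals = totals.replace(0, np.nan)
        return self.abundance.div(totals, axis=0)

    def sites_of(self, landscape: str, habitat: str | None = None) -> pd.Index:
        m = self.meta["landscape"] == landscape
        if habitat is not None:
            m &= self.meta["habitat"] == habitat
        return self.meta.index[m]

    def subset_sites(self, sites: Sequence[str]) -> "CommunityMatrix":
        sites = pd.Index(sites)
        return CommunityMatrix(
            self.abundance.loc[sites],
            self.meta.loc[sites],
            tuple(s for s in self.empty_sites if s in sites),
        )

    def check_against(self, traits: TraitTable) -> None:
        unknown = self.species.difference(traits.species)
        if len(unknown):
            raise ValidationError(
                f"community species absent from trait table: {list(unknown[:5])}"
            )

    def to_csv(self, path: str | Path) -> None:
        out = pd.concat([self.meta, self.abundance], axis=1)
        out.to_csv(path, index_label="site_id")


def validate_community(
    abundance: pd.DataFrame,
    meta: pd.DataFrame,
    allow_empty: set[str] | None = None,
) -> None:
    allow_empty = allow_empty or set()
    if abundance.index.has_duplicates:
        raise ValidationError("duplicate site_id in community matrix")
    if not abundance.index.equals(meta.index):
        raise ValidationError("abundance and metadata site indices differ")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"missing site metadata column(s): {missing}")
    bad_hab = ~meta["habitat"].isin(HABITATS)
    if bad_hab.any():
        raise ValidationError(
            f"habitat must be one of {HABITATS}; site "
            f"{meta.index[bad_hab][0]!r} has {meta['habitat'][bad_hab].iloc[0]!r}"
        )
    vals = abundance.to_numpy(dtype=float)
    if np.isnan(vals).any() or (vals < 0).any():
        raise ValidationError("abundances must be non-negative numbers")
    occupied = (vals > 0).sum(axis=1)
    empty = abundance.index[occupied == 0].difference(pd.Index(sorted(allow_empty)))
    if len(empty):
        raise ValidationError(f"site {empty[0]!r} has no species with abundance > 0")


def load_community_matrix(path: str | Path) -> CommunityMatrix:
    """Read a community CSV: site_id, landscape, habitat, coord_x, coord_y, species…"""
    df = pd.read_csv(path)
    if "site_id" not in df.columns:
        raise ValidationError("community CSV must have a 'site_id' column")
    df = df.set_index("site_id")
    meta = df[list(METADATA_COLUMNS)]
    abundance = df.drop(columns=list(METADATA_COLUMNS)).astype(float)
    return CommunityMatrix(abundance, meta)


def subgroup_mask(traits: TraitTable, group: str) -> pd.Index:
    """Species labels belonging to an ecological subgroup.

    ALL — every species; SPE — high forest dependency; GEN — low forest
    dependency (medium-dependency species fall in neither); FGr — diet
    contains fruits and/or seeds; INV — diet contains invertebrates.
    FGr and INV may overlap.
    """
    if group not in SUBGROUPS:
        raise ValueError(f"unknown subgroup {group!r}; expected one of {SUBGROUPS}")
    if group == "ALL":
        return traits.species
    if group == "SPE":
        return traits.species[traits.forest_dependency == "high"]
    if group == "GEN":
        return traits.species[traits.forest_dependency == "low"]
    if group == "FGr":
        cols = list(traits.schema.frugivore_granivore_traits)
        return traits.species[traits.data[cols].sum(axis=1) > 0]
    cols = list(traits.schema.invertebrate_traits)
    return traits.species[traits.data[cols].sum(axis=1) > 0]


def subgroup_masks(traits: TraitTable, groups: Iterable[str] = SUBGROUPS) -> dict[str, np.ndarray]:
    """Boolean membership arrays aligned with ``traits.species``, per subgroup."""
    out = {}
    for g in groups:
        members = subgroup_mask(traits, g)
        out[g] = traits.species.isin(members)
    return out


def restrict_community(community: CommunityMatrix, subset: Sequence[str]) -> CommunityMatrix:
    """Drop abundance columns outside ``subset``; flag sites left empty.

    Flagged sites are retained in the matrix (so site bookkeeping is stable)
    but listed in ``empty_sites`` and excluded from downstream index
    computations, with a logged count.
    """
    subset = pd.Index(subset)
    if len(subset) == 0:
        raise ValidationError("cannot restrict community to an empty species subset")
    unknown = subset.difference(community.species)
    if len(unknown):
        raise ValidationError(f"subset species not in community: {list(unknown[:5])}")
    kept = community.species.intersection(subset)
    abundance = community.abundance[kept]
    occupied = (abundance.to_numpy(dtype=float) > 0).sum(axis=1)
    empty = tuple(abundance.index[occupied == 0])
    if empty:
        logger.warning(
            "restrict_community: %d site(s) left with no species and flagged empty",
            len(empty),
        )
    return CommunityMatrix(abundance, community.meta, empty)
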
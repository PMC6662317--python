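"""Shared fixtures: a compact trait schema and hand-sized tables.

The mini schema keeps the mixed-trait structure (one continuous trait, binary
food types and foraging strata) at 7 traits so per-trait arithmetic can be
checked by hand; full-scale tables come from the synthetic generator.
"""

import numpy as np
import pandas as pd
import pytest

from traitdiv import CommunityMatrix, TraitSchema, TraitTable


@pytest.fixture
def mini_schema() -> TraitSchema:
    return TraitSchema(
        continuous=("body_mass",),
        binary={
            "invertebrates": "food_type",
            "fruits": "food_type",
            "seeds_grains": "food_type",
            "vertebrates": "food_type",
            "canopy": "foraging_stratum",
            "ground": "foraging_stratum",
            "mixed_flock": "mixed_flock",
        },
    )


def make_traits(schema: TraitSchema, rows: dict) -> TraitTable:
    """Build a TraitTable from {species: [mass, *binary..., dependency]}."""
    cols = list(schema.trait_columns) + [schema.forest_dependency]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "species_id"
    return TraitTable(df, schema)


@pytest.fixture
def mini_traits(mini_schema) -> TraitTable:
    # mass, invertebrates, fruits, seeds_grains, vertebrates, canopy, ground,
    # mixed_flock, forest_dependency
    return make_traits(mini_schema, {
        "tyran": [12.0, 1, 0, 0, 0, 1, 0, 1, "high"],
        "pipra": [15.0, 1, 1, 0, 0, 0, 1, 0, "high"],
        "colum": [180.0, 0, 1, 1, 0, 0, 1, 0, "medium"],
        "accip": [320.0, 0, 0, 0, 1, 1, 0, 0, "low"],
        "thrau": [30.0, 1, 1, 0, 0, 1, 1, 1, "low"],
        "picid": [55.0, 1, 0, 0, 0, 1, 0, 0, "medium"],
    })


@pytest.fixture
def mini_community(mini_traits) -> CommunityMatrix:
    sp = list(mini_traits.species)
    abundance = pd.DataFrame(
        [
            [4, 2, 0, 1, 3, 0],
            [1, 0, 5, 0, 2, 2],
            [0, 3, 1, 1, 0, 4],
            [2, 2, 2, 2, 2, 2],
        ],
        index=pd.Index(["f1", "f2", "a1", "a2"], name="site_id"),
        columns=sp,
        dtype=float,
    )
    meta = pd.DataFrame(
        {
            "landscape": ["L", "L", "L", "L"],
            "habitat": ["forest", "forest", "agroforestry", "agroforestry"],
            "coord_x": [0.0, 10.0, 25.0, 40.0],
            "coord_y": [0.0, 8.0, 3.0, 12.0],
        },
        index=abundance.index,
    )
    return CommunityMatrix(abundance, meta)


def gower_by_hand(traits: TraitTable) -> np.ndarray:
    """Per-trait arithmetic Gower oracle, written as an explicit double loop."""
    schema = traits.schema
    ids = list(traits.species)
    n = len(ids)
    d = np.zeros((n, n))
    ranges = traits.continuous_ranges()
    for i in range(n):
        for j in range(n):
            total = 0.0
            for c in schema.continuous:
                lo, hi = ranges[c]
                xi, xj = traits.data[c].iloc[i], traits.data[c].iloc[j]
                if schema.log10_mass:
                    xi, xj = np.log10(xi), np.log10(xj)
                total += abs(xi - xj) / (hi - lo)
            for c in schema.binary_traits:
                total += abs(traits.data[c].iloc[i] - traits.data[c].iloc[j])
            d[i, j] = total / (len(schema.continuous) + len(schema.binary_traits))
    return d
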
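"""Stand generation, the simplified growth surrogate, and mortality.

The full ecophysiology (photosynthesis, water balance, carbon allocation)
is deliberately replaced by a growth surrogate that preserves the one
property the eco-evolutionary dynamics depend on: annual stem increment is
proportional to realized growing-season length times a light-competition
index, so an earlier (frost-free) bud burst buys productivity and a frost
hit costs part of the year's increment.  Height follows diameter through a
fixed allometry.

Mortality combines frost deaths (seedlings with emerged leaves die outright
in a post-burst frost), suppression (trees growing far below the stand
median face an elevated death probability) and a small background rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Tree",
    "StandStats",
    "GrowthParams",
    "MortalityParams",
    "Stand",
    "generate_stand",
    "annual_growth",
    "growth_increment",
    "light_competition",
    "mortality_step",
    "ADULT_HEIGHT_M",
    "dbh_to_height",
]

#: stage boundary: trees below this height are seedlings (management
#: retention threshold reused as the stage boundary)
ADULT_HEIGHT_M = 5.0

#: height = ALLOM_A * dbh**ALLOM_B (height m, dbh cm); anchored so an
#: 18.5 cm beech stands ~18.6 m
ALLOM_A = 1.80
ALLOM_B = 0.80

SEEDLING_DBH_CM = 0.5


def dbh_to_height(dbh) -> np.ndarray:
    return ALLOM_A * np.asarray(dbh, dtype=float) ** ALLOM_B


@dataclass(frozen=True)
class GrowthParams:
    """Constants of the growth surrogate."""

    max_dbh_increment: float = 0.6  # cm/yr under full light, full season
    reference_season: float = 165.0  # days; season of this length gives full increment
    senescence_doy: int = 280  # growing season ends here (fixed, early October)
    frost_rebuild_cost: float = 0.5  # fraction of the increment lost after frost
    competition_radius: float = 8.0  # m; neighbors within this radius shade
    competition_coef: float = 6.0  # 1/m² of taller-neighbor basal area


@dataclass(frozen=True)
class MortalityParams:
    p_background: float = 0.005  # yr⁻¹
    p_suppress: float = 0.4  # yr⁻¹ once suppressed
    suppress_frac: float = 0.5  # suppressed if increment < frac × canopy median


@dataclass
class Tree:
    """One individual tree (scalar view; the simulator itself works on the
    array-backed ``Stand``)."""

    id: int
    x: float
    y: float
    age: int
    height: float
    dbh: float
    genotypes: dict = field(default_factory=dict)  # trait -> (n_loci, 2) alleles
    phenotypes: dict = field(default_factory=dict)  # trait -> value (trait units)
    alive: bool = True

    @property
    def stage(self) -> str:
        return "adult" if self.height >= ADULT_HEIGHT_M else "seedling"


@dataclass(frozen=True)
class StandStats:
    """Plot summary of the kind a national forest inventory provides."""

    species: str
    density: float  # trees/ha
    mean_height: float  # m
    cv_height: float
    mean_dbh: float  # cm
    cv_dbh: float
    age: int  # yr

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if self.cv_height < 0 or self.cv_dbh < 0:
            raise ValueError("coefficients of variation must be >= 0")


class Stand:
    """Array-backed collection of trees on a rectangular plot.

    All per-tree attributes are parallel numpy arrays; genotypes are stored
    per trait as (n_trees, n_loci, 2) allele-index arrays and phenotypes as
    (n_trees,) trait-value arrays (the environmental deviate is folded in
    at birth and never redrawn).
    """

    def __init__(self, plot_area_ha: float):
        if plot_area_ha <= 0:
            raise ValueError("plot area must be > 0")
        self.plot_area_ha = float(plot_area_ha)
        side = 100.0 * np.sqrt(plot_area_ha)
        self.extent = (side, side)  # m × m
        self.x = np.empty(0)
        self.y = np.empty(0)
        self.age = np.empty(0, dtype=np.int32)
        self.height = np.empty(0)
        self.dbh = np.empty(0)
        self.genotypes: dict[str, np.ndarray] = {}
        self.phenotypes: dict[str, np.ndarray] = {}
        self._next_id = 0
        self.ids = np.empty(0, dtype=np.int64)

    # -- basic accessors -------------------------------------------------
    @property
    def n_trees(self) -> int:
        return self.x.shape[0]

    @property
    def is_adult(self) -> np.ndarray:
        return self.height >= ADULT_HEIGHT_M

    @property
    def basal_area_m2(self) -> np.ndarray:
        return np.pi * (self.dbh / 200.0) ** 2  # dbh cm -> radius m

    def density_per_ha(self) -> float:
        return self.n_trees / self.plot_area_ha

    def add(
        self,
        x,
        y,
        age,
        height,
        dbh,
        genotypes: dict[str, np.ndarray],
        phenotypes: dict[str, np.ndarray],
    ) -> None:
        n_new = np.asarray(x).shape[0]
        self.x = np.concatenate([self.x, np.asarray(x, dtype=float)])
        self.y = np.concatenate([self.y, np.asarray(y, dtype=float)])
        self.age = np.concatenate([self.age, np.asarray(age, dtype=np.int32)])
        self.height = np.concatenate([self.height, np.asarray(height, dtype=float)])
        self.dbh = np.concatenate([self.dbh, np.asarray(dbh, dtype=float)])
        for trait, g in genotypes.items():
            old = self.genotypes.get(trait)
            g = np.asarray(g, dtype=np.int8)
            self.genotypes[trait] = g if old is None else np.concatenate([old, g])
        for trait, ph in phenotypes.items():
            old = self.phenotypes.get(trait)
            ph = np.asarray(ph, dtype=float)
            self.phenotypes[trait] = ph if old is None else np.concatenate([old, ph])
        self.ids = np.concatenate(
            [self.ids, np.arange(self._next_id, self._next_id + n_new)]
        )
        self._next_id += n_new

    def keep(self, mask: np.ndarray) -> None:
        """Drop all trees where mask is False (deaths, harvests)."""
        mask = np.asarray(mask, dtype=bool)
        self.x = self.x[mask]
        self.y = self.y[mask]
        self.age = self.age[mask]
        self.height = self.height[mask]
        self.dbh = self.dbh[mask]
        self.ids = self.ids[mask]
        for trait in self.genotypes:
            self.genotypes[trait] = self.genotypes[trait][mask]
        for trait in self.phenotypes:
            self.phenotypes[trait] = self.phenotypes[trait][mask]

    def tree(self, i: int) -> Tree:
        """Scalar view of tree at array position i."""
        return Tree(
            id=int(self.ids[i]),
            x=float(self.x[i]),
            y=float(self.y[i]),
            age=int(self.age[i]),
            height=float(self.height[i]),
            dbh=float(self.dbh[i]),
            genotypes={t: g[i] for t, g in self.genotypes.items()},
            phenotypes={t: p[i] for t, p in self.phenotypes.items()},
        )

    def to_table(self):
        """Delimited-table export (id, x, y, age, height, dbh)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "id": self.ids,
                "x": self.x,
                "y": self.y,
                "age": self.age,
                "height": self.height,
                "dbh": self.dbh,
            }
        )


def generate_stand(
    stats: StandStats,
    plot_area_ha: float,
    rng: np.random.Generator,
    genotypes: dict[str, np.ndarray] | None = None,
    phenotypes: dict[str, np.ndarray] | None = None,
) -> Stand:
    """Generate a stand matching inventory plot statistics.

    round(density × area) trees; heights and diameters drawn from normal
    laws with the stated means and coefficients of variation (truncated at
    zero); positions uniform on the plot (no spatial structure); uniform
    age.  Genotype/phenotype arrays, if given, must have one row per tree.
    """
    if plot_area_ha <= 0:
        raise ValueError("plot area must be > 0")
    n = int(round(stats.density * plot_area_ha))
    stand = Stand(plot_area_ha)
    sx, sy = stand.extent
    height = np.maximum(
        rng.normal(stats.mean_height, stats.cv_height * stats.mean_height, n), 1e-3
    )
    dbh = np.maximum(
        rng.normal(stats.mean_dbh, stats.cv_dbh * stats.mean_dbh, n), 1e-3
    )
    stand.add(
        x=rng.uniform(0, sx, n),
        y=rng.uniform(0, sy, n),
        age=np.full(n, stats.age, dtype=np.int32),
        height=height,
        dbh=dbh,
        genotypes=genotypes or {},
        phenotypes=phenotypes or {},
    )
    return stand


def growth_increment(
    dbh,
    season_length,
    light_index,
    frost_damaged,
    params: GrowthParams,
) -> np.ndarray:
    """Diameter increment (cm/yr) of the growth surrogate; elementwise.

    increment = max_increment × min(season/reference, 1) × light ×
    (1 − rebuild_cost if frost-damaged).  Non-negative by construction.
    """
    season = np.clip(np.asarray(season_length, dtype=float) / params.reference_season, 0.0, 1.0)
    light = np.asarray(light_index, dtype=float)
    inc = params.max_dbh_increment * season * light
    inc = np.where(np.asarray(frost_damaged, dtype=bool), inc * (1.0 - params.frost_rebuild_cost), inc)
    return inc


def annual_growth(
    tree: Tree,
    season_length: float,
    light_index: float,
    frost_damaged: bool,
    params: GrowthParams | None = None,
) -> tuple[float, float]:
    """Grow one tree for one year; returns (dbh increment cm, height
    increment m) and updates the tree in place."""
    if not tree.alive:
        raise ValueError("annual_growth on a dead tree")
    if not 0.0 <= light_index <= 1.0:
        raise ValueError("light_index must lie in [0, 1]")
    params = params or GrowthParams()
    d_dbh = float(growth_increment(tree.dbh, season_length, light_index, frost_damaged, params))
    new_dbh = tree.dbh + d_dbh
    new_height = max(tree.height, float(dbh_to_height(new_dbh)))
    d_height = new_height - tree.height
    tree.dbh = new_dbh
    tree.height = new_height
    return d_dbh, d_height


def light_competition(stand: Stand, params: GrowthParams | None = None) -> np.ndarray:
    """Per-tree light index in (0, 1].

    index_i = exp(−c · B_i) with B_i the summed basal area (m²) of
    strictly taller trees within the competition radius — an extinction-law
    surrogate for canopy shading.  A tree with no taller neighbor gets
    exactly 1; the index only depends on the configuration, not the
    ordering, of trees.
    """
    params = params or GrowthParams()
    n = stand.n_trees
    if n == 0:
        return np.empty(0)
    shade = np.zeros(n)
    if n > 1:
        pts = np.column_stack([stand.x, stand.y])
        tree_index = cKDTree(pts)
        pairs = tree_index.query_pairs(params.competition_radius, output_type="ndarray")
        if pairs.size:
            ba = stand.basal_area_m2
            h = stand.height
            i, j = pairs[:, 0], pairs[:, 1]
            taller_j = h[j] > h[i]
            np.add.at(shade, i[taller_j], ba[j][taller_j])
            taller_i = h[i] > h[j]
            np.add.at(shade, j[taller_i], ba[i][taller_i])
    return np.exp(-params.competition_coef * shade)


def mortality_step(
    stand: Stand,
    increments: np.ndarray,
    frost_dead: np.ndarray,
    rng: np.random.Generator,
    params: MortalityParams | None = None,
) -> np.ndarray:
    """Decide which trees die this year; returns the death mask.

    Deaths combine (i) frost deaths passed in from the phenology check
    (seedlings with emerged leaves in a post-burst frost), (ii) suppression
    — death with probability ``p_suppress`` for trees whose increment fell
    below ``suppress_frac`` × the stand median increment (the median is
    taken over canopy trees when any exist, so a deep regeneration layer
    cannot drag the reference down), and (iii) a small background
    probability.  The caller removes the dead with ``stand.keep``.
    """
    params = params or MortalityParams()
    n = stand.n_trees
    dead = np.asarray(frost_dead, dtype=bool).copy()
    if n == 0:
        return dead
    inc = np.asarray(increments, dtype=float)
    canopy = stand.is_adult
    median = float(np.median(inc[canopy])) if canopy.any() else float(np.median(inc))
    suppressed = inc < params.suppress_frac * median
    u = rng.random(n)
    dead |= suppressed & (u < params.p_suppress)
    dead |= rng.random(n) < params.p_background
    return dead
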
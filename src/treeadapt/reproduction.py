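"""Mating, pollen and seed dispersal, and seedling establishment.

Seed output of an adult scales with stem cross-section (dbh²) and is lost
entirely in a year its flowers were frosted.  Pollen donors are sampled
with exponentially distance-decaying weights; seeds disperse from the
mother with an exponential distance kernel; recruitment is capped per unit
area by genotype-blind random thinning.  Offspring receive one free-
recombination gamete from each parent per trait and a fresh environmental
deviate, so their genetic composition differs from their parents'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import genetics
from .genetics import TraitArchitecture
from .growth_mortality import SEEDLING_DBH_CM, Stand, dbh_to_height

__all__ = [
    "MatingConfig",
    "produce_seed_count",
    "select_father",
    "make_offspring",
    "establish_seedlings",
    "reproduce",
]


@dataclass(frozen=True)
class MatingConfig:
    seeds_per_adult_scale: float = 0.01  # expected seeds per cm² of dbh²
    pollen_kernel_scale: float = 30.0  # m
    seed_kernel_scale: float = 15.0  # m
    selfing_allowed: bool = False
    establishment_cap: float = 0.01  # seedlings per m² per year

    def __post_init__(self) -> None:
        if self.seeds_per_adult_scale < 0:
            raise ValueError("seeds_per_adult_scale must be >= 0")
        if self.pollen_kernel_scale <= 0 or self.seed_kernel_scale <= 0:
            raise ValueError("kernel scales must be > 0")
        if self.establishment_cap < 0:
            raise ValueError("establishment cap must be >= 0")


def produce_seed_count(
    dbh: float,
    frost_damaged: bool,
    cfg: MatingConfig,
    rng: np.random.Generator,
    is_adult: bool = True,
) -> int:
    """Seeds set by one mother this year: Poisson around scale × dbh²,
    zero if her flowers were lost to frost."""
    if not is_adult:
        raise ValueError("only adult trees produce seed")
    if frost_damaged:
        return 0
    lam = cfg.seeds_per_adult_scale * float(dbh) ** 2
    return int(rng.poisson(lam))


def _kernel_weights(
    mother_xy: np.ndarray, donor_xy: np.ndarray, scale: float
) -> np.ndarray:
    d = np.hypot(donor_xy[:, 0] - mother_xy[0], donor_xy[:, 1] - mother_xy[1])
    return np.exp(-d / scale)


def select_father(
    mother_index: int,
    donor_indices: np.ndarray,
    stand: Stand,
    cfg: MatingConfig,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Sample pollen donor(s) for one mother.

    Donors are drawn with probability proportional to
    exp(−distance / pollen_kernel_scale); the mother is excluded unless
    selfing is allowed.  Raises ``ValueError`` when no donor is eligible
    (a mating failure: the mother sets no seed that year).
    """
    donors = np.asarray(donor_indices)
    if not cfg.selfing_allowed:
        donors = donors[donors != mother_index]
    if donors.size == 0:
        raise ValueError("no eligible pollen donor")
    w = _kernel_weights(
        np.array([stand.x[mother_index], stand.y[mother_index]]),
        np.column_stack([stand.x[donors], stand.y[donors]]),
        cfg.pollen_kernel_scale,
    )
    cdf = np.cumsum(w)
    picks = np.searchsorted(cdf, rng.random(size) * cdf[-1], side="right")
    return donors[np.minimum(picks, donors.size - 1)]


def make_offspring(
    mother_indices,
    father_indices,
    stand: Stand,
    architectures: dict[str, TraitArchitecture],
    cfg: MatingConfig,
    rng: np.random.Generator,
) -> dict:
    """Create seedling candidates (vectorized over crosses).

    ``mother_indices`` may be a scalar (one mother, many seeds) or an array
    paired element-wise with ``father_indices``.  Each offspring receives
    one gamete from its mother and one from its father per trait (free
    recombination), a phenotype with a freshly drawn environmental deviate,
    and a position dispersed from the mother by an exponential distance
    kernel, clipped to the plot.
    """
    fathers = np.atleast_1d(np.asarray(father_indices))
    mothers = np.broadcast_to(np.atleast_1d(np.asarray(mother_indices)), fathers.shape)
    n_off = fathers.size
    genos: dict[str, np.ndarray] = {}
    phenos: dict[str, np.ndarray] = {}
    for trait, arch in architectures.items():
        g = stand.genotypes[trait]
        if g.shape[1] != arch.n_loci:
            raise ValueError(
                f"trait {trait!r}: stand genotypes have {g.shape[1]} loci, "
                f"architecture {arch.n_loci}"
            )
        maternal = genetics.make_gametes(g[mothers], rng)
        paternal = genetics.make_gametes(g[fathers], rng)
        geno = np.stack([maternal, paternal], axis=-1).astype(np.int8)
        genos[trait] = geno
        G = genetics.genotypic_values(geno, arch)
        phenos[trait] = genetics.phenotypic_value(G, arch, rng)

    dist = rng.exponential(cfg.seed_kernel_scale, n_off)
    angle = rng.uniform(0.0, 2.0 * np.pi, n_off)
    sx, sy = stand.extent
    x = np.clip(stand.x[mothers] + dist * np.cos(angle), 0.0, sx)
    y = np.clip(stand.y[mothers] + dist * np.sin(angle), 0.0, sy)
    return {
        "x": x,
        "y": y,
        "mother": mothers.copy(),
        "father": fathers,
        "genotypes": genos,
        "phenotypes": phenos,
    }


def establish_seedlings(
    candidates: dict,
    stand: Stand,
    cfg: MatingConfig,
    rng: np.random.Generator,
) -> int:
    """Recruit seedling candidates into the stand, up to the establishment
    cap (candidates per m² of plot per year); the excess is thinned at
    random, blind to genotype.  Returns the number recruited."""
    n_cand = candidates["x"].shape[0]
    if n_cand == 0:
        return 0
    cap = int(np.floor(cfg.establishment_cap * stand.plot_area_ha * 1e4))
    if n_cand > cap:
        keep = rng.choice(n_cand, size=cap, replace=False)
        keep.sort()
    else:
        keep = np.arange(n_cand)
    n = keep.size
    if n == 0:
        return 0
    dbh = np.full(n, SEEDLING_DBH_CM)
    stand.add(
        x=candidates["x"][keep],
        y=candidates["y"][keep],
        age=np.zeros(n, dtype=np.int32),
        height=dbh_to_height(dbh),
        dbh=dbh,
        genotypes={t: g[keep] for t, g in candidates["genotypes"].items()},
        phenotypes={t: p[keep] for t, p in candidates["phenotypes"].items()},
    )
    return n


def reproduce(
    stand: Stand,
    architectures: dict[str, TraitArchitecture],
    frost_damaged: np.ndarray,
    cfg: MatingConfig,
    rng: np.random.Generator,
) -> int:
    """One year of reproduction over the whole stand; returns births.

    Mothers and pollen donors are living adults whose flowers survived any
    frost.  All candidate seedlings compete for the establishment cap
    together.
    """
    adults = np.flatnonzero(stand.is_adult & ~np.asarray(frost_damaged, dtype=bool))
    n_ad = adults.size
    if n_ad == 0:
        return 0
    seeds = rng.poisson(cfg.seeds_per_adult_scale * stand.dbh[adults] ** 2)
    if seeds.sum() == 0:
        return 0

    # batched kernel-weighted father sampling (same law as select_father)
    ax, ay = stand.x[adults], stand.y[adults]
    w = np.exp(-np.hypot(ax[:, None] - ax[None, :], ay[:, None] - ay[None, :])
               / cfg.pollen_kernel_scale)
    if not cfg.selfing_allowed:
        np.fill_diagonal(w, 0.0)
    cdf = np.cumsum(w, axis=1)
    total = cdf[:, -1]
    seeds[total <= 0.0] = 0  # no eligible donor: mating failure
    if seeds.sum() == 0:
        return 0
    rows = np.repeat(np.arange(n_ad), seeds)
    u = rng.random(rows.size) * total[rows]
    picks = np.sum(cdf[rows] < u[:, None], axis=1)
    mothers = adults[rows]
    fathers = adults[np.minimum(picks, n_ad - 1)]

    cand = make_offspring(mothers, fathers, stand, architectures, cfg, rng)
    return establish_seedlings(cand, stand, cfg, rng)
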
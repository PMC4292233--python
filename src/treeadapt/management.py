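"""Forest Management Approach (FMA) scheduling.

Five FMA intensity classes are recognized, from unmanaged nature reserve
(FMA 1) to short-rotation forestry (FMA 5).  The simulated experiments use
FMA 4, intensive even-aged forestry with a seed-tree system: at stand age
60 the stand is cut back to 50 dominant seed trees per hectare (trees below
5 m are retained to regenerate naturally), and the seed trees themselves
are harvested ten years after the realized cut.  Stand age is the mean age
of all trees that have reached at least half the maximum height.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .growth_mortality import Stand

__all__ = ["ManagementPlan", "ManagementState", "HarvestRecord", "stand_age", "apply_management"]


@dataclass(frozen=True)
class ManagementPlan:
    fma: int = 4
    seed_tree_cut_age: float = 60.0  # yr
    seed_tree_density: float = 50.0  # trees/ha retained at the cut
    retention_height: float = 5.0  # m; smaller trees are never cut
    final_harvest_age: float = 70.0  # yr (nominal; see apply_management)

    def __post_init__(self) -> None:
        if not 1 <= self.fma <= 5:
            raise ValueError("fma must be 1..5")
        if self.seed_tree_cut_age >= self.final_harvest_age:
            raise ValueError("seed-tree cut age must precede final harvest age")
        if self.seed_tree_density <= 0:
            raise ValueError("seed_tree_density must be > 0")


@dataclass
class ManagementState:
    """Per-replicate memory of what the plan has already done."""

    cut_year: int | None = None
    final_done: bool = False
    seed_tree_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


@dataclass(frozen=True)
class HarvestRecord:
    year: int
    event: str  # "seed_tree_cut" | "final_harvest"
    trees_removed: int
    basal_area_removed: float  # m²


def stand_age(stand: Stand) -> float:
    """Mean age of trees having reached at least 50% of the maximum height."""
    if stand.n_trees == 0:
        raise ValueError("stand age of an empty stand is undefined")
    threshold = 0.5 * float(np.max(stand.height))
    qualifies = stand.height >= threshold
    return float(np.mean(stand.age[qualifies]))


def apply_management(
    stand: Stand,
    plan: ManagementPlan,
    state: ManagementState,
    year: int,
) -> list[HarvestRecord]:
    """Apply the plan for one year; mutates the stand, returns harvests.

    FMA 1 never intervenes; FMA 4 performs the seed-tree cut on the first
    year stand age crosses ``seed_tree_cut_age`` (keeping the
    ``seed_tree_density`` largest-dbh trees per hectare among those at or
    above the retention height) and removes the surviving seed trees ten
    years after the realized cut year.  Idempotent within a year.
    """
    if plan.fma == 1:
        return []
    if plan.fma != 4:
        raise NotImplementedError(f"FMA {plan.fma} is a configuration stub")
    records: list[HarvestRecord] = []
    if stand.n_trees == 0:
        return records

    if state.cut_year is None and stand_age(stand) >= plan.seed_tree_cut_age:
        big = np.flatnonzero(stand.height >= plan.retention_height)
        n_keep = int(round(plan.seed_tree_density * stand.plot_area_ha))
        if big.size > n_keep:
            order = big[np.argsort(stand.dbh[big])[::-1]]
            kept = order[:n_keep]
            removed = order[n_keep:]
            mask = np.ones(stand.n_trees, dtype=bool)
            mask[removed] = False
            ba = float(np.sum(stand.basal_area_m2[removed]))
            state.seed_tree_ids = stand.ids[kept].copy()
            stand.keep(mask)
            records.append(HarvestRecord(year, "seed_tree_cut", removed.size, ba))
        else:
            state.seed_tree_ids = stand.ids[big].copy()
        state.cut_year = year

    elif (
        state.cut_year is not None
        and not state.final_done
        and year >= state.cut_year + (plan.final_harvest_age - plan.seed_tree_cut_age)
    ):
        is_seed_tree = np.isin(stand.ids, state.seed_tree_ids) & (
            stand.height >= plan.retention_height
        )
        removed = np.flatnonzero(is_seed_tree)
        if removed.size:
            ba = float(np.sum(stand.basal_area_m2[removed]))
            mask = ~is_seed_tree
            stand.keep(mask)
            records.append(HarvestRecord(year, "final_harvest", removed.size, ba))
        # rotation complete: reset so the regenerated even-aged stand is
        # managed the same way when it matures
        state.cut_year = None
        state.final_done = False
        state.seed_tree_ids = np.empty(0, dtype=np.int64)

    return records
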
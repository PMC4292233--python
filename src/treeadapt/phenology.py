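"""Sequential chilling–forcing model of bud burst, plus the frost rule.

Dormancy release is sequential: chilling units accumulate from the start of
dormancy (November 1 by convention) at a temperature-dependent rate; once
the accumulated state of chilling reaches the tree's critical value S*_c,
warm-temperature forcing starts to count, and bud burst occurs on the first
day the state of forcing reaches the critical value S*_f.  S*_c and S*_f
are the adaptive traits of the model — each tree carries its own values.

The penalty of too early a bud burst: if the daily minimum temperature
falls below the frost-hardiness threshold (−2 °C for deciduous broadleaves)
on any day after bud burst, an adult loses its foliage and flowers for the
year (no seed production, a canopy-rebuild growth cost) and a seedling with
emerged leaves dies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhenologyParams",
    "PhenologyState",
    "chilling_rate",
    "forcing_rate",
    "bud_burst_day",
    "bud_burst_indices",
    "frost_check",
    "DORMANCY_START_DOY",
    "WINDOW_DAYS",
]

#: day-of-year (1-based, 365-day calendar) on which chilling accumulation
#: starts in the *preceding* calendar year
DORMANCY_START_DOY = 305  # November 1
#: length of the dormancy-to-spring window: Nov 1 .. Jun 30
WINDOW_DAYS = (365 - DORMANCY_START_DOY + 1) + 181  # 61 + 181 = 242


@dataclass(frozen=True)
class PhenologyParams:
    """Constants of the annual-cycle model (all trees share these; only
    S*_c and S*_f vary genetically).

    Temperatures in °C; rates in units/day.  The chilling response is
    triangular between ``chill_T_min`` and ``chill_T_max`` peaking at
    ``chill_T_opt``; the forcing response is 0 at or below
    ``force_T_base`` and saturating-logistic above it.
    """

    chill_T_min: float = -20.0
    chill_T_opt: float = 0.5
    chill_T_max: float = 12.0
    force_T_base: float = 0.0
    force_slope: float = 0.2
    accumulation_start: int = DORMANCY_START_DOY
    frost_hardiness: float = -2.0

    def __post_init__(self) -> None:
        if not self.chill_T_min < self.chill_T_opt < self.chill_T_max:
            raise ValueError("need chill_T_min < chill_T_opt < chill_T_max")


@dataclass
class PhenologyState:
    """Per-tree annual-cycle state."""

    S_c: float = 0.0
    S_f: float = 0.0
    chilling_met: bool = False
    bud_burst_day: int | None = None
    frost_damaged: bool = False


def chilling_rate(T, params: PhenologyParams):
    """Triangular chilling response in [0, 1] units/day."""
    T = np.asarray(T, dtype=float)
    p = params
    up = (T - p.chill_T_min) / (p.chill_T_opt - p.chill_T_min)
    down = (p.chill_T_max - T) / (p.chill_T_max - p.chill_T_opt)
    out = np.clip(np.minimum(up, down), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def forcing_rate(T, params: PhenologyParams):
    """Saturating forcing response: 0 at or below the base temperature,
    logistic-family (tanh) and strictly increasing above it, < 1 always."""
    T = np.asarray(T, dtype=float)
    x = np.maximum(T - params.force_T_base, 0.0)
    out = np.tanh(0.5 * params.force_slope * x)
    return float(out) if out.ndim == 0 else out


def _window_index_to_doy(idx: np.ndarray, params: PhenologyParams) -> np.ndarray:
    """Map an index into the dormancy window onto a 1-based day-of-year.

    Indices before the new year map to (negative-offset) days of the
    preceding year expressed as doy − 365 (so ordering stays monotone);
    index ``pre`` is January 1 = doy 1.
    """
    pre = 365 - params.accumulation_start + 1
    return idx - pre + 1


def bud_burst_indices(
    tmean: np.ndarray,
    S_c_star: np.ndarray,
    S_f_star: np.ndarray,
    params: PhenologyParams,
) -> np.ndarray:
    """Vectorized bud burst over trees for one dormancy-to-spring window.

    Parameters
    ----------
    tmean : (n_days,) daily mean temperature over the window starting at
        ``params.accumulation_start`` of the previous year
    S_c_star, S_f_star : per-tree critical states (broadcastable arrays)

    Returns
    -------
    (n_trees,) int window index of bud burst, or -1 where the forcing
    requirement is never reached.  The chilling requirement must be met
    before forcing accumulates (sequential model); with S*_f = 0 bud burst
    falls on the day chilling is first met.
    """
    tmean = np.asarray(tmean, dtype=float)
    n_days = tmean.shape[0]
    Sc = np.cumsum(chilling_rate(tmean, params))
    Sf = np.cumsum(forcing_rate(tmean, params))
    S_c_star = np.asarray(S_c_star, dtype=float)
    S_f_star = np.asarray(S_f_star, dtype=float)

    i_chill = np.searchsorted(Sc, S_c_star, side="left")
    no_chill = i_chill >= n_days
    i_safe = np.minimum(i_chill, n_days - 1)
    base = Sf[i_safe]
    j = np.searchsorted(Sf, base + S_f_star, side="left")
    j = np.maximum(j, i_chill)  # burst never precedes chilling fulfilment
    out = np.where(no_chill | (j >= n_days), -1, j)
    return out.astype(np.int64)


def bud_burst_day(
    daily_T: np.ndarray, params: PhenologyParams, S_c_star: float, S_f_star: float
) -> int | None:
    """Bud-burst day-of-year for one tree and one dormancy window.

    ``daily_T`` must cover ``accumulation_start`` of the preceding year
    through the end of June (242 days on the 365-day calendar).  Returns a
    1-based day-of-year (values ≤ 0 would denote the preceding year, which
    cannot occur: forcing is non-negative and chilling precedes it), or
    ``None`` if bud burst is never reached.
    """
    daily_T = np.asarray(daily_T, dtype=float)
    expected = 365 - params.accumulation_start + 1 + 181
    if daily_T.shape[0] < expected:
        raise ValueError(
            f"temperature series too short: {daily_T.shape[0]} days, "
            f"need {expected} (dormancy start through end of June)"
        )
    idx = bud_burst_indices(daily_T, np.array([S_c_star]), np.array([S_f_star]), params)[0]
    if idx < 0:
        return None
    return int(_window_index_to_doy(np.array([idx]), params)[0])


def frost_check(
    state: PhenologyState,
    tmin_after_burst: np.ndarray,
    stage: str,
    params: PhenologyParams,
) -> PhenologyState:
    """Apply the frost-damage rule after bud burst.

    If any daily minimum after the bud-burst day is strictly below the
    frost-hardiness threshold: adults are flagged ``frost_damaged``
    (foliage and flowers lost that year), seedlings with emerged leaves are
    marked dead (encoded here as frost_damaged on a seedling; the mortality
    step removes them).  A minimum exactly at the threshold does no damage.
    """
    if state.bud_burst_day is None:
        raise ValueError("frost_check called before bud burst")
    if stage not in ("seedling", "adult"):
        raise ValueError(f"unknown stage {stage!r}")
    tmin = np.asarray(tmin_after_burst, dtype=float)
    if tmin.size and np.min(tmin) < params.frost_hardiness:
        state.frost_damaged = True
    return state
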
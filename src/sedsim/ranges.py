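"""Contiguous, climate-constrained candidate range options.

For every hemisphere and time slice a pool of fixed-size contiguous ranges
is generated with a climate-driven spreading-dye algorithm: a seed cell is
drawn with probability proportional to 1/(1 + S_h) (S_h = number of already
simulated species occurring in cell h), two of its neighbours are added,
and the range then grows by repeatedly annexing 25% (rounded up) of the
unoccupied frontier, preferring cells climatically close to the running
optimum — the mean climatic-space position of the cells annexed so far.
Frontier cell c, at climatic distance d from the optimum and adjacent to
m occupied cells, carries weight m * 2 (d + 1)^-x (default x = 30).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .energyscape import ClimateSpace
from .hexgrid import HexGrid

DEFAULT_X = 30.0
DEFAULT_N_OPTIONS = {"WH": 400, "EH": 600}
DEFAULT_RANGE_SIZES = {"WH": 131, "EH": 180}


class CannotSeedError(RuntimeError):
    """No habitable cell to seed from in the requested hemisphere."""


class StalledGrowthError(RuntimeError):
    """The frontier emptied before the range reached its target size."""


class GenerationError(RuntimeError):
    """Retry budget exhausted while generating the option set."""


@dataclass
class RangeOption:
    """A contiguous fixed-size candidate range within one hemisphere."""

    option_id: int
    hemisphere: str
    cells: np.ndarray          # sorted cell ids
    seed_cell: int
    centroid_lat: float
    centroid_lon: float
    final_optimum: np.ndarray  # (z_T, z_logP) at the last growth step

    @property
    def size(self) -> int:
        return len(self.cells)


def seed_probabilities(s_h: np.ndarray, eligible: np.ndarray) -> np.ndarray:
    """Normalised seeding probabilities 1/(1 + S_h) over eligible cells."""
    s_h = np.asarray(s_h, dtype=float)
    if np.any(s_h < 0):
        raise ValueError("S_h must be non-negative")
    eligible = np.asarray(eligible, dtype=bool)
    if not eligible.any():
        raise CannotSeedError("no eligible cell to seed from")
    w = np.where(eligible, 1.0 / (1.0 + s_h), 0.0)
    return w / w.sum()


def frontier_weights(
    d: np.ndarray,
    x: float = DEFAULT_X,
    multiplicity: np.ndarray | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Selection weights 2 (d + 1)^-x per frontier cell.

    ``multiplicity`` counts how many occupied cells each frontier cell
    touches; its weight is the sum over those adjacencies.  Normalised
    weights are computed in log space, so steep exponents (x = 30 by
    default) cannot underflow to an all-zero distribution.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("climatic distances must be non-negative")
    if x <= 0:
        raise ValueError("exponent x must be positive")
    if d.size == 0:
        raise StalledGrowthError("empty frontier")
    mult = np.ones_like(d) if multiplicity is None else np.asarray(multiplicity, dtype=float)
    if not normalize:
        return mult * 2.0 * (d + 1.0) ** (-x)
    logw = np.log(mult) + math.log(2.0) - x * np.log1p(d)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def _weighted_sample_without_replacement(
    rng: np.random.Generator, items: np.ndarray, probs: np.ndarray, k: int
) -> np.ndarray:
    return rng.choice(items, size=k, replace=False, p=probs)


def grow_range(
    grid: HexGrid,
    space: ClimateSpace,
    eligible: np.ndarray,
    seed_cell: int,
    size: int,
    x: float = DEFAULT_X,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Grow one contiguous range of exactly ``size`` cells from ``seed_cell``.

    ``eligible`` marks the cells growth may enter (habitable cells of the
    option's hemisphere).  Returns the sorted member cell ids; raises
    :class:`StalledGrowthError` if the frontier empties first.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    if not eligible[seed_cell]:
        raise ValueError("seed cell is not eligible")
    rng = np.random.default_rng() if rng is None else rng

    occupied = np.zeros(grid.n_cells, dtype=bool)
    occupied[seed_cell] = True
    members = [seed_cell]
    optimum = space.position([seed_cell])[0]

    def frontier_of(members_new):
        """Update multiplicities with the neighbours of newly occupied cells."""
        for cell in members_new:
            for nb in grid.neighbors[cell]:
                nb = int(nb)
                if eligible[nb] and not occupied[nb]:
                    mult[nb] = mult.get(nb, 0) + 1

    mult: dict[int, int] = {}
    frontier_of([seed_cell])

    first_batch = True
    while len(members) < size:
        mult = {c: m for c, m in mult.items() if not occupied[c]}
        if not mult:
            raise StalledGrowthError(
                f"frontier emptied at {len(members)}/{size} cells"
            )
        cells = np.fromiter(mult.keys(), dtype=int)
        m_arr = np.fromiter(mult.values(), dtype=float)
        d = np.sqrt(((space.position(cells) - optimum) ** 2).sum(axis=1))
        probs = frontier_weights(d, x=x, multiplicity=m_arr)
        if first_batch:
            k = 2  # two neighbours of the seed join first
            first_batch = False
        else:
            k = math.ceil(0.25 * len(cells))
        k = min(k, len(cells))
        chosen = _weighted_sample_without_replacement(rng, cells, probs, k)
        overshoot = len(members) + len(chosen) - size
        if overshoot > 0:
            # drop the lowest-weight selected cells to hit the size exactly
            lookup = {int(c): float(probs[i]) for i, c in enumerate(cells)}
            order = sorted(range(len(chosen)), key=lambda i: (-lookup[int(chosen[i])], i))
            chosen = chosen[order[: len(chosen) - overshoot]]
        occupied[chosen] = True
        members.extend(int(c) for c in chosen)
        frontier_of(chosen)
        optimum = space.position(members).mean(axis=0)
    return np.array(sorted(members), dtype=int)


def _spherical_centroid(grid: HexGrid, cells: np.ndarray) -> tuple[float, float]:
    """Area-weighted spherical mean of member-cell centroids, as (lat, lon)."""
    w = grid.area_km2[cells][:, None]
    v = (grid.xyz[cells] * w).sum(axis=0)
    v /= np.linalg.norm(v)
    lat = math.degrees(math.asin(max(-1.0, min(1.0, v[2]))))
    lon = math.degrees(math.atan2(v[1], v[0]))
    return lat, lon


def make_option(
    grid: HexGrid,
    space: ClimateSpace,
    eligible: np.ndarray,
    seed_cell: int,
    size: int,
    option_id: int,
    hemisphere: str,
    x: float = DEFAULT_X,
    rng: np.random.Generator | None = None,
) -> RangeOption:
    cells = grow_range(grid, space, eligible, seed_cell, size, x=x, rng=rng)
    lat, lon = _spherical_centroid(grid, cells)
    final_opt = space.position(cells).mean(axis=0)
    return RangeOption(
        option_id=option_id,
        hemisphere=hemisphere,
        cells=cells,
        seed_cell=int(seed_cell),
        centroid_lat=lat,
        centroid_lon=lon,
        final_optimum=final_opt,
    )


def generate_option_set(
    grid: HexGrid,
    space: ClimateSpace,
    habitable: np.ndarray,
    n_per_hemisphere: dict[str, int] | None = None,
    sizes: dict[str, int] | None = None,
    s_h: np.ndarray | None = None,
    x: float = DEFAULT_X,
    rng: np.random.Generator | None = None,
    max_retries_per_option: int = 50,
) -> list[RangeOption]:
    """Generate the per-hemisphere pools of range options for one time slice.

    Options are seeded via :func:`seed_probabilities` (S_h defaults to zero
    everywhere — options are generated before any species exists in a fresh
    slice) and grown via :func:`grow_range`; stalled growths are re-seeded
    up to ``max_retries_per_option`` times each before a
    :class:`GenerationError` is raised.
    """
    n_per_hemisphere = DEFAULT_N_OPTIONS if n_per_hemisphere is None else n_per_hemisphere
    sizes = DEFAULT_RANGE_SIZES if sizes is None else sizes
    rng = np.random.default_rng() if rng is None else rng
    s_h = np.zeros(grid.n_cells) if s_h is None else np.asarray(s_h, dtype=float)
    habitable = np.asarray(habitable, dtype=bool)

    options: list[RangeOption] = []
    oid = 0
    for hemi in sorted(n_per_hemisphere):
        eligible = habitable & (grid.hemisphere == hemi)
        n_hab = int(eligible.sum())
        size = sizes[hemi]
        for _ in range(n_per_hemisphere[hemi]):
            last_err: Exception | None = None
            for _attempt in range(max_retries_per_option):
                try:
                    probs = seed_probabilities(s_h, eligible)
                    seed = int(rng.choice(grid.n_cells, p=probs))
                    options.append(
                        make_option(grid, space, eligible, seed, size, oid, hemi, x=x, rng=rng)
                    )
                    oid += 1
                    break
                except (StalledGrowthError, CannotSeedError) as err:
                    last_err = err
            else:
                raise GenerationError(
                    f"could not grow a {size}-cell range in {hemi} "
                    f"({n_hab} habitable cells) after {max_retries_per_option} "
                    f"attempts: {last_err}"
                )
    return options


def check_option(option: RangeOption, grid: HexGrid, habitable: np.ndarray, size: int) -> None:
    """Assert the structural invariants of a range option (test helper)."""
    cells = option.cells
    assert len(cells) == size, "wrong size"
    assert len(np.unique(cells)) == len(cells), "duplicate cells"
    assert habitable[cells].all(), "non-habitable member"
    assert (grid.hemisphere[cells] == option.hemisphere).all(), "hemisphere impurity"
    # contiguity under grid adjacency
    member = set(int(c) for c in cells)
    seen = {int(cells[0])}
    stack = [int(cells[0])]
    while stack:
        c = stack.pop()
        for nb in grid.neighbors[c]:
            nb = int(nb)
            if nb in member and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    assert len(seen) == len(member), "range not contiguous"
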
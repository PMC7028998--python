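"""Greedy assembly of the virtual avifauna by energetic-fitness maximisation.

Starting from an empty world (E_A = E_S), each step considers every ordered
pair of same-hemisphere range options as a candidate distribution — the
first option hosting the species in northern summer (NS), the second in
northern winter (NW) — and scores it with the annual energy budget

    E_prod = beta * (E_A^NS + E_A^NW) - 2 * (BE_U + alpha * d_m)

where E_A^s is the mean energy available over the seasonal range, BE_U = 1
is the basal energy use per season, and alpha * d_m the per-season
migration cost over the great-circle distance d_m (km) between the two
range centroids (zero for residents, whose two options coincide).  The best
candidate is added as a new species, its breeding season is the season with
the higher seasonal production, and the energy it assimilates is removed
from its cells (each cell loses the fraction beta of its current E_A in the
occupied season).  The loop stops at saturation: by default when the best
E_prod is no longer positive, alternatively when the best candidate's
annual assimilation falls below BE_U.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .energyscape import Energyscape, SeasonalEnergyField
from .flight import DEFAULT_ALPHA
from .hexgrid import great_circle_km
from .ranges import (
    DEFAULT_N_OPTIONS,
    DEFAULT_RANGE_SIZES,
    DEFAULT_X,
    RangeOption,
    generate_option_set,
)

NS, NW = 0, 1

STOP_RULES = ("eprod_nonpositive", "assim_below_beu")


@dataclass(frozen=True)
class SimParams:
    """All knobs of one simulation."""

    beta: float = 0.012            # type I functional-response slope
    alpha: float = DEFAULT_ALPHA   # per-km migration cost
    mu: float = 65.0               # NPP-to-energy-supply scaling
    be_u: float = 1.0              # basal energy use per season (arbitrary unit)
    x: float = DEFAULT_X           # climatic-constraint exponent of range growth
    n_options: dict = field(default_factory=lambda: dict(DEFAULT_N_OPTIONS))
    range_sizes: dict = field(default_factory=lambda: dict(DEFAULT_RANGE_SIZES))
    stop_rule: str = "eprod_nonpositive"
    n_max: int = 1_000_000         # safety cap on species per hemisphere
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.stop_rule not in STOP_RULES:
            raise ValueError(f"stop_rule must be one of {STOP_RULES}")

    def with_(self, **kw) -> "SimParams":
        return replace(self, **kw)


@dataclass
class VirtualSpecies:
    """One simulated species: a selected pair of seasonal range options."""

    species_id: int
    hemisphere: str
    breeding_option: int       # option_id of the breeding range
    nonbreeding_option: int
    breeding_season: str       # "NS" or "NW"
    d_m: float                 # km between the two range centroids
    e_assim_ns: float
    e_assim_nw: float
    e_prod: float

    @property
    def resident(self) -> bool:
        return self.breeding_option == self.nonbreeding_option


@dataclass
class Assemblage:
    """Result of one simulation: species in addition order plus world state."""

    species: list[VirtualSpecies]
    field: SeasonalEnergyField      # depleted energy field
    richness: np.ndarray            # S_h per cell
    options: list[RangeOption]
    params: SimParams
    slice_id: str = "present"
    best_eprod_log: list[float] = None

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_table(self) -> pd.DataFrame:
        rows = [
            dict(
                species_id=s.species_id,
                hemisphere=s.hemisphere,
                breeding_option=s.breeding_option,
                nonbreeding_option=s.nonbreeding_option,
                breeding_season=s.breeding_season,
                resident=s.resident,
                d_m_km=s.d_m,
                e_assim_ns=s.e_assim_ns,
                e_assim_nw=s.e_assim_nw,
                e_prod=s.e_prod,
            )
            for s in self.species
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "species_id", "hemisphere", "breeding_option", "nonbreeding_option",
                "breeding_season", "resident", "d_m_km", "e_assim_ns", "e_assim_nw",
                "e_prod",
            ],
        )

    def option_by_id(self, option_id: int) -> RangeOption:
        return self.options[option_id]

    def seasonal_ranges(self, s: VirtualSpecies) -> tuple[np.ndarray, np.ndarray]:
        """(breeding cells, non-breeding cells) of a species."""
        return (
            self.options[s.breeding_option].cells,
            self.options[s.nonbreeding_option].cells,
        )


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def seasonal_energy_available(option: RangeOption, fld: SeasonalEnergyField, season: int) -> float:
    """Mean energy available over the option's cells in one season."""
    return float(fld.e_a[season, option.cells].mean())


def candidate_fitness(
    e_a_ns: float, e_a_nw: float, d_m: float, params: SimParams
) -> tuple[float, float, float]:
    """(E_prod, E_assim^NS, E_assim^NW) of one candidate distribution."""
    assim_ns = params.beta * e_a_ns
    assim_nw = params.beta * e_a_nw
    e_prod = assim_ns + assim_nw - 2.0 * (params.be_u + params.alpha * d_m)
    return e_prod, assim_ns, assim_nw


def assign_breeding(e_assim_ns: float, e_assim_nw: float, d_m: float, params: SimParams) -> str:
    """Season with the higher seasonal production (cost is season-symmetric).

    The per-season production beta*E_A^s - (BE_U + alpha*d_m) carries the
    same cost in both seasons, so the comparison reduces to the seasonal
    assimilation; ties break to NS.
    """
    season_cost = params.be_u + params.alpha * d_m
    prod_ns = e_assim_ns - season_cost
    prod_nw = e_assim_nw - season_cost
    return "NS" if prod_ns >= prod_nw else "NW"


def enumerate_candidates(options: list[RangeOption]):
    """All ordered (NS option, NW option) pairs within one hemisphere pool.

    Identical pairs are the resident candidates; n options yield n^2
    candidates.
    """
    for i in options:
        for j in options:
            yield i, j


# ---------------------------------------------------------------------------
# Per-hemisphere greedy loop
# ---------------------------------------------------------------------------

class _HemisphereEngine:
    """Vectorised candidate scoring over one hemisphere's option pool."""

    def __init__(self, options: list[RangeOption], n_cells: int, params: SimParams):
        self.options = options
        self.params = params
        n = len(options)
        rows, cols, vals = [], [], []
        for k, opt in enumerate(options):
            rows.extend([k] * opt.size)
            cols.extend(int(c) for c in opt.cells)
            vals.extend([1.0 / opt.size] * opt.size)
        self.mean_op = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(n, n_cells)
        )
        lat = np.array([o.centroid_lat for o in options])
        lon = np.array([o.centroid_lon for o in options])
        self.d_matrix = great_circle_km(
            (lat[:, None], lon[:, None]), (lat[None, :], lon[None, :])
        )
        np.fill_diagonal(self.d_matrix, 0.0)
        self.cost = 2.0 * (params.be_u + params.alpha * self.d_matrix)

    def best_candidate(self, fld: SeasonalEnergyField):
        """argmax of E_prod over ordered pairs; first-occurrence tie-break.

        Returns (i, j, e_prod, e_assim_ns, e_assim_nw, d_m) with i the NS
        option index and j the NW option index.
        """
        ea_ns = self.mean_op @ fld.e_a[NS]
        ea_nw = self.mean_op @ fld.e_a[NW]
        p = self.params
        eprod = p.beta * (ea_ns[:, None] + ea_nw[None, :]) - self.cost
        flat = int(np.argmax(eprod))  # first max in C order: lowest (i, j)
        i, j = divmod(flat, eprod.shape[1])
        return (
            i,
            j,
            float(eprod[i, j]),
            float(p.beta * ea_ns[i]),
            float(p.beta * ea_nw[j]),
            float(self.d_matrix[i, j]),
        )


def deplete(fld: SeasonalEnergyField, ns_cells: np.ndarray, nw_cells: np.ndarray, beta: float) -> None:
    """Remove the assimilated fraction beta of E_A in the occupied cells.

    The NS range depletes the NS layer and the NW range the NW layer; a
    resident's congruent ranges therefore deplete both seasons, and a cell
    lying in both seasonal ranges of a migrant is depleted in both seasons
    independently.
    """
    fld.e_a[NS, ns_cells] *= 1.0 - beta
    fld.e_a[NW, nw_cells] *= 1.0 - beta


def _saturated(e_prod: float, assim_total: float, params: SimParams) -> bool:
    if params.stop_rule == "eprod_nonpositive":
        return e_prod <= 0.0
    return assim_total < params.be_u


def simulate_hemisphere(
    options: list[RangeOption],
    fld: SeasonalEnergyField,
    params: SimParams,
    hemisphere: str,
    first_species_id: int = 0,
    richness: np.ndarray | None = None,
    log: list[float] | None = None,
) -> list[VirtualSpecies]:
    """Run the greedy loop for one hemisphere, mutating ``fld`` (and richness)."""
    if not options:
        return []
    engine = _HemisphereEngine(options, fld.n_cells, params)
    species: list[VirtualSpecies] = []
    sid = first_species_id
    while len(species) < params.n_max:
        i, j, e_prod, assim_ns, assim_nw, d_m = engine.best_candidate(fld)
        if log is not None:
            log.append(e_prod)
        if _saturated(e_prod, assim_ns + assim_nw, params):
            break
        season = assign_breeding(assim_ns, assim_nw, d_m, params)
        opt_ns, opt_nw = options[i], options[j]
        breeding, nonbreeding = (opt_ns, opt_nw) if season == "NS" else (opt_nw, opt_ns)
        species.append(
            VirtualSpecies(
                species_id=sid,
                hemisphere=hemisphere,
                breeding_option=breeding.option_id,
                nonbreeding_option=nonbreeding.option_id,
                breeding_season=season,
                d_m=d_m,
                e_assim_ns=assim_ns,
                e_assim_nw=assim_nw,
                e_prod=e_prod,
            )
        )
        sid += 1
        deplete(fld, opt_ns.cells, opt_nw.cells, params.beta)
        if richness is not None:
            covered = np.union1d(opt_ns.cells, opt_nw.cells)
            richness[covered] += 1
    return species


def run_simulation(
    scape: Energyscape,
    params: SimParams,
    options: list[RangeOption] | None = None,
    rng: np.random.Generator | None = None,
) -> Assemblage:
    """Full assembly for one time slice: both hemispheres to saturation.

    The energy field is copied, so ``scape`` can be reused across runs.  If
    no option pool is passed, one is generated from ``params`` (fresh
    world: S_h = 0) with randomness drawn from ``rng`` (or ``params.seed``).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if options is None:
        options = generate_option_set(
            scape.grid,
            scape.space,
            scape.climate.habitable,
            n_per_hemisphere=params.n_options,
            sizes=params.range_sizes,
            x=params.x,
            rng=rng,
        )
    fld = scape.field.copy()
    richness = np.zeros(scape.grid.n_cells, dtype=int)
    log: list[float] = []
    species: list[VirtualSpecies] = []
    for hemi in sorted(params.n_options):
        pool = [o for o in options if o.hemisphere == hemi]
        species.extend(
            simulate_hemisphere(
                pool, fld, params, hemi,
                first_species_id=len(species), richness=richness, log=log,
            )
        )
    fld.check()
    return Assemblage(
        species=species,
        field=fld,
        richness=richness,
        options=options,
        params=params,
        slice_id=scape.slice_id,
        best_eprod_log=log,
    )
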
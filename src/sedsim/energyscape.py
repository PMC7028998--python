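"""Seasonal climate summaries, climatic space, ice mask and energy supply.

Monthly per-cell temperature, precipitation and NPP are reduced to the two
seasons the simulator knows about — northern summer (NS, May–August) and
northern winter (NW, November–February) — and NPP is converted to an energy
supply acting as a carrying capacity for birds:

    E_S = mu * log10(NPP + 1)        (negative NPP clamped to zero)

Range growth is constrained in a 2-D climatic space of z-standardised mean
annual temperature and z-standardised log10(P + 1) mean annual
precipitation; standardisation constants are computed over habitable
(ice-free) cells only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hexgrid import HexGrid

#: Month indices (0 = January) of the two seasons.
NS_MONTHS = (4, 5, 6, 7)        # May..August
NW_MONTHS = (10, 11, 0, 1)      # November..February

#: Default NPP-to-energy-supply scaling.
DEFAULT_MU = 65.0


class InputError(ValueError):
    """Malformed or incomplete climate/NPP input."""


class DegenerateClimateSpaceError(ValueError):
    """All habitable cells share the same value in one climatic dimension."""


def _require_monthly(monthly: np.ndarray) -> np.ndarray:
    monthly = np.asarray(monthly, dtype=float)
    if monthly.ndim != 2 or monthly.shape[0] != 12:
        raise InputError(
            f"expected 12 monthly layers of shape (12, n_cells), got {monthly.shape}"
        )
    return monthly


def seasonal_means(monthly: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (NS, NW) means of a (12, n_cells) monthly field.

    NS averages May–August; NW averages November, December, January and
    February.  The remaining four months do not enter either season.
    """
    monthly = _require_monthly(monthly)
    ns = monthly[list(NS_MONTHS)].mean(axis=0)
    nw = monthly[list(NW_MONTHS)].mean(axis=0)
    return ns, nw


@dataclass
class SeasonalClimate:
    """Seasonal and annual climate per cell, plus the habitability mask."""

    t_ns: np.ndarray
    t_nw: np.ndarray
    p_ns: np.ndarray
    p_nw: np.ndarray
    t_ann: np.ndarray
    p_ann: np.ndarray
    habitable: np.ndarray  # bool; False on ice regardless of climate

    @classmethod
    def from_monthly(
        cls,
        monthly_temp: np.ndarray,
        monthly_precip: np.ndarray,
        ice: np.ndarray | None = None,
    ) -> "SeasonalClimate":
        t = _require_monthly(monthly_temp)
        p = _require_monthly(monthly_precip)
        if t.shape != p.shape:
            raise InputError("temperature and precipitation shapes differ")
        n = t.shape[1]
        habitable = np.ones(n, dtype=bool) if ice is None else ~np.asarray(ice, dtype=bool)
        t_ns, t_nw = seasonal_means(t)
        p_ns, p_nw = seasonal_means(p)
        return cls(
            t_ns=t_ns, t_nw=t_nw, p_ns=p_ns, p_nw=p_nw,
            t_ann=t.mean(axis=0), p_ann=p.mean(axis=0), habitable=habitable,
        )


def apply_ice_mask(climate: SeasonalClimate, ice: np.ndarray) -> SeasonalClimate:
    """Mark ice-covered cells non-habitable (in place) and return the climate."""
    climate.habitable = climate.habitable & ~np.asarray(ice, dtype=bool)
    return climate


@dataclass
class ClimateSpace:
    """z-standardised (T_ann, log10(P_ann + 1)) coordinates per cell.

    Standardisation constants are estimated over habitable cells with the
    sample standard deviation; a dimension with zero variance makes the
    space degenerate in that dimension (its coordinate contributes 0 to
    climatic distances) unless ``strict`` construction raised instead.
    """

    z_t: np.ndarray
    z_logp: np.ndarray
    t_mean: float
    t_sd: float
    logp_mean: float
    logp_sd: float

    def position(self, cells) -> np.ndarray:
        """(k, 2) climatic-space coordinates of the given cells."""
        return np.column_stack([self.z_t[cells], self.z_logp[cells]])


def build_climate_space(
    t_ann: np.ndarray,
    p_ann: np.ndarray,
    habitable: np.ndarray | None = None,
    strict: bool = True,
) -> ClimateSpace:
    t_ann = np.asarray(t_ann, dtype=float)
    p_ann = np.asarray(p_ann, dtype=float)
    logp = np.log10(np.maximum(p_ann, 0.0) + 1.0)
    hab = np.ones_like(t_ann, dtype=bool) if habitable is None else np.asarray(habitable, bool)
    if hab.sum() < 2:
        raise DegenerateClimateSpaceError("need at least 2 habitable cells")
    zs = []
    consts = []
    for vals in (t_ann, logp):
        m = float(np.mean(vals[hab]))
        sd = float(np.std(vals[hab], ddof=1))
        if sd == 0.0:
            if strict:
                raise DegenerateClimateSpaceError(
                    "zero variance across habitable cells in one climatic dimension"
                )
            zs.append(np.zeros_like(vals))
        else:
            zs.append((vals - m) / sd)
        consts.extend([m, sd])
    return ClimateSpace(
        z_t=zs[0], z_logp=zs[1],
        t_mean=consts[0], t_sd=consts[1], logp_mean=consts[2], logp_sd=consts[3],
    )


def climatic_distance(point: np.ndarray, optimum) -> np.ndarray | float:
    """Euclidean distance in the 2-D climatic space."""
    point = np.asarray(point, dtype=float)
    optimum = np.asarray(optimum, dtype=float)
    d = np.sqrt(((point - optimum) ** 2).sum(axis=-1))
    return float(d) if np.ndim(d) == 0 else d


SEASONS = ("NS", "NW")


@dataclass
class SeasonalEnergyField:
    """Energy supply E_S and still-available energy E_A per cell and season.

    Row 0 is NS, row 1 is NW.  E_A starts equal to E_S and is depleted by
    the simulator; the invariant 0 <= E_A <= E_S holds throughout.
    """

    e_s: np.ndarray  # (2, n_cells), immutable reference supply
    e_a: np.ndarray  # (2, n_cells), mutable

    @property
    def n_cells(self) -> int:
        return self.e_s.shape[1]

    def copy(self) -> "SeasonalEnergyField":
        return SeasonalEnergyField(e_s=self.e_s.copy(), e_a=self.e_a.copy())

    def check(self) -> None:
        if np.any(self.e_a < -1e-12) or np.any(self.e_a - self.e_s > 1e-9):
            raise AssertionError("energy bounds violated: 0 <= E_A <= E_S")


def energy_supply(
    npp_ns: np.ndarray,
    npp_nw: np.ndarray,
    mu: float = DEFAULT_MU,
    habitable: np.ndarray | None = None,
) -> SeasonalEnergyField:
    """Convert seasonal NPP (gC m^-2 month^-1) into the seasonal energy field.

    Negative NPP is clamped to zero before the log transform; ice
    (non-habitable) cells get E_S = E_A = 0.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    e_s = np.empty((2, len(np.atleast_1d(npp_ns))))
    for row, npp in enumerate((npp_ns, npp_nw)):
        npp = np.asarray(npp, dtype=float)
        if not np.all(np.isfinite(npp)):
            raise InputError("non-finite NPP values")
        e_s[row] = mu * np.log10(np.maximum(npp, 0.0) + 1.0)
    if habitable is not None:
        e_s[:, ~np.asarray(habitable, dtype=bool)] = 0.0
    return SeasonalEnergyField(e_s=e_s, e_a=e_s.copy())


def energy_supply_from_monthly(
    monthly_npp: np.ndarray,
    mu: float = DEFAULT_MU,
    habitable: np.ndarray | None = None,
) -> SeasonalEnergyField:
    """Seasonal NPP is the mean of the season's monthly values before the log."""
    ns, nw = seasonal_means(monthly_npp)
    return energy_supply(ns, nw, mu=mu, habitable=habitable)


@dataclass
class Energyscape:
    """Everything the simulator needs about one time slice's environment."""

    grid: HexGrid
    climate: SeasonalClimate
    space: ClimateSpace
    field: SeasonalEnergyField
    slice_id: str = "present"
    mu: float = DEFAULT_MU

    @classmethod
    def from_monthly(
        cls,
        grid: HexGrid,
        monthly_temp: np.ndarray,
        monthly_precip: np.ndarray,
        monthly_npp: np.ndarray,
        ice: np.ndarray | None = None,
        mu: float = DEFAULT_MU,
        slice_id: str = "present",
    ) -> "Energyscape":
        climate = SeasonalClimate.from_monthly(monthly_temp, monthly_precip, ice=ice)
        space = build_climate_space(climate.t_ann, climate.p_ann, climate.habitable)
        fld = energy_supply_from_monthly(monthly_npp, mu=mu, habitable=climate.habitable)
        return cls(grid=grid, climate=climate, space=space, field=fld,
                   slice_id=slice_id, mu=mu)
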
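"""Self-contained synthetic planets: climate, productivity and ice.

These fixtures emulate the structure of the climate-model inputs the
simulator expects, on the same grid and unit conventions (temperature in
deg C, precipitation in mm/month, NPP in gC m^-2 month^-1): a latitudinal
annual-mean temperature gradient with anti-phased seasonal cycles peaking
in July in the north and January in the south; wet tropics, dry subtropics
and moderately wet temperate belts; productivity from a logistic
temperature limit and a saturating moisture limit (Miami-model constants);
and a configurable polar ice extent for glacial scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .energyscape import Energyscape
from .hexgrid import HexGrid, build_geodesic_grid

#: Subdivision frequency of the default full-resolution world (~23,100 km^2 cells).
DEFAULT_FREQUENCY = 47


@dataclass(frozen=True)
class PlanetSpec:
    """Parameters of a synthetic planet.

    Temperature: annual mean falls from ``equator_temp_c`` at the equator by
    ``pole_temp_drop_c`` toward the poles (as sin^2 of latitude); the
    seasonal cycle has amplitude ``seasonal_amplitude_c`` * sin|lat|,
    anti-phased between hemispheres (July peak in the north).  Monthly
    precipitation follows a three-belt profile (wet tropics, dry
    subtropics, moderate temperate) with a mild summer-wet modulation.
    Cells poleward of the ice latitudes are ice.  Gaussian noise with the
    given standard deviations is added per cell and month.
    """

    frequency: int = DEFAULT_FREQUENCY
    equator_temp_c: float = 27.0
    pole_temp_drop_c: float = 50.0
    seasonal_amplitude_c: float = 22.0       # amplitude at the pole
    precip_tropics_mm: float = 150.0         # mm/month at the equator
    precip_temperate_mm: float = 60.0        # mm/month peak of the ~50 deg belt
    precip_base_mm: float = 15.0
    precip_seasonality: float = 0.3          # fractional summer-wet modulation
    npp_max_annual: float = 3000.0           # gC m^-2 yr^-1 saturation
    npp_temp_a: float = 1.315                # logistic temperature constants
    npp_temp_b: float = 0.119
    npp_precip_c: float = 0.000664           # per mm annual precipitation
    ice_latitude_north: float = 72.0
    ice_latitude_south: float = -65.0
    temp_noise_sd_c: float = 0.8
    precip_noise_sd_mm: float = 8.0
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.seasonal_amplitude_c < 0:
            raise ValueError("seasonal amplitude must be non-negative")
        if not (0.0 < self.ice_latitude_north <= 90.0):
            raise ValueError("northern ice latitude must lie in (0, 90]")
        if not (-90.0 <= self.ice_latitude_south < 0.0):
            raise ValueError("southern ice latitude must lie in [-90, 0)")


@dataclass
class Planet:
    """Monthly fields (12, n_cells) of one synthetic planet plus its grid."""

    grid: HexGrid
    temp_c: np.ndarray
    precip_mm: np.ndarray
    npp: np.ndarray
    ice: np.ndarray
    spec: PlanetSpec


def _month_phase(month_idx: np.ndarray) -> np.ndarray:
    """cos phase peaking in July (month index 6) in the north."""
    return np.cos(2.0 * math.pi * (month_idx - 6) / 12.0)


def make_climate(spec: PlanetSpec, grid: HexGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Monthly temperature (deg C), precipitation (mm/month) and ice mask."""
    lat = grid.lat
    rad = np.radians(lat)
    t_ann = spec.equator_temp_c - spec.pole_temp_drop_c * np.sin(rad) ** 2
    amp = spec.seasonal_amplitude_c * np.abs(np.sin(rad))
    months = np.arange(12)
    phase = _month_phase(months)[:, None] * np.sign(rad)[None, :]
    temp = t_ann[None, :] + amp[None, :] * phase

    abs_lat = np.abs(lat)
    p_profile = (
        spec.precip_tropics_mm * np.exp(-((lat / 15.0) ** 2))
        + spec.precip_temperate_mm * np.exp(-(((abs_lat - 50.0) / 15.0) ** 2))
        + spec.precip_base_mm
    )
    precip = p_profile[None, :] * (1.0 + spec.precip_seasonality * phase)

    rng = np.random.default_rng(spec.seed)
    if spec.temp_noise_sd_c > 0:
        temp = temp + rng.normal(0.0, spec.temp_noise_sd_c, temp.shape)
    if spec.precip_noise_sd_mm > 0:
        precip = precip + rng.normal(0.0, spec.precip_noise_sd_mm, precip.shape)
    precip = np.maximum(precip, 0.0)

    ice = (lat >= spec.ice_latitude_north) | (lat <= spec.ice_latitude_south)
    return temp, precip, ice


def make_npp(
    temp_c: np.ndarray,
    precip_mm: np.ndarray,
    spec: PlanetSpec | None = None,
) -> np.ndarray:
    """Monthly NPP (gC m^-2 month^-1) from monthly climate.

    Liebig's minimum of a logistic temperature response and a saturating
    moisture response (classic climate-productivity constants; the moisture
    term sees the month's precipitation on an annualised scale), divided by
    12 to put the annual-scale saturation on a monthly basis.  Zero
    precipitation gives zero productivity; cold months are strongly
    suppressed by the temperature term.
    """
    spec = PlanetSpec() if spec is None else spec
    a_max = spec.npp_max_annual
    npp_t = a_max / (1.0 + np.exp(spec.npp_temp_a - spec.npp_temp_b * np.asarray(temp_c)))
    annualised_p = 12.0 * np.maximum(np.asarray(precip_mm), 0.0)
    npp_p = a_max * (1.0 - np.exp(-spec.npp_precip_c * annualised_p))
    return np.minimum(npp_t, npp_p) / 12.0


def make_planet(spec: PlanetSpec | None = None, grid: HexGrid | None = None) -> Planet:
    """Materialise a planet: grid, monthly climate, NPP and ice mask."""
    spec = PlanetSpec() if spec is None else spec
    if grid is None:
        grid = build_geodesic_grid(spec.frequency)
    temp, precip, ice = make_climate(spec, grid)
    npp = make_npp(temp, precip, spec)
    return Planet(grid=grid, temp_c=temp, precip_mm=precip, npp=npp, ice=ice, spec=spec)


def glacial_scenario(
    spec: PlanetSpec,
    delta_t_c: float = 6.0,
    ice_latitude_north: float = 50.0,
    ice_latitude_south: float | None = None,
) -> PlanetSpec:
    """A uniformly cooled planet with expanded ice; all other knobs kept."""
    if delta_t_c < 0:
        raise ValueError("cooling must be non-negative")
    kw = dict(
        equator_temp_c=spec.equator_temp_c - delta_t_c,
        ice_latitude_north=ice_latitude_north,
    )
    if ice_latitude_south is not None:
        kw["ice_latitude_south"] = ice_latitude_south
    return replace(spec, **kw)


def planet_energyscape(planet: Planet, mu: float = 65.0, slice_id: str = "present") -> Energyscape:
    """Reduce a planet's monthly fields to the simulator's seasonal inputs."""
    return Energyscape.from_monthly(
        planet.grid, planet.temp_c, planet.precip_mm, planet.npp,
        ice=planet.ice, mu=mu, slice_id=slice_id,
    )


# Named fixture planets --------------------------------------------------

def fixture_spec(name: str, frequency: int = DEFAULT_FREQUENCY, seed: int = 1234) -> PlanetSpec:
    """Named fixtures: default, no-seasonality, mirror, glacial."""
    base = PlanetSpec(frequency=frequency, seed=seed)
    if name == "default":
        return base
    if name == "no-seasonality":
        return replace(
            base,
            seasonal_amplitude_c=0.0,
            precip_seasonality=0.0,
            temp_noise_sd_c=0.0,
            precip_noise_sd_mm=0.0,
        )
    if name == "mirror":
        return replace(
            base,
            ice_latitude_south=-base.ice_latitude_north,
            temp_noise_sd_c=0.0,
            precip_noise_sd_mm=0.0,
        )
    if name == "glacial":
        return glacial_scenario(base)
    raise ValueError(f"unknown fixture {name!r}; expected default, no-seasonality, mirror or glacial")
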
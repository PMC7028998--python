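"""Diversity patterns, migration statistics, calibration scans, time series.

An assemblage is reduced to the three per-cell richness maps used both to
describe the simulated world and to score it against gridded empirical
counts: richness in breeding migrants (species present only during their
breeding season), richness in non-breeding migrants, and richness in
residents.  Calibration scores a simulation by the sum of the three
Pearson correlations between simulated and empirical maps; the parameter
scans rerun the full simulation per grid point from a pristine energy
field with shared seeds.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .energyscape import Energyscape
from .simulator import Assemblage, SimParams, run_simulation


@dataclass
class PatternSet:
    """The three per-cell richness maps of one assemblage (or of the data)."""

    breeding_migrants: np.ndarray
    nonbreeding_migrants: np.ndarray
    residents: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.arange(len(self.residents)),
                "richness_breeding_migrants": self.breeding_migrants,
                "richness_nonbreeding_migrants": self.nonbreeding_migrants,
                "richness_residents": self.residents,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PatternSet":
        df = df.sort_values("cell_id")
        return cls(
            breeding_migrants=df["richness_breeding_migrants"].to_numpy(int),
            nonbreeding_migrants=df["richness_nonbreeding_migrants"].to_numpy(int),
            residents=df["richness_residents"].to_numpy(int),
        )


def diversity_patterns(asm: Assemblage, overlap_as_resident: bool = False) -> PatternSet:
    """Count breeding-migrant, non-breeding-migrant and resident richness.

    Cells lying in both seasonal ranges of a migrant host that species
    year-round, so they count toward neither migrant map ("only during" the
    season); with ``overlap_as_resident`` they are instead counted as
    resident occurrences.
    """
    n = asm.field.n_cells
    breed = np.zeros(n, dtype=int)
    nonbreed = np.zeros(n, dtype=int)
    resident = np.zeros(n, dtype=int)
    for s in asm.species:
        b, w = asm.seasonal_ranges(s)
        if s.resident:
            resident[b] += 1
            continue
        overlap = np.intersect1d(b, w, assume_unique=True)
        breed[np.setdiff1d(b, overlap, assume_unique=True)] += 1
        nonbreed[np.setdiff1d(w, overlap, assume_unique=True)] += 1
        if overlap_as_resident:
            resident[overlap] += 1
    return PatternSet(breeding_migrants=breed, nonbreeding_migrants=nonbreed, residents=resident)


def seasonal_difference(patterns: PatternSet) -> np.ndarray:
    """Breeding-migrant richness minus non-breeding-migrant richness per cell."""
    return patterns.breeding_migrants - patterns.nonbreeding_migrants


def migration_stats(asm: Assemblage, region: str | None = None) -> tuple[float, float]:
    """(proportion of migrants, mean migration distance among migrants).

    ``region`` filters species by hemisphere label ("WH" = Americas,
    "EH" = Old World).  An empty selection yields (nan, nan); a selection
    without migrants yields (0.0, nan).
    """
    species = [s for s in asm.species if region is None or s.hemisphere == region]
    if not species:
        return float("nan"), float("nan")
    migrants = [s for s in species if s.d_m > 0]
    prop = len(migrants) / len(species)
    mean_d = float(np.mean([s.d_m for s in migrants])) if migrants else float("nan")
    return prop, mean_d


def pattern_correlation(
    simulated: PatternSet, empirical: PatternSet
) -> tuple[float, float, float, float]:
    """Per-pattern Pearson r over all cells and their sum (the composite).

    A pattern with zero variance on either side has no defined correlation;
    it is reported as nan, excluded from the composite, and warned about.
    """
    rs = []
    for name in ("breeding_migrants", "nonbreeding_migrants", "residents"):
        a = np.asarray(getattr(simulated, name), dtype=float)
        b = np.asarray(getattr(empirical, name), dtype=float)
        if a.shape != b.shape:
            raise ValueError("pattern grids differ in length")
        if np.std(a) == 0.0 or np.std(b) == 0.0:
            warnings.warn(f"zero-variance pattern {name!r}: correlation undefined")
            rs.append(float("nan"))
        else:
            rs.append(float(stats.pearsonr(a, b)[0]))
    composite = float(np.nansum(rs)) if not all(np.isnan(rs)) else float("nan")
    return rs[0], rs[1], rs[2], composite


# ---------------------------------------------------------------------------
# Parameter scans
# ---------------------------------------------------------------------------

DEFAULT_BETA_GRID = np.round(np.arange(0.003, 0.0351, 0.001), 4)

SCANNABLE = ("alpha", "mu", "range_size", "x")


def _scan_point(
    scape: Energyscape,
    params: SimParams,
    empirical: PatternSet | None,
) -> dict:
    asm = run_simulation(scape, params)
    prop, mean_d = migration_stats(asm)
    row = dict(
        n_species=asm.n_species,
        proportion_migrants=prop,
        mean_d_m_km=mean_d,
        r_breeding=np.nan,
        r_nonbreeding=np.nan,
        r_residents=np.nan,
        composite=np.nan,
    )
    if empirical is not None and asm.n_species > 0:
        rb, rn, rr, comp = pattern_correlation(diversity_patterns(asm), empirical)
        row.update(r_breeding=rb, r_nonbreeding=rn, r_residents=rr, composite=comp)
    return row


def beta_scan(
    scape: Energyscape,
    base_params: SimParams,
    betas=DEFAULT_BETA_GRID,
    empirical: PatternSet | None = None,
) -> pd.DataFrame:
    """One full simulation per beta, shared seed, pristine field each time."""
    rows = []
    for b in betas:
        row = _scan_point(scape, base_params.with_(beta=float(b)), empirical)
        rows.append(dict(parameter="beta", value=float(b), **row))
    return pd.DataFrame(rows)


def sensitivity_scan(
    scape: Energyscape,
    base_params: SimParams,
    parameter: str,
    grid,
    empirical: PatternSet | None = None,
) -> pd.DataFrame:
    """Scan alpha, mu, range_size or x, keeping all other parameters fixed.

    ``range_size`` values scale both hemispheres' sizes by value/size_WH;
    pass explicit dicts to control hemispheres separately.
    """
    if parameter not in SCANNABLE:
        raise ValueError(f"parameter must be one of {SCANNABLE}")
    rows = []
    for v in grid:
        if parameter == "alpha":
            p = base_params.with_(alpha=float(v))
        elif parameter == "mu":
            p = base_params.with_(mu=float(v))
            scaled = Energyscape(
                grid=scape.grid,
                climate=scape.climate,
                space=scape.space,
                field=scape.field.copy(),
                slice_id=scape.slice_id,
                mu=float(v),
            )
            scaled.field.e_s *= float(v) / scape.mu
            scaled.field.e_a = scaled.field.e_s.copy()
            row = _scan_point(scaled, p, empirical)
            rows.append(dict(parameter="mu", value=float(v), **row))
            continue
        elif parameter == "x":
            p = base_params.with_(x=float(v))
        else:  # range_size
            if isinstance(v, dict):
                sizes = v
                label = float(sizes["WH"])
            else:
                ratio = float(v) / base_params.range_sizes["WH"]
                sizes = {
                    h: max(1, round(s * ratio))
                    for h, s in base_params.range_sizes.items()
                }
                label = float(v)
            p = base_params.with_(range_sizes=sizes)
            row = _scan_point(scape, p, empirical)
            rows.append(dict(parameter="range_size", value=label, **row))
            continue
        row = _scan_point(scape, p, empirical)
        rows.append(dict(parameter=parameter, value=float(v), **row))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Time series across slices
# ---------------------------------------------------------------------------

def timeseries_runner(
    slices: list[Energyscape],
    params: SimParams,
    master_seed: int | None = None,
) -> tuple[pd.DataFrame, list[PatternSet], list[Assemblage]]:
    """Independent simulation per time slice with derived sub-seeds.

    The first slice is treated as the present; ``*_rel`` columns are
    normalised to that slice's values, so the present row equals 1 where
    defined.  Returns (time series table, per-slice patterns, assemblages).
    """
    master_seed = params.seed if master_seed is None else master_seed
    rows, patterns, assemblages = [], [], []
    for scape in slices:
        # sub-seed from (master seed, slice id): a slice keeps its randomness
        # no matter which other slices run alongside it
        tag = zlib.crc32(str(scape.slice_id).encode())
        sub = int(np.random.SeedSequence([master_seed, tag]).generate_state(1)[0] % (2**31))
        asm = run_simulation(scape, params.with_(seed=sub))
        ps = diversity_patterns(asm)
        row = dict(slice_id=scape.slice_id, n_species=asm.n_species)
        for region, name in ((None, "global"), ("WH", "americas"), ("EH", "old_world")):
            prop, mean_d = migration_stats(asm, region)
            row[f"proportion_migrants_{name}"] = prop
            row[f"mean_d_m_km_{name}"] = mean_d
        rows.append(row)
        patterns.append(ps)
        assemblages.append(asm)
    ts = pd.DataFrame(rows)
    for col in [c for c in ts.columns if c.startswith(("proportion", "mean_d"))] + ["n_species"]:
        present = ts[col].iloc[0]
        ts[col + "_rel"] = ts[col] / present if present and np.isfinite(present) else np.nan
    return ts, patterns, assemblages


def contrast_maps(patterns: list[PatternSet], present_index: int = 0) -> list[PatternSet]:
    """Per-slice (slice minus present) difference maps of the three patterns."""
    ref = patterns[present_index]
    return [
        PatternSet(
            breeding_migrants=p.breeding_migrants - ref.breeding_migrants,
            nonbreeding_migrants=p.nonbreeding_migrants - ref.nonbreeding_migrants,
            residents=p.residents - ref.residents,
        )
        for p in patterns
    ]
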
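"""Per-hexagon CSV I/O, run configuration and run metadata.

All gridded inputs and outputs travel as per-hexagon CSV tables keyed by
``cell_id`` (monthly variables as ``<var>_01``..``<var>_12`` columns), plus
a JSON run-metadata record holding every simulation-affecting setting, so
any published output is reproducible from its metadata alone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .energyscape import InputError
from .hexgrid import HexGrid, build_geodesic_grid
from .simulator import Assemblage, SimParams
from .synthetic import Planet, PlanetSpec

MONTH_COLS = {var: [f"{var}_{m:02d}" for m in range(1, 13)] for var in ("temp", "precip", "npp")}


def _monthly_from_frame(df: pd.DataFrame, var: str) -> np.ndarray:
    cols = MONTH_COLS[var]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"missing monthly column(s) for {var!r}: {', '.join(missing)}")
    return df[cols].to_numpy(float).T


def planet_to_csv(planet: Planet, path) -> None:
    df = pd.DataFrame({"cell_id": np.arange(planet.grid.n_cells)})
    df["lat"] = planet.grid.lat
    df["lon"] = planet.grid.lon
    for var, monthly in (("temp", planet.temp_c), ("precip", planet.precip_mm), ("npp", planet.npp)):
        for m in range(12):
            df[MONTH_COLS[var][m]] = monthly[m]
    df["ice"] = planet.ice.astype(int)
    df.to_csv(path, index=False)
    meta = {"frequency": planet.grid.frequency, "spec": asdict(planet.spec)}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def planet_from_csv(path, grid: HexGrid | None = None) -> Planet:
    df = pd.read_csv(path)
    if grid is None:
        meta_path = Path(str(path) + ".meta.json")
        if not meta_path.exists():
            raise InputError(
                f"no grid given and no metadata file {meta_path.name}; "
                "cannot reconstruct the grid"
            )
        meta = json.loads(meta_path.read_text())
        grid = build_geodesic_grid(int(meta["frequency"]))
        spec = PlanetSpec(**meta["spec"])
    else:
        spec = PlanetSpec(frequency=grid.frequency)
    if len(df) != grid.n_cells:
        raise InputError(f"table has {len(df)} rows but the grid has {grid.n_cells} cells")
    df = df.sort_values("cell_id")
    temp = _monthly_from_frame(df, "temp")
    precip = _monthly_from_frame(df, "precip")
    npp = _monthly_from_frame(df, "npp")
    if np.nanmin(temp) < -95.0 or np.nanmax(temp) > 65.0:
        warnings.warn("temperature outside [-95, 65] degC; check units")
    if (npp < 0).any():
        warnings.warn("negative NPP values present; they will be clamped to 0")
    ice = df["ice"].to_numpy(bool) if "ice" in df.columns else np.zeros(len(df), bool)
    return Planet(grid=grid, temp_c=temp, precip_mm=precip, npp=npp, ice=ice, spec=spec)


def assemblage_to_dir(asm: Assemblage, out_dir, extra_meta: dict | None = None) -> Path:
    """Write species table, option membership, richness and run metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    asm.species_table().to_csv(out / "species.csv", index=False)
    pd.DataFrame(
        {
            "option_id": [o.option_id for o in asm.options],
            "hemisphere": [o.hemisphere for o in asm.options],
            "seed_cell": [o.seed_cell for o in asm.options],
            "centroid_lat": [o.centroid_lat for o in asm.options],
            "centroid_lon": [o.centroid_lon for o in asm.options],
            "cells": [" ".join(str(int(c)) for c in o.cells) for o in asm.options],
        }
    ).to_csv(out / "options.csv", index=False)
    pd.DataFrame(
        {"cell_id": np.arange(len(asm.richness)), "richness": asm.richness}
    ).to_csv(out / "richness.csv", index=False)
    meta = {
        "slice_id": asm.slice_id,
        "n_species": asm.n_species,
        "params": asdict(asm.params),
        **(extra_meta or {}),
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=1))
    return out


def load_run(run_dir, grid: HexGrid) -> tuple[pd.DataFrame, dict[int, np.ndarray], dict]:
    """Load a saved run: species table, option cell sets, metadata."""
    run_dir = Path(run_dir)
    species = pd.read_csv(run_dir / "species.csv")
    opts = pd.read_csv(run_dir / "options.csv")
    cells = {
        int(r.option_id): np.array([int(c) for c in str(r.cells).split()], dtype=int)
        for r in opts.itertuples()
    }
    meta = json.loads((run_dir / "run_metadata.json").read_text())
    return species, cells, meta


def load_config(path) -> dict:
    """Load a YAML run-configuration file (empty dict if path is None)."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InputError("configuration file must contain a mapping")
    return cfg


def params_from_config(cfg: dict, **overrides) -> SimParams:
    block = dict(cfg.get("params", {}))
    block.update({k: v for k, v in overrides.items() if v is not None})
    return SimParams(**block)
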
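"""Synthetic landscapes and parameter tables, plus printed-table fixtures.

The survey databases behind the real model (land-use grid, permanent-plot
stand morphology, species conversion coefficients, per-ecozone volume
equations) are not publicly available.  This module generates internally
consistent stand-ins with realistic magnitudes — carbon densities land inside
the 7–222 t C ha^-1 span observed across the 51 forest types — so that every
stage of the pipeline is exercisable and testable offline.  Synthetic values
are NOT the survey's values; only their schemas and ranges are faithful.

It also ships machine-readable transcriptions of the printed summary tables
(storage, Monte Carlo bounds, sequestration) used by the reporting layer's
fixtures check.  Printed cells below the table resolution ("<0.005",
"<0.05") are preserved as :class:`BelowThreshold` sentinels, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import M2_PER_CELL, GridCell, Landscape
from .typology import (DEFAULT_SPECIES_GROUPS, ECOZONES, ForestTypeRegistry,
                       SpeciesTable, StandParams, load_registry,
                       load_species_table, load_stand_params)

# ---------------------------------------------------------------------------
# Printed-table fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BelowThreshold:
    """A printed value below the table's resolution, e.g. "<0.005".

    Carries the exclusive upper bound; it is a distinct sentinel rather than
    zero so aggregation code cannot silently treat it as exact.
    """

    threshold: float

    def __str__(self) -> str:  # renders back as printed
        return f"<{self.threshold:g}"


def _parse_cell(x):
    if isinstance(x, str) and x.strip().startswith("<"):
        return BelowThreshold(float(x.strip()[1:]))
    return float(x)


_FIXTURE_FILES = {
    "storage": ("table1_carbon_storage.csv", ("c_a", "c_mt", "proportion_pct")),
    "uncertainty": ("table2_uncertainty.csv",
                    ("c_p97_5_mt", "c_p2_5_mt", "r_97_5_pct", "r_2_5_pct")),
    "sequestration": ("table3_sequestration.csv",
                      ("dc_a", "dc_mt", "proportion_pct")),
}


def load_fixture_tables() -> dict[str, pd.DataFrame]:
    """Load the bundled printed summary tables.

    Returns a dict with keys ``storage`` (51 type rows plus subtotal rows),
    ``uncertainty`` (26 type rows plus a total row) and ``sequestration``
    (51 type rows plus subtotal rows).  Sub-resolution cells come back as
    :class:`BelowThreshold`.
    """
    out = {}
    for key, (fname, value_cols) in _FIXTURE_FILES.items():
        with resources.files("forestcarbon.data").joinpath(fname).open() as fh:
            df = pd.read_csv(fh, dtype=str, keep_default_na=False)
        for col in value_cols:
            df[col] = df[col].map(_parse_cell)
        out[key] = df
    return out


def numeric(series: pd.Series) -> pd.Series:
    """Exact printed values of a fixture column; sentinels become NaN."""
    return series.map(lambda x: np.nan if isinstance(x, BelowThreshold) else float(x))


# ---------------------------------------------------------------------------
# Synthetic configuration
# ---------------------------------------------------------------------------

#: Per-group (low, high) ranges for the conversion parameters and stand
#: morphology of the generator.  Chosen so resulting carbon densities span
#: roughly 10–200 t C ha^-1 for tree types and 15–40 t C ha^-1 for bamboo.
DEFAULT_PARAM_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "conifer": {"ef": (1.2, 1.8), "d": (0.35, 0.55), "cf": (0.45, 0.52),
                "dbh": (25.0, 42.0), "h": (15.0, 28.0), "n": (300.0, 700.0)},
    "broadleaf": {"ef": (1.3, 1.8), "d": (0.45, 0.65), "cf": (0.45, 0.52),
                  "dbh": (15.0, 30.0), "h": (10.0, 22.0), "n": (400.0, 900.0)},
    "bamboo": {"ef": (1.1, 1.6), "d": (0.5, 0.8), "cf": (0.45, 0.52),
               "dbh": (5.0, 10.0), "h": (8.0, 15.0), "n": (2000.0, 5000.0)},
    "mixed": {"dbh": (15.0, 35.0), "h": (12.0, 25.0), "n": (500.0, 1000.0)},
}

_WOOD_TO_GROUP = {"coniferous": "conifer", "broadleaved": "broadleaf",
                  "bamboo": "bamboo", "mixed": "mixed"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Stated world of the generator.

    The landscape is a rectangular grid of 1-km cells with five ecozones in
    latitudinal bands (``ecozone_geometry="blobs"`` gives irregular patches
    instead); about 40% of each land cell is non-forest and 10% of cells are
    no-data (sea).  DBH/H standard deviations default to 20% of the mean,
    the magnitude needed to produce survey-scale type-level carbon intervals.
    """

    seed: int
    nrows: int = 20
    ncols: int = 20
    ecozone_geometry: str = "bands"
    nonforest_fraction: float = 0.4
    nodata_fraction: float = 0.1
    sd_frac_dbh: float = 0.2
    sd_frac_h: float = 0.2
    max_types_per_cell: int = 4
    growth_rate_range: tuple[float, float] = (0.01, 0.06)
    mortality_rate_range: tuple[float, float] = (0.002, 0.02)
    param_ranges: dict = field(default_factory=lambda: DEFAULT_PARAM_RANGES)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.ecozone_geometry not in ("bands", "blobs"):
            raise ValueError(f"unknown ecozone geometry {self.ecozone_geometry!r}")
        for grp, ranges in self.param_ranges.items():
            for name, (lo, hi) in ranges.items():
                if not (0 < lo <= hi):
                    raise ValueError(f"range {grp}.{name} = ({lo}, {hi}) invalid")


# ---------------------------------------------------------------------------
# Parameter-table generation
# ---------------------------------------------------------------------------

@dataclass
class ParameterTables:
    species_params: pd.DataFrame
    volume_equations: pd.DataFrame
    stand_params: pd.DataFrame

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "species_params": directory / "species_params.csv",
            "volume_equations": directory / "volume_equations.csv",
            "stand_params": directory / "stand_params.csv",
        }
        self.species_params.to_csv(paths["species_params"], index=False)
        self.volume_equations.to_csv(paths["volume_equations"], index=False)
        self.stand_params.to_csv(paths["stand_params"], index=False)
        return paths

    def to_species_table(self, fallback_ecozone: str | None = None,
                         directory: str | Path | None = None) -> SpeciesTable:
        import tempfile
        with tempfile.TemporaryDirectory() as tmp:
            paths = self.write(directory or tmp)
            return load_species_table(paths["species_params"],
                                      paths["volume_equations"],
                                      fallback_ecozone=fallback_ecozone)

    def to_stand_params(self) -> dict[str, StandParams]:
        import tempfile
        with tempfile.TemporaryDirectory() as tmp:
            paths = self.write(tmp)
            return load_stand_params(paths["stand_params"])


def _uniform(rng: np.random.Generator, lohi: tuple[float, float]) -> float:
    return float(rng.uniform(*lohi))


def generate_parameter_tables(config: SyntheticConfig,
                              registry: ForestTypeRegistry | None = None
                              ) -> ParameterTables:
    """Generate species, volume-equation and stand-parameter tables.

    Every species referenced by the registry gets an EF/D/CF row and a
    log-log (Schumacher–Hall type) stem-volume equation per ecozone, with
    mild per-ecozone coefficient jitter standing in for climatic morphology
    shifts.  The "mixed_conifer"/"mixed_broadleaf" pseudo-species get the
    mean EF, D and CF of their group's concrete species.  All values are
    synthetic stand-ins, not survey data.
    """
    registry = registry if registry is not None else load_registry()
    rng = np.random.default_rng(config.seed)

    species_ids = sorted({sp for ft in registry for sp in ft.species})
    concrete = [s for s in species_ids if not s.startswith("mixed_")]
    pseudo = [s for s in species_ids if s.startswith("mixed_")]

    sp_rows: list[dict] = []
    for sp in concrete:
        grp = DEFAULT_SPECIES_GROUPS.get(sp, "broadleaf")
        r = config.param_ranges[grp]
        sp_rows.append({"species": sp, "ef": round(_uniform(rng, r["ef"]), 3),
                        "d": round(_uniform(rng, r["d"]), 3),
                        "cf": round(_uniform(rng, r["cf"]), 3)})
    sp_df = pd.DataFrame(sp_rows)
    for sp in pseudo:
        grp = DEFAULT_SPECIES_GROUPS[sp]
        members = [s for s in concrete
                   if DEFAULT_SPECIES_GROUPS.get(s) == grp]
        sub = sp_df[sp_df["species"].isin(members)]
        sp_df = pd.concat([sp_df, pd.DataFrame([{
            "species": sp,
            "ef": round(float(sub["ef"].mean()), 3),
            "d": round(float(sub["d"].mean()), 3),
            "cf": round(float(sub["cf"].mean()), 3),
        }])], ignore_index=True)
    sp_df = sp_df.sort_values("species", ignore_index=True)

    # reference stem (DBH cm, H m) and plausible stem-volume range (m^3) per
    # group; the log-log intercept is anchored so exponent draws cannot drift
    # the predicted volume out of the realistic envelope
    stem_refs = {"conifer": ((30.0, 20.0), (0.4, 0.8)),
                 "broadleaf": ((22.0, 15.0), (0.15, 0.4)),
                 "bamboo": ((8.0, 12.0), (0.015, 0.04))}
    eq_rows = []
    for sp in sp_df["species"]:
        grp = DEFAULT_SPECIES_GROUPS.get(sp, "broadleaf")
        (dbh_ref, h_ref), vref_range = stem_refs[grp]
        v_ref = rng.uniform(*vref_range)
        c1 = rng.uniform(1.7, 2.0)
        c2 = rng.uniform(0.8, 1.1)
        c0 = float(np.log(v_ref) - c1 * np.log(dbh_ref) - c2 * np.log(h_ref))
        for zone in ECOZONES:
            jitter = rng.uniform(0.85, 1.15)
            eq_rows.append({
                "species": sp, "ecozone": zone, "form": "schumacher_hall",
                "c0": round(c0 + float(np.log(jitter)), 6),
                "c1": round(c1, 4), "c2": round(c2, 4),
                "c3": "",
                "dbh_min": 1.0, "dbh_max": 200.0, "h_min": 1.0, "h_max": 80.0,
            })
    eq_df = pd.DataFrame(eq_rows)

    st_rows = []
    for ft in registry:
        grp = _WOOD_TO_GROUP[ft.wood_type]
        r = config.param_ranges[grp]
        dbh = round(_uniform(rng, r["dbh"]), 1)
        h = round(_uniform(rng, r["h"]), 1)
        n = _uniform(rng, r["n"])
        if grp != "bamboo":
            # self-thinning: stands of larger-than-typical stems carry fewer
            dbh_mid = 0.5 * (r["dbh"][0] + r["dbh"][1])
            n *= (dbh_mid / dbh) ** 1.4
        st_rows.append({
            "abbreviation": ft.abbreviation,
            "dbh_mean": dbh, "dbh_sd": round(config.sd_frac_dbh * dbh, 2),
            "h_mean": h, "h_sd": round(config.sd_frac_h * h, 2),
            "n_stems_ha": round(n),
            "growth_rate": round(_uniform(rng, config.growth_rate_range), 4),
            "mortality_rate": round(_uniform(rng, config.mortality_rate_range), 4),
        })
    st_df = pd.DataFrame(st_rows)
    return ParameterTables(species_params=sp_df, volume_equations=eq_df,
                           stand_params=st_df)


# ---------------------------------------------------------------------------
# Landscape generation
# ---------------------------------------------------------------------------

def _ecozone_grid(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Integer ecozone index per cell: latitudinal bands or Voronoi blobs."""
    if config.ecozone_geometry == "bands":
        band = np.linspace(0, len(ECOZONES), config.nrows, endpoint=False).astype(int)
        return np.repeat(band[:, None], config.ncols, axis=1)
    # blobs: nearest of five random centres (keeps patches contiguous)
    centres = rng.uniform([0, 0], [config.nrows, config.ncols], size=(len(ECOZONES), 2))
    rr, cc = np.meshgrid(np.arange(config.nrows), np.arange(config.ncols),
                         indexing="ij")
    d2 = [(rr - r0) ** 2 + (cc - c0) ** 2 for r0, c0 in centres]
    return np.argmin(d2, axis=0)


def generate_landscape(config: SyntheticConfig,
                       registry: ForestTypeRegistry | None = None) -> Landscape:
    """Generate a synthetic land-use grid.

    A handful of widespread types (natural mixed broadleaved, private
    broadleaved plantation, natural conifer–broadleaf mixed forest) get
    higher sampling weight so the type-area distribution is as skewed as a
    real survey's; each forest cell carries one to four types."""
    registry = registry if registry is not None else load_registry()
    rng = np.random.default_rng(config.seed + 1)  # decoupled from parameter draws

    abbrs = list(registry.abbreviations)
    weights = np.ones(len(abbrs))
    for dominant, w in (("MB-NF", 25.0), ("P-B-P", 15.0), ("M-CB-NF", 10.0)):
        if dominant in abbrs:
            weights[abbrs.index(dominant)] = w
    weights /= weights.sum()

    zones = _ecozone_grid(config, rng)
    cells: list[GridCell] = []
    for r in range(config.nrows):
        for c in range(config.ncols):
            if rng.uniform() < config.nodata_fraction:
                continue
            if config.nonforest_fraction == 0.0:
                forest_frac = 1.0  # fully forested world, no jitter
            else:
                forest_frac = float(np.clip(
                    rng.normal(1.0 - config.nonforest_fraction, 0.15), 0.0, 1.0))
            forest_m2 = int(round(forest_frac * M2_PER_CELL))
            alloc: dict[str, int] = {}
            if forest_m2 > 0:
                k = int(rng.integers(1, config.max_types_per_cell + 1))
                chosen = rng.choice(len(abbrs), size=k, replace=False, p=weights)
                shares = rng.dirichlet(np.ones(k))
                areas = np.floor(shares * forest_m2).astype(int)
                areas[0] += forest_m2 - int(areas.sum())  # integer remainder
                for idx, a in zip(chosen, areas):
                    if a > 0:
                        alloc[abbrs[idx]] = alloc.get(abbrs[idx], 0) + int(a)
            cells.append(GridCell(
                cell_id=f"c{r:03d}_{c:03d}", row=r, col=c,
                ecozone=ECOZONES[int(zones[r, c])], allocations=alloc))
    return Landscape(nrows=config.nrows, ncols=config.ncols, cells=cells)


def generate_dataset(config: SyntheticConfig):
    """Convenience: registry, species table, stand parameters and landscape."""
    registry = load_registry()
    tables = generate_parameter_tables(config, registry)
    species = tables.to_species_table(fallback_ecozone=ECOZONES[0])
    stands = tables.to_stand_params()
    landscape = generate_landscape(config, registry)
    return registry, species, stands, landscape, tables
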
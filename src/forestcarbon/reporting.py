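"""Summary tables in the survey's layout, printed-table checks, manifests.

The survey layout groups the forest types by wood type (coniferous,
broadleaved, bamboo, mixed) and regeneration (nature, plantation) with
subtotal rows per group and a grand-total row; each row shows a per-area
density, a total in Mt C (or Mt C yr^-1) and a proportion of the grand total.

Printed "Average" rows mix two conventions that cannot both be recovered, so
subtotal rows here carry both the area-weighted mean (total mass / total
area) and the unweighted mean of per-type densities, clearly labeled.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import BelowThreshold, load_fixture_tables, numeric
from .typology import ForestTypeRegistry
from .uncertainty import STATE_OWNED_TYPES, relative_bounds

T_PER_MT = 1e6

_MODE_COLS = {"storage": "c_t", "sequestration": "dc_t_per_yr"}


class ReportingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize(per_type: pd.DataFrame, registry: ForestTypeRegistry,
              mode: str = "storage") -> pd.DataFrame:
    """Aggregate per-type results into the survey's table structure.

    ``per_type`` needs forest_type, area_ha and (per ``mode``) c_t or
    dc_t_per_yr columns; rows of the same type are pooled first.  Output rows
    are keyed by (wood_type, regeneration, forest_type) with ``row_kind`` in
    {type, subtotal, wood_total, grand_total}; columns carry the total in
    Mt, the proportion of the grand total in %, and both per-area averaging
    conventions (area-weighted and unweighted across types).
    """
    if mode not in _MODE_COLS:
        raise ReportingError(f"unknown mode {mode!r}")
    value_col = _MODE_COLS[mode]
    df = per_type.groupby("forest_type", as_index=False).agg(
        area_ha=("area_ha", "sum"), value=(value_col, "sum"))
    for ft in df["forest_type"]:
        if ft not in registry:
            raise ReportingError(f"forest type {ft!r} not in registry")
    df["wood_type"] = [registry[ft].wood_type for ft in df["forest_type"]]
    df["regeneration"] = [registry[ft].regeneration for ft in df["forest_type"]]
    df["per_area"] = np.where(df["area_ha"] > 0, df["value"] / df["area_ha"], 0.0)

    grand_value = float(df["value"].sum())
    grand_area = float(df["area_ha"].sum())

    def _row(wood, regen, ft, kind, area, value, per_area_w, per_area_u):
        return {
            "wood_type": wood, "regeneration": regen, "forest_type": ft,
            "row_kind": kind, "area_ha": area,
            "value_mt": value / T_PER_MT,
            "proportion_pct": (value / grand_value * 100.0) if grand_value else 0.0,
            "per_area_weighted": per_area_w, "per_area_unweighted": per_area_u,
        }

    rows = []
    wood_order = [w for w in ("coniferous", "broadleaved", "bamboo", "mixed")
                  if (df["wood_type"] == w).any()]
    for wood in wood_order:
        wdf = df[df["wood_type"] == wood]
        for regen in ("nature", "plantation"):
            g = wdf[wdf["regeneration"] == regen]
            if g.empty:
                continue
            for r in g.sort_values("forest_type").itertuples(index=False):
                rows.append(_row(wood, regen, r.forest_type, "type", r.area_ha,
                                 r.value, r.per_area, r.per_area))
            area, value = float(g["area_ha"].sum()), float(g["value"].sum())
            rows.append(_row(wood, regen, "", "subtotal", area, value,
                             value / area if area else 0.0,
                             float(g["per_area"].mean())))
        area, value = float(wdf["area_ha"].sum()), float(wdf["value"].sum())
        rows.append(_row(wood, "", "", "wood_total", area, value,
                         value / area if area else 0.0,
                         float(wdf["per_area"].mean())))
    rows.append(_row("", "", "", "grand_total", grand_area, grand_value,
                     grand_value / grand_area if grand_area else 0.0,
                     float(df["per_area"].mean())))
    return pd.DataFrame(rows)


def format_value(v: float, decimals: int = 2, floor: float = 0.005) -> str:
    """Two-decimal rendering with the tables' sub-resolution convention."""
    if 0 < v < floor:
        return f"<{floor:g}"
    return f"{v:.{decimals}f}"


def render_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Printed-style strings (exact values stay in the machine columns)."""
    out = table.copy()
    out["value_mt_printed"] = out["value_mt"].map(
        lambda v: format_value(v, 2, 0.005))
    out["proportion_printed"] = out["proportion_pct"].map(
        lambda v: format_value(v, 1, 0.05))
    return out


# ---------------------------------------------------------------------------
# Stock-volume endpoint comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnualizedChange:
    difference_m3: float
    per_year_m3: float
    per_year_rounded_m3: float  # nearest 1,000 m3, report parity


def compare_totals(volume_earlier_m3: float, volume_later_m3: float,
                   year_earlier: int, year_later: int) -> AnnualizedChange:
    """Difference and mean annual change between two inventory endpoints."""
    span = year_later - year_earlier
    if span == 0:
        raise ReportingError("endpoint years must differ")
    diff = volume_later_m3 - volume_earlier_m3
    rate = diff / span
    return AnnualizedChange(
        difference_m3=diff, per_year_m3=rate,
        per_year_rounded_m3=round(rate / 1000.0) * 1000.0)


# ---------------------------------------------------------------------------
# Fixtures check: recompute the printed aggregates from the printed type rows
# ---------------------------------------------------------------------------

#: Inventory growing-stock endpoints (m^3) of the bracketing surveys and the
#: modeled mid-year, used by the annualized-change checks.
SURVEY_VOLUMES_M3 = {1993: 358_209_000.0, 2006: 411_349_000.0,
                     2015: 494_016_000.0}


def fixtures_check() -> pd.DataFrame:
    """Recompute the printed headline aggregates from the bundled tables.

    Each row is one check: grand totals and group subtotals re-summed from
    type/subtotal rows, maxima, Monte Carlo relative bounds recomputed from
    the storage table's point estimates, and the annualized stock-volume
    changes between survey endpoints.  Sub-resolution cells never enter a
    sum; where they would, the printed subtotal rows are used instead.
    """
    fx = load_fixture_tables()
    t1, t2, t3 = fx["storage"], fx["uncertainty"], fx["sequestration"]

    def rows(df, kind):
        return df[df["row_kind"] == kind]

    checks: list[tuple[str, float, float, float]] = []  # name, got, want, tol

    # --- storage table -----------------------------------------------------
    wood = rows(t1, "wood_total")
    checks.append(("storage_grand_total_mt",
                   float(numeric(wood["c_mt"]).sum()), 165.65, 0.01))
    sub = rows(t1, "subtotal")
    nat = sub[sub["regeneration"] == "nature"]
    pla = sub[sub["regeneration"] == "plantation"]
    checks.append(("storage_natural_mt",
                   float(numeric(nat["c_mt"]).sum()), 114.15, 0.02))
    checks.append(("storage_plantation_mt",
                   float(numeric(pla["c_mt"]).sum()), 51.50, 0.02))
    con_nat = rows(t1, "type").query(
        "wood_type == 'coniferous' and regeneration == 'nature'")
    checks.append(("storage_natural_coniferous_mt",
                   float(numeric(con_nat["c_mt"]).sum()), 27.73, 0.02))
    bl = wood[wood["wood_type"] == "broadleaved"]
    bl_total = float(numeric(bl["c_mt"]).iloc[0])
    checks.append(("storage_broadleaved_mt", bl_total, 86.75, 0.01))
    grand = float(numeric(wood["c_mt"]).sum())
    checks.append(("storage_broadleaved_proportion_pct",
                   bl_total / grand * 100.0, 52.4, 0.05))
    types1 = rows(t1, "type")
    c_vals = numeric(types1["c_mt"])
    max_c_row = types1.loc[c_vals.idxmax()]
    checks.append(("storage_max_type_mt",
                   float(c_vals.max()) if max_c_row["forest_type"] == "MB-NF"
                   else float("nan"), 51.79, 1e-12))
    ca_vals = numeric(types1["c_a"])
    max_ca_row = types1.loc[ca_vals.idxmax()]
    checks.append(("storage_max_density_t_ha",
                   float(ca_vals.max()) if max_ca_row["forest_type"] == "SPR-NF"
                   else float("nan"), 221.48, 1e-12))

    # --- sequestration table ----------------------------------------------
    wood3 = rows(t3, "wood_total")
    checks.append(("sequestration_grand_total_mt_yr",
                   float(numeric(wood3["dc_mt"]).sum()), 5.21, 0.01))
    bl3 = float(numeric(wood3[wood3["wood_type"] == "broadleaved"]["dc_mt"]).iloc[0])
    checks.append(("sequestration_broadleaved_mt_yr", bl3, 3.46, 0.01))
    grand3 = float(numeric(wood3["dc_mt"]).sum())
    checks.append(("sequestration_broadleaved_proportion_pct",
                   bl3 / grand3 * 100.0, 66.4, 0.05))

    # --- Monte Carlo relative bounds recomputed from point estimates -------
    point_by_type = dict(zip(types1["forest_type"], c_vals))
    mc_types = rows(t2, "type")
    total_point = float(sum(point_by_type[ft] for ft in mc_types["forest_type"]))
    tot = t2[t2["row_kind"] == "total"].iloc[0]
    checks.append(("mc_total_r_lower_pct",
                   round(relative_bounds(float(tot["c_p97_5_mt"]), total_point)),
                   -16.0, 0.0))
    checks.append(("mc_total_r_upper_pct",
                   round(relative_bounds(float(tot["c_p2_5_mt"]), total_point)),
                   22.0, 0.0))
    fir = mc_types[mc_types["forest_type"] == "FIR-NF"].iloc[0]
    checks.append(("mc_fir_r_lower_pct",
                   round(relative_bounds(float(fir["c_p97_5_mt"]),
                                         point_by_type["FIR-NF"])),
                   -74.0, 0.0))

    # --- annualized stock-volume changes between survey endpoints ----------
    first = compare_totals(SURVEY_VOLUMES_M3[1993], SURVEY_VOLUMES_M3[2006],
                           1993, 2006)
    checks.append(("volume_increase_1993_2006_m3",
                   first.difference_m3, 53_140_000.0, 0.0))
    checks.append(("volume_rate_1993_2006_m3_yr",
                   first.per_year_rounded_m3, 4_088_000.0, 0.0))
    second = compare_totals(SURVEY_VOLUMES_M3[2006], SURVEY_VOLUMES_M3[2015],
                            2006, 2015)
    checks.append(("volume_rate_2006_2015_m3_yr",
                   second.per_year_rounded_m3, 9_185_000.0, 0.0))

    out = pd.DataFrame(checks, columns=["check", "computed", "printed", "tolerance"])
    out["passed"] = (out["computed"] - out["printed"]).abs() <= out["tolerance"]
    return out


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def write_manifest(path: str | Path, *, seed: int | None,
                   config: dict, totals: dict) -> None:
    """JSON record of a run: seed, config hash, headline totals."""
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "totals": totals,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
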
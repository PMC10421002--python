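"""One-year carbon sequestration from stock-volume growth and tree mortality.

Under a no-disturbance assumption (stable land use, no harvest, fire or pest
losses over the year) next year's stock volume is this year's scaled by
(1 + G)(1 - M), with G the annual growth rate of growing-stock volume and M
the annual tree mortality rate, both fractions per year.  Because the
volume-to-carbon conversion is linear, carbon scales by the same factor:

    C_next = C * (1 + G) * (1 - M)
    dC     = C_next - C = C * [(1 + G)(1 - M) - 1]
    dC_A   = dC / A

dC is the annual carbon sequestration (t C yr^-1, reported in Mt C yr^-1);
dC_A its per-hectare density (t C ha^-1 yr^-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


def _check_rates(growth_rate: float, mortality_rate: float) -> None:
    if growth_rate <= -1.0:
        raise ValueError(f"growth rate must exceed -1, got {growth_rate}")
    if not (0.0 <= mortality_rate < 1.0):
        raise ValueError(f"mortality rate must lie in [0, 1), got {mortality_rate}")


@dataclass(frozen=True)
class SequestrationResult:
    forest_type: str
    area_ha: float
    c_tonnes: float
    c_next_tonnes: float
    dc_tonnes_per_yr: float
    dc_per_area: float          # t C ha^-1 yr^-1


def next_year_carbon(c_tonnes: float, growth_rate: float,
                     mortality_rate: float) -> float:
    """Carbon stock after one year of growth and mortality, t C."""
    _check_rates(growth_rate, mortality_rate)
    if c_tonnes < 0:
        raise ValueError(f"carbon stock must be nonnegative, got {c_tonnes}")
    return c_tonnes * (1.0 + growth_rate) * (1.0 - mortality_rate)


def annual_sequestration(c_tonnes: float, growth_rate: float,
                         mortality_rate: float) -> float:
    """One-year carbon change dC = C[(1+G)(1-M) - 1], t C yr^-1."""
    _check_rates(growth_rate, mortality_rate)
    if c_tonnes < 0:
        raise ValueError(f"carbon stock must be nonnegative, got {c_tonnes}")
    return c_tonnes * ((1.0 + growth_rate) * (1.0 - mortality_rate) - 1.0)


def sequestration_per_area(dc_tonnes_per_yr: float, area_ha: float) -> float:
    """Sequestration density dC_A = dC / A, t C ha^-1 yr^-1."""
    if area_ha <= 0:
        raise ValueError(f"area must be positive, got {area_ha}")
    return dc_tonnes_per_yr / area_ha


def type_sequestration(forest_type: str, area_ha: float, c_tonnes: float,
                       growth_rate: float, mortality_rate: float) -> SequestrationResult:
    """Bundle the one-year update of a single forest type."""
    c_next = next_year_carbon(c_tonnes, growth_rate, mortality_rate)
    dc = c_next - c_tonnes
    return SequestrationResult(
        forest_type=forest_type, area_ha=area_ha, c_tonnes=c_tonnes,
        c_next_tonnes=c_next, dc_tonnes_per_yr=dc,
        dc_per_area=sequestration_per_area(dc, area_ha) if area_ha > 0 else 0.0,
    )


def add_sequestration(per_type: pd.DataFrame, stands) -> pd.DataFrame:
    """Append dc_t_per_yr and dc_a columns to a per-type results table.

    ``per_type`` needs forest_type, area_ha and c_t columns (the output of the
    grid engine); ``stands`` maps abbreviation -> stand parameters carrying G
    and M."""
    out = per_type.copy()
    dc, dca = [], []
    for row in out.itertuples(index=False):
        s = stands[row.forest_type]
        d = annual_sequestration(row.c_t, s.growth_rate, s.mortality_rate)
        dc.append(d)
        dca.append(d / row.area_ha if row.area_ha > 0 else 0.0)
    out["dc_t_per_yr"] = dc
    out["dc_a"] = dca
    return out
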
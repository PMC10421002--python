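"""Growing-stock volume and above-ground carbon storage.

The conversion chain is the standard volume-expansion route of national
greenhouse-gas inventories:

    V_stand = N * V_stem(DBH, H)              [m^3 ha^-1]
    C       = A * V_stand * EF * D * CF       [t C]
    C_A     = V_stand * EF * D * CF           [t C ha^-1]

with N the stand density (stems ha^-1), EF the above-ground biomass expansion
factor, D the basic wood density (t m^-3) and CF the carbon fraction
(t C t^-1).  All quantities are carried internally in tonnes of carbon;
megatonnes appear only when formatting reports (1 Mt C = 1e6 t C).

An alternative conversion using a combined biomass conversion and expansion
factor (BCEF) and a below-ground/above-ground ratio R is provided for
completeness but is not used by the default pipeline, which is above-ground
only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

from .typology import (EffectiveParams, ForestType, SpeciesTable, StandParams,
                       effective_params, effective_volume_equation)

logger = logging.getLogger(__name__)

T_PER_MT = 1e6


class RangeWarning(UserWarning):
    """DBH or H lies outside a volume equation's fitted domain."""


@dataclass(frozen=True)
class CarbonResult:
    """Carbon storage of one forest type over an area A (hectares)."""

    forest_type: str
    area_ha: float
    v_stand: float          # m^3 ha^-1
    c_per_area: float       # t C ha^-1
    c_tonnes: float         # t C

    @property
    def v_total(self) -> float:
        """Total growing stock, m^3."""
        return self.area_ha * self.v_stand

    @property
    def c_mt(self) -> float:
        """Carbon storage in Mt C, the reporting unit."""
        return self.c_tonnes / T_PER_MT


def stand_volume(n_stems_ha: float, vstem: Callable[[float, float], float],
                 dbh: float, h: float, *, out_of_range: str = "warn") -> float:
    """Per-hectare growing stock: N stems, each of volume V_stem(DBH, H).

    ``out_of_range`` controls what happens when (DBH, H) falls outside a
    component equation's declared valid range: ``"warn"`` (default),
    ``"raise"``, or ``"ignore"``.
    """
    if n_stems_ha <= 0:
        raise ValueError(f"stand density must be positive, got {n_stems_ha}")
    if dbh <= 0 or h <= 0:
        raise ValueError(f"DBH and H must be positive, got ({dbh}, {h})")
    if out_of_range != "ignore":
        for eq in getattr(vstem, "equations", ()):
            if not eq.in_range(dbh, h):
                msg = (f"(DBH={dbh}, H={h}) outside fitted range "
                       f"DBH {eq.dbh_range}, H {eq.h_range}")
                if out_of_range == "raise":
                    raise ValueError(msg)
                warnings.warn(msg, RangeWarning, stacklevel=2)
    v = float(n_stems_ha) * float(vstem(dbh, h))
    if not v >= 0:
        raise ValueError(f"stem volume equation returned negative/NaN value {v}")
    return v


def carbon_storage(area_ha: float, v_stand: float, ef: float, d: float,
                   cf: float) -> float:
    """Above-ground carbon storage C = A * V_stand * EF * D * CF, in t C."""
    for name, val in (("area_ha", area_ha), ("v_stand", v_stand), ("ef", ef),
                      ("d", d), ("cf", cf)):
        if val < 0:
            raise ValueError(f"{name} must be nonnegative, got {val}")
    return area_ha * v_stand * ef * d * cf


def carbon_per_area(v_stand: float, ef: float, d: float, cf: float) -> float:
    """Carbon storage density C_A = V_stand * EF * D * CF, in t C ha^-1."""
    return carbon_storage(1.0, v_stand, ef, d, cf)


def carbon_storage_bcef(area_ha: float, v_stand: float, bcef: float, r: float,
                        cf: float) -> float:
    """General inventory form C = A * V_stand * BCEF * (1 + R) * CF (t C).

    Includes below-ground biomass through R; not used by the default
    (above-ground only) pipeline.
    """
    for name, val in (("area_ha", area_ha), ("v_stand", v_stand),
                      ("bcef", bcef), ("r", r), ("cf", cf)):
        if val < 0:
            raise ValueError(f"{name} must be nonnegative, got {val}")
    return area_ha * v_stand * bcef * (1.0 + r) * cf


def type_carbon(forest_type: ForestType, stand: StandParams,
                species: SpeciesTable, ecozone: str, area_ha: float,
                *, out_of_range: str = "warn",
                params: EffectiveParams | None = None) -> CarbonResult:
    """Full chain for one forest type in one ecozone.

    Evaluates the type's composite stem-volume equation at the representative
    (DBH, H), scales by stand density and applies the species-weighted
    EF * D * CF conversion.
    """
    p = params if params is not None else effective_params(forest_type, species)
    vstem = effective_volume_equation(forest_type, species, ecozone)
    v_stand = stand_volume(stand.n_stems_ha, vstem, stand.dbh_mean,
                           stand.h_mean, out_of_range=out_of_range)
    c_a = carbon_per_area(v_stand, p.ef, p.d, p.cf)
    return CarbonResult(
        forest_type=forest_type.abbreviation,
        area_ha=area_ha,
        v_stand=v_stand,
        c_per_area=c_a,
        c_tonnes=area_ha * c_a,
    )
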
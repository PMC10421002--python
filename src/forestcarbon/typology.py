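"""Forest-type taxonomy, species parameters and species-weighted conversion factors.

A *forest type* (e.g. ``MB-NF``, natural mixed broadleaved forest) is the unit
of the carbon model.  Each type references one or more plant species with
weights summing to one; the effective biomass-expansion factor (EF), basic
wood density (D, t m^-3) and carbon fraction (CF, t C t^-1) of a type are the
weight-sums over its component species.  Stem-volume equations are species- and
ecozone-specific, so the effective stem-volume function of a type also depends
on the ecozone of the grid cell being evaluated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

WOOD_TYPES = ("coniferous", "broadleaved", "bamboo", "mixed")
REGENERATIONS = ("nature", "plantation")

#: The five climatic strata that select which stem-volume equation applies.
ECOZONES = (
    "subtropical_mountain_system",
    "subtropical_humid_forest",
    "tropical_rainforest",
    "tropical_dry_forest",
    "tropical_moist_deciduous",
)

#: Broad taxonomic group of each species id in the default registry.  Used to
#: validate the bamboo-weighting rule and by the synthetic parameter generator
#: to pick realistic magnitude ranges.
DEFAULT_SPECIES_GROUPS: dict[str, str] = {
    "abies_kawakamii": "conifer",
    "tsuga_chinensis": "conifer",
    "chamaecyparis_formosensis": "conifer",
    "chamaecyparis_taiwanensis": "conifer",
    "pinus_taiwanensis": "conifer",
    "pinus_massoniana": "conifer",
    "picea_morrisonicola": "conifer",
    "cunninghamia_konishii": "conifer",
    "taiwania_cryptomerioides": "conifer",
    "cryptomeria_japonica": "conifer",
    "calocedrus_formosana": "conifer",
    "mixed_conifer": "conifer",
    "acacia_confusa": "broadleaf",
    "liquidambar_formosana": "broadleaf",
    "cinnamomum_camphora": "broadleaf",
    "fraxinus_griffithii": "broadleaf",
    "zelkova_serrata": "broadleaf",
    "paulownia_kawakamii": "broadleaf",
    "mixed_broadleaf": "broadleaf",
    "phyllostachys_makinoi": "bamboo",
    "phyllostachys_pubescens": "bamboo",
    "dendrocalamus_latiflorus": "bamboo",
}

_WEIGHT_TOL = 1e-9


class TypologyError(ValueError):
    """Raised on malformed registries or parameter tables."""


# ---------------------------------------------------------------------------
# Volume equations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeEquationSpec:
    """A stem-volume equation V_stem(DBH, H) in m^3 per stem.

    Supported forms (c = ``coefficients``):

    ``schumacher_hall``
        ``exp(c0 + c1*ln(DBH) + c2*ln(H))`` — the log-log allometry that
        dominates regional volume tables.
    ``power``
        ``c0 * DBH**c1 * H**c2``.
    ``linear``
        ``c0 + c1*DBH + c2*H``.

    DBH in cm, H in m.  ``dbh_range``/``h_range`` declare the fitted domain;
    evaluation outside it is allowed but flagged by :meth:`in_range`.
    """

    form: str
    coefficients: tuple[float, ...]
    dbh_range: tuple[float, float] = (0.0, math.inf)
    h_range: tuple[float, float] = (0.0, math.inf)

    def __post_init__(self) -> None:
        if self.form not in ("schumacher_hall", "power", "linear"):
            raise TypologyError(f"unknown volume-equation form {self.form!r}")
        if len(self.coefficients) < 3:
            raise TypologyError("volume equations need at least 3 coefficients")

    def evaluate(self, dbh, h):
        """Stem volume in m^3; accepts scalars or numpy arrays (DBH, H > 0)."""
        import numpy as np

        c = self.coefficients
        if self.form == "schumacher_hall":
            return np.exp(c[0] + c[1] * np.log(dbh) + c[2] * np.log(h))
        if self.form == "power":
            return c[0] * np.asarray(dbh, dtype=float) ** c[1] * np.asarray(h, dtype=float) ** c[2]
        return c[0] + c[1] * np.asarray(dbh, dtype=float) + c[2] * np.asarray(h, dtype=float)

    def in_range(self, dbh: float, h: float) -> bool:
        return (self.dbh_range[0] <= dbh <= self.dbh_range[1]
                and self.h_range[0] <= h <= self.h_range[1])


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForestType:
    abbreviation: str
    name: str
    wood_type: str
    regeneration: str
    species_weights: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.wood_type not in WOOD_TYPES:
            raise TypologyError(
                f"{self.abbreviation}: unknown wood_type {self.wood_type!r}")
        if self.regeneration not in REGENERATIONS:
            raise TypologyError(
                f"{self.abbreviation}: unknown regeneration {self.regeneration!r}")
        if not self.species_weights:
            raise TypologyError(f"{self.abbreviation}: no species weights")
        total = sum(w for _, w in self.species_weights)
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise TypologyError(
                f"{self.abbreviation}: species weights sum to {total}, not 1")
        for sp, w in self.species_weights:
            if not (0.0 <= w <= 1.0):
                raise TypologyError(f"{self.abbreviation}: weight {w} for {sp} "
                                    "outside [0, 1]")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sp for sp, _ in self.species_weights)


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species biomass–carbon conversion parameters.

    EF is the above-ground biomass expansion factor (unit-free, >= 1), D the
    basic wood density (t dry biomass per m^3 trunk volume), CF the carbon
    fraction of dry biomass (t C per t).
    """

    species: str
    ef: float
    d: float
    cf: float
    volume_equations: Mapping[str, VolumeEquationSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ef < 1.0:
            raise TypologyError(f"{self.species}: EF {self.ef} < 1")
        if not (0.0 < self.d < 2.0):
            raise TypologyError(f"{self.species}: D {self.d} outside (0, 2)")
        if not (0.0 < self.cf < 1.0):
            raise TypologyError(f"{self.species}: CF {self.cf} outside (0, 1)")


@dataclass(frozen=True)
class StandParams:
    """Stand morphology and dynamics of one forest type.

    DBH/H are the type-representative stem dimensions (mean and standard
    deviation over the permanent-plot records); N is stand density in stems
    per hectare; G and M are the annual stock-volume growth rate and tree
    mortality rate as fractions per year.
    """

    abbreviation: str
    dbh_mean: float
    dbh_sd: float
    h_mean: float
    h_sd: float
    n_stems_ha: float
    growth_rate: float
    mortality_rate: float

    def __post_init__(self) -> None:
        if self.dbh_mean <= 0 or self.h_mean <= 0 or self.n_stems_ha <= 0:
            raise TypologyError(f"{self.abbreviation}: nonpositive mean or density")
        if self.dbh_sd < 0 or self.h_sd < 0:
            raise TypologyError(f"{self.abbreviation}: negative sd")
        if not (0.0 <= self.mortality_rate < 1.0):
            raise TypologyError(f"{self.abbreviation}: mortality rate outside [0, 1)")
        if self.growth_rate <= -1.0:
            raise TypologyError(f"{self.abbreviation}: growth rate <= -1")


@dataclass(frozen=True)
class EffectiveParams:
    ef: float
    d: float
    cf: float


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

class ForestTypeRegistry:
    """Ordered, abbreviation-unique collection of :class:`ForestType`."""

    def __init__(self, types: Iterable[ForestType],
                 species_groups: Mapping[str, str] | None = None):
        self._types: dict[str, ForestType] = {}
        groups = DEFAULT_SPECIES_GROUPS if species_groups is None else species_groups
        for ft in types:
            if ft.abbreviation in self._types:
                raise TypologyError(f"duplicate abbreviation {ft.abbreviation!r}")
            _check_bamboo_rule(ft, groups)
            self._types[ft.abbreviation] = ft

    def __len__(self) -> int:
        return len(self._types)

    def __iter__(self) -> Iterator[ForestType]:
        return iter(self._types.values())

    def __contains__(self, abbreviation: str) -> bool:
        return abbreviation in self._types

    def __getitem__(self, abbreviation: str) -> ForestType:
        try:
            return self._types[abbreviation]
        except KeyError:
            raise TypologyError(f"unknown forest type {abbreviation!r}") from None

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(self._types)


def _check_bamboo_rule(ft: ForestType, groups: Mapping[str, str]) -> None:
    """Mixed types containing bamboo carry weight 0.5 on the bamboo component,
    with the remainder split evenly among the other components."""
    if ft.wood_type != "mixed":
        return
    known = [(sp, w) for sp, w in ft.species_weights if sp in groups]
    if len(known) != len(ft.species_weights):
        return  # user-supplied species outside the default taxonomy: skip
    bamboo = [(sp, w) for sp, w in known if groups[sp] == "bamboo"]
    if not bamboo:
        return
    bamboo_w = sum(w for _, w in bamboo)
    if abs(bamboo_w - 0.5) > _WEIGHT_TOL:
        raise TypologyError(
            f"{ft.abbreviation}: bamboo component weight {bamboo_w}, expected 0.5")
    others = [w for sp, w in known if groups[sp] != "bamboo"]
    if others:
        share = 0.5 / len(others)
        if any(abs(w - share) > _WEIGHT_TOL for w in others):
            raise TypologyError(
                f"{ft.abbreviation}: non-bamboo components must split 0.5 evenly")


def _parse_weights(text: str) -> tuple[tuple[str, float], ...]:
    pairs = []
    for chunk in str(text).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            sp, w = chunk.rsplit(":", 1)
            pairs.append((sp.strip(), float(w)))
        except ValueError as exc:
            raise TypologyError(f"malformed species weight {chunk!r}") from exc
    return tuple(pairs)


def _format_weights(weights: tuple[tuple[str, float], ...]) -> str:
    return ";".join(f"{sp}:{w:g}" for sp, w in weights)


def load_registry(path: str | Path | None = None,
                  species_groups: Mapping[str, str] | None = None) -> ForestTypeRegistry:
    """Load a forest-type registry from ``forest_types.csv``.

    Columns: ``abbreviation, name, wood_type, regeneration, species_weights``
    with weights as semicolon-separated ``species:weight`` pairs.  With no
    path, the bundled default registry of the 51 island forest types is loaded.
    """
    if path is None:
        with resources.files("forestcarbon.data").joinpath("forest_types.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    required = {"abbreviation", "name", "wood_type", "regeneration", "species_weights"}
    missing = required - set(df.columns)
    if missing:
        raise TypologyError(f"registry file missing columns {sorted(missing)}")
    types = [
        ForestType(
            abbreviation=row.abbreviation,
            name=row.name_,
            wood_type=row.wood_type,
            regeneration=row.regeneration,
            species_weights=_parse_weights(row.species_weights),
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]
    return ForestTypeRegistry(types, species_groups=species_groups)


def write_registry(registry: ForestTypeRegistry, path: str | Path) -> None:
    """Serialize a registry back to the CSV schema of :func:`load_registry`."""
    df = pd.DataFrame(
        {
            "abbreviation": [ft.abbreviation for ft in registry],
            "name": [ft.name for ft in registry],
            "wood_type": [ft.wood_type for ft in registry],
            "regeneration": [ft.regeneration for ft in registry],
            "species_weights": [_format_weights(ft.species_weights) for ft in registry],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Species / stand parameter tables
# ---------------------------------------------------------------------------

class SpeciesTable:
    """Mapping species id -> :class:`SpeciesParams`, with an optional default
    ecozone used as a fallback when a species lacks an equation for the
    requested zone (a warning is logged on every fallback)."""

    def __init__(self, params: Iterable[SpeciesParams],
                 fallback_ecozone: str | None = None):
        self._params = {p.species: p for p in params}
        self.fallback_ecozone = fallback_ecozone

    def __contains__(self, species: str) -> bool:
        return species in self._params

    def __getitem__(self, species: str) -> SpeciesParams:
        try:
            return self._params[species]
        except KeyError:
            raise TypologyError(f"unknown species {species!r}") from None

    def __iter__(self):
        return iter(self._params.values())

    def __len__(self) -> int:
        return len(self._params)

    def equation_for(self, species: str, ecozone: str) -> VolumeEquationSpec:
        eqs = self[species].volume_equations
        if ecozone in eqs:
            return eqs[ecozone]
        fb = self.fallback_ecozone
        if fb is not None and fb in eqs:
            logger.warning("no volume equation for (%s, %s); falling back to %s",
                           species, ecozone, fb)
            return eqs[fb]
        raise TypologyError(
            f"no volume equation for species {species!r} in ecozone {ecozone!r} "
            "and no fallback configured")


def load_species_table(species_csv: str | Path, equations_csv: str | Path,
                       fallback_ecozone: str | None = None) -> SpeciesTable:
    """Build a :class:`SpeciesTable` from ``species_params.csv`` (species, EF,
    D, CF) and ``volume_equations.csv`` (species, ecozone, form, c0..c3,
    dbh_min, dbh_max, h_min, h_max)."""
    sp_df = pd.read_csv(species_csv)
    eq_df = pd.read_csv(equations_csv)
    eqs: dict[str, dict[str, VolumeEquationSpec]] = {}
    for row in eq_df.itertuples(index=False):
        coeffs = tuple(float(getattr(row, c)) for c in ("c0", "c1", "c2", "c3")
                       if hasattr(row, c) and pd.notna(getattr(row, c)))
        spec = VolumeEquationSpec(
            form=row.form,
            coefficients=coeffs,
            dbh_range=(float(row.dbh_min), float(row.dbh_max)),
            h_range=(float(row.h_min), float(row.h_max)),
        )
        eqs.setdefault(row.species, {})[row.ecozone] = spec
    params = [
        SpeciesParams(
            species=row.species,
            ef=float(row.ef),
            d=float(row.d),
            cf=float(row.cf),
            volume_equations=eqs.get(row.species, {}),
        )
        for row in sp_df.itertuples(index=False)
    ]
    return SpeciesTable(params, fallback_ecozone=fallback_ecozone)


def load_stand_params(path: str | Path) -> dict[str, StandParams]:
    """Load ``stand_params.csv``.

    G and M are stored internally as fractions per year.  A leading comment
    line ``# rate_units: percent`` declares that the file carries them as
    percentages (the convention of printed survey tables); they are divided
    by 100 on load.
    """
    path = Path(path)
    percent = False
    with open(path) as fh:
        first = fh.readline()
        if first.lstrip().startswith("#"):
            percent = "percent" in first.lower()
    df = pd.read_csv(path, comment="#")
    scale = 0.01 if percent else 1.0
    out = {}
    for row in df.itertuples(index=False):
        out[row.abbreviation] = StandParams(
            abbreviation=row.abbreviation,
            dbh_mean=float(row.dbh_mean),
            dbh_sd=float(row.dbh_sd),
            h_mean=float(row.h_mean),
            h_sd=float(row.h_sd),
            n_stems_ha=float(row.n_stems_ha),
            growth_rate=float(row.growth_rate) * scale,
            mortality_rate=float(row.mortality_rate) * scale,
        )
    return out


# ---------------------------------------------------------------------------
# Species weighting
# ---------------------------------------------------------------------------

def effective_params(forest_type: ForestType, species: SpeciesTable) -> EffectiveParams:
    """Weight-sum EF, D and CF over the component species of a forest type.

    Terms are accumulated in sorted species order with exact summation, so
    the result is independent of how the weight list is ordered."""
    terms = sorted(forest_type.species_weights)
    return EffectiveParams(
        ef=math.fsum(w * species[sp].ef for sp, w in terms),
        d=math.fsum(w * species[sp].d for sp, w in terms),
        cf=math.fsum(w * species[sp].cf for sp, w in terms),
    )


def effective_volume_equation(forest_type: ForestType, species: SpeciesTable,
                              ecozone: str) -> Callable[[float, float], float]:
    """Composite stem-volume function of a forest type in one ecozone.

    Returns ``f(dbh, h)`` equal to the weight-sum of the component species'
    ecozone-specific stem-volume equations.
    """
    terms = [(w, species.equation_for(sp, ecozone))
             for sp, w in forest_type.species_weights]

    def vstem(dbh, h):
        return sum(w * eq.evaluate(dbh, h) for w, eq in terms)

    vstem.equations = tuple(eq for _, eq in terms)  # type: ignore[attr-defined]
    return vstem
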
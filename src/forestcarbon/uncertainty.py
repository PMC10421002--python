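"""Monte Carlo propagation of stand-morphology variability into carbon bounds.

The dominant uncertainty in the stock-volume route is the type-level spread of
the representative DBH and H.  For each varied forest type and each iteration
one (DBH, H) pair is drawn from independent normal distributions centred on
the type's mean with the recorded standard deviation (draws <= 0 are
resampled), the carbon chain is recomputed for that type in every ecozone it
occupies, and non-varied types are held at their point estimates.  The
empirical 2.5th and 97.5th percentiles of the resulting per-type and total
carbon samples form the two-tailed 95% interval; relative bounds are

    R = (C_percentile - C_point) / C_point * 100%.

Survey convention note: because carbon is monotone increasing in DBH and H,
the value labelled with the *97.5th percentile of the error distribution* in
survey reports is the numerically LOWER carbon bound.  This module exposes
unambiguous ``c_lower``/``c_upper`` fields; the reporting layer maps them back
to percentile labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .typology import (ForestTypeRegistry, SpeciesTable, StandParams,
                       effective_params, effective_volume_equation)

#: The 26 state-owned forest types whose DBH/H variability is propagated by
#: default; newly added, private, bamboo and bamboo-mixed types stay fixed.
STATE_OWNED_TYPES: tuple[str, ...] = (
    "FIR-NF", "TSU-NF", "CYP-NF", "PIN-NF", "SPR-NF", "O-C-NF",
    "CYP-P", "PIN-P", "LF-P", "TAI-P", "JC-P", "TIC-P", "O-C-P", "MC-P",
    "B-NF", "MB-NF",
    "ACA-P", "SG-P", "CAM-P", "ASH-P", "JE-P", "SDT-P", "O-B-P", "MB-P",
    "M-CB-NF", "M-CB-P",
)

_MAX_RESAMPLE_ROUNDS = 1000


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo design: 10,000 iterations by default, explicit seed."""

    seed: int
    n_iterations: int = 10_000
    varied_types: tuple[str, ...] = STATE_OWNED_TYPES
    truncation: str = "resample"   # policy for nonpositive normal draws

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.truncation not in ("resample", "error"):
            raise ValueError(f"unknown truncation policy {self.truncation!r}")


@dataclass
class UncertaintyResult:
    """Point estimates and 95% interval bounds, per type and for the total.

    ``table`` columns: forest_type, c_point, c_lower, c_upper, r_lower_pct,
    r_upper_pct, n_iter, seed (carbon in t C; the final row is the total).
    ``total_samples`` optionally holds the full sampled-total distribution.
    """

    table: pd.DataFrame
    total_samples: np.ndarray | None = None
    type_samples: dict[str, np.ndarray] = field(default_factory=dict)


def relative_bounds(sampled_value: float, point_estimate: float) -> float:
    """Signed percentage deviation of a percentile value from the point estimate."""
    if point_estimate <= 0:
        raise ValueError("point estimate must be positive")
    return (sampled_value - point_estimate) / point_estimate * 100.0


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      n: int, policy: str) -> np.ndarray:
    """Normal draws constrained positive; nonpositive values are resampled."""
    if mean <= 0:
        raise ValueError(f"nonpositive mean {mean} for normal draw")
    if sd == 0.0:
        return np.full(n, mean)
    x = rng.normal(mean, sd, size=n)
    bad = x <= 0
    if policy == "error" and bad.any():
        raise ValueError("nonpositive normal draw under truncation='error'")
    rounds = 0
    while bad.any():
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = x <= 0
        rounds += 1
        if rounds > _MAX_RESAMPLE_ROUNDS:
            raise RuntimeError("resampling failed to produce positive draws")
    return x


def run_monte_carlo(config: MCConfig, registry: ForestTypeRegistry,
                    species: SpeciesTable, stands: Mapping[str, StandParams],
                    areas: pd.DataFrame, *,
                    keep_samples: bool = False) -> UncertaintyResult:
    """Propagate DBH/H variability through the landscape carbon total.

    ``areas`` is the per-(forest type, ecozone) area table produced by the
    grid engine (columns forest_type, ecozone, area_ha).  Returns per-type and
    total point estimates, empirical 95% bounds and relative bounds.
    """
    for ft in config.varied_types:
        if ft not in registry:
            raise ValueError(f"varied type {ft!r} not in registry")
    rng = np.random.default_rng(config.seed)
    n = config.n_iterations

    by_type: dict[str, list[tuple[float, object, float]]] = {}
    for row in areas.itertuples(index=False):
        ft = registry[row.forest_type]
        p = effective_params(ft, species)
        vstem = effective_volume_equation(ft, species, row.ecozone)
        conv = p.ef * p.d * p.cf
        by_type.setdefault(row.forest_type, []).append(
            (float(row.area_ha), vstem, conv))

    present_varied = [ft for ft in config.varied_types if ft in by_type]

    def carbon_of(ft_abbr: str, dbh, h):
        s = stands[ft_abbr]
        return sum(area * s.n_stems_ha * np.asarray(vstem(dbh, h)) * conv
                   for area, vstem, conv in by_type[ft_abbr])

    points = {ft: float(carbon_of(ft, stands[ft].dbh_mean, stands[ft].h_mean))
              for ft in by_type}
    fixed_total = sum(v for ft, v in points.items() if ft not in present_varied)

    # draws are made type by type in the order of config.varied_types so that
    # results are reproducible regardless of which types occur in the landscape
    samples: dict[str, np.ndarray] = {}
    for ft_abbr in config.varied_types:
        s = stands.get(ft_abbr)
        if s is None:
            raise ValueError(f"no stand parameters for varied type {ft_abbr!r}")
        dbh = _truncated_normal(rng, s.dbh_mean, s.dbh_sd, n, config.truncation)
        h = _truncated_normal(rng, s.h_mean, s.h_sd, n, config.truncation)
        if ft_abbr in by_type:
            samples[ft_abbr] = np.asarray(carbon_of(ft_abbr, dbh, h), dtype=float)

    totals = fixed_total + (np.sum(list(samples.values()), axis=0)
                            if samples else np.zeros(n))

    rows = []
    for ft_abbr in present_varied:
        sm = samples[ft_abbr]
        lo, hi = np.percentile(sm, [2.5, 97.5])
        pt = points[ft_abbr]
        rows.append((ft_abbr, pt, lo, hi,
                     relative_bounds(lo, pt), relative_bounds(hi, pt)))
    total_point = float(sum(points.values()))
    lo, hi = np.percentile(totals, [2.5, 97.5])
    rows.append(("Total", total_point, float(lo), float(hi),
                 relative_bounds(float(lo), total_point),
                 relative_bounds(float(hi), total_point)))

    table = pd.DataFrame(rows, columns=["forest_type", "c_point", "c_lower",
                                        "c_upper", "r_lower_pct", "r_upper_pct"])
    table["n_iter"] = n
    table["seed"] = config.seed
    return UncertaintyResult(
        table=table,
        total_samples=totals if keep_samples else None,
        type_samples=samples if keep_samples else {},
    )


def write_mc_results(result: UncertaintyResult, path) -> None:
    """Serialize the bounds table to ``mc_results.csv``."""
    result.table.to_csv(path, index=False)
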
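"""Trait-table assembly: aggregation of literature records, derived volumes,
length-to-mass conversion, and log transformation.

Raw inputs are long-format records (one row per species x trait x source),
optionally sex-tagged and optionally given as min/max ranges.  Aggregation
follows the conventions of comparative life-history compilations: ranges are
replaced by their midpoint, multiple values are averaged — except maximum
longevity, where the maximum encountered value is kept — and female values
are preferred for body-size traits when available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import Phylogeny, normalize_label, prune

__all__ = [
    "TraitRecord",
    "LengthMassAllometry",
    "TRAIT_UNITS",
    "BODY_SIZE_TRAITS",
    "MAX_TRAITS",
    "BIPHASIC_ONLY_TRAITS",
    "UnitMismatchError",
    "UnresolvedAllometryError",
    "InsufficientDataError",
    "aggregate",
    "egg_volume_cm3",
    "clutch_volume",
    "annual_clutch_volume",
    "mass_from_length",
    "read_records",
    "build_trait_table",
    "log10_table",
    "assemble_pair",
]

#: Controlled trait vocabulary and the unit each trait must carry.
TRAIT_UNITS: dict[str, str] = {
    "body_mass": "g",
    "svl": "mm",
    "total_length": "mm",
    "egg_diameter": "mm",
    "egg_volume": "cm3",
    "clutch_size": "count",
    "clutch_volume": "cm3",
    "annual_clutch_number": "count",
    "annual_clutch_volume": "cm3",
    "incubation_time": "days",
    "hatchling_total_length": "mm",
    "hatchling_svl": "mm",
    "larval_period": "days",
    "metamorphosis_total_length": "mm",
    "metamorphosis_svl": "mm",
    "juvenile_mass": "g",
    "size_at_maturity": "mm",
    "age_at_maturity": "years",
    "max_longevity": "years",
}

#: Traits for which female records take precedence over mixed/male records.
BODY_SIZE_TRAITS = frozenset({"body_mass", "svl", "total_length"})

#: Traits aggregated by the maximum value encountered rather than the mean.
MAX_TRAITS = frozenset({"max_longevity"})

#: Traits defined only for species with a free-living larval stage; species
#: flagged as direct-developing or viviparous are excluded from their models.
BIPHASIC_ONLY_TRAITS = frozenset(
    {"larval_period", "metamorphosis_total_length", "metamorphosis_svl"}
)


class UnitMismatchError(ValueError):
    pass


class UnresolvedAllometryError(LookupError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class TraitRecord:
    """One literature datum: a point value or a (min, max) range."""

    species: str
    trait: str
    value: float | None = None
    value_min: float | None = None
    value_max: float | None = None
    unit: str | None = None
    sex: str = "unspecified"

    def resolved(self, prefer_max: bool = False) -> float:
        """Point value: ranges collapse to their midpoint (or max, for
        maximum-encountered traits)."""
        if self.value is not None:
            v = float(self.value)
        elif self.value_min is not None and self.value_max is not None:
            v = float(self.value_max) if prefer_max else 0.5 * (
                float(self.value_min) + float(self.value_max)
            )
        else:
            raise ValueError(f"record for {self.species}/{self.trait} has no value")
        if v <= 0:
            raise ValueError(f"non-positive value for {self.species}/{self.trait}: {v}")
        return v


def aggregate(records: list[TraitRecord], trait: str) -> tuple[float, str]:
    """Aggregate all records of one species x trait into a single value.

    Returns ``(value, provenance)`` where provenance is one of
    ``mean``, ``midpoint``, ``max``, ``female-preferred`` (possibly combined
    with ``+midpoint``).
    """
    recs = [r for r in records if r.trait == trait]
    if not recs:
        raise ValueError(f"no records for trait {trait!r}")
    expected_unit = TRAIT_UNITS.get(trait)
    units = {r.unit for r in recs if r.unit is not None}
    if len(units) > 1:
        raise UnitMismatchError(f"mixed units for {trait!r}: {sorted(units)}")
    if expected_unit is not None and units and units != {expected_unit}:
        raise UnitMismatchError(
            f"trait {trait!r} expects unit {expected_unit!r}, got {units.pop()!r}"
        )

    tags = []
    if trait in BODY_SIZE_TRAITS and any(r.sex == "female" for r in recs):
        recs = [r for r in recs if r.sex == "female"]
        tags.append("female-preferred")

    prefer_max = trait in MAX_TRAITS
    has_range = any(r.value is None for r in recs)
    values = [r.resolved(prefer_max=prefer_max) for r in recs]
    if prefer_max:
        tags.append("max")
        return max(values), "+".join(tags)
    if has_range:
        tags.append("midpoint")
    tags.append("mean")
    return float(np.mean(values)), "+".join(tags)


def egg_volume_cm3(diameter_mm: float) -> float:
    """Spherical egg volume in cm^3 from a diameter in mm: (pi/6) d^3 / 1000."""
    if diameter_mm <= 0:
        raise ValueError(f"egg diameter must be positive, got {diameter_mm}")
    return (math.pi / 6.0) * diameter_mm**3 / 1000.0


def clutch_volume(egg_volume: float, clutch_size: float) -> float:
    """Clutch volume (cm^3) = egg volume x clutch size."""
    if egg_volume <= 0 or clutch_size <= 0:
        raise ValueError("egg volume and clutch size must both be positive")
    return egg_volume * clutch_size


def annual_clutch_volume(clutch_vol: float, clutches_per_year: float) -> float:
    """Annual clutch volume (cm^3/year) = clutch volume x clutches per year."""
    if clutch_vol <= 0 or clutches_per_year <= 0:
        raise ValueError("clutch volume and clutches/year must both be positive")
    return clutch_vol * clutches_per_year


@dataclass(frozen=True)
class LengthMassAllometry:
    """Power law M = a * L^b converting a length (mm) to a mass (g), keyed by
    family or by a coarser group (e.g. microhabitat class) used as fallback."""

    group: str
    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("allometry coefficient a must be positive")


def mass_from_length(length_mm: float, allom: LengthMassAllometry) -> float:
    if length_mm <= 0:
        raise ValueError(f"length must be positive, got {length_mm}")
    return allom.a * length_mm**allom.b


def resolve_allometry(
    family: str | None,
    fallback_group: str | None,
    table: dict[str, LengthMassAllometry],
) -> LengthMassAllometry:
    """Family-specific equation first, then the coarser group average."""
    if family is not None and family in table:
        return table[family]
    if fallback_group is not None and fallback_group in table:
        return table[fallback_group]
    raise UnresolvedAllometryError(
        f"no length-mass allometry for family={family!r} or group={fallback_group!r}"
    )


RECORD_COLUMNS = ["species", "trait", "value", "value_min", "value_max", "unit", "sex", "source"]


def read_records(path) -> list[TraitRecord]:
    """Read long-format trait records from CSV (columns: species, trait,
    value, value_min, value_max, unit, sex, source)."""
    df = pd.read_csv(path)
    recs = []
    for row in df.itertuples(index=False):
        recs.append(
            TraitRecord(
                species=normalize_label(str(row.species)),
                trait=str(row.trait),
                value=None if pd.isna(getattr(row, "value", np.nan)) else float(row.value),
                value_min=None if pd.isna(getattr(row, "value_min", np.nan)) else float(row.value_min),
                value_max=None if pd.isna(getattr(row, "value_max", np.nan)) else float(row.value_max),
                unit=None if pd.isna(getattr(row, "unit", np.nan)) else str(row.unit),
                sex=str(row.sex) if not pd.isna(getattr(row, "sex", np.nan)) else "unspecified",
            )
        )
    return recs


def build_trait_table(records: list[TraitRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate records into a wide species x trait table plus a provenance table."""
    by_key: dict[tuple[str, str], list[TraitRecord]] = {}
    for r in records:
        by_key.setdefault((normalize_label(r.species), r.trait), []).append(r)
    values: dict[tuple[str, str], float] = {}
    prov: dict[tuple[str, str], str] = {}
    for (sp, tr), recs in by_key.items():
        v, p = aggregate(recs, tr)
        values[(sp, tr)] = v
        prov[(sp, tr)] = p
    table = pd.Series(values).unstack()
    provenance = pd.Series(prov).unstack()
    table.index.name = "species"
    provenance.index.name = "species"
    return table, provenance


def log10_table(table: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log10; missing cells stay missing; non-positive cells are errors."""
    bad = (table <= 0).any()
    if bad.any():
        col = bad[bad].index[0]
        sp = table.index[(table[col] <= 0).fillna(False)][0]
        raise ValueError(f"non-positive value at species={sp!r}, trait={col!r}")
    return np.log10(table)


def assemble_pair(
    table: pd.DataFrame, x_trait: str, y_trait: str, tree: Phylogeny
) -> tuple[np.ndarray, np.ndarray, Phylogeny, list[str]]:
    """Complete-case alignment of (x, y) with the tree.

    Returns x, y vectors in the order of the pruned tree's tips, the pruned
    tree, and the list of species dropped because they were absent from the
    tree.  Raises :class:`InsufficientDataError` below 3 complete cases.
    """
    for tr in (x_trait, y_trait):
        if tr not in table.columns:
            raise KeyError(f"trait {tr!r} not in table")
    sub = table[[x_trait, y_trait]].dropna()
    species = [normalize_label(s) for s in sub.index]
    sub = sub.set_axis(species, axis=0)
    in_tree = set(tree.tip_labels)
    keep = [s for s in species if s in in_tree]
    dropped = [s for s in species if s not in in_tree]
    if len(keep) < 3:
        raise InsufficientDataError(
            f"only {len(keep)} species have {x_trait!r}, {y_trait!r} and a tree tip"
        )
    pruned = prune(tree, keep)
    order = list(pruned.tip_labels)
    x = sub.loc[order, x_trait].to_numpy(dtype=float)
    y = sub.loc[order, y_trait].to_numpy(dtype=float)
    return x, y, pruned, dropped
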
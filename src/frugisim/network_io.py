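"""Read, validate and write weighted plant-frugivore interaction networks and trait tables.

A network is a plants x birds matrix of non-negative integer counts of observed
fruit-consumption events. The interchange format is delimited text (CSV): matrix
form with plant labels as row index and bird labels as column header, or long
form with columns ``plant,bird,count``. Trait tables are CSV with a ``species``
column, a body-mass column (grams by default, converted to kg internally) and
optional ``bill_width`` / ``fruit_diameter`` columns in millimetres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import NetworkFormatError, TraitError

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "TraitTable",
    "read_network",
    "read_traits",
    "write_network",
    "write_traits",
    "write_table",
]


@dataclass(frozen=True, eq=False)
class InteractionNetwork:
    """Weighted bipartite network of fruit-consumption events.

    Attributes
    ----------
    network_id : str
        Label of the study site / network.
    plants, birds : tuple of str
        Ordered species labels for rows and columns.
    counts : ndarray of int64, shape (n_plants, n_birds)
        Observed interaction events; non-negative integers.
    """

    network_id: str
    plants: tuple[str, ...]
    birds: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise NetworkFormatError("counts must be a 2-D matrix")
        if counts.shape != (len(self.plants), len(self.birds)):
            raise NetworkFormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.plants)} plants x {len(self.birds)} birds"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            float_counts = np.asarray(counts, dtype=float)
            if not np.all(np.isfinite(float_counts)) or np.any(float_counts != np.round(float_counts)):
                bad = np.argwhere(float_counts != np.round(float_counts))
                loc = self._cell_name(bad[0]) if len(bad) else "<non-finite>"
                raise NetworkFormatError(f"non-integer interaction count at {loc}")
            counts = float_counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise NetworkFormatError(f"negative interaction count at {self._cell_name(bad)}")
        for kind, labels in (("plant", self.plants), ("bird", self.birds)):
            if len(set(labels)) != len(labels):
                dupes = sorted({x for x in labels if list(labels).count(x) > 1})
                raise NetworkFormatError(f"duplicate {kind} labels: {dupes}")
        counts.setflags(write=False)
        object.__setattr__(self, "plants", tuple(self.plants))
        object.__setattr__(self, "birds", tuple(self.birds))
        object.__setattr__(self, "counts", counts)

    def _cell_name(self, index) -> str:
        i, j = (int(v) for v in index)
        plant = self.plants[i] if i < len(self.plants) else f"row {i}"
        bird = self.birds[j] if j < len(self.birds) else f"col {j}"
        return f"(plant={plant!r}, bird={bird!r})"

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def n_birds(self) -> int:
        return len(self.birds)

    @property
    def total_events(self) -> int:
        """Total number of observed interaction events (sum of the matrix)."""
        return int(self.counts.sum())

    @property
    def n_links(self) -> int:
        """Number of realized (non-zero) plant-bird links."""
        return int(np.count_nonzero(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.plants), columns=list(self.birds))

    def drop_empty(self, warn: bool = True) -> "InteractionNetwork":
        """Drop all-zero plant rows and bird columns (e.g. after filtering)."""
        row_keep = self.counts.sum(axis=1) > 0
        col_keep = self.counts.sum(axis=0) > 0
        if row_keep.all() and col_keep.all():
            return self
        if warn:
            dropped_p = [p for p, k in zip(self.plants, row_keep) if not k]
            dropped_b = [b for b, k in zip(self.birds, col_keep) if not k]
            logger.warning(
                "network %s: dropping species with no interactions (plants=%s, birds=%s)",
                self.network_id, dropped_p, dropped_b,
            )
        return InteractionNetwork(
            network_id=self.network_id,
            plants=tuple(p for p, k in zip(self.plants, row_keep) if k),
            birds=tuple(b for b, k in zip(self.birds, col_keep) if k),
            counts=self.counts[np.ix_(row_keep, col_keep)],
        )

    def equals(self, other: "InteractionNetwork") -> bool:
        return (
            self.network_id == other.network_id
            and self.plants == other.plants
            and self.birds == other.birds
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class TraitTable:
    """Per-species traits: bird body mass (kg, required for birds used in a
    network), optional bird bill width (mm) and plant fruit diameter (mm)."""

    body_mass: Mapping[str, float]
    bill_width: Mapping[str, float] = field(default_factory=dict)
    fruit_diameter: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = sorted(s for s, m in self.body_mass.items() if not (np.isfinite(m) and m > 0))
        if bad:
            raise TraitError(f"non-positive or non-finite body mass for species: {bad}")
        object.__setattr__(self, "body_mass", dict(self.body_mass))
        object.__setattr__(self, "bill_width", dict(self.bill_width))
        object.__setattr__(self, "fruit_diameter", dict(self.fruit_diameter))

    def mass(self, bird: str) -> float:
        try:
            return self.body_mass[bird]
        except KeyError:
            raise TraitError(f"no body mass for bird {bird!r}") from None

    def masses(self, birds: Sequence[str]) -> np.ndarray:
        missing = [b for b in birds if b not in self.body_mass]
        if missing:
            raise TraitError(f"missing body mass for birds: {sorted(missing)}")
        return np.array([self.body_mass[b] for b in birds], dtype=float)

    def validate_for(self, network: InteractionNetwork) -> None:
        """Raise TraitError unless every bird in the network has a body mass."""
        self.masses(network.birds)


def _build_network(df: pd.DataFrame, network_id: str, drop_empty: bool) -> InteractionNetwork:
    if df.index.has_duplicates:
        raise NetworkFormatError(f"duplicate plant labels: {sorted(df.index[df.index.duplicated()])}")
    if df.columns.has_duplicates:
        raise NetworkFormatError(f"duplicate bird labels: {sorted(df.columns[df.columns.duplicated()])}")
    values = df.to_numpy()
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise NetworkFormatError(f"non-numeric cell in network {network_id!r}: {exc}") from None
    if np.any(~np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise NetworkFormatError(
            f"missing or non-finite count at (plant={df.index[i]!r}, bird={df.columns[j]!r})"
        )
    if np.any(values != np.round(values)):
        i, j = np.argwhere(values != np.round(values))[0]
        raise NetworkFormatError(
            f"non-integer interaction count at (plant={df.index[i]!r}, bird={df.columns[j]!r})"
        )
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise NetworkFormatError(
            f"negative interaction count at (plant={df.index[i]!r}, bird={df.columns[j]!r})"
        )
    net = InteractionNetwork(
        network_id=network_id,
        plants=tuple(str(p) for p in df.index),
        birds=tuple(str(b) for b in df.columns),
        counts=values.astype(np.int64),
    )
    return net.drop_empty() if drop_empty else net


def read_network(
    path,
    network_id: str | None = None,
    transpose: bool = False,
    long_form: bool = False,
    drop_empty: bool = True,
) -> InteractionNetwork:
    """Read an interaction network from CSV.

    Parameters
    ----------
    path : path-like
        CSV file. Matrix form: first column = plant labels, header = bird
        labels. Long form (``long_form=True``): columns plant, bird, count.
    transpose : bool
        Set when the file stores birds in rows and plants in columns.
    drop_empty : bool
        Drop all-zero rows/columns with a logged warning (default) rather
        than keeping degenerate species.
    """
    network_id = network_id or str(getattr(path, "stem", path))
    if long_form:
        df = pd.read_csv(path)
        required = {"plant", "bird", "count"}
        if not required.issubset(df.columns):
            raise NetworkFormatError(
                f"long-form network needs columns {sorted(required)}, got {list(df.columns)}"
            )
        if df.duplicated(subset=["plant", "bird"]).any():
            dup = df[df.duplicated(subset=["plant", "bird"])].iloc[0]
            raise NetworkFormatError(f"duplicate link (plant={dup['plant']!r}, bird={dup['bird']!r})")
        wide = df.pivot(index="plant", columns="bird", values="count").fillna(0)
    else:
        wide = pd.read_csv(path, index_col=0)
    if transpose:
        wide = wide.T
    return _build_network(wide, network_id, drop_empty)


_MASS_COLUMNS = {"body_mass": None, "body_mass_g": "g", "body_mass_kg": "kg"}


def read_traits(path, mass_unit: str = "g") -> TraitTable:
    """Read a species trait table from CSV.

    The body-mass column may declare its unit in the header (``body_mass_g``
    or ``body_mass_kg``); a bare ``body_mass`` column uses ``mass_unit``
    (default grams, the convention of avian trait databases). Masses are
    stored in kg.
    """
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise TraitError(f"trait table needs a 'species' column, got {list(df.columns)}")
    mass_col = next((c for c in _MASS_COLUMNS if c in df.columns), None)
    if mass_col is None:
        raise TraitError("trait table needs a body_mass / body_mass_g / body_mass_kg column")
    unit = _MASS_COLUMNS[mass_col] or mass_unit
    if unit not in ("g", "kg"):
        raise TraitError(f"mass_unit must be 'g' or 'kg', got {unit!r}")
    if df["species"].duplicated().any():
        raise TraitError(f"duplicate species in trait table: "
                         f"{sorted(df.loc[df['species'].duplicated(), 'species'])}")
    factor = 1e-3 if unit == "g" else 1.0
    mass = {}
    for species, value in zip(df["species"], df[mass_col]):
        if pd.isna(value):
            continue  # plants carry no body mass; networks are checked via validate_for
        value = float(value)
        if not (np.isfinite(value) and value > 0):
            raise TraitError(f"non-positive body mass for species {species!r}: {value}")
        mass[str(species)] = value * factor

    def _optional(col: str) -> dict[str, float]:
        if col not in df.columns:
            return {}
        sub = df[["species", col]].dropna()
        return {str(s): float(v) for s, v in zip(sub["species"], sub[col])}

    return TraitTable(
        body_mass=mass,
        bill_width=_optional("bill_width"),
        fruit_diameter=_optional("fruit_diameter"),
    )


def write_network(network: InteractionNetwork, path) -> None:
    """Write a network in matrix CSV form (plants in rows)."""
    network.to_frame().to_csv(path, index_label="plant")


def write_traits(traits: TraitTable, path) -> None:
    species = sorted(set(traits.body_mass) | set(traits.bill_width) | set(traits.fruit_diameter))
    df = pd.DataFrame({
        "species": species,
        "body_mass_kg": [traits.body_mass.get(s, np.nan) for s in species],
        "bill_width": [traits.bill_width.get(s, np.nan) for s in species],
        "fruit_diameter": [traits.fruit_diameter.get(s, np.nan) for s in species],
    })
    df.to_csv(path, index=False)


def write_table(records, path, columns: Iterable[str] | None = None) -> None:
    """Write any record set (DataFrame or list of dicts) as CSV with a header.

    Column order is deterministic: as given, or sorted when records are dicts
    and no explicit order is supplied.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records))
        if columns is None and len(df.columns):
            columns = sorted(df.columns)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    df.to_csv(path, index=False)
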
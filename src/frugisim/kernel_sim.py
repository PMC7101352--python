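"""Simulate per-event seed-dispersal distances and community-wide kernels.

Every observed interaction event in a network is replicated ``multiplier``
times (default 1000, to damp stochastic noise while preserving the relative
frequencies of links). Each simulated event draws a gut passage time (Gamma)
and a flight speed (truncated Normal) for the bird involved and yields a
displacement

    distance [m] = fc * GPT[s] * FS[m/s].

Pooling the events of all plants gives the community-wide kernel; its 0.95
quantile is the long-distance dispersal (LDD) statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allometry import (
    DEFAULT_ALLOMETRY,
    AllometryParams,
    SECONDS_PER_HOUR,
    draw_flight_speed,
    draw_gut_passage_time,
)
from .errors import ConfigError, TraitError
from .network_io import InteractionNetwork, TraitTable

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "DispersalKernel",
    "simulate_event_distance",
    "simulate_network_kernel",
    "community_ldd",
    "plant_kernels",
    "regurgitation_filter",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the kernel and extinction simulations.

    multiplier
        Simulated events per observed event (>= 1).
    ldd_quantile
        Quantile of the pooled kernel defining long-distance dispersal.
    n_random_sequences
        Number of random extinction orders averaged in the random scenario.
    pooling
        ``"events"`` pools all events with equal weight (abundant links
        dominate, the default); ``"plants"`` weights each plant's kernel
        equally, for sensitivity analysis.
    """

    multiplier: int = 1000
    ldd_quantile: float = 0.95
    n_random_sequences: int = 1000
    seed: int | None = None
    regurgitation_filter: bool = False
    pooling: str = "events"

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ConfigError(f"multiplier must be >= 1, got {self.multiplier}")
        if not 0 < self.ldd_quantile < 1:
            raise ConfigError(f"ldd_quantile must be in (0, 1), got {self.ldd_quantile}")
        if self.n_random_sequences < 1:
            raise ConfigError(f"n_random_sequences must be >= 1, got {self.n_random_sequences}")
        if self.pooling not in ("events", "plants"):
            raise ConfigError(f"pooling must be 'events' or 'plants', got {self.pooling!r}")


@dataclass(frozen=True, eq=False)
class DispersalKernel:
    """Simulated dispersal events of one network.

    ``plant_idx``/``bird_idx`` index into ``plants``/``birds``; ``distances``
    holds one displacement (m) per simulated event. Event count equals
    ``multiplier`` x total observed events of the simulated network.
    """

    plants: tuple[str, ...]
    birds: tuple[str, ...]
    plant_idx: np.ndarray
    bird_idx: np.ndarray
    distances: np.ndarray
    multiplier: int = 1

    def __post_init__(self) -> None:
        for name in ("plant_idx", "bird_idx", "distances"):
            arr = np.asarray(getattr(self, name))
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        if not (len(self.plant_idx) == len(self.bird_idx) == len(self.distances)):
            raise ValueError("event arrays must have equal length")

    @property
    def n_events(self) -> int:
        return len(self.distances)

    def sorted_desc(self) -> tuple[np.ndarray, np.ndarray]:
        """Distances sorted descending with matching bird indices (cached).

        Backs the fast per-step quantile lookups of the extinction module.
        """
        cache = getattr(self, "_desc_cache", None)
        if cache is None:
            order = np.argsort(-self.distances, kind="stable")
            cache = (self.distances[order], self.bird_idx[order])
            object.__setattr__(self, "_desc_cache", cache)
        return cache

    def events_per_bird(self) -> np.ndarray:
        """Event counts per bird column (cached)."""
        cache = getattr(self, "_per_bird_cache", None)
        if cache is None:
            cache = np.bincount(self.bird_idx, minlength=len(self.birds))
            cache.setflags(write=False)
            object.__setattr__(self, "_per_bird_cache", cache)
        return cache

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "plant": np.asarray(self.plants, dtype=object)[self.plant_idx]
            if self.n_events else np.array([], dtype=object),
            "bird": np.asarray(self.birds, dtype=object)[self.bird_idx]
            if self.n_events else np.array([], dtype=object),
            "distance_m": self.distances,
        })


def simulate_event_distance(rng: np.random.Generator, bm,
                            params: AllometryParams = DEFAULT_ALLOMETRY, size=None):
    """Displacement (m) of one or ``size`` dispersal events for mass ``bm`` (kg)."""
    gpt_h = draw_gut_passage_time(rng, bm, params, size=size)
    fs = draw_flight_speed(rng, bm, params, size=size)
    return params.fc * gpt_h * SECONDS_PER_HOUR * fs


def simulate_network_kernel(
    network: InteractionNetwork,
    traits: TraitTable,
    config: SimulationConfig,
    rng: np.random.Generator,
    params: AllometryParams = DEFAULT_ALLOMETRY,
) -> DispersalKernel:
    """Simulate the dispersal kernel of a whole network.

    Every non-zero cell (plant p, bird b) with observed count w contributes
    ``w * config.multiplier`` events drawn with the body mass of b. Cells are
    processed in row-major order, so results are reproducible for a given
    seeded generator.
    """
    traits.validate_for(network)
    rows, cols = np.nonzero(network.counts)
    n_per_cell = network.counts[rows, cols] * config.multiplier
    total = int(n_per_cell.sum())
    plant_idx = np.repeat(rows, n_per_cell)
    bird_idx = np.repeat(cols, n_per_cell)
    distances = np.empty(total, dtype=float)
    offset = 0
    for r, c, n in zip(rows, cols, n_per_cell):
        n = int(n)
        distances[offset:offset + n] = simulate_event_distance(
            rng, traits.mass(network.birds[c]), params, size=n)
        offset += n
    logger.debug("network %s: simulated %d events (%d observed x %d)",
                 network.network_id, total, network.total_events, config.multiplier)
    return DispersalKernel(
        plants=network.plants, birds=network.birds,
        plant_idx=plant_idx, bird_idx=bird_idx,
        distances=distances, multiplier=config.multiplier,
    )


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    # plotting positions analogous to the unweighted linear-interpolation rule
    p = (cum - 0.5 * w) / cum[-1]
    return float(np.interp(q, p, v, left=v[0], right=v[-1]))


def community_ldd(kernel: DispersalKernel | np.ndarray, q: float = 0.95,
                  pooling: str = "events") -> float:
    """Long-distance dispersal statistic: the q-quantile of the pooled kernel.

    Uses the linear-interpolation quantile convention (the default of
    statistical software). Returns NaN for an empty kernel ("undefined LDD"),
    which callers treat as total functional loss.
    """
    if isinstance(kernel, DispersalKernel):
        distances = kernel.distances
    else:
        distances = np.asarray(kernel, dtype=float)
        if pooling == "plants":
            raise ValueError("plant pooling needs a DispersalKernel, not bare distances")
    if distances.size == 0:
        return float("nan")
    if not 0 < q <= 1:
        raise ValueError(f"quantile must be in (0, 1], got {q}")
    if pooling == "events":
        return float(np.quantile(distances, q, method="linear"))
    if pooling == "plants":
        counts = np.bincount(kernel.plant_idx, minlength=len(kernel.plants)).astype(float)
        weights = 1.0 / counts[kernel.plant_idx]
        return _weighted_quantile(distances, weights, q)
    raise ValueError(f"unknown pooling {pooling!r}")


def plant_kernels(kernel: DispersalKernel) -> dict[str, np.ndarray]:
    """Partition the community kernel into per-plant distance arrays.

    The multiset union of the returned arrays equals the pooled kernel.
    Plants without events are absent from the map.
    """
    out: dict[str, np.ndarray] = {}
    order = np.argsort(kernel.plant_idx, kind="stable")
    sorted_pidx = kernel.plant_idx[order]
    sorted_d = kernel.distances[order]
    boundaries = np.flatnonzero(np.diff(sorted_pidx)) + 1
    for chunk_idx, chunk in zip(
        np.split(sorted_pidx, boundaries), np.split(sorted_d, boundaries)
    ):
        if len(chunk_idx):
            out[kernel.plants[int(chunk_idx[0])]] = chunk
    return out


def regurgitation_filter(network: InteractionNetwork, traits: TraitTable,
                         drop_empty: bool = True) -> InteractionNetwork:
    """Remove links whose fruit cannot be swallowed whole.

    Interactions where the plant's fruit diameter exceeds the bird's bill
    width are assumed to end in regurgitation rather than gut passage and
    are zeroed out. Requires fruit diameter for every plant and bill width
    for every bird participating in a non-zero link.
    """
    missing_p = [p for p, row in zip(network.plants, network.counts)
                 if row.any() and p not in traits.fruit_diameter]
    missing_b = [b for b, col in zip(network.birds, network.counts.T)
                 if col.any() and b not in traits.bill_width]
    if missing_p or missing_b:
        raise TraitError(
            f"regurgitation filter needs fruit_diameter for plants {missing_p} "
            f"and bill_width for birds {missing_b}"
        )
    fruit = np.array([traits.fruit_diameter.get(p, 0.0) for p in network.plants])
    bill = np.array([traits.bill_width.get(b, np.inf) for b in network.birds])
    keep = fruit[:, None] <= bill[None, :]
    counts = np.where(keep, network.counts, 0)
    removed = int(network.counts.sum() - counts.sum())
    if removed:
        logger.info("network %s: regurgitation filter removed %d events",
                    network.network_id, removed)
    filtered = InteractionNetwork(network.network_id, network.plants, network.birds, counts)
    return filtered.drop_empty() if drop_empty else filtered
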
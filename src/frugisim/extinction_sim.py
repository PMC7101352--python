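"""Extinction sequences and the structural/functional state of shrinking networks.

Two scenarios are compared: *downsizing* (a deterministic sequence removing
birds from the largest to the smallest body mass) and *random* (the mean over
many uniform random removal orders). After each removal step the network is
scored relative to the full assemblage:

* percentage of interaction events lost,
* percentage of plant species secondarily extinct (all partners gone —
  topological coextinction, no rewiring and no density compensation),
* percentage change of long-distance dispersal (LDD), the 0.95 quantile of
  the community kernel re-evaluated on the surviving subnetwork.

LDD can be re-simulated from scratch at each step (the default for single
deterministic sequences) or read off a cached master event table by dropping
the events of removed birds (the fast path used for the many random
iterations; the two routes agree statistically).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .allometry import DEFAULT_ALLOMETRY, AllometryParams
from .errors import TraitError
from .kernel_sim import DispersalKernel, SimulationConfig, community_ldd, simulate_network_kernel
from .network_io import InteractionNetwork, TraitTable

__all__ = [
    "ExtinctionTrajectory",
    "downsizing_sequence",
    "random_sequences",
    "remove_birds",
    "structural_state",
    "run_extinction",
    "run_random_scenario",
    "aggregate_random",
]

STEP_COLUMNS = [
    "n_removed",
    "pct_birds_removed",
    "pct_interactions_lost",
    "pct_plants_extinct",
    "pct_ldd_change",
]


@dataclass(frozen=True)
class ExtinctionTrajectory:
    """Per-step state of a network along one removal order (or a mean of many).

    ``steps`` has one row per number of removed birds, 0..n_birds, with
    columns n_removed, pct_birds_removed, pct_interactions_lost,
    pct_plants_extinct, pct_ldd_change.
    """

    network_id: str
    scenario: str
    steps: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in STEP_COLUMNS if c not in self.steps.columns]
        if missing:
            raise ValueError(f"trajectory steps missing columns {missing}")

    @property
    def n_birds(self) -> int:
        return len(self.steps) - 1


def downsizing_sequence(birds: Sequence[str], traits: TraitTable) -> list[str]:
    """Birds ordered from the largest to the smallest body mass.

    Ties are broken by label (lexicographic) so the sequence is deterministic.
    """
    masses = traits.masses(birds)
    return [b for _, b in sorted(zip(-masses, birds))]


def random_sequences(rng: np.random.Generator, birds: Sequence[str],
                     n_iter: int) -> list[list[str]]:
    """``n_iter`` independent uniform random removal orders."""
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    birds = list(birds)
    return [[birds[i] for i in rng.permutation(len(birds))] for _ in range(n_iter)]


def remove_birds(network: InteractionNetwork, removed) -> InteractionNetwork:
    """Subnetwork after removing a set of birds.

    Bird columns are dropped; plant rows are retained even when all-zero,
    because zero rows are exactly the secondary extinctions to be counted.
    """
    removed = set(removed)
    unknown = removed - set(network.birds)
    if unknown:
        raise ValueError(f"cannot remove birds absent from network: {sorted(unknown)}")
    keep = [i for i, b in enumerate(network.birds) if b not in removed]
    return InteractionNetwork(
        network_id=network.network_id,
        plants=network.plants,
        birds=tuple(network.birds[i] for i in keep),
        counts=network.counts[:, keep] if keep else np.zeros((network.n_plants, 0), dtype=np.int64),
    )


def structural_state(sub: InteractionNetwork, original: InteractionNetwork) -> tuple[float, float]:
    """(pct interaction events lost, pct plants secondarily extinct) of ``sub``
    relative to ``original``. Plants of the original network absent from
    ``sub``'s rows, or present with no remaining partner, count as extinct."""
    total = original.total_events
    lost = 100.0 * (1.0 - sub.total_events / total) if total else 0.0
    sub_alive = {p for p, row in zip(sub.plants, sub.counts) if row.sum() > 0}
    extinct = sum(1 for p in original.plants if p not in sub_alive)
    pct_extinct = 100.0 * extinct / original.n_plants if original.n_plants else 0.0
    return lost, pct_extinct


def _order_positions(network: InteractionNetwork, order: Sequence[str]) -> np.ndarray:
    if sorted(order) != sorted(network.birds):
        raise ValueError("order must be a permutation of the network's birds")
    pos_of = {b: m for m, b in enumerate(order)}
    return np.array([pos_of[b] for b in network.birds], dtype=np.int64)


def _structural_profiles(network: InteractionNetwork, positions: np.ndarray):
    """Vectorized per-step structural metrics for one removal order.

    ``positions[j]`` is the step at which bird column j is removed. Returns
    (pct_interactions_lost, pct_plants_extinct), each of length n_birds + 1.
    """
    n = network.n_birds
    colsums = network.counts.sum(axis=0).astype(float)
    lost_at_step = np.zeros(n + 1)
    np.add.at(lost_at_step, positions + 1, colsums)
    cum_lost = np.cumsum(lost_at_step)
    total = network.total_events
    pct_lost = 100.0 * cum_lost / total if total else np.zeros(n + 1)

    # a plant goes extinct one step after its last surviving partner is removed
    has_link = network.counts > 0
    last_partner_step = np.where(
        has_link.any(axis=1),
        np.max(np.where(has_link, positions[None, :], -1), axis=1),
        -1,  # plants with no links are extinct from step 0
    )
    extinct_at = np.zeros(n + 2)
    np.add.at(extinct_at, last_partner_step + 1, 1.0)
    cum_extinct = np.cumsum(extinct_at)[: n + 1]
    pct_extinct = 100.0 * cum_extinct / network.n_plants if network.n_plants else np.zeros(n + 1)
    return pct_lost, pct_extinct


def _ldd_profile_masked(kernel: DispersalKernel, positions: np.ndarray, q: float,
                        pooling: str = "events") -> np.ndarray:
    """LDD at every step by explicitly masking the master event table.

    Straightforward reference route (one boolean mask and one quantile per
    step); ``_ldd_profile_cached`` must agree with it to rounding error.
    """
    n_steps = len(positions) + 1
    ldd = np.full(n_steps, np.nan)
    if kernel.n_events == 0:
        return ldd
    removal_step = positions[kernel.bird_idx]
    for m in range(n_steps):
        mask = removal_step >= m
        if not mask.any():
            continue
        if pooling == "events":
            ldd[m] = np.quantile(kernel.distances[mask], q, method="linear")
        else:
            sub = DispersalKernel(
                plants=kernel.plants, birds=kernel.birds,
                plant_idx=kernel.plant_idx[mask], bird_idx=kernel.bird_idx[mask],
                distances=kernel.distances[mask], multiplier=kernel.multiplier,
            )
            ldd[m] = community_ldd(sub, q, pooling=pooling)
    return ldd


def _lerp(a: float, b: float, t: float) -> float:
    # numpy's branch-symmetric linear interpolation between order statistics
    diff = b - a
    return b - diff * (1.0 - t) if t >= 0.5 else a + t * diff


def _ldd_profile_cached(kernel: DispersalKernel, positions: np.ndarray, q: float,
                        pooling: str = "events") -> np.ndarray:
    """LDD at every step by subsetting a master event table.

    Exact linear-interpolation quantiles read off a cached descending
    distance sort: at each step the required order statistics sit within
    roughly the top (1-q) fraction of surviving events, so only a short
    prefix of the sorted table is scanned; rare deep ranks (very small
    survivor sets) fall back to scanning the full table.
    """
    if pooling != "events":
        return _ldd_profile_masked(kernel, positions, q, pooling)
    n = len(positions)
    ldd = np.full(n + 1, np.nan)
    if kernel.n_events == 0:
        return ldd
    if len(kernel.birds) != n:
        raise ValueError("kernel and removal order describe different bird sets")
    d_desc, bird_desc = kernel.sorted_desc()
    total = kernel.n_events
    # survivors at step m = events of birds removed at steps >= m
    events_at_step = np.zeros(n, dtype=np.int64)
    events_at_step[positions] = kernel.events_per_bird()
    n_sub = total - np.concatenate([[0], np.cumsum(events_at_step)])

    chunk_len = min(total, int((1.0 - q) * 3.0 * total) + 64)
    r_chunk = positions[bird_desc[:chunk_len]]
    r_full = None
    for m in range(n + 1):
        ns = int(n_sub[m])
        if ns == 0:
            continue
        h = q * (ns - 1)
        lo = int(np.floor(h))
        frac = h - lo
        need = ns - lo  # descending rank (1-based) of the lower order statistic
        cs = np.cumsum(r_chunk >= m)
        if cs[-1] < need and chunk_len < total:
            if r_full is None:
                r_full = positions[bird_desc]
            cs = np.cumsum(r_full >= m)
        v_lo = d_desc[int(np.searchsorted(cs, need))]
        if frac > 0:
            v_hi = d_desc[int(np.searchsorted(cs, need - 1))]
            ldd[m] = _lerp(v_lo, v_hi, frac)
        else:
            ldd[m] = v_lo
    return ldd


def _pct_change(ldd: np.ndarray, baseline: float) -> np.ndarray:
    """Percentage change of LDD vs. the full assemblage; no events -> -100%."""
    out = 100.0 * (ldd - baseline) / baseline
    out[np.isnan(ldd)] = -100.0
    return out


def run_extinction(
    network: InteractionNetwork,
    traits: TraitTable,
    order: Sequence[str],
    config: SimulationConfig,
    seed_seq: np.random.SeedSequence,
    params: AllometryParams = DEFAULT_ALLOMETRY,
    ldd_mode: str = "resimulate",
    kernel: DispersalKernel | None = None,
    scenario: str = "custom",
) -> ExtinctionTrajectory:
    """Record the structural and functional state after each removal step.

    ``ldd_mode="resimulate"`` simulates a fresh subnetwork kernel at every
    step with a step-specific child seed; ``"cached"`` subsets one master
    event table (pass a pre-simulated ``kernel`` to reuse it across orders).
    """
    positions = _order_positions(network, order)
    pct_lost, pct_extinct = _structural_profiles(network, positions)
    n = network.n_birds

    if ldd_mode == "cached":
        if kernel is None:
            kernel = simulate_network_kernel(
                network, traits, config, np.random.default_rng(seed_seq), params)
        ldd = _ldd_profile_cached(kernel, positions, config.ldd_quantile, config.pooling)
    elif ldd_mode == "resimulate":
        ldd = np.full(n + 1, np.nan)
        step_seeds = seed_seq.spawn(n + 1)
        for m in range(n + 1):
            sub = remove_birds(network, order[:m])
            if sub.total_events == 0:
                continue
            sub_kernel = simulate_network_kernel(
                sub, traits, config, np.random.default_rng(step_seeds[m]), params)
            ldd[m] = community_ldd(sub_kernel, config.ldd_quantile, config.pooling)
    else:
        raise ValueError(f"ldd_mode must be 'resimulate' or 'cached', got {ldd_mode!r}")

    steps = pd.DataFrame({
        "n_removed": np.arange(n + 1),
        "pct_birds_removed": 100.0 * np.arange(n + 1) / n if n else [0.0],
        "pct_interactions_lost": pct_lost,
        "pct_plants_extinct": pct_extinct,
        "pct_ldd_change": _pct_change(ldd, ldd[0]),
    })
    return ExtinctionTrajectory(network.network_id, scenario, steps)


def run_random_scenario(
    network: InteractionNetwork,
    traits: TraitTable,
    config: SimulationConfig,
    seed_seq: np.random.SeedSequence,
    params: AllometryParams = DEFAULT_ALLOMETRY,
    kernel: DispersalKernel | None = None,
    return_iterations: bool = False,
):
    """Mean trajectory over ``config.n_random_sequences`` random orders.

    One master kernel is simulated (or passed in) and subset for every order
    and step. Equivalent to averaging ``run_extinction(..., ldd_mode="cached",
    kernel=...)`` over ``random_sequences`` with the same seeds, but without
    building per-iteration objects.
    """
    kernel_seed, orders_seed = seed_seq.spawn(2)
    if kernel is None:
        kernel = simulate_network_kernel(
            network, traits, config, np.random.default_rng(kernel_seed), params)
    orders = random_sequences(np.random.default_rng(orders_seed),
                              network.birds, config.n_random_sequences)
    n = network.n_birds
    sums = np.zeros((3, n + 1))
    iterations = [] if return_iterations else None
    for it, order in enumerate(orders):
        positions = _order_positions(network, order)
        pct_lost, pct_extinct = _structural_profiles(network, positions)
        ldd = _ldd_profile_cached(kernel, positions, config.ldd_quantile, config.pooling)
        pct_ldd = _pct_change(ldd, ldd[0])
        sums[0] += pct_lost
        sums[1] += pct_extinct
        sums[2] += pct_ldd
        if iterations is not None:
            iterations.append(ExtinctionTrajectory(
                network.network_id, f"random({it})",
                pd.DataFrame({
                    "n_removed": np.arange(n + 1),
                    "pct_birds_removed": 100.0 * np.arange(n + 1) / n if n else [0.0],
                    "pct_interactions_lost": pct_lost,
                    "pct_plants_extinct": pct_extinct,
                    "pct_ldd_change": pct_ldd,
                })))
    means = sums / len(orders)
    mean_traj = ExtinctionTrajectory(
        network.network_id, "random",
        pd.DataFrame({
            "n_removed": np.arange(n + 1),
            "pct_birds_removed": 100.0 * np.arange(n + 1) / n if n else [0.0],
            "pct_interactions_lost": means[0],
            "pct_plants_extinct": means[1],
            "pct_ldd_change": means[2],
        }))
    if return_iterations:
        return mean_traj, iterations
    return mean_traj


def aggregate_random(trajectories: Sequence[ExtinctionTrajectory]) -> ExtinctionTrajectory:
    """Pointwise mean of metric columns across iterations on one network."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    ids = {t.network_id for t in trajectories}
    if len(ids) > 1:
        raise ValueError(f"trajectories come from different networks: {sorted(ids)}")
    lengths = {len(t.steps) for t in trajectories}
    if len(lengths) > 1:
        raise ValueError("trajectories have different numbers of steps")
    first = trajectories[0].steps
    metric_cols = ["pct_interactions_lost", "pct_plants_extinct", "pct_ldd_change"]
    stacked = np.mean([t.steps[metric_cols].to_numpy() for t in trajectories], axis=0)
    steps = first[["n_removed", "pct_birds_removed"]].copy()
    steps[metric_cols] = stacked
    return ExtinctionTrajectory(trajectories[0].network_id, "random", steps)
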
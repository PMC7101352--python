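"""Generate synthetic multi-network frugivory studies.

The generator emulates the statistical structure the analysis assumes: a set
of weighted plant-bird networks (default eight, mirroring a multi-site Andean
study design) with

* 20-45 bird and plant species per network,
* bird body masses log-normal within 0.01-1.77 kg (small tanager-sized
  species common, large guan-sized species rare),
* fruit diameters log-normal (mm),
* size matching: the probability of a link decays with the squared mismatch
  between a bird's log mass and the plant's "matched mass" implied by its
  fruit size (Gaussian kernel on log-mass mismatch; strength 0 = random
  attachment),
* skewed integer link weights (1 + negative binomial), emulating the
  heavy-tailed event counts typical of frugivory networks.

Networks are resampled per species until every plant and bird holds at least
one link, so every generated community passes network validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .network_io import InteractionNetwork, TraitTable, write_network, write_traits

__all__ = ["GeneratorParams", "generate_community", "generate_study"]


@dataclass(frozen=True)
class GeneratorParams:
    """Defaults describe the study conditions every pipeline test assumes."""

    n_networks: int = 8
    n_birds_range: tuple[int, int] = (20, 45)
    n_plants_range: tuple[int, int] = (20, 45)
    mass_range_kg: tuple[float, float] = (0.01, 1.77)
    mass_meanlog: float = float(np.log(0.05))  # median body mass ~50 g
    mass_sdlog: float = 1.2
    fruit_range_mm: tuple[float, float] = (2.0, 40.0)
    fruit_meanlog: float = float(np.log(8.0))  # median fruit diameter ~8 mm
    fruit_sdlog: float = 0.45
    connectance: float = 0.15
    size_matching_strength: float = 4.0  # 0 = random attachment
    count_mean: float = 3.0  # mean events per realized link
    count_dispersion: float = 0.7  # negative-binomial dispersion (smaller = more skew)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_networks < 1:
            raise ConfigError("n_networks must be >= 1")
        for name in ("n_birds_range", "n_plants_range", "mass_range_kg", "fruit_range_mm"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ConfigError(f"{name} must satisfy 0 < low <= high, got {(lo, hi)}")
        if not 0 < self.connectance <= 1:
            raise ConfigError(f"connectance must be in (0, 1], got {self.connectance}")
        if self.size_matching_strength < 0:
            raise ConfigError("size_matching_strength must be >= 0")
        if self.count_mean < 1 or self.count_dispersion <= 0:
            raise ConfigError("count_mean must be >= 1 and count_dispersion > 0")


def _truncated_lognormal(rng, meanlog, sdlog, lo, hi, size):
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.lognormal(meanlog, sdlog, size=todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def generate_community(params: GeneratorParams, rng: np.random.Generator,
                       network_id: str = "synthetic") -> tuple[InteractionNetwork, TraitTable]:
    """One synthetic network plus its trait table.

    Link weights between plant p and bird b are Bernoulli-realized with
    probability proportional to ``exp(-s * (log m_b - mu_p)^2)`` normalized
    per plant, where ``mu_p`` maps the plant's fruit-size z-score onto the
    community's log-mass scale and ``s`` is the size-matching strength
    (s = 0 gives uniform random attachment).
    """
    nb = int(rng.integers(params.n_birds_range[0], params.n_birds_range[1] + 1))
    npl = int(rng.integers(params.n_plants_range[0], params.n_plants_range[1] + 1))
    birds = tuple(f"bird_{i+1:02d}" for i in range(nb))
    plants = tuple(f"plant_{i+1:02d}" for i in range(npl))

    mass = _truncated_lognormal(rng, params.mass_meanlog, params.mass_sdlog,
                                *params.mass_range_kg, size=nb)
    fruit = _truncated_lognormal(rng, params.fruit_meanlog, params.fruit_sdlog,
                                 *params.fruit_range_mm, size=npl)
    # bill width scales roughly with the cube root of body mass
    bill = 18.0 * mass ** 0.33 * rng.lognormal(0.0, 0.1, size=nb)

    logm = np.log(mass)
    logf = np.log(fruit)
    f_sd = logf.std() or 1.0
    matched_logmass = logm.mean() + (logf - logf.mean()) / f_sd * (logm.std() or 1.0)

    s = params.size_matching_strength
    weight = np.exp(-s * (logm[None, :] - matched_logmass[:, None]) ** 2)
    probs = weight / weight.sum(axis=1, keepdims=True)
    expected_degree = params.connectance * nb
    if expected_degree < 1:
        raise ConfigError(
            f"infeasible connectance {params.connectance}: expected plant degree < 1")
    p_link = np.clip(expected_degree * probs, 0.0, 1.0)

    adj = rng.random((npl, nb)) < p_link
    # guarantee every species at least one link, preferring the best size match
    for i in np.flatnonzero(~adj.any(axis=1)):
        adj[i, int(np.argmax(weight[i]))] = True
    for j in np.flatnonzero(~adj.any(axis=0)):
        adj[int(np.argmax(weight[:, j])), j] = True

    k = params.count_dispersion
    mu = params.count_mean - 1.0
    counts = np.zeros((npl, nb), dtype=np.int64)
    n_links = int(adj.sum())
    if mu > 0:
        extra = rng.negative_binomial(k, k / (k + mu), size=n_links)
    else:
        extra = np.zeros(n_links, dtype=np.int64)
    counts[adj] = 1 + extra

    network = InteractionNetwork(network_id, plants, birds, counts)
    traits = TraitTable(
        body_mass=dict(zip(birds, mass)),
        bill_width=dict(zip(birds, bill)),
        fruit_diameter=dict(zip(plants, fruit)),
    )
    return network, traits


def generate_study(params: GeneratorParams, rng: np.random.Generator | None = None,
                   out_dir=None) -> list[tuple[InteractionNetwork, TraitTable]]:
    """Generate ``params.n_networks`` communities; optionally write CSVs.

    With ``out_dir`` set, each community is written as
    ``network_<i>.csv`` / ``traits_<i>.csv`` plus a ``study.yaml`` manifest,
    ready for the file-based CLI pipeline.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    communities = [
        generate_community(params, rng, network_id=f"synthetic-{i+1:02d}")
        for i in range(params.n_networks)
    ]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        entries = []
        for i, (net, traits) in enumerate(communities):
            npath = out / f"network_{i+1:02d}.csv"
            tpath = out / f"traits_{i+1:02d}.csv"
            write_network(net, npath)
            write_traits(traits, tpath)
            entries.append({"network_id": net.network_id,
                            "network": npath.name, "traits": tpath.name})
        (out / "study.yaml").write_text(
            yaml.safe_dump({"networks": entries, "mass_unit": "kg"}, sort_keys=False))
    return communities
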
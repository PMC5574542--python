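"""Synthetic study regions with the statistical shape of a shire county.

The generator emulates the structure of aggregated sexual-health demand in a
county like Hampshire: a couple of hundred postcode-sector demand points, a
few dozen existing clinics sitting at urban cluster centres, demand heavily
skewed towards the conurbations, car travel times derived from straight-line
distance with a detour factor, and public-transport times a constant multiple
of car times plus a waiting overhead.

It also builds *planted-optimum* instances: geometries in which a designated
set of sites is provably the unique coverage maximiser, used as an oracle for
solver testing.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .instance import (
    CandidateSite,
    DemandNode,
    Instance,
    TravelTimeMatrix,
    ValidationError,
)

__all__ = ["GeneratorParams", "PlantedInstance", "generate_instance", "plant_optimum"]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic county.

    Defaults emulate the Hampshire configuration: 278 postcode-sector demand
    nodes, 28 existing clinics at urban cluster centres (305-ish candidates
    once sector centroids are added), roughly half the demand urban, about
    188k annual visits, and public transport ~2-3x slower than car.
    """

    n_demand: int = 278
    n_centres: int = 28
    cluster_sd_km: float = 2.0
    urban_fraction: float = 0.5
    total_demand: float = 188_054.0
    car_speed_kmh: float = 40.0
    detour_factor: float = 1.3
    pt_multiplier: float = 2.2
    pt_wait_min: float = 8.0
    region_size_km: float = 60.0
    demand_noise_sd: float = 0.8  # lognormal sigma on node demand
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_demand < 1:
            raise ValidationError("n_demand must be >= 1")
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ValidationError("urban_fraction must be in [0, 1]")
        if self.car_speed_kmh <= 0:
            raise ValidationError("car_speed_kmh must be > 0")
        if self.detour_factor < 1:
            raise ValidationError("detour_factor must be >= 1")
        if self.pt_multiplier < 1:
            raise ValidationError("pt_multiplier must be >= 1")
        if self.pt_wait_min < 0:
            raise ValidationError("pt_wait_min must be >= 0")


@dataclass
class PlantedInstance:
    """An instance whose unique coverage optimum is known by construction."""

    instance: Instance
    planted_sites: set[int]
    planted_P: int
    planted_coverage: float


def _travel_matrices(
    node_xy: np.ndarray, site_xy: np.ndarray, p: GeneratorParams
) -> dict[str, TravelTimeMatrix]:
    """Straight-line-derived times: car = dist * detour / speed, PT = car *
    multiplier + wait.  Both scale linearly with Euclidean distance."""
    diff = node_xy[:, None, :] - site_xy[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    car = dist * p.detour_factor / p.car_speed_kmh * 60.0
    pt = car * p.pt_multiplier + p.pt_wait_min
    return {
        "car": TravelTimeMatrix(mode="car", times=car),
        "public_transport": TravelTimeMatrix(mode="public_transport", times=pt),
    }


def _assemble(
    node_xy: np.ndarray,
    demands: np.ndarray,
    centre_xy: np.ndarray,
    p: GeneratorParams,
    extra_meta: dict | None = None,
) -> Instance:
    """Build the Instance: clinics (existing) first, then sector centroids."""
    nodes = [
        DemandNode(i, f"SEC{i:03d} 1", float(x), float(y), float(h))
        for i, ((x, y), h) in enumerate(zip(node_xy, demands))
    ]
    sites = [
        CandidateSite(k, f"CLINIC{k:02d}", float(x), float(y), True)
        for k, (x, y) in enumerate(centre_xy)
    ]
    off = len(sites)
    sites += [
        CandidateSite(off + i, f"SEC{i:03d} 1", float(x), float(y), False)
        for i, (x, y) in enumerate(node_xy)
    ]
    site_xy = np.vstack([centre_xy, node_xy])
    meta = {"generator": asdict(p)}
    meta.update(extra_meta or {})
    return Instance(nodes, sites, _travel_matrices(node_xy, site_xy, p), meta)


def generate_instance(params: GeneratorParams) -> Instance:
    """Draw a synthetic instance; fully reproducible from ``params.seed``.

    Cluster centres are uniform in the region with skewed (lognormal) weights
    so a couple of conurbation-like clusters dominate.  A ``urban_fraction``
    share of the demand nodes is Gaussian-scattered around weighted clusters,
    the rest uniform rural background.  Node demand is proportional to the
    cluster-weighted mixture intensity with lognormal multiplicative noise,
    rescaled so it sums to ``total_demand`` exactly.  Candidates are every
    sector centroid plus the cluster centres, the latter flagged as existing
    clinics.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    L = p.region_size_km
    margin = min(0.1 * L, 2.0 * p.cluster_sd_km)

    centre_xy = rng.uniform(margin, L - margin, size=(p.n_centres, 2))
    # skewed cluster weights: a few clusters act as the conurbations
    w = rng.lognormal(mean=0.0, sigma=1.0, size=p.n_centres)
    w /= w.sum()

    n_urban = int(round(p.n_demand * p.urban_fraction))
    node_xy = np.empty((p.n_demand, 2))
    if n_urban:
        ks = rng.choice(p.n_centres, size=n_urban, p=w)
        node_xy[:n_urban] = centre_xy[ks] + rng.normal(
            0.0, p.cluster_sd_km, size=(n_urban, 2)
        )
    node_xy[n_urban:] = rng.uniform(0.0, L, size=(p.n_demand - n_urban, 2))
    node_xy = np.clip(node_xy, 0.0, L)

    # mixture intensity at each node: urban gaussian bumps + rural floor
    d2 = ((node_xy[:, None, :] - centre_xy[None, :, :]) ** 2).sum(axis=2)
    var = p.cluster_sd_km**2
    bumps = (w[None, :] * np.exp(-d2 / (2 * var)) / (2 * np.pi * var)).sum(axis=1)
    intensity = p.urban_fraction * bumps + (1.0 - p.urban_fraction) / L**2
    demands = intensity * rng.lognormal(0.0, p.demand_noise_sd, size=p.n_demand)
    demands *= p.total_demand / demands.sum()

    return _assemble(node_xy, demands, centre_xy, p)


def plant_optimum(
    params: GeneratorParams, planted_P: int, T: float
) -> PlantedInstance:
    """Construct an instance whose unique optimum at budget ``planted_P`` and
    car threshold ``T`` is known.

    Geometry: ``planted_P`` well-separated clusters, each a ring of 8 demand
    nodes at radius 0.95r around its centre, where r is the distance a car
    covers in T minutes.  Each planted centre covers its whole ring; the ring
    spacing makes any sector-centroid candidate cover at most 3 ring nodes
    (itself and its two 45-degree neighbours, since the 90-degree chord
    already exceeds r).  Hence every budget-``planted_P`` set other than the
    centres leaves most of one ring uncovered and is strictly worse, making
    the planted set the unique maximiser — and the unique minimum-cardinality
    one.
    """
    p = params
    if planted_P < 1:
        raise ValidationError("planted_P must be >= 1")
    if planted_P > p.n_centres:
        raise ValidationError(
            f"planted_P={planted_P} exceeds n_centres={p.n_centres}"
        )
    rng = np.random.default_rng(p.seed)
    r = T / 60.0 * p.car_speed_kmh / p.detour_factor  # car range at threshold
    spacing = 4.0 * r
    g = math.ceil(math.sqrt(planted_P))
    extent = (g - 1) * spacing + 2 * r
    if extent > p.region_size_km:
        raise ValidationError(
            f"cannot fit {planted_P} clusters of range {r:.2f} km in a "
            f"{p.region_size_km} km region; shrink T or enlarge the region"
        )
    pad = r
    centre_xy = np.array(
        [(pad + (k % g) * spacing, pad + (k // g) * spacing)
         for k in range(planted_P)]
    )

    m = 8  # ring size; 90-degree chord 1.343r > r keeps centroid cover <= 3
    phases = rng.uniform(0, 2 * np.pi, size=planted_P)
    ang = (np.arange(m) * 2 * np.pi / m)[None, :] + phases[:, None]
    ring = 0.95 * r * np.stack([np.cos(ang), np.sin(ang)], axis=-1)
    node_xy = (centre_xy[:, None, :] + ring).reshape(-1, 2)

    base = rng.uniform(80.0, 120.0, size=planted_P)  # per-cluster node demand
    demands = np.repeat(base, m)

    inst = _assemble(node_xy, demands, centre_xy, p,
                     extra_meta={"planted_P": planted_P, "planted_T": T})
    planted = set(range(planted_P))  # clinics come first in _assemble
    return PlantedInstance(
        instance=inst,
        planted_sites=planted,
        planted_P=planted_P,
        planted_coverage=float(demands.sum()),
    )
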
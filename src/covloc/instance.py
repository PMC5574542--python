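"""Problem instances for travel-time coverage analysis.

A location instance couples three tables: demand nodes (aggregated demand
points, e.g. UK postcode sectors with annual clinic visits), candidate
facility sites (existing clinics and/or sector centroids), and one
travel-time matrix per transport mode (minutes from every demand node to
every candidate site).  The optimisation layer consumes only demands and
travel times; coordinates are carried for reporting and synthesis.

File dialect (delimited text, comma or tab):

* demand table:  ``sector,x_km,y_km,demand``
* sites table:   ``site,x_km,y_km,existing``   (existing in {0,1})
* travel matrix: first column ``sector``, one column per site label,
  cells in minutes.

Row/column alignment between tables is by label after whitespace trimming
and uppercasing, so formatting differences between sources do not matter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .solvers import Solution

__all__ = [
    "ValidationError",
    "DemandNode",
    "CandidateSite",
    "TravelTimeMatrix",
    "Instance",
    "DemandProjection",
    "read_instance",
    "write_instance",
    "restrict_candidates",
    "project_demand",
    "write_solution_report",
    "import_s1_workbook",
]

MODES = ("car", "public_transport")


class ValidationError(ValueError):
    """Raised when an input table violates an instance invariant."""


def _norm_label(label: str) -> str:
    return str(label).strip().upper()


@dataclass(frozen=True)
class DemandNode:
    """An aggregated demand point (postcode-sector centroid).

    ``demand`` is annual visits (h_i); real-valued because projected demand
    is fractional.
    """

    id: int
    label: str
    x: float
    y: float
    demand: float

    def __post_init__(self) -> None:
        if self.demand < 0:
            raise ValidationError(
                f"demand node {self.label!r}: negative demand {self.demand}"
            )
        if not str(self.label).strip():
            raise ValidationError(f"demand node id {self.id}: empty label")


@dataclass(frozen=True)
class CandidateSite:
    """A location where a facility may be opened.

    ``existing_clinic`` distinguishes currently operating clinics from
    potential new locations (sector centroids).
    """

    id: int
    label: str
    x: float
    y: float
    existing_clinic: bool


@dataclass(frozen=True)
class TravelTimeMatrix:
    """Minutes of travel from every demand node (row) to every site (column)."""

    mode: str
    times: np.ndarray  # shape (|I|, |J|), minutes

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if not np.all(np.isfinite(t)):
            i, j = np.argwhere(~np.isfinite(t))[0]
            raise ValidationError(
                f"travel matrix ({self.mode}): non-finite time at row {i}, col {j}"
            )
        if np.any(t < 0):
            i, j = np.argwhere(t < 0)[0]
            raise ValidationError(
                f"travel matrix ({self.mode}): negative time {t[i, j]} "
                f"at row {i}, col {j}"
            )


@dataclass
class Instance:
    """Demand nodes, candidate sites and per-mode travel matrices (sets I, J)."""

    demand_nodes: list[DemandNode]
    candidate_sites: list[CandidateSite]
    travel: dict[str, TravelTimeMatrix]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, m = len(self.demand_nodes), len(self.candidate_sites)
        if n == 0:
            raise ValidationError("instance has no demand nodes")
        for seq, kind in ((self.demand_nodes, "demand node"),
                          (self.candidate_sites, "candidate site")):
            ids = [e.id for e in seq]
            if ids != list(range(len(ids))):
                raise ValidationError(f"{kind} ids not contiguous from 0: {ids[:5]}...")
        for mode, tm in self.travel.items():
            if tm.times.shape != (n, m):
                raise ValidationError(
                    f"travel matrix ({mode}) shape {tm.times.shape} "
                    f"!= (|I|, |J|) = ({n}, {m})"
                )
        if self.total_demand <= 0:
            raise ValidationError("total demand must be positive")

    # -- convenience accessors ------------------------------------------------

    @property
    def demands(self) -> np.ndarray:
        return np.array([d.demand for d in self.demand_nodes], dtype=float)

    @property
    def total_demand(self) -> float:
        return float(self.demands.sum())

    @property
    def n_demand(self) -> int:
        return len(self.demand_nodes)

    @property
    def n_sites(self) -> int:
        return len(self.candidate_sites)

    @property
    def modes(self) -> tuple[str, ...]:
        return tuple(self.travel)

    def equals(self, other: "Instance", tol: float = 1e-9) -> bool:
        """Field-level equality with travel times compared to ``tol`` minutes."""
        if (self.n_demand, self.n_sites, set(self.modes)) != (
            other.n_demand, other.n_sites, set(other.modes)
        ):
            return False
        for a, b in zip(self.demand_nodes, other.demand_nodes):
            if (a.id, a.label) != (b.id, b.label):
                return False
            if max(abs(a.x - b.x), abs(a.y - b.y), abs(a.demand - b.demand)) > tol:
                return False
        for a, b in zip(self.candidate_sites, other.candidate_sites):
            if (a.id, a.label, a.existing_clinic) != (b.id, b.label, b.existing_clinic):
                return False
            if max(abs(a.x - b.x), abs(a.y - b.y)) > tol:
                return False
        return all(
            np.allclose(self.travel[m].times, other.travel[m].times, atol=tol)
            for m in self.modes
        )


@dataclass
class DemandProjection:
    """Stratified demand forecast: per-node baseline shares times growth factors.

    ``baseline_share[i, s]`` is the fraction of node *i*'s baseline demand in
    stratum *s* (an age-band/gender cell); rows sum to one.  ``growth_factor[s]``
    scales that stratum to the target year, so projected demand is
    ``h_i * sum_s share[i, s] * growth[s]``.  Over a 3-5 year horizon the
    factors sit near 1 and the total shifts only slightly.
    """

    strata: list[str]
    baseline_share: np.ndarray  # (|I|, n_strata), rows sum to 1
    growth_factor: np.ndarray  # (n_strata,), > 0

    def __post_init__(self) -> None:
        self.baseline_share = np.asarray(self.baseline_share, dtype=float)
        self.growth_factor = np.asarray(self.growth_factor, dtype=float)
        if self.baseline_share.ndim != 2 or self.baseline_share.shape[1] != len(self.strata):
            raise ValidationError("baseline_share shape must be (n_nodes, n_strata)")
        rowsum = self.baseline_share.sum(axis=1)
        bad = np.where(np.abs(rowsum - 1.0) > 1e-9)[0]
        if bad.size:
            raise ValidationError(
                f"baseline shares of node {bad[0]} sum to {rowsum[bad[0]]}, not 1"
            )
        if np.any(self.growth_factor <= 0):
            raise ValidationError("growth factors must be positive")


# -- readers / writers --------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    return pd.read_csv(path, sep=None, engine="python")


def read_instance(
    demand_table_path: str | Path,
    sites_table_path: str | Path,
    travel_table_paths_by_mode: Mapping[str, str | Path],
    metadata: dict | None = None,
) -> Instance:
    """Load and validate an instance from the canonical delimited tables.

    Travel-matrix rows and columns are aligned to the demand and site tables
    by normalised label; a demand node missing from any travel matrix is an
    error naming the offending row.
    """
    dem = _read_table(demand_table_path)
    for col in ("sector", "x_km", "y_km", "demand"):
        if col not in dem.columns:
            raise ValidationError(f"demand table missing column {col!r}")
    if len(dem) == 0:
        raise ValidationError("demand table has zero rows")

    sit = _read_table(sites_table_path)
    for col in ("site", "x_km", "y_km", "existing"):
        if col not in sit.columns:
            raise ValidationError(f"sites table missing column {col!r}")
    if len(sit) == 0:
        raise ValidationError("sites table has zero rows")

    nodes = []
    for i, row in enumerate(dem.itertuples(index=False)):
        if row.demand < 0:
            raise ValidationError(
                f"demand table row {i} ({row.sector!r}): negative demand {row.demand}"
            )
        nodes.append(DemandNode(i, str(row.sector).strip(), float(row.x_km),
                                float(row.y_km), float(row.demand)))
    dup = dem["sector"].map(_norm_label).duplicated()
    if dup.any():
        raise ValidationError(f"duplicate demand label {dem['sector'][dup].iloc[0]!r}")

    sites = [
        CandidateSite(j, str(row.site).strip(), float(row.x_km), float(row.y_km),
                      bool(int(row.existing)))
        for j, row in enumerate(sit.itertuples(index=False))
    ]
    if sit["site"].map(_norm_label).duplicated().any():
        raise ValidationError("duplicate site label in sites table")

    node_keys = [_norm_label(n.label) for n in nodes]
    site_keys = [_norm_label(s.label) for s in sites]

    travel: dict[str, TravelTimeMatrix] = {}
    for mode, tpath in travel_table_paths_by_mode.items():
        tt = _read_table(tpath)
        first = tt.columns[0]
        tt = tt.set_index(tt[first].map(_norm_label)).drop(columns=[first])
        tt.columns = [_norm_label(c) for c in tt.columns]
        missing = [k for k in node_keys if k not in tt.index]
        if missing:
            raise ValidationError(
                f"travel matrix ({mode}): demand node {missing[0]!r} has no row"
            )
        missing_c = [k for k in site_keys if k not in tt.columns]
        if missing_c:
            raise ValidationError(
                f"travel matrix ({mode}): site {missing_c[0]!r} has no column"
            )
        aligned = tt.loc[node_keys, site_keys].to_numpy(dtype=float)
        neg = np.argwhere(aligned < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"travel matrix ({mode}): negative time {aligned[i, j]} at "
                f"row {nodes[i].label!r}, column {sites[j].label!r}"
            )
        travel[mode] = TravelTimeMatrix(mode=mode, times=aligned)

    return Instance(nodes, sites, travel, metadata=dict(metadata or {}))


def write_instance(instance: Instance, out_dir: str | Path) -> dict[str, Path]:
    """Write an instance back to the canonical dialect; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    dem = pd.DataFrame(
        {"sector": [n.label for n in instance.demand_nodes],
         "x_km": [n.x for n in instance.demand_nodes],
         "y_km": [n.y for n in instance.demand_nodes],
         "demand": [n.demand for n in instance.demand_nodes]}
    )
    paths["demand"] = out / "demand.csv"
    dem.to_csv(paths["demand"], index=False)

    sit = pd.DataFrame(
        {"site": [s.label for s in instance.candidate_sites],
         "x_km": [s.x for s in instance.candidate_sites],
         "y_km": [s.y for s in instance.candidate_sites],
         "existing": [int(s.existing_clinic) for s in instance.candidate_sites]}
    )
    paths["sites"] = out / "sites.csv"
    sit.to_csv(paths["sites"], index=False)

    for mode, tm in instance.travel.items():
        df = pd.DataFrame(tm.times, columns=[s.label for s in instance.candidate_sites])
        df.insert(0, "sector", [n.label for n in instance.demand_nodes])
        paths[f"travel_{mode}"] = out / f"travel_{mode}.csv"
        df.to_csv(paths[f"travel_{mode}"], index=False)
    return paths


# -- transformations ----------------------------------------------------------


def restrict_candidates(instance: Instance, selector: str) -> Instance:
    """Filter the candidate set: ``existing_only`` keeps current clinics, ``all``
    keeps everything.  Demand nodes are unchanged; travel columns follow."""
    if selector not in ("existing_only", "all"):
        raise ValidationError(
            f"unknown candidate selector {selector!r}; use 'existing_only' or 'all'"
        )
    if selector == "all":
        keep = list(range(instance.n_sites))
    else:
        keep = [s.id for s in instance.candidate_sites if s.existing_clinic]
    if not keep:
        raise ValidationError("candidate selector yields an empty candidate set")
    sites = [
        replace(instance.candidate_sites[j], id=new_id)
        for new_id, j in enumerate(keep)
    ]
    travel = {
        mode: TravelTimeMatrix(mode=mode, times=tm.times[:, keep])
        for mode, tm in instance.travel.items()
    }
    meta = dict(instance.metadata)
    meta["candidate_selector"] = selector
    return Instance(list(instance.demand_nodes), sites, travel, metadata=meta)


def project_demand(instance: Instance, projection: DemandProjection) -> Instance:
    """Scale each node's demand through the stratified growth factors.

    New demand is ``h_i * sum_s baseline_share[i, s] * growth_factor[s]``;
    with all factors at 1 this is the identity.
    """
    if projection.baseline_share.shape[0] != instance.n_demand:
        raise ValidationError(
            f"projection covers {projection.baseline_share.shape[0]} nodes, "
            f"instance has {instance.n_demand}"
        )
    mult = projection.baseline_share @ projection.growth_factor
    nodes = [
        replace(n, demand=float(n.demand * mult[i]))
        for i, n in enumerate(instance.demand_nodes)
    ]
    meta = dict(instance.metadata)
    meta["demand_projection"] = {
        "strata": list(projection.strata),
        "growth_factor": [float(g) for g in projection.growth_factor],
    }
    return Instance(nodes, list(instance.candidate_sites), dict(instance.travel),
                    metadata=meta)


# -- solution reporting -------------------------------------------------------


def write_solution_report(
    solution: "Solution",
    instance: Instance,
    path: str | Path,
) -> tuple[Path, Path]:
    """Write a machine-readable solution report plus a GeoJSON of selected sites.

    The JSON report carries the selected sites (with labels and coordinates),
    per-node coverage flags, covered demand, coverage percentage and solver
    metadata; coverage figures are recomputed from the instance demands so the
    report is self-consistent.  Returns (json_path, geojson_path).
    """
    path = Path(path)
    for j in solution.selected:
        if not 0 <= j < instance.n_sites:
            raise ValidationError(
                f"solution references site id {j}; instance has "
                f"{instance.n_sites} sites"
            )
    h = instance.demands
    covered = np.asarray(solution.covered, dtype=bool)
    covered_demand = float(h[covered].sum())
    total = instance.total_demand
    meta = dict(solution.solver_meta)
    report = {
        "selected_sites": [
            {
                "id": int(j),
                "label": instance.candidate_sites[j].label,
                "x_km": instance.candidate_sites[j].x,
                "y_km": instance.candidate_sites[j].y,
                "existing_clinic": instance.candidate_sites[j].existing_clinic,
            }
            for j in sorted(solution.selected)
        ],
        "covered_nodes": [int(z) for z in covered],
        "covered_demand": covered_demand,
        "total_demand": total,
        "coverage_pct": 100.0 * covered_demand / total,
        "mode": meta.get("mode"),
        "threshold_minutes": meta.get("threshold_minutes"),
        "solver": meta.get("method"),
        "seed": meta.get("seed"),
        "iterations": meta.get("iterations"),
        "runtime_s": meta.get("runtime_s"),
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2))

    geojson = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point",
                             "coordinates": [s["x_km"], s["y_km"]]},
                "properties": {k: s[k] for k in ("id", "label", "existing_clinic")},
            }
            for s in report["selected_sites"]
        ],
    }
    geo_path = path.with_suffix(".geojson")
    geo_path.write_text(json.dumps(geojson, indent=2))
    return path, geo_path


# -- supplementary workbook import -------------------------------------------


def import_s1_workbook(
    xlsx_path: str | Path,
    out_dir: str | Path,
    modes: Iterable[str] = MODES,
) -> dict[str, Path]:
    """Convert a supplementary XLSX workbook to the canonical delimited tables.

    Expects sheets named ``demand``, ``sites`` and ``travel_<mode>`` carrying
    the canonical columns.  Workbooks from other sources usually need their
    sheets renamed or reshaped to this layout first; this function is the
    single adaptation point for that.
    """
    xlsx_path = Path(xlsx_path)
    if not xlsx_path.exists():
        raise ValidationError(f"workbook not found: {xlsx_path}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    book = pd.read_excel(xlsx_path, sheet_name=None)
    lowered = {str(k).strip().lower(): v for k, v in book.items()}
    wanted = ["demand", "sites"] + [f"travel_{m}" for m in modes]
    paths: dict[str, Path] = {}
    for name in wanted:
        if name not in lowered:
            raise ValidationError(
                f"workbook sheet {name!r} not found; sheets present: "
                f"{sorted(lowered)}"
            )
        paths[name] = out / f"{name}.csv"
        lowered[name].to_csv(paths[name], index=False)
    return paths
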
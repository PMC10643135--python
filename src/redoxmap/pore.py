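"""Channel radius profiling by probe-sphere maximization.

Along a user-supplied pathway line (start point + direction, e.g. the
membrane normal through a transporter), the profiler finds at each
station the largest probe sphere that fits without overlapping any atom's
van der Waals sphere, with the probe center free to move in the plane
normal to the pathway.  The objective at a center c is

    radius(c) = min_i ( |c - x_i| - vdw_i )

maximized by seeded random restarts followed by derivative-free local
refinement (Nelder–Mead; the objective is piecewise smooth).  Station
centers are chained — each station starts from the previous optimum — so
the profile tracks a continuous channel.  The profile terminates on
either side once the radius exceeds a bulk cap (default 10 Å), i.e. the
probe has escaped into solvent.

The global minimum of the profile is the channel's constriction; the
residues owning the atoms nearest to it are the gate-forming residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from redoxmap.structures import Structure, AtomRecord

__all__ = [
    "PorePoint",
    "PoreProfile",
    "pore_profile",
    "constriction_report",
    "DEFAULT_VDW_TABLE",
]

#: Bondi-style van der Waals radii (Å) for the elements lining protein channels.
DEFAULT_VDW_TABLE: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "FE": 1.40, "NA": 2.27, "K": 2.75, "MG": 1.73, "CL": 1.75,
}
_VDW_DEFAULT = 1.70


@dataclass(frozen=True)
class PorePoint:
    station: float                 # Å along the pathway
    center: np.ndarray             # 3-vector
    radius: float                  # Å, largest non-overlapping probe
    nearest_atoms: tuple[tuple[AtomRecord, float], ...]  # (atom, gap), sorted by gap

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("pore radius must be >= 0")


@dataclass
class PoreProfile:
    points: list[PorePoint]        # stations strictly increasing
    seed: int
    step: float
    bulk_cap: float
    vdw_table_id: str = "bondi"

    def __post_init__(self):
        st = [p.station for p in self.points]
        if any(b <= a for a, b in zip(st, st[1:])):
            raise ValueError("stations must be strictly increasing")

    @property
    def constriction(self) -> PorePoint:
        return min(self.points, key=lambda p: p.radius)

    @property
    def stations(self) -> np.ndarray:
        return np.array([p.station for p in self.points])

    @property
    def radii(self) -> np.ndarray:
        return np.array([p.radius for p in self.points])

    def to_tsv(self) -> str:
        lines = ["station_A\tradius_A\tx\ty\tz\tnearest_residues"]
        for p in self.points:
            res = ";".join(f"{a.residue_name}{a.chain_id}{a.residue_seq}"
                           for a, _ in p.nearest_atoms)
            x, y, z = p.center
            lines.append(f"{p.station:.2f}\t{p.radius:.3f}\t{x:.3f}\t{y:.3f}\t{z:.3f}\t{res}")
        return "\n".join(lines) + "\n"


def _clearance(center: np.ndarray, coords: np.ndarray, vdw: np.ndarray) -> float:
    return float(np.min(np.linalg.norm(coords - center, axis=1) - vdw))


def _optimize_station(
    origin: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    coords: np.ndarray,
    vdw: np.ndarray,
    rng: np.random.Generator,
    n_restarts: int,
    search_radius: float,
    prev_offset: np.ndarray | None,
):
    """Maximize clearance over the normal plane; returns (offset_2d, radius)."""

    def neg(xy):
        c = origin + xy[0] * u + xy[1] * v
        return -_clearance(c, coords, vdw)

    starts = [np.zeros(2)]
    if prev_offset is not None:
        starts.append(prev_offset.copy())
    starts.extend(rng.uniform(-search_radius, search_radius, size=(n_restarts, 2)))
    best_xy, best_val = np.zeros(2), neg(np.zeros(2))
    for x0 in starts:
        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
        # reject optima that wandered out of the channel search disc
        if np.linalg.norm(res.x) > search_radius:
            continue
        if res.fun < best_val:
            best_val, best_xy = res.fun, res.x
    return best_xy, -best_val


def _plane_basis(direction: np.ndarray):
    w = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, w)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(w, helper)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return w, u, v


def pore_profile(
    s: Structure,
    start: np.ndarray | list[float],
    direction: np.ndarray | list[float],
    step: float = 0.25,
    seed: int = 0,
    bulk_cap: float = 10.0,
    n_restarts: int = 16,
    max_stations: int = 400,
) -> PoreProfile:
    """Probe-sphere radius profile along a pathway through a structure.

    Marches from ``start`` in both directions along ``direction`` in
    ``step`` Å increments, terminating on each side when the radius
    exceeds ``bulk_cap`` or after ``max_stations`` stations.  Deterministic
    for a given seed.
    """
    if not 0.1 < step <= 1.0:
        raise ValueError(f"step {step} outside the supported (0.1, 1.0] Å window")
    start = np.asarray(start, float)
    direction = np.asarray(direction, float)
    if np.linalg.norm(direction) < 1e-12:
        raise ValueError("direction must be non-zero")
    w, u, v = _plane_basis(direction)

    coords = s.coords
    if len(coords) == 0:
        raise ValueError("no channel environment: structure is empty")
    vdw = np.array([DEFAULT_VDW_TABLE.get(a.element.upper(), _VDW_DEFAULT) for a in s.atoms])
    # restrict to atoms near the pathway cylinder
    rel = coords - start
    axial = rel @ w
    radial = np.linalg.norm(rel - np.outer(axial, w), axis=1)
    near = radial <= bulk_cap + np.max(vdw) + 2.0
    if not np.any(near):
        raise ValueError("no channel environment: no atoms near the pathway")
    coords_n = coords[near]
    vdw_n = vdw[near]
    atoms_n = [a for a, keep in zip(s.atoms, near) if keep]

    rng = np.random.default_rng(seed)
    search_radius = bulk_cap

    def march(sign: int):
        pts = []
        prev = None
        for k in range(0 if sign > 0 else 1, max_stations):
            station = sign * k * step
            origin = start + station * w
            xy, radius = _optimize_station(origin, u, v, coords_n, vdw_n, rng,
                                           n_restarts, search_radius, prev)
            prev = xy
            center = origin + xy[0] * u + xy[1] * v
            if radius < 0:
                warnings.warn(f"station {station:.2f} Å: probe center inside an atom; "
                              "radius clamped at 0", stacklevel=3)
                radius = 0.0
            gaps = np.linalg.norm(coords_n - center, axis=1) - vdw_n
            order = np.argsort(gaps)[:3]
            nearest = tuple((atoms_n[int(i)], float(gaps[int(i)])) for i in order)
            pts.append(PorePoint(station, center, float(radius), nearest))
            if radius > bulk_cap:
                break
        return pts

    forward = march(+1)
    backward = march(-1)
    points = list(reversed(backward)) + forward
    return PoreProfile(points, seed=seed, step=step, bulk_cap=bulk_cap)


def constriction_report(p: PoreProfile, s: Structure, n_nearest: int = 5):
    """The profile's global minimum and the residues owning its nearest atoms.

    Returns ``(constriction_point, residues)`` where residues is a list of
    (chain_id, residue_seq, residue_name) owning the ``n_nearest`` atoms
    closest (by vdW gap) to the constriction center.
    """
    if not p.points:
        raise ValueError("empty profile")
    c = p.constriction
    coords = s.coords
    vdw = np.array([DEFAULT_VDW_TABLE.get(a.element.upper(), _VDW_DEFAULT) for a in s.atoms])
    gaps = np.linalg.norm(coords - c.center, axis=1) - vdw
    order = np.argsort(gaps)[:n_nearest]
    residues = []
    for i in order:
        a = s.atoms[int(i)]
        key = (a.chain_id, a.residue_seq, a.residue_name)
        if key not in residues:
            residues.append(key)
    return c, residues
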
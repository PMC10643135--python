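"""Synthetic structures and spectra with exactly known ground truth.

Every analysis stage in this package can be exercised on a fixture whose
answer is known by construction: ideal α-helices at controlled tilts,
planar isoalloxazine-like ring pairs with a prescribed closest ring–ring
gap, [2Fe-2S] rhombs at the canonical Fe–Fe 2.70 Å / Fe–S 2.28 Å
geometry, ion sites with a chosen coordination number and mean ligand
distance, atom-lined channels with a known radius profile, two-state
hinge-motion pairs with a prescribed rotation, and noisy 1-D spectra.
Fixtures are minimal geometric scaffolds, not physically realistic
decoys; each writes to a standard PDB file so the file-reading path is
exercised end to end.

All randomness is drawn from a per-recipe seed; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import math

import numpy as np

from redoxmap.structures import AtomRecord, Structure
from redoxmap.spectra import Spectrum1D, MossbauerDoublet, EprComponent, simulate_mossbauer, simulate_epr_powder

__all__ = [
    "FixtureRecipe",
    "make_ideal_helix",
    "make_fes_cluster",
    "make_flavin_pair",
    "make_ion_site",
    "make_channel",
    "make_hinge_pair",
    "make_noisy_spectrum",
    "rotation_about_axis",
]

# canonical geometry constants
HELIX_TWIST_DEG = 100.0     # per residue
HELIX_RISE = 1.5            # Å per residue
HELIX_RADIUS = 2.3          # Å, Cα radius
FE_FE_DISTANCE = 2.70       # Å, typical [2Fe-2S]
FE_S_DISTANCE = 2.28        # Å


@dataclass(frozen=True)
class FixtureRecipe:
    """A serializable description of one fixture."""

    kind: str
    parameters: dict
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FixtureRecipe":
        d = json.loads(text)
        return cls(kind=d["kind"], parameters=d.get("parameters", {}), seed=d.get("seed", 0))

    def build(self):
        builders = {
            "helix": make_ideal_helix,
            "fes_cluster": make_fes_cluster,
            "flavin_pair": make_flavin_pair,
            "ion_site": make_ion_site,
            "channel": make_channel,
            "hinge_motion_pair": make_hinge_pair,
            "spectrum": make_noisy_spectrum,
        }
        if self.kind not in builders:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        kwargs = dict(self.parameters)
        if self.kind in ("hinge_motion_pair", "spectrum"):
            kwargs.setdefault("seed", self.seed)
        return builders[self.kind](**kwargs)


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (normalized) axis."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    t = math.radians(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)


def _frame_for(axis: np.ndarray) -> np.ndarray:
    """Rotation taking +z to the given axis."""
    z = np.array([0.0, 0.0, 1.0])
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    v = np.cross(z, a)
    c = float(np.dot(z, a))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else rotation_about_axis(np.array([1.0, 0, 0]), 180.0)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K * ((1 - c) / (np.linalg.norm(v) ** 2))


def make_ideal_helix(
    n_res: int,
    axis: np.ndarray | list[float] = (0.0, 0.0, 1.0),
    origin: np.ndarray | list[float] = (0.0, 0.0, 0.0),
    chain_id: str = "A",
    start_seq: int = 1,
    structure_id: str = "helix",
) -> Structure:
    """Ideal poly-Ala Cα helix: 100° twist, 1.5 Å rise, 2.3 Å radius."""
    if n_res < 7:
        raise ValueError("an analyzable helix needs >= 7 residues")
    R = _frame_for(np.asarray(axis, float))
    origin = np.asarray(origin, float)
    atoms = []
    for i in range(n_res):
        t = math.radians(HELIX_TWIST_DEG * i)
        local = np.array([HELIX_RADIUS * math.cos(t), HELIX_RADIUS * math.sin(t), HELIX_RISE * i])
        atoms.append(AtomRecord(
            serial=i + 1, name="CA", element="C", altloc="",
            residue_name="ALA", chain_id=chain_id, residue_seq=start_seq + i,
            insertion_code="", position=R @ local + origin,
        ))
    return Structure(structure_id, atoms)


def make_fes_cluster(
    center: np.ndarray | list[float] = (0.0, 0.0, 0.0),
    orientation: np.ndarray | None = None,
    chain_id: str = "X",
    residue_seq: int = 501,
    structure_id: str = "fes",
) -> Structure:
    """Planar [2Fe-2S] rhomb: Fe–Fe 2.70 Å, all four Fe–S 2.28 Å."""
    center = np.asarray(center, float)
    R = np.eye(3) if orientation is None else np.asarray(orientation, float)
    half_fe = FE_FE_DISTANCE / 2.0
    half_s = math.sqrt(FE_S_DISTANCE ** 2 - half_fe ** 2)
    local = {
        "FE1": np.array([+half_fe, 0.0, 0.0]),
        "FE2": np.array([-half_fe, 0.0, 0.0]),
        "S1": np.array([0.0, +half_s, 0.0]),
        "S2": np.array([0.0, -half_s, 0.0]),
    }
    atoms = []
    for i, (name, pos) in enumerate(local.items()):
        atoms.append(AtomRecord(
            serial=i + 1, name=name, element="FE" if name.startswith("FE") else "S",
            altloc="", residue_name="FES", chain_id=chain_id,
            residue_seq=residue_seq, insertion_code="",
            position=R @ pos + center, is_hetero=True,
        ))
    return Structure(structure_id, atoms)


def _isoalloxazine_coords() -> dict[str, np.ndarray]:
    """Planar idealized isoalloxazine ring system (xy plane, 1.40 Å bonds).

    Three fused six-membered rings laid out on a regular hexagonal grid;
    chemically idealized, geometrically flat — sufficient for edge-distance
    work where only planarity and atom names matter.
    """
    b = 1.40
    h = b * math.sqrt(3) / 2.0
    # hexagonal lattice columns x = k*h, rows offset by b/2
    def p(col, row):
        return np.array([col * h, row * b / 2.0, 0.0])
    coords = {
        # ring I (pyrimidinedione): N1 C2 N3 C4 C4A C10
        "N1": p(0, 2), "C2": p(0, 0), "N3": p(1, -1), "C4": p(2, 0),
        "C4A": p(2, 2), "C10": p(1, 3),
        # exocyclic carbonyl oxygens
        "O2": p(-1, -1), "O4": p(3, -1),
        # ring II (pyrazine): C4A N5 C5A C9A N10 C10
        "N5": p(3, 3), "C5A": p(3, 5), "C9A": p(2, 6), "N10": p(1, 5),
        # ring III (benzene): C5A C6 C7 C8 C9 C9A
        "C6": p(4, 6), "C7": p(4, 8), "C8": p(3, 9), "C9": p(2, 8),
    }
    return coords


def make_flavin_pair(
    gap: float,
    residue_name: str = "FMN",
    structure_id: str = "flavin_pair",
) -> Structure:
    """Two coplanar flavin ring systems with closest ring–ring gap ``gap`` Å.

    The second ring is the first translated along +x; the translation is
    solved numerically (bisection on the brute-force minimum inter-ring
    distance, which is monotone in the translation) so the realized gap
    matches the request to < 1e-6 Å.
    """
    if gap <= 0:
        raise ValueError("gap must be > 0")
    ring = _isoalloxazine_coords()
    pts = np.stack(list(ring.values()))

    def min_gap(dx: float) -> float:
        shifted = pts + np.array([dx, 0.0, 0.0])
        d = np.linalg.norm(pts[:, None, :] - shifted[None, :, :], axis=-1)
        return float(d.min())

    extent = pts[:, 0].max() - pts[:, 0].min()
    lo, hi = extent, extent + gap + 10.0
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if min_gap(mid) < gap:
            lo = mid
        else:
            hi = mid
    dx = (lo + hi) / 2.0

    atoms = []
    serial = 0
    for copy, (chain, seq, shift) in enumerate(
            [("A", 901, 0.0), ("B", 902, dx)]):
        for name, pos in ring.items():
            serial += 1
            atoms.append(AtomRecord(
                serial=serial, name=name, element=name[0], altloc="",
                residue_name=residue_name, chain_id=chain, residue_seq=seq,
                insertion_code="", position=pos + np.array([shift, 0.0, 0.0]),
                is_hetero=True,
            ))
    return Structure(structure_id, atoms)


# near-uniform unit directions for up to 8 ligands (octahedron + cube corners)
_LIGAND_DIRECTIONS = [
    np.array(v, float) for v in [
        (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
        (1, 1, 1), (-1, -1, -1),
    ]
]


def make_ion_site(
    identity: str = "NA",
    cn: int = 5,
    mean_dist: float = 2.4,
    ligand_classes: list[str] | None = None,
    structure_id: str = "ion_site",
) -> Structure:
    """An ion with ``cn`` oxygen ligands at exactly ``mean_dist`` Å.

    ``ligand_classes`` selects per-ligand chemistry from
    {"carbonyl", "water"} (default: all carbonyl).  Carbonyl ligands are
    backbone O atoms of glycine residues; water ligands are HOH oxygens.
    Geometrically infeasible requests (too many ligands too close) raise.
    """
    if not 0 <= cn <= len(_LIGAND_DIRECTIONS):
        raise ValueError(f"coordination number {cn} unsupported (max {len(_LIGAND_DIRECTIONS)})")
    if cn > 0 and mean_dist < 1.8:
        raise ValueError(f"mean distance {mean_dist} Å infeasible for an O shell")
    if ligand_classes is None:
        ligand_classes = ["carbonyl"] * cn
    if len(ligand_classes) != cn:
        raise ValueError("ligand_classes length must equal cn")
    center = np.zeros(3)
    atoms = [AtomRecord(
        serial=1, name=identity.upper(), element=identity.upper(), altloc="",
        residue_name=identity.upper(), chain_id="I", residue_seq=601,
        insertion_code="", position=center, is_hetero=True,
    )]
    # minimum inter-ligand separation check (hard O–O clash below 2.2 Å)
    if cn >= 2:
        pos = [mean_dist * d / np.linalg.norm(d) for d in _LIGAND_DIRECTIONS[:cn]]
        dmin = min(np.linalg.norm(a - b) for i, a in enumerate(pos) for b in pos[i + 1:])
        if dmin < 2.2:
            raise ValueError(
                f"CN {cn} at {mean_dist} Å gives O–O contacts of {dmin:.2f} Å: infeasible")
    wat_seq = 701
    gly_seq = 101
    for k in range(cn):
        d = _LIGAND_DIRECTIONS[k]
        pos = mean_dist * d / np.linalg.norm(d)
        cls = ligand_classes[k]
        if cls == "water":
            atoms.append(AtomRecord(
                serial=len(atoms) + 1, name="O", element="O", altloc="",
                residue_name="HOH", chain_id="W", residue_seq=wat_seq,
                insertion_code="", position=pos, is_hetero=True,
            ))
            wat_seq += 1
        elif cls == "carbonyl":
            atoms.append(AtomRecord(
                serial=len(atoms) + 1, name="O", element="O", altloc="",
                residue_name="GLY", chain_id="P", residue_seq=gly_seq,
                insertion_code="", position=pos,
            ))
            # carbonyl carbon pointing away from the ion (excluded as ligand)
            atoms.append(AtomRecord(
                serial=len(atoms) + 1, name="C", element="C", altloc="",
                residue_name="GLY", chain_id="P", residue_seq=gly_seq,
                insertion_code="", position=pos + 1.23 * pos / np.linalg.norm(pos),
            ))
            gly_seq += 1
        else:
            raise ValueError(f"unknown ligand class {cls!r}")
    return Structure(structure_id, atoms)


def make_channel(
    radius_profile: list[tuple[float, float]],
    atoms_per_ring: int = 12,
    element: str = "C",
    vdw_radius: float = 1.70,
    structure_id: str = "channel",
) -> Structure:
    """A channel of stacked atom rings along +z with known pore radii.

    ``radius_profile`` lists (z_station, pore_radius) pairs; each ring of
    ``atoms_per_ring`` atoms is placed at ring radius pore_radius +
    vdw_radius, so the analytic probe radius in the ring plane is exactly
    the requested pore radius.
    """
    if not radius_profile:
        raise ValueError("radius_profile must be non-empty")
    atoms = []
    serial = 0
    for ri, (z, pore_r) in enumerate(radius_profile):
        if pore_r <= 0:
            raise ValueError("pore radii must be > 0")
        ring_r = pore_r + vdw_radius
        for k in range(atoms_per_ring):
            t = 2.0 * math.pi * k / atoms_per_ring
            serial += 1
            atoms.append(AtomRecord(
                serial=serial, name=f"{element}{k + 1}", element=element, altloc="",
                residue_name="RNG", chain_id="R", residue_seq=801 + ri,
                insertion_code="",
                position=np.array([ring_r * math.cos(t), ring_r * math.sin(t), z]),
                is_hetero=True,
            ))
    return Structure(structure_id, atoms)


def make_hinge_pair(
    angle_deg: float,
    axis: np.ndarray | list[float] = (0.0, 1.0, 0.0),
    pivot: np.ndarray | list[float] = (0.0, 0.0, 30.0),
    core_res: int = 20,
    domain_res: int = 20,
    seed: int = 0,
) -> tuple[Structure, Structure]:
    """Two-state pair: shared core helix + domain helix rotated about a hinge.

    Returns (ref, mov).  The core (chain A, residues 1..core_res) is
    identical in both states; the domain (chain B) is rotated by
    ``angle_deg`` about the axis through ``pivot`` in the second state.
    """
    core = make_ideal_helix(core_res, axis=(0, 0, 1), origin=(0, 0, 0), chain_id="A")
    dom = make_ideal_helix(domain_res, axis=(1, 0, 0), origin=(5.0, 3.0, 34.0),
                           chain_id="B", structure_id="domain")
    R = rotation_about_axis(np.asarray(axis, float), angle_deg)
    pivot = np.asarray(pivot, float)
    moved = dom.transformed(R, pivot - R @ pivot)
    ref = Structure("hinge_ref", list(core.atoms) + list(dom.atoms))
    mov = Structure("hinge_mov", list(core.atoms) + list(moved.atoms))
    return ref, mov


def make_noisy_spectrum(
    model: str = "mossbauer",
    params: dict | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    axis: np.ndarray | None = None,
) -> Spectrum1D:
    """Simulate a model spectrum and add seeded Gaussian noise.

    ``noise_sigma`` is in the same (absolute) units as the ordinate.
    ``model`` is "mossbauer" (params for :class:`MossbauerDoublet`) or
    "epr" (params: components=[EprComponent kwargs...], frequency_ghz).
    """
    if noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    params = params or {}
    if model == "mossbauer":
        if axis is None:
            axis = np.linspace(-2.0, 2.0, 801)
        clean = simulate_mossbauer(MossbauerDoublet(**params), axis)
    elif model == "epr":
        comp = [EprComponent(**kw) for kw in params["components"]]
        freq = params["frequency_ghz"]
        if axis is None:
            axis = np.linspace(300.0, 370.0, 1401)
        clean = simulate_epr_powder(comp, freq, axis)
    else:
        raise ValueError(f"unknown spectrum model {model!r}")
    rng = np.random.default_rng(seed)
    noisy = clean.ordinate + rng.normal(0.0, noise_sigma, size=clean.ordinate.shape) \
        if noise_sigma > 0 else clean.ordinate.copy()
    return Spectrum1D(clean.axis, noisy, axis_unit=clean.axis_unit,
                      frequency_ghz=clean.frequency_ghz,
                      noise_sigma=noise_sigma, seed=seed)
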
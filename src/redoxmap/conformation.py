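"""Rigid-body motions between conformational states.

Two experimental structures of the same complex are compared by (1)
least-squares superposition of a static *core* selection (for a membrane
complex, typically the transmembrane subunits), then (2) quantifying how a
mobile *domain* selection moves in that common frame: rotation
angle/axis, screw translation along the axis, and the maximum per-residue
Cα displacement.  Transmembrane helix reorientation is measured as the
angle between the principal axes of the helix Cα sets in the two states,
and crosslinking mass-spectrometry restraints are validated as Cα–Cα
distances against the crosslinker span (~30 Å Cα–Cα for the
lysine-reactive reagent DSS).

Atom pairing between states is strictly by (chain, residue number,
insertion code, atom name): the states are the same protein, so no
sequence alignment is attempted, and residues present in only one state
are reported rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
import warnings

import numpy as np

from redoxmap.structures import Structure, AtomRecord

__all__ = [
    "SelectionSpec",
    "RigidTransform",
    "DomainTransform",
    "HelixTiltResult",
    "CrosslinkRecord",
    "GeometryError",
    "superpose",
    "domain_motion",
    "helix_tilt",
    "crosslink_check",
    "kabsch",
]


class GeometryError(ValueError):
    """Raised when a selection is too degenerate to superpose."""


@dataclass(frozen=True)
class SelectionSpec:
    """A set of residues on one chain, filtered by atom name (default Cα)."""

    chain_id: str
    residue_ranges: tuple[tuple[int, int], ...]
    atom_names: tuple[str, ...] = ("CA",)

    def __post_init__(self):
        if not self.residue_ranges:
            raise ValueError("selection needs at least one residue range")
        for lo, hi in self.residue_ranges:
            if hi < lo:
                raise ValueError(f"empty residue range {lo}-{hi}")

    def contains(self, seq: int) -> bool:
        return any(lo <= seq <= hi for lo, hi in self.residue_ranges)

    def resolve(self, s: Structure) -> list[AtomRecord]:
        names = {n.upper() for n in self.atom_names}
        out = [
            a for a in s.chain_atoms(self.chain_id)
            if self.contains(a.residue_seq) and a.name.upper() in names
        ]
        return out


@dataclass(frozen=True)
class RigidTransform:
    """x -> R @ x + t with det(R) = +1."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    @property
    def angle_deg(self) -> float:
        tr = float(np.trace(self.rotation))
        c = min(1.0, max(-1.0, (tr - 1.0) / 2.0))
        return math.degrees(math.acos(c))

    @property
    def axis(self) -> np.ndarray:
        """Unit rotation axis (arbitrary for the identity)."""
        R = self.rotation
        w, v = np.linalg.eig(R)
        i = int(np.argmin(np.abs(w - 1.0)))
        axis = np.real(v[:, i])
        axis /= np.linalg.norm(axis)
        # orient so that the rotation about +axis has positive angle
        skew = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        if np.dot(skew, axis) < 0:
            axis = -axis
        return axis


def kabsch(P: np.ndarray, Q: np.ndarray) -> RigidTransform:
    """Optimal proper rotation + translation mapping P onto Q (least squares)."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return RigidTransform(R, t)


def _paired_coords(ref: Structure, mov: Structure, sel: SelectionSpec):
    """Coordinates of atoms present in both states, paired by identity."""
    ref_atoms = {(a.residue_seq, a.insertion_code, a.name.upper()): a for a in sel.resolve(ref)}
    mov_atoms = {(a.residue_seq, a.insertion_code, a.name.upper()): a for a in sel.resolve(mov)}
    common = sorted(set(ref_atoms) & set(mov_atoms))
    unmatched = sorted((set(ref_atoms) ^ set(mov_atoms)))
    if unmatched:
        warnings.warn(
            f"selection chain {sel.chain_id}: {len(unmatched)} atoms present in "
            f"only one state (first: {unmatched[0]})", stacklevel=3)
    P = np.array([ref_atoms[k].position for k in common]).reshape(-1, 3)
    Q = np.array([mov_atoms[k].position for k in common]).reshape(-1, 3)
    return P, Q, common


def _check_nondegenerate(P: np.ndarray, what: str):
    if len(P) < 3:
        raise GeometryError(f"{what}: needs >= 3 paired atoms, got {len(P)}")
    s = np.linalg.svd(P - P.mean(axis=0), compute_uv=False)
    if s[1] < 1e-6:
        raise GeometryError(f"{what}: paired atoms are collinear")


def superpose(ref: Structure, mov: Structure, core: SelectionSpec | list[SelectionSpec]):
    """Superpose ``mov`` onto ``ref`` over the core selection.

    Returns ``(transform, rmsd)`` where ``transform`` maps mov coordinates
    into the ref frame and ``rmsd`` is over the paired core atoms (Å).
    """
    specs = core if isinstance(core, list) else [core]
    Ps, Qs = [], []
    for spec in specs:
        P, Q, _ = _paired_coords(ref, mov, spec)
        Ps.append(P)
        Qs.append(Q)
    P = np.vstack(Ps)
    Q = np.vstack(Qs)
    _check_nondegenerate(P, "superposition core")
    tf = kabsch(Q, P)   # maps mov -> ref frame
    rmsd = float(np.sqrt(np.mean(np.sum((tf.apply(Q) - P) ** 2, axis=1))))
    return tf, rmsd


@dataclass(frozen=True)
class DomainTransform:
    """Rigid motion of a domain between two states, in the core frame."""

    rotation_angle: float      # degrees, in [0, 180]
    rotation_axis: np.ndarray  # unit 3-vector
    screw_translation: float   # Å along the axis
    max_displacement: float    # Å, largest per-atom shift after core superposition
    rmsd_domain: float         # Å, residual of the domain's own rigid fit
    centroid_shift: float      # Å, domain centroid displacement

    def __post_init__(self):
        if not (0.0 <= self.rotation_angle <= 180.0 + 1e-9):
            raise ValueError("rotation angle outside [0, 180]")
        if abs(np.linalg.norm(self.rotation_axis) - 1.0) > 1e-6:
            raise ValueError("rotation axis must be unit norm")
        if self.max_displacement < 0:
            raise ValueError("max displacement must be >= 0")


def domain_motion(
    ref: Structure,
    mov: Structure,
    core: SelectionSpec | list[SelectionSpec],
    domain: SelectionSpec | list[SelectionSpec],
) -> DomainTransform:
    """Quantify a rigid domain motion between two states.

    After superposing the states on the core, the domain's own optimal
    rigid transform (ref-domain -> mov-domain, both in the core frame)
    gives the rotation angle/axis and the screw translation; the maximum
    displacement is the largest per-atom shift of the paired domain atoms.
    """
    core_specs = core if isinstance(core, list) else [core]
    dom_specs = domain if isinstance(domain, list) else [domain]
    for cs in core_specs:
        for ds in dom_specs:
            if cs.chain_id == ds.chain_id:
                overlap = [
                    (lo, hi) for lo, hi in cs.residue_ranges
                    for lo2, hi2 in ds.residue_ranges
                    if lo <= hi2 and lo2 <= hi
                ]
                if overlap:
                    raise ValueError("core and domain selections overlap")

    tf, _ = superpose(ref, mov, core_specs)
    Ps, Qs = [], []
    for spec in dom_specs:
        P, Q, _ = _paired_coords(ref, mov, spec)
        Ps.append(P)
        Qs.append(Q)
    P = np.vstack(Ps)             # domain in ref
    Q = tf.apply(np.vstack(Qs))   # domain in mov, expressed in ref/core frame
    _check_nondegenerate(P, "domain selection")

    disp = np.linalg.norm(Q - P, axis=1)
    dom_tf = kabsch(P, Q)
    resid = dom_tf.apply(P) - Q
    rmsd_domain = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    axis = dom_tf.axis
    screw = float(np.dot(dom_tf.translation
                         + (dom_tf.rotation - np.eye(3)) @ P.mean(axis=0), axis))
    return DomainTransform(
        rotation_angle=dom_tf.angle_deg,
        rotation_axis=axis,
        screw_translation=screw,
        max_displacement=float(disp.max()),
        rmsd_domain=rmsd_domain,
        centroid_shift=float(np.linalg.norm(Q.mean(axis=0) - P.mean(axis=0))),
    )


@dataclass(frozen=True)
class HelixTiltResult:
    tilt_deg: float
    centroid_shift: float           # Å, in the core frame
    fit_rmsd_ref: float             # Å, perpendicular scatter about the axis
    fit_rmsd_mov: float

    def __float__(self) -> float:
        return self.tilt_deg


def _helix_axis(coords: np.ndarray):
    """Principal axis of a Cα set, oriented N->C; returns (centroid, axis, rmsd).

    The fit rmsd is the scatter of the Cα radial distances about their
    mean — zero for a perfect cylinder (any ideal helix), large for a
    bent helix or a non-helical blob.
    """
    c = coords.mean(axis=0)
    X = coords - c
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    axis = Vt[0]
    if np.dot(coords[-1] - coords[0], axis) < 0:
        axis = -axis
    perp = X - np.outer(X @ axis, axis)
    radial = np.linalg.norm(perp, axis=1)
    rmsd = float(np.std(radial))
    return c, axis, rmsd


def helix_tilt(
    ref: Structure,
    mov: Structure,
    core: SelectionSpec | list[SelectionSpec],
    helix: SelectionSpec,
) -> HelixTiltResult:
    """Tilt (degrees) of a helix between two states, in the core frame.

    The helix axis in each state is the principal component of its Cα
    coordinates, disambiguated to point N->C.  A perpendicular scatter
    above 1 Å triggers a warning: the selection is unlikely to be a single
    straight helix.
    """
    n_res = sum(hi - lo + 1 for lo, hi in helix.residue_ranges)
    if n_res < 7:
        raise ValueError("helix selection must span >= 7 residues")
    tf, _ = superpose(ref, mov, core)
    P, Q, _ = _paired_coords(ref, mov, helix)
    if len(P) < 7:
        raise GeometryError(f"helix selection resolves only {len(P)} paired Cα")
    Q = tf.apply(Q)
    c1, a1, r1 = _helix_axis(P)
    c2, a2, r2 = _helix_axis(Q)
    for tag, r in (("ref", r1), ("mov", r2)):
        if r > 1.0:
            warnings.warn(f"helix fit rmsd {r:.2f} Å in {tag}: selection may not be helical",
                          stacklevel=2)
    cosang = min(1.0, max(-1.0, float(np.dot(a1, a2))))
    return HelixTiltResult(
        tilt_deg=math.degrees(math.acos(cosang)),
        centroid_shift=float(np.linalg.norm(c2 - c1)),
        fit_rmsd_ref=r1,
        fit_rmsd_mov=r2,
    )


@dataclass(frozen=True)
class CrosslinkRecord:
    chain_1: str
    residue_1: int
    chain_2: str
    residue_2: int
    ca_distance: float | None       # Å; None when a residue is unresolved
    max_allowed: float
    compatible: bool | None
    resolved: bool

    def __post_init__(self):
        if self.resolved and self.compatible != (self.ca_distance <= self.max_allowed):
            raise ValueError("compatibility flag inconsistent with distance")


#: Default Cα–Cα upper bound for a DSS (disuccinimidyl suberate) crosslink:
#: two lysine side chains plus the 11.4 Å spacer arm, with conformational slack.
DSS_MAX_CA_DISTANCE = 30.0


def crosslink_check(
    s: Structure,
    pairs: list[tuple[str, int, str, int]],
    max_allowed: float = DSS_MAX_CA_DISTANCE,
) -> list[CrosslinkRecord]:
    """Check residue pairs against a crosslinker Cα–Cα distance bound.

    Unresolvable residues produce a flagged (``resolved=False``) record
    rather than being dropped, so the report length always equals the
    input length.
    """
    out = []
    for c1, r1, c2, r2 in pairs:
        a1 = s.find_atom(c1, r1, "CA")
        a2 = s.find_atom(c2, r2, "CA")
        if a1 is None or a2 is None:
            out.append(CrosslinkRecord(c1, r1, c2, r2, None, max_allowed, None, False))
            continue
        d = float(np.linalg.norm(a1.position - a2.position))
        out.append(CrosslinkRecord(c1, r1, c2, r2, d, max_allowed, d <= max_allowed, True))
    return out
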
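"""Ion-binding-site identification from first-shell coordination geometry.

Cryo-EM density alone cannot distinguish a bound alkali ion from a water
molecule, but the identity of the occupant can be inferred from the
number and geometry of the atoms in its first coordination shell: Na+
is typically coordinated by 4–6 oxygen ligands at 2.2–2.6 Å (backbone
carbonyls and waters in protein sites), K+ by 5–8 oxygens at 2.6–3.1 Å,
while a water merely hydrogen-bonds to a couple of partners at 2.6–3.2 Å.
This module computes coordination shells around candidate positions,
classifies them against configurable distance/coordination-number bands,
and screens every modeled water and monatomic ion in a structure.

Carbon and hydrogen are never counted as ligands (neither coordinates an
alkali cation in a protein site).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from redoxmap.structures import Structure, AtomRecord, WATER_CODES

__all__ = [
    "CoordinationShell",
    "Ligand",
    "SiteCall",
    "ClassificationRules",
    "find_coordination",
    "classify_site",
    "scan_candidate_ions",
    "DEFAULT_RULES",
]

logger = logging.getLogger(__name__)

_AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

_MONATOMIC_IONS = {"NA", "K", "RB", "CS", "LI", "MG", "CA", "ZN", "CL", "MN", "FE"}


def _ligand_class(a: AtomRecord) -> str:
    el = a.element.upper()
    if el == "O":
        if a.residue_name in WATER_CODES:
            return "water O"
        if a.residue_name in _AMINO3:
            return "backbone carbonyl O" if a.name.upper() in ("O", "OXT") else "side-chain O"
        return "other O"
    if el == "N":
        return "N"
    if el == "S":
        return "S"
    return "other"


@dataclass(frozen=True)
class Ligand:
    atom: AtomRecord
    distance: float
    ligand_class: str


@dataclass(frozen=True)
class CoordinationShell:
    center: np.ndarray
    ligands: tuple[Ligand, ...]
    cutoff: float

    @property
    def coordination_number(self) -> int:
        return len(self.ligands)

    @property
    def mean_distance(self) -> float:
        if not self.ligands:
            return float("nan")
        return float(np.mean([l.distance for l in self.ligands]))

    @property
    def min_angle(self) -> float:
        """Smallest ligand–center–ligand angle (degrees); nan for CN < 2."""
        if len(self.ligands) < 2:
            return float("nan")
        vecs = np.stack([l.atom.position - self.center for l in self.ligands])
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        best = 180.0
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                c = float(np.clip(np.dot(vecs[i], vecs[j]), -1.0, 1.0))
                best = min(best, float(np.degrees(np.arccos(c))))
        return best

    @property
    def oxygen_fraction(self) -> float:
        if not self.ligands:
            return 0.0
        return sum(1 for l in self.ligands if l.atom.element.upper() == "O") / len(self.ligands)

    def ligand_class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for l in self.ligands:
            out[l.ligand_class] = out.get(l.ligand_class, 0) + 1
        return out


def find_coordination(
    s: Structure,
    center: AtomRecord | np.ndarray | Sequence[float],
    cutoff: float = 3.0,
) -> CoordinationShell:
    """First coordination shell around a candidate ion position.

    All non-hydrogen, non-carbon atoms within ``cutoff`` Å (excluding the
    center atom itself) are ligands.  Cutoff must lie in (2.0, 3.5] Å:
    shorter cutoffs truncate genuine Na–O contacts, longer ones pull in
    second-shell atoms.
    """
    if not 2.0 < cutoff <= 3.5:
        raise ValueError(f"cutoff {cutoff} outside the supported (2.0, 3.5] Å window")
    exclude_id = None
    if isinstance(center, AtomRecord):
        exclude_id = id(center)
        pos = center.position
    else:
        pos = np.asarray(center, float)
        if pos.shape != (3,):
            raise ValueError("center must be an atom or a 3-vector")
    ligands = []
    if len(s):
        d = cdist(pos[None, :], s.coords)[0]
        for i in np.nonzero(d <= cutoff)[0]:
            a = s.atoms[int(i)]
            if id(a) == exclude_id or d[i] < 1e-6:
                continue
            if a.element.upper() in ("H", "D", "C"):
                continue
            ligands.append(Ligand(a, float(d[i]), _ligand_class(a)))
    ligands.sort(key=lambda l: l.distance)
    return CoordinationShell(pos, tuple(ligands), cutoff)


@dataclass(frozen=True)
class ClassificationRules:
    """Distance/CN bands of the site decision table (Å, inclusive unless noted).

    The Na+ mean-distance band is half-open at its upper edge so that the
    Na+ and K+ bands partition the axis without overlap.
    """

    na_cn: tuple[int, int] = (4, 6)
    na_dist: tuple[float, float] = (2.2, 2.6)   # [lo, hi)
    na_min_o_fraction: float = 0.8
    k_cn: tuple[int, int] = (5, 8)
    k_dist: tuple[float, float] = (2.6, 3.1)    # [lo, hi]
    hbond_dist: tuple[float, float] = (2.6, 3.2)
    water_max_cn: int = 4


DEFAULT_RULES = ClassificationRules()


@dataclass(frozen=True)
class SiteCall:
    identity: str            # Na+, K+, water, ambiguous
    score: float             # fraction of criteria met, in [0, 1]
    rationale: tuple[tuple[str, bool], ...]

    def __post_init__(self):
        if self.identity != "ambiguous" and self.score < 0.5:
            raise ValueError("definite identity requires score >= 0.5")


def _evaluate(checks: list[tuple[str, bool]]) -> float:
    return sum(ok for _, ok in checks) / len(checks)


def classify_site(shell: CoordinationShell, rules: ClassificationRules = DEFAULT_RULES) -> SiteCall:
    """Classify a coordination shell as Na+, K+, water, or ambiguous.

    The decision table is evaluated in order Na+ -> K+ -> water; a
    definite call requires every criterion of its row to hold, which
    together with the non-overlapping distance bands makes the calls
    mutually exclusive.  The score is the fraction of criteria met by the
    best row.
    """
    cn = shell.coordination_number
    md = shell.mean_distance
    na_checks = [
        (f"CN in [{rules.na_cn[0]}, {rules.na_cn[1]}]", rules.na_cn[0] <= cn <= rules.na_cn[1]),
        (f"mean distance in [{rules.na_dist[0]}, {rules.na_dist[1]}) Å",
         cn > 0 and rules.na_dist[0] <= md < rules.na_dist[1]),
        (f">= {rules.na_min_o_fraction:.0%} O ligands", cn > 0 and shell.oxygen_fraction >= rules.na_min_o_fraction),
    ]
    if all(ok for _, ok in na_checks):
        return SiteCall("Na+", 1.0, tuple(na_checks))
    k_checks = [
        (f"CN in [{rules.k_cn[0]}, {rules.k_cn[1]}]", rules.k_cn[0] <= cn <= rules.k_cn[1]),
        (f"mean distance in [{rules.k_dist[0]}, {rules.k_dist[1]}] Å",
         cn > 0 and rules.k_dist[0] <= md <= rules.k_dist[1]),
    ]
    if all(ok for _, ok in k_checks):
        return SiteCall("K+", 1.0, tuple(k_checks))
    water_checks = [
        ("CN <= 2", cn <= 2),
        (f"hydrogen-bond band with CN <= {rules.water_max_cn}",
         cn > 0 and cn <= rules.water_max_cn and rules.hbond_dist[0] <= md <= rules.hbond_dist[1]),
    ]
    if any(ok for _, ok in water_checks):
        return SiteCall("water", max(0.5, _evaluate(water_checks)), tuple(water_checks))
    all_checks = na_checks + k_checks + water_checks
    best = max(_evaluate(na_checks), _evaluate(k_checks), _evaluate(water_checks))
    return SiteCall("ambiguous", min(best, 0.49), tuple(all_checks))


def scan_candidate_ions(
    s: Structure,
    solvent_codes: set[str] | None = None,
    cutoff: float = 3.0,
    rules: ClassificationRules = DEFAULT_RULES,
) -> list[tuple[np.ndarray, CoordinationShell, SiteCall]]:
    """Screen every modeled water and monatomic ion as an ion-site candidate.

    Returns (position, shell, call) triples sorted by score descending,
    with definite ion calls ranked before water/ambiguous calls of equal
    score.  An empty structure or one with no solvent yields an empty list.
    """
    solvent_codes = WATER_CODES | _MONATOMIC_IONS if solvent_codes is None else solvent_codes
    candidates = [
        a for a in s.atoms
        if a.residue_name in solvent_codes and not a.is_hydrogen
    ]
    if not candidates:
        logger.info("structure %s: no solvent or monatomic-ion candidates", s.id)
        return []
    results = []
    for a in candidates:
        shell = find_coordination(s, a, cutoff)
        call = classify_site(shell, rules)
        results.append((a.position, shell, call))
    rank = {"Na+": 0, "K+": 0, "water": 1, "ambiguous": 1}
    results.sort(key=lambda r: (-r[2].score, rank[r[2].identity]))
    return results
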
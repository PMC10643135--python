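"""Atomic models: reading, writing, and cofactor recognition.

Structures are read from standard PDB or mmCIF files through gemmi and
flattened into a uniform chain -> residue -> atom hierarchy addressed by
author numbering (the numbering used in the structural literature for
residues such as NqrB F338).  Alternate locations are collapsed to the
highest-occupancy conformer and hydrogens are dropped: deposited models of
large membrane complexes are heavy-atom models, and every downstream
distance in this package is defined on heavy atoms.

Cofactor recognition is registry-driven: each cofactor kind maps to a set
of residue codes and a list of *edge atom* names — the conjugated,
redox-active heavy atoms that define the tunneling edge in the
Moser–Dutton sense.  For flavins that is the isoalloxazine ring system
plus its two exocyclic carbonyl oxygens; for a [2Fe-2S] cluster the two
irons and two bridging sulfurs (coordinating cysteine thiolates are not
part of the cluster edge); for ubiquinones the quinone head group without
the isoprenoid tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np
import gemmi

__all__ = [
    "AtomRecord",
    "Structure",
    "CofactorInstance",
    "CofactorRegistryEntry",
    "DEFAULT_REGISTRY",
    "read_structure",
    "write_pdb",
    "extract_cofactors",
    "StructureParseError",
    "RegistryError",
]

# Recognized element symbols (subset of the periodic table that occurs in
# macromolecular models; extended on demand).
_ELEMENTS = {
    "H", "D", "C", "N", "O", "F", "NA", "MG", "P", "S", "CL", "K", "CA",
    "MN", "FE", "CO", "NI", "CU", "ZN", "SE", "BR", "RB", "MO", "I", "CS",
    "W", "X",
}

WATER_CODES = {"HOH", "WAT", "DOD", "H2O"}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class RegistryError(ValueError):
    """Raised for malformed cofactor registry entries."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a model, in Å, author-numbered."""

    serial: int
    name: str
    element: str
    altloc: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.element.upper() not in _ELEMENTS:
            raise ValueError(f"atom {self.name}: unknown element symbol {self.element!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_CODES

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


class Structure:
    """An ordered collection of atoms with chain and residue indices."""

    def __init__(self, id: str, atoms: Sequence[AtomRecord], source_format: str = "pdb"):
        self.id = id
        self.atoms: list[AtomRecord] = list(atoms)
        self.source_format = source_format
        self._chain_index: dict[str, list[int]] = {}
        self._residue_index: dict[tuple[str, int, str], list[int]] = {}
        seen: set[tuple] = set()
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.residue_seq, a.insertion_code, a.name, a.altloc)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in structure {id!r}")
            seen.add(key)
            self._chain_index.setdefault(a.chain_id, []).append(i)
            self._residue_index.setdefault(a.residue_key, []).append(i)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.position for a in self.atoms])

    @property
    def chain_ids(self) -> list[str]:
        return list(self._chain_index)

    def chain_atoms(self, chain_id: str) -> list[AtomRecord]:
        return [self.atoms[i] for i in self._chain_index.get(chain_id, [])]

    def residue_atoms(self, chain_id: str, residue_seq: int, insertion_code: str = "") -> list[AtomRecord]:
        return [self.atoms[i] for i in self._residue_index.get((chain_id, residue_seq, insertion_code), [])]

    def residues(self) -> Iterable[tuple[tuple[str, int, str], list[AtomRecord]]]:
        for key, idx in self._residue_index.items():
            yield key, [self.atoms[i] for i in idx]

    def find_atom(self, chain_id: str, residue_seq: int, name: str, insertion_code: str = "") -> AtomRecord | None:
        for a in self.residue_atoms(chain_id, residue_seq, insertion_code):
            if a.name == name:
                return a
        return None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with every position mapped to R @ x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new = [replace(a, position=R @ a.position + t) for a in self.atoms]
        return Structure(self.id, new, self.source_format)

    def heterogen_inventory(self) -> dict[str, int]:
        """Count hetero residues by residue code (waters excluded)."""
        counts: dict[str, int] = {}
        for (chain, seq, icode), atoms in self.residues():
            if atoms[0].is_hetero and not atoms[0].is_water:
                counts[atoms[0].residue_name] = counts.get(atoms[0].residue_name, 0) + 1
        return counts


@dataclass(frozen=True)
class CofactorRegistryEntry:
    residue_codes: tuple[str, ...]
    edge_atom_names: tuple[str, ...]


# Edge-atom conventions.  Name variants cover the differing atom
# nomenclature of FAD (C4X/C5X/C10) versus FMN/riboflavin (C4A/C5A/C10A in
# some components); an instance is kept when at least half of the listed
# names resolve, so variant names simply fail to match.
_ISOALLOXAZINE = (
    "N1", "C2", "O2", "N3", "C4", "O4",
    "C4A", "C4X", "N5", "C5A", "C5X",
    "C6", "C7", "C8", "C9", "C9A", "N10", "C10", "C10A",
)
_QUINONE_HEAD = ("C1", "C2", "C3", "C4", "C5", "C6", "O1", "O2", "O3", "O4")
_NICOTINAMIDE = ("N1N", "C2N", "C3N", "C4N", "C5N", "C6N", "C7N", "O7N", "N7N")

DEFAULT_REGISTRY: dict[str, CofactorRegistryEntry] = {
    "FAD": CofactorRegistryEntry(("FAD",), _ISOALLOXAZINE),
    "FMN": CofactorRegistryEntry(("FMN",), _ISOALLOXAZINE),
    "RBF": CofactorRegistryEntry(("RBF",), _ISOALLOXAZINE),
    "FES": CofactorRegistryEntry(("FES", "FS2"), ("FE1", "FE2", "S1", "S2")),
    "UQ1": CofactorRegistryEntry(("UQ1",), _QUINONE_HEAD),
    "UQ2": CofactorRegistryEntry(("UQ2", "UQ"), _QUINONE_HEAD),
    "HQNO": CofactorRegistryEntry(("HQO",), _QUINONE_HEAD),
    "NAD": CofactorRegistryEntry(("NAD", "NAI"), _NICOTINAMIDE),
    "ion": CofactorRegistryEntry(("NA", "K", "RB", "CS"), ()),
}


@dataclass
class CofactorInstance:
    """A recognized cofactor with its redox-active edge-atom subset."""

    kind: str
    label: str
    chain_id: str
    residue_seq: int
    atoms: list[AtomRecord]
    edge_atoms: list[AtomRecord]
    missing_edge_atoms: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.edge_atoms:
            raise ValueError(f"cofactor {self.label}: empty edge-atom set")
        ids = {id(a) for a in self.atoms}
        if any(id(a) not in ids for a in self.edge_atoms):
            raise ValueError(f"cofactor {self.label}: edge atoms not a subset of atoms")
        if any(a.is_hydrogen for a in self.edge_atoms):
            raise ValueError(f"cofactor {self.label}: hydrogens in edge set")

    @property
    def edge_coords(self) -> np.ndarray:
        return np.stack([a.position for a in self.edge_atoms])


def _collapse_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep altloc 'A' (or the highest-occupancy alternate) per atom site."""
    by_site: dict[tuple, list[AtomRecord]] = {}
    order: list[tuple] = []
    for a in atoms:
        site = (a.chain_id, a.residue_seq, a.insertion_code, a.name)
        if site not in by_site:
            order.append(site)
        by_site.setdefault(site, []).append(a)
    out = []
    for site in order:
        group = by_site[site]
        if len(group) == 1:
            chosen = group[0]
        else:
            a_alts = [g for g in group if g.altloc == "A"]
            chosen = a_alts[0] if a_alts else max(group, key=lambda g: g.occupancy)
        out.append(replace(chosen, altloc=""))
    return out


def read_structure(path: str | Path, format_hint: str | None = None) -> Structure:
    """Read the first model of a PDB or mmCIF file.

    Author numbering is preserved; alternate locations are collapsed to the
    'A' (or highest-occupancy) conformer; hydrogens are dropped.  Multi-model
    files trigger a warning and only the first model is returned.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = format_hint
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "mmcif" if suffix in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models found")
    if len(st) > 1:
        warnings.warn(f"{path}: {len(st)} models present; using the first", stacklevel=2)
    st.setup_entities()
    model = st[0]
    atoms: list[AtomRecord] = []
    serial = 0
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            seqid = res.seqid.num if res.seqid.num is not None else 0
            icode = res.seqid.icode.strip()
            for at in res:
                elem = at.element.name.upper()
                if elem in ("H", "D"):
                    continue
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=at.serial if at.serial else serial,
                        name=at.name,
                        element=elem if elem in _ELEMENTS else "X",
                        altloc=at.altloc.strip() if at.altloc else "",
                        residue_name=res.name,
                        chain_id=chain.name,
                        residue_seq=seqid,
                        insertion_code=icode,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        b_factor=at.b_iso,
                        is_hetero=het,
                    )
                )
    atoms = _collapse_altlocs(atoms)
    if not atoms:
        raise StructureParseError(f"{path}: no atoms in first model")
    return Structure(path.stem, atoms, source_format="mmcif" if fmt == "mmcif" else "pdb")


def write_pdb(s: Structure, path: str | Path) -> Path:
    """Write a structure as a fixed-column PDB file (coordinates to 1e-3 Å)."""
    path = Path(path)
    lines = []
    serial = 0
    for a in s.atoms:
        serial += 1
        record = "HETATM" if a.is_hetero else "ATOM  "
        name = a.name
        # Standard alignment: element symbols of one letter start in col 14.
        if len(name) < 4 and len(a.element) == 1:
            name = " " + name
        x, y, z = a.position
        lines.append(
            f"{record}{serial:5d} {name:<4s}{a.altloc or ' ':1s}{a.residue_name:<3s} "
            f"{a.chain_id[:1]:1s}{a.residue_seq:4d}{a.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}          "
            f"{a.element:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def extract_cofactors(
    s: Structure,
    registry: Mapping[str, CofactorRegistryEntry] | None = None,
    min_edge_fraction: float = 0.5,
) -> list[CofactorInstance]:
    """Recognize cofactor residues and resolve their edge-atom subsets.

    One instance is produced per hetero residue whose code appears in the
    registry.  Edge atoms are resolved by name; an instance is kept when at
    least ``min_edge_fraction`` of the *resolvable* edge set is present
    (name variants for other chemistries simply do not match).  Monatomic
    ion kinds use the lone atom as its own edge.
    """
    registry = DEFAULT_REGISTRY if registry is None else registry
    code_to_kind: dict[str, str] = {}
    for kind, entry in registry.items():
        if not entry.edge_atom_names and kind != "ion":
            raise RegistryError(f"registry kind {kind!r} has no edge atom names")
        for code in entry.residue_codes:
            code_to_kind[code] = kind

    instances: list[CofactorInstance] = []
    residues = sorted(s.residues(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2]))
    for (chain, seq, icode), atoms in residues:
        resname = atoms[0].residue_name
        kind = code_to_kind.get(resname)
        if kind is None:
            continue
        heavy = [a for a in atoms if not a.is_hydrogen]
        if not heavy:
            continue
        entry = registry[kind]
        if kind == "ion" or not entry.edge_atom_names:
            edge = heavy
            missing: tuple[str, ...] = ()
        else:
            wanted = [n.upper() for n in entry.edge_atom_names]
            by_name = {a.name.upper(): a for a in heavy}
            edge = [by_name[n] for n in wanted if n in by_name]
            missing = tuple(n for n in wanted if n not in by_name)
            if not edge or len(edge) < min_edge_fraction * len(wanted):
                continue
        if not edge:
            continue
        label = f"{kind}_{chain}{seq}" if kind != "ion" else f"{resname}_{chain}{seq}"
        instances.append(
            CofactorInstance(
                kind=kind,
                label=label,
                chain_id=chain,
                residue_seq=seq,
                atoms=heavy,
                edge_atoms=edge,
                missing_edge_atoms=missing,
            )
        )
    return instances
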
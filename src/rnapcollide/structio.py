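"""Atomic-structure I/O and residue-range selections.

Structures are read with gemmi (PDB and mmCIF), flattened into a simple
ordered atom list, and addressed by author residue numbering (1-based,
inclusive ranges) — the convention used throughout bacterial RNA polymerase
depositions.  Alternate locations are collapsed to the highest-occupancy
conformer at read time so that downstream geometry never sees duplicated
atoms.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "ResidueSelection",
    "read_structure",
    "write_structure",
    "select_calpha",
    "residue_centers_of_mass",
    "read_selection_file",
    "DEFAULT_CHAIN_MAP",
]

# Canonical subunit labels used by module definitions; deposited E. coli
# RNAP entries conventionally label the two alpha copies A/B, beta C,
# beta-prime D and omega E, but the mapping is configurable.
DEFAULT_CHAIN_MAP: dict[str, str] = {
    "A": "alpha",
    "B": "alpha",
    "C": "beta",
    "D": "betaprime",
    "E": "omega",
}


class StructureError(ValueError):
    """Raised for unreadable, empty or inconsistent structure inputs."""


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """One atom: author-numbered residue identity plus Cartesian position (Å)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    occupancy: float
    altloc: str
    position: np.ndarray  # shape (3,), Å
    mass: float  # daltons

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"non-finite position for atom {self.atom_name}")
        object.__setattr__(self, "position", pos)
        if not (0.0 <= self.occupancy <= 1.0):
            raise StructureError(
                f"occupancy {self.occupancy} outside [0,1] for atom {self.atom_name}"
            )
        if self.mass <= 0:
            raise StructureError(f"non-positive mass for atom {self.atom_name}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.residue_number, self.atom_name, self.altloc)


class StructureModel:
    """Ordered atom list with a (chain → residue → atoms) index."""

    def __init__(self, identifier: str, atoms: Sequence[AtomRecord]):
        self.identifier = identifier
        self.atoms: list[AtomRecord] = list(atoms)
        self._index: dict[str, dict[int, list[AtomRecord]]] = {}
        seen: set[tuple[str, int, str, str]] = set()
        for atom in self.atoms:
            key = atom.key()
            if key in seen:
                raise StructureError(f"duplicate atom key {key} in {identifier}")
            seen.add(key)
            self._index.setdefault(atom.chain_id, {}).setdefault(
                atom.residue_number, []
            ).append(atom)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        return list(self._index)

    def residues(self, chain_id: str) -> list[int]:
        """Sorted author residue numbers present in a chain."""
        return sorted(self._index.get(chain_id, {}))

    def atoms_of(self, chain_id: str, residue_number: int) -> list[AtomRecord]:
        return self._index.get(chain_id, {}).get(residue_number, [])

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coordinates(self, coords: np.ndarray) -> "StructureModel":
        """Copy of the model with every atom moved to the given positions."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise StructureError("coordinate array shape mismatch")
        atoms = [
            dataclasses.replace(a, position=coords[i])
            for i, a in enumerate(self.atoms)
        ]
        return StructureModel(self.identifier, atoms)

    def subset(self, selection: "ResidueSelection") -> "StructureModel":
        atoms = [
            a
            for part in selection.parts
            for num in self._part_residues(part)
            for a in self.atoms_of(part[0], num)
        ]
        return StructureModel(f"{self.identifier}:{selection.label}", atoms)

    def _part_residues(self, part: tuple[str, int | None, int | None]) -> list[int]:
        chain, start, end = part
        present = self.residues(chain)
        if start is None:
            return present
        return [n for n in present if start <= n <= end]


@dataclasses.dataclass(frozen=True)
class ResidueSelection:
    """List of (chain, start, end) parts; start/end None means the whole chain."""

    parts: tuple[tuple[str, int | None, int | None], ...]
    label: str = ""

    def __post_init__(self) -> None:
        parts = tuple(
            (str(c), None if s is None else int(s), None if e is None else int(e))
            for c, s, e in self.parts
        )
        object.__setattr__(self, "parts", parts)
        by_chain: dict[str, list[tuple[int, int]]] = {}
        for chain, start, end in parts:
            if start is None:
                continue
            if start > end:
                raise ValueError(f"selection part {chain} {start}-{end}: start > end")
            for s0, e0 in by_chain.get(chain, []):
                if start <= e0 and s0 <= end:
                    raise ValueError(
                        f"overlapping selection parts on chain {chain}: "
                        f"{s0}-{e0} and {start}-{end}"
                    )
            by_chain.setdefault(chain, []).append((start, end))

    def contains(self, chain_id: str, residue_number: int) -> bool:
        for chain, start, end in self.parts:
            if chain != chain_id:
                continue
            if start is None or start <= residue_number <= end:
                return True
        return False

    def mapped(self, chain_map: Mapping[str, str]) -> "ResidueSelection":
        """Expand canonical-subunit parts to the model's actual chain ids.

        ``chain_map`` maps actual chain id → canonical name.  A part whose
        chain matches a canonical name is duplicated for every actual chain
        mapped to it; parts naming actual chains pass through unchanged.
        """
        reverse: dict[str, list[str]] = {}
        for actual, canonical in chain_map.items():
            reverse.setdefault(canonical, []).append(actual)
        parts: list[tuple[str, int | None, int | None]] = []
        for chain, start, end in self.parts:
            for actual in reverse.get(chain, [chain]):
                parts.append((actual, start, end))
        return ResidueSelection(tuple(parts), self.label)


def _atom_mass(element: gemmi.Element, fallback_name: str) -> float:
    weight = element.weight
    if weight and weight > 0:
        return float(weight)
    # Element field missing: guess from the first letter of the atom name.
    guess = gemmi.Element(fallback_name.strip()[:1] or "C")
    return float(guess.weight) if guess.weight > 0 else 12.011


def read_structure(path: str | Path, format_hint: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    Only the highest-occupancy conformer of each alternate-location group is
    retained (ties broken by lexicographically smallest altloc).  Hydrogens
    are kept and flagged via :attr:`AtomRecord.is_hydrogen`.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format_hint)
    if fmt is None:
        raise ValueError(f"unknown format hint {format_hint!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]

    # group altlocs per (chain, residue, atom name) and keep the winner
    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            groups: dict[str, list[gemmi.Atom]] = {}
            order: list[str] = []
            for atom in residue:
                if atom.name not in groups:
                    order.append(atom.name)
                groups.setdefault(atom.name, []).append(atom)
            for name in order:
                group = groups[name]
                best = min(group, key=lambda a: (-a.occ, a.altloc or ""))
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=name,
                        element=best.element.name,
                        occupancy=min(max(float(best.occ), 0.0), 1.0),
                        altloc=best.altloc or "",
                        position=np.array(
                            [best.pos.x, best.pos.y, best.pos.z], dtype=float
                        ),
                        mass=_atom_mass(best.element, name),
                    )
                )
    if not atoms:
        raise StructureError(f"{path}: empty model")
    return StructureModel(st.name or path.stem, atoms)


def write_structure(
    model: StructureModel,
    path: str | Path,
    format: str = "pdb",
    chain_rename: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Write a StructureModel to PDB (fixed columns, 3-decimal coordinates).

    Chain ids longer than two characters are renamed through
    ``chain_rename`` (auto-generated when not given); the applied mapping is
    returned so callers can emit it alongside the file.
    """
    if format != "pdb":
        raise ValueError("only PDB output is supported")
    if len(model) == 0:
        raise StructureError("refusing to write an empty model")

    mapping: dict[str, str] = dict(chain_rename or {})
    available = iter(
        [c for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"]
    )
    used = set(mapping.values())
    for chain_id in dict.fromkeys(a.chain_id for a in model.atoms):
        if chain_id in mapping:
            continue
        if len(chain_id) <= 2:
            mapping[chain_id] = chain_id
            used.add(chain_id)
        else:
            name = next(c for c in available if c not in used)
            mapping[chain_id] = name
            used.add(name)

    st = gemmi.Structure()
    st.name = model.identifier
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int], gemmi.Residue] = {}
    for atom in model.atoms:
        cname = mapping[atom.chain_id]
        if cname not in chains:
            chains[cname] = gemmi.Chain(cname)
        rkey = (cname, atom.residue_number)
        if rkey not in residues:
            res = gemmi.Residue()
            res.name = atom.residue_name
            res.seqid = gemmi.SeqId(atom.residue_number, " ")
            chains[cname].add_residue(res)
            residues[rkey] = chains[cname][-1]
        ga = gemmi.Atom()
        ga.name = atom.atom_name
        ga.element = gemmi.Element(atom.element or "X")
        ga.occ = atom.occupancy
        ga.altloc = atom.altloc or "\0"
        ga.pos = gemmi.Position(*atom.position)
        residues[rkey].add_atom(ga)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
    return mapping


def select_calpha(
    model: StructureModel, selection: ResidueSelection
) -> tuple[list[tuple[str, int, np.ndarray]], list[tuple[str, int]]]:
    """Ordered CA positions for a selection.

    Returns ``(entries, skipped)``: one ``(chain, residue_number, position)``
    per selected residue that has a CA atom, ordered by part then ascending
    residue number, plus the list of selected residues lacking a CA.
    """
    entries: list[tuple[str, int, np.ndarray]] = []
    skipped: list[tuple[str, int]] = []
    matched = False
    for part in selection.parts:
        chain = part[0]
        for num in model._part_residues(part):
            matched = True
            ca = [a for a in model.atoms_of(chain, num) if a.atom_name == "CA"]
            if ca:
                entries.append((chain, num, ca[0].position))
            else:
                skipped.append((chain, num))
    if not matched:
        raise StructureError(
            f"selection {selection.label!r} matches no residues in {model.identifier}"
        )
    return entries, skipped


def residue_centers_of_mass(
    model: StructureModel,
    selection: ResidueSelection,
    mass_weighted: bool = True,
    include_hydrogens: bool = False,
) -> list[tuple[tuple[str, int], np.ndarray]]:
    """Per-residue center of mass (default: mass-weighted over heavy atoms)."""
    out: list[tuple[tuple[str, int], np.ndarray]] = []
    for part in selection.parts:
        chain = part[0]
        for num in model._part_residues(part):
            atoms = [
                a
                for a in model.atoms_of(chain, num)
                if include_hydrogens or not a.is_hydrogen
            ]
            if not atoms:
                raise StructureError(
                    f"residue {chain}:{num} has no qualifying atoms for COM"
                )
            pos = np.array([a.position for a in atoms])
            if mass_weighted:
                w = np.array([a.mass for a in atoms])
                com = (pos * w[:, None]).sum(axis=0) / w.sum()
            else:
                com = pos.mean(axis=0)
            out.append(((chain, num), com))
    if not out:
        raise StructureError(f"selection {selection.label!r} matches no residues")
    return out


def read_selection_file(path: str | Path, label: str = "") -> ResidueSelection:
    """Parse a plain-text selection: one part per line, ``CHAIN START END``.

    ``CHAIN all`` (or ``CHAIN * *``) selects every residue of the chain.
    Blank lines and ``#`` comments are ignored.
    """
    parts: list[tuple[str, int | None, int | None]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) == 2 and fields[1].lower() in ("all", "*"):
            parts.append((fields[0], None, None))
        elif len(fields) == 3:
            try:
                parts.append((fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad residue range") from exc
        else:
            raise ValueError(f"{path}:{lineno}: expected 'CHAIN START END'")
    if not parts:
        raise ValueError(f"{path}: empty selection file")
    return ResidueSelection(tuple(parts), label or Path(path).stem)
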
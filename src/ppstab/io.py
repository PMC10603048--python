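"""Reading, writing and selecting PDB-format structures and trajectories.

Coordinates live in biotite :class:`AtomArray` / plain numpy arrays; a
multi-MODEL PDB file is interpreted as a trajectory over a fixed topology
(the first model).  Alternate locations are resolved to the
highest-occupancy conformer at parse time, waters and monatomic ions are
dropped by default, and active-site HETATM groups (ADP, inhibitors) are
kept.  All residue numbering is author numbering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Selection",
    "ComplexDefinition",
    "Structure",
    "Trajectory",
    "FragmentStats",
    "PDBError",
    "parse_selection",
    "read_pdb",
    "write_pdb",
    "select_atoms",
    "fragment_stats",
]

#: residue names treated as solvent when ``drop_waters`` is set
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "SOL", "TIP", "TIP3", "TIP4"})
#: monatomic ions dropped together with waters (HETATM only)
ION_NAMES = frozenset(
    {"NA", "CL", "K", "MG", "ZN", "CA", "MN", "FE", "CU", "NI", "CD", "CO",
     "LI", "CS", "BR", "IOD", "F"}
)

# largest coordinate magnitude representable in the fixed-width %8.3f field
_PDB_COORD_LIMIT = 9999.999


class PDBError(ValueError):
    """Raised for unreadable or structurally inconsistent PDB input."""


@dataclass(frozen=True)
class Selection:
    """A chain plus optional inclusive residue ranges (author numbering).

    An empty ``segments`` tuple selects the whole chain.
    """

    chain: str
    segments: tuple[tuple[int, int], ...] = ()

    def __str__(self) -> str:
        if not self.segments:
            return self.chain
        seg = ",".join(f"{a}-{b}" for a, b in self.segments)
        return f"{self.chain}:{seg}"

    def residue_mask(self, atoms: struc.AtomArray) -> np.ndarray:
        mask = atoms.chain_id == self.chain
        if self.segments:
            in_range = np.zeros(atoms.array_length(), dtype=bool)
            for start, end in self.segments:
                in_range |= (atoms.res_id >= start) & (atoms.res_id <= end)
            mask &= in_range
        return mask


_SEL_RE = re.compile(r"^([A-Za-z0-9]):?((?:-?\d+--?\d+)(?:,-?\d+--?\d+)*)?$")


def parse_selection(text: str) -> Selection:
    """Parse ``"A"``, ``"A:19-89"`` or ``"B:7-43,61-89"`` into a Selection."""
    text = text.strip()
    if ":" in text:
        chain, _, rest = text.partition(":")
        segments = []
        for part in rest.split(","):
            m = re.match(r"^(-?\d+)-(-?\d+)$", part.strip())
            if m is None:
                raise ValueError(f"malformed residue range {part!r} in {text!r}")
            a, b = int(m.group(1)), int(m.group(2))
            if b < a:
                raise ValueError(f"descending residue range {part!r}")
            segments.append((a, b))
        return Selection(chain.strip(), tuple(segments))
    if not text:
        raise ValueError("empty selection string")
    return Selection(text)


@dataclass(frozen=True)
class ComplexDefinition:
    """Receptor/partner split of a two-component complex.

    The receptor is a single chain (optionally restricted to a residue
    range); the partner may consist of several chain segments, e.g. a fused
    construct spanning two ranges.  Selections must not overlap.
    """

    receptor: Selection
    partner: tuple[Selection, ...]
    label: str = ""

    def __post_init__(self):
        if isinstance(self.partner, Selection):
            object.__setattr__(self, "partner", (self.partner,))
        for p in self.partner:
            if p.chain == self.receptor.chain:
                if not p.segments or not self.receptor.segments:
                    raise ValueError(
                        "receptor and partner share a chain without disjoint ranges"
                    )
                for a, b in p.segments:
                    for c, d in self.receptor.segments:
                        if a <= d and c <= b:
                            raise ValueError(
                                f"receptor and partner ranges overlap on chain {p.chain}"
                            )

    def receptor_mask(self, atoms: struc.AtomArray) -> np.ndarray:
        return self.receptor.residue_mask(atoms)

    def partner_mask(self, atoms: struc.AtomArray) -> np.ndarray:
        mask = np.zeros(atoms.array_length(), dtype=bool)
        for p in self.partner:
            mask |= p.residue_mask(atoms)
        return mask


@dataclass
class Structure:
    """A single-model structure: a biotite AtomArray plus optional header."""

    atoms: struc.AtomArray
    header: str | None = None
    model_id: int = 1

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.atoms.chain_id:
            seen.setdefault(str(c))
        return list(seen)

    @property
    def coord(self) -> np.ndarray:
        return self.atoms.coord

    def copy(self) -> "Structure":
        return Structure(self.atoms.copy(), self.header, self.model_id)

    def residue_ids(self, chain: str) -> list[tuple[int, str]]:
        """Ordered (res_id, ins_code) pairs of a chain."""
        mask = self.atoms.chain_id == chain
        if not mask.any():
            raise KeyError(f"unknown chain {chain!r}")
        sub = self.atoms[mask]
        out, seen = [], set()
        for rid, ins in zip(sub.res_id, sub.ins_code):
            key = (int(rid), str(ins))
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology."""

    topology: struc.AtomArray
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: float | None = None  # ns between frames, if known

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.array_length():
            raise ValueError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.array_length()}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.array_length()

    def frame(self, i: int) -> Structure:
        atoms = self.topology.copy()
        atoms.coord = self.coords[i].copy()
        return Structure(atoms, model_id=i + 1)

    def frames(self):
        for i in range(self.n_frames):
            yield self.frame(i)


@dataclass(frozen=True)
class FragmentStats:
    n_residues: int
    n_heavy_atoms: int


def _drop_solvent(atoms: struc.AtomArray) -> struc.AtomArray:
    res = np.char.strip(atoms.res_name.astype(str))
    drop = np.isin(res, list(WATER_NAMES))
    drop |= atoms.hetero & np.isin(res, list(ION_NAMES))
    return atoms[~drop]


def read_pdb(path, drop_waters: bool = True) -> Structure | Trajectory:
    """Read a PDB file into a Structure (1 MODEL) or Trajectory (several).

    Altlocs are resolved to the highest-occupancy conformer (ties resolve to
    the first-listed conformer, conventionally "A").  HETATM records are
    kept; waters and monatomic ions are dropped unless ``drop_waters`` is
    False.
    """
    try:
        pdb = PDBFile.read(str(path))
    except (OSError, UnicodeDecodeError) as exc:
        raise PDBError(f"cannot read PDB file {path}: {exc}") from exc
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise PDBError(f"{path}: no coordinate records")
    try:
        if n_models == 1:
            atoms = pdb.get_structure(
                model=1, altloc="occupancy", extra_fields=["occupancy"]
            )
        else:
            atoms = pdb.get_structure(
                altloc="occupancy", extra_fields=["occupancy"]
            )
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        raise PDBError(f"{path}: inconsistent or malformed MODEL records: {exc}") from exc
    if n_models == 1:
        atoms = _maybe_drop(atoms, drop_waters)
        if atoms.array_length() == 0:
            raise PDBError(f"{path}: no ATOM records")
        return Structure(atoms)
    template = atoms[0]
    template = _maybe_drop(template, drop_waters)
    if template.array_length() == 0:
        raise PDBError(f"{path}: no ATOM records")
    if drop_waters:
        keep = _solvent_keep_mask(atoms[0])
        coords = atoms.coord[:, keep, :]
    else:
        coords = atoms.coord
    return Trajectory(template, coords.astype(float))


def _solvent_keep_mask(atoms: struc.AtomArray) -> np.ndarray:
    res = np.char.strip(atoms.res_name.astype(str))
    drop = np.isin(res, list(WATER_NAMES))
    drop |= atoms.hetero & np.isin(res, list(ION_NAMES))
    return ~drop


def _maybe_drop(atoms: struc.AtomArray, drop_waters: bool) -> struc.AtomArray:
    return _drop_solvent(atoms) if drop_waters else atoms


def write_pdb(obj: Structure | Trajectory, path) -> None:
    """Write a Structure (single model) or Trajectory (MODEL blocks).

    Round-tripping preserves atom names, residue numbering, chain IDs and
    coordinates to the 3 decimals of the fixed-width PDB format.
    """
    if isinstance(obj, Structure):
        coords = obj.atoms.coord
        payload = obj.atoms
    elif isinstance(obj, Trajectory):
        coords = obj.coords
        payload = struc.from_template(obj.topology, obj.coords.astype(np.float32))
    else:
        raise TypeError(f"cannot write object of type {type(obj)!r}")
    if not np.all(np.isfinite(coords)):
        raise PDBError("non-finite coordinates cannot be written")
    if np.abs(coords).max() > _PDB_COORD_LIMIT:
        raise PDBError(
            f"coordinate magnitude exceeds PDB field width ({_PDB_COORD_LIMIT} A)"
        )
    pdb = PDBFile()
    pdb.set_structure(payload)
    pdb.write(str(path))


def select_atoms(
    structure: Structure,
    chain: str,
    residue_range: tuple[int, int] | None = None,
    atom_names: list[str] | tuple[str, ...] | None = None,
    heavy_only: bool = True,
    include_hetero: bool = True,
) -> struc.AtomArray:
    """Ordered atom subset of one chain; empty selections are allowed.

    Hydrogens are excluded by default — all downstream analyses are
    Calpha/Cbeta/heavy-atom based.
    """
    atoms = structure.atoms
    mask = atoms.chain_id == chain
    if not mask.any():
        raise KeyError(f"unknown chain {chain!r}")
    if residue_range is not None:
        start, end = residue_range
        mask &= (atoms.res_id >= start) & (atoms.res_id <= end)
    if atom_names is not None:
        mask &= np.isin(atoms.atom_name, list(atom_names))
    if heavy_only:
        mask &= atoms.element != "H"
    if not include_hetero:
        mask &= ~atoms.hetero
    return atoms[mask]


def selection_atom_indices(
    structure: Structure, selection: Selection, heavy_only: bool = True
) -> np.ndarray:
    """Indices into the structure's atom array covered by a Selection."""
    mask = selection.residue_mask(structure.atoms)
    if heavy_only:
        mask &= structure.atoms.element != "H"
    return np.flatnonzero(mask)


def fragment_stats(structure: Structure, cdef: ComplexDefinition) -> FragmentStats:
    """Residue and heavy-atom bookkeeping of the partner fragment.

    The residue count is range arithmetic — the sum of (end - start + 1)
    over partner segments — so unmodelled residues inside a declared range
    still count, matching how construct sizes are quoted.  The heavy-atom
    count is the number of non-hydrogen atoms actually present.
    """
    n_res = 0
    n_heavy = 0
    atoms = structure.atoms
    for sel in cdef.partner:
        mask = sel.residue_mask(atoms)
        if not mask.any():
            raise ValueError(f"partner selection {sel} matches no atoms")
        if sel.segments:
            n_res += sum(end - start + 1 for start, end in sel.segments)
        else:
            sub = atoms[mask]
            n_res += len({(int(r), str(i)) for r, i in zip(sub.res_id, sub.ins_code)})
        n_heavy += int(((atoms.element != "H") & mask).sum())
    return FragmentStats(n_res, n_heavy)
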
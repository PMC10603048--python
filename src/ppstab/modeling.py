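"""Completion of a complex by template grafting and terminus extension.

A missing partner fragment is rebuilt by copying the backbone of a
template partner that occupies the same binding surface, renaming and
renumbering its residues to the desired sequence, and optionally growing
the chain from either terminus with ideal trans-peptide geometry.
Sidechains are represented by an idealized Cbeta only — every downstream
metric in this package is Calpha/Cbeta based — and no refinement is
performed: steric clashes are reported, not fixed, and the junction to any
pre-existing fragment is reported as a bond length rather than closed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.structure as struc

from . import geometry as geom
from .io import Selection, Structure

__all__ = [
    "StructureBuildError",
    "Clash",
    "graft_fragment",
    "mutate_residue",
    "extend_terminus",
    "build_peptide",
    "peptide_bond_lengths",
]

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

CLASH_CUTOFF = 2.0  # heavy-atom distance (A) reported as a steric clash


class StructureBuildError(ValueError):
    """Raised when a build request is geometrically or logically invalid."""


@dataclass(frozen=True)
class Clash:
    atom_a: str  # "chain/resname resid/atom"
    atom_b: str
    distance: float


_ELEMENT_OF = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "OXT": "O"}


def _atoms_from_records(records, like: struc.AtomArray | None = None) -> struc.AtomArray:
    """Build an AtomArray from (chain, res_id, res_name, atom_name, coord) records."""
    arr = struc.AtomArray(len(records))
    arr.chain_id = np.array([r[0] for r in records], dtype="U4")
    arr.res_id = np.array([r[1] for r in records], dtype=int)
    arr.ins_code = np.array([""] * len(records), dtype="U1")
    arr.res_name = np.array([r[2] for r in records], dtype="U5")
    arr.atom_name = np.array([r[3] for r in records], dtype="U6")
    arr.hetero = np.zeros(len(records), dtype=bool)
    arr.element = np.array(
        [_ELEMENT_OF.get(r[3], r[3][:1]) for r in records], dtype="U2"
    )
    arr.coord = np.array([r[4] for r in records], dtype=np.float32)
    if like is not None:
        for category in like.get_annotation_categories():
            if category not in arr.get_annotation_categories():
                template = like.get_annotation(category)
                fill = np.zeros(len(records), dtype=template.dtype)
                if category == "occupancy":
                    fill[:] = 1.0
                arr.set_annotation(category, fill)
    return arr


def _iter_residues(atoms: struc.AtomArray):
    """Yield (start, stop) index slices of consecutive residues."""
    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    for a, b in zip(starts[:-1], starts[1:]):
        yield int(a), int(b)


def _residue_backbone(atoms: struc.AtomArray, start: int, stop: int) -> dict[str, np.ndarray]:
    out = {}
    for i in range(start, stop):
        name = str(atoms.atom_name[i])
        if name in ("N", "CA", "C", "O"):
            out[name] = atoms.coord[i].astype(float)
    return out


def _make_residue(chain, res_id, res_name, backbone: dict[str, np.ndarray]):
    """Records for one residue: backbone plus idealized Cbeta (absent for Gly)."""
    n, ca, c = backbone["N"], backbone["CA"], backbone["C"]
    if "O" in backbone:
        o = backbone["O"]
    else:
        # carbonyl O in the N-CA-C plane, anti to N across the carbonyl
        o = geom.place_atom(n, ca, c, geom.BOND_C_O, geom.ANGLE_CA_C_O, 180.0)
    records = [
        (chain, res_id, res_name, "N", n),
        (chain, res_id, res_name, "CA", ca),
        (chain, res_id, res_name, "C", c),
        (chain, res_id, res_name, "O", o),
    ]
    if res_name != "GLY":
        records.append((chain, res_id, res_name, "CB", geom.place_cbeta(n, ca, c)))
    return records


def _insert_chain_atoms(target: Structure, new: struc.AtomArray, chain: str,
                        prepend: bool) -> Structure:
    atoms = target.atoms
    chain_idx = np.flatnonzero(atoms.chain_id == chain)
    if chain_idx.size == 0:
        combined = atoms + new
    else:
        pos = int(chain_idx[0]) if prepend else int(chain_idx[-1]) + 1
        combined = atoms[:pos] + new + atoms[pos:]
    return Structure(combined, target.header, target.model_id)


def graft_fragment(
    target: Structure,
    template: Structure,
    segment: Selection,
    sequence: str,
    start: int,
    chain_id: str | None = None,
) -> Structure:
    """Copy a template segment's backbone into the target under a new identity.

    The template must already be positioned in the target's frame (e.g. by
    superposing the two receptors).  Grafted residues take the one-letter
    ``sequence`` and author numbering ``start``, ``start+1``, ...; their
    backbone coincides with the template segment by construction, and
    sidechains are idealized Cbeta stubs.
    """
    sequence = sequence.strip().upper()
    mask = segment.residue_mask(template.atoms)
    if not mask.any():
        raise StructureBuildError(f"template segment {segment} matches no atoms")
    seg_atoms = template.atoms[mask]
    residues = list(_iter_residues(seg_atoms))
    if len(sequence) != len(residues):
        raise StructureBuildError(
            f"sequence length {len(sequence)} != template segment residue "
            f"count {len(residues)}"
        )
    chain = chain_id if chain_id is not None else str(seg_atoms.chain_id[0])
    existing = set()
    if chain in target.chains:
        existing = {rid for rid, _ in target.residue_ids(chain)}
    records = []
    for i, ((a, b), letter) in enumerate(zip(residues, sequence)):
        if letter not in ONE_TO_THREE:
            raise StructureBuildError(f"unknown one-letter code {letter!r}")
        res_id = start + i
        if res_id in existing:
            raise StructureBuildError(
                f"numbering collision: residue {res_id} already exists in chain {chain}"
            )
        backbone = _residue_backbone(seg_atoms, a, b)
        for name in ("N", "CA", "C"):
            if name not in backbone:
                raise StructureBuildError(
                    f"template residue {int(seg_atoms.res_id[a])} lacks backbone atom {name}"
                )
        records.extend(_make_residue(chain, res_id, ONE_TO_THREE[letter], backbone))
    new = _atoms_from_records(records, like=target.atoms)
    prepend = bool(existing) and start < min(existing)
    return _insert_chain_atoms(target, new, chain, prepend)


def mutate_residue(
    structure: Structure, chain: str, res_id: int, new_name: str
) -> Structure:
    """Rename a residue, preserving its backbone and idealizing the sidechain.

    The sidechain beyond Cbeta is discarded; Cbeta is rebuilt at 1.53 A
    from Calpha with tetrahedral geometry (omitted for Gly).  Mutating a
    residue to its own name is a no-op.
    """
    new_name = new_name.strip().upper()
    if new_name not in STANDARD_RESIDUES:
        raise StructureBuildError(f"unknown target residue name {new_name!r}")
    atoms = structure.atoms
    mask = (atoms.chain_id == chain) & (atoms.res_id == res_id) & (~atoms.hetero)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise StructureBuildError(f"residue {chain}/{res_id} not found")
    old_name = str(atoms.res_name[idx[0]])
    if old_name == new_name:
        return structure.copy()
    a, b = int(idx[0]), int(idx[-1]) + 1
    backbone = _residue_backbone(atoms, a, b)
    for name in ("N", "CA", "C"):
        if name not in backbone:
            raise StructureBuildError(
                f"residue {chain}/{res_id} lacks backbone atom {name}"
            )
    new = _atoms_from_records(
        _make_residue(chain, res_id, new_name, backbone), like=atoms
    )
    combined = atoms[:a] + new + atoms[b:]
    return Structure(combined, structure.header, structure.model_id)


def _terminal_residue(atoms: struc.AtomArray, chain: str, which: str):
    idx = np.flatnonzero((atoms.chain_id == chain) & (~atoms.hetero))
    if idx.size == 0:
        raise StructureBuildError(f"unknown chain {chain!r}")
    res_ids = atoms.res_id[idx]
    rid = int(res_ids.min() if which == "first" else res_ids.max())
    rmask = idx[res_ids == rid]
    coords = {}
    for i in rmask:
        name = str(atoms.atom_name[i])
        if name in ("N", "CA", "C"):
            coords[name] = atoms.coord[i].astype(float)
    if len(coords) != 3:
        raise StructureBuildError(
            f"terminal residue {chain}/{rid} lacks a complete N/CA/C backbone"
        )
    return rid, coords


def extend_terminus(
    structure: Structure,
    chain: str,
    sequence: str,
    direction: str = "N",
    conformation: str = "extended",
) -> tuple[Structure, list[Clash]]:
    """Grow a chain terminus with ideal trans-peptide geometry.

    ``sequence`` is given N-to-C; for an N-terminal extension its last
    residue ends up bonded to the current first residue.  phi/psi come
    from the named conformation ("extended": -140/135, "helical": -57/-47).
    Heavy-atom contacts < 2 A between new residues and other chains are
    returned as clashes, not repaired.
    """
    sequence = sequence.strip().upper()
    if conformation not in geom.CONFORMATIONS:
        raise StructureBuildError(f"unknown conformation {conformation!r}")
    if direction not in ("N", "C"):
        raise StructureBuildError("direction must be 'N' or 'C'")
    if not sequence:
        return structure.copy(), []
    for letter in sequence:
        if letter not in ONE_TO_THREE:
            raise StructureBuildError(f"unknown one-letter code {letter!r}")
    phi, psi = geom.CONFORMATIONS[conformation]
    atoms = structure.atoms
    records = []
    if direction == "N":
        rid0, bb = _terminal_residue(atoms, chain, "first")
        n0, ca0, c0 = bb["N"], bb["CA"], bb["C"]
        # build backwards; sequence[-1] sits adjacent to the current terminus
        built = []
        for offset, letter in enumerate(reversed(sequence), start=1):
            c_new = geom.place_atom(c0, ca0, n0, geom.BOND_C_N, geom.ANGLE_C_N_CA, phi)
            ca_new = geom.place_atom(ca0, n0, c_new, geom.BOND_CA_C,
                                     geom.ANGLE_CA_C_N, geom.OMEGA_TRANS)
            n_new = geom.place_atom(n0, c_new, ca_new, geom.BOND_N_CA,
                                    geom.ANGLE_N_CA_C, psi)
            o_new = geom.place_atom(ca0, n0, c_new, geom.BOND_C_O, 122.7, 180.0)
            backbone = {"N": n_new, "CA": ca_new, "C": c_new, "O": o_new}
            built.append(_make_residue(chain, rid0 - offset,
                                       ONE_TO_THREE[letter], backbone))
            n0, ca0, c0 = n_new, ca_new, c_new
        for res in reversed(built):
            records.extend(res)
        prepend = True
    else:
        rid0, bb = _terminal_residue(atoms, chain, "last")
        n0, ca0, c0 = bb["N"], bb["CA"], bb["C"]
        for offset, letter in enumerate(sequence, start=1):
            n_new = geom.place_atom(n0, ca0, c0, geom.BOND_C_N,
                                    geom.ANGLE_CA_C_N, psi)
            ca_new = geom.place_atom(ca0, c0, n_new, geom.BOND_N_CA,
                                     geom.ANGLE_C_N_CA, geom.OMEGA_TRANS)
            c_new = geom.place_atom(c0, n_new, ca_new, geom.BOND_CA_C,
                                    geom.ANGLE_N_CA_C, phi)
            o_new = geom.place_atom(n_new, ca_new, c_new, geom.BOND_C_O,
                                    geom.ANGLE_CA_C_O, psi + 180.0)
            backbone = {"N": n_new, "CA": ca_new, "C": c_new, "O": o_new}
            records.extend(_make_residue(chain, rid0 + offset,
                                         ONE_TO_THREE[letter], backbone))
            n0, ca0, c0 = n_new, ca_new, c_new
        prepend = False
    new = _atoms_from_records(records, like=atoms)
    out = _insert_chain_atoms(structure, new, chain, prepend)
    clashes = _clash_scan(new, atoms, exclude_chain=chain)
    return out, clashes


def _clash_scan(new: struc.AtomArray, existing: struc.AtomArray,
                exclude_chain: str) -> list[Clash]:
    """Brute-force heavy-atom pair scan of new atoms against other chains."""
    other = existing[(existing.chain_id != exclude_chain)
                     & (existing.element != "H")]
    heavy_new = new[new.element != "H"]
    clashes = []
    if other.array_length() == 0 or heavy_new.array_length() == 0:
        return clashes
    diff = heavy_new.coord[:, None, :] - other.coord[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    for i, j in zip(*np.nonzero(dist < CLASH_CUTOFF)):
        clashes.append(Clash(_atom_label(heavy_new, i), _atom_label(other, j),
                             float(dist[i, j])))
    return clashes


def _atom_label(atoms: struc.AtomArray, i: int) -> str:
    return (f"{atoms.chain_id[i]}/{atoms.res_name[i]} "
            f"{atoms.res_id[i]}/{atoms.atom_name[i]}")


def build_peptide(
    sequence: str,
    conformation: str = "extended",
    chain_id: str = "A",
    start_id: int = 1,
) -> Structure:
    """Build an ideal-geometry peptide (backbone + Cbeta) from scratch."""
    sequence = sequence.strip().upper()
    if not sequence:
        raise StructureBuildError("empty sequence")
    if conformation not in geom.CONFORMATIONS:
        raise StructureBuildError(f"unknown conformation {conformation!r}")
    for letter in sequence:
        if letter not in ONE_TO_THREE:
            raise StructureBuildError(f"unknown one-letter code {letter!r}")
    phi, psi = geom.CONFORMATIONS[conformation]
    # canonical placement of residue 1 in the xy-plane
    n0 = np.zeros(3)
    ca0 = np.array([geom.BOND_N_CA, 0.0, 0.0])
    theta = np.deg2rad(180.0 - geom.ANGLE_N_CA_C)
    c0 = ca0 + geom.BOND_CA_C * np.array([np.cos(theta), np.sin(theta), 0.0])
    backbones = [{"N": n0, "CA": ca0, "C": c0}]
    n, ca, c = n0, ca0, c0
    for _ in sequence[1:]:
        n_new = geom.place_atom(n, ca, c, geom.BOND_C_N, geom.ANGLE_CA_C_N, psi)
        ca_new = geom.place_atom(ca, c, n_new, geom.BOND_N_CA,
                                 geom.ANGLE_C_N_CA, geom.OMEGA_TRANS)
        c_new = geom.place_atom(c, n_new, ca_new, geom.BOND_CA_C,
                                geom.ANGLE_N_CA_C, phi)
        backbones.append({"N": n_new, "CA": ca_new, "C": c_new})
        n, ca, c = n_new, ca_new, c_new
    records = []
    for i, (letter, bb) in enumerate(zip(sequence, backbones)):
        bb["O"] = geom.place_atom(bb["N"], bb["CA"], bb["C"], geom.BOND_C_O,
                                  geom.ANGLE_CA_C_O, psi + 180.0)
        records.extend(_make_residue(chain_id, start_id + i,
                                     ONE_TO_THREE[letter], bb))
    return Structure(_atoms_from_records(records))


def peptide_bond_lengths(structure: Structure, chain: str) -> list[tuple[tuple[int, int], float]]:
    """C(i)-N(i+1) distances between numbering-consecutive residues.

    Used to inspect the junction between a grafted fragment and a
    pre-existing one instead of enforcing loop closure.
    """
    atoms = structure.atoms
    mask = (atoms.chain_id == chain) & (~atoms.hetero)
    if not mask.any():
        raise StructureBuildError(f"unknown chain {chain!r}")
    sub = atoms[mask]
    c_pos, n_pos = {}, {}
    for i in range(sub.array_length()):
        rid = int(sub.res_id[i])
        if sub.atom_name[i] == "C":
            c_pos[rid] = sub.coord[i].astype(float)
        elif sub.atom_name[i] == "N":
            n_pos[rid] = sub.coord[i].astype(float)
    out = []
    for rid in sorted(c_pos):
        if rid + 1 in n_pos:
            d = float(np.linalg.norm(n_pos[rid + 1] - c_pos[rid]))
            out.append(((rid, rid + 1), d))
    return out
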
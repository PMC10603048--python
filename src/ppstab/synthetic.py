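"""Seeded synthetic structures, ensembles and trajectories.

Everything the analysis stages consume can be generated here without
external downloads:

* ideal-geometry toy peptides and two-chain complexes at a controlled
  interface gap,
* structure ensembles whose coordinate variance is concentrated on a few
  planted orthonormal modes (test bed for coordinate PCA),
* trajectories of a bound complex (stationary per-atom Gaussian jitter)
  or a dissociating one (rigid partner drift plus jitter),
* tiny charged/apolar atom systems with closed-form solvation energies.

Every generator takes a seed and is bit-reproducible.  The jitter model
is i.i.d. Gaussian noise per atom coordinate and the drift is a rigid
whole-chain translation, cleanly separating the "fluctuation" and
"dissociation" signals that the interface metrics are designed to pick
up; neither emulates force-field-driven dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.structure as struc
from scipy.optimize import brentq

from .gbsa import AtomParams, toy_params
from .io import ComplexDefinition, Selection, Structure, Trajectory
from .modeling import build_peptide

__all__ = [
    "build_toy_peptide",
    "make_complex",
    "orthonormal_modes",
    "ensemble_with_planted_modes",
    "trajectory_bound",
    "trajectory_dissociating",
    "born_ion",
    "ion_pair",
    "sphere_pair",
]


def build_toy_peptide(
    sequence: str,
    conformation: str = "extended",
    chain_id: str = "A",
    start_id: int = 1,
) -> Structure:
    """Ideal-geometry peptide: backbone N/CA/C/O plus Cbeta for non-Gly."""
    return build_peptide(sequence, conformation, chain_id, start_id)


def make_complex(
    receptor: Structure,
    partner: Structure,
    gap: float = 4.0,
    axis=(1.0, 0.0, 0.0),
) -> tuple[Structure, ComplexDefinition]:
    """Place the partner so the minimum inter-chain heavy-atom distance is ``gap``.

    The partner is first centred against the receptor, then translated
    along ``axis``; the translation magnitude is solved so the minimum
    heavy-atom separation equals ``gap`` to within 0.01 A.
    """
    if gap <= 0:
        raise ValueError("gap must be positive")
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("zero axis")
    axis = axis / norm
    rec_atoms = receptor.atoms
    par_atoms = partner.atoms.copy()
    if set(np.unique(par_atoms.chain_id)) & set(np.unique(rec_atoms.chain_id)):
        # relabel partner chains to avoid identifier collisions
        mapping = {}
        used = set(np.unique(rec_atoms.chain_id))
        candidates = [c for c in "BCDEFGHIJKLMNOPQRSTUVWXYZA" if c not in used]
        for c in np.unique(par_atoms.chain_id):
            mapping[c] = candidates.pop(0)
        par_atoms.chain_id = np.array(
            [mapping[c] for c in par_atoms.chain_id], dtype="U4"
        )
    # start from receptor centroid so the bracketing below is well defined
    par_atoms.coord = (
        par_atoms.coord - par_atoms.coord.mean(axis=0) + rec_atoms.coord.mean(axis=0)
    ).astype(np.float32)
    rec_heavy = rec_atoms.coord[rec_atoms.element != "H"].astype(float)
    par_heavy0 = par_atoms.coord[par_atoms.element != "H"].astype(float)

    def min_dist(shift: float) -> float:
        moved = par_heavy0 + shift * axis
        diff = rec_heavy[:, None, :] - moved[None, :, :]
        return float(np.sqrt((diff ** 2).sum(axis=2)).min())

    # bracket: far enough out the minimum distance grows ~linearly in shift
    span = float(
        np.linalg.norm(rec_heavy.max(0) - rec_heavy.min(0))
        + np.linalg.norm(par_heavy0.max(0) - par_heavy0.min(0))
    )
    if min_dist(0.0) >= gap:
        raise ValueError(
            "centred chains are already separated beyond the requested gap; "
            "choose a larger gap or a different axis"
        )
    lo, hi = 0.0, span + gap + 10.0
    while min_dist(hi) < gap:
        hi += span + 10.0
    shift = brentq(lambda s: min_dist(s) - gap, lo, hi, xtol=1e-4)
    par_atoms.coord = (par_atoms.coord + (shift * axis).astype(np.float32))
    combined = rec_atoms + par_atoms
    rec_chain = str(rec_atoms.chain_id[0])
    par_chain = str(par_atoms.chain_id[0])
    cdef = ComplexDefinition(
        receptor=Selection(rec_chain),
        partner=(Selection(par_chain),),
        label=f"{rec_chain}-{par_chain} toy complex",
    )
    return Structure(combined), cdef


def _ca_indices(atoms: struc.AtomArray) -> np.ndarray:
    return np.flatnonzero((atoms.atom_name == "CA") & (~atoms.hetero))


def orthonormal_modes(
    base: Structure, n_modes: int, seed: int
) -> np.ndarray:
    """Random orthonormal displacement modes over the Calpha coordinate space.

    Modes are orthogonalized against the six rigid-body motions of the
    base Calpha geometry (and each other), so planted variance cannot be
    absorbed by the superposition step of a downstream PCA.
    """
    ca = _ca_indices(base.atoms)
    m = ca.size
    if n_modes > 3 * m - 6:
        raise ValueError("too many modes for this many residues")
    coords = base.atoms.coord[ca].astype(float)
    center = coords - coords.mean(axis=0)
    rigid = []
    for axis in np.eye(3):
        t = np.tile(axis, m)
        rigid.append(t / np.linalg.norm(t))
        r = np.cross(center, axis).ravel()
        n = np.linalg.norm(r)
        if n > 1e-9:
            rigid.append(r / n)
    rng = np.random.default_rng(seed)
    basis = list(rigid)
    modes = []
    while len(modes) < n_modes:
        v = rng.standard_normal(3 * m)
        for b in basis:
            v -= np.dot(v, b) * b
        n = np.linalg.norm(v)
        if n < 1e-6:
            continue
        v /= n
        basis.append(v)
        modes.append(v)
    return np.array(modes)


def ensemble_with_planted_modes(
    base: Structure,
    modes: np.ndarray,
    variances,
    n: int,
    seed: int,
    rigid_motion: bool = False,
) -> list[Structure]:
    """Ensemble members displaced along planted modes with Gaussian amplitudes.

    Member k = base + sum_j a_kj mode_j with a_kj ~ Normal(0, variance_j).
    Mode vectors act on the Calpha coordinates; every atom of a residue is
    displaced by its Calpha's 3-vector, keeping residues intact.  With
    ``rigid_motion`` each member additionally receives a random rotation
    and translation (which a correct PCA must remove by superposition).
    """
    modes = np.asarray(modes, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if (variances < 0).any():
        raise ValueError("variances must be nonnegative")
    gram = modes @ modes.T
    if not np.allclose(gram, np.eye(len(modes)), atol=1e-8):
        raise ValueError("modes are not orthonormal")
    ca = _ca_indices(base.atoms)
    if modes.shape[1] != 3 * ca.size:
        raise ValueError("mode length does not match Calpha coordinate space")
    # map each atom to its residue's Calpha row
    atoms = base.atoms
    ca_of_res = {
        (str(atoms.chain_id[i]), int(atoms.res_id[i])): k
        for k, i in enumerate(ca)
    }
    atom_row = np.array([
        ca_of_res[(str(atoms.chain_id[i]), int(atoms.res_id[i]))]
        for i in range(atoms.array_length())
    ])
    rng = np.random.default_rng(seed)
    amplitudes = rng.standard_normal((n, len(modes))) * np.sqrt(variances)
    members = []
    for k in range(n):
        disp = (amplitudes[k] @ modes).reshape(-1, 3)  # per-Calpha 3-vectors
        coords = atoms.coord.astype(float) + disp[atom_row]
        if rigid_motion:
            R = _random_rotation(rng)
            t = rng.uniform(-10, 10, size=3)
            coords = coords @ R.T + t
        member = atoms.copy()
        member.coord = coords.astype(np.float32)
        members.append(Structure(member, model_id=k + 1))
    return members


def _random_rotation(rng) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def trajectory_bound(
    complex_structure: Structure,
    sigma: float,
    n_frames: int,
    seed: int,
) -> Trajectory:
    """Stationary-jitter trajectory: frame = complex + N(0, sigma) per coordinate."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    base = complex_structure.atoms.coord.astype(float)
    noise = rng.standard_normal((n_frames,) + base.shape) * sigma
    return Trajectory(complex_structure.atoms.copy(), base[None] + noise)


def trajectory_dissociating(
    complex_structure: Structure,
    cdef: ComplexDefinition,
    drift,
    sigma: float,
    n_frames: int,
    seed: int,
) -> Trajectory:
    """Progressive-dissociation trajectory: rigid partner drift plus jitter.

    At frame k the partner chain is rigidly translated by k * drift; all
    atoms additionally receive N(0, sigma) jitter.
    """
    drift = np.asarray(drift, dtype=float)
    if np.linalg.norm(drift) < 1e-12:
        raise ValueError("drift vector must be nonzero")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    atoms = complex_structure.atoms
    base = atoms.coord.astype(float)
    partner = cdef.partner_mask(atoms)
    coords = np.repeat(base[None], n_frames, axis=0)
    for k in range(n_frames):
        coords[k][partner] += k * drift
    coords += rng.standard_normal(coords.shape) * sigma
    return Trajectory(atoms.copy(), coords)


# ---------------------------------------------------------------------------
# tiny charged/apolar systems with closed-form reference energies


def _bare_atoms(coords, elements, names=None) -> Structure:
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.chain_id = np.array(["A"] * n, dtype="U4")
    arr.res_id = np.arange(1, n + 1)
    arr.ins_code = np.array([""] * n, dtype="U1")
    arr.res_name = np.array(["ION"] * n, dtype="U5")
    arr.atom_name = np.array(names or [f"X{i+1}" for i in range(n)], dtype="U6")
    arr.hetero = np.ones(n, dtype=bool)
    arr.element = np.array(elements, dtype="U2")
    arr.coord = np.asarray(coords, dtype=np.float32)
    return Structure(arr)


def _uniform_params(n, charge, gb_radius, eps=0.1, rmin=1.7) -> AtomParams:
    charge = np.broadcast_to(np.asarray(charge, float), (n,)).copy()
    gb = np.broadcast_to(np.asarray(gb_radius, float), (n,)).copy()
    return AtomParams(
        charge=charge,
        eps=np.full(n, eps), rmin=np.full(n, rmin), gb_radius=gb,
        lcpo_p1=np.ones(n), lcpo_p2=-np.ones(n),
        lcpo_p3=np.zeros(n), lcpo_p4=np.zeros(n),
        lcpo_radius=gb.copy(),
    )


def born_ion(charge: float = 1.0, radius: float = 2.0):
    """A single ion; its GB self-energy has the Born closed form.

    Returns (structure, params).  Note ``radius`` is the *effective* Born
    radius to use directly in the polar-energy formula.
    """
    s = _bare_atoms([[0.0, 0.0, 0.0]], ["O"])
    return s, _uniform_params(1, charge, radius + GB_OFFSET_FOR_TOYS)


# for toy systems we want the effective radius of an isolated atom to be
# exactly the requested one: the OBC limit at Psi=0 gives R = rho - offset
GB_OFFSET_FOR_TOYS = 0.09


def ion_pair(q1: float, q2: float, separation: float, radius: float = 2.0):
    """Two ions on the x axis; at large separation the GB cross term
    approaches the screened Coulomb interaction."""
    if separation <= 0:
        raise ValueError("separation must be positive")
    s = _bare_atoms([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]], ["O", "O"])
    return s, _uniform_params(2, [q1, q2], radius + GB_OFFSET_FOR_TOYS)


def sphere_pair(separation: float, radius_a: float = 1.7, radius_b: float = 1.7):
    """Two neutral spheres for SASA overlap tests."""
    s = _bare_atoms([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]], ["C", "C"])
    params = _uniform_params(2, 0.0, [radius_a, radius_b])
    params.lcpo_radius = np.array([radius_a, radius_b])
    params.gb_radius = np.array([radius_a, radius_b])
    return s, params
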
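"""Implicit-solvent MM-GBSA binding-enthalpy scoring.

The binding score of a receptor-partner complex is composed as

    dG_binding = dG_complex - (dG_receptor + dG_partner)
    dG         = dE_MM + dG_solvation            (entropy omitted)

under the single-trajectory convention: receptor and partner conformations
are extracted from the complex frame, so all intramolecular bonded terms
cancel exactly and dE_MM reduces to the intermolecular Coulomb and
Lennard-Jones energies.  dG_solvation is the generalized-Born polar term
(OBC-II tanh-rescaled effective radii) plus a SASA-proportional nonpolar
term with the surface area from the LCPO pairwise-overlap approximation.

Energies are computed in kcal/mol; reported binding scores are converted
to kJ/mol (x 4.184).  Multi-pose scoring averages evenly spaced frames
from the last half of a trajectory, and ligand efficiency normalizes the
mean score by the partner's heavy-atom count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .io import ComplexDefinition, Structure, Trajectory

__all__ = [
    "AtomParams",
    "EnergyBreakdown",
    "BindingScore",
    "COULOMB_CONSTANT",
    "coulomb_energy",
    "lj_energy",
    "effective_born_radii",
    "gb_polar_energy",
    "lcpo_sasa",
    "nonpolar_energy",
    "binding_energy",
    "multi_pose_score",
    "ligand_efficiency",
    "toy_params",
    "load_params",
    "save_params",
]

#: electrostatic conversion constant, kcal mol^-1 A e^-2
COULOMB_CONSTANT = 332.0637
KCAL_TO_KJ = 4.184

DEFAULT_CUTOFF = 18.0  # nonbonded cutoff, A
DEFAULT_SOLVENT_DIELECTRIC = 78.5
DEFAULT_INTERIOR_DIELECTRIC = 1.0
DEFAULT_PROBE = 1.4  # solvent probe radius, A
DEFAULT_SURFACE_TENSION = 0.005  # kcal/mol/A^2
GB_OFFSET = 0.09  # intrinsic radius offset, A
OBC_ALPHA, OBC_BETA, OBC_GAMMA = 1.0, 0.8, 4.85  # OBC-II tanh coefficients
DEFAULT_HCT_SCALE = 0.8  # descreening scaling factor

# element-based intrinsic GB radii (mbondi-like) and LJ parameters used by
# the toy parameter assigner; eps in kcal/mol, rmin is Rmin/2 in A
_ELEMENT_GB_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.5, "S": 1.8, "P": 1.85}
_ELEMENT_LJ = {
    "H": (0.0157, 0.6),
    "C": (0.086, 1.908),
    "N": (0.17, 1.824),
    "O": (0.21, 1.661),
    "S": (0.25, 2.0),
    "P": (0.2, 2.1),
}


@dataclass
class AtomParams:
    """Per-atom nonbonded, GB and LCPO parameters, aligned with an atom array."""

    charge: np.ndarray  # e
    eps: np.ndarray  # kcal/mol
    rmin: np.ndarray  # Rmin/2, A
    gb_radius: np.ndarray  # intrinsic Born radius, A
    lcpo_p1: np.ndarray
    lcpo_p2: np.ndarray
    lcpo_p3: np.ndarray
    lcpo_p4: np.ndarray
    lcpo_radius: np.ndarray  # atomic radius for LCPO, A (probe added later)

    def __post_init__(self):
        n = len(self.charge)
        for name in ("eps", "rmin", "gb_radius", "lcpo_p1", "lcpo_p2",
                     "lcpo_p3", "lcpo_p4", "lcpo_radius"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if len(arr) != n:
                raise ValueError(f"parameter column {name} has wrong length")
        self.charge = np.asarray(self.charge, dtype=float)
        if (self.gb_radius <= 0).any() or (self.lcpo_radius <= 0).any():
            raise ValueError("radii must be positive")
        if (self.lcpo_radius < self.gb_radius - 0.5).any():
            raise ValueError("LCPO radius implausibly small relative to GB radius")

    def __len__(self) -> int:
        return len(self.charge)

    def subset(self, idx: np.ndarray) -> "AtomParams":
        return AtomParams(*(getattr(self, f)[idx] for f in (
            "charge", "eps", "rmin", "gb_radius",
            "lcpo_p1", "lcpo_p2", "lcpo_p3", "lcpo_p4", "lcpo_radius")))


@dataclass
class EnergyBreakdown:
    """Component energies in kcal/mol; total = elec + vdw + polar + nonpolar."""

    e_elec: float
    e_vdw: float
    g_polar: float
    g_nonpolar: float

    @property
    def e_mm(self) -> float:
        return self.e_elec + self.e_vdw

    @property
    def g_solvation(self) -> float:
        return self.g_polar + self.g_nonpolar

    @property
    def total(self) -> float:
        return self.e_elec + self.e_vdw + self.g_polar + self.g_nonpolar

    @property
    def total_kj(self) -> float:
        return self.total * KCAL_TO_KJ

    def as_dict(self, units: str = "kcal") -> dict[str, float]:
        f = 1.0 if units == "kcal" else KCAL_TO_KJ
        return {
            "e_elec": self.e_elec * f,
            "e_vdw": self.e_vdw * f,
            "g_polar": self.g_polar * f,
            "g_nonpolar": self.g_nonpolar * f,
            "total": self.total * f,
            "units": units + "/mol",
        }


@dataclass
class BindingScore:
    """Multi-pose binding-enthalpy summary; energies in kJ/mol."""

    per_pose_kj: np.ndarray
    pose_indices: list[int]
    partner_heavy_atoms: int
    label: str = ""

    @property
    def mean_kj(self) -> float:
        return float(np.mean(self.per_pose_kj))

    @property
    def sd_kj(self) -> float:
        if len(self.per_pose_kj) < 2:
            return 0.0
        return float(np.std(self.per_pose_kj, ddof=1))

    @property
    def ligand_efficiency(self) -> float:
        return ligand_efficiency(self.mean_kj, self.partner_heavy_atoms)

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "per_pose_kj": [float(x) for x in self.per_pose_kj],
            "pose_indices": list(self.pose_indices),
            "mean_kj": self.mean_kj,
            "sd_kj": self.sd_kj,
            "partner_heavy_atoms": self.partner_heavy_atoms,
            "ligand_efficiency_kj_per_heavy_atom": self.ligand_efficiency,
        }


def _pair_distances(coords_a, coords_b):
    diff = coords_a[:, None, :] - coords_b[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def _pair_iter(coords, idx_a=None, idx_b=None):
    """Distance matrix and index grids for a pair set.

    With ``idx_a``/``idx_b`` given, pairs run across the two groups;
    otherwise over all unordered pairs within ``coords``.
    """
    if idx_a is None:
        n = coords.shape[0]
        ia, ib = np.triu_indices(n, k=1)
        d = np.linalg.norm(coords[ia] - coords[ib], axis=1)
        return ia, ib, d
    ia, ib = np.meshgrid(idx_a, idx_b, indexing="ij")
    ia, ib = ia.ravel(), ib.ravel()
    d = np.linalg.norm(coords[ia] - coords[ib], axis=1)
    return ia, ib, d


def coulomb_energy(
    coords: np.ndarray,
    params: AtomParams,
    idx_a: np.ndarray | None = None,
    idx_b: np.ndarray | None = None,
    cutoff: float | None = DEFAULT_CUTOFF,
    interior_dielectric: float = DEFAULT_INTERIOR_DIELECTRIC,
) -> float:
    """Pairwise Coulomb energy, kcal/mol: sum 332.0637 q_i q_j / (eps_in r_ij)."""
    ia, ib, d = _pair_iter(np.asarray(coords, float), idx_a, idx_b)
    if d.size == 0:
        return 0.0
    if (d < 1e-8).any():
        raise ValueError("coincident atoms in Coulomb pair set")
    q = params.charge
    e = COULOMB_CONSTANT * q[ia] * q[ib] / (interior_dielectric * d)
    if cutoff is not None:
        e = e[d < cutoff]
    return float(e.sum())


def lj_energy(
    coords: np.ndarray,
    params: AtomParams,
    idx_a: np.ndarray | None = None,
    idx_b: np.ndarray | None = None,
    cutoff: float | None = DEFAULT_CUTOFF,
) -> float:
    """12-6 Lennard-Jones energy with Lorentz-Berthelot combining, kcal/mol.

    Per-atom parameters are the AMBER-style (eps_i, Rmin_i/2); for a pair,
    Rmin_ij = rmin_i + rmin_j and eps_ij = sqrt(eps_i eps_j), giving
    E = eps_ij [ (Rmin_ij/r)^12 - 2 (Rmin_ij/r)^6 ].
    """
    if (params.rmin <= 0).any():
        raise ValueError("nonpositive LJ radius")
    ia, ib, d = _pair_iter(np.asarray(coords, float), idx_a, idx_b)
    if d.size == 0:
        return 0.0
    if (d < 1e-8).any():
        raise ValueError("coincident atoms in LJ pair set")
    rmin_ij = params.rmin[ia] + params.rmin[ib]
    eps_ij = np.sqrt(params.eps[ia] * params.eps[ib])
    x6 = (rmin_ij / d) ** 6
    e = eps_ij * (x6 ** 2 - 2.0 * x6)
    if cutoff is not None:
        e = e[d < cutoff]
    return float(e.sum())


def _hct_integral(r: float, rho_i: float, s_j: float) -> float:
    """Pairwise descreening integral H(r, rho_i, s_j) of the HCT scheme.

    Equals (1/4pi) * integral of |x|^-4 over the part of the descreening
    sphere (radius s_j at distance r) lying outside radius rho_i of atom i.
    """
    u = r + s_j
    if rho_i >= u:
        return 0.0
    if rho_i > abs(r - s_j):
        low = rho_i
    else:
        low = abs(r - s_j)
    term = (
        1.0 / low - 1.0 / u
        + (r / 4.0) * (1.0 / u ** 2 - 1.0 / low ** 2)
        + (1.0 / (2.0 * r)) * math.log(low / u)
        + (s_j ** 2 / (4.0 * r)) * (1.0 / low ** 2 - 1.0 / u ** 2)
    )
    h = 0.5 * term
    if rho_i < s_j - r:
        # atom i fully engulfed by the descreening sphere of j
        h += 1.0 / rho_i - 1.0 / low
    return h


def effective_born_radii(
    coords: np.ndarray,
    params: AtomParams,
    scale: float = DEFAULT_HCT_SCALE,
    offset: float = GB_OFFSET,
) -> np.ndarray:
    """OBC-II effective Born radii (A).

    Pairwise HCT descreening integrals are summed into Psi and rescaled
    through the OBC tanh formula:

        1/R_i = 1/rho~_i - tanh(a*Psi - b*Psi^2 + g*Psi^3) / rho_i

    with rho~_i = rho_i - offset, (a, b, g) = (1.0, 0.8, 4.85).
    """
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    rho = params.gb_radius
    rho_t = rho - offset
    if (rho_t <= 0).any():
        raise ValueError("intrinsic radius smaller than GB offset")
    radii = np.empty(n)
    if n > 1:
        d = _pair_distances(coords, coords)
        if (d[~np.eye(n, dtype=bool)] < 1e-8).any():
            raise ValueError("overlapping identical atom centers")
    for i in range(n):
        integral = 0.0
        for j in range(n):
            if i == j:
                continue
            integral += _hct_integral(d[i, j], rho_t[i], scale * rho_t[j])
        psi = rho_t[i] * integral
        inv = 1.0 / rho_t[i] - math.tanh(
            OBC_ALPHA * psi - OBC_BETA * psi ** 2 + OBC_GAMMA * psi ** 3
        ) / rho[i]
        radii[i] = 1.0 / inv
    return radii


def gb_polar_energy(
    coords: np.ndarray,
    params: AtomParams,
    born_radii: np.ndarray | None = None,
    solvent_dielectric: float = DEFAULT_SOLVENT_DIELECTRIC,
    interior_dielectric: float = DEFAULT_INTERIOR_DIELECTRIC,
) -> float:
    """Generalized-Born polar solvation energy, kcal/mol.

    -1/2 (1/eps_in - 1/eps_solv) k sum_ij q_i q_j / f_GB(r_ij, R_i, R_j),
    f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / (4 R_i R_j))), including i = j
    self terms (f_GB = R_i), which reduce to the Born ion formula.
    """
    coords = np.asarray(coords, float)
    if born_radii is None:
        born_radii = effective_born_radii(coords, params)
    R = np.asarray(born_radii, float)
    q = params.charge
    r2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    rr = R[:, None] * R[None, :]
    f = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    qq = q[:, None] * q[None, :]
    prefactor = -0.5 * (1.0 / interior_dielectric - 1.0 / solvent_dielectric)
    return float(prefactor * COULOMB_CONSTANT * (qq / f).sum())


def lcpo_sasa(
    coords: np.ndarray,
    params: AtomParams,
    probe: float = DEFAULT_PROBE,
):
    """LCPO solvent-accessible surface area, A^2.

    Per atom, with R = lcpo_radius + probe and A_ij the area of sphere i
    buried inside neighbour j:

        A_i = P1 S_i + P2 sum_j A_ij + P3 sum_{j,k} A_jk
              + P4 sum_j [ A_ij sum_k A_jk ]

    (j over neighbours of i; k over mutual neighbours of i and j).
    Negative per-atom areas are clamped to zero.  Returns (per-atom, total).
    """
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    R = params.lcpo_radius + probe
    if n == 0:
        return np.zeros(0), 0.0
    d = _pair_distances(coords, coords)
    neighbor = (d < (R[:, None] + R[None, :])) & ~np.eye(n, dtype=bool)

    def buried(i, j):
        """Area of sphere i buried by overlapping sphere j."""
        dij = d[i, j]
        return 2.0 * math.pi * R[i] * (
            R[i] - dij / 2.0 - (R[i] ** 2 - R[j] ** 2) / (2.0 * dij)
        )

    s1 = 4.0 * math.pi * R ** 2
    per_atom = np.empty(n)
    neighbors = [np.flatnonzero(neighbor[i]) for i in range(n)]
    for i in range(n):
        term2 = 0.0
        term3 = 0.0
        term4 = 0.0
        for j in neighbors[i]:
            aij = buried(i, j)
            term2 += aij
            inner = 0.0
            for k in neighbors[j]:
                if k != i and neighbor[i, k]:
                    inner += buried(j, k)
            term3 += inner
            term4 += aij * inner
        area = (
            params.lcpo_p1[i] * s1[i]
            + params.lcpo_p2[i] * term2
            + params.lcpo_p3[i] * term3
            + params.lcpo_p4[i] * term4
        )
        per_atom[i] = max(area, 0.0)
    return per_atom, float(per_atom.sum())


def nonpolar_energy(
    total_sasa: float,
    surface_tension: float = DEFAULT_SURFACE_TENSION,
    offset: float = 0.0,
) -> float:
    """SASA-proportional nonpolar solvation term: gamma * SASA + b (kcal/mol)."""
    if total_sasa < 0:
        raise ValueError("negative SASA")
    return surface_tension * total_sasa + offset


def _species_energy(coords, params, cutoff, eps_in, eps_solv, probe, gamma):
    """Solvation free energy (polar + nonpolar) of one species, kcal/mol."""
    radii = effective_born_radii(coords, params)
    polar = gb_polar_energy(coords, params, radii, eps_solv, eps_in)
    _, sasa = lcpo_sasa(coords, params, probe)
    return polar, nonpolar_energy(sasa, gamma)


def binding_energy(
    frame: Structure,
    cdef: ComplexDefinition,
    params: AtomParams,
    cutoff: float | None = DEFAULT_CUTOFF,
    interior_dielectric: float = DEFAULT_INTERIOR_DIELECTRIC,
    solvent_dielectric: float = DEFAULT_SOLVENT_DIELECTRIC,
    probe: float = DEFAULT_PROBE,
    surface_tension: float = DEFAULT_SURFACE_TENSION,
) -> EnergyBreakdown:
    """Single-frame MM-GBSA binding enthalpy (kcal/mol).

    Receptor and partner conformations are taken from the complex frame
    (single-trajectory convention), so intramolecular MM terms cancel and
    the MM part is the intermolecular Coulomb + LJ energy; the solvation
    terms are evaluated for complex, receptor and partner and differenced.
    """
    atoms = frame.atoms
    rec = np.flatnonzero(cdef.receptor_mask(atoms))
    par = np.flatnonzero(cdef.partner_mask(atoms))
    if rec.size == 0 or par.size == 0:
        raise ValueError("empty receptor or partner selection")
    if np.intersect1d(rec, par).size:
        raise ValueError("receptor and partner selections overlap")
    if len(params) != atoms.array_length():
        raise ValueError("parameter set does not match atom count")
    coords = atoms.coord.astype(float)
    e_elec = coulomb_energy(coords, params, rec, par, cutoff, interior_dielectric)
    e_vdw = lj_energy(coords, params, rec, par, cutoff)
    both = np.concatenate([rec, par])
    polar_c, np_c = _species_energy(
        coords[both], params.subset(both), cutoff,
        interior_dielectric, solvent_dielectric, probe, surface_tension)
    polar_r, np_r = _species_energy(
        coords[rec], params.subset(rec), cutoff,
        interior_dielectric, solvent_dielectric, probe, surface_tension)
    polar_p, np_p = _species_energy(
        coords[par], params.subset(par), cutoff,
        interior_dielectric, solvent_dielectric, probe, surface_tension)
    return EnergyBreakdown(
        e_elec=e_elec,
        e_vdw=e_vdw,
        g_polar=polar_c - polar_r - polar_p,
        g_nonpolar=np_c - np_r - np_p,
    )


def pose_indices(n_frames: int, n_poses: int) -> list[int]:
    """Evenly spaced frame indices over the last half of a trajectory.

    The first pose is the midpoint frame; subsequent poses advance by the
    integer step (n_frames - 1 - midpoint) // (n_poses - 1).  A 100-frame
    trajectory with 5 poses yields frames 50, 62, 74, 86, 98.
    """
    if n_frames < 2 * n_poses:
        raise ValueError(
            f"need at least {2 * n_poses} frames for {n_poses} poses, got {n_frames}"
        )
    start = n_frames // 2
    if n_poses == 1:
        return [start]
    step = (n_frames - 1 - start) // (n_poses - 1)
    return [start + k * step for k in range(n_poses)]


def relax_pose(
    frame: Structure,
    params: AtomParams,
    max_steps: int = 500,
    force_tolerance: float = 1.0,
    restraint_k: float = 10.0,
    cutoff: float = DEFAULT_CUTOFF,
) -> Structure:
    """Steepest-descent Cartesian relaxation of a pose before scoring.

    Minimizes the nonbonded Coulomb + Lennard-Jones energy plus harmonic
    positional restraints (``restraint_k`` kcal/mol/A^2) to the input
    coordinates — the restraints stand in for the bonded terms this
    scoring function does not carry, so relaxation resolves clashes
    without unfolding the geometry.  Stops after ``max_steps`` steps or
    when the maximum atomic force drops below ``force_tolerance``
    (kcal/mol/A).
    """
    x0 = frame.atoms.coord.astype(float)
    x = x0.copy()
    q = params.charge
    n = len(q)

    def forces(pos):
        diff = pos[:, None, :] - pos[None, :, :]
        r = np.sqrt((diff ** 2).sum(axis=2))
        np.fill_diagonal(r, np.inf)
        mask = r < cutoff
        qq = q[:, None] * q[None, :]
        dedr = -COULOMB_CONSTANT * qq / r ** 2
        rmin_ij = params.rmin[:, None] + params.rmin[None, :]
        eps_ij = np.sqrt(params.eps[:, None] * params.eps[None, :])
        x6 = (rmin_ij / r) ** 6
        dedr += -12.0 * eps_ij / r * (x6 ** 2 - x6)
        dedr = np.where(mask, dedr, 0.0)
        f = -(dedr / r)[:, :, None] * diff
        return f.sum(axis=1) - 2.0 * restraint_k * (pos - x0)

    step = 1e-3
    max_move = 0.05  # A per step, guards against clash-driven force spikes
    for _ in range(max_steps):
        f = forces(x)
        fmax = np.abs(f).max()
        if fmax < force_tolerance:
            break
        dx = step * f
        biggest = np.linalg.norm(dx, axis=1).max()
        if biggest > max_move:
            dx *= max_move / biggest
        x = x + dx
    out = frame.copy()
    out.atoms.coord = x.astype(np.float32)
    return out


def multi_pose_score(
    trajectory: Trajectory,
    cdef: ComplexDefinition,
    params: AtomParams,
    n_poses: int = 5,
    label: str = "",
    relax: bool = False,
    **energy_kwargs,
) -> BindingScore:
    """Mean +/- SD binding enthalpy (kJ/mol) over MD poses from the last half.

    With ``relax`` each pose is first relaxed by :func:`relax_pose`
    (off by default: the rigid-geometry score is the reference behaviour).
    """
    idx = pose_indices(trajectory.n_frames, n_poses)
    per_pose = []
    for i in idx:
        frame = trajectory.frame(i)
        if relax:
            frame = relax_pose(frame, params)
        bd = binding_energy(frame, cdef, params, **energy_kwargs)
        per_pose.append(bd.total_kj)
    top = Structure(trajectory.topology)
    heavy = int(
        (cdef.partner_mask(trajectory.topology)
         & (trajectory.topology.element != "H")).sum()
    )
    return BindingScore(np.array(per_pose), idx, heavy, label or cdef.label)


def ligand_efficiency(mean_kj: float, heavy_atoms: int) -> float:
    """Binding score per partner heavy atom, rounded half-away-from-zero to 2 dp."""
    if heavy_atoms <= 0:
        raise ValueError("heavy-atom count must be positive")
    value = mean_kj / heavy_atoms
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# parameter assignment and plain-text table I/O

_PARAM_COLUMNS = [
    "chain", "resnum", "atomname", "charge", "eps", "rmin", "gb_radius",
    "lcpo_p1", "lcpo_p2", "lcpo_p3", "lcpo_p4", "lcpo_radius",
]


def toy_params(structure: Structure) -> AtomParams:
    """Schematic parameters for synthetic systems.

    Unit charges sit on the Cbeta of charged residues (+1 Lys/Arg,
    -1 Asp/Glu; the charged-group atom is used instead when present), all
    other atoms are neutral.  GB radii are element based (mbondi-like),
    and the LCPO coefficients are (1, -1, 0, 0) — exact for isolated atoms
    and pairwise overlaps.  These are deliberately schematic bookkeeping
    parameters, not a force field.
    """
    atoms = structure.atoms
    n = atoms.array_length()
    charge = np.zeros(n)
    gb = np.empty(n)
    eps = np.empty(n)
    rmin = np.empty(n)
    charge_bearer = {"LYS": "NZ", "ARG": "NH1", "ASP": "OD1", "GLU": "OE1"}
    sign = {"LYS": 1.0, "ARG": 1.0, "ASP": -1.0, "GLU": -1.0}
    # locate the charge-bearing atom per charged residue: named group atom
    # if present, else the Cbeta stub
    for key in np.unique(
        np.stack([atoms.chain_id.astype("U4"), atoms.res_id.astype("U8")], axis=1),
        axis=0,
    ):
        chain, rid = key[0], int(key[1])
        mask = (atoms.chain_id == chain) & (atoms.res_id == rid)
        resname = str(atoms.res_name[np.flatnonzero(mask)[0]])
        if resname not in sign:
            continue
        names = atoms.atom_name[mask]
        idx = np.flatnonzero(mask)
        want = charge_bearer[resname]
        hit = idx[names == want]
        if hit.size == 0:
            hit = idx[names == "CB"]
        if hit.size == 0:
            hit = idx[names == "CA"]
        if hit.size:
            charge[hit[0]] = sign[resname]
    for i in range(n):
        el = str(atoms.element[i]).upper() or "C"
        gb[i] = _ELEMENT_GB_RADII.get(el, 1.7)
        e, r = _ELEMENT_LJ.get(el, _ELEMENT_LJ["C"])
        eps[i] = e
        rmin[i] = r
    return AtomParams(
        charge=charge, eps=eps, rmin=rmin, gb_radius=gb,
        lcpo_p1=np.ones(n), lcpo_p2=-np.ones(n),
        lcpo_p3=np.zeros(n), lcpo_p4=np.zeros(n),
        lcpo_radius=gb.copy(),
    )


def save_params(structure: Structure, params: AtomParams, path) -> None:
    """Write the whitespace-delimited per-atom parameter table."""
    atoms = structure.atoms
    rows = []
    for i in range(atoms.array_length()):
        rows.append([
            str(atoms.chain_id[i]), int(atoms.res_id[i]), str(atoms.atom_name[i]),
            params.charge[i], params.eps[i], params.rmin[i], params.gb_radius[i],
            params.lcpo_p1[i], params.lcpo_p2[i], params.lcpo_p3[i],
            params.lcpo_p4[i], params.lcpo_radius[i],
        ])
    df = pd.DataFrame(rows, columns=_PARAM_COLUMNS)
    df.to_csv(path, sep=" ", index=False)


def load_params(structure: Structure, path) -> AtomParams:
    """Read a parameter table and align it with the structure's atoms.

    Rows are keyed by (chain, residue number, atom name); every atom of
    the structure must be covered.
    """
    df = pd.read_csv(path, sep=r"\s+")
    missing_cols = set(_PARAM_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"parameter table lacks columns: {sorted(missing_cols)}")
    table = {
        (str(r.chain), int(r.resnum), str(r.atomname)): r
        for r in df.itertuples(index=False)
    }
    atoms = structure.atoms
    cols = {name: [] for name in _PARAM_COLUMNS[3:]}
    for i in range(atoms.array_length()):
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]), str(atoms.atom_name[i]))
        if key not in table:
            raise ValueError(f"no parameters for atom {key}")
        row = table[key]
        for name in cols:
            cols[name].append(float(getattr(row, name)))
    return AtomParams(
        charge=np.array(cols["charge"]), eps=np.array(cols["eps"]),
        rmin=np.array(cols["rmin"]), gb_radius=np.array(cols["gb_radius"]),
        lcpo_p1=np.array(cols["lcpo_p1"]), lcpo_p2=np.array(cols["lcpo_p2"]),
        lcpo_p3=np.array(cols["lcpo_p3"]), lcpo_p4=np.array(cols["lcpo_p4"]),
        lcpo_radius=np.array(cols["lcpo_radius"]),
    )
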
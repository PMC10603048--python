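"""Interface metrics between a receptor and its bound partner.

Four views of partner behaviour on the receptor surface:

* residue-residue contact maps at a distance cutoff (default 5 A),
* the start-vs-end change in Calpha-Calpha separation over a trajectory
  (positive = approaching, negative = separating),
* per-frame Cbeta-Cbeta distance series and their distribution summaries,
* salt-bridge distance series (minimum over carboxylate-O / basic-N pairs)
  and their persistence fraction below a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ComplexDefinition, Structure, Trajectory

__all__ = [
    "ContactMap",
    "SeparationMap",
    "DistanceSeries",
    "DistributionSummary",
    "contact_map",
    "separation_change",
    "cb_distance_series",
    "distribution_summary",
    "salt_bridge_series",
    "persistence",
]

ACIDIC = frozenset({"ASP", "GLU"})
BASIC = frozenset({"LYS", "ARG"})
CARBOXYLATE_O = ("OD1", "OD2", "OE1", "OE2")
BASIC_N = ("NZ", "NH1", "NH2", "NE")

DEFAULT_CONTACT_CUTOFF = 5.0
DEFAULT_SALT_BRIDGE_CUTOFF = 4.0
PERSISTENT_FRACTION = 0.5
DEFAULT_BIN_WIDTH = 0.25


@dataclass
class ContactMap:
    receptor_residues: list[tuple[str, int]]
    partner_residues: list[tuple[str, int]]
    matrix: np.ndarray  # bool, (n_receptor, n_partner)
    min_distances: np.ndarray  # float, same shape
    cutoff: float
    mode: str

    @property
    def n_contacts(self) -> int:
        return int(self.matrix.sum())


@dataclass
class SeparationMap:
    """Delta d = d(first frame) - d(last frame) per Calpha pair.

    Positive entries mean the pair approached over the trajectory,
    negative entries mean separation; swapping the two frames negates the
    map.
    """

    receptor_residues: list[tuple[str, int]]
    partner_residues: list[tuple[str, int]]
    delta: np.ndarray
    first_index: int
    last_index: int


@dataclass
class DistanceSeries:
    residue_a: tuple[str, int]
    residue_b: tuple[str, int]
    atom_type: str  # "CB", "CA-surrogate", or "chargegroup"
    distances: np.ndarray
    surrogate: bool = False

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.size == 0:
            raise ValueError("empty distance series")
        if (self.distances <= 0).any():
            raise ValueError("distances must be positive")

    def __len__(self) -> int:
        return self.distances.size


@dataclass
class DistributionSummary:
    median: float
    iqr: float
    fraction_below: float | None
    bin_edges: np.ndarray
    counts: np.ndarray


def _residue_groups(structure: Structure, mask: np.ndarray, mode: str):
    """Ordered residue keys and their atom index lists under the mask."""
    atoms = structure.atoms
    idx = np.flatnonzero(mask & (atoms.element != "H"))
    if mode == "calpha":
        idx = idx[atoms.atom_name[idx] == "CA"]
    keys, groups = [], {}
    for i in idx:
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]))
        if key not in groups:
            groups[key] = []
            keys.append(key)
        groups[key].append(int(i))
    return keys, groups


def contact_map(
    structure: Structure,
    cdef: ComplexDefinition,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    mode: str = "heavy",
) -> ContactMap:
    """Residue-level contact map: contact iff min inter-residue distance < cutoff.

    ``mode="heavy"`` uses all heavy atoms (the field convention);
    ``mode="calpha"`` restricts to Calpha, appropriate for backbone-only or
    Cbeta-stub models.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if mode not in ("heavy", "calpha"):
        raise ValueError(f"unknown contact mode {mode!r}")
    rec_keys, rec_groups = _residue_groups(structure, cdef.receptor_mask(structure.atoms), mode)
    par_keys, par_groups = _residue_groups(structure, cdef.partner_mask(structure.atoms), mode)
    if not rec_keys or not par_keys:
        raise ValueError("empty receptor or partner selection")
    coord = structure.atoms.coord
    dmin = np.empty((len(rec_keys), len(par_keys)))
    for a, rk in enumerate(rec_keys):
        ra = coord[rec_groups[rk]]
        for b, pk in enumerate(par_keys):
            pb = coord[par_groups[pk]]
            diff = ra[:, None, :] - pb[None, :, :]
            dmin[a, b] = np.sqrt((diff ** 2).sum(axis=2)).min()
    return ContactMap(rec_keys, par_keys, dmin < cutoff, dmin, cutoff, mode)


def _ca_indices(structure: Structure, mask: np.ndarray):
    atoms = structure.atoms
    idx = np.flatnonzero(mask & (atoms.atom_name == "CA") & (~atoms.hetero))
    keys = [(str(atoms.chain_id[i]), int(atoms.res_id[i])) for i in idx]
    return keys, idx


def separation_change(
    trajectory: Trajectory,
    cdef: ComplexDefinition,
    first_index: int = 0,
    last_index: int = -1,
) -> SeparationMap:
    """Two-snapshot Calpha separation change between receptor and partner."""
    n = trajectory.n_frames
    if n < 2:
        raise ValueError("need at least 2 frames")
    first = first_index % n
    last = last_index % n
    if first == last:
        raise ValueError("first and last frame indices coincide")
    top = Structure(trajectory.topology)
    rec_keys, rec_idx = _ca_indices(top, cdef.receptor_mask(trajectory.topology))
    par_keys, par_idx = _ca_indices(top, cdef.partner_mask(trajectory.topology))
    if not rec_keys or not par_keys:
        raise ValueError("empty receptor or partner Calpha selection")

    def dmat(frame):
        diff = trajectory.coords[frame][rec_idx][:, None, :] - \
            trajectory.coords[frame][par_idx][None, :, :]
        return np.sqrt((diff ** 2).sum(axis=2))

    delta = dmat(first) - dmat(last)
    return SeparationMap(rec_keys, par_keys, delta, first, last)


def _beta_carbon_index(topology, chain: str, res_id: int):
    """Index of the residue's CB, falling back to CA (surrogate) for Gly
    or Cbeta-less models."""
    mask = (topology.chain_id == chain) & (topology.res_id == res_id) & (~topology.hetero)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise KeyError(f"residue {chain}/{res_id} not in topology")
    names = topology.atom_name[idx]
    cb = idx[names == "CB"]
    if cb.size:
        return int(cb[0]), False
    ca = idx[names == "CA"]
    if ca.size:
        return int(ca[0]), True
    raise KeyError(f"residue {chain}/{res_id} has neither CB nor CA")


def cb_distance_series(
    trajectory: Trajectory,
    residue_a: tuple[str, int],
    residue_b: tuple[str, int],
) -> DistanceSeries:
    """Per-frame Cbeta-Cbeta distance (Calpha surrogate for glycine)."""
    ia, sur_a = _beta_carbon_index(trajectory.topology, *residue_a)
    ib, sur_b = _beta_carbon_index(trajectory.topology, *residue_b)
    d = np.linalg.norm(trajectory.coords[:, ia, :] - trajectory.coords[:, ib, :], axis=1)
    surrogate = sur_a or sur_b
    return DistanceSeries(
        residue_a, residue_b,
        "CA-surrogate" if surrogate else "CB",
        d, surrogate,
    )


def distribution_summary(
    series: DistanceSeries,
    threshold: float | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> DistributionSummary:
    """Median, IQR, below-threshold fraction and a fixed-grid histogram.

    Bin edges are multiples of ``bin_width`` so histograms of different
    series are directly comparable.
    """
    d = series.distances
    median = float(np.median(d))
    q1, q3 = np.percentile(d, [25, 75])
    frac = None if threshold is None else float((d < threshold).mean())
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    return DistributionSummary(median, float(q3 - q1), frac, edges, counts)


def salt_bridge_series(
    trajectory: Trajectory,
    acidic_residue: tuple[str, int],
    basic_residue: tuple[str, int],
) -> DistanceSeries:
    """Per-frame minimum carboxylate-O to basic-N distance.

    On Cbeta-stub models without charged-group atoms the series falls back
    to Cbeta-Cbeta distances and is flagged as a surrogate.
    """
    top = trajectory.topology

    def residue_atoms(chain, res_id, names):
        mask = (top.chain_id == chain) & (top.res_id == res_id) & (~top.hetero)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise KeyError(f"residue {chain}/{res_id} not in topology")
        resname = str(top.res_name[idx[0]])
        sel = idx[np.isin(top.atom_name[idx], list(names))]
        return resname, sel

    acid_name, acid_idx = residue_atoms(*acidic_residue, CARBOXYLATE_O)
    base_name, base_idx = residue_atoms(*basic_residue, BASIC_N)
    if acid_name not in ACIDIC:
        raise ValueError(f"{acid_name} is not an acidic residue (ASP/GLU)")
    if base_name not in BASIC:
        raise ValueError(f"{base_name} is not a basic residue (LYS/ARG)")
    if acid_idx.size == 0 or base_idx.size == 0:
        cb = cb_distance_series(trajectory, acidic_residue, basic_residue)
        cb.surrogate = True
        return cb
    diff = trajectory.coords[:, acid_idx, None, :] - trajectory.coords[:, None, base_idx, :]
    d = np.sqrt((diff ** 2).sum(axis=3)).min(axis=(1, 2))
    return DistanceSeries(acidic_residue, basic_residue, "chargegroup", d)


def persistence(series: DistanceSeries, cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF):
    """Fraction of frames with distance below the cutoff.

    Returns ``(fraction, persistent)`` where the interaction is labelled
    persistent when at least half of the frames are below the cutoff.
    """
    frac = float((series.distances < cutoff).mean())
    return frac, frac >= PERSISTENT_FRACTION
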
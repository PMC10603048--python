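"""Essential dynamics: superposition, 2D-RMSD maps and coordinate PCA.

PCA runs on the Calpha trace of an ensemble (crystal structures or
trajectory frames).  All members are first superposed — iteratively onto
the ensemble mean, the standard essential-dynamics convention — and the
3N-dimensional mean-centred coordinate covariance is decomposed via SVD of
the centred data matrix.  Eigenvalues use the 1/n normalisation, so
summing eigenvalue-weighted squared loadings over *all* components
reproduces the RMSF about the mean exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import kabsch
from .io import Structure, Trajectory

__all__ = [
    "CommonCore",
    "PCAResult",
    "kabsch_superpose",
    "pairwise_rmsd_matrix",
    "common_core",
    "coordinate_pca",
    "fluctuation_profile",
]

ResidueKey = tuple[str, int, str]  # (chain, author number, insertion code)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Proper-rotation least-squares fit; returns (rotation, translation, rmsd)."""
    return kabsch(mobile, reference)


@dataclass(frozen=True)
class CommonCore:
    """Residues with a Calpha present in every ensemble member."""

    residues: tuple[ResidueKey, ...]

    def __post_init__(self):
        if len(self.residues) == 0:
            raise ValueError("common core is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PCAResult:
    """Coordinate PCA over the Calpha trace of an ensemble.

    loadings have shape (n_components, n_residues, 3); scores have shape
    (n_members, n_components).  Eigenvalues are in A^2, descending.
    """

    mean: np.ndarray
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    residues: tuple[ResidueKey, ...]

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def scores_frame(self) -> pd.DataFrame:
        cols = {f"pc{j + 1}": self.scores[:, j] for j in range(self.n_components)}
        return pd.DataFrame({"member": np.arange(self.scores.shape[0]), **cols})


def _ca_mask(atoms) -> np.ndarray:
    return (atoms.atom_name == "CA") & (atoms.element != "H") & (~atoms.hetero)


def _residue_ca_map(structure: Structure) -> dict[ResidueKey, int]:
    atoms = structure.atoms
    idx = np.flatnonzero(_ca_mask(atoms))
    out: dict[ResidueKey, int] = {}
    for i in idx:
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]), str(atoms.ins_code[i]))
        out.setdefault(key, int(i))
    return out


def common_core(
    structures: list[Structure],
    excluded_ranges: list[tuple[str | None, int, int]] = (),
) -> CommonCore:
    """Intersection of Calpha-bearing residues over >= 2 structures.

    ``excluded_ranges`` entries are (chain, start, end); a ``None`` chain
    applies the range to every chain — used to drop flexible windows such
    as a kinase activation loop that is unmodelled in many members.
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 structures for a common core")
    maps = [_residue_ca_map(s) for s in structures]
    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    for chain, start, end in excluded_ranges:
        common = {
            k for k in common
            if not ((chain is None or k[0] == chain) and start <= k[1] <= end)
        }
    if not common:
        raise ValueError("no residues shared by all structures")
    ordered = tuple(sorted(common))
    return CommonCore(ordered)


def _ensemble_ca_coords(
    ensemble: list[Structure] | Trajectory, core: CommonCore | None
):
    """(n_members, m, 3) Calpha coordinates plus the residue keys used."""
    if isinstance(ensemble, Trajectory):
        top = Structure(ensemble.topology)
        camap = _residue_ca_map(top)
        if core is None:
            keys = tuple(sorted(camap))
        else:
            keys = core.residues
        try:
            idx = np.array([camap[k] for k in keys])
        except KeyError as exc:
            raise ValueError(f"core residue {exc} has no Calpha in topology") from exc
        return ensemble.coords[:, idx, :].copy(), keys
    structures = list(ensemble)
    if core is None:
        core = common_core(structures) if len(structures) > 1 else CommonCore(
            tuple(sorted(_residue_ca_map(structures[0])))
        )
    keys = core.residues
    coords = np.empty((len(structures), len(keys), 3))
    for i, s in enumerate(structures):
        camap = _residue_ca_map(s)
        try:
            idx = [camap[k] for k in keys]
        except KeyError as exc:
            raise ValueError(
                f"structure {i} lacks a Calpha for core residue {exc}"
            ) from exc
        coords[i] = s.atoms.coord[idx]
    return coords, keys


def pairwise_rmsd_matrix(
    trajectory: Trajectory | list[Structure], core: CommonCore | None = None
) -> np.ndarray:
    """Symmetric frame-vs-frame Calpha RMSD matrix after pairwise superposition."""
    coords, _ = _ensemble_ca_coords(trajectory, core)
    n = coords.shape[0]
    if coords.shape[1] == 0:
        raise ValueError("empty Calpha selection")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if np.allclose(coords[i], coords[j]):
                continue
            _, _, rmsd = kabsch(coords[j], coords[i])
            mat[i, j] = mat[j, i] = rmsd
    return mat


def _superpose_ensemble(coords: np.ndarray, reference: int, n_iter: int = 2):
    """Fit all members to the reference, then iteratively to the mean."""
    out = coords.copy()
    ref = out[reference]
    for i in range(out.shape[0]):
        R, t, _ = kabsch(out[i], ref)
        out[i] = out[i] @ R.T + t
    for _ in range(n_iter):
        mean = out.mean(axis=0)
        for i in range(out.shape[0]):
            R, t, _ = kabsch(out[i], mean)
            out[i] = out[i] @ R.T + t
    return out


def coordinate_pca(
    ensemble: list[Structure] | Trajectory,
    core: CommonCore | None = None,
    reference: int = 0,
) -> PCAResult:
    """PCA of the 3N Calpha coordinate vectors of a superposed ensemble."""
    coords, keys = _ensemble_ca_coords(ensemble, core)
    n, m, _ = coords.shape
    if n < 3:
        raise ValueError("need at least 3 ensemble members for PCA")
    coords = _superpose_ensemble(coords, reference)
    X = coords.reshape(n, 3 * m)
    mean = X.mean(axis=0)
    Xc = X - mean
    total = float((Xc ** 2).sum()) / n
    if total < 1e-12:
        raise ValueError("zero variance: all ensemble members are identical")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = S ** 2 / n
    keep = eigvals > 1e-12 * eigvals[0]
    eigvals = eigvals[keep]
    scores = (U * S)[:, keep]
    loadings = Vt[keep].reshape(-1, m, 3)
    fractions = eigvals / eigvals.sum()
    return PCAResult(
        mean=mean,
        eigenvalues=eigvals,
        variance_fractions=fractions,
        scores=scores,
        loadings=loadings,
        residues=keys,
    )


def fluctuation_profile(result: PCAResult, k: int | None = None) -> np.ndarray:
    """Per-residue fluctuation magnitude (A) from the first k components.

    For residue i: sqrt( sum_{j<=k} lambda_j * |loading_j(i)|^2 ).  With
    k equal to the number of components this is exactly the Calpha RMSF
    about the ensemble mean.
    """
    if k is None:
        k = result.n_components
    if not 1 <= k <= result.n_components:
        raise ValueError(f"k={k} out of range 1..{result.n_components}")
    lam = result.eigenvalues[:k, None]
    sq = (result.loadings[:k] ** 2).sum(axis=2)  # (k, m)
    return np.sqrt((lam * sq).sum(axis=0))
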
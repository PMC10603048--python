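"""Partner engagement with named surface tunnels of the receptor.

Tunnel *detection* is outside this package's scope: a tunnel is specified
by its lining residues.  The two AurA kinase-domain surface tunnels that
overlap the partner binding interfaces ship as ready-made definitions
(author numbering): tunnel 1 at the lower central lobe
(E183 I184 H187 L188 K250 V252 H280) and the more confined tunnel 2 at
the N-terminal lobe (K166 L169 L178 V182 V206 L208).

Distances are Cbeta-Cbeta (Calpha surrogate for glycine), matching the
distance-distribution analyses this module feeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interface import _beta_carbon_index
from .io import Selection, Structure, Trajectory

__all__ = [
    "TunnelDefinition",
    "AURA_TUNNELS",
    "parse_tunnel_file",
    "min_distance_to_tunnel",
    "closest_partner_residue",
    "engagement_fraction",
]

DEFAULT_ENGAGEMENT_THRESHOLD = 8.0  # A


@dataclass(frozen=True)
class TunnelDefinition:
    """A named set of receptor residues lining one tunnel."""

    label: str
    residues: tuple[tuple[str, int], ...]  # (three-letter name, author number)
    radius: float | None = None
    length: float | None = None
    curvature: float | None = None

    def __post_init__(self):
        if len(self.residues) == 0:
            raise ValueError("tunnel definition needs at least one residue")

    def resolve(self, topology, chain: str) -> list[int]:
        """Cbeta (or surrogate Calpha) atom indices of the tunnel residues."""
        idx = []
        for name, rid in self.residues:
            mask = (topology.chain_id == chain) & (topology.res_id == rid)
            hits = np.flatnonzero(mask)
            if hits.size == 0:
                raise KeyError(f"tunnel residue {name}{rid} absent from chain {chain}")
            found = str(topology.res_name[hits[0]])
            if found != name:
                raise ValueError(
                    f"tunnel residue {rid} is {found}, expected {name} "
                    f"(check receptor numbering)"
                )
            i, _ = _beta_carbon_index(topology, chain, rid)
            idx.append(i)
        return idx


#: surface tunnels of the AurA kinase domain used for proximity analysis
AURA_TUNNELS = {
    "tunnel1": TunnelDefinition(
        "tunnel1",
        (("GLU", 183), ("ILE", 184), ("HIS", 187), ("LEU", 188),
         ("LYS", 250), ("VAL", 252), ("HIS", 280)),
        radius=2.1, length=1.4, curvature=1.3,
    ),
    "tunnel2": TunnelDefinition(
        "tunnel2",
        (("LYS", 166), ("LEU", 169), ("LEU", 178), ("VAL", 182),
         ("VAL", 206), ("LEU", 208)),
        radius=1.5, length=1.5, curvature=1.0,
    ),
}

_THREE_FROM_ONE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def parse_tunnel_file(path) -> dict[str, TunnelDefinition]:
    """Parse ``label: RES123,RES456,...`` lines into tunnel definitions.

    Residues may be written as three-letter (``GLU183``) or one-letter
    (``E183``) codes.
    """
    out: dict[str, TunnelDefinition] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"line {lineno}: expected 'label: residues'")
            label, _, rest = line.partition(":")
            residues = []
            for token in rest.split(","):
                token = token.strip().upper()
                if len(token) >= 4 and token[:3].isalpha():
                    name, num = token[:3], token[3:]
                elif token and token[0].isalpha():
                    name, num = _THREE_FROM_ONE.get(token[0], ""), token[1:]
                else:
                    raise ValueError(f"line {lineno}: malformed residue {token!r}")
                if not name or not num.lstrip("-").isdigit():
                    raise ValueError(f"line {lineno}: malformed residue {token!r}")
                residues.append((name, int(num)))
            out[label.strip()] = TunnelDefinition(label.strip(), tuple(residues))
    return out


def min_distance_to_tunnel(
    frame: Structure,
    tunnel: TunnelDefinition,
    partner_residue: tuple[str, int],
    receptor_chain: str,
) -> float:
    """Minimum Cbeta-Cbeta distance from a partner residue to the tunnel."""
    idx = tunnel.resolve(frame.atoms, receptor_chain)
    pi, _ = _beta_carbon_index(frame.atoms, *partner_residue)
    tun = frame.atoms.coord[idx]
    p = frame.atoms.coord[pi]
    return float(np.linalg.norm(tun - p, axis=1).min())


def _min_distance_series(
    trajectory: Trajectory,
    tunnel: TunnelDefinition,
    partner_residue: tuple[str, int],
    receptor_chain: str,
) -> np.ndarray:
    idx = tunnel.resolve(trajectory.topology, receptor_chain)
    pi, _ = _beta_carbon_index(trajectory.topology, *partner_residue)
    tun = trajectory.coords[:, idx, :]  # (n, t, 3)
    p = trajectory.coords[:, pi, :]  # (n, 3)
    d = np.linalg.norm(tun - p[:, None, :], axis=2)
    return d.min(axis=1)


def closest_partner_residue(
    trajectory: Trajectory,
    tunnel: TunnelDefinition,
    partner: Selection,
    receptor_chain: str,
) -> tuple[str, int]:
    """Partner residue with the lowest median tunnel min-distance.

    Ties resolve to the lower residue number (then chain identifier).
    """
    top = trajectory.topology
    mask = partner.residue_mask(top) & (~top.hetero)
    keys = []
    for i in np.flatnonzero(mask):
        key = (str(top.chain_id[i]), int(top.res_id[i]))
        if key not in keys:
            keys.append(key)
    if not keys:
        raise ValueError("empty partner selection")
    best_key, best_median = None, np.inf
    for key in sorted(keys, key=lambda k: (k[1], k[0])):
        med = float(np.median(_min_distance_series(trajectory, tunnel, key, receptor_chain)))
        if med < best_median - 1e-12:
            best_key, best_median = key, med
    return best_key


def engagement_fraction(
    trajectory: Trajectory,
    tunnel: TunnelDefinition,
    partner_residue: tuple[str, int],
    receptor_chain: str,
    threshold: float = DEFAULT_ENGAGEMENT_THRESHOLD,
) -> float:
    """Fraction of frames with tunnel min-distance below the threshold."""
    d = _min_distance_series(trajectory, tunnel, partner_residue, receptor_chain)
    return float((d < threshold).mean())
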
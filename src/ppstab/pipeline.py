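"""End-to-end synthetic pipeline: build -> simulate -> analyze -> score.

Chains the package stages in the order a complex-stability study runs
them: construct a two-chain toy complex, generate a bound or dissociating
trajectory, compute interface metrics (contact map, start-vs-end
separation, distance series, salt-bridge persistence) and an MM-GBSA
multi-pose binding score with ligand efficiency.  Driven by a plain-text
INI config; all outputs are deterministic for a fixed config and carry
the config hash and seed.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import gbsa, interface, synthetic, tunnels
from .io import Structure, write_pdb

__all__ = ["ConfigError", "load_config", "run_pipeline"]

logger = logging.getLogger("ppstab")

_AXES = {"x": (1.0, 0.0, 0.0), "y": (0.0, 1.0, 0.0), "z": (0.0, 0.0, 1.0)}

# section -> field -> (type, required, default)
_SCHEMA = {
    "pipeline": {
        "seed": (int, False, 0),
        "label": (str, False, "pipeline"),
    },
    "receptor": {
        "sequence": (str, True, None),
        "conformation": (str, True, None),
    },
    "partner": {
        "sequence": (str, True, None),
        "conformation": (str, True, None),
    },
    "complex": {
        "gap": (float, True, None),
        "axis": (str, False, "x"),
    },
    "trajectory": {
        "kind": (str, True, None),
        "n_frames": (int, True, None),
        "sigma": (float, True, None),
        "drift": (float, False, 0.05),
    },
    "analysis": {
        "contact_cutoff": (float, False, 5.0),
        "contact_mode": (str, False, "calpha"),
        "n_poses": (int, False, 5),
        "salt_bridge_cutoff": (float, False, 4.0),
    },
}


class ConfigError(ValueError):
    """Raised when the pipeline config violates the documented schema."""


def load_config(path) -> dict:
    """Parse and validate the INI config into nested {section: {field: value}}."""
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise ConfigError(f"config file {path} not found or unreadable")
    cfg: dict = {}
    for section, fields in _SCHEMA.items():
        required_section = any(req for _, req, _ in fields.values())
        if section not in parser:
            if required_section:
                raise ConfigError(f"missing required section [{section}]")
            parser[section] = {}
        cfg[section] = {}
        for name, (caster, required, default) in fields.items():
            if name in parser[section]:
                raw = parser[section][name]
                try:
                    cfg[section][name] = caster(raw)
                except ValueError as exc:
                    raise ConfigError(
                        f"field {section}.{name}={raw!r}: {exc}"
                    ) from exc
            elif required:
                raise ConfigError(f"missing required field {section}.{name}")
            else:
                cfg[section][name] = default
    if cfg["trajectory"]["kind"] not in ("bound", "dissociating"):
        raise ConfigError("trajectory.kind must be 'bound' or 'dissociating'")
    if cfg["complex"]["axis"] not in _AXES:
        raise ConfigError("complex.axis must be one of x, y, z")
    for side in ("receptor", "partner"):
        if cfg[side]["conformation"] not in ("extended", "helical"):
            raise ConfigError(f"{side}.conformation must be 'extended' or 'helical'")
    if cfg["analysis"]["contact_mode"] not in ("heavy", "calpha"):
        raise ConfigError("analysis.contact_mode must be 'heavy' or 'calpha'")
    return cfg


def _config_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _stamped_csv(df: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, index=False)


def _stamped_json(payload: dict, path: Path, stamp: str) -> None:
    key, _, seed = stamp.partition(" ")
    payload = {"config_sha256": key.split("=")[1], "seed": int(seed.split("=")[1]),
               **payload}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _charged_pair(structure: Structure, cdef):
    """First acidic/basic residue pair spanning the interface, if any."""
    atoms = structure.atoms

    def residues_of(mask, names):
        out = []
        for i in np.flatnonzero(mask):
            if str(atoms.res_name[i]) in names:
                key = (str(atoms.chain_id[i]), int(atoms.res_id[i]))
                if key not in out:
                    out.append(key)
        return out

    rec, par = cdef.receptor_mask(atoms), cdef.partner_mask(atoms)
    for acid_mask, base_mask in ((rec, par), (par, rec)):
        acids = residues_of(acid_mask, interface.ACIDIC)
        bases = residues_of(base_mask, interface.BASIC)
        if acids and bases:
            return acids[0], bases[0]
    return None


def run_pipeline(config_path, out_dir, seed: int | None = None) -> Path:
    """Run the full synthetic pipeline; returns the report directory."""
    cfg = load_config(config_path)
    if seed is not None:
        cfg["pipeline"]["seed"] = int(seed)
    stamp = f"config_sha256={_config_hash(config_path)} seed={cfg['pipeline']['seed']}"
    out = Path(out_dir)
    for sub in ("structures", "metrics", "scores", "logs"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "logs" / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    if logger.level == logging.NOTSET:
        logger.setLevel(logging.INFO)
    try:
        _run(cfg, out, stamp)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def _run(cfg: dict, out: Path, stamp: str) -> None:
    seed = cfg["pipeline"]["seed"]
    logger.info("run %s label=%s", stamp, cfg["pipeline"]["label"])

    receptor = synthetic.build_toy_peptide(
        cfg["receptor"]["sequence"], cfg["receptor"]["conformation"], chain_id="A"
    )
    partner = synthetic.build_toy_peptide(
        cfg["partner"]["sequence"], cfg["partner"]["conformation"], chain_id="B"
    )
    complex_structure, cdef = synthetic.make_complex(
        receptor, partner, gap=cfg["complex"]["gap"],
        axis=_AXES[cfg["complex"]["axis"]],
    )
    logger.info("complex built: gap=%.2f axis=%s label=%s",
                cfg["complex"]["gap"], cfg["complex"]["axis"], cdef.label)
    write_pdb(complex_structure, out / "structures" / "complex.pdb")

    tcfg = cfg["trajectory"]
    if tcfg["kind"] == "bound":
        traj = synthetic.trajectory_bound(
            complex_structure, tcfg["sigma"], tcfg["n_frames"], seed
        )
    else:
        drift = np.array(_AXES[cfg["complex"]["axis"]]) * tcfg["drift"]
        traj = synthetic.trajectory_dissociating(
            complex_structure, cdef, drift, tcfg["sigma"], tcfg["n_frames"], seed
        )
    logger.info("trajectory: kind=%s n_frames=%d sigma=%.3f seed=%d",
                tcfg["kind"], tcfg["n_frames"], tcfg["sigma"], seed)
    write_pdb(traj, out / "structures" / "trajectory.pdb")

    acfg = cfg["analysis"]
    cmap = interface.contact_map(
        complex_structure, cdef, cutoff=acfg["contact_cutoff"],
        mode=acfg["contact_mode"],
    )
    logger.info("contact map: cutoff=%.2f mode=%s contacts=%d",
                acfg["contact_cutoff"], acfg["contact_mode"], cmap.n_contacts)
    rows = []
    for a, rk in enumerate(cmap.receptor_residues):
        for b, pk in enumerate(cmap.partner_residues):
            rows.append({
                "rec_chain": rk[0], "rec_res": rk[1],
                "par_chain": pk[0], "par_res": pk[1],
                "min_dist": round(float(cmap.min_distances[a, b]), 4),
                "contact": bool(cmap.matrix[a, b]),
            })
    _stamped_csv(pd.DataFrame(rows), out / "metrics" / "contact_map.csv", stamp)

    smap = interface.separation_change(traj, cdef)
    rows = []
    for a, rk in enumerate(smap.receptor_residues):
        for b, pk in enumerate(smap.partner_residues):
            rows.append({
                "rec_chain": rk[0], "rec_res": rk[1],
                "par_chain": pk[0], "par_res": pk[1],
                "delta_d": round(float(smap.delta[a, b]), 4),
            })
    _stamped_csv(pd.DataFrame(rows), out / "metrics" / "separation_map.csv", stamp)

    # distance series for the closest interface residue pair at frame 0
    a, b = np.unravel_index(np.argmin(cmap.min_distances), cmap.min_distances.shape)
    pair = (cmap.receptor_residues[a], cmap.partner_residues[b])
    series = interface.cb_distance_series(traj, *pair)
    logger.info("distance series: pair=%s atom_type=%s", pair, series.atom_type)
    _stamped_csv(
        pd.DataFrame({"frame": np.arange(len(series)),
                      "distance": np.round(series.distances, 4)}),
        out / "metrics" / "distance_series.csv", stamp,
    )
    summary = interface.distribution_summary(series, threshold=acfg["contact_cutoff"])

    metrics_summary = {
        "label": cfg["pipeline"]["label"],
        "closest_pair": [list(pair[0]), list(pair[1])],
        "distance_median": summary.median,
        "distance_iqr": summary.iqr,
        "fraction_below_cutoff": summary.fraction_below,
        "mean_interface_delta_d": float(smap.delta.mean()),
        "n_contacts": cmap.n_contacts,
    }

    charged = _charged_pair(complex_structure, cdef)
    if charged is not None:
        acid, base = charged
        sb = interface.salt_bridge_series(traj, acid, base)
        frac, persistent = interface.persistence(
            sb, cutoff=acfg["salt_bridge_cutoff"]
        )
        logger.info("salt bridge %s-%s: persistence=%.3f cutoff=%.1f surrogate=%s",
                    acid, base, frac, acfg["salt_bridge_cutoff"], sb.surrogate)
        metrics_summary["salt_bridge"] = {
            "acidic": list(acid), "basic": list(base),
            "persistence": frac, "persistent": persistent,
            "surrogate": sb.surrogate,
        }
    _stamped_json(metrics_summary, out / "metrics" / "summary.json", stamp)

    params = gbsa.toy_params(complex_structure)
    score = gbsa.multi_pose_score(
        traj, cdef, params, n_poses=acfg["n_poses"],
        label=cfg["pipeline"]["label"],
    )
    logger.info("gbsa: poses=%s mean=%.2f kJ/mol sd=%.2f LE=%.2f",
                score.pose_indices, score.mean_kj, score.sd_kj,
                score.ligand_efficiency)
    _stamped_json(score.as_dict(), out / "scores" / "binding_score.json", stamp)
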
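"""File formats: Cα-PDB structures with JSON tag sidecars, XYZ trajectories
with JSON metadata sidecars, CSV/GraphML analysis exports.

Conventions:
- ``model.pdb``: one CA atom per residue; chain A = bundle 1, chain B =
  bundle 2, chain C = loop particles; the ion is a HETATM (NA) on chain X.
  MODEL 1 holds the OF reference, MODEL 2 the IF reference.
- ``model.json`` sidecar: role tags, helix/bundle map, rocking axis/angle,
  full-precision coordinates (PDB fields round to 3 decimals; the sidecar is
  authoritative for lossless round-trips).
- trajectories: plain multi-frame ``.xyz`` (written/read through MDAnalysis)
  plus a ``.json`` sidecar carrying dt, stride, seed, provenance.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np

from .dynamics import Trajectory
from .model import ReferencePair, ToyStructure

__all__ = [
    "write_structure",
    "read_structure",
    "write_trajectory",
    "read_trajectory",
    "write_network",
    "SidecarError",
]


class SidecarError(ValueError):
    """Structure/trajectory sidecar missing or inconsistent with the data file."""


def _chain_for(bundle: int) -> str:
    return {1: "A", 2: "B", 0: "C"}[int(bundle)]


def _pdb_atom_line(serial, name, resname, chain, resseq, pos, hetatm=False) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    return (
        f"{record}{serial:>5d}  {name:<3s}{resname:>4s} {chain}{resseq:>4d}    "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {name[:2]:>2s}\n"
    )


def write_structure(structure: ToyStructure, refs: ReferencePair, path) -> None:
    """Write ``model.pdb`` (MODEL 1 = OF, MODEL 2 = IF) and ``model.json``
    into directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "model.pdb", "w") as fh:
        for model_no, coords in ((1, refs.of_coords), (2, refs.if_coords)):
            fh.write(f"MODEL     {model_no:>4d}\n")
            serial = 0
            for i in range(structure.n_atoms):
                serial += 1
                fh.write(
                    _pdb_atom_line(
                        serial, "CA", "ALA", _chain_for(structure.bundle_id[i]),
                        int(structure.residue_id[i]), coords[i],
                    )
                )
            if structure.ion_present and model_no == 1:
                serial += 1
                fh.write(
                    _pdb_atom_line(
                        serial, "NA", "NA", "X", 1, structure.ion_position, hetatm=True
                    )
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
    sidecar = {
        "n_atoms": structure.n_atoms,
        "residue_id": structure.residue_id.tolist(),
        "helix_id": structure.helix_id.tolist(),
        "bundle_id": structure.bundle_id.tolist(),
        "role": structure.role.tolist(),
        "helix_bundle": {str(k): int(v) for k, v in structure.helix_bundle.items()},
        "ion_present": bool(structure.ion_present),
        "ion_position": (
            structure.ion_position.tolist() if structure.ion_position is not None else None
        ),
        "site_radius": structure.site_radius,
        "rocking_axis": refs.rocking_axis.tolist(),
        "rocking_angle_deg": refs.rocking_angle_deg,
        "rocking_center": refs.rocking_center.tolist(),
        "of_coords": refs.of_coords.tolist(),
        "if_coords": refs.if_coords.tolist(),
    }
    with open(path / "model.json", "w") as fh:
        json.dump(sidecar, fh)


def _parse_pdb_ca(path: Path):
    """Cα records per MODEL: list of (chain, resseq, xyz); plus ion position."""
    models: list[list[tuple[str, int, np.ndarray]]] = []
    ion = None
    current: Optional[list] = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    models.append(current)
                current = None
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    chain = line[21]
                    resseq = int(line[22:26])
                    xyz = np.array(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    )
                except (ValueError, IndexError) as exc:
                    raise SidecarError(
                        f"malformed PDB record at line {ln}: {line.rstrip()!r}"
                    ) from exc
                if rec == "HETATM" or chain == "X":
                    ion = xyz
                elif current is not None:
                    current.append((chain, resseq, xyz))
                else:
                    raise SidecarError(
                        f"ATOM record outside MODEL block at line {ln}"
                    )
    if not models:
        raise SidecarError(f"no MODEL blocks found in {path}")
    return models, ion


def read_structure(path) -> tuple[ToyStructure, ReferencePair]:
    """Read the ``model.pdb`` / ``model.json`` pair written by
    :func:`write_structure`; round-trips are lossless for labels and
    coordinates (sidecar precision)."""
    path = Path(path)
    pdb_path = path / "model.pdb"
    sidecar_path = path / "model.json"
    if not pdb_path.exists():
        raise SidecarError(f"missing structure file {pdb_path}")
    if not sidecar_path.exists():
        raise SidecarError(f"missing tag sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        sc = json.load(fh)
    models, ion = _parse_pdb_ca(pdb_path)
    if len(models) != 2:
        raise SidecarError(f"expected 2 MODEL blocks (OF, IF), found {len(models)}")
    n = sc["n_atoms"]
    for m_idx, model in enumerate(models):
        if len(model) != n:
            raise SidecarError(
                f"MODEL {m_idx + 1} has {len(model)} CA atoms, sidecar says {n}"
            )
    # verify PDB vs sidecar consistency (PDB coordinates are 3-decimal)
    of_sc = np.asarray(sc["of_coords"], dtype=float)
    if_sc = np.asarray(sc["if_coords"], dtype=float)
    for model, ref, label in ((models[0], of_sc, "OF"), (models[1], if_sc, "IF")):
        got = np.array([xyz for _, _, xyz in model])
        if not np.allclose(got, ref, atol=2e-3):
            bad = int(np.abs(got - ref).max(axis=1).argmax())
            raise SidecarError(
                f"{label} coordinates disagree between PDB and sidecar at atom {bad}"
            )
        for i, (chain, _, _) in enumerate(model):
            if chain != _chain_for(sc["bundle_id"][i]):
                raise SidecarError(
                    f"chain/bundle mismatch at atom {i}: chain {chain!r} vs "
                    f"bundle {sc['bundle_id'][i]}"
                )
    structure = ToyStructure(
        residue_id=np.asarray(sc["residue_id"], dtype=int),
        helix_id=np.asarray(sc["helix_id"], dtype=int),
        bundle_id=np.asarray(sc["bundle_id"], dtype=int),
        role=np.asarray(sc["role"], dtype="U16"),
        coords=of_sc.copy(),
        helix_bundle={int(k): int(v) for k, v in sc["helix_bundle"].items()},
        ion_present=bool(sc["ion_present"]),
        ion_position=(
            np.asarray(sc["ion_position"], dtype=float)
            if sc["ion_position"] is not None
            else None
        ),
        site_radius=float(sc.get("site_radius", 3.0)),
    )
    refs = ReferencePair(
        of_coords=of_sc,
        if_coords=if_sc,
        rocking_axis=np.asarray(sc["rocking_axis"], dtype=float),
        rocking_angle_deg=float(sc["rocking_angle_deg"]),
        rocking_center=np.asarray(sc["rocking_center"], dtype=float),
    )
    return structure, refs


def write_trajectory(traj: Trajectory, path) -> None:
    """Multi-frame XYZ plus JSON sidecar; ``path`` is the ``.xyz`` filename."""
    import MDAnalysis as mda

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = traj.frames.shape[1]
    u = mda.Universe.empty(n, trajectory=True)
    names = ["CA"] * (n - 1) + ["NA"] if traj.ion_present else ["CA"] * n
    u.add_TopologyAttr("names", names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n) as w:
            for frame in traj.frames:
                u.atoms.positions = frame
                w.write(u.atoms)
    sidecar = {
        "dt": traj.dt,
        "stride": traj.stride,
        "seed": traj.seed,
        "ion_present": traj.ion_present,
        "n_frames": traj.n_frames,
        "provenance": traj.provenance,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh)


def read_trajectory(path) -> Trajectory:
    """Read an XYZ/JSON trajectory pair written by :func:`write_trajectory`."""
    import MDAnalysis as mda

    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not path.exists():
        raise SidecarError(f"missing trajectory file {path}")
    if not sidecar_path.exists():
        raise SidecarError(f"missing trajectory sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        sc = json.load(fh)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    if frames.shape[0] != sc["n_frames"]:
        raise SidecarError(
            f"sidecar says {sc['n_frames']} frames, file has {frames.shape[0]}"
        )
    return Trajectory(
        frames=frames,
        dt=float(sc["dt"]),
        stride=int(sc["stride"]),
        seed=int(sc["seed"]),
        ion_present=bool(sc["ion_present"]),
        provenance=dict(sc.get("provenance", {})),
    )


def write_network(net, path_prefix) -> None:
    """Edge-list CSV (i, j, C_ij, w_ij) and GraphML export of a
    :class:`~rockbundle.analysis.CorrelationNetwork`."""
    import networkx as nx
    import pandas as pd

    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    rows = net.edge_table()
    pd.DataFrame(rows, columns=["i", "j", "correlation", "weight"]).to_csv(
        prefix.with_suffix(".csv"), index=False
    )
    nx.write_graphml(net.graph, prefix.with_suffix(".graphml"))
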
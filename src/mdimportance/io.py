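"""Readers and writers: trajectories, label tables, feature matrices,
importance profiles, and structure projection.

Real trajectories come in as standard MD formats through MDTraj (PDB/GRO
topology + XTC/DCD/multi-model PDB coordinates); labels as a CSV table
``frame,state`` with 0-based frame indices in trajectory order.  Feature
matrices round-trip through CSV (descriptor header) or .npy plus a JSON
descriptor sidecar.  Per-residue importance can be projected onto a
structure by writing it into the PDB B-factor column.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import mdtraj as md
import numpy as np
import pandas as pd

from .extractors import ImportanceProfile
from .featurization import FeatureMatrix, LabelSet
from .toy_model import ToyTrajectory

__all__ = [
    "load_trajectory",
    "trajectory_residue_features",
    "read_labels_csv",
    "write_labels_csv",
    "read_matrix",
    "write_matrix",
    "write_profile",
    "toy_trajectory_to_mdtraj",
    "write_toy_trajectory",
    "project_importance_to_structure",
    "write_manifest",
]


def load_trajectory(trajectory: str, topology: str | None = None) -> md.Trajectory:
    """Load coordinates with MDTraj; ``topology`` is required for formats
    that do not embed one (XTC/DCD)."""
    if topology is not None:
        return md.load(trajectory, top=topology)
    return md.load(trajectory)


def trajectory_residue_features(
    traj: md.Trajectory, scheme: str = "ca", mode: str = "full"
) -> FeatureMatrix:
    """Per-residue-pair distances (nm) from a real trajectory.

    ``scheme='ca'`` uses Calpha-Calpha distances; ``scheme='closest-heavy'``
    the minimum heavy-atom distance per residue pair.  ``mode`` selects all
    pairs or the sequential i..i+4 reduced set.  Descriptors are 0-based
    residue indices; raw distances are returned so the contact filters can
    be applied before inversion.
    """
    n_res = traj.topology.n_residues
    if mode == "full":
        pairs = [(i, j) for i in range(n_res) for j in range(i + 1, n_res)]
    elif mode == "reduced":
        pairs = [(i, i + k) for i in range(n_res) for k in range(1, 5) if i + k < n_res]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    distances, kept = md.compute_contacts(traj, contacts=pairs, scheme=scheme)
    descriptors = [(int(i), int(j)) for i, j in kept]
    return FeatureMatrix(np.asarray(distances, dtype=float), descriptors, f"distance_{mode}")


def read_labels_csv(path: str) -> LabelSet:
    table = pd.read_csv(path)
    table = table.sort_values("frame")
    if not np.array_equal(table["frame"].to_numpy(), np.arange(len(table))):
        raise ValueError("labels CSV must cover frames 0..n-1 exactly once")
    return LabelSet(table["state"].to_numpy())


def write_labels_csv(labels: LabelSet, path: str) -> None:
    pd.DataFrame(
        {"frame": np.arange(len(labels.state_index)), "state": labels.state_index}
    ).to_csv(path, index=False)


def _descriptor_str(d: tuple) -> str:
    return f"{d[0]}.{d[1]}" if isinstance(d[1], str) else f"{d[0]}-{d[1]}"


def _parse_descriptor(s: str) -> tuple:
    if "." in s:
        a, ax = s.split(".")
        return (int(a), ax)
    i, j = s.split("-")
    return (int(i), int(j))


def write_matrix(fm: FeatureMatrix, path: str) -> None:
    """CSV with a descriptor header, or .npy + JSON descriptor sidecar."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, fm.values)
        sidecar = {"kind": fm.kind, "descriptors": [list(d) for d in fm.descriptors]}
        path.with_suffix(".json").write_text(json.dumps(sidecar))
    else:
        pd.DataFrame(fm.values, columns=[_descriptor_str(d) for d in fm.descriptors]).to_csv(
            path, index=False
        )


def read_matrix(path: str, kind: str = "cartesian") -> FeatureMatrix:
    path = Path(path)
    if path.suffix == ".npy":
        values = np.load(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        descriptors = [tuple(d) for d in sidecar["descriptors"]]
        return FeatureMatrix(values, descriptors, sidecar["kind"])
    table = pd.read_csv(path)
    descriptors = [_parse_descriptor(c) for c in table.columns]
    return FeatureMatrix(table.to_numpy(dtype=float), descriptors, kind)


def write_profile(profile: ImportanceProfile, csv_path: str, meta_path: str | None = None) -> None:
    """Profile as long CSV (descriptor index, state, importance, std) plus
    a JSON run-metadata sidecar."""
    rows = []
    for i, v in enumerate(profile.per_feature):
        rows.append(
            {"feature": i, "state": "ensemble", "importance": v,
             "std": profile.std[i] if profile.std is not None else np.nan}
        )
    if profile.per_state is not None:
        for s, row in enumerate(profile.per_state):
            for i, v in enumerate(row):
                rows.append({"feature": i, "state": s, "importance": v, "std": np.nan})
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if meta_path is not None:
        meta = {
            "method": profile.method,
            "hyperparameters": {k: _jsonable(v) for k, v in profile.hyperparameters.items()},
            "n_iterations": profile.n_iterations,
            "model_score": profile.model_score,
            "all_zero": profile.all_zero,
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2))


def _jsonable(v):
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    if isinstance(v, (tuple, list)):
        return [_jsonable(x) for x in v]
    return v


def toy_trajectory_to_mdtraj(traj: ToyTrajectory) -> md.Trajectory:
    """Toy atoms as CA beads of consecutive ALA residues on one chain."""
    top = md.Topology()
    chain = top.add_chain()
    for i in range(traj.coords.shape[1]):
        res = top.add_residue("ALA", chain, resSeq=i + 1)
        top.add_atom("CA", md.element.carbon, res)
    return md.Trajectory(traj.coords.copy(), top)


def write_toy_trajectory(traj: ToyTrajectory, pdb_path: str, labels_path: str) -> None:
    """Multi-model PDB (one MODEL per frame) + labels CSV."""
    toy_trajectory_to_mdtraj(traj).save_pdb(pdb_path)
    write_labels_csv(LabelSet(traj.labels), labels_path)


def project_importance_to_structure(
    per_residue: np.ndarray, topology: str, out_pdb: str
) -> None:
    """Write per-residue importance into the B-factor column.

    Every atom of a residue carries importance x 100 (importance lives in
    [0, 1]; the PDB field has two decimals), clamped to [0, 99.99].
    Coordinates are untouched.
    """
    struct = load_trajectory(topology)[0]
    per_residue = np.asarray(per_residue, dtype=float)
    if len(per_residue) != struct.topology.n_residues:
        raise ValueError(
            f"profile has {len(per_residue)} residues but topology has "
            f"{struct.topology.n_residues}"
        )
    bfactors = np.array(
        [np.clip(per_residue[a.residue.index] * 100.0, 0.0, 99.99) for a in struct.topology.atoms]
    )
    struct.save_pdb(out_pdb, bfactors=bfactors)


def read_bfactor_profile(pdb_path: str) -> np.ndarray:
    """Recover a per-residue profile written by
    :func:`project_importance_to_structure` (first atom per residue)."""
    values: dict[int, float] = {}
    order: list[int] = []
    with open(pdb_path) as fh:
        for line in fh:
            if line.startswith(("ATOM", "HETATM")):
                resseq = int(line[22:26])
                if resseq not in values:
                    values[resseq] = float(line[60:66])
                    order.append(resseq)
            elif line.startswith("ENDMDL"):
                break
    return np.array([values[r] for r in order]) / 100.0


def write_manifest(path: str, config: dict, seeds: dict, inputs: list[str]) -> None:
    """Reproducibility manifest: config, seeds, library versions, input
    checksums."""
    import sklearn

    checksums = {}
    for p in inputs:
        p = Path(p)
        if p.exists():
            checksums[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    doc = {
        "config": config,
        "seeds": seeds,
        "inputs_sha256": checksums,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "mdtraj": getattr(md, "__version__", "unknown"),
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=_jsonable))
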
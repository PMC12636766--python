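"""Snapshot and trace persistence: HDF5 arrays with a JSON metadata sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .network import NetworkSpec
from .simulation import SnapshotSet

__all__ = ["save_snapshots", "load_snapshots", "encode_snapshot"]

#: Inclusion sites are encoded as ``INCLUSION_CODE_BASE + type_index`` in the
#: exported spin grid (lipid sites keep their +-1 spin).
INCLUSION_CODE_BASE = 10


def encode_snapshot(sval: np.ndarray, occ: np.ndarray, inc_type: np.ndarray):
    """Single int8 grid: lipid spins +-1, sentinel codes on inclusion sites."""
    coded = sval.astype(np.int16).copy()
    covered = occ >= 0
    if covered.any():
        coded[covered] = INCLUSION_CODE_BASE + inc_type[occ[covered]]
    return coded


def save_snapshots(path: str | Path, snapshots: SnapshotSet, meta: dict | None = None):
    """Write snapshots to HDF5 plus a ``<path>.json`` metadata sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("sweeps", data=snapshots.sweeps)
        fh.create_dataset("sval", data=snapshots.sval, compression="gzip")
        fh.create_dataset("occ", data=snapshots.occ, compression="gzip")
        fh.create_dataset("inc_state", data=snapshots.inc_state)
        fh.create_dataset("inc_type", data=snapshots.inc_type)
        coded = np.stack(
            [
                encode_snapshot(snapshots.sval[i], snapshots.occ[i], snapshots.inc_type)
                for i in range(len(snapshots))
            ]
        ) if len(snapshots) else np.zeros((0,) + snapshots.sval.shape[1:], np.int16)
        fh.create_dataset("coded", data=coded, compression="gzip")
    sidecar = {"network": snapshots.network.to_dict()}
    if meta:
        sidecar.update(meta)
    Path(f"{path}.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_snapshots(path: str | Path) -> tuple[SnapshotSet, dict]:
    path = Path(path)
    meta = json.loads(Path(f"{path}.json").read_text())
    network = NetworkSpec.from_dict(meta["network"])
    with h5py.File(path, "r") as fh:
        snaps = SnapshotSet(
            sweeps=fh["sweeps"][...],
            sval=fh["sval"][...],
            occ=fh["occ"][...],
            inc_state=fh["inc_state"][...],
            inc_type=fh["inc_type"][...],
            network=network,
        )
    return snaps, meta
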
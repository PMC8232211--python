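"""Trajectory archives and tabular exports.

A trajectory archive is a single HDF5 file holding the time grid, the full
variational parameters (alpha, lam), conservation diagnostics and the
resolved configuration used for the run, under a versioned schema, so any
observable can be recomputed offline.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .davydov import Trajectory

SCHEMA_VERSION = "1.0"

__all__ = ["save_trajectory", "load_trajectory", "export_ring_populations_tsv"]


def save_trajectory(traj: Trajectory, path, extra_config: dict | None = None) -> None:
    cfg = dict(traj.config)
    if extra_config:
        cfg.update(extra_config)
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["config_json"] = json.dumps(cfg, default=str)
        fh.create_dataset("times", data=traj.times)
        fh.create_dataset("alpha", data=traj.alpha, compression="gzip", shuffle=True)
        fh.create_dataset("lam", data=traj.lam, compression="gzip", shuffle=True)
        fh.create_dataset("norms", data=traj.norms)
        fh.create_dataset("energies", data=traj.energies)
        fh.create_dataset("energy_imag", data=traj.energy_imag)


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as fh:
        version = fh.attrs.get("schema_version", "0.0")
        major = int(str(version).split(".")[0])
        if major > int(SCHEMA_VERSION.split(".")[0]):
            raise ValueError(
                f"archive schema {version} is newer than supported {SCHEMA_VERSION}"
            )
        return Trajectory(
            times=fh["times"][...],
            alpha=fh["alpha"][...],
            lam=fh["lam"][...],
            norms=fh["norms"][...],
            energies=fh["energies"][...],
            energy_imag=fh["energy_imag"][...],
            config=json.loads(fh.attrs.get("config_json", "{}")),
        )


def export_ring_populations_tsv(traj: Trajectory, path) -> None:
    """Per-ring population time series as TSV (time_fs, ring_0, ...)."""
    pops = np.sum(np.abs(traj.alpha) ** 2, axis=2)
    nr = pops.shape[1]
    header = "time_fs\t" + "\t".join(f"ring_{r}" for r in range(nr))
    data = np.column_stack([traj.times, pops])
    np.savetxt(path, data, delimiter="\t", header=header, comments="")
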
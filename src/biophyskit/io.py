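"""Plain-text input/output for every analysis.

File conventions:

* sensorgrams — CSV with columns ``time_s,response_RU``, one file per
  concentration, tied together by a JSON manifest mapping file name to
  molar concentration and recording the phase boundaries;
* peak lists and calibration standards — two-column CSV;
* toy/synthetic structures — PDB ``ATOM`` records (written here; real
  structures are read with Bio.PDB via
  :meth:`~biophyskit.hydrodynamics.StructureModel.from_pdb`);
* ground-truth sidecars — JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PreconditionError
from .hydrodynamics import StructureModel
from .ms_utils import PeakList
from .spr_kinetics import InjectionProtocol, Sensorgram

__all__ = [
    "write_sensorgram",
    "read_sensorgram",
    "write_sensorgram_series",
    "read_sensorgram_series",
    "write_peaks",
    "read_peaks",
    "write_table",
    "read_table",
    "write_sidecar",
    "read_sidecar",
    "write_structure_pdb",
]


def write_sensorgram(sensorgram: Sensorgram, path) -> None:
    pd.DataFrame({"time_s": sensorgram.time,
                  "response_RU": sensorgram.response}).to_csv(path, index=False)


def read_sensorgram(path, protocol: InjectionProtocol) -> Sensorgram:
    df = pd.read_csv(path)
    if not {"time_s", "response_RU"} <= set(df.columns):
        raise PreconditionError(f"{path}: expected columns time_s,response_RU")
    return Sensorgram(time=df["time_s"].to_numpy(),
                      response=df["response_RU"].to_numpy(), protocol=protocol)


def write_sensorgram_series(sensorgrams, directory, prefix: str = "sensorgram") -> Path:
    """Write one CSV per curve plus a JSON manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(sensorgrams):
        name = f"{prefix}_{i:02d}.csv"
        write_sensorgram(s, directory / name)
        entries.append({
            "file": name,
            "concentration_molar": s.protocol.analyte_concentration,
            "t_association_s": s.protocol.t_association,
            "t_dissociation_s": s.protocol.t_dissociation,
            "sampling_interval_s": s.protocol.sampling_interval,
        })
    manifest = directory / f"{prefix}_manifest.json"
    manifest.write_text(json.dumps({"curves": entries}, indent=1))
    return manifest


def read_sensorgram_series(manifest_path) -> list:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    out = []
    for entry in manifest["curves"]:
        protocol = InjectionProtocol(
            analyte_concentration=entry["concentration_molar"],
            t_association=entry["t_association_s"],
            t_dissociation=entry["t_dissociation_s"],
            sampling_interval=entry["sampling_interval_s"],
        )
        out.append(read_sensorgram(manifest_path.parent / entry["file"], protocol))
    return out


def write_peaks(peaks: PeakList, path) -> None:
    pd.DataFrame({"mz": peaks.mz, "intensity": peaks.intensity}).to_csv(path, index=False)


def read_peaks(path) -> PeakList:
    df = pd.read_csv(path)
    return PeakList(mz=df["mz"].to_numpy(), intensity=df["intensity"].to_numpy())


def write_table(rows, path, columns) -> None:
    """Generic two-or-more column CSV (SEC standards, isotherms, ...)."""
    pd.DataFrame(np.asarray(list(rows), dtype=float), columns=list(columns)).to_csv(
        path, index=False)


def read_table(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=float)


def write_sidecar(ground_truth: dict, path) -> None:
    Path(path).write_text(json.dumps(ground_truth, indent=1, default=float))


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())


def write_structure_pdb(structure: StructureModel, path) -> None:
    """Write ATOM records for a (possibly synthetic) structure.

    Coordinates are truncated to PDB's fixed 8.3 columns, so round-trips
    are exact only to 1e-3 angstrom.
    """
    lines = []
    for i in range(len(structure)):
        x, y, z = structure.coords[i]
        elem = str(structure.elements[i])[:2].rjust(2)
        name = str(structure.elements[i])[:4]
        lines.append(
            f"ATOM  {(i + 1) % 100000:5d} {name:<4s} {str(structure.residue_names[i])[:3]:>3s} A"
            f"{int(structure.residue_indices[i]) % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {elem}\n"
        )
    lines.append("END\n")
    Path(path).write_text("".join(lines))
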
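"""CSV/JSON file formats and run manifests.

Formats are deliberately plain: comma-separated UTF-8 with a mandatory
header row, units encoded in the column names, '.' decimal; metadata that
does not fit a rectangular table (temperature, concentration ratio, ground
truth) travels in a JSON sidecar next to the CSV.
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .exchange_kinetics import KineticsDataset
from .thermo_analysis import RateTable

__all__ = [
    "read_kinetics_csv",
    "write_kinetics_csv",
    "read_rate_table_csv",
    "write_rate_table_csv",
    "write_map_csv",
    "sidecar_path",
    "write_manifest",
]

KINETICS_COLUMNS = ("tau_e_s", "M_e", "M_f")
RATE_COLUMNS = ("temperature_K", "kd_per_s", "sigma_kd")


def sidecar_path(path: "str | Path") -> Path:
    return Path(str(path) + ".meta.json")


def read_kinetics_csv(path: "str | Path") -> KineticsDataset:
    """Read a kinetics table (tau_e_s, M_e, M_f[, sigma_e, sigma_f]).

    A ``<path>.meta.json`` sidecar, if present, supplies ``temperature_K``
    and the concentration ratio ``ratio``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in KINETICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df[list(KINETICS_COLUMNS)].isna().any().any():
        raise ValueError(f"{path}: NaN amplitudes or mixing times")
    tau = df["tau_e_s"].to_numpy()
    if np.any(np.diff(tau) <= 0):
        raise ValueError(f"{path}: non-monotone mixing times")
    meta = {}
    side = sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
    return KineticsDataset(
        tau, df["M_e"].to_numpy(), df["M_f"].to_numpy(),
        df["sigma_e"].to_numpy() if "sigma_e" in df.columns else None,
        df["sigma_f"].to_numpy() if "sigma_f" in df.columns else None,
        temperature=meta.get("temperature_K"),
        ratio=meta.get("ratio"))


def write_kinetics_csv(dataset: KineticsDataset, path: "str | Path",
                       extra_meta: dict | None = None) -> Path:
    path = Path(path)
    cols = {"tau_e_s": dataset.tau_e, "M_e": dataset.M_e, "M_f": dataset.M_f}
    if dataset.sigma_e is not None:
        cols["sigma_e"] = dataset.sigma_e
    if dataset.sigma_f is not None:
        cols["sigma_f"] = dataset.sigma_f
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {"temperature_K": dataset.temperature, "ratio": dataset.ratio}
    if extra_meta:
        meta.update(extra_meta)
    sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_rate_table_csv(path: "str | Path") -> RateTable:
    df = pd.read_csv(path)
    missing = [c for c in RATE_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return RateTable(
        df["temperature_K"].to_numpy(), df["kd_per_s"].to_numpy(),
        df["sigma_kd"].to_numpy() if "sigma_kd" in df.columns else None,
        list(df["model"]) if "model" in df.columns else None)


def write_rate_table_csv(table: RateTable, path: "str | Path") -> Path:
    path = Path(path)
    cols = {"temperature_K": table.temperature, "kd_per_s": table.k_d}
    if table.sigma is not None:
        cols["sigma_kd"] = table.sigma
    if table.model is not None:
        cols["model"] = list(table.model)
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


def write_map_csv(pmap, path: "str | Path") -> Path:
    """Polarization map as long-format CSV (tau1_s, tau2_s, polarization)."""
    path = Path(path)
    pmap.to_frame().to_csv(path, index=False)
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: "str | Path", command: str, params: dict,
                   inputs: list | None = None, outputs: list | None = None,
                   seed: int | None = None) -> Path:
    """Record everything needed to reproduce a run.

    The manifest lists the command, its resolved parameters, SHA-256
    checksums of input/output files, the seed, the package version and the
    design conventions in effect (phase set, ratio orientation, kappa).
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "parameters": {k: _jsonable(v) for k, v in params.items()},
        "seed": seed,
        "inputs": {str(p): _sha256(Path(p)) for p in (inputs or [])
                   if Path(p).exists()},
        "outputs": {str(p): _sha256(Path(p)) for p in (outputs or [])
                    if Path(p).exists()},
        "package_version": __version__,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "conventions": {
            "ratio_orientation": "bound_to_free ([CsS2]/[S]) in k_d = "
                                 "k/(0.5 + r)",
            "per_ligand_rate": "k_d/2",
            "transmission_coefficient": 1.0,
            "polarization": "magnitude of 2|<I+>| (sign convention-free)",
            "pulse_rotation": "exp(-i*theta*F_phi); +90x takes Iz to -Iy",
        },
    }
    path = out_dir / f"manifest_{command.replace(' ', '_')}.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, Path):
        return str(v)
    return v
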